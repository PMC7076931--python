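"""Reading, writing and reshaping OTU count tables and sample/environment metadata.

On-disk OTU tables use the QIIME-classic TSV dialect (rows = OTUs, columns =
samples, first header cell ``#OTU ID``, optional trailing ``taxonomy``
column).  In memory the orientation is samples x OTUs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("archaea", "bacteria", "eukarya")
REQUIRED_METADATA = ("site", "region", "domain")

#: canonical names for environmental covariates whose spelling varies between
#: sources; lookups are case-insensitive.
ENV_ALIASES = {
    "no2": "no2_no3",
    "no3": "no2_no3",
    "no2/no3": "no2_no3",
    "no2_no3": "no2_no3",
    "cond": "conductivity",
    "grvl": "gravel",
    "al2o3": "al2o3",
    "tio2": "tio2",
}


class TableParseError(ValueError):
    """Raised when an on-disk table violates the expected dialect."""


@dataclass
class OTUTable:
    """Integer count matrix (samples x OTUs) with per-sample metadata.

    Parameters
    ----------
    counts:
        Non-negative integer DataFrame, index = sample ids, columns = OTU ids.
    metadata:
        Optional DataFrame indexed by sample id with at least the columns
        ``site``, ``region`` and ``domain``.  Operations that group by
        metadata raise if it is absent.
    taxonomy:
        Optional opaque annotation string per OTU id.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].tolist()
            raise TableParseError(f"duplicate sample ids: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].tolist()
            raise TableParseError(f"duplicate OTU ids: {dups}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                i, j = np.argwhere(~(np.isfinite(values) & (values == np.floor(values))))[0]
                raise TableParseError(
                    f"non-integer count {values[i, j]!r} for OTU "
                    f"{c.columns[j]!r}, sample {c.index[i]!r}"
                )
            self.counts = c = c.astype(np.int64)
            values = c.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableParseError(
                f"negative count {values[i, j]} for OTU {c.columns[j]!r}, "
                f"sample {c.index[i]!r}"
            )
        if self.metadata is not None:
            self._validate_metadata(self.metadata)

    def _validate_metadata(self, meta: pd.DataFrame) -> None:
        missing = [m for m in REQUIRED_METADATA if m not in meta.columns]
        if missing:
            raise TableParseError(f"metadata missing required columns: {missing}")
        absent = [s for s in self.counts.index if s not in meta.index]
        if absent:
            raise TableParseError(f"samples without metadata: {absent[:5]}")
        bad = set(meta.loc[self.counts.index, "domain"]) - set(DOMAINS)
        if bad:
            raise TableParseError(f"unknown domain labels: {sorted(bad)}")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def with_metadata(self, metadata: pd.DataFrame) -> "OTUTable":
        self._validate_metadata(metadata)
        return OTUTable(self.counts, metadata, self.taxonomy)

    def subset_samples(self, sample_ids) -> "OTUTable":
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return OTUTable(self.counts.loc[sample_ids], meta, self.taxonomy)

    def require_metadata(self) -> pd.DataFrame:
        if self.metadata is None:
            raise ValueError("this operation requires sample metadata (site/region/domain)")
        return self.metadata.loc[self.counts.index]


@dataclass
class EnvTable:
    """Numeric environmental covariates keyed by sample id.

    Missing values stay as NaN; ``units`` documents measurement units per
    column when known.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise TableParseError("duplicate sample ids in environment table")
        non_numeric = [c for c in self.data.columns
                       if not np.issubdtype(self.data[c].dtype, np.number)]
        if non_numeric:
            raise TableParseError(f"non-numeric environment columns: {non_numeric}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AbundanceVector:
    """Pooled per-OTU counts (all >= 1) for one group (site or region)."""

    label: str
    counts: np.ndarray
    otu_ids: list[str] | None = None
    domain: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("abundances must be one-dimensional")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError(f"abundance vector {self.label!r} has entries < 1")
        if self.otu_ids is not None and len(self.otu_ids) != self.counts.size:
            raise ValueError("otu_ids length does not match counts")

    def __len__(self) -> int:
        return self.counts.size


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata: pd.DataFrame | None = None) -> OTUTable:
    """Parse a QIIME-classic TSV OTU table into an :class:`OTUTable`.

    The first non-comment header line must start with ``#OTU ID``; an
    optional last column named ``taxonomy`` (any case) is preserved as an
    opaque per-OTU annotation rather than a count column.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header_idx = i
            break
        if not line.startswith("#"):
            break
    if header_idx is None:
        raise TableParseError(f"{path}: no '#OTU ID' header line found")
    df = pd.read_csv(path, sep="\t", skiprows=header_idx, index_col=0, dtype=str)
    df.index.name = "otu_id"
    taxonomy = None
    if len(df.columns) and df.columns[-1].strip().lower() == "taxonomy":
        taxonomy = dict(zip(df.index, df.iloc[:, -1].fillna("")))
        df = df.iloc[:, :-1]
    if df.index.duplicated().any():
        raise TableParseError(f"{path}: duplicate OTU ids in first column")
    if df.columns.duplicated().any():
        raise TableParseError(f"{path}: duplicate sample ids in header")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise TableParseError(
                    f"{path}: non-integer count {raw!r} at OTU {df.index[i]!r}, "
                    f"sample {col!r}") from None
            if v < 0:
                raise TableParseError(
                    f"{path}: negative count {v} at OTU {df.index[i]!r}, sample {col!r}")
            counts[i, j] = v
    frame = pd.DataFrame(counts.T, index=list(df.columns), columns=list(df.index))
    return OTUTable(frame, metadata, taxonomy)


def write_otu_table(table: OTUTable, path) -> None:
    """Write an OTUTable back to the QIIME-classic TSV dialect."""
    df = table.counts.T.copy()
    if table.taxonomy is not None:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in df.index]
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_metadata(path, sample_col: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata CSV; the key column defaults to the first."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    key = sample_col.lower() if sample_col else df.columns[0]
    df = df.set_index(key)
    df.index = df.index.astype(str)
    return df


def read_env_table(path, sample_col: str | None = None) -> EnvTable:
    """Read a CSV of environmental covariates keyed by sample id.

    Column names are normalized case-insensitively through :data:`ENV_ALIASES`
    (nitrite is reported under two spellings in the wild; both map to
    ``no2_no3`` and the substitution is logged).
    """
    df = pd.read_csv(path)
    key = sample_col if sample_col else df.columns[0]
    df = df.set_index(key)
    df.index = df.index.astype(str)
    renames = {}
    for col in df.columns:
        canon = ENV_ALIASES.get(col.strip().lower())
        if canon is not None and canon != col:
            renames[col] = canon
    if renames:
        logger.info("environment column aliases applied: %s", renames)
        df = df.rename(columns=renames)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.apply(pd.to_numeric, errors="coerce")
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    env.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# core table operations
# ---------------------------------------------------------------------------

def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total read count is below ``depth`` are dropped (with a
    logged warning), never padded.  Deterministic for a given seed.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    rows = []
    kept = []
    dropped = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept.append(sid)
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d: %s",
                       len(dropped), depth, dropped[:10])
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64).reshape(len(kept), -1),
                          index=kept, columns=table.otu_ids)
    meta = table.metadata.loc[kept] if table.metadata is not None else None
    return OTUTable(counts, meta, table.taxonomy)


def filter_rel_abundance(table: OTUTable, threshold_pct: float = 0.001) -> OTUTable:
    """Keep OTUs contributing strictly more than ``threshold_pct`` percent of
    the table's grand total.  The caller pre-splits by region/domain when the
    threshold is meant per group."""
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be >= 0")
    grand = int(table.counts.to_numpy().sum())
    if table.counts.size == 0 or grand == 0:
        raise ValueError("cannot filter an empty table")
    pct = table.counts.sum(axis=0) / grand * 100.0
    keep = pct.index[pct > threshold_pct]
    tax = None
    if table.taxonomy is not None:
        tax = {o: t for o, t in table.taxonomy.items() if o in set(keep)}
    return OTUTable(table.counts.loc[:, keep], table.metadata, tax)


def pool_abundances(table: OTUTable, group_by: str) -> list[AbundanceVector]:
    """Pool counts across samples per site or per region.

    Per group, per-OTU counts are summed across samples; OTUs with a zero
    pooled total are excluded.  Groups and OTU ids come back lexicographically
    sorted for reproducibility.
    """
    if group_by not in ("site", "region"):
        raise ValueError(f"group_by must be 'site' or 'region', got {group_by!r}")
    meta = table.require_metadata()
    vectors = []
    for label in sorted(meta[group_by].unique()):
        samples = meta.index[meta[group_by] == label]
        pooled = table.counts.loc[samples].sum(axis=0)
        pooled = pooled[pooled > 0].sort_index()
        domains = set(meta.loc[samples, "domain"])
        vectors.append(AbundanceVector(
            label=str(label),
            counts=pooled.to_numpy(),
            otu_ids=list(pooled.index),
            domain=domains.pop() if len(domains) == 1 else None,
        ))
    return vectors


# ---------------------------------------------------------------------------
# generic result serialization
# ---------------------------------------------------------------------------

def write_results(obj, path, format: str = "tsv") -> None:
    """Serialize a result table (DataFrame) or mapping losslessly.

    TSV keeps one header row; JSON uses pandas' ``split`` orientation for
    frames so a round trip restores values and column order.
    """
    path = Path(path)
    if format == "tsv":
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame([obj]) if isinstance(obj, dict) else pd.DataFrame(obj)
        obj.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with path.open("w") as fh:
            if isinstance(obj, pd.DataFrame):
                fh.write(obj.to_json(orient="split", double_precision=15))
            else:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path, format: str = "tsv"):
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with path.open() as fh:
            payload = json.load(fh)
        if isinstance(payload, dict) and set(payload) == {"columns", "index", "data"}:
            return pd.DataFrame(payload["data"], index=payload["index"],
                                columns=payload["columns"])
        return payload
    raise ValueError(f"unknown format {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
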