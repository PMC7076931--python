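"""Synthetic OTU tables, environment tables and planted co-occurrence
structure with known ground truth.

All randomness flows from a single master seed, split deterministically per
stage with :class:`numpy.random.SeedSequence`, so regenerating a fixture
from the same config is byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (AbundanceVector, EnvTable, OTUTable,
                        write_env_table, write_otu_table)

logger = logging.getLogger(__name__)


@dataclass
class CommunitySpec:
    """Generative model for one community's species abundance distribution.

    model is one of ``pln`` (params mu, sigma), ``nb`` (params m, k) or
    ``mixture`` (params components = list of (weight, mu, sigma) PLN tuples).
    """

    S: int
    model: str
    params: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.model == "pln":
            if self.params.get("sigma", 0) <= 0:
                raise ValueError("pln requires sigma > 0")
        elif self.model == "nb":
            if self.params.get("m", 0) <= 0 or self.params.get("k", 0) <= 0:
                raise ValueError("nb requires m > 0 and k > 0")
        elif self.model == "mixture":
            comps = self.params.get("components", [])
            if not comps:
                raise ValueError("mixture requires at least one component")
            w = sum(c[0] for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w}")
            if any(c[2] <= 0 for c in comps):
                raise ValueError("mixture component sigmas must be > 0")
        else:
            raise ValueError(f"unknown model {self.model!r}")


def simulate_sad(spec: CommunitySpec, return_rates: bool = False):
    """Draw an observed (zero-truncated) abundance vector from ``spec``.

    PLN: lam_i ~ LogNormal(mu, sigma), n_i ~ Poisson(lam_i).
    NB: n_i ~ NegativeBinomial(mean m, dispersion k).
    Mixture: each species draws its PLN component by weight.
    Zero draws are discarded — communities are defined over observed species.
    """
    rng = np.random.default_rng(spec.seed)
    rates = None
    if spec.model == "pln":
        rates = rng.lognormal(spec.params["mu"], spec.params["sigma"], spec.S)
        draws = rng.poisson(rates)
    elif spec.model == "nb":
        m, k = spec.params["m"], spec.params["k"]
        draws = rng.negative_binomial(k, k / (k + m), spec.S)
    else:
        comps = spec.params["components"]
        weights = np.array([c[0] for c in comps])
        which = rng.choice(len(comps), size=spec.S, p=weights)
        mus = np.array([comps[i][1] for i in which])
        sigmas = np.array([comps[i][2] for i in which])
        rates = rng.lognormal(mus, sigmas)
        draws = rng.poisson(rates)
    keep = draws > 0
    vec = AbundanceVector(label=f"sim-{spec.model}", counts=draws[keep],
                          otu_ids=[f"OTU{i:05d}" for i in np.nonzero(keep)[0]])
    if return_rates:
        return vec, (rates[keep] if rates is not None else None)
    return vec


def simulate_otu_table(community: AbundanceVector, n_samples: int, depth: int,
                       overdispersion: float = 0.0, seed: int = 0,
                       site: str = "S1", region: str = "R1",
                       domain: str = "bacteria",
                       sample_prefix: str | None = None) -> OTUTable:
    """Sequencing layer: multinomial reads per sample at fixed ``depth``.

    Per sample the community's relative abundances are perturbed by
    lognormal noise of scale ``overdispersion`` before the multinomial draw
    (0 recovers plain multinomial sampling).
    """
    if n_samples < 1 or depth < 1:
        raise ValueError("n_samples and depth must be >= 1")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    p = community.counts / community.counts.sum()
    rows = np.empty((n_samples, p.size), dtype=np.int64)
    for i in range(n_samples):
        w = p
        if overdispersion > 0:
            w = p * rng.lognormal(0.0, overdispersion, p.size)
            w = w / w.sum()
        rows[i] = rng.multinomial(depth, w)
    prefix = sample_prefix or f"{site}"
    sample_ids = [f"{prefix}.{i + 1:03d}" for i in range(n_samples)]
    otu_ids = community.otu_ids or [f"OTU{i:05d}" for i in range(p.size)]
    counts = pd.DataFrame(rows, index=sample_ids, columns=otu_ids)
    meta = pd.DataFrame({"site": site, "region": region, "domain": domain},
                        index=sample_ids)
    return OTUTable(counts, meta)


def plant_cooccurrence(table: OTUTable, pairs, seed: int = 0) -> OTUTable:
    """Rescale pairs of OTU columns by shared latent lognormal factors.

    ``pairs`` is a list of ``(otuA, otuB, sign, strength)``; a positive sign
    applies the same per-sample factor to both columns, a negative sign the
    factor and its reciprocal.  Rows are re-rounded back to (approximately,
    +-1) their original depth.
    """
    for a, b, sign, strength in pairs:
        for otu in (a, b):
            if otu not in table.counts.columns:
                raise KeyError(f"unknown OTU id {otu!r}")
        if sign not in ("positive", "negative"):
            raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    rng = np.random.default_rng(seed)
    values = table.counts.to_numpy().astype(np.float64)
    depths = values.sum(axis=1)
    cols = {o: j for j, o in enumerate(table.counts.columns)}
    touched = False
    for a, b, sign, strength in pairs:
        if strength == 0:
            continue
        touched = True
        factor = rng.lognormal(0.0, strength, values.shape[0])
        values[:, cols[a]] *= factor
        values[:, cols[b]] *= factor if sign == "positive" else 1.0 / factor
    if not touched:
        return table
    out = np.empty_like(values, dtype=np.int64)
    for i in range(values.shape[0]):
        out[i] = _round_preserving_sum(values[i], int(depths[i]))
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OTUTable(counts, table.metadata, table.taxonomy)


def _round_preserving_sum(row: np.ndarray, target: int) -> np.ndarray:
    """Largest-remainder rounding of a non-negative row to sum ``target``."""
    if row.sum() <= 0:
        return np.zeros(row.size, dtype=np.int64)
    scaled = row * (target / row.sum())
    base = np.floor(scaled).astype(np.int64)
    short = target - int(base.sum())
    if short > 0:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_env(n_samples: int, predictors: list[str],
                 true_effects: dict[str, float], richness: np.ndarray,
                 noise_sd: float = 0.0, seed: int = 0,
                 sample_ids=None, correlated_pairs=None) -> tuple[EnvTable, dict]:
    """Environment table whose true-effect linear predictor explains
    ``richness`` up to Gaussian noise of sd ``noise_sd``.

    Covariates are standard-normal; the last true-effect column is solved so
    that ``richness = sum_j beta_j x_j + eps`` holds exactly.  For every
    requested correlated pair ``(a, b)`` column ``b`` is rebuilt as a noisy
    copy of ``a`` with sample |R| > 0.6 to exercise covariate pruning.
    """
    richness = np.asarray(richness, dtype=np.float64)
    if richness.size != n_samples:
        raise ValueError("richness length must equal n_samples")
    unknown = set(true_effects) - set(predictors)
    if unknown:
        raise ValueError(f"true_effects refer to unknown predictors: {sorted(unknown)}")
    if not true_effects:
        raise ValueError("at least one true effect is required")
    rng = np.random.default_rng(seed)
    data = {p: rng.normal(0.0, 1.0, n_samples) for p in predictors}
    if correlated_pairs:
        for a, b in correlated_pairs:
            if b in true_effects:
                raise ValueError("the dependent member of a correlated pair "
                                 "cannot carry a true effect")
            data[b] = 0.9 * data[a] + rng.normal(0.0, 0.3, n_samples)
    eps = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
    names = sorted(true_effects)
    solved = names[-1]
    partial = sum(true_effects[p] * data[p] for p in names[:-1])
    data[solved] = (richness - eps - partial) / true_effects[solved]
    if sample_ids is None:
        sample_ids = [f"sample.{i + 1:03d}" for i in range(n_samples)]
    frame = pd.DataFrame({p: data[p] for p in predictors}, index=list(sample_ids))
    truth = {"true_effects": dict(true_effects), "noise_sd": noise_sd,
             "correlated_pairs": [list(p) for p in (correlated_pairs or [])]}
    return EnvTable(frame), truth


# ---------------------------------------------------------------------------
# full fixture bundle
# ---------------------------------------------------------------------------

VESTFOLD_SITES = ("AF", "HV", "OW", "RL", "TR")
WINDMILL_SITES = ("BP", "HI", "MP", "RR")


@dataclass
class FixtureConfig:
    """Desk-scale knobs for the two-region, nine-site, three-domain bundle."""

    seed: int = 0
    samples_per_site: dict = field(default_factory=lambda: {
        "bacteria": 6, "eukarya": 3, "archaea": 3})
    depths: dict = field(default_factory=lambda: {
        "bacteria": 10_000, "eukarya": 2_000, "archaea": 5_000})
    richness: dict = field(default_factory=lambda: {
        "bacteria": 600, "eukarya": 120, "archaea": 60})
    #: generative SAD per (domain, region); defaults mirror the qualitative
    #: pattern of niche-like bacteria and neutral-ish eukarya in one region
    sad_models: dict = field(default_factory=lambda: {
        ("bacteria", "Vestfold"): ("pln", {"mu": 1.0, "sigma": 2.0}),
        ("bacteria", "Windmill"): ("pln", {"mu": 1.5, "sigma": 2.2}),
        ("eukarya", "Vestfold"): ("nb", {"m": 25.0, "k": 0.4}),
        ("eukarya", "Windmill"): ("pln", {"mu": 1.0, "sigma": 1.8}),
        ("archaea", "Vestfold"): ("pln", {"mu": 2.0, "sigma": 1.5}),
        ("archaea", "Windmill"): ("pln", {"mu": 2.0, "sigma": 1.8}),
    })
    overdispersion: float = 0.3
    planted_pairs: tuple = (
        ("bacteria", "OTU00000", "OTU00001", "positive", 2.0),
        ("bacteria", "OTU00002", "OTU00003", "negative", 2.0),
    )
    env_predictors: tuple = ("ph", "conductivity", "tc", "tn", "tp", "cu",
                             "al", "tio2", "gravel", "mud")
    env_true_effects: dict = field(default_factory=lambda: {
        "conductivity": 40.0, "tp": 30.0, "cu": -25.0})
    env_noise_sd: float = 5.0


@dataclass
class FixtureBundle:
    tables: dict[str, OTUTable]
    env: EnvTable
    truth: dict


def make_fixture(config: FixtureConfig | None = None) -> FixtureBundle:
    """Assemble the full two-region, nine-site, three-domain bundle."""
    config = config or FixtureConfig()
    master = np.random.SeedSequence(config.seed)
    seeds = iter(master.generate_state(200))
    tables: dict[str, OTUTable] = {}
    truth: dict = {"sad_models": {}, "planted_pairs": [], "env": {}}
    region_of = {s: "Vestfold" for s in VESTFOLD_SITES}
    region_of.update({s: "Windmill" for s in WINDMILL_SITES})

    for domain in ("bacteria", "eukarya", "archaea"):
        site_tables = []
        for site in VESTFOLD_SITES + WINDMILL_SITES:
            region = region_of[site]
            model, params = config.sad_models[(domain, region)]
            spec = CommunitySpec(S=config.richness[domain], model=model,
                                 params=params, seed=int(next(seeds)))
            community = simulate_sad(spec)
            tbl = simulate_otu_table(
                community, n_samples=config.samples_per_site[domain],
                depth=config.depths[domain],
                overdispersion=config.overdispersion, seed=int(next(seeds)),
                site=site, region=region, domain=domain,
                sample_prefix=f"{domain[:3]}.{site}")
            site_tables.append(tbl)
            truth["sad_models"][f"{domain}/{region}"] = [model, params]
        counts = pd.concat([t.counts for t in site_tables]).fillna(0).astype(np.int64)
        meta = pd.concat([t.metadata for t in site_tables])
        meta["location"] = [f"{meta.loc[s, 'site']}.{s.split('.')[-1]}"
                            for s in meta.index]
        table = OTUTable(counts, meta)
        pairs = [(a, b, sign, strength)
                 for (dom, a, b, sign, strength) in config.planted_pairs
                 if dom == domain and a in counts.columns and b in counts.columns]
        if pairs:
            table = plant_cooccurrence(table, pairs, seed=int(next(seeds)))
            truth["planted_pairs"] += [[domain, *p] for p in pairs]
        tables[domain] = table

    # environment covers every sample of every domain; the true-effect linear
    # predictor explains each sample's observed richness
    all_ids: list[str] = []
    richness: list[float] = []
    for domain in sorted(tables):
        t = tables[domain]
        all_ids.extend(t.sample_ids)
        richness.extend((t.counts > 0).sum(axis=1).astype(float))
    env, env_truth = simulate_env(
        n_samples=len(all_ids),
        predictors=list(config.env_predictors),
        true_effects=dict(config.env_true_effects),
        richness=np.asarray(richness), noise_sd=config.env_noise_sd,
        seed=int(next(seeds)), sample_ids=all_ids,
        correlated_pairs=[("al", "tio2")])
    truth["env"] = env_truth
    bundle = FixtureBundle(tables=tables, env=env, truth=truth)
    _check_truth_ids(bundle)
    return bundle


def _check_truth_ids(bundle: FixtureBundle) -> None:
    for dom, a, b, _sign, _strength in bundle.truth["planted_pairs"]:
        for otu in (a, b):
            if otu not in bundle.tables[dom].counts.columns:
                raise ValueError(f"ground truth references missing OTU {otu!r}")
    for pred in bundle.truth["env"]["true_effects"]:
        if pred not in bundle.env.data.columns:
            raise ValueError(f"ground truth references missing covariate {pred!r}")


def write_fixture(bundle: FixtureBundle, outdir) -> None:
    """Write the bundle as the TSV/CSV dialects the readers understand."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for domain, table in bundle.tables.items():
        write_otu_table(table, outdir / f"otu_table_{domain}.tsv")
        table.metadata.to_csv(outdir / f"metadata_{domain}.csv",
                              index_label="sample_id")
    write_env_table(bundle.env, outdir / "env.csv")
    with (outdir / "truth.json").open("w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
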