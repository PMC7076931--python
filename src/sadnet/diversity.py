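"""Chao1 richness, individual-based rarefaction and richness correlations."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_tables import OTUTable

logger = logging.getLogger(__name__)


@dataclass
class Chao1Estimate:
    s_obs: int
    f1: int
    f2: int
    chao1: float
    variant: str


def chao1(sample_counts, variant: str = "bias_corrected") -> Chao1Estimate:
    """Chao1 richness estimate from a single count vector.

    classic:        S_obs + F1^2 / (2 F2)
    bias_corrected: S_obs + F1 (F1 - 1) / (2 (F2 + 1))

    The classic form falls back to the bias-corrected one when F2 = 0 (with a
    log note), matching common implementations.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if counts.size == 0 or counts.max() <= 0:
        raise ValueError("chao1 requires at least one positive count")
    if counts.min() < 0:
        raise ValueError("counts must be >= 0")
    if variant not in ("classic", "bias_corrected"):
        raise ValueError(f"unknown variant {variant!r}")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    used = variant
    if variant == "classic" and f2 == 0:
        logger.info("chao1: F2 = 0, falling back to bias-corrected form")
        used = "bias_corrected"
    if used == "classic":
        est = s_obs + f1 ** 2 / (2.0 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return Chao1Estimate(s_obs=s_obs, f1=f1, f2=f2, chao1=float(est), variant=used)


def chao1_by_sample(table: OTUTable, variant: str = "bias_corrected") -> pd.Series:
    """Per-sample Chao1 estimates down an OTU table."""
    return pd.Series(
        {sid: chao1(table.counts.loc[sid].to_numpy(), variant).chao1
         for sid in table.sample_ids}, name="chao1")


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    expected_richness: np.ndarray


def rarefaction_curve(pooled_counts, depths) -> RarefactionCurve:
    """Hypergeometric expected richness E[S_m] at each subsample size m.

    E[S_m] = sum_i [1 - C(N - n_i, m) / C(N, m)], evaluated with log-gamma
    arithmetic so large N stay exact to floating point.
    """
    counts = np.asarray(pooled_counts, dtype=np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("rarefaction requires at least one positive count")
    n_total = int(counts.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if depths.size == 0 or depths.min() < 1:
        raise ValueError("depths must be positive integers")
    if depths.max() > n_total:
        raise ValueError(f"depth {depths.max()} exceeds total reads {n_total}")
    exp_s = np.empty(depths.size, dtype=np.float64)
    lg_n = _log_choose(n_total, depths)
    for j, m in enumerate(depths):
        rest = n_total - counts
        with np.errstate(invalid="ignore"):
            log_miss = _log_choose(rest, m) - lg_n[j]
        miss = np.where(rest >= m, np.exp(log_miss), 0.0)
        exp_s[j] = float(np.sum(1.0 - miss))
    return RarefactionCurve(depths=depths, expected_richness=exp_s)


def _log_choose(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def richness_correlation(x, y) -> tuple[float, float]:
    """Pearson R with a two-sided p-value from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("richness_correlation: zero variance input, returning NA")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cross_domain_correlations(chao1_tables: dict[str, pd.Series],
                              pair_keys: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-sample Chao1 across domains.

    ``pair_keys`` maps each domain to a Series of shared location keys
    indexed by sample id; samples without a partner in the other domain are
    dropped (the dropped count is logged).
    """
    rows = []
    domains = sorted(chao1_tables)
    for i, a in enumerate(domains):
        for b in domains[i + 1:]:
            ka = pd.Series(chao1_tables[a].values, index=pair_keys[a].loc[
                chao1_tables[a].index].values)
            kb = pd.Series(chao1_tables[b].values, index=pair_keys[b].loc[
                chao1_tables[b].index].values)
            ka = ka[~ka.index.duplicated()]
            kb = kb[~kb.index.duplicated()]
            shared = ka.index.intersection(kb.index)
            dropped = (len(ka) - len(shared)) + (len(kb) - len(shared))
            if dropped:
                logger.info("cross_domain_correlations %s~%s: dropped %d "
                            "unpaired samples", a, b, dropped)
            if len(shared) < 3:
                rows.append({"domain_a": a, "domain_b": b, "n": len(shared),
                             "R": float("nan"), "P": float("nan")})
                continue
            r, p = richness_correlation(ka.loc[shared].values, kb.loc[shared].values)
            rows.append({"domain_a": a, "domain_b": b, "n": len(shared),
                         "R": r, "P": p})
    return pd.DataFrame(rows)
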