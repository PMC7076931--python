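"""Maximal-information-coefficient co-occurrence networks.

The MIC of two vectors is the maximum over grid resolutions (nx, ny) with
nx * ny <= B(n) = n^alpha of the normalized mutual information
max_G I(x, y | G) / log2(min(nx, ny)).  One axis is equipartitioned; the
other axis' partition is optimized exactly by dynamic programming over clump
candidate boundaries (at most c * nx of them), and the procedure is applied
in both orientations with the maximum taken.  The DP is exact because, with
the row partition fixed, H(P) - H(P,Q) decomposes into a sum of per-column
terms.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._micfast import HAVE_NUMBA, mic_kernel
from .io_tables import OTUTable, filter_rel_abundance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MIC core
# ---------------------------------------------------------------------------

def _equipartition(values: np.ndarray, k: int) -> np.ndarray:
    """Assign points to ~equal-size ordered bins, never splitting ties."""
    order = np.argsort(values, kind="stable")
    n = values.size
    assign = np.empty(n, dtype=np.int64)
    i = 0
    row = 0
    row_size = 0
    desired = n / k
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        block = j - i
        if row_size != 0 and abs(row_size + block - desired) >= abs(row_size - desired) \
                and row < k - 1:
            row += 1
            row_size = 0
            desired = (n - i) / (k - row)
        assign[order[i:j]] = row
        row_size += block
        i = j
    return assign


def _clump_boundaries(x_sorted: np.ndarray, rows_sorted: np.ndarray,
                      max_candidates: int) -> np.ndarray:
    """Candidate column-boundary positions (cumulative point counts).

    Points sharing an x value can never be separated; adjacent runs whose
    points all sit in one common row are merged (lossless for the DP).  If
    more than ``max_candidates`` clumps remain they are coarsened into
    approximately that many superclumps.
    """
    n = x_sorted.size
    bounds = [0]
    i = 0
    cur_pure_row = None  # row of current clump if pure, else -1
    started = False
    while i < n:
        j = i
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        atom_rows = rows_sorted[i:j]
        atom_pure = int(atom_rows[0]) if (atom_rows == atom_rows[0]).all() else -1
        if not started:
            cur_pure_row = atom_pure
            started = True
        elif atom_pure == -1 or cur_pure_row == -1 or atom_pure != cur_pure_row:
            bounds.append(i)
            cur_pure_row = atom_pure
        i = j
    bounds.append(n)
    bounds = np.asarray(bounds, dtype=np.int64)
    k = bounds.size - 1
    if k > max_candidates:
        # superclumps: greedy merge towards equal point counts
        target = n / max_candidates
        keep = [0]
        for t in range(1, k):
            if bounds[t] >= target * len(keep):
                keep.append(int(bounds[t]))
        if keep[-1] != n:
            keep.append(n)
        bounds = np.asarray(sorted(set(keep)), dtype=np.int64)
    return bounds


def _optimize_axis(x: np.ndarray, rows: np.ndarray, ny: int, max_nx: int,
                   c: float) -> np.ndarray:
    """Best I(P;Q) (nats) over x-axis partitions into <= l columns, l = 1..max_nx.

    Exact interval-partition DP over clump candidate boundaries.
    """
    n = x.size
    order = np.lexsort((rows, x))
    xs = x[order]
    qs = rows[order]
    bounds = _clump_boundaries(xs, qs, max(int(c * max_nx), max_nx))
    k = bounds.size - 1
    # cumulative per-row counts at each boundary
    cum = np.zeros((k + 1, ny), dtype=np.float64)
    for t in range(1, k + 1):
        seg = qs[bounds[t - 1]:bounds[t]]
        cum[t] = cum[t - 1]
        np.add.at(cum[t], seg, 1.0)
    row_tot = cum[-1]
    pr = row_tot[row_tot > 0] / n
    h_q = float(-np.sum(pr * np.log(pr)))
    # per-interval additive scores f(a, b) = sum_r g(h_r) - g(count)
    diff = cum[None, :, :] - cum[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(diff > 0, (diff / n) * np.log(diff / n), 0.0).sum(axis=2)
    cnt = (bounds[None, :] - bounds[:, None]).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_cnt = np.where(cnt > 0, (cnt / n) * np.log(cnt / n), 0.0)
    fmat = g - g_cnt
    fmat[cnt <= 0] = -np.inf  # only a < b intervals are valid

    best = np.full(max_nx + 1, -np.inf)
    f_prev = np.full(k + 1, -np.inf)
    f_prev[0] = 0.0
    for l in range(1, max_nx + 1):
        f_new = (f_prev[:, None] + fmat).max(axis=0)
        f_new[0] = -np.inf
        best[l] = f_new[k]
        f_prev = f_new
    # allow fewer nonempty columns than l
    running = np.maximum.accumulate(best[1:])
    out = np.full(max_nx + 1, -np.inf)
    out[1:] = h_q + running
    return out


def mic(x, y, alpha: float = 0.6, c: float = 15.0,
        max_bins: int | None = None) -> float:
    """Maximal information coefficient of two equal-length vectors.

    ``max_bins`` overrides the grid-size budget B(n) = n^alpha (useful for
    oracle comparisons at tiny n).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("MIC requires at least 4 points")
    b = max_bins if max_bins is not None else max(int(n ** alpha), 4)
    if HAVE_NUMBA:
        return float(mic_kernel(np.ascontiguousarray(x),
                                np.ascontiguousarray(y), b, float(c)))
    best = 0.0
    for xs, ys in ((x, y), (y, x)):
        for ny in range(2, b // 2 + 1):
            max_nx = b // ny
            if max_nx < 2:
                break
            rows = _equipartition(ys, ny)
            scores = _optimize_axis(xs, rows, int(rows.max()) + 1, max_nx, c)
            for l in range(2, max_nx + 1):
                if np.isfinite(scores[l]):
                    val = scores[l] / math.log(min(l, ny))
                    if val > best:
                        best = val
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# pairwise computation and significance
# ---------------------------------------------------------------------------

@dataclass
class MICResult:
    otu_a: str
    otu_b: str
    mic: float
    sign: str
    p_perm: float | None = None
    p_adj: float | None = None


def _relative_abundances(table: OTUTable) -> pd.DataFrame:
    totals = table.counts.sum(axis=1).replace(0, 1)
    return table.counts.div(totals, axis=0)


def _pearson_sign(x: np.ndarray, y: np.ndarray, pair: str = "") -> str:
    if np.std(x) == 0 or np.std(y) == 0:
        logger.debug("constant relative abundance in pair %s; sign set positive", pair)
        return "positive"
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        logger.warning("zero Pearson correlation for pair %s; sign set positive", pair)
        return "positive"
    return "positive" if r > 0 else "negative"


def pairwise_mic_frame(rel: pd.DataFrame, alpha: float = 0.6,
                       c: float = 15.0) -> list[MICResult]:
    """MIC over all unordered column pairs of a relative-abundance frame."""
    if len(rel) < 4:
        raise ValueError("pairwise MIC requires at least 4 samples")
    otus = sorted(rel.columns)
    results = []
    for a, b in itertools.combinations(otus, 2):
        xa = rel[a].to_numpy()
        xb = rel[b].to_numpy()
        results.append(MICResult(
            otu_a=a, otu_b=b, mic=mic(xa, xb, alpha=alpha, c=c),
            sign=_pearson_sign(xa, xb, f"{a}~{b}")))
    return results


def pairwise_mic(table: OTUTable, min_rel_abundance_pct: float = 0.001,
                 alpha: float = 0.6, c: float = 15.0) -> list[MICResult]:
    """MIC over all unordered OTU pairs surviving the relative-abundance filter.

    Association is computed on within-sample relative abundances (denominator
    = the full sample's reads, so filtering does not change the composition);
    the edge sign comes from the Pearson correlation of the same vectors.
    """
    filtered = filter_rel_abundance(table, min_rel_abundance_pct)
    rel = _relative_abundances(table)[filtered.otu_ids]
    return pairwise_mic_frame(rel, alpha=alpha, c=c)


def permutation_pvalues_frame(rel: pd.DataFrame, pairs: list[MICResult],
                              n_perm: int = 999, seed: int = 0,
                              alpha: float = 0.6, c: float = 15.0,
                              return_null: bool = False):
    """Permutation p-values for observed pair MICs.

    The null permutes every OTU's sample order independently per replicate;
    p = (b + 1) / (n_perm + 1) with b = number of null MICs >= observed, so
    p is never 0 and never above 1.  Results come back as a new list with
    ``p_perm`` filled in.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    otus = sorted({r.otu_a for r in pairs} | {r.otu_b for r in pairs})
    missing = [o for o in otus if o not in rel.columns]
    if missing:
        raise KeyError(f"pairs reference OTUs absent from table: {missing[:5]}")
    cols = {o: rel[o].to_numpy() for o in otus}
    rng = np.random.default_rng(seed)
    n = len(rel)
    null = np.empty((n_perm, len(pairs)), dtype=np.float64)
    for it in range(n_perm):
        perms = {o: cols[o][rng.permutation(n)] for o in otus}
        for j, pr in enumerate(pairs):
            null[it, j] = mic(perms[pr.otu_a], perms[pr.otu_b], alpha=alpha, c=c)
    out = []
    for j, pr in enumerate(pairs):
        b = int(np.sum(null[:, j] >= pr.mic))
        out.append(MICResult(pr.otu_a, pr.otu_b, pr.mic, pr.sign,
                             p_perm=(b + 1) / (n_perm + 1)))
    if return_null:
        return out, null
    return out


def permutation_pvalues(table: OTUTable, pairs: list[MICResult],
                        n_perm: int = 999, seed: int = 0,
                        alpha: float = 0.6, c: float = 15.0,
                        return_null: bool = False):
    """Table-level wrapper around :func:`permutation_pvalues_frame`."""
    return permutation_pvalues_frame(_relative_abundances(table), pairs,
                                     n_perm=n_perm, seed=seed, alpha=alpha,
                                     c=c, return_null=return_null)


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment: step-up BH (default), Bonferroni, or
    ``none`` (pass-through; note a permutation p floor of 1/(n_perm+1) makes
    BH-adjusted values below m/(t*(n_perm+1)) unattainable)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=np.float64)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# network construction and topology
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: list[MICResult]
    topology: dict = field(default_factory=dict)


def build_network(results: list[MICResult], mic_threshold: float = 0.8,
                  p_threshold: float = 0.001,
                  domains: dict[str, str] | None = None,
                  adjust_method: str = "benjamini_hochberg") -> CooccurrenceNetwork:
    """Filtered co-occurrence network: mic > mic_threshold AND adjusted
    p <= p_threshold.  Isolated OTUs are excluded from the node set."""
    results = list(results)
    if results and results[0].p_adj is None:
        if any(r.p_perm is None for r in results):
            raise ValueError("results need p_perm (run permutation_pvalues first)")
        adj = adjust_pvalues([r.p_perm for r in results], adjust_method)
        results = [MICResult(r.otu_a, r.otu_b, r.mic, r.sign, r.p_perm, float(a))
                   for r, a in zip(results, adj)]
    kept = [r for r in results
            if r.mic > mic_threshold and (r.p_adj is None or r.p_adj <= p_threshold)]
    g = nx.Graph()
    for r in kept:
        g.add_edge(r.otu_a, r.otu_b, mic=r.mic, sign=r.sign,
                   p=r.p_perm if r.p_perm is not None else float("nan"),
                   p_adj=r.p_adj if r.p_adj is not None else float("nan"))
    if domains:
        nx.set_node_attributes(
            g, {n: domains.get(n, "unknown") for n in g.nodes}, "domain")
    net = CooccurrenceNetwork(graph=g, edges=kept)
    net.topology = topology_stats(net)
    return net


def topology_stats(net: CooccurrenceNetwork) -> dict:
    """Undirected topology summary.

    Clustering coefficient is the mean of local coefficients with degree-<2
    nodes contributing 0; characteristic path length averages shortest paths
    over connected pairs only; diameter is the longest finite shortest path.
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_nodes == 0:
        return {"n_nodes": 0, "n_edges": 0, "avg_neighbours": 0.0,
                "clustering_coefficient": float("nan"),
                "characteristic_path_length": float("nan"),
                "diameter": 0, "n_components": 0}
    cc = nx.average_clustering(g)
    dists = []
    diameter = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, d in lengths.items():
                if src < dst:
                    dists.append(d)
                    diameter = max(diameter, d)
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "avg_neighbours": 2.0 * n_edges / n_nodes,
        "clustering_coefficient": float(cc),
        "characteristic_path_length":
            float(np.mean(dists)) if dists else float("nan"),
        "diameter": int(diameter),
        "n_components": nx.number_connected_components(g),
    }


def cooccurrence_null_test(table: OTUTable, n_perm: int = 999, seed: int = 0,
                           mic_threshold: float = 0.8, p_threshold: float = 0.001,
                           min_rel_abundance_pct: float = 0.001,
                           alpha: float = 0.6, c: float = 15.0,
                           adjust_method: str = "benjamini_hochberg") -> float:
    """Do OTUs co-occur more than expected by chance?

    The statistic is the number of pairs passing both network filters.  Null
    replicates reuse the permutation MIC ensemble: replicate j's pair MICs
    get leave-one-out empirical p-values against the other replicates, the
    same multiple-testing correction, and the same thresholds.  Returns
    p = (b + 1) / (n_perm + 1) with b = number of null statistics >= observed.
    """
    observed = pairwise_mic(table, min_rel_abundance_pct, alpha=alpha, c=c)
    filtered = filter_rel_abundance(table, min_rel_abundance_pct)
    rel = _relative_abundances(table)[filtered.otu_ids]
    observed, null = permutation_pvalues_frame(rel, observed, n_perm=n_perm,
                                               seed=seed, alpha=alpha, c=c,
                                               return_null=True)
    adj = adjust_pvalues([r.p_perm for r in observed], adjust_method)
    obs_stat = int(np.sum((np.array([r.mic for r in observed]) > mic_threshold)
                          & (adj <= p_threshold)))
    n_pairs = len(observed)
    # leave-one-out p-values for every null replicate, vectorized per pair
    null_p = np.empty_like(null)
    for j in range(n_pairs):
        col = null[:, j]
        srt = np.sort(col)
        ge = n_perm - np.searchsorted(srt, col, side="left") - 1  # exclude self
        null_p[:, j] = (ge + 1) / n_perm
    null_stats = np.empty(n_perm, dtype=np.int64)
    for it in range(n_perm):
        adj_it = adjust_pvalues(null_p[it], adjust_method)
        null_stats[it] = int(np.sum((null[it] > mic_threshold)
                                    & (adj_it <= p_threshold)))
    b = int(np.sum(null_stats >= obs_stat))
    return (b + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    return pd.DataFrame([{
        "otuA": r.otu_a, "otuB": r.otu_b, "mic": r.mic, "sign": r.sign,
        "p": r.p_perm, "p_adj": r.p_adj} for r in net.edges],
        columns=["otuA", "otuB", "mic", "sign", "p", "p_adj"])


def write_sif(net: CooccurrenceNetwork, path) -> None:
    """Cytoscape-compatible SIF: 'A cooccurs_pos B' / 'A cooccurs_neg B'."""
    with open(path, "w") as fh:
        for r in net.edges:
            rel = "cooccurs_pos" if r.sign == "positive" else "cooccurs_neg"
            fh.write(f"{r.otu_a}\t{rel}\t{r.otu_b}\n")


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        for key, val in list(data.items()):
            if val is None or (isinstance(val, float) and math.isnan(val)):
                data[key] = -1.0
    nx.write_graphml(g, path)


def topology_table(nets: dict[str, CooccurrenceNetwork]) -> pd.DataFrame:
    rows = []
    for label, net in sorted(nets.items()):
        row = {"network": label}
        row.update(net.topology)
        rows.append(row)
    return pd.DataFrame(rows)
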