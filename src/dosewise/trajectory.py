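"""Root-anchored graph pseudotime and genotype timing statistics.

Pseudotime is the shortest-path geodesic distance from a chosen root cell
on a symmetric kNN graph of the embedding, min-max scaled to [0, 1].
Downstream: Moran's I dynamic-gene detection on the same graph, per-cluster
Kolmogorov-Smirnov shift tests between genotypes, binned density-difference
curves, and a Kullback-Leibler divergence timing test with a shuffled-
genotype permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import dijkstra
from sklearn.neighbors import kneighbors_graph

from ._utils import bh_adjust
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryModel:
    graph: sp.csr_matrix  # symmetric weighted kNN graph
    adjacency: sp.csr_matrix  # symmetric binary kNN adjacency
    root: str
    pseudotime: pd.Series  # scaled to [0, 1]; NaN = unreachable


def assign_pseudotime(embedding: pd.DataFrame, root: str, k: int = 15) -> TrajectoryModel:
    """Geodesic pseudotime from ``root`` on a symmetric kNN graph."""
    if root not in embedding.index:
        raise KeyError(f"root cell {root!r} not in embedding")
    coords = embedding.to_numpy(dtype=float)
    n = len(embedding)
    k_eff = min(k, n - 1)
    g = kneighbors_graph(coords, n_neighbors=k_eff, mode="distance")
    g = g.maximum(g.T)  # symmetrize
    adj = (g > 0).astype(float)
    adj = adj.maximum(adj.T)
    root_idx = embedding.index.get_loc(root)
    dist = dijkstra(g, directed=False, indices=root_idx)
    reachable = np.isfinite(dist)
    if not reachable.all():
        logger.warning(
            "%d cells unreachable from root; pseudotime set missing", (~reachable).sum()
        )
    pt = np.full(n, np.nan)
    span = dist[reachable].max()
    pt[reachable] = dist[reachable] / span if span > 0 else 0.0
    return TrajectoryModel(
        graph=sp.csr_matrix(g),
        adjacency=sp.csr_matrix(adj),
        root=root,
        pseudotime=pd.Series(pt, index=embedding.index, name="pseudotime"),
    )


# ---------------------------------------------------------------------------
# Moran's I dynamic-gene test
# ---------------------------------------------------------------------------


def morans_i_test(expr: np.ndarray | pd.DataFrame, weights: sp.spmatrix, fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene Moran's I with the randomization-assumption normal test.

    One-sided (positive autocorrelation) p-values; genes at q < ``fdr`` are
    flagged dynamic. Constant genes get missing statistics.
    """
    if isinstance(expr, pd.DataFrame):
        genes = expr.columns
        Xm = expr.to_numpy(dtype=float)
    else:
        Xm = np.asarray(expr, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        genes = pd.RangeIndex(Xm.shape[1])
    W = sp.csr_matrix(weights, dtype=float)
    n = Xm.shape[0]
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match expression rows")
    w_sum = W.sum()
    Z = Xm - Xm.mean(axis=0)
    den = (Z**2).sum(axis=0)
    constant = den == 0
    num = (Z * (W @ Z)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = (n / w_sum) * num / den

    # randomization-assumption moments (standard closed forms)
    e_i = -1.0 / (n - 1)
    Wd = W.toarray()
    s1 = 0.5 * ((Wd + Wd.T) ** 2).sum()
    s2 = ((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = n * (Z**4).sum(axis=0) / np.maximum(den, 1e-300) ** 2
    w2 = w_sum**2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * w2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * w2)
    ) / ((n - 1) * (n - 2) * (n - 3) * w2) - e_i**2
    var = np.maximum(var, 1e-300)
    z = (I - e_i) / np.sqrt(var)
    p = scipy.stats.norm.sf(z)
    I[constant] = np.nan
    z[constant] = np.nan
    p[constant] = np.nan
    q = bh_adjust(p)
    dynamic = np.where(np.isnan(q), False, q < fdr)
    return pd.DataFrame(
        {"morans_i": I, "zscore": z, "pvalue": p, "qvalue": q, "dynamic": dynamic},
        index=genes,
    )


# ---------------------------------------------------------------------------
# KS shift tests and density differences
# ---------------------------------------------------------------------------


def ks_shift_test(
    pseudotime: pd.Series,
    cells: pd.DataFrame,
    pairs: list[tuple[int, int]] | None = None,
    by: str = "cluster",
    min_cells: int = 20,
) -> pd.DataFrame:
    """Two-sided two-sample KS tests on pseudotime, per (cluster, dose pair).

    BH adjustment is applied across all (cluster, pair) tests performed.
    """
    pairs = pairs or [(2, 1), (2, 0)]
    cells = cells.loc[pseudotime.index]
    ok = pseudotime.notna()
    rows = []
    for cl, sub in cells[ok].groupby(by):
        pt = pseudotime.loc[sub.index]
        for a, b in pairs:
            x = pt[sub["dose"] == a]
            y = pt[sub["dose"] == b]
            if len(x) < min_cells or len(y) < min_cells:
                logger.warning("%s=%s pair (%s,%s): < %d cells per arm; skipped", by, cl, a, b, min_cells)
                continue
            res = scipy.stats.ks_2samp(x, y, alternative="two-sided")
            rows.append(
                {
                    by: cl,
                    "dose_a": a,
                    "dose_b": b,
                    "n_a": len(x),
                    "n_b": len(y),
                    "D": res.statistic,
                    "median_shift": float(np.median(y) - np.median(x)),
                    "pvalue": res.pvalue,
                }
            )
    out = pd.DataFrame(rows, columns=[by, "dose_a", "dose_b", "n_a", "n_b", "D", "median_shift", "pvalue"])
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


def pseudotime_density_diff(
    pseudotime: pd.Series,
    doses: pd.Series,
    bins: int = 10,
    wt_dose: int = 2,
) -> pd.DataFrame:
    """Per-bin relative difference of each mutant dose's density vs WT.

    Entry = (frac_mutant - frac_WT) / frac_WT; bins where frac_WT = 0 are
    missing. Entries are bounded below by -1.
    """
    doses = doses.loc[pseudotime.index]
    ok = pseudotime.notna()
    pt, ds = pseudotime[ok], doses[ok]
    if not (ds == wt_dose).any():
        raise ValueError("no WT cells present")
    edges = np.linspace(0.0, 1.0, bins + 1)
    lo, hi = float(pt.min()), float(pt.max())
    if lo < 0 or hi > 1:  # unscaled pseudotime: bin over observed range
        edges = np.linspace(lo, hi, bins + 1)
    wt_frac, _ = np.histogram(pt[ds == wt_dose], bins=edges)
    wt_frac = wt_frac / wt_frac.sum()
    out = {"bin_lo": edges[:-1], "bin_hi": edges[1:], "wt_frac": wt_frac}
    for d in sorted(ds.unique()):
        if d == wt_dose:
            continue
        frac, _ = np.histogram(pt[ds == d], bins=edges)
        frac = frac / frac.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(wt_frac > 0, (frac - wt_frac) / wt_frac, np.nan)
        out[f"dose{d}_rel_diff"] = rel
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# KL-divergence timing test
# ---------------------------------------------------------------------------


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(p || q) in nats for distributions summing to 1."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


@dataclass
class TimingResult:
    table: pd.DataFrame  # per gene: kl, pvalue, qvalue
    profiles_wt: pd.DataFrame  # genes x bins, each row sums to 1
    profiles_mut: pd.DataFrame
    bin_edges: np.ndarray


def _binned_profiles(
    E: np.ndarray, bin_idx: np.ndarray, arm_mask: np.ndarray, n_bins: int, eps: float
) -> np.ndarray:
    """Mean expression per bin for one arm -> normalized profiles (genes x bins)."""
    sums = np.zeros((n_bins, E.shape[1]))
    cnts = np.zeros(n_bins)
    np.add.at(sums, bin_idx[arm_mask], E[arm_mask])
    np.add.at(cnts, bin_idx[arm_mask], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts[:, None] > 0, sums / np.maximum(cnts, 1.0)[:, None], 0.0)
    prof = means.T + eps
    return prof / prof.sum(axis=1, keepdims=True)


def kl_timing_test(
    norm: NormalizedMatrix,
    pseudotime: pd.Series,
    doses: pd.Series,
    genes: list[str],
    mutant_dose: int = 0,
    wt_dose: int = 2,
    bins: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    eps: float = 1e-6,
    min_cells_per_bin: int = 10,
) -> TimingResult:
    """Permutation test of pseudotemporal expression-profile divergence.

    Per gene: WT and mutant mean-expression profiles over WT-quantile
    pseudotime bins, pseudocount ``eps``, renormalized; statistic is
    D_KL(WT || mutant) in nats. The null shuffles genotype labels across
    cells (one shared permutation set for all genes); p = (1 + #{null >=
    observed}) / (1 + n_perm), BH across genes.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in norm.genes]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    doses = doses.loc[norm.cells]
    pt = pseudotime.loc[norm.cells]
    use = pt.notna() & doses.isin([wt_dose, mutant_dose])
    if not (doses[use] == wt_dose).any() or not (doses[use] == mutant_dose).any():
        raise ValueError("both genotype arms must be nonempty")
    cell_idx = np.flatnonzero(use.to_numpy())
    gene_idx = norm.genes.get_indexer(genes)
    E = norm.matrix[np.ix_(cell_idx, gene_idx)]
    ptv = pt.to_numpy()[cell_idx]
    is_wt = (doses.to_numpy()[cell_idx] == wt_dose)

    # quantile bins on pooled WT pseudotime -> near-uniform WT support
    qs = np.quantile(ptv[is_wt], np.linspace(0, 1, bins + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < bins:
        logger.info("collapsed %d duplicate bin edges", bins - (len(edges) - 1))
    n_bins = len(edges) - 1
    bin_idx = np.clip(np.searchsorted(edges, ptv, side="right") - 1, 0, n_bins - 1)

    # merge bins with too few cells in either observed arm into their left
    # neighbor (a bin empty in one arm has an undefined profile entry;
    # near-empty bins make the observed statistic noisier than its
    # permutation null, so they are pooled too)
    while n_bins > 1:
        counts_wt = np.bincount(bin_idx[is_wt], minlength=n_bins)
        counts_mut = np.bincount(bin_idx[~is_wt], minlength=n_bins)
        thin = (counts_wt < min_cells_per_bin) | (counts_mut < min_cells_per_bin)
        if not thin.any():
            break
        b = int(np.flatnonzero(thin)[-1])
        target = b - 1 if b > 0 else 1
        logger.info("merging under-occupied bin %d into %d", b, target)
        bin_idx = np.where(bin_idx == b, target, bin_idx)
        bin_idx = np.where(bin_idx > b, bin_idx - 1, bin_idx)
        n_bins -= 1

    P = _binned_profiles(E, bin_idx, is_wt, n_bins, eps)
    Q = _binned_profiles(E, bin_idx, ~is_wt, n_bins, eps)
    obs = np.sum(P * np.log(P / Q), axis=1)

    rng = np.random.default_rng(seed)
    n_wt = int(is_wt.sum())
    exceed = np.zeros(len(genes))
    for _ in range(n_perm):
        perm = rng.permutation(len(cell_idx))
        mask = np.zeros(len(cell_idx), dtype=bool)
        mask[perm[:n_wt]] = True
        Pn = _binned_profiles(E, bin_idx, mask, n_bins, eps)
        Qn = _binned_profiles(E, bin_idx, ~mask, n_bins, eps)
        null = np.sum(Pn * np.log(Pn / Qn), axis=1)
        exceed += null >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    table = pd.DataFrame(
        {"kl": obs, "pvalue": pvals, "qvalue": bh_adjust(pvals)},
        index=pd.Index(genes, name="gene"),
    )
    return TimingResult(
        table=table,
        profiles_wt=pd.DataFrame(P, index=genes),
        profiles_mut=pd.DataFrame(Q, index=genes),
        bin_edges=edges,
    )
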