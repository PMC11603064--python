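"""Per-cell QC, normalization, mixing metric, cell-cycle scoring, markers."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors

from ._utils import bh_adjust
from .io import CountMatrix
from .simulate import MITO_PREFIX

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    umi_min: int = 800
    umi_max: int = 6000
    genes_min: int = 300
    genes_max: int = 3000
    mito_pct_max: float = 1.0  # percent
    log_ratio_min: float = 0.9  # log(genes)/log(UMIs), base-invariant

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not self.genes_min < self.genes_max:
            raise ValueError("genes_min must be < genes_max")


def apply_qc_filters(
    counts: CountMatrix,
    cells: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Filter cells on depth, detected genes, mito fraction and log-ratio.

    A cell is kept iff all rules pass; the report enumerates every violated
    rule per cell. Zero-depth cells are dropped with reason ``zero-depth``.
    """
    thr = thresholds or QCThresholds()
    umis = counts.umis_per_cell().astype(float)
    ngenes = counts.genes_per_cell().astype(float)
    mito_mask = np.asarray(counts.genes.str.startswith(mito_prefix))
    mito_counts = np.asarray(counts.matrix[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(umis > 0, 100.0 * mito_counts / umis, np.nan)
        log_ratio = np.where(
            (umis > 1) & (ngenes > 0), np.log(ngenes) / np.log(umis), np.nan
        )

    reasons: list[list[str]] = [[] for _ in range(len(umis))]
    zero = umis == 0
    checks = [
        (zero, "zero-depth"),
        (~zero & (umis < thr.umi_min), "umi-low"),
        (umis > thr.umi_max, "umi-high"),
        (~zero & (ngenes < thr.genes_min), "genes-low"),
        (ngenes > thr.genes_max, "genes-high"),
        (~zero & (mito_pct > thr.mito_pct_max), "mito-high"),
        (~zero & ~(log_ratio >= thr.log_ratio_min), "log-ratio"),
    ]
    for mask, label in checks:
        for i in np.flatnonzero(mask):
            reasons[i].append(label)
    keep = np.array([not r for r in reasons])

    report = pd.DataFrame(
        {
            "umis": umis.astype(int),
            "genes": ngenes.astype(int),
            "mito_pct": mito_pct,
            "log_ratio": log_ratio,
            "keep": keep,
            "reasons": [";".join(r) for r in reasons],
        },
        index=counts.cells,
    )
    filtered = counts.subset_cells(keep)
    return filtered, cells.loc[filtered.cells], report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """Cells x genes log-normalized expression with its provenance record."""

    matrix: np.ndarray
    cells: pd.Index
    genes: pd.Index
    scale_factor: float = 10000.0
    log_base: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cells, columns=self.genes)


def normalize_log(counts: CountMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """Depth-normalize to ``scale`` counts per cell, then log2(1 + x)."""
    depth = counts.umis_per_cell().astype(float)
    if (depth == 0).any():
        bad = counts.cells[depth == 0][:5].tolist()
        raise ValueError(f"zero-depth cells present (run QC first): {bad}")
    dense = counts.to_dense().astype(float)
    norm = np.log2(1.0 + dense / depth[:, None] * scale)
    return NormalizedMatrix(norm, counts.cells, counts.genes, scale_factor=scale, log_base=2.0)


# ---------------------------------------------------------------------------
# LISI mixing score
# ---------------------------------------------------------------------------


def _calibrate_kernel(d2: np.ndarray, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Gaussian kernel weights over one cell's neighbors, entropy-calibrated."""
    target = np.log(perplexity)
    lo, hi = 0.0, np.inf
    beta = 1.0
    p = None
    for _ in range(64):
        w = np.exp(-beta * d2)
        total = w.sum()
        if total <= 0:
            p = np.full(d2.shape, 1.0 / len(d2))
            break
        p = w / total
        h = -(p * np.log(np.maximum(p, 1e-300))).sum()
        if abs(h - target) < tol:
            break
        if h > target:
            lo = beta
            beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
    return p


def compute_lisi(
    embedding: np.ndarray | pd.DataFrame,
    labels,
    perplexity: int = 30,
) -> np.ndarray:
    """Local inverse Simpson's index per cell (1 = unmixed, #labels = mixed).

    Gaussian-kernel neighborhood probabilities over the 3*perplexity nearest
    neighbors, bandwidth calibrated per cell to the target perplexity.
    """
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim == 1:
        emb = emb[:, None]
    labels = np.asarray(labels)
    n = emb.shape[0]
    uniq, codes = np.unique(labels, return_inverse=True)
    if n < 2 or len(uniq) < 2:
        return np.ones(n)
    if n < 3 * perplexity:
        raise ValueError(f"need >= {3 * perplexity} cells for perplexity={perplexity}")
    k = min(3 * perplexity, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    scores = np.empty(n)
    n_labels = len(uniq)
    for i in range(n):
        p = _calibrate_kernel(dist[i] ** 2, perplexity)
        pk = np.bincount(codes[idx[i]], weights=p, minlength=n_labels)
        scores[i] = 1.0 / np.maximum((pk**2).sum(), 1.0 / n_labels)
    return scores


# ---------------------------------------------------------------------------
# cell-cycle scoring
# ---------------------------------------------------------------------------


@dataclass
class CellCycleScores:
    scores: pd.DataFrame  # columns: S_score, G2M_score, phase
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)


def _signature_score(
    expr: pd.DataFrame,
    gene_list: list[str],
    bins: np.ndarray,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    sig = [g for g in expr.columns if g in set(gene_list)]
    ctrl: set[str] = set()
    by_bin: dict[int, np.ndarray] = {}
    for b in np.unique(bins):
        by_bin[b] = expr.columns[bins == b].to_numpy()
    gene_bin = pd.Series(bins, index=expr.columns)
    for g in sig:
        pool = by_bin[gene_bin[g]]
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    ctrl -= set(sig)
    ctrl_cols = sorted(ctrl)
    sig_mean = expr[sig].mean(axis=1).to_numpy()
    ctrl_mean = expr[ctrl_cols].mean(axis=1).to_numpy() if ctrl_cols else 0.0
    return sig_mean - ctrl_mean


def score_cell_cycle(
    norm: NormalizedMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> CellCycleScores:
    """Signature minus expression-matched control score per cell, per phase.

    Phase is the argmax of (S, G2M) when either score is positive, else
    G1/G0.
    """
    expr = norm.to_frame()
    present_s = [g for g in s_genes if g in expr.columns]
    present_g2m = [g for g in g2m_genes if g in expr.columns]
    if len(present_s) < 5:
        raise ValueError(f"fewer than 5 S-phase genes found (got {len(present_s)})")
    if len(present_g2m) < 5:
        raise ValueError(f"fewer than 5 G2M-phase genes found (got {len(present_g2m)})")

    means = expr.mean(axis=0)
    # equal-frequency bins on mean expression; ties broken by gene label
    tie_order = np.lexsort((means.index.to_numpy(), means.to_numpy()))
    ranks = pd.Series(np.empty(len(means), dtype=int), index=means.index)
    ranks.iloc[tie_order] = np.arange(len(means))
    bins = (ranks.to_numpy() * n_bins // len(means)).astype(int)

    rng = np.random.default_rng(seed)
    s_score = _signature_score(expr, present_s, bins, n_ctrl, rng)
    g2m_score = _signature_score(expr, present_g2m, bins, n_ctrl, rng)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1/G0",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    scores = pd.DataFrame(
        {"S_score": s_score, "G2M_score": g2m_score, "phase": phase}, index=norm.cells
    )
    return CellCycleScores(scores, present_s, present_g2m)


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------


def find_markers(
    norm: NormalizedMatrix,
    clusters,
    logfc_thresh: float = 0.5,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection.

    Only genes passing the fold-change and detection-rate prefilters are
    tested; BH adjustment is applied within each cluster.
    """
    clusters = np.asarray(clusters)
    expr = norm.matrix
    detected = expr > 0
    uniq = pd.unique(clusters)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for cl in uniq:
        in_mask = clusters == cl
        if in_mask.sum() < 3:
            logger.warning("cluster %r has < 3 cells; skipped", cl)
            continue
        out_mask = ~in_mask
        if out_mask.sum() < 3:
            logger.warning("complement of cluster %r has < 3 cells; skipped", cl)
            continue
        mean_in = expr[in_mask].mean(axis=0)
        mean_out = expr[out_mask].mean(axis=0)
        lfc = mean_in - mean_out
        pct1 = detected[in_mask].mean(axis=0)
        pct2 = detected[out_mask].mean(axis=0)
        test = (lfc >= logfc_thresh) & (np.maximum(pct1, pct2) >= min_pct)
        pvals = np.full(expr.shape[1], np.nan)
        for j in np.flatnonzero(test):
            x, y = expr[in_mask, j], expr[out_mask, j]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                pvals[j] = 1.0
            else:
                pvals[j] = scipy.stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic"
                ).pvalue
        qvals = bh_adjust(pvals)
        for j in np.flatnonzero(test):
            rows.append(
                {
                    "gene": norm.genes[j],
                    "cluster": cl,
                    "log2fc": lfc[j],
                    "pct.1": pct1[j],
                    "pct.2": pct2[j],
                    "pvalue": pvals[j],
                    "qvalue": qvals[j],
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "cluster", "log2fc", "pct.1", "pct.2", "pvalue", "qvalue"]
    )
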