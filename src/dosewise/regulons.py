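"""Rank-based regulon activity (recovery AUC), specificity, and differences.

Regulon definitions (TF -> target set) are inputs; network inference is out
of scope. Activity per cell is the area under the recovery curve of regulon
genes within the top ``top_frac`` of that cell's gene ranking, normalized so
a set fully inside the window scores 1. Specificity of a regulon for a
cluster is 1 minus the base-2 Jensen-Shannon divergence between the
regulon's normalized cell-activity distribution and the cluster indicator
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import bh_adjust
from .io import CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RegulonActivity:
    auc: pd.DataFrame  # cells x regulons, in [0, 1]
    top_frac: float
    regulons: GeneSetCollection
    low_coverage: list[str]  # regulons with < 5 detected genes


def recovery_auc(ranks: np.ndarray, window: int, set_size: int) -> float:
    """Brute-force-equivalent closed form of the normalized recovery AUC.

    ``ranks`` are the 1-based ranks of the set's genes in one cell.
    """
    hits = np.clip(window - np.asarray(ranks, dtype=float) + 1.0, 0.0, None).sum()
    m = set_size
    max_area = window * m - m * (m - 1) / 2.0 if m <= window else window * (window + 1) / 2.0
    return float(hits / max_area) if max_area > 0 else np.nan


def aucell_scores(
    counts: CountMatrix,
    regulons: GeneSetCollection,
    top_frac: float = 0.05,
    seed: int = 0,
) -> RegulonActivity:
    """Per-cell recovery-curve AUC for each regulon (top-``top_frac`` window).

    Ranking is by descending count; ties are broken by a seeded uniform
    jitter far below the count scale, so scores depend only on ranks.
    """
    G = len(counts.genes)
    window = int(np.ceil(top_frac * G))
    rng = np.random.default_rng(seed)
    dense = counts.to_dense().astype(float)
    jitter = rng.uniform(0.0, 1e-9, size=dense.shape)
    keyed = dense + jitter
    order = np.argsort(-keyed, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(dense.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, G + 1)[None, :]

    gene_pos = {g: i for i, g in enumerate(counts.genes)}
    cols = {}
    low = []
    for name, genes in regulons.sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            logger.warning("regulon %r has no detected genes; scores missing", name)
            cols[name] = np.full(dense.shape[0], np.nan)
            continue
        if len(idx) < 5:
            low.append(name)
        m = len(idx)
        max_area = (
            window * m - m * (m - 1) / 2.0 if m <= window else window * (window + 1) / 2.0
        )
        r = ranks[:, idx].astype(float)
        hits = np.clip(window - r + 1.0, 0.0, None).sum(axis=1)
        cols[name] = hits / max_area
    auc = pd.DataFrame(cols, index=counts.cells)
    return RegulonActivity(auc=auc, top_frac=top_frac, regulons=regulons, low_coverage=low)


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions (in [0,1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0

    def _kl2(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl2(p, m) + 0.5 * _kl2(q, m)


def regulon_specificity(activity: RegulonActivity, clusters) -> pd.DataFrame:
    """RSS = 1 - JSD(normalized activity, cluster indicator), per pair."""
    clusters = pd.Series(np.asarray(clusters), index=activity.auc.index)
    levels = sorted(clusters.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 clusters")
    out = pd.DataFrame(index=pd.Index(activity.auc.columns, name="regulon"), columns=levels, dtype=float)
    for name in activity.auc.columns:
        a = activity.auc[name].to_numpy(dtype=float)
        total = np.nansum(a)
        if not np.isfinite(total) or total <= 0:
            out.loc[name] = np.nan
            continue
        p = np.nan_to_num(a) / total
        for cl in levels:
            ind = (clusters == cl).to_numpy(dtype=float)
            q = ind / ind.sum()
            out.loc[name, cl] = 1.0 - jensen_shannon_divergence(p, q)
    return out


def specific_regulons(rss: pd.DataFrame, n_mads: float = 2.0) -> list[str]:
    """Regulons with cell-type-specific activity (max RSS above the herd).

    Convention: max RSS exceeding the across-regulon median by at least
    ``n_mads`` median absolute deviations.
    """
    top = rss.max(axis=1).dropna()
    med = top.median()
    mad = (top - med).abs().median()
    cut = med + n_mads * mad
    return list(top.index[top >= cut])


def differential_regulons(
    activity: RegulonActivity,
    cells: pd.DataFrame,
    dose_a: int = 2,
    dose_b: int = 0,
    min_cells: int = 20,
    effect_floor: float = 0.01,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum on per-cell AUCs per (regulon, cluster).

    BH across all tests; flagged iff q < fdr and |mean AUC difference| >=
    ``effect_floor``.
    """
    cells = cells.loc[activity.auc.index]
    rows = []
    for cl, sub in cells.groupby("cluster"):
        a_cells = sub.index[sub["dose"] == dose_a]
        b_cells = sub.index[sub["dose"] == dose_b]
        if len(a_cells) < min_cells or len(b_cells) < min_cells:
            logger.warning("cluster %s: undersized genotype arms; skipped", cl)
            continue
        for name in activity.auc.columns:
            x = activity.auc.loc[a_cells, name].to_numpy()
            y = activity.auc.loc[b_cells, name].to_numpy()
            if np.isnan(x).all() or np.isnan(y).all():
                continue
            delta = float(np.nanmean(y) - np.nanmean(x))
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0
            else:
                p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            rows.append(
                {"regulon": name, "cluster": cl, "delta_auc": delta, "pvalue": float(p)}
            )
    out = pd.DataFrame(rows, columns=["regulon", "cluster", "delta_auc", "pvalue"])
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    out["flagged"] = (out["qvalue"] < fdr) & (out["delta_auc"].abs() >= effect_floor)
    return out


def flagged_percent(n_flagged: int, n_specific: int) -> int:
    """Share of specific regulons flagged, rounded to the nearest percent."""
    if n_specific <= 0:
        raise ValueError("n_specific must be > 0")
    return round(100.0 * n_flagged / n_specific)
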