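"""Gene-set over-representation, resampling enrichment, 2x2 association."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import bh_adjust, round_sigfigs
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_ora(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation, BH across sets.

    ``universe`` is the caller-supplied background (e.g. all genes expressed
    in the cluster); sets are intersected with it first. p = P(X >= k)
    under Hypergeometric(N, K, n).
    """
    uni = set(universe)
    offenders = [g for g in query if g not in uni]
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:5]}")
    qset = set(query)
    N, n = len(uni), len(qset)
    rows = []
    for name, genes in sets.sets.items():
        members = [g for g in genes if g in uni]
        K = len(members)
        hits = sorted(qset.intersection(members))
        k = len(hits)
        if k < min_overlap or K == 0:
            continue
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        expected = K * n / N
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe": N,
                "fold": k / expected if expected > 0 else np.nan,
                "pvalue": p,
                "genes": ";".join(hits),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe", "fold", "pvalue", "genes"]
    )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


@dataclass
class ResampleEnrichment:
    """Expression-matched resampling enrichment result.

    ``fold`` is observed / median(null), the paper-facing convention;
    ``fold_display`` rounds it to two significant figures.
    """

    observed: int
    null_overlaps: np.ndarray
    draw_size: int
    pool_size: int
    pvalue: float = field(init=False)
    median_null: float = field(init=False)

    def __post_init__(self) -> None:
        null = np.asarray(self.null_overlaps)
        self.median_null = float(np.median(null)) if null.size else np.nan
        B = null.size
        self.pvalue = float((1.0 + (null >= self.observed).sum()) / (1.0 + B)) if B else np.nan

    @property
    def fold(self) -> float:
        if not self.median_null:
            return np.nan
        return self.observed / self.median_null

    @property
    def fold_display(self) -> float:
        return round_sigfigs(self.fold, 2)


def resample_enrichment(
    query: list[str],
    ranked_genes: list[str],
    target: list[str],
    draw_size: int,
    top_frac: float = 0.5,
    n_draws: int = 1000,
    seed: int = 0,
) -> ResampleEnrichment:
    """Overlap with ``target`` versus draws from the top-expressed pool.

    ``ranked_genes`` must be ordered by decreasing expression; the null pool
    is its top ``top_frac`` fraction. Each of ``n_draws`` draws samples
    ``draw_size`` genes without replacement and records the target overlap.
    """
    pool = np.asarray(ranked_genes[: int(np.ceil(top_frac * len(ranked_genes)))])
    if draw_size > len(pool):
        raise ValueError(f"draw_size {draw_size} exceeds pool size {len(pool)}")
    tset = set(target)
    if not tset.intersection(pool):
        logger.warning("target set is disjoint from the sampling pool; fold is flagged")
    observed = len(set(query).intersection(tset))
    rng = np.random.default_rng(seed)
    in_target = np.isin(pool, list(tset))
    nulls = np.empty(n_draws, dtype=int)
    for b in range(n_draws):
        take = rng.choice(len(pool), size=draw_size, replace=False)
        nulls[b] = int(in_target[take].sum())
    return ResampleEnrichment(
        observed=observed, null_overlaps=nulls, draw_size=draw_size, pool_size=len(pool)
    )


def overlap_percent(k: int, n: int, ndigits: int = 1) -> float:
    """Overlap as a percentage of the query, rounded for reporting."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return round(100.0 * k / n, ndigits)


def chisq_yates(table) -> tuple[float, int, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    Returns (chi2, df=1, p). The statistic is clamped to 0 when
    |ad - bc| <= N/2; any zero margin gives (0, 1, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    N = t.sum()
    if N == 0:
        raise ValueError("empty table")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        return 0.0, 1, 1.0
    diff = abs(a * d - b * c)
    if diff <= N / 2.0:
        return 0.0, 1, 1.0
    chi2 = N * (diff - N / 2.0) ** 2 / np.prod(margins)
    return float(chi2), 1, float(scipy.stats.chi2.sf(chi2, 1))


def fisher_exact(table, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p). Zero margins give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if any(m == 0 for m in margins):
        return np.nan, 1.0
    orr = scipy.stats.contingency.odds_ratio(t, kind="conditional").statistic
    p = scipy.stats.fisher_exact(t, alternative=alternative)[1]
    return float(orr), float(p)
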