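"""Per-sample cluster/phase proportions with moderated (empirical-Bayes) tests.

Proportions are arcsin-sqrt transformed, fit with a per-cluster linear model
across samples, and the residual variances are shrunk with a scaled
inverse-chi-square prior whose parameters are estimated by moment matching
on the log variances (limma-style). Two groups give a moderated t, three or
more a moderated F; BH across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import polygamma

from ._utils import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ProportionTable:
    proportions: pd.DataFrame  # samples x clusters, rows sum to 1
    totals: pd.Series
    transform: str = "none"


def proportions_table(cells: pd.DataFrame, by: str = "cluster") -> ProportionTable:
    """Per-sample proportions of each cluster (or any label column)."""
    for col in ("sample", by):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    tab = pd.crosstab(cells["sample"], cells[by])
    totals = tab.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("dropping empty samples: %s", list(totals.index[empty]))
        tab = tab.loc[~empty]
        totals = totals.loc[~empty]
    props = tab.div(totals, axis=0)
    return ProportionTable(proportions=props, totals=totals)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, limma's algorithm)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of sample variances.

    Fits the scaled inverse-chi-square prior (d0, s0^2) by moment matching
    on log variances; returns (posterior variances, d0, s0^2). ``d0 = 0``
    means no shrinkage (posterior = sample variances).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.nanmean(s2)) if ok.any() else 0.0
    z = np.log(s2[ok])
    e_z = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    mean_e = e_z.mean()
    var_e = e_z.var(ddof=1) - polygamma(1, df / 2.0)
    if var_e > 0:
        d0 = 2.0 * _trigamma_inverse(float(var_e))
        s02 = float(np.exp(mean_e + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(mean_e))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    post[~ok] = s02 if np.isfinite(s02) else np.nan
    return post, float(d0), s02


def moderated_prop_test(
    props: ProportionTable,
    groups: pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t (2 groups) or moderated F (>= 3 groups) per cluster.

    ``groups`` maps sample -> group label (e.g. genotype dose).
    ``prior_df = 0`` disables shrinkage (ordinary t/F); ``None`` estimates
    the prior from the data.
    """
    groups = pd.Series(groups).loc[props.proportions.index].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with a single sample: {list(small.index)}")

    y = np.arcsin(np.sqrt(props.proportions.to_numpy(dtype=float)))  # samples x clusters
    n, k = len(groups), len(levels)
    codes = groups.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    X = np.zeros((n, k))
    X[np.arange(n), codes] = 1.0  # cell-means coding
    df_resid = n - k

    # per-cluster OLS residual variances and group means
    means = np.stack([y[codes == i].mean(axis=0) for i in range(k)])  # k x clusters
    resid = y - means[codes]
    s2 = (resid**2).sum(axis=0) / df_resid

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            s2_post = s2.copy()
        else:
            _, _, s02 = squeeze_variances(s2, df_resid)
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
    df_total = df_resid + (d0 if np.isfinite(d0) else np.inf)

    rows = []
    counts_per_group = np.bincount(codes, minlength=k).astype(float)
    for j, cluster in enumerate(props.proportions.columns):
        if k == 2:
            diff = means[1, j] - means[0, j]
            varc = s2_post[j] * (1.0 / counts_per_group[0] + 1.0 / counts_per_group[1])
            if varc == 0:
                stat = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                stat = diff / np.sqrt(varc)
                p = (
                    2.0 * scipy.stats.t.sf(abs(stat), df_total)
                    if np.isfinite(df_total)
                    else 2.0 * scipy.stats.norm.sf(abs(stat))
                )
            rows.append({"cluster": cluster, "statistic": stat, "effect": diff, "pvalue": p})
        else:
            grand = y[:, j].mean()
            ss_between = float(np.sum(counts_per_group * (means[:, j] - grand) ** 2))
            ms_between = ss_between / (k - 1)
            if s2_post[j] == 0:
                stat = 0.0 if ms_between == 0 else np.inf
                p = 1.0 if ms_between == 0 else 0.0
            else:
                stat = ms_between / s2_post[j]
                p = (
                    scipy.stats.f.sf(stat, k - 1, df_total)
                    if np.isfinite(df_total)
                    else scipy.stats.chi2.sf(stat * (k - 1), k - 1)
                )
            rows.append({"cluster": cluster, "statistic": stat, "effect": ms_between, "pvalue": p})
    out = pd.DataFrame(rows).set_index("cluster")
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
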