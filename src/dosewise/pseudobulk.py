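"""Pseudobulk negative-binomial differential expression.

Workflow: sum counts per (cluster, sample), normalize with median-of-ratios
size factors, estimate gene-wise NB dispersions (method-of-moments start,
profile-likelihood refinement, shrinkage toward a mean-dispersion trend),
fit NB GLMs with a log link and size-factor offsets, then test with pairwise
Wald contrasts or nested likelihood-ratio tests. The ordinal gene-dose model
codes the number of functional alleles (0 = KO, 1 = Het, 2 = WT) as a
numeric covariate, so the dose LRT has one degree of freedom.

Coefficients are reported on the log2 scale; fold-change thresholds apply to
unshrunk MLEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.special import gammaln

from ._utils import bh_adjust, stable_label_seed
from .io import CountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
ALPHA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# aggregation and normalization
# ---------------------------------------------------------------------------


@dataclass
class PseudobulkTable:
    """(cluster, sample) x gene integer sums plus sample covariates."""

    counts: pd.DataFrame  # genes x columns, integer
    coldata: pd.DataFrame  # per column: cluster, sample, dose, n_cells, ...
    size_factors: pd.Series | None = None
    dispersions: pd.Series | None = None

    def columns_for_cluster(self, cluster) -> pd.Index:
        return self.coldata.index[self.coldata["cluster"] == cluster]


def aggregate_pseudobulk(counts: CountMatrix, cells: pd.DataFrame) -> PseudobulkTable:
    """Sum single-cell counts within each (cluster, sample) combination."""
    for col in ("cluster", "sample"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    cells = cells.loc[counts.cells]
    key = cells["cluster"].astype(str) + "|" + cells["sample"].astype(str)
    uniq, codes = np.unique(key.to_numpy(), return_inverse=True)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(len(uniq), len(codes)),
    )
    sums = np.asarray((ind @ counts.matrix).todense()).astype(np.int64)  # groups x genes
    pb = pd.DataFrame(sums.T, index=counts.genes, columns=uniq)
    meta_rows = []
    for i, k in enumerate(uniq):
        cluster, sample = k.split("|", 1)
        members = cells.index[codes == i]
        row = {"cluster": cluster, "sample": sample, "n_cells": len(members)}
        for cov in ("dose", "sex", "age"):
            if cov in cells.columns:
                row[cov] = cells.loc[members[0], cov]
        meta_rows.append(row)
    coldata = pd.DataFrame(meta_rows, index=pd.Index(uniq, name="column"))
    return PseudobulkTable(pb, coldata)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every column enter the reference.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all columns; consider the "
            "positive-counts-only fallback flag"
        )
    logs = np.log(mat[all_pos])
    log_geomean = logs.mean(axis=1)
    s = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB dispersion estimation
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; y, mu are genes x samples, alpha per gene."""
    a = np.maximum(alpha, ALPHA_FLOOR)[:, None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=1)


def _cr_adjustment(mu: np.ndarray, alpha: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cox-Reid adjustment term -0.5 log det(X'WX) per gene.

    Removes the downward bias of the dispersion MLE when the means are
    estimated from the same data.
    """
    a = np.maximum(alpha, ALPHA_FLOOR)
    W = mu / (1.0 + a[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + np.eye(X.shape[1])[None] * 1e-12
    sign, logdet = np.linalg.slogdet(XtWX)
    return -0.5 * logdet


def _fit_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Fisher-scoring NB GLM fit for all genes at once.

    Returns natural-log-scale (beta, covariance, converged flags);
    Y is genes x samples, X is samples x p.
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialize intercept-ish start from mean expression
    mean0 = np.maximum(Y.mean(axis=1), 0.1)
    sol, *_ = np.linalg.lstsq(X, np.tile(np.log(mean0)[:, None], (1, n)).T - offset[:, None], rcond=None)
    beta = sol.T
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    a = np.maximum(alpha, ALPHA_FLOOR)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        denom = 1.0 + a[idx, None] * mu
        W = mu / denom
        score = (Y[idx] - mu) / denom  # dl/deta
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
        XtS = np.einsum("ni,gn->gi", X, score)
        XtWX += np.eye(p)[None] * 1e-10
        try:
            delta = np.linalg.solve(XtWX, XtS[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(m, v, rcond=None)[0] for m, v in zip(XtWX, XtS)])
        delta = np.clip(delta, -5.0, 5.0)
        beta[idx] += delta
        done = np.abs(delta).max(axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    eta = np.clip(beta @ X.T + offset[None, :], -50.0, 50.0)
    mu = np.exp(eta)
    W = mu / (1.0 + a[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + np.eye(p)[None] * 1e-12
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: np.ndarray | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Gene-wise NB dispersion (variance = mu + alpha mu^2).

    Method-of-moments start, profile-likelihood maximization given fitted
    means, then log-scale shrinkage toward a trend log-linear in 1/mean.
    Genes at the likelihood boundary stay at the floor; all-zero genes are
    NaN and excluded from testing.
    """
    Y = counts.to_numpy(dtype=float)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    G, n = Y.shape
    if n < 2:
        raise ValueError("need >= 2 pseudobulk columns")
    norm = Y / s[None, :]
    base_mean = norm.mean(axis=1)
    nonzero = base_mean > 0
    alpha = np.full(G, np.nan)
    if not nonzero.any():
        return pd.Series(alpha, index=counts.index, name="dispersion")

    Yn = Y[nonzero]
    # method-of-moments on normalized counts
    v = norm[nonzero].var(axis=1, ddof=1)
    m = base_mean[nonzero]
    mom = np.clip((v - m) / np.maximum(m, 1e-12) ** 2, ALPHA_FLOOR, 10.0)

    # fitted means under the design (or intercept-only)
    X = design if design is not None else np.ones((n, 1))
    offset = np.log(s)
    beta, _, _ = _fit_glm_batch(Yn, X, offset, mom)
    mu = np.exp(np.clip(beta @ X.T + offset[None, :], -50.0, 50.0))

    # Cox-Reid adjusted profile likelihood over a log-spaced alpha grid,
    # means held fixed
    def _apl(a_vec: np.ndarray) -> np.ndarray:
        return _nb_loglik(Yn, mu, a_vec) + _cr_adjustment(mu, a_vec, X)

    grid = np.concatenate([[ALPHA_FLOOR], np.exp(np.linspace(np.log(1e-6), np.log(50.0), 120))])
    ll = np.stack([_apl(np.full(Yn.shape[0], a)) for a in grid], axis=1)
    best = np.argmax(ll, axis=1)
    alpha_mle = grid[best]

    # local refinement: golden-section between neighboring grid points
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]
    for _ in range(25):
        m1 = np.exp(np.log(lo) + 0.382 * (np.log(hi) - np.log(lo)))
        m2 = np.exp(np.log(lo) + 0.618 * (np.log(hi) - np.log(lo)))
        l1 = _apl(m1)
        l2 = _apl(m2)
        take1 = l1 >= l2
        hi = np.where(take1, m2, hi)
        lo = np.where(take1, lo, m1)
    refined = np.exp((np.log(lo) + np.log(hi)) / 2.0)
    interior = alpha_mle > grid[1]
    alpha_mle = np.where(interior, refined, alpha_mle)

    # trend: log(alpha) ~ a + b / mean, fit on interior genes
    fit_mask = alpha_mle > 10 * ALPHA_FLOOR
    alpha_final = alpha_mle.copy()
    if fit_mask.sum() >= 10:
        A = np.column_stack([np.ones(fit_mask.sum()), 1.0 / m[fit_mask]])
        coef, *_ = np.linalg.lstsq(A, np.log(alpha_mle[fit_mask]), rcond=None)
        trend = np.exp(coef[0] + coef[1] / m)
        trend = np.clip(trend, ALPHA_FLOOR, 50.0)
        alpha_final = np.where(
            fit_mask,
            np.exp(
                (1 - shrink_weight) * np.log(alpha_mle) + shrink_weight * np.log(trend)
            ),
            alpha_mle,
        )
    alpha_final = np.maximum(alpha_final, ALPHA_FLOOR)
    alpha[nonzero] = alpha_final
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# GLM fitting and tests
# ---------------------------------------------------------------------------


@dataclass
class NBFit:
    """Batch NB GLM fit; beta/cov are on the log2 scale."""

    beta: pd.DataFrame  # genes x coefficients
    cov: np.ndarray  # genes x p x p (log2 scale)
    loglik: pd.Series
    converged: pd.Series
    design: np.ndarray
    coef_names: list[str]


def fit_nb_glm(
    counts: pd.DataFrame,
    design: np.ndarray,
    size_factors: pd.Series,
    dispersions: pd.Series,
    coef_names: list[str] | None = None,
) -> NBFit:
    """Fit one NB GLM per gene with log link and log size-factor offsets."""
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if X.shape[0] != counts.shape[1]:
        raise ValueError("design rows must match pseudobulk columns")
    Y = counts.to_numpy(dtype=float)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)
    usable = np.isfinite(alpha)
    beta = np.full((counts.shape[0], X.shape[1]), np.nan)
    cov = np.full((counts.shape[0], X.shape[1], X.shape[1]), np.nan)
    ll = np.full(counts.shape[0], np.nan)
    conv = np.zeros(counts.shape[0], dtype=bool)
    if usable.any():
        b, c, cv = _fit_glm_batch(Y[usable], X, np.log(s), alpha[usable])
        mu = np.exp(np.clip(b @ X.T + np.log(s)[None, :], -50.0, 50.0))
        ll[usable] = _nb_loglik(Y[usable], mu, alpha[usable])
        beta[usable] = b / LN2
        cov[usable] = c / LN2**2
        conv[usable] = cv
    names = coef_names or [f"b{i}" for i in range(X.shape[1])]
    return NBFit(
        beta=pd.DataFrame(beta, index=counts.index, columns=names),
        cov=cov,
        loglik=pd.Series(ll, index=counts.index, name="loglik"),
        converged=pd.Series(conv, index=counts.index, name="converged"),
        design=X,
        coef_names=names,
    )


def wald_test(fit: NBFit, contrast) -> pd.DataFrame:
    """Two-sided Wald z-test of a single contrast c'beta = 0."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.coef_names),):
        raise ValueError(
            f"contrast length {c.shape} does not match {len(fit.coef_names)} coefficients"
        )
    est = fit.beta.to_numpy() @ c
    var = np.einsum("i,gij,j->g", c, fit.cov, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var)
        z = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.nan))
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    bad = ~fit.converged.to_numpy() | ~np.isfinite(z)
    z = np.where(bad, np.nan, z)
    p = np.where(bad, np.nan, p)
    return pd.DataFrame(
        {"log2fc": est, "se": se, "stat": z, "pvalue": p}, index=fit.beta.index
    )


def lrt_test(full: NBFit, reduced: NBFit) -> pd.DataFrame:
    """Likelihood-ratio test of nested designs; same dispersions in both."""
    Xf, Xr = full.design, reduced.design
    # nestedness: every reduced column must lie in the span of the full design
    proj, *_ = np.linalg.lstsq(Xf, Xr, rcond=None)
    if not np.allclose(Xf @ proj, Xr, atol=1e-8):
        raise ValueError("reduced design is not nested in the full design")
    df = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr)
    lam = 2.0 * (full.loglik - reduced.loglik)
    lam = lam.clip(lower=0.0)
    # df = 0 (identical designs) degenerates to lambda = 0, p = 1
    p = scipy.stats.chi2.sf(lam, df) if df > 0 else np.ones(len(lam))
    bad = ~(full.converged & reduced.converged)
    lam[bad] = np.nan
    p[bad.to_numpy()] = np.nan
    return pd.DataFrame({"stat": lam, "df": df, "pvalue": p}, index=full.beta.index)


# ---------------------------------------------------------------------------
# design construction, DEG calling, classification
# ---------------------------------------------------------------------------


def design_matrix(coldata: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build an intercept-plus-terms design from pseudobulk column metadata.

    ``dose`` is numeric (ordinal alleles); other covariates are treatment-
    coded factors. ``a:b`` denotes an interaction of the coded columns.
    """
    cols: list[np.ndarray] = [np.ones(len(coldata))]
    names: list[str] = ["intercept"]

    def coded(term: str) -> tuple[list[np.ndarray], list[str]]:
        if term == "dose":
            return [coldata["dose"].to_numpy(dtype=float)], ["dose"]
        values = coldata[term].astype(str)
        levels = sorted(values.unique())
        out, nm = [], []
        for lev in levels[1:]:
            out.append((values == lev).to_numpy(dtype=float))
            nm.append(f"{term}[{lev}]")
        return out, nm

    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            ca, na = coded(a)
            cb, nb = coded(b)
            for va, la in zip(ca, na):
                for vb, lb in zip(cb, nb):
                    cols.append(va * vb)
                    names.append(f"{la}:{lb}")
        else:
            c, n = coded(term)
            cols.extend(c)
            names.extend(n)
    return np.column_stack(cols), names


def call_degs(results: pd.DataFrame, lfc_min: float = 0.2, fdr: float = 0.05) -> pd.DataFrame:
    """BH-adjust and call DEGs: q < fdr AND |log2FC| >= lfc_min."""
    out = results.copy()
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    if "log2fc" in out.columns:
        out["called"] = (out["qvalue"] < fdr) & (out["log2fc"].abs() >= lfc_min)
        out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
        out.loc[~out["called"], "direction"] = "ns"
    else:
        out["called"] = out["qvalue"] < fdr
    return out


def classify_dose_response(
    lrt_results: pd.DataFrame,
    dose_means: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.Series:
    """Classify dose-LRT-significant genes by where expression peaks.

    ``repressed``: highest at dose 0 (KO); ``activated``: highest at dose 2
    (WT); genes peaking at dose 1 are ``non-monotone`` and excluded from
    both classes; everything else ``ns``.
    """
    for d in (0, 1, 2):
        if d not in dose_means.columns:
            raise ValueError(f"dose level {d} missing from dose_means")
    q = lrt_results["qvalue"] if "qvalue" in lrt_results else pd.Series(
        bh_adjust(lrt_results["pvalue"].to_numpy()), index=lrt_results.index
    )
    peak_dose = dose_means[[0, 1, 2]].idxmax(axis=1)
    klass = pd.Series("ns", index=lrt_results.index, name="class")
    sig = q < fdr
    klass[sig & (peak_dose == 0)] = "repressed"
    klass[sig & (peak_dose == 2)] = "activated"
    klass[sig & (peak_dose == 1)] = "non-monotone"
    return klass


def normalized_dose_means(
    counts: pd.DataFrame, coldata: pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    """Mean size-factor-normalized expression per dose level."""
    norm = counts / size_factors.loc[counts.columns]
    out = {}
    for dose, cols in coldata.groupby("dose").groups.items():
        out[dose] = norm[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end DE drivers
# ---------------------------------------------------------------------------


def run_dose_lrt(
    pb_counts: pd.DataFrame,
    coldata: pd.DataFrame,
    extra_terms: list[str] | None = None,
) -> pd.DataFrame:
    """Ordinal-dose LRT (full: intercept + dose [+ extras]; reduced drops dose)."""
    full_terms = (extra_terms or []) + ["dose"]
    Xf, names_f = design_matrix(coldata, full_terms)
    Xr, _ = design_matrix(coldata, extra_terms or [])
    s = estimate_size_factors(pb_counts)
    alpha = estimate_dispersions(pb_counts, s, design=Xf)
    full = fit_nb_glm(pb_counts, Xf, s, alpha, coef_names=names_f)
    reduced = fit_nb_glm(pb_counts, Xr, s, alpha)
    res = lrt_test(full, reduced)
    res["log2fc"] = full.beta["dose"] * -2.0  # per-2-allele effect, KO vs WT sign
    res["baseMean"] = (pb_counts / s).mean(axis=1)
    res = call_degs(res)
    dm = normalized_dose_means(pb_counts, coldata, s)
    res["class"] = classify_dose_response(res, dm)
    return res


def run_pairwise_wald(
    pb_counts: pd.DataFrame,
    coldata: pd.DataFrame,
    dose_a: int = 2,
    dose_b: int = 0,
) -> pd.DataFrame:
    """Wald test of dose_b vs dose_a (log2FC > 0 means higher in dose_b)."""
    keep = coldata["dose"].isin([dose_a, dose_b])
    cd = coldata.loc[keep]
    counts = pb_counts[cd.index]
    X = np.column_stack([np.ones(len(cd)), (cd["dose"] == dose_b).to_numpy(float)])
    s = estimate_size_factors(counts)
    alpha = estimate_dispersions(counts, s, design=X)
    fit = fit_nb_glm(counts, X, s, alpha, coef_names=["intercept", "doseB"])
    res = wald_test(fit, [0.0, 1.0])
    res["baseMean"] = (counts / s).mean(axis=1)
    return call_degs(res)


# ---------------------------------------------------------------------------
# DEG-burden downsampling
# ---------------------------------------------------------------------------


@dataclass
class BurdenResult:
    table: pd.DataFrame  # per cluster: burden stats or N/A flag
    rep_counts: dict[str, list[int]] = field(default_factory=dict)


def deg_burden(
    counts: CountMatrix,
    cells: pd.DataFrame,
    dose_a: int = 2,
    dose_b: int = 0,
    n_cells: int = 700,
    reps: int = 10,
    seed: int = 0,
    lfc_min: float = 0.2,
    fdr: float = 0.05,
) -> BurdenResult:
    """DEG count per cluster after repeated fixed-size downsampling.

    Each rep draws ``n_cells`` nuclei from the cluster (balanced halves per
    genotype arm, without replacement), reruns the full pseudobulk DE and
    counts called DEGs. Clusters whose arms cannot supply the draw are
    flagged ``N/A``. Each cluster's rep counts are compared against the
    pooled rep counts of all other clusters (two-sided Mann-Whitney U, BH
    across clusters).
    """
    cells = cells.loc[counts.cells]
    half_a = n_cells - n_cells // 2
    half_b = n_cells // 2
    clusters = sorted(cells["cluster"].astype(str).unique())
    rep_counts: dict[str, list[int]] = {}
    na_flag: dict[str, bool] = {}
    for cl in clusters:
        in_cl = cells["cluster"].astype(str) == cl
        arm_a = cells.index[in_cl & (cells["dose"] == dose_a)]
        arm_b = cells.index[in_cl & (cells["dose"] == dose_b)]
        if len(arm_a) < half_a or len(arm_b) < half_b:
            na_flag[cl] = True
            logger.info("cluster %s: insufficient nuclei for downsampling (N/A)", cl)
            continue
        na_flag[cl] = False
        rng = stable_label_seed(seed, cl)
        counts_cl = []
        for _ in range(reps):
            take = np.concatenate(
                [
                    rng.choice(arm_a.to_numpy(), size=half_a, replace=False),
                    rng.choice(arm_b.to_numpy(), size=half_b, replace=False),
                ]
            )
            sub = counts.subset_cells(take)
            sub_cells = cells.loc[sub.cells].copy()
            sub_cells["cluster"] = cl
            pb = aggregate_pseudobulk(sub, sub_cells)
            ok = pb.coldata.groupby("dose").size()
            if ok.get(dose_a, 0) < 2 or ok.get(dose_b, 0) < 2:
                counts_cl.append(0)
                continue
            res = run_pairwise_wald(pb.counts, pb.coldata, dose_a, dose_b)
            counts_cl.append(int(res["called"].sum()))
        rep_counts[cl] = counts_cl

    rows = []
    tested = [cl for cl in clusters if not na_flag[cl]]
    pvals, ustats = {}, {}
    for cl in tested:
        others = np.concatenate([rep_counts[o] for o in tested if o != cl]) if len(tested) > 1 else None
        if others is None or len(others) == 0:
            pvals[cl] = np.nan
            ustats[cl] = np.nan
            continue
        own = np.asarray(rep_counts[cl])
        if np.all(own == own[0]) and np.all(others == own[0]):
            pvals[cl] = 1.0
            ustats[cl] = len(own) * len(others) / 2.0
        else:
            mwu = scipy.stats.mannwhitneyu(own, others, alternative="two-sided")
            pvals[cl] = mwu.pvalue
            ustats[cl] = mwu.statistic
    qvals = dict(zip(tested, bh_adjust([pvals[cl] for cl in tested])))
    total = n_cells
    for cl in clusters:
        if na_flag[cl]:
            rows.append(
                {"cluster": cl, "burden": np.nan, "normalized_burden": np.nan,
                 "statistic": np.nan, "pvalue": np.nan, "qvalue": np.nan, "status": "N/A"}
            )
        else:
            own = np.asarray(rep_counts[cl], dtype=float)
            rows.append(
                {
                    "cluster": cl,
                    "burden": own.mean(),
                    "normalized_burden": own.mean() / total,
                    "statistic": ustats[cl],
                    "pvalue": pvals[cl],
                    "qvalue": qvals[cl],
                    "status": "ok",
                }
            )
    table = pd.DataFrame(rows).set_index("cluster")
    return BurdenResult(table=table, rep_counts=rep_counts)
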