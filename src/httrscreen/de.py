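"""Differential expression between a treatment group and vehicle controls.

Five engines share one result contract (gene, log2FC, statistic, p, BH-
adjusted p, mean abundance):

``nbql``
    NB GLM with log link and quasi-likelihood F-tests: genes are fitted
    at a binned likelihood-based mean-dispersion trend, gene-specific
    variability is carried by a deviance-based quasi-dispersion
    moderated across genes, and the treatment coefficient is tested
    with an F on moderated denominator degrees of freedom (edgeR-style).
``voom``
    log2-CPM with precision weights from the lowess mean-variance trend
    followed by moderated t (limma-voom-style); uses TMMwsp scaling by
    default since plate data are zero-heavy.
``trend``
    log2-CPM with an intensity-dependent prior variance (limma-trend
    style) and moderated t.
``wald_nb``
    NB GLM with median-of-ratios offsets and a Wald z test
    (DESeq2-style).
``ranksum``
    Two-sided Wilcoxon rank-sum on CPM values (Seurat-style), exact by
    enumeration for small tie-free groups.

ZINB observation weights (see :mod:`httrscreen.zinb`) can be passed to the
likelihood-based engines; all-ones weights reproduce the unweighted result
bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from httrscreen.normalize import (
    NormFactors,
    norm_cpm,
    norm_median_of_ratios,
    norm_tmm,
)
from httrscreen.plate_io import Screen

__all__ = [
    "DEDesign",
    "DEResult",
    "EBayesState",
    "ENGINES",
    "de_nbql",
    "de_voom",
    "de_trend",
    "de_wald_nb",
    "de_ranksum",
    "de_with_weights",
    "run_de",
    "adjust_bh",
]

RESULT_COLUMNS = (
    "gene_id",
    "gene_name",
    "base_mean",
    "log2fc",
    "stat",
    "pvalue",
    "padj",
    "engine",
)


@dataclass
class DEDesign:
    """A two-group comparison: treatment wells vs control wells, with
    optional additive covariates (wells x q, aligned to the full screen)
    and optional observation weights (genes x wells, full screen)."""

    treatment_wells: np.ndarray
    control_wells: np.ndarray
    covariates: np.ndarray | None = None
    normalisation: str | None = None
    weights: np.ndarray | None = None
    engine: str | None = None

    def __post_init__(self) -> None:
        self.treatment_wells = np.asarray(self.treatment_wells, dtype=int)
        self.control_wells = np.asarray(self.control_wells, dtype=int)
        if set(self.treatment_wells) & set(self.control_wells):
            raise ValueError("treatment and control wells overlap")
        if len(self.treatment_wells) == 0 or len(self.control_wells) == 0:
            raise ValueError("both sides of the design need at least one well")
        if min(len(self.treatment_wells), len(self.control_wells)) < 2:
            warnings.warn(
                "a design side has a single well; no within-group variance "
                "is estimable", stacklevel=2,
            )


@dataclass
class DEResult:
    """Per-gene DE table under the fixed engine-independent contract."""

    table: pd.DataFrame
    engine: str
    n_treat: int
    n_ctrl: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table[list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)

    def de_genes(self, padj_cut: float = 0.05, lfc_cut: float = 1.0,
                 direction: str | None = None) -> set[str]:
        t = self.table
        mask = (t["padj"] < padj_cut) & (t["log2fc"].abs() > lfc_cut)
        if direction == "up":
            mask &= t["log2fc"] > 0
        elif direction == "down":
            mask &= t["log2fc"] < 0
        return set(t.loc[mask, "gene_id"])


@dataclass
class EBayesState:
    """Empirical-Bayes variance moderation state: prior df d0, prior
    variance s0^2 (scalar or per gene), posterior variances."""

    d0: float
    s0_sq: np.ndarray | float
    s_post_sq: np.ndarray


# ---------------------------------------------------------------------------
# shared helpers


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    NaNs are propagated and excluded from the number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


def _lowess_trend(y: np.ndarray, x: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Lowess fit returned as (x_sorted, fitted) for interpolation.

    Points are ordered by (x, y) before fitting so the result is exactly
    invariant under permutation of the input rows, ties included.
    """
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    fitted = lowess(ys, xs, frac=frac, return_sorted=False)
    return xs, fitted


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton, as in variance moderation)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(
    s_sq: np.ndarray, df: float, covariate: np.ndarray | None = None
) -> EBayesState:
    """Moment-match a scaled inverse-chi-square prior on log variances.

    With a covariate, the prior variance is a lowess trend over it
    (intensity-dependent prior); otherwise it is a scalar.  A non-positive
    moment estimate of the prior df gives d0 = inf (complete shrinkage)
    with a warning.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    z = np.log(s_sq[ok])
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[ok]
        xs, fitted = _lowess_trend(z, cov, frac=0.5)
        trend_at = np.interp(np.asarray(covariate, dtype=float), xs, fitted)
        e_z = trend_at
        resid_var = float(np.var(z - trend_at[ok], ddof=1)) if z.size > 1 else 0.0
    else:
        e_z = float(np.mean(z)) if z.size else 0.0
        resid_var = float(np.var(z, ddof=1)) if z.size > 1 else 0.0

    gap = resid_var - polygamma(1, df / 2.0)
    if gap <= 0:
        if z.size > 1:
            warnings.warn(
                "moment estimate of prior df is non-positive; using complete "
                "shrinkage (d0 = inf)", stacklevel=2,
            )
        d0 = np.inf
        offset = -digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * trigamma_inverse(gap)
        offset = (
            -digamma(df / 2.0) + np.log(df / 2.0)
            + digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    s0_sq = np.exp(e_z + offset)
    s_sq_filled = np.where(ok, s_sq, 0.0)
    if np.isinf(d0):
        s_post = np.broadcast_to(np.asarray(s0_sq), s_sq.shape).astype(float).copy()
    else:
        s_post = (d0 * s0_sq + df * s_sq_filled) / (d0 + df)
    return EBayesState(d0=float(d0), s0_sq=s0_sq, s_post_sq=s_post)


def _subset(screen: Screen, design: DEDesign):
    """Subset counts to [control, treatment] order; return (y, x, X)."""
    idx = np.concatenate([design.control_wells, design.treatment_wells])
    counts = screen.counts.values[:, idx].astype(float)
    x = np.concatenate(
        [np.zeros(len(design.control_wells)), np.ones(len(design.treatment_wells))]
    )
    cols = [np.ones(len(idx)), x]
    if design.covariates is not None:
        cov = np.asarray(design.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov[idx].T)
    X = np.column_stack(cols)
    ext_w = None
    if design.weights is not None:
        w = np.asarray(design.weights, dtype=float)
        if w.shape != screen.counts.values.shape:
            raise ValueError("weight matrix does not match the screen dimensions")
        ext_w = w[:, idx]
    return counts, idx, X, ext_w


def _result(
    screen: Screen,
    engine: str,
    design: DEDesign,
    base_mean: np.ndarray,
    log2fc: np.ndarray,
    stat: np.ndarray,
    pvalue: np.ndarray,
    metadata: dict | None = None,
) -> DEResult:
    table = pd.DataFrame(
        {
            "gene_id": screen.counts.gene_ids,
            "gene_name": screen.counts.gene_names,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pvalue,
            "padj": adjust_bh(pvalue),
            "engine": engine,
        }
    )
    return DEResult(
        table,
        engine,
        n_treat=len(design.treatment_wells),
        n_ctrl=len(design.control_wells),
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# NB GLM machinery


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    theta: np.ndarray,
    obs_weights: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Batched IRLS for per-gene NB GLMs with a shared design matrix.

    Returns (beta, mu, cov) where cov is the per-gene unscaled inverse
    information (X' W X)^-1 at convergence.
    """
    g, n = y.shape
    p = X.shape[1]
    w_ext = np.ones_like(y) if obs_weights is None else obs_weights
    th = np.broadcast_to(np.asarray(theta, dtype=float)[:, None], y.shape)

    # init from a least-squares fit on the log scale
    z0 = np.log(y + 0.5) - offset
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    fallback = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = w_ext * mu / (1.0 + mu / th)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("gn,np,nq->gpq", w, X, X)
        b = np.einsum("gn,gn,np->gp", w, z, X)
        A = A + 1e-10 * np.eye(p)
        try:
            new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            new_beta = np.einsum("gpq,gq->gp", np.linalg.pinv(A), b)
        bad = ~np.all(np.isfinite(new_beta), axis=1)
        if bad.any():
            fallback |= bad
            new_beta[bad] = beta[bad]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        if np.all(delta < tol):
            break
    eta = np.clip(beta @ X.T + offset, -30, 30)
    mu = np.exp(eta)
    w = w_ext * mu / (1.0 + mu / th)
    A = np.einsum("gn,np,nq->gpq", w, X, X) + 1e-10 * np.eye(p)
    cov = np.linalg.inv(A)
    return beta, mu, cov, fallback


def _profile_theta_adjusted(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    obs_weights: np.ndarray | None = None,
    iters: int = 40,
) -> np.ndarray:
    """Per-gene dispersion by maximising the Cox-Reid adjusted profile
    likelihood on log(theta) (ternary search), given fitted means."""
    from httrscreen.zinb import THETA_CAP, THETA_FLOOR, _nb_logpmf

    g, n = y.shape
    w_ext = np.ones_like(y) if obs_weights is None else obs_weights

    def neg_apl(log_theta: np.ndarray) -> np.ndarray:
        theta = np.exp(log_theta)[:, None]
        ll = (w_ext * _nb_logpmf(y, mu, theta)).sum(axis=1)
        w = w_ext * mu / (1.0 + mu / theta)
        A = np.einsum("gn,np,nq->gpq", w, X, X) + 1e-10 * np.eye(X.shape[1])
        sign, logdet = np.linalg.slogdet(A)
        return -(ll - 0.5 * logdet)

    lo = np.full(g, np.log(THETA_FLOOR))
    hi = np.full(g, np.log(THETA_CAP))
    for _ in range(iters):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        shrink_hi = neg_apl(m1) < neg_apl(m2)
        hi = np.where(shrink_hi, m2, hi)
        lo = np.where(shrink_hi, lo, m1)
    return np.clip(np.exp((lo + hi) / 2.0), THETA_FLOOR, THETA_CAP)


def _dispersion_trend_binned(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    mean_abund: np.ndarray,
    obs_weights: np.ndarray | None = None,
    n_bins: int = 20,
    iters: int = 40,
) -> np.ndarray:
    """Mean-dispersion trend by binned common-dispersion likelihood.

    Genes are sorted by abundance and cut into bins; each bin's
    dispersion maximises the summed Cox-Reid adjusted profile likelihood
    of its genes, and the per-gene trend interpolates log-dispersion over
    log-abundance.  Estimating the trend on the likelihood scale (rather
    than averaging per-gene estimates) lets heavy-tailed genes — dropout
    zeros above all — pull the local dispersion up, which is what keeps
    those genes from looking artificially precise downstream.
    """
    from httrscreen.zinb import THETA_CAP, THETA_FLOOR, _nb_logpmf

    g, n = y.shape
    w_ext = np.ones_like(y) if obs_weights is None else obs_weights
    order = np.lexsort((np.arange(g), mean_abund))
    n_bins = max(1, min(n_bins, g // 20 or 1))
    bins = np.array_split(order, n_bins)

    def bin_negll(idx: np.ndarray, log_theta: float) -> float:
        theta = np.full((len(idx), 1), np.exp(log_theta))
        ll = (w_ext[idx] * _nb_logpmf(y[idx], mu[idx], theta)).sum()
        w = w_ext[idx] * mu[idx] / (1.0 + mu[idx] / theta)
        A = np.einsum("gn,np,nq->gpq", w, X, X) + 1e-10 * np.eye(X.shape[1])
        _, logdet = np.linalg.slogdet(A)
        return -(ll - 0.5 * logdet.sum())

    bin_x, bin_y = [], []
    for idx in bins:
        lo, hi = np.log(THETA_FLOOR), np.log(THETA_CAP)
        for _ in range(iters):
            m1, m2 = lo + (hi - lo) / 3.0, hi - (hi - lo) / 3.0
            if bin_negll(idx, m1) < bin_negll(idx, m2):
                hi = m2
            else:
                lo = m1
        bin_x.append(float(np.median(np.log2(mean_abund[idx] + 0.5))))
        bin_y.append(-(lo + hi) / 2.0)  # log dispersion = -log theta
    a = np.log2(mean_abund + 0.5)
    trend_log_disp = np.interp(a, np.asarray(bin_x), np.asarray(bin_y))
    return 1.0 / np.clip(np.exp(trend_log_disp), 1e-6, 1e3)


def _shrink_dispersion(
    theta: np.ndarray,
    theta_trend: np.ndarray,
    df_res: float,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Shrink per-gene log-dispersions toward the trend with weight
    prior_df / (prior_df + residual df)."""
    log_disp = np.log(1.0 / theta)
    trend = np.log(1.0 / theta_trend)
    shrunk = (prior_df * trend + df_res * log_disp) / (prior_df + df_res)
    return 1.0 / np.clip(np.exp(shrunk), 1e-6, 1e3)


def _robust_mom_dispersion(
    norm_counts: np.ndarray, ctrl_cols: np.ndarray, trim: float = 0.125,
    scale: float = 1.51, floor: float = 0.04,
) -> np.ndarray:
    """Robust method-of-moments dispersion from the control wells.

    Trimmed mean and scaled trimmed variance across the (large) control
    cell give a per-gene dispersion that an outlying observation cannot
    inflate; the 1.51 factor corrects the 12.5%-trimmed variance of a
    normal back to unbiasedness.  Used only for outlier diagnostics.
    """
    x = norm_counts[:, ctrl_cols]
    n = x.shape[1]
    k = int(np.floor(n * trim))
    xs = np.sort(x, axis=1)
    kept = xs[:, k : n - k] if k else xs
    m = kept.mean(axis=1)
    sq = (x - m[:, None]) ** 2
    sqs = np.sort(sq, axis=1)
    v = scale * (sqs[:, : n - 2 * k].mean(axis=1) if k else sqs.mean(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v - m) / np.maximum(m, 1e-12) ** 2
    return np.clip(np.nan_to_num(disp, nan=floor), floor, 1e3)


def _cooks_distance(
    y: np.ndarray,
    mu: np.ndarray,
    dispersion: np.ndarray,
    X: np.ndarray,
    cov: np.ndarray,
    obs_weights: np.ndarray | None,
) -> np.ndarray:
    """Per-observation Cook's distance for the NB GLM fits.

    D = r_pearson^2 / p * h / (1 - h)^2 with the NB variance function and
    GLM leverages.  Measures how much a single well drives a gene's
    coefficient; used to refuse a test (p = NaN) when one observation
    dominates — the standard guard against dropout zeros and count
    outliers in small groups.  ``dispersion`` should be an estimate the
    outlier itself cannot inflate (see :func:`_robust_mom_dispersion`).
    """
    p = X.shape[1]
    w_ext = np.ones_like(y) if obs_weights is None else obs_weights
    d = dispersion[:, None]
    v = mu + d * mu**2
    w = w_ext * mu / (1.0 + d * mu)  # IRLS working weights
    # leverage h_ij = w_ij * x_j' (X'WX)^-1 x_j
    xcx = np.einsum("jp,gpq,jq->gj", X, cov, X)
    h = np.clip(w * xcx, 0.0, 0.9999)
    r_sq = w_ext * (y - mu) ** 2 / np.maximum(v, 1e-12)
    return (r_sq / p) * h / (1.0 - h) ** 2


def _nb_engine_core(
    screen: Screen,
    design: DEDesign,
    factors: NormFactors,
    prior_df: float = 10.0,
    cooks_filter: bool = True,
    dispersion_mode: str = "trend",
):
    """Shared NB GLM pipeline: initial fit, dispersion estimation, final
    fit.  Returns per-gene coefficient, SE pieces and residual df.

    ``dispersion_mode`` selects how gene-wise dispersions enter the final
    GLM.  ``trend`` fits every gene at the mean-dispersion trend, leaving
    gene-specific variability (and outliers) to inflate the downstream
    quasi-likelihood dispersion — the QL convention.  ``map`` shrinks the
    gene-wise estimate toward the trend with weight ``prior_df``, except
    for dispersion outliers (log-dispersion more than 2 residual sd above
    trend), which keep their own estimate so that erratic genes are not
    anti-conservatively squeezed — the Wald convention.
    """
    y, idx, X, ext_w = _subset(screen, design)
    n, p = X.shape
    df_res = n - p
    if df_res < 1:
        raise ValueError("NB engines need positive residual degrees of freedom")
    offset = np.log(factors.effective_libsize)

    informative = y.sum(axis=1) > 0
    yi = y[informative]
    wi = ext_w[informative] if ext_w is not None else None

    theta0 = np.full(yi.shape[0], 100.0)
    _, mu0, _, _ = _nb_irls(yi, X, offset, theta0, wi, max_iter=25)
    base_mean_i = (yi / np.exp(offset)).mean(axis=1)
    theta_trend = _dispersion_trend_binned(yi, mu0, X, base_mean_i, wi)
    if dispersion_mode == "trend":
        theta_fit = theta_trend
    else:
        theta_hat = _profile_theta_adjusted(yi, mu0, X, wi)
        theta_shrunk = _shrink_dispersion(theta_hat, theta_trend, df_res, prior_df)
        log_resid = np.log(1.0 / theta_hat) - np.log(1.0 / theta_trend)
        sd = max(float(np.std(log_resid)), 0.25)
        disp_outlier = log_resid > 2.0 * sd
        theta_fit = np.where(disp_outlier, theta_hat, theta_shrunk)
    beta, mu, cov, fallback = _nb_irls(yi, X, offset, theta_fit, wi)
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} gene(s) failed NB convergence; "
            "Poisson-like fallback retained", stacklevel=3,
        )

    # quasi-likelihood dispersion from the NB deviance (the deviance
    # penalises poorly fitted observations harder than Pearson residuals,
    # which matters for dropout zeros)
    w_ext = np.ones_like(yi) if wi is None else wi
    th = theta_fit[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term_y = np.where(yi > 0, yi * np.log(yi / np.maximum(mu, 1e-12)), 0.0)
        term_th = (yi + th) * np.log((th + mu) / (th + yi))
    deviance = (2.0 * w_ext * (term_y + term_th)).sum(axis=1)
    s_sq = np.maximum(deviance, 0.0) / df_res

    # Cook's-distance outlier guard: with >= 3 wells per side, refuse to
    # test genes whose fit is dominated by a single observation (dropout
    # zeros in a small group are the typical culprit)
    outliers_i = np.zeros(yi.shape[0], dtype=bool)
    if cooks_filter and min(
        len(design.treatment_wells), len(design.control_wells)
    ) >= 3:
        n_ctrl = len(design.control_wells)
        disp_robust = np.maximum(
            _robust_mom_dispersion(yi / np.exp(offset), np.arange(n_ctrl)),
            1.0 / theta_fit,
        )
        cooks = _cooks_distance(yi, mu, disp_robust, X, cov, wi)
        cutoff = scipy.stats.f.ppf(0.99, p, df_res)
        outliers_i = cooks.max(axis=1) > cutoff

    g = y.shape[0]

    def expand(arr, fill=np.nan):
        out = np.full(g, fill, dtype=float)
        out[informative] = arr
        return out

    from httrscreen.normalize import normalised_matrix

    base_mean = normalised_matrix(y, factors).mean(axis=1)
    outliers = np.zeros(g, dtype=bool)
    outliers[informative] = outliers_i
    return {
        "informative": informative,
        "coef": expand(beta[:, 1], 0.0),
        "cov11": expand(cov[:, 1, 1]),
        "s_sq": s_sq,
        "df_res": df_res,
        "base_mean": base_mean,
        "theta": expand(theta_fit),
        "outliers": outliers,
    }


LN2 = np.log(2.0)


def de_nbql(
    screen: Screen, design: DEDesign, prior_df: float = 10.0,
    cooks_filter: bool = False,
) -> DEResult:
    """NB GLM with quasi-likelihood F-tests (edgeR-style), TMM offsets.

    Genes are fitted at the trended dispersion; gene-specific variability
    is carried by the moderated quasi-likelihood dispersion, so outlier
    observations deflate rather than inflate the F statistic.
    """
    factors = norm_tmm(screen.counts.values[:, np.concatenate(
        [design.control_wells, design.treatment_wells])])
    core = _nb_engine_core(screen, design, factors, prior_df, cooks_filter,
                           dispersion_mode="trend")
    informative = core["informative"]
    eb = squeeze_var(core["s_sq"], core["df_res"])
    g = len(informative)
    fstat = np.full(g, np.nan)
    pval = np.full(g, np.nan)
    fstat[informative] = (
        core["coef"][informative] ** 2
        / (core["cov11"][informative] * eb.s_post_sq)
    )
    df2 = core["df_res"] + min(eb.d0, 1e6)
    pval[informative] = scipy.stats.f.sf(fstat[informative], 1, df2)
    pval[core["outliers"]] = np.nan
    stat = np.sign(core["coef"]) * np.sqrt(fstat)
    return _result(
        screen, "nbql", design, core["base_mean"], core["coef"] / LN2, stat, pval,
        metadata={"d0": eb.d0, "df_res": core["df_res"], "normalisation": factors.method,
                  "n_outlier_masked": int(core["outliers"].sum())},
    )


def de_wald_nb(
    screen: Screen, design: DEDesign, prior_df: float = 10.0,
    cooks_filter: bool = True,
) -> DEResult:
    """NB GLM with median-of-ratios offsets and a Wald z test
    (DESeq2-style)."""
    sub = screen.counts.values[:, np.concatenate(
        [design.control_wells, design.treatment_wells])]
    factors = norm_median_of_ratios(sub)
    core = _nb_engine_core(screen, design, factors, prior_df, cooks_filter,
                           dispersion_mode="map")
    informative = core["informative"]
    g = len(informative)
    z = np.full(g, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z[informative] = core["coef"][informative] / np.sqrt(core["cov11"][informative])
    pval = np.where(informative, 2.0 * scipy.stats.norm.sf(np.abs(z)), np.nan)
    pval[core["outliers"]] = np.nan
    return _result(
        screen, "wald_nb", design, core["base_mean"], core["coef"] / LN2, z, pval,
        metadata={"df_res": core["df_res"], "normalisation": factors.method,
                  "n_outlier_masked": int(core["outliers"].sum())},
    )


# ---------------------------------------------------------------------------
# limma-style engines


def _ls_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray | None = None):
    """Per-gene (weighted) least squares with a shared design.

    Returns beta, fitted, s_sq (residual variance), cov11 (unscaled
    variance of the treatment coefficient), df_res.
    """
    n, p = X.shape
    df_res = n - p
    if df_res <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if w is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = y @ X @ xtx_inv
        fitted = beta @ X.T
        resid = y - fitted
        s_sq = (resid**2).sum(axis=1) / df_res
        cov11 = np.full(y.shape[0], xtx_inv[1, 1])
    else:
        A = np.einsum("gn,np,nq->gpq", w, X, X) + 1e-12 * np.eye(p)
        b = np.einsum("gn,gn,np->gp", w, y, X)
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        fitted = beta @ X.T
        resid = y - fitted
        s_sq = (w * resid**2).sum(axis=1) / df_res
        cov11 = np.linalg.inv(A)[:, 1, 1]
    return beta, fitted, s_sq, cov11, df_res


def _log_cpm(y: np.ndarray, elib: np.ndarray, prior_count: float = 0.5) -> np.ndarray:
    """log2 CPM with a library-size-scaled prior count.

    The prior count is scaled per well in proportion to library size so a
    constant gene stays constant across wells (the limma convention);
    voom uses 0.5, the trend engine 3 (a larger prior damps the huge
    fold changes that all-zero groups would otherwise produce).
    """
    scaled_prior = prior_count * elib / elib.mean()
    return np.log2((y + scaled_prior) / (elib + 2.0 * scaled_prior) * 1e6)


def _moderated_t(beta1, s_sq, cov11, df_res, covariate=None):
    eb = squeeze_var(s_sq, df_res, covariate=covariate)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta1 / np.sqrt(eb.s_post_sq * cov11)
    df_total = df_res + min(eb.d0, 1e6)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
    return t, p, eb


def de_voom(screen: Screen, design: DEDesign, span: float = 0.5) -> DEResult:
    """log2-CPM + mean-variance precision weights + moderated t.

    The lowess trend of sqrt(residual sd) against mean log2 count is
    evaluated at each observation's fitted log2 count; the observation
    weight is the inverse fourth power of the trend value.  External ZINB
    weights, when present on the design, multiply the voom weights.
    """
    y, idx, X, ext_w = _subset(screen, design)
    factors = norm_tmm(y, singleton_pairing=True)
    elib = factors.effective_libsize
    logcpm = _log_cpm(y, elib)

    beta, fitted, s_sq, _, df_res = _ls_fit(logcpm, X)
    mean_log_count = logcpm.mean(axis=1) + np.mean(np.log2(elib + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(np.sqrt(s_sq))
    xs, trend_fit = _lowess_trend(sqrt_sd, mean_log_count, frac=span)
    lam = fitted + (np.log2(elib + 1.0) - np.log2(1e6))[None, :]
    lam = np.clip(lam, xs[0], xs[-1])
    trend = np.interp(lam, xs, trend_fit)
    w = 1.0 / np.maximum(trend, 1e-6) ** 4
    if ext_w is not None:
        w = w * ext_w

    beta, _, s_sq, cov11, df_res = _ls_fit(logcpm, X, w)
    t, p, eb = _moderated_t(beta[:, 1], s_sq, cov11, df_res)
    base_mean = ((y / elib) * 1e6).mean(axis=1)
    return _result(
        screen, "voom", design, base_mean, beta[:, 1], t, p,
        metadata={"d0": eb.d0, "df_res": df_res, "normalisation": factors.method},
    )


def de_trend(screen: Screen, design: DEDesign) -> DEResult:
    """log2-CPM + moderated t with an intensity-trend prior variance
    (limma-trend style; DRUG-seq's model of choice)."""
    y, idx, X, _ = _subset(screen, design)
    factors = norm_tmm(y, singleton_pairing=True)
    elib = factors.effective_libsize
    logcpm = _log_cpm(y, elib, prior_count=3.0)
    beta, _, s_sq, cov11, df_res = _ls_fit(logcpm, X)
    abund = logcpm.mean(axis=1)
    t, p, eb = _moderated_t(beta[:, 1], s_sq, cov11, df_res, covariate=abund)
    base_mean = ((y / elib) * 1e6).mean(axis=1)
    return _result(
        screen, "trend", design, base_mean, beta[:, 1], t, p,
        metadata={"d0": eb.d0, "df_res": df_res, "normalisation": factors.method},
    )


# ---------------------------------------------------------------------------
# rank-sum engine


def de_ranksum(screen: Screen, design: DEDesign) -> DEResult:
    """Two-sided Wilcoxon rank-sum per gene on CPM values.

    Exact p by enumeration when both groups have <= 8 wells and the gene
    has no tied values; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    y, idx, X, _ = _subset(screen, design)
    cpm, _ = norm_cpm(y)
    n_c = len(design.control_wells)
    treat = cpm[:, n_c:]
    ctrl = cpm[:, :n_c]
    n_t = treat.shape[1]

    res = scipy.stats.mannwhitneyu(
        treat, ctrl, axis=1, alternative="two-sided", method="asymptotic"
    )
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)

    if n_t <= 8 and n_c <= 8:
        for gidx in range(cpm.shape[0]):
            row = cpm[gidx]
            if len(np.unique(row)) == len(row):  # tie-free: exact enumeration
                r = scipy.stats.mannwhitneyu(
                    treat[gidx], ctrl[gidx], alternative="two-sided", method="exact"
                )
                stat[gidx] = r.statistic
                pval[gidx] = r.pvalue

    constant = np.all(y == y[:, [0]], axis=1)
    pval[constant] = 1.0
    log2fc = np.log2((treat.mean(axis=1) + 1.0) / (ctrl.mean(axis=1) + 1.0))
    base_mean = cpm.mean(axis=1)
    return _result(screen, "ranksum", design, base_mean, log2fc, stat, pval)


# ---------------------------------------------------------------------------
# dispatch


ENGINES = {
    "nbql": de_nbql,
    "voom": de_voom,
    "trend": de_trend,
    "wald_nb": de_wald_nb,
    "ranksum": de_ranksum,
}


def run_de(screen: Screen, design: DEDesign, engine: str = "nbql") -> DEResult:
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    return ENGINES[engine](screen, design)


def de_with_weights(
    engine: str, screen: Screen, design: DEDesign, weights: np.ndarray
) -> DEResult:
    """Run a likelihood-based engine with ZINB observation weights.

    Weights multiply the engine's observation weighting; an all-ones
    matrix reproduces the unweighted engine bit-for-bit.
    """
    if engine not in ("nbql", "voom"):
        raise ValueError("observation weights are supported for engines 'nbql' and 'voom'")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != screen.counts.values.shape:
        raise ValueError(
            f"weight matrix shape {weights.shape} does not match the screen "
            f"{screen.counts.values.shape}"
        )
    weighted = replace(design, weights=weights)
    return ENGINES[engine](screen, weighted)
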