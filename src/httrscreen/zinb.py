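"""Zero-inflated negative binomial (ZINB) modelling for sparse plate data.

Plate screens with limited input material show more zeros than a negative
binomial (NB) predicts.  This module fits per-gene NB models, quantifies
excess zeros, and runs a per-gene EM for the ZINB mixture to produce
observation-level weights in [0, 1]: a zero that the NB component cannot
plausibly explain is treated as technical dropout and down-weighted in the
differential-expression engines, while every positive count keeps weight 1.

The EM is intentionally a per-gene mixture without sample-level latent
factors: the weight formula the DE engines consume,
``w = 1 - pi / (pi + (1 - pi) * NB(0))`` for zero observations, is the
same in either formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NBFit",
    "ZINBFit",
    "fit_nb",
    "zero_inflation_assessment",
    "estimate_zinb_weights",
    "zero_weight",
]

THETA_FLOOR = 1e-3
THETA_CAP = 1e6


@dataclass
class NBFit:
    """Per-gene NB fit: fitted means per well (group mean x size factor),
    size parameter theta (dispersion = 1/theta), log-likelihood.
    ``degenerate`` marks all-zero genes excluded from weighting."""

    mu: np.ndarray
    theta: np.ndarray
    loglik: np.ndarray
    degenerate: np.ndarray


@dataclass
class ZINBFit:
    mu: np.ndarray
    theta: np.ndarray
    loglik: np.ndarray
    degenerate: np.ndarray
    pi: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """NB log-pmf, safe at mu == 0 (point mass at zero)."""
    theta = np.broadcast_to(theta, mu.shape)
    safe_mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(safe_mu / (theta + mu))
    )
    return np.where((mu == 0) & (y == 0), 0.0, np.where(mu == 0, -np.inf, ll))


def _profile_theta(
    y: np.ndarray, mu: np.ndarray, obs_weights: np.ndarray | None = None, iters: int = 60
) -> np.ndarray:
    """Per-gene ML of theta given fitted means, by vectorised ternary
    search on log(theta) over [THETA_FLOOR, THETA_CAP]."""

    w = np.ones_like(mu) if obs_weights is None else obs_weights

    def negll(log_theta: np.ndarray) -> np.ndarray:
        theta = np.exp(log_theta)[:, None]
        return -(w * _nb_logpmf(y, mu, theta)).sum(axis=1)

    lo = np.full(y.shape[0], np.log(THETA_FLOOR))
    hi = np.full(y.shape[0], np.log(THETA_CAP))
    for _ in range(iters):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        shrink_hi = negll(m1) < negll(m2)
        hi = np.where(shrink_hi, m2, hi)
        lo = np.where(shrink_hi, lo, m1)
    return np.clip(np.exp((lo + hi) / 2.0), THETA_FLOOR, THETA_CAP)


def zero_weight(mu, theta, pi):
    """NB-component weight of a zero observation under given parameters.

    ``w = 1 - pi / (pi + (1 - pi) * NB0)`` with
    ``NB0 = (theta / (theta + mu)) ** theta``.  As mu -> 0 the zero is
    uninformative and w -> 1 - pi; for large mu the zero is near-certain
    dropout and w -> NB0 / pi-ish small values.
    """
    mu = np.asarray(mu, dtype=float)
    nb0 = (theta / (theta + mu)) ** theta
    return 1.0 - pi / (pi + (1.0 - pi) * nb0)


def _group_masks(grouping: np.ndarray) -> list[np.ndarray]:
    grouping = np.asarray(grouping)
    return [grouping == g for g in np.unique(grouping)]


def _group_means(
    counts: np.ndarray,
    size_factors: np.ndarray,
    masks: list[np.ndarray],
    obs_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Fitted mean per well: (weighted) group mean of y/s, times s_j."""
    g, n = counts.shape
    mu = np.zeros((g, n))
    w = np.ones_like(counts, dtype=float) if obs_weights is None else obs_weights
    scaled = counts / size_factors
    for mask in masks:
        wm = w[:, mask]
        denom = np.maximum(wm.sum(axis=1, keepdims=True), 1e-12)
        m = (wm * scaled[:, mask]).sum(axis=1, keepdims=True) / denom
        mu[:, mask] = m * size_factors[mask]
    return mu


def fit_nb(
    counts: np.ndarray, size_factors: np.ndarray, grouping: np.ndarray
) -> NBFit:
    """Fit per-gene NB models with group-specific means.

    Group means are the mean of size-factor-scaled counts; theta is the
    per-gene profile maximum-likelihood estimate, floored at 1e-3 and
    capped at 1e6.  All-zero genes are flagged ``degenerate`` and excluded
    from downstream weighting.
    """
    counts = np.asarray(counts, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    masks = _group_masks(grouping)
    if any(mask.sum() < 2 for mask in masks):
        raise ValueError("each group needs at least 2 wells")
    mu = _group_means(counts, size_factors, masks)
    theta = _profile_theta(counts, mu)
    degenerate = counts.sum(axis=1) == 0
    theta[degenerate] = THETA_CAP
    loglik = _nb_logpmf(counts, mu, theta[:, None]).sum(axis=1)
    return NBFit(mu, theta, loglik, degenerate)


def zero_inflation_assessment(counts: np.ndarray, nbfit: NBFit):
    """Observed vs NB-expected zero fractions, per gene.

    Expected zero fraction under the NB fit is the per-well average of
    ``(theta / (theta + mu_j)) ** theta``; excess = observed - expected.
    Returns a DataFrame plus its screen-level mean excess in ``.attrs``.
    """
    import pandas as pd

    counts = np.asarray(counts, dtype=float)
    observed = (counts == 0).mean(axis=1)
    theta = nbfit.theta[:, None]
    expected = ((theta / (theta + nbfit.mu)) ** theta).mean(axis=1)
    excess = observed - expected
    table = pd.DataFrame(
        {"observed_zero_fraction": observed, "expected_zero_fraction": expected,
         "excess_zero_fraction": excess}
    )
    table.attrs["mean_excess"] = float(excess.mean())
    return table


def _mu_newton(
    counts: np.ndarray,
    size_factors: np.ndarray,
    masks: list[np.ndarray],
    theta: np.ndarray,
    obs_weights: np.ndarray,
    init: np.ndarray,
    steps: int = 8,
) -> np.ndarray:
    """Weighted NB ML for group means (Newton on log m per gene x group)."""
    g, n = counts.shape
    mu = init.copy()
    th = theta[:, None]
    for mask in masks:
        y = counts[:, mask]
        s = size_factors[mask]
        w = obs_weights[:, mask]
        # group mean on the y/s scale, per gene
        m = np.maximum(
            (w * y / s).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-12), 1e-8
        )
        for _ in range(steps):
            ms = m[:, None] * s
            score = (w * (y - ms) * th / (th + ms)).sum(axis=1)
            info = (w * ms * th * (th + y) / (th + ms) ** 2).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            m = m * np.exp(np.clip(step, -2, 2))
        mu[:, mask] = m[:, None] * s
    return mu


def estimate_zinb_weights(
    counts: np.ndarray,
    size_factors: np.ndarray,
    grouping: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[ZINBFit, np.ndarray]:
    """Per-gene EM for the ZINB mixture; returns the fit and the weights.

    E-step: for each zero observation the dropout responsibility is
    ``z = pi / (pi + (1 - pi) * NB0)`` with ``NB0 = (theta/(theta+mu))**theta``.
    M-step: ``pi`` becomes the mean of z over all observations (z is 0 at
    positive counts); mu and theta are re-estimated with NB-component
    weights ``1 - z``.  Weights are ``1 - z`` at zeros and exactly 1 at
    positive counts.  The observed-data log-likelihood is tracked and is
    non-decreasing; genes that do not move by *tol* within *max_iter*
    iterations are returned with ``converged=False`` and a warning.
    """
    counts = np.asarray(counts, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    g, n = counts.shape
    masks = _group_masks(grouping)
    is_zero = counts == 0
    degenerate = counts.sum(axis=1) == 0

    nb = fit_nb(counts, size_factors, grouping)
    mu, theta = nb.mu, nb.theta
    pi = np.clip((is_zero.mean(axis=1) - 0.05), 0.01, 0.9)
    loglik = np.full(g, -np.inf)
    converged = np.zeros(g, dtype=bool)
    iterations = np.zeros(g, dtype=int)
    z = np.zeros_like(counts)

    for it in range(1, max_iter + 1):
        th = theta[:, None]
        nb0 = (th / (th + mu)) ** th
        with np.errstate(divide="ignore", invalid="ignore"):
            z_new = np.where(
                is_zero, pi[:, None] / (pi[:, None] + (1 - pi[:, None]) * nb0), 0.0
            )
        active = ~(converged | degenerate)
        z[active] = z_new[active]

        # observed-data log-likelihood under current parameters
        ll_zero = np.log(np.maximum(pi[:, None] + (1 - pi[:, None]) * nb0, 1e-300))
        ll_pos = np.log(np.maximum(1 - pi[:, None], 1e-300)) + _nb_logpmf(counts, mu, th)
        ll = np.where(is_zero, ll_zero, ll_pos).sum(axis=1)

        newly_done = active & (np.abs(ll - loglik) < tol)
        converged |= newly_done
        loglik = np.where(active, ll, loglik)
        iterations = np.where(active, it, iterations)
        if (converged | degenerate).all():
            break

        # M-step on still-active genes (computed for all, applied to active)
        w_nb = 1.0 - z
        pi_new = z.mean(axis=1)
        mu_new = _mu_newton(counts, size_factors, masks, theta, w_nb, mu)
        theta_new = _profile_theta(counts, mu_new, obs_weights=w_nb)
        upd = ~(converged | degenerate)
        pi = np.where(upd, pi_new, pi)
        mu[upd] = mu_new[upd]
        theta = np.where(upd, theta_new, theta)

    if not (converged | degenerate).all():
        warnings.warn(
            f"{int((~(converged | degenerate)).sum())} gene(s) did not converge "
            f"within {max_iter} EM iterations; last iterate returned",
            stacklevel=2,
        )

    weights = np.where(is_zero, 1.0 - z, 1.0)
    weights[degenerate] = 1.0
    pi = np.where(degenerate, 0.0, pi)
    fit = ZINBFit(mu, theta, loglik, degenerate, pi, converged, iterations)
    return fit, weights
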