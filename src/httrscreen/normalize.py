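"""Per-well scaling factors and normalised matrices.

Implements the normalisation families compared in plate-screen QC:
library-size CPM, DESeq-style median-of-ratios, edgeR-style TMM with its
singleton-pairing variant (TMMwsp) for heavily zero-inflated data, and an
SVD-based removal of unwanted variation estimated on control genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormFactors",
    "TMMParams",
    "norm_cpm",
    "norm_median_of_ratios",
    "norm_tmm",
    "normalised_matrix",
    "remove_control_variation",
    "effective_libsize",
]


@dataclass
class NormFactors:
    """Per-well scaling produced by one normalisation method.

    ``effective_libsize`` is what log-link GLM offsets and CPM use:
    raw library size x scaling factor for the TMM family, and the size
    factor itself for median-of-ratios.
    """

    method: str
    size_factor: np.ndarray
    effective_libsize: np.ndarray

    def __post_init__(self) -> None:
        self.size_factor = np.asarray(self.size_factor, dtype=float)
        self.effective_libsize = np.asarray(self.effective_libsize, dtype=float)
        if not np.all(np.isfinite(self.size_factor)) or (self.size_factor <= 0).any():
            raise ValueError("size factors must be finite and positive")
        if not np.all(np.isfinite(self.effective_libsize)) or (
            self.effective_libsize <= 0
        ).any():
            raise ValueError("effective library sizes must be finite and positive")


@dataclass
class TMMParams:
    """Trimming and reference configuration for TMM.

    logratio_trim (M-trim) and abundance_trim (A-trim) are the two-sided
    quantile fractions removed from the M and A distributions before the
    weighted mean; defaults follow the published convention (0.3 / 0.05).
    """

    logratio_trim: float = 0.3
    abundance_trim: float = 0.05
    reference_well: int | None = None
    min_count: int = 0

    def __post_init__(self) -> None:
        for trim in (self.logratio_trim, self.abundance_trim):
            if not 0 <= trim < 0.5:
                raise ValueError("trim fractions must lie in [0, 0.5)")


def _libsizes(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = np.flatnonzero(lib == 0)
        raise ValueError(f"all-zero well(s) at column index {bad.tolist()}")
    return lib


def norm_cpm(counts: np.ndarray) -> tuple[np.ndarray, NormFactors]:
    """Counts per million: value[g, j] = counts[g, j] / libsize_j * 1e6."""
    counts = np.asarray(counts, dtype=float)
    lib = _libsizes(counts)
    cpm = counts / lib * 1e6
    factors = NormFactors("cpm", np.ones(counts.shape[1]), lib)
    return cpm, factors


def norm_median_of_ratios(counts: np.ndarray) -> NormFactors:
    """DESeq-style size factors from median ratios to per-gene geometric means.

    Genes with a zero in any well are excluded from the reference (the
    classic behaviour), so heavily sparse matrices should be filtered
    first; the error message says as much when no gene survives.
    Factors are returned unscaled (no geometric-mean-1 rescaling).
    """
    counts = np.asarray(counts, dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "median-of-ratios needs at least one gene with nonzero counts in "
            "every well; filter low-count genes first"
        )
    ref = counts[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    sf = np.median(ref / geomean[:, None], axis=0)
    return NormFactors("median_of_ratios", sf, sf)


def _choose_tmm_reference(counts: np.ndarray) -> int:
    """Well whose upper-quartile proportion is closest to the mean UQ."""
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    params: TMMParams,
    singleton_pairing: bool,
) -> float:
    """log2 scaling factor of one well against the reference well."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > params.min_count) & (ref > params.min_count)
    y_obs, y_ref = obs[both].astype(float), ref[both].astype(float)

    if singleton_pairing:
        # Genes positive in exactly one of the pair are ranked by count and
        # greedily paired largest-to-largest to build surrogate ratios that
        # keep the factor stable under heavy zero inflation.
        only_obs = np.sort(obs[(obs > params.min_count) & (ref <= params.min_count)])[::-1]
        only_ref = np.sort(ref[(ref > params.min_count) & (obs <= params.min_count)])[::-1]
        k = min(len(only_obs), len(only_ref))
        if k:
            y_obs = np.concatenate([y_obs, only_obs[:k].astype(float)])
            y_ref = np.concatenate([y_ref, only_ref[:k].astype(float)])

    if len(y_obs) < 10:
        warnings.warn(
            "fewer than 10 usable gene pairs for TMM; factor set to 1", stacklevel=3
        )
        return 0.0

    p_obs, p_ref = y_obs / n_obs, y_ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) inverse variance of M per gene pair
    v = (n_obs - y_obs) / (n_obs * y_obs) + (n_ref - y_ref) / (n_ref * y_ref)

    n = len(m)
    lo_m = np.floor(n * params.logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * params.abundance_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks tie-broken on the full (value, other value, weight) key so the
    # trimmed set does not depend on gene order
    rank_m = np.empty(n, dtype=int)
    rank_m[np.lexsort((v, a, m))] = np.arange(1, n + 1)
    rank_a = np.empty(n, dtype=int)
    rank_a[np.lexsort((v, m, a))] = np.arange(1, n + 1)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m[keep]) / np.sum(w))
    return 0.0 if not np.isfinite(f) else f


def norm_tmm(
    counts: np.ndarray,
    params: TMMParams | None = None,
    singleton_pairing: bool = False,
) -> NormFactors:
    """Trimmed mean of M-values scaling factors (TMM; TMMwsp when
    ``singleton_pairing``), rescaled to geometric mean 1 across wells."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two wells")
    params = params or TMMParams()
    lib = _libsizes(counts)
    ref_idx = (
        params.reference_well
        if params.reference_well is not None
        else _choose_tmm_reference(counts)
    )
    log2f = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_pair_factor(counts[:, j], counts[:, ref_idx], params, singleton_pairing)
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log2f - log2f.mean())  # geometric mean exactly 1
    method = "tmmwsp" if singleton_pairing else "tmm"
    return NormFactors(method, factors, lib * factors)


def effective_libsize(counts: np.ndarray, factors: NormFactors) -> np.ndarray:
    """Offsets for log-link GLMs under the given normalisation."""
    return factors.effective_libsize


def normalised_matrix(counts: np.ndarray, factors: NormFactors) -> np.ndarray:
    """Normalised abundance matrix under *factors*.

    TMM-family and CPM report counts per million of effective library
    size; median-of-ratios reports counts divided by the size factor.
    """
    counts = np.asarray(counts, dtype=float)
    if factors.method == "median_of_ratios":
        return counts / factors.size_factor
    return counts / factors.effective_libsize * 1e6


def remove_control_variation(
    log_counts: np.ndarray, control_genes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """RUV-style correction: learn *k* unwanted factors on control genes,
    regress them out of every gene.

    Factors are the first *k* right singular vectors of the row-centred
    control-gene submatrix; the corrected matrix is the per-gene residual
    plus the gene mean (gene means are preserved exactly).  Returns
    ``(corrected, factor_scores)`` where scores (wells x k) can also serve
    as DE covariates.
    """
    log_counts = np.asarray(log_counts, dtype=float)
    control_genes = np.asarray(control_genes)
    if k == 0:
        return log_counts.copy(), np.zeros((log_counts.shape[1], 0))
    if k >= log_counts.shape[1]:
        raise ValueError("k must be smaller than the number of wells")
    ctrl = log_counts[control_genes]
    ctrl_centred = ctrl - ctrl.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(ctrl_centred)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the control submatrix")
    _, s, vt = np.linalg.svd(ctrl_centred, full_matrices=False)
    if s[k - 1] <= 1e-12 * s[0]:
        raise ValueError(f"k={k} meets or exceeds the effective rank of the control submatrix")
    scores = vt[:k].T  # wells x k, orthonormal columns with zero well-mean
    gene_means = log_counts.mean(axis=1, keepdims=True)
    centred = log_counts - gene_means
    fitted = (centred @ scores) @ scores.T
    return centred - fitted + gene_means, scores
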