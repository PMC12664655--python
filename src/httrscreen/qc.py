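"""Quality control for plate screens.

Per-well summaries, relative log expression (RLE) distributions with a
scalar normalisation-quality score (the average coefficient of variation),
group-wise gene filtering, per-gene variance decomposition over declared
metadata factors, and rule-based outlier flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from httrscreen.plate_io import Screen

__all__ = [
    "QCSummary",
    "RLEResult",
    "GeneFilterSpec",
    "OutlierRule",
    "VarianceDecomposition",
    "compute_qc_summary",
    "compute_rle",
    "average_cv",
    "filter_genes",
    "flag_outliers",
    "variance_decomposition",
]


@dataclass
class RLEResult:
    """RLE matrix (log-ratios to the gene-wise reference median) plus
    per-well medians/IQRs and the scalar average-CV score."""

    rle_values: np.ndarray
    per_well_summary: pd.DataFrame
    avg_cv: float
    pseudocount: float


@dataclass
class QCSummary:
    """One row per well: depth, detection, sparsity, RLE location/spread,
    outlier flag."""

    table: pd.DataFrame


@dataclass
class GeneFilterSpec:
    """Keep genes with aggregated count >= min_count in >= min_groups
    sample groups.

    ``grouping`` names the metadata columns that define a sample group
    (default treatment x concentration).  ``group_sum`` aggregates counts
    over the wells of a group; ``per_well_min`` requires every well of the
    group to reach the threshold (the stricter reading).
    """

    min_count: int = 5
    min_groups: int = 2
    grouping: tuple[str, ...] = ("treatment", "concentration")
    aggregation: str = "group_sum"

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be non-negative")
        if self.min_groups < 1:
            raise ValueError("min_groups must be positive")
        if self.aggregation not in ("group_sum", "per_well_min"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class OutlierRule:
    """Thresholds for :func:`flag_outliers`.

    A well is flagged when |median RLE| exceeds ``max_abs_median_rle``,
    when its RLE IQR exceeds ``iqr_factor`` times the cohort median IQR,
    or when fewer than ``min_detected_genes`` genes are detected.
    """

    max_abs_median_rle: float = 1.0
    iqr_factor: float = 2.0
    min_detected_genes: int = 200


@dataclass
class VarianceDecomposition:
    """Average fraction of per-gene variance explained by each declared
    factor (sequential sums of squares, in declared order) plus residual."""

    fractions: dict[str, float]
    residual: float
    per_gene: pd.DataFrame
    order: tuple[str, ...] = field(default_factory=tuple)


def compute_rle(
    norm: np.ndarray,
    pseudocount: float = 1.0,
    reference_wells: np.ndarray | None = None,
    min_mean: float = 1.0,
) -> RLEResult:
    """RLE values: log2(norm + pc) minus the gene-wise median over the
    reference wells (default: all wells)."""
    norm = np.asarray(norm, dtype=float)
    if not np.all(np.isfinite(norm)):
        raise ValueError("normalised matrix must be finite")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if norm.shape[1] < 2:
        raise ValueError("RLE needs at least two wells")
    log = np.log2(norm + pseudocount)
    ref = log if reference_wells is None else log[:, np.asarray(reference_wells)]
    rle = log - np.median(ref, axis=1, keepdims=True)
    q1, med, q3 = np.percentile(rle, [25, 50, 75], axis=0)
    summary = pd.DataFrame({"median_rle": med, "rle_iqr": q3 - q1})
    try:
        cv = average_cv(norm, np.arange(norm.shape[1]), min_mean=min_mean)
    except ValueError:
        cv = float("nan")
    return RLEResult(rle, summary, cv, pseudocount)


def average_cv(
    norm: np.ndarray,
    wells: np.ndarray | None = None,
    min_mean: float = 1.0,
    per_well: bool = False,
) -> float:
    """Average coefficient of variation of normalised counts.

    Default (``per_well=False``): per-gene CV = sample sd / mean across
    the selected wells, over genes with mean >= ``min_mean``; the mean of
    those CVs is returned.  ``per_well=True`` gives the alternative
    reading — mean over wells of the sd of that well's RLE values.
    """
    norm = np.asarray(norm, dtype=float)
    sub = norm if wells is None else norm[:, np.asarray(wells)]
    if sub.shape[1] < 2:
        raise ValueError("average_cv needs at least two wells")
    if per_well:
        log = np.log2(sub + 1.0)
        rle = log - np.median(log, axis=1, keepdims=True)
        return float(np.mean(np.std(rle, axis=0, ddof=1)))
    means = sub.mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        raise ValueError(f"no gene reaches min_mean={min_mean}")
    cv = np.std(sub[keep], axis=1, ddof=1) / means[keep]
    return float(cv.mean())


def compute_qc_summary(
    screen: Screen,
    norm: np.ndarray | None = None,
    rule: OutlierRule | None = None,
) -> QCSummary:
    """Per-well QC metrics; RLE metrics use *norm* (CPM if omitted)."""
    counts = screen.counts.values
    if norm is None:
        from httrscreen.normalize import norm_cpm

        norm, _ = norm_cpm(counts)
    rle = compute_rle(norm)
    n_genes = counts.shape[0]
    detected = (counts > 0).sum(axis=0)
    table = pd.DataFrame(
        {
            "barcode": screen.counts.barcodes,
            "total_counts": counts.sum(axis=0),
            "detected_genes": detected,
            "fraction_zero": 1.0 - detected / n_genes,
            "median_rle": rle.per_well_summary["median_rle"].to_numpy(),
            "rle_iqr": rle.per_well_summary["rle_iqr"].to_numpy(),
        }
    )
    summary = QCSummary(table)
    table["outlier"] = flag_outliers(rle, summary, rule)
    return summary


def flag_outliers(
    rle: RLEResult, qc: QCSummary, rule: OutlierRule | None = None
) -> np.ndarray:
    """Boolean per-well flag under the explicit threshold rule."""
    rule = rule or OutlierRule()
    med = np.abs(rle.per_well_summary["median_rle"].to_numpy())
    iqr = rle.per_well_summary["rle_iqr"].to_numpy()
    detected = qc.table["detected_genes"].to_numpy()
    cohort_iqr = np.median(iqr)
    return (
        (med > rule.max_abs_median_rle)
        | (iqr > rule.iqr_factor * cohort_iqr)
        | (detected < rule.min_detected_genes)
    )


def _group_labels(screen: Screen, grouping: tuple[str, ...]) -> pd.Series:
    t = screen.metadata.table
    for col in grouping:
        if col not in t.columns:
            raise ValueError(f"grouping column {col!r} not in metadata")
    return t[list(grouping)].astype(str).agg("|".join, axis=1)


def filter_genes(screen: Screen, spec: GeneFilterSpec | None = None) -> Screen:
    """Group-wise low-count filter.

    Under ``group_sum`` a gene is kept iff its summed count within a
    sample group reaches ``min_count`` in at least ``min_groups`` groups
    (the screening convention "at least 5 reads in at least 2 sample
    groups"); ``per_well_min`` requires every well of the group to reach
    the threshold instead.
    """
    spec = spec or GeneFilterSpec()
    labels = _group_labels(screen, spec.grouping)
    groups = labels.unique()
    if spec.min_groups > len(groups):
        raise ValueError(
            f"min_groups={spec.min_groups} exceeds the {len(groups)} sample groups"
        )
    counts = screen.counts.values
    hits = np.zeros(counts.shape[0], dtype=int)
    for g in groups:
        cols = np.flatnonzero((labels == g).to_numpy())
        if spec.aggregation == "group_sum":
            agg = counts[:, cols].sum(axis=1)
        else:
            agg = counts[:, cols].min(axis=1)
        hits += agg >= spec.min_count
    keep = hits >= spec.min_groups
    note = (
        f"filter_genes(min_count={spec.min_count}, min_groups={spec.min_groups}, "
        f"grouping={spec.grouping}, aggregation={spec.aggregation}): "
        f"removed {int((~keep).sum())} of {counts.shape[0]} genes"
    )
    return screen.with_counts(screen.counts.subset_genes(keep), note)


def variance_decomposition(
    log_norm: np.ndarray, metadata: pd.DataFrame, factors: tuple[str, ...]
) -> VarianceDecomposition:
    """Sequential (type-I) sum-of-squares decomposition per gene.

    Factors are entered in declared order; each factor's fraction is the
    drop in residual sum of squares when its dummy block joins the design,
    divided by the total sum of squares.  Fractions are averaged over
    genes with nonzero variance.  Aliased (rank-deficient) factor blocks
    are reported as NaN with a warning.
    """
    y = np.asarray(log_norm, dtype=float)
    n = y.shape[1]
    for col in factors:
        if col not in metadata.columns:
            raise ValueError(f"factor column {col!r} not in metadata")
        if metadata[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")

    total = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    nonzero = total > 0
    design = np.ones((n, 1))
    rank = 1
    resid_ss = total.copy()
    frac: dict[str, np.ndarray] = {}
    for col in factors:
        dummies = pd.get_dummies(metadata[col].astype(str), drop_first=True).to_numpy(float)
        design = np.hstack([design, dummies])
        new_rank = np.linalg.matrix_rank(design)
        if new_rank < rank + dummies.shape[1]:
            warnings.warn(
                f"factor {col!r} is aliased with earlier factors; fraction undefined",
                stacklevel=2,
            )
            frac[col] = np.full(y.shape[0], np.nan)
            rank = new_rank
            continue
        rank = new_rank
        q, _ = np.linalg.qr(design)
        fitted = (y @ q) @ q.T
        new_resid = ((y - fitted) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac[col] = np.where(nonzero, (resid_ss - new_resid) / total, np.nan)
        resid_ss = new_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        residual = np.where(nonzero, resid_ss / total, np.nan)

    per_gene = pd.DataFrame({**frac, "residual": residual})
    means = per_gene.mean(axis=0, skipna=True)
    return VarianceDecomposition(
        fractions={c: float(means[c]) for c in factors},
        residual=float(means["residual"]),
        per_gene=per_gene,
        order=tuple(factors),
    )
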