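"""Resampling benchmark harness for screen designs.

Reusable procedures that probe how analysis choices shape results:

* ``filter_sweep`` — sparsity, detected genes and average CV across
  normalisation methods as the low-count filter threshold rises;
* ``null_split_fpr`` — false-positive estimation by comparing two random
  groups of vehicle wells drawn from two fixed pools;
* ``replicate_subsample`` — leave-one-out duplicates vs the full
  triplicate reference DE set;
* ``control_count_sweep`` — DE yield as a function of the number of
  control replicates;
* ``engine_overlap`` — UpSet-style overlap of DE calls across engines,
  split by direction.

Every procedure is a pure function of (screen, config, seed): re-running
with the same seed reproduces every count.  Reported uncertainties are
standard errors over repeats or subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from httrscreen.de import DEDesign, ENGINES
from httrscreen.normalize import norm_cpm, norm_median_of_ratios, norm_tmm, normalised_matrix
from httrscreen.plate_io import Screen
from httrscreen.qc import GeneFilterSpec, average_cv, filter_genes
from httrscreen.screen import OverlapTable, overlap_counts

__all__ = [
    "BenchConfig",
    "filter_sweep",
    "null_split_fpr",
    "replicate_subsample",
    "control_count_sweep",
    "engine_overlap",
]


@dataclass
class BenchConfig:
    """Shared benchmark settings: filter thresholds, engines, DE cuts,
    repeat count and master seed."""

    thresholds: tuple[int, ...] = (0, 1, 5, 10, 20, 50)
    engines: tuple[str, ...] = ("nbql", "voom", "wald_nb")
    lfc_cut: float = 1.0
    padj_cut: float = 0.05
    p_cut: float = 0.05
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for cut in (self.lfc_cut, self.padj_cut, self.p_cut):
            if cut <= 0:
                raise ValueError("cuts must be positive")


def _se(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def filter_sweep(
    screen: Screen, config: BenchConfig, wells: np.ndarray | None = None
) -> pd.DataFrame:
    """Sparsity, detected genes and average CV per normalisation method at
    each filter threshold (computed on *wells*, default the vehicle pool)."""
    if wells is None:
        wells = screen.vehicle_wells()
    thresholds = sorted(config.thresholds)
    rows = []
    for t in thresholds:
        spec = GeneFilterSpec(min_count=t)
        filtered = filter_genes(screen, spec)
        sub = filtered.counts.values[:, wells]
        if sub.shape[0] == 0:
            warnings.warn(f"threshold {t} removed every gene", stacklevel=2)
            rows.append({"threshold": t, "sparsity": np.nan, "detected_genes": 0})
            continue
        row = {
            "threshold": t,
            "sparsity": float((sub == 0).mean()),
            "detected_genes": int(((sub > 0).any(axis=1)).sum()),
            "n_genes": sub.shape[0],
        }
        cpm, _ = norm_cpm(sub)
        row["avg_cv_cpm"] = average_cv(cpm)
        try:
            mor = norm_median_of_ratios(sub)
            row["avg_cv_median_of_ratios"] = average_cv(
                normalised_matrix(sub, mor)
            )
        except ValueError:
            row["avg_cv_median_of_ratios"] = np.nan
        for name, sp in (("tmm", False), ("tmmwsp", True)):
            fac = norm_tmm(sub, singleton_pairing=sp)
            row[f"avg_cv_{name}"] = average_cv(normalised_matrix(sub, fac))
        rows.append(row)
    return pd.DataFrame(rows)


def null_split_fpr(
    screen: Screen,
    control_label: str = "DMSO",
    group_size: int = 3,
    pool_size: int = 8,
    engines: tuple[str, ...] = ("nbql", "voom", "wald_nb"),
    n_repeats: int = 3,
    seed: int = 0,
    p_cut: float = 0.05,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """False positives from comparisons of two random vehicle groups.

    The available control wells are first partitioned (seeded) into two
    fixed pools of ``pool_size``; each repeat draws ``group_size`` wells
    from each pool and runs every engine.  Reported per engine: mean and
    standard error over repeats of the number of genes passing the nominal
    cut (p < p_cut and |log2FC| > lfc_cut) and the adjusted cut
    (padj < padj_cut and |log2FC| > lfc_cut).
    """
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    if len(ctrl) < 2 * pool_size:
        raise ValueError(
            f"need >= {2 * pool_size} control wells for two pools of "
            f"{pool_size}; found {len(ctrl)}"
        )
    if group_size > pool_size:
        raise ValueError("group_size cannot exceed pool_size")
    rng = np.random.default_rng(seed)
    pools = rng.permutation(ctrl)
    pool_a, pool_b = pools[:pool_size], pools[pool_size : 2 * pool_size]

    counts: dict[str, dict[str, list[int]]] = {
        e: {"nominal": [], "adjusted": []} for e in engines
    }
    for _ in range(n_repeats):
        ga = rng.choice(pool_a, size=group_size, replace=False)
        gb = rng.choice(pool_b, size=group_size, replace=False)
        design = DEDesign(ga, gb)
        for e in engines:
            res = ENGINES[e](screen, design)
            tab = res.table
            big_lfc = tab["log2fc"].abs() > lfc_cut
            counts[e]["nominal"].append(int(((tab["pvalue"] < p_cut) & big_lfc).sum()))
            counts[e]["adjusted"].append(
                int(((tab["padj"] < padj_cut) & big_lfc).sum())
            )
    rows = []
    for e in engines:
        for kind in ("nominal", "adjusted"):
            vals = np.asarray(counts[e][kind])
            rows.append(
                {
                    "engine": e,
                    "criterion": kind,
                    "mean_count": float(vals.mean()),
                    "se_count": _se(vals),
                    "counts": vals.tolist(),
                }
            )
    return pd.DataFrame(rows)


def replicate_subsample(
    screen: Screen,
    treatment: str,
    control_label: str = "DMSO",
    n_full: int = 3,
    engines: tuple[str, ...] = ("nbql", "voom", "wald_nb"),
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out duplicates vs the full replicate reference.

    The reference DE set uses all ``n_full`` replicates; each of the
    ``n_full`` leave-one-out subsets is re-analysed and its DE set
    compared with the reference: overlap percent = 100 |sub ∩ ref| / |ref|
    and the change in DE count.
    """
    wells = screen.wells_for(treatment=treatment)
    if len(wells) != n_full:
        raise ValueError(
            f"{treatment!r} has {len(wells)} replicates; expected exactly {n_full}"
        )
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    rows = []
    for e in engines:
        ref = ENGINES[e](screen, DEDesign(wells, ctrl)).de_genes(padj_cut, lfc_cut)
        overlaps, n_des = [], []
        for drop in range(n_full):
            sub_wells = np.delete(wells, drop)
            sub = ENGINES[e](screen, DEDesign(sub_wells, ctrl)).de_genes(
                padj_cut, lfc_cut
            )
            n_des.append(len(sub))
            if ref:
                overlaps.append(100.0 * len(sub & ref) / len(ref))
        if not ref:
            warnings.warn(
                f"reference DE set empty for engine {e}; overlap undefined",
                stacklevel=2,
            )
        rows.append(
            {
                "engine": e,
                "n_ref_de": len(ref),
                "mean_overlap_pct": float(np.mean(overlaps)) if overlaps else np.nan,
                "se_overlap_pct": _se(np.asarray(overlaps)) if overlaps else np.nan,
                "mean_subset_de": float(np.mean(n_des)),
                "se_subset_de": _se(np.asarray(n_des)),
                "subset_de_counts": n_des,
            }
        )
    return pd.DataFrame(rows)


def control_count_sweep(
    screen: Screen,
    treatment: str,
    control_label: str = "DMSO",
    control_counts: tuple[int, ...] = (2, 3, 5, 8, 12, 19),
    engines: tuple[str, ...] = ("nbql", "voom", "wald_nb"),
    n_repeats: int = 3,
    seed: int = 0,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """DE yield as a function of the number of control replicates.

    For each requested control count c, ``n_repeats`` seeded draws of c
    vehicle wells are analysed against the treatment; mean and standard
    error of the DE count are reported per engine.
    """
    wells = screen.wells_for(treatment=treatment)
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    if max(control_counts) > len(ctrl):
        raise ValueError(
            f"largest control count {max(control_counts)} exceeds the "
            f"{len(ctrl)} available control wells"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(control_counts):
        per_engine: dict[str, list[int]] = {e: [] for e in engines}
        reps = 1 if c == len(ctrl) else n_repeats
        for _ in range(reps):
            chosen = (
                ctrl if c == len(ctrl) else rng.choice(ctrl, size=c, replace=False)
            )
            design = DEDesign(wells, chosen)
            for e in engines:
                n_de = len(ENGINES[e](screen, design).de_genes(padj_cut, lfc_cut))
                per_engine[e].append(n_de)
        for e in engines:
            vals = np.asarray(per_engine[e])
            rows.append(
                {
                    "n_controls": c,
                    "engine": e,
                    "mean_de": float(vals.mean()),
                    "se_de": _se(vals),
                    "de_counts": vals.tolist(),
                }
            )
    return pd.DataFrame(rows)


def engine_overlap(
    screen: Screen,
    treatment: str,
    control_label: str = "DMSO",
    engines: tuple[str, ...] = ("nbql", "voom", "wald_nb"),
    direction: str = "up",
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> OverlapTable:
    """UpSet-style overlap of directional DE calls across engines."""
    if len(engines) < 2:
        raise ValueError("need at least two engines")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    wells = screen.wells_for(treatment=treatment)
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    design = DEDesign(wells, ctrl)
    sets = {
        e: ENGINES[e](screen, design).de_genes(padj_cut, lfc_cut, direction=direction)
        for e in engines
    }
    return overlap_counts(sets)
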