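"""Multi-treatment screen mode.

Runs differential expression for every treatment group against the shared
vehicle controls, and summarises the results across treatments: DE gene
counts and up/down ratios, UpSet-style exclusive overlap tables, and
between-treatment distance matrices for downstream embedding.

Per-treatment runs are pure functions of (filtered screen, design), so any
execution backend yields bit-identical results; parallelism is provided
through joblib with a determinism contract (no RNG inside engines).
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from httrscreen.de import DEDesign, DEResult, ENGINES
from httrscreen.plate_io import Screen

__all__ = [
    "ScreenDEResults",
    "OverlapTable",
    "run_all_de",
    "de_summary",
    "overlap_counts",
    "treatment_distance",
]


@dataclass
class ScreenDEResults:
    """Mapping (treatment, concentration) -> DEResult plus run metadata."""

    results: dict[tuple[str, float], DEResult]
    control_wells: np.ndarray
    engine: str
    run_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __getitem__(self, key) -> DEResult:
        if isinstance(key, str):
            hits = [k for k in self.results if k[0] == key]
            if len(hits) != 1:
                raise KeyError(
                    f"{key!r} matches {len(hits)} treatment x concentration groups"
                )
            return self.results[hits[0]]
        return self.results[key]

    def keys(self):
        return self.results.keys()


@dataclass
class OverlapTable:
    """Exclusive-intersection (UpSet) counts over a family of named sets."""

    labels: tuple[str, ...]
    combinations: dict[tuple[str, ...], int]
    set_sizes: dict[str, int]
    union_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": "&".join(combo), "degree": len(combo), "count": n}
            for combo, n in sorted(
                self.combinations.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows)


def _one_de(screen: Screen, engine: str, treat_idx: np.ndarray, ctrl_idx: np.ndarray):
    design = DEDesign(treat_idx, ctrl_idx)
    return ENGINES[engine](screen, design)


def run_all_de(
    screen: Screen,
    control_label: str = "DMSO",
    engine: str = "nbql",
    min_replicates: int = 2,
    collapse_concentrations: bool = False,
    n_jobs: int = 1,
) -> ScreenDEResults:
    """One DE run per treatment x concentration group against the shared
    vehicle wells.

    Groups with fewer than ``min_replicates`` wells are skipped with a
    warning.  Results are identical for any ``n_jobs`` (the engines hold
    no RNG and each task is a pure function of screen + design).
    """
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    if len(ctrl) == 0:
        raise ValueError(f"no control wells found for label {control_label!r}")
    t = screen.metadata.table
    is_treat = (t["sample_type"] == "treatment").to_numpy()
    if collapse_concentrations:
        keys = [(tr, float("nan")) for tr in t["treatment"]]
    else:
        keys = list(zip(t["treatment"], t["concentration"].astype(float)))

    groups: dict[tuple[str, float], np.ndarray] = {}
    for j in np.flatnonzero(is_treat):
        groups.setdefault(keys[j], []).append(j)
    groups = {k: np.asarray(v) for k, v in sorted(groups.items())}
    if not groups:
        raise ValueError("screen contains no treatment wells")

    tasks = []
    for key, wells in groups.items():
        if len(wells) < min_replicates:
            warnings.warn(
                f"skipping {key}: {len(wells)} replicate(s) < {min_replicates}",
                stacklevel=2,
            )
            continue
        tasks.append((key, wells))

    t0 = time.perf_counter()
    outputs = Parallel(n_jobs=n_jobs)(
        delayed(_one_de)(screen, engine, wells, ctrl) for _, wells in tasks
    )
    elapsed = time.perf_counter() - t0
    results = {key: res for (key, _), res in zip(tasks, outputs)}
    info = pd.DataFrame(
        {
            "treatment": [k[0] for k in results],
            "concentration": [k[1] for k in results],
            "n_wells": [len(w) for _, w in tasks],
            "engine": engine,
            "total_wall_time_s": elapsed,
        }
    )
    return ScreenDEResults(results, ctrl, engine, info)


def de_summary(
    results: ScreenDEResults, lfc_cut: float = 1.0, padj_cut: float = 0.05,
    top_k: int = 10,
) -> pd.DataFrame:
    """Per-treatment counts of up/down DE genes at the stated cuts.

    The up/down ratio is reported as +inf when nothing is down-regulated
    but something is up (the positive-infinity sentinel of screen summary
    plots), and NA when there are no DE genes at all.
    """
    rows = []
    for (treatment, conc), res in results.results.items():
        tab = res.table
        sig = (tab["padj"] < padj_cut) & (tab["log2fc"].abs() > lfc_cut)
        n_up = int((sig & (tab["log2fc"] > 0)).sum())
        n_down = int((sig & (tab["log2fc"] < 0)).sum())
        if n_up == 0 and n_down == 0:
            ratio = float("nan")
        elif n_down == 0:
            ratio = float("inf")
        else:
            ratio = n_up / n_down
        top = tab.loc[sig].nsmallest(top_k, "padj")["gene_id"].tolist()
        rows.append(
            {
                "treatment": treatment,
                "concentration": conc,
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
                "up_down_ratio": ratio,
                "top_genes": "|".join(top),
            }
        )
    return pd.DataFrame(rows)


def overlap_counts(sets: dict[str, set]) -> OverlapTable:
    """Exact exclusive-intersection counts over all 2^k - 1 non-empty
    label combinations (UpSet semantics); k is capped at 12."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if len(sets) > 12:
        raise ValueError("more than 12 sets would need a 4096-row table; refusing")
    labels = tuple(sets)
    union = set().union(*sets.values())
    combos: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo)) if combo else set()
            outside = set().union(*(sets[l] for l in labels if l not in combo), set())
            exclusive = inside - outside
            if exclusive:
                combos[combo] = len(exclusive)
    return OverlapTable(
        labels=labels,
        combinations=combos,
        set_sizes={l: len(s) for l, s in sets.items()},
        union_size=len(union),
    )


def treatment_distance(
    results: ScreenDEResults,
    metric: str = "jaccard_on_sets",
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Symmetric between-treatment distance matrix.

    ``jaccard_on_sets``: 1 - |intersection| / |union| of DE gene sets at
    the stated cuts (1, with a warning, when both sets are empty).
    ``spearman_on_lfc``: 1 - Spearman rank correlation of log2FC vectors
    over the shared gene universe.
    """
    import scipy.stats

    keys = list(results.results)
    if len(keys) < 2:
        raise ValueError("need at least two treatments")
    n = len(keys)
    d = np.zeros((n, n))
    if metric == "jaccard_on_sets":
        gene_sets = [results.results[k].de_genes(padj_cut, lfc_cut) for k in keys]
        for i in range(n):
            for j in range(i + 1, n):
                union = gene_sets[i] | gene_sets[j]
                if not union:
                    warnings.warn(
                        f"empty DE sets for {keys[i]} and {keys[j]}; distance set to 1",
                        stacklevel=2,
                    )
                    dist = 1.0
                else:
                    dist = 1.0 - len(gene_sets[i] & gene_sets[j]) / len(union)
                d[i, j] = d[j, i] = dist
    elif metric == "spearman_on_lfc":
        lfc = [
            results.results[k].table.set_index("gene_id")["log2fc"] for k in keys
        ]
        shared = lfc[0].index
        for v in lfc[1:]:
            shared = shared.intersection(v.index)
        for i in range(n):
            for j in range(i + 1, n):
                rho = scipy.stats.spearmanr(
                    lfc[i].loc[shared], lfc[j].loc[shared]
                ).statistic
                d[i, j] = d[j, i] = 1.0 - rho
    else:
        raise ValueError(f"unknown metric {metric!r}")
    names = [f"{t}@{c:g}" for t, c in keys]
    return pd.DataFrame(d, index=names, columns=names)
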