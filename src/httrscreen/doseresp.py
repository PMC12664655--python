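"""Concentration-response modelling.

Per-gene response profiles (log2FC vs vehicle at each concentration of a
compound), per-pathway profiles (NES vs concentration), and four-parameter
logistic (4PL) fits

    y(x) = lower + (upper - lower) / (1 + (ec50 / x) ** h)

on the log10-dose axis, with a grid of starts over Hill slopes and dose
quantiles.  ``y(ec50)`` is the exact midpoint of the asymptotes, so the
fitted ``ec50`` is the half-maximal effective concentration; the sign of
``h`` covers rising and falling curves.  Vehicle (x = 0) anchors the
response definition (fold change vs vehicle) and never enters the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from httrscreen.de import DEDesign, ENGINES
from httrscreen.enrich import GeneSetCollection, gsea_preranked
from httrscreen.plate_io import Screen

__all__ = [
    "DoseSeries",
    "FourPLFit",
    "fit_4pl",
    "gene_response_profile",
    "pathway_response_profile",
]


@dataclass
class DoseSeries:
    """Responses of one target (gene or pathway) across a dose series."""

    compound: str
    doses: np.ndarray
    responses: np.ndarray
    unit: str = ""
    target: str = ""
    response_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive (vehicle is the baseline)")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses differ in length")


@dataclass
class FourPLFit:
    lower: float
    upper: float
    hill: float
    ec50: float
    rss: float
    converged: bool
    ec50_in_range: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + (self.ec50 / x) ** self.hill
        )


def _4pl_log(logx: np.ndarray, lower: float, upper: float, hill: float,
             log_ec50: float) -> np.ndarray:
    # (ec50/x)^h == 2^... computed on the log10 axis for conditioning
    return lower + (upper - lower) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))


def fit_4pl(
    series: DoseSeries,
    hill_bounds: tuple[float, float] = (-10.0, 10.0),
    ec50_expand: float = 100.0,
    flat_tolerance: float = 1e-8,
) -> FourPLFit:
    """Nonlinear least squares on the log10-dose axis with grid starts.

    Starts combine h in {+-0.5, +-1, +-2} with EC50 at dose quantiles;
    the best start is refined.  ``ec50_in_range`` flags whether the
    estimate lies within the tested dose range; EC50 bounds extend
    ``ec50_expand``-fold beyond it.  A flat response (range below
    ``flat_tolerance``) is reported as non-converged with EC50 undefined.
    """
    if len(series.doses) < 4:
        raise ValueError("4PL fitting needs at least 4 distinct doses")
    logx = np.log10(series.doses)
    y = series.responses
    span = y.max() - y.min()
    if span < flat_tolerance:
        return FourPLFit(float(y.mean()), float(y.mean()), 0.0, float("nan"),
                         0.0, False, False)

    lo_b = np.log10(series.doses.min() / ec50_expand)
    hi_b = np.log10(series.doses.max() * ec50_expand)
    bounds = (
        [y.min() - 2 * span, y.min() - 2 * span, hill_bounds[0], lo_b],
        [y.max() + 2 * span, y.max() + 2 * span, hill_bounds[1], hi_b],
    )

    def residuals(p):
        return _4pl_log(logx, *p) - y

    starts = []
    for h0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
        for q in (0.25, 0.5, 0.75):
            starts.append([y[0], y[-1], h0, float(np.quantile(logx, q))])

    best = None
    best_rss = np.inf
    for p0 in starts:
        rss0 = float((residuals(p0) ** 2).sum())
        if rss0 < best_rss:
            best_rss, best = rss0, p0
    try:
        sol = scipy.optimize.least_squares(
            residuals, best, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        rss = float((sol.fun**2).sum())
        # refinement must not lose to the raw grid start
        if rss > best_rss + 1e-12:
            sol_params, rss, ok = best, best_rss, False
        else:
            sol_params, ok = sol.x, sol.success
    except Exception:
        sol_params, rss, ok = best, best_rss, False

    lower, upper, hill, log_ec50 = sol_params
    ec50 = float(10.0**log_ec50)
    in_range = bool(series.doses.min() <= ec50 <= series.doses.max())
    return FourPLFit(float(lower), float(upper), float(hill), ec50, rss,
                     bool(ok), in_range)


def _dose_designs(screen: Screen, compound: str, control_label: str):
    t = screen.metadata.table
    mask = t["treatment"].astype(str).str.lower() == compound.lower()
    concs = sorted(set(t.loc[mask, "concentration"].astype(float)))
    concs = [c for c in concs if c > 0]
    if len(concs) < 4:
        raise ValueError(
            f"{compound!r} has {len(concs)} positive concentration(s); dose-"
            "response needs >= 4 (consider a descriptive per-dose summary)"
        )
    ctrl = screen.vehicle_wells(fallback_name=control_label)
    if len(ctrl) == 0:
        raise ValueError("no vehicle control wells found")
    designs = []
    for conc in concs:
        wells = screen.wells_for(treatment=compound, concentration=conc)
        designs.append((conc, DEDesign(wells, ctrl)))
    return concs, designs


def gene_response_profile(
    screen: Screen,
    compound: str,
    engine: str = "voom",
    control_label: str = "DMSO",
) -> tuple[pd.DataFrame, dict[str, DoseSeries]]:
    """Per-gene log2FC across the compound's dose series.

    Runs the chosen DE engine at each concentration against the shared
    vehicle wells.  Returns a tidy table (gene x dose) and a DoseSeries
    per gene.
    """
    concs, designs = _dose_designs(screen, compound, control_label)
    lfc = {}
    for conc, design in designs:
        res = ENGINES[engine](screen, design)
        lfc[conc] = res.table.set_index("gene_id")["log2fc"]
    frame = pd.DataFrame(lfc)
    doses = np.asarray(concs)
    series = {
        gene: DoseSeries(compound, doses, frame.loc[gene].to_numpy(), target=gene)
        for gene in frame.index
    }
    tidy = frame.reset_index().melt(
        id_vars="gene_id", var_name="concentration", value_name="log2fc"
    )
    return tidy, series


def pathway_response_profile(
    screen: Screen,
    compound: str,
    sets: GeneSetCollection,
    engine: str = "voom",
    control_label: str = "DMSO",
    response_type: str = "mean_lfc",
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[dict[str, DoseSeries], dict[str, FourPLFit]]:
    """Pathway-level dose response with a 4PL fit per gene set.

    Two response scales are available per concentration:

    ``mean_lfc`` (default)
        mean log2FC of the set members — an effect-size scale whose
        half-maximal point tracks the member genes' EC50s, hence the
        scale used for EC50 fitting.
    ``nes``
        permutation-normalised enrichment score of the set against the
        ranked DE statistics — a detection scale; it saturates once the
        coordinated shift is clearly detectable, well below the genes'
        half-maximal concentration, so fitted midpoints are shifted left.
    """
    if response_type not in ("mean_lfc", "nes"):
        raise ValueError("response_type must be 'mean_lfc' or 'nes'")
    concs, designs = _dose_designs(screen, compound, control_label)
    tables = []
    for conc, design in designs:
        res = ENGINES[engine](screen, design)
        tables.append(res.table.set_index("gene_id"))

    series: dict[str, DoseSeries] = {}
    fits: dict[str, FourPLFit] = {}
    for name, genes in sets.items():
        universe_hits = genes & set(tables[0].index)
        if not universe_hits:
            raise ValueError(f"set {name!r} does not intersect the gene universe")
        values = []
        for table in tables:
            if response_type == "mean_lfc":
                values.append(float(table.loc[sorted(universe_hits), "log2fc"].mean()))
            else:
                r = gsea_preranked(table["stat"].dropna(), genes, n_perm=n_perm,
                                   seed=seed)
                values.append(r.nes if np.isfinite(r.nes) else 0.0)
        ds = DoseSeries(compound, np.asarray(concs), np.asarray(values), target=name)
        series[name] = ds
        try:
            fits[name] = fit_4pl(ds)
        except ValueError as exc:
            warnings.warn(f"4PL fit failed for set {name!r}: {exc}", stacklevel=2)
    return series, fits
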