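"""Synthetic plate screens with known ground truth.

The generator emulates the data model of a 384-well MAC-Seq style screen:
per-gene baseline means drawn on the log2 scale, a mean-dispersion trend,
mean-dependent zero inflation, log-normal library-size variation, planted
differential-expression signatures per treatment, dose-response compounds
whose per-gene log2 fold change follows a four-parameter logistic in
concentration, and optional plate-geometry batch effects.  Counts are
drawn from a zero-inflated negative binomial:

    count[g, j] ~ ZINB(mean = s_j * mu_g * 2**delta_g(j) * batch_j,
                       theta_g, pi_{g, j})

Everything is deterministic given the config seed, and the planted truth
(DE membership, true LFCs, true EC50s, size factors) is returned alongside
the screen as the oracle for the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from httrscreen.plate_io import (
    CountMatrix,
    PlateMetadata,
    Screen,
    PLATE_FORMATS,
    write_count_triplet,
    write_metadata,
)

__all__ = ["SimConfig", "SimTruth", "TreatmentSpec", "DoseCompoundSpec",
           "simulate_screen", "write_fixture", "default_screen_config"]


@dataclass
class TreatmentSpec:
    """A fixed-dose treatment with planted DE."""

    name: str
    concentration: float = 1.0
    replicates: int = 3
    frac_de: float = 0.05
    lfc_sd: float = 0.0          # 0 => point-mass LFCs at +/- lfc_location
    lfc_location: float = 2.0
    mu_floor: float = 0.0        # restrict planted DE to genes with mu >= floor


@dataclass
class DoseCompoundSpec:
    """A dose-series compound whose per-gene LFC follows a 4PL curve."""

    name: str
    concentrations: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
    replicates: int = 2
    n_responsive: int = 50
    lower: float = 0.0
    upper: float = 3.0
    hill: float = 1.0
    ec50_range: tuple[float, float] = (0.1, 3.0)
    mu_floor: float = 20.0


@dataclass
class SimConfig:
    """Full description of a simulated screen.

    Defaults mirror a realistic 384-well screen: log2 baseline means
    N(3, 2), an edgeR-like dispersion trend 1/theta = 0.05 + 2/mu,
    mean-dependent dropout logit(pi) = -1.5 - 0.75*log(mu+1) (so only
    low-abundance genes are appreciably zero-inflated), and library sizes
    log-normal with sd 0.3 around 2e5 reads per well.
    """

    n_genes: int = 2000
    plate_format: int = 384
    treatments: tuple[TreatmentSpec, ...] = ()
    dose_compounds: tuple[DoseCompoundSpec, ...] = ()
    n_vehicle: int = 19
    vehicle_name: str = "DMSO"
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    dispersion_a0: float = 0.05
    dispersion_a1: float = 2.0
    zero_inflation_b0: float = -1.5
    zero_inflation_b1: float = 0.75
    zero_inflation: bool = True
    libsize_location: float = 2e5
    libsize_log_sd: float = 0.3
    batch_row_sd: float = 0.0    # log2 sd of a per-plate-row multiplicative effect
    plate_name: str = "plate1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(f"unsupported plate format {self.plate_format}")
        if not 0 <= self.libsize_log_sd:
            raise ValueError("libsize_log_sd must be non-negative")
        for t in self.treatments:
            if not 0 <= t.frac_de <= 1:
                raise ValueError(f"frac_de for {t.name} outside [0, 1]")
            if t.replicates < 1:
                raise ValueError(f"{t.name}: replicates must be positive")
        n_wells = self._n_wells()
        rows, ncol = PLATE_FORMATS[self.plate_format]
        if n_wells > len(rows) * ncol:
            raise ValueError(
                f"layout needs {n_wells} wells; a {self.plate_format}-well plate "
                f"has only {len(rows) * ncol}"
            )

    def _n_wells(self) -> int:
        n = self.n_vehicle + sum(t.replicates for t in self.treatments)
        n += sum(len(d.concentrations) * d.replicates for d in self.dose_compounds)
        return n


@dataclass
class SimTruth:
    """Planted ground truth: per-treatment DE gene LFCs, per-compound 4PL
    parameters and per-gene EC50s, per-well size factors and batch
    multipliers."""

    de_lfc: dict[str, dict[str, float]]
    dose_truth: dict[str, dict]
    size_factors: np.ndarray
    batch_multipliers: np.ndarray
    baseline_mu: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    config: SimConfig

    def de_genes(self, treatment: str) -> set[str]:
        return set(self.de_lfc.get(treatment, {}))


def default_screen_config(
    n_genes: int = 5000, n_treatments: int = 32, seed: int = 0
) -> SimConfig:
    """The full-plate default: 32 fixed-dose treatments x 3 replicates,
    19 vehicle wells, and two 8-point dose compounds in duplicate."""
    treatments = tuple(
        TreatmentSpec(name=f"compound_{i:02d}", concentration=10.0, mu_floor=5.0)
        for i in range(1, n_treatments + 1)
    )
    dose = (
        DoseCompoundSpec(name="dose_A"),
        DoseCompoundSpec(name="dose_B", upper=-2.5, ec50_range=(0.3, 3.0)),
    )
    return SimConfig(
        n_genes=n_genes, treatments=treatments, dose_compounds=dose, seed=seed
    )


def _plate_wells(plate_format: int) -> list[str]:
    rows, ncol = PLATE_FORMATS[plate_format]
    return [f"{r}{c}" for r in rows for c in range(1, ncol + 1)]


def _fourpl(x: np.ndarray, lower: float, upper: float, hill: float, ec50: float):
    return lower + (upper - lower) / (1.0 + (ec50 / x) ** hill)


def simulate_screen(config: SimConfig) -> tuple[Screen, SimTruth]:
    """Draw a complete screen plus its ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    gene_ids = np.array([f"GENE{i:05d}" for i in range(g)], dtype=object)
    mu = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, g)
    disp = config.dispersion_a0 + config.dispersion_a1 / mu
    theta = 1.0 / np.clip(disp, 1e-4, 1e4)

    # ---- layout ---------------------------------------------------------
    records: list[dict] = []

    def add_wells(name, conc, unit, stype, n_reps):
        start = sum(1 for r in records if r["treatment"] == name)
        for rep in range(1, n_reps + 1):
            records.append(
                dict(treatment=name, concentration=conc, unit=unit,
                     sample_type=stype, replicate=start + rep)
            )

    add_wells(config.vehicle_name, 0.0, "percent", "vehicle", config.n_vehicle)
    for t in config.treatments:
        add_wells(t.name, t.concentration, "uM", "treatment", t.replicates)
    for d in config.dose_compounds:
        for conc in d.concentrations:
            add_wells(d.name, conc, "uM", "treatment", d.replicates)

    n_wells = len(records)
    wells = _plate_wells(config.plate_format)[:n_wells]
    meta = pd.DataFrame(records)
    meta.insert(0, "well", wells)
    meta.insert(0, "barcode", [f"BC{i:04d}" for i in range(n_wells)])
    meta["plate"] = config.plate_name
    metadata = PlateMetadata(meta, plate_format=config.plate_format)

    # ---- planted effects ------------------------------------------------
    delta = np.zeros((g, n_wells))
    de_lfc: dict[str, dict[str, float]] = {}
    col_of = {
        (r["treatment"], r["concentration"]): [] for r in records
    }
    for j, r in enumerate(records):
        col_of[(r["treatment"], r["concentration"])].append(j)

    for t in config.treatments:
        eligible = np.flatnonzero(mu >= t.mu_floor)
        n_de = int(round(t.frac_de * g))
        n_de = min(n_de, len(eligible))
        chosen = rng.choice(eligible, size=n_de, replace=False)
        if t.lfc_sd > 0:
            lfcs = rng.normal(0.0, t.lfc_sd, n_de)
        else:
            signs = rng.choice([-1.0, 1.0], size=n_de)
            lfcs = signs * t.lfc_location
        de_lfc[t.name] = {gene_ids[i]: float(l) for i, l in zip(chosen, lfcs)}
        cols = col_of[(t.name, t.concentration)]
        for i, l in zip(chosen, lfcs):
            delta[i, cols] += l

    dose_truth: dict[str, dict] = {}
    for d in config.dose_compounds:
        eligible = np.flatnonzero(mu >= d.mu_floor)
        chosen = rng.choice(eligible, size=min(d.n_responsive, len(eligible)),
                            replace=False)
        ec50 = np.exp(rng.uniform(np.log(d.ec50_range[0]), np.log(d.ec50_range[1]),
                                  len(chosen)))
        dose_truth[d.name] = {
            "lower": d.lower, "upper": d.upper, "hill": d.hill,
            "genes": {gene_ids[i]: float(e) for i, e in zip(chosen, ec50)},
        }
        for conc in d.concentrations:
            cols = col_of[(d.name, conc)]
            lfc_at = _fourpl(np.asarray(conc, dtype=float), d.lower, d.upper,
                             d.hill, ec50)
            for i, l in zip(chosen, lfc_at):
                delta[i, cols] += l

    # ---- nuisance structure --------------------------------------------
    s = np.exp(rng.normal(0.0, config.libsize_log_sd, n_wells))
    batch = np.ones(n_wells)
    if config.batch_row_sd > 0:
        row_labels = [w[0] for w in wells]
        effects = {
            r: 2.0 ** rng.normal(0.0, config.batch_row_sd)
            for r in sorted(set(row_labels))
        }
        batch = np.array([effects[r] for r in row_labels])

    # scale so a typical well lands near the target library size
    base_total = mu.sum()
    depth = config.libsize_location / base_total
    mean = depth * (s * batch)[None, :] * mu[:, None] * 2.0 ** delta

    # ---- sampling -------------------------------------------------------
    p_nb = theta[:, None] / (theta[:, None] + np.maximum(mean, 1e-12))
    counts = rng.negative_binomial(theta[:, None], p_nb, size=(g, n_wells))
    pi = np.zeros(g)
    if config.zero_inflation:
        pi = 1.0 / (1.0 + np.exp(-(config.zero_inflation_b0
                                   - config.zero_inflation_b1 * np.log(mu + 1.0))))
        dropout = rng.random((g, n_wells)) < pi[:, None]
        counts = np.where(dropout, 0, counts)

    counts_cm = CountMatrix(
        counts.astype(np.int64), gene_ids, gene_ids.copy(), metadata.barcodes
    )
    screen = Screen(counts_cm, metadata, [f"simulated screen (seed={config.seed})"])
    truth = SimTruth(
        de_lfc=de_lfc,
        dose_truth=dose_truth,
        size_factors=s,
        batch_multipliers=batch,
        baseline_mu=depth * mu,
        theta=theta,
        pi=pi,
        config=config,
    )
    return screen, truth


def write_fixture(
    screen: Screen, truth: SimTruth, directory: str | Path, overwrite: bool = False
) -> None:
    """Write triplet counts + metadata TSV + truth JSON; the triplet and
    sheet round-trip exactly through the plate_io readers."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)
    write_count_triplet(screen.counts, directory)
    write_metadata(screen.metadata, directory / "metadata.tsv")

    cfg = asdict(truth.config)
    payload = {
        "schema_version": 1,
        "config": cfg,
        "de_lfc": truth.de_lfc,
        "dose_truth": truth.dose_truth,
        "size_factors": truth.size_factors.tolist(),
        "batch_multipliers": truth.batch_multipliers.tolist(),
        "baseline_mu": truth.baseline_mu.tolist(),
        "theta": truth.theta.tolist(),
        "pi": truth.pi.tolist(),
    }
    (directory / "truth.json").write_text(json.dumps(payload, indent=1))
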