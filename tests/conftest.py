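"""Shared fixtures: small simulated screens with known ground truth."""

import numpy as np
import pytest

from httrscreen.qc import GeneFilterSpec, filter_genes
from httrscreen.sim import (
    DoseCompoundSpec,
    SimConfig,
    TreatmentSpec,
    simulate_screen,
)


@pytest.fixture(scope="session")
def signal_screen():
    """One treatment with planted |log2FC| = 2 DE among expressed genes,
    3 replicates vs 19 vehicle wells."""
    cfg = SimConfig(
        n_genes=1000,
        treatments=(TreatmentSpec("campto", frac_de=0.05, mu_floor=50.0),),
        seed=42,
    )
    screen, truth = simulate_screen(cfg)
    return filter_genes(screen, GeneFilterSpec()), truth


@pytest.fixture(scope="session")
def null_screen():
    """No planted DE anywhere; used for calibration checks."""
    cfg = SimConfig(
        n_genes=1000, treatments=(TreatmentSpec("sham", frac_de=0.0),), seed=7
    )
    screen, truth = simulate_screen(cfg)
    return filter_genes(screen, GeneFilterSpec()), truth


@pytest.fixture(scope="session")
def dose_screen():
    """A dose-series compound with 4PL-shaped planted responses."""
    cfg = SimConfig(
        n_genes=600,
        treatments=(TreatmentSpec("ref", frac_de=0.05, mu_floor=50.0),),
        dose_compounds=(DoseCompoundSpec("doseA", n_responsive=40, mu_floor=50.0),),
        seed=11,
    )
    screen, truth = simulate_screen(cfg)
    return filter_genes(screen, GeneFilterSpec()), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
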