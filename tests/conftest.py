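"""Shared fixtures: small synthetic cohorts and spectra."""

from __future__ import annotations

import numpy as np
import pytest

import plaquescope as ps
from plaquescope.synthetic import (
    CohortConfig,
    GenotypeSpec,
    NoiseSpec,
    PlaqueTruth,
    SpeciesSpec,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_panel() -> list[SpeciesSpec]:
    """A minimal panel: one depleted, one enriched, one background lipid and
    one A-beta-like peptide."""
    return [
        SpeciesSpec("sulfatide", 888.6, "neg", 20.0, "depleted", 0.8,
                    plaque_jitter=0.05),
        SpeciesSpec("gm1", 1544.9, "neg", 10.0, "enriched_whole", 2.0,
                    maturity_coupling=3.0, plaque_jitter=0.05),
        SpeciesSpec("pc_bg", 760.6, "neg", 50.0),
        SpeciesSpec("abeta40", 4330.9, "peptide", 2.0, "enriched_whole", 30.0,
                    maturity_exponent=1.0, plaque_jitter=0.03),
        SpeciesSpec("bg_pep", 2100.0, "peptide", 20.0),
    ]


@pytest.fixture(scope="module")
def small_config() -> CohortConfig:
    return CohortConfig(
        genotypes=[GenotypeSpec("gA", "compact", small_panel()),
                   GenotypeSpec("gB", "cored", small_panel())],
        animals_per_genotype=1, plaques_per_animal=(2, 2), grid=(56, 56),
        noise=NoiseSpec(0.05, 0.002, 0.01), seed=7,
        radius_range=(25.0, 40.0))


@pytest.fixture(scope="module")
def small_cohort(small_config):
    return ps.generate_cohort(small_config)


@pytest.fixture(scope="module")
def small_animal(small_cohort):
    return small_cohort.animals[0]


@pytest.fixture()
def plaque() -> PlaqueTruth:
    return PlaqueTruth(center=(32, 32), radius=50.0, core_radius=20.0,
                       maturity=0.8, phenotype="cored")


def gaussian_spectrum(mz0: float, amplitude: float, resolution: float,
                      lo: float, hi: float, spacing: float):
    """Noiseless single-Gaussian spectrum fixture."""
    axis = np.arange(lo, hi + spacing, spacing)
    fwhm = mz0 / resolution
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return ps.MassSpectrum(axis, amplitude * np.exp(-0.5 * ((axis - mz0) / sigma) ** 2))
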