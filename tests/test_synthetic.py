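"""The synthetic cohort generator: determinism, geometry, planted effects."""

import math

import numpy as np
import pytest

from plaquescope.synthetic import (
    CohortConfig,
    GenotypeSpec,
    NoiseSpec,
    PlacementError,
    PlaqueTruth,
    SpeciesSpec,
    generate_cohort,
    make_mz_axis,
    spatial_modulation,
    synth_spectrum,
)
from tests.conftest import small_panel

FWHM_TO_SIGMA = 1 / (2 * math.sqrt(2 * math.log(2)))


class TestPlaqueTruth:
    def test_phenotype_invariants_enforced(self):
        with pytest.raises(ValueError):
            PlaqueTruth((5, 5), 50.0, 30.0, 0.5, "compact")  # ratio 0.6
        with pytest.raises(ValueError):
            PlaqueTruth((5, 5), 50.0, 30.0, 0.5, "cored")  # ratio 0.6
        PlaqueTruth((5, 5), 50.0, 45.0, 0.5, "compact")
        PlaqueTruth((5, 5), 50.0, 20.0, 0.5, "cored")

    def test_core_radius_bounds(self):
        with pytest.raises(ValueError):
            PlaqueTruth((0, 0), 40.0, 50.0, 0.5, "compact")


class TestSpeciesSpec:
    def test_mz_must_match_modality_range(self):
        with pytest.raises(ValueError, match="outside"):
            SpeciesSpec("x", 3000.0, "neg", 1.0)
        with pytest.raises(ValueError, match="outside"):
            SpeciesSpec("x", 700.0, "peptide", 1.0)

    def test_depleted_needs_bounded_effect(self):
        with pytest.raises(ValueError):
            SpeciesSpec("x", 800.0, "neg", 1.0, "depleted", 1.5)


class TestSynthSpectrum:
    def test_zero_amplitudes_zero_noise_all_zero(self):
        axis = make_mz_axis("peptide", 1.0)
        rng = np.random.default_rng(0)
        y = synth_spectrum({"a@2000": 0.0}, axis, 1000.0, NoiseSpec(0, 0, 0),
                           rng)
        np.testing.assert_array_equal(y, 0.0)

    def test_peak_width_follows_resolution_model(self):
        axis = np.arange(4400.0, 4630.0, 0.1)
        rng = np.random.default_rng(0)
        y = synth_spectrum({"ab@4515": 10.0}, axis, 1000.0, NoiseSpec(0, 0, 0),
                           rng)
        half = y >= 5.0
        fwhm = axis[half][-1] - axis[half][0]
        assert fwhm == pytest.approx(4.515, abs=0.2)

    def test_trapezoid_area_matches_gaussian_integral(self):
        amp = 8.0
        axis = np.arange(4000.0, 5000.0, 0.25)
        rng = np.random.default_rng(0)
        y = synth_spectrum({"ab@4515": amp}, axis, 1000.0, NoiseSpec(0, 0, 0),
                           rng)
        sigma = 4.515 * FWHM_TO_SIGMA
        assert np.trapezoid(y, axis) == pytest.approx(
            amp * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_out_of_axis_species_named_in_error(self):
        axis = make_mz_axis("lipid_neg", 1.0)
        with pytest.raises(ValueError, match="pepx"):
            synth_spectrum({"pepx@4000": 1.0}, axis, 1000.0,
                           NoiseSpec(0, 0, 0), np.random.default_rng(0))


class TestSpatialModulation:
    def plaque(self, phenotype="cored"):
        ratio = 0.9 if phenotype == "compact" else 0.4
        return PlaqueTruth((50, 50), 50.0, ratio * 50.0, 0.8, phenotype)

    @pytest.mark.parametrize("pattern", ["depleted", "enriched_whole",
                                         "enriched_core",
                                         "enriched_periphery",
                                         "background_only"])
    def test_far_pixel_unmodulated(self, pattern):
        s = SpeciesSpec("x", 800.0, "neg", 1.0, pattern,
                        0.8 if pattern == "depleted" else 2.0,
                        maturity_coupling=1.0)
        mult = spatial_modulation(s, [self.plaque()], (50, 90), 10.0)
        assert mult == pytest.approx(1.0, abs=1e-6)

    def test_periphery_pattern_silent_at_center(self):
        s = SpeciesSpec("x", 800.0, "neg", 1.0, "enriched_periphery", 3.0)
        mult = spatial_modulation(s, [self.plaque()], (50, 50), 10.0)
        assert mult == pytest.approx(1.0, abs=1e-9)

    def test_total_depletion_zero_at_center(self):
        s = SpeciesSpec("x", 800.0, "neg", 1.0, "depleted", 1.0)
        mult = spatial_modulation(s, [self.plaque()], (50, 50), 10.0)
        assert mult == pytest.approx(0.0, abs=1e-12)

    def test_enrichment_scales_with_maturity(self):
        s = SpeciesSpec("x", 800.0, "neg", 1.0, "enriched_whole", 2.0,
                        maturity_coupling=3.0)
        lo = PlaqueTruth((50, 50), 50.0, 20.0, 0.3, "cored")
        hi = PlaqueTruth((50, 50), 50.0, 20.0, 0.9, "cored")
        m_lo = spatial_modulation(s, [lo], (50, 50), 10.0)
        m_hi = spatial_modulation(s, [hi], (50, 50), 10.0)
        assert m_hi > m_lo > 1.0


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self, small_config):
        c1 = generate_cohort(small_config)
        c2 = generate_cohort(small_config)
        for a1, a2 in zip(c1.animals, c2.animals):
            for m in a1.datasets:
                np.testing.assert_array_equal(a1.datasets[m].intensities,
                                              a2.datasets[m].intensities)
            assert [p.center for p in a1.plaques] == \
                [p.center for p in a2.plaques]
            np.testing.assert_array_equal(
                a1.fluorescence.channels["qFTAA"],
                a2.fluorescence.channels["qFTAA"])

    def test_plaque_count_within_configured_range(self):
        from plaquescope.synthetic import iter_generate_cohort

        cfg = CohortConfig(
            genotypes=[GenotypeSpec("g", "cored", small_panel())],
            animals_per_genotype=3, plaques_per_animal=(4, 6),
            grid=(120, 120), seed=5)
        counts = []
        for animal in iter_generate_cohort(cfg):
            counts.append(len(animal.plaques))
            animal.datasets = {}  # only the truth lists matter here
        assert len(counts) == 3
        assert all(c in (4, 5, 6) for c in counts)

    def test_plaques_inside_grid_and_separated(self, small_cohort):
        cfg = small_cohort.config
        max_r_px = cfg.radius_range[1] / cfg.pixel_pitch
        for animal in small_cohort.animals:
            centers = [p.center for p in animal.plaques]
            for p in animal.plaques:
                r, c = p.center
                assert max_r_px <= r <= cfg.grid[0] - max_r_px
                assert max_r_px <= c <= cfg.grid[1] - max_r_px
            for (r1, c1), (r2, c2) in zip(centers, centers[1:]):
                sep_um = cfg.pixel_pitch * math.hypot(r1 - r2, c1 - c2)
                assert sep_um > 2 * cfg.radius_range[1]

    def test_grid_too_small_raises_placement_error(self):
        cfg = CohortConfig(
            genotypes=[GenotypeSpec("g", "cored", small_panel())],
            animals_per_genotype=1, plaques_per_animal=(6, 6),
            grid=(20, 20), seed=0)
        with pytest.raises(PlacementError, match="separation"):
            generate_cohort(cfg)

    def test_depleted_species_suppressed_in_plaques(self, small_animal,
                                                    small_config):
        ds = small_animal.datasets["lipid_neg"]
        grid = small_config.grid
        # sulfatide-like species at 888.6: pick its channel window
        window = (ds.mz_axis > 887.5) & (ds.mz_axis < 889.7)
        img = ds.intensities[:, window].sum(axis=1).reshape(grid)
        in_plaque = np.zeros(grid, bool)
        far = np.ones(grid, bool)
        rr, cc = np.meshgrid(np.arange(grid[0]), np.arange(grid[1]),
                             indexing="ij")
        for p in small_animal.plaques:
            d = 10.0 * np.hypot(rr - p.center[0], cc - p.center[1])
            in_plaque |= d <= 0.5 * p.radius
            far &= d > 4 * p.radius
        assert img[in_plaque].mean() < 0.5 * img[far].mean()

    def test_fluorescence_channels_follow_kernels(self, small_animal):
        q = small_animal.fluorescence.channels["qFTAA"]
        h = small_animal.fluorescence.channels["hFTAA"]
        p = small_animal.plaques[0]
        r, c = p.center
        assert h[r, c] >= 0.9  # whole kernel peaks at the center
        # q (core kernel x maturity) peaks at center too but decays faster
        r_off = int(round(0.8 * p.radius / 10.0))
        assert q[r, c] > q[r, c + r_off]

    def test_conservation_without_noise_and_plaque_species(self):
        bg_only = [SpeciesSpec("bg1", 800.0, "neg", 10.0),
                   SpeciesSpec("bg2", 1200.0, "neg", 5.0)]
        cfg = CohortConfig(
            genotypes=[GenotypeSpec("g", "cored", bg_only)],
            animals_per_genotype=1, plaques_per_animal=(2, 2),
            grid=(48, 48), noise=NoiseSpec(0, 0, 0), seed=3,
            texture_sigma=0.0)
        cohort = generate_cohort(cfg)
        cube = cohort.animals[0].datasets["lipid_neg"].intensities
        # every pixel spectrum identical to the pure background composition
        np.testing.assert_allclose(cube - cube[0][None, :], 0.0, atol=1e-5)
        assert cube[0].max() > 0

    def test_abeta_amplitude_increasing_in_maturity(self):
        s = SpeciesSpec("ab40", 4330.9, "peptide", 2.0, "enriched_whole",
                        30.0, maturity_exponent=1.0)
        maturities = np.linspace(0.3, 1.0, 8)
        amps = []
        for m in maturities:
            p = PlaqueTruth((50, 50), 50.0, 20.0, float(m), "cored")
            amps.append(spatial_modulation(s, [p], (50, 50), 10.0))
        assert np.all(np.diff(amps) > 0)


class TestCohortTables:
    def test_species_table_lists_both_genotypes(self, small_cohort):
        table = small_cohort.species_table()
        assert set(table["genotype"]) == {"gA", "gB"}
        assert "truth_class" in table.columns

    def test_annotation_table_unique_names(self, small_cohort):
        ann = small_cohort.annotation_table()
        assert ann["name"].is_unique
        assert set(ann.columns) == {"name", "mz", "ion_mode", "class"}

    def test_write_cohort_artifacts(self, small_cohort, tmp_path):
        from plaquescope.synthetic import write_cohort

        out = write_cohort(small_cohort, tmp_path / "cohort")
        a0 = small_cohort.animals[0].animal_id
        assert (out / "species.csv").exists()
        assert (out / a0 / "lipid_neg.imzML").exists()
        assert (out / a0 / "fluorescence.tiff").exists()
        assert (out / a0 / "truth.json").exists()
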