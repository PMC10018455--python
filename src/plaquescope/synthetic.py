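"""Synthetic multimodal MSI cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: amyloid plaques as disk-shaped spatial features on a cortical
background, species-specific whole-plaque / core / periphery enrichment and
sulfatide-like depletion, two genotype phenotypes (compact vs cored plaques),
and inter-plaque amplitude covariation between lipids and A-beta driven by a
latent per-plaque *maturity* variable.

Model summary
-------------
Each plaque has a center, a radius r, a core radius r_c and a maturity
m in (0, 1].  Spatial influence is carried by three Gaussian kernels of
distance d from the center, each equal to 1 at its own peak:

* whole-plaque  K_w = exp(-d^2 / (2 (r/2)^2))
* core          K_c = exp(-d^2 / (2 (min(r_c, r/2)/2.2)^2))
* periphery     K_a = exp(-(d - r_a)^2 / (2 (0.07 r)^2)),  r_a = r_c + 0.6 (r - r_c)

A species with pattern ``enriched_whole`` multiplies its background level at
a pixel by ``1 + e * (1 + beta m) * m**gamma * J_p * K_w`` where e is the
effect size, beta the maturity coupling, gamma an optional maturity exponent
(used for the A-beta proteoforms) and J_p a per-plaque log-normal
"biological" amplitude factor modelling plaque-to-plaque heterogeneity
beyond maturity.  ``enriched_core`` / ``enriched_periphery`` use K_c / K_a;
``depleted`` multiplies by ``1 - e * K_w``; ``background_only`` is flat.
Each species additionally rides on its own smooth multiplicative tissue
texture field (tissue heterogeneity unrelated to plaques).

Spectra are sums of Gaussian peaks whose widths follow a constant-resolving-
power model FWHM(m) = m / R (R = 1000 FWHM, anchored at m/z 4515 for the
linear-mode peptide modality), with per-peak multiplicative log-normal noise
and an additive Gaussian baseline, clipped at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .msi_io import (
    MODALITY_ION_MODE,
    MODALITY_RANGES,
    FluorescenceImage,
    MSIDataset,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

PATTERNS = ("depleted", "enriched_whole", "enriched_core",
            "enriched_periphery", "background_only")


class PlacementError(RuntimeError):
    """Plaques could not be placed under the separation constraint."""


@dataclass
class PlaqueTruth:
    """Ground-truth geometry and latent state of one planted plaque."""

    center: tuple[int, int]  # (row, col), 0-based
    radius: float  # micrometres
    core_radius: float  # micrometres
    maturity: float  # in (0, 1]
    phenotype: str  # compact | cored

    def __post_init__(self) -> None:
        if not (0 < self.core_radius <= self.radius):
            raise ValueError("need 0 < core_radius <= radius")
        if not (0 < self.maturity <= 1):
            raise ValueError("maturity must lie in (0, 1]")
        ratio = self.core_radius / self.radius
        if self.phenotype == "compact" and ratio < 0.8:
            raise ValueError("compact phenotype requires core_radius/radius >= 0.8")
        if self.phenotype == "cored" and ratio > 0.5:
            raise ValueError("cored phenotype requires core_radius/radius <= 0.5")
        if self.phenotype not in ("compact", "cored"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class SpeciesSpec:
    """One molecular species planted in a modality.

    ``maturity_coupling`` (beta) couples the enrichment amplitude to plaque
    maturity; ``maturity_exponent`` (gamma) additionally scales the amplitude
    by maturity**gamma (A-beta 1-40 uses gamma=1, A-beta 1-42 gamma=2).
    ``plaque_jitter`` is the sigma of the per-plaque log-normal amplitude
    factor.  ``annotate=False`` keeps a species out of the annotation table
    (used for co-binned secondary pools); ``truth_class`` records the planted
    interplay class for recovery scoring.
    """

    name: str
    mz: float
    ion_mode: str  # neg | pos | peptide
    base_abundance: float
    pattern: str = "background_only"
    effect_size: float = 0.0
    maturity_coupling: float = 0.0
    maturity_exponent: float = 0.0
    plaque_jitter: float = 0.05
    annotate: bool = True
    truth_class: str = "none"
    lipid_class: str = ""
    discriminative: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.base_abundance < 0 or self.effect_size < 0:
            raise ValueError("abundance and effect size must be >= 0")
        if self.pattern == "depleted" and not (0 <= self.effect_size <= 1):
            raise ValueError("depleted species need effect_size in [0, 1]")
        modality = ION_MODE_TO_MODALITY[self.ion_mode]
        lo, hi = MODALITY_RANGES[modality]
        if not (lo <= self.mz <= hi):
            raise ValueError(
                f"species {self.name!r}: m/z {self.mz} outside the "
                f"{modality} acquisition range {lo}-{hi}")

    @property
    def modality(self) -> str:
        return ION_MODE_TO_MODALITY[self.ion_mode]


ION_MODE_TO_MODALITY = {"neg": "lipid_neg", "pos": "lipid_pos", "peptide": "peptide"}


@dataclass
class NoiseSpec:
    """Instrument noise: per-peak log-normal sigma, additive Gaussian sigma and
    a constant baseline, the latter two as fractions of the modality's largest
    expected peak amplitude."""

    multiplicative_sigma: float = 0.15
    additive_sigma: float = 0.005
    baseline: float = 0.01

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(self.multiplicative_sigma * factor,
                         self.additive_sigma * factor,
                         self.baseline * factor)


@dataclass
class GenotypeSpec:
    label: str
    phenotype: str  # compact | cored
    species: list[SpeciesSpec] = field(default_factory=list)


@dataclass
class CohortConfig:
    """Study design of one synthetic cohort."""

    genotypes: list[GenotypeSpec]
    animals_per_genotype: int = 3
    plaques_per_animal: tuple[int, int] = (4, 6)
    grid: tuple[int, int] = (200, 200)
    pixel_pitch: float = 10.0  # micrometres
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    radius_range: tuple[float, float] = (30.0, 60.0)  # micrometres
    maturity_range: tuple[float, float] = (0.3, 1.0)
    resolution: float = 1000.0  # m / FWHM(m)
    mz_spacing: dict = field(default_factory=lambda: {"lipid": 0.25, "peptide": 1.0})
    texture_sigma: float = 0.05  # sd of per-species tissue texture field
    texture_length: float = 10.0  # texture correlation length, pixels
    separation_factor: float = 3.0  # min center separation, x max radius (>= 2)
    max_placement_attempts: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.plaques_per_animal
        if not (1 <= lo <= hi):
            raise ValueError("invalid plaques_per_animal range")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass
class AnimalData:
    """Everything generated for one animal (one synthetic tissue section)."""

    animal_id: str
    genotype: str
    phenotype: str
    datasets: dict[str, MSIDataset]
    fluorescence: FluorescenceImage
    plaques: list[PlaqueTruth]
    species: list[SpeciesSpec]


@dataclass
class Cohort:
    config: CohortConfig
    animals: list[AnimalData]

    def species_table(self) -> pd.DataFrame:
        rows = []
        seen = set()
        for a in self.animals:
            for s in a.species:
                key = (s.name, a.genotype)
                if key in seen:
                    continue
                seen.add(key)
                rows.append({"name": s.name, "mz": s.mz, "ion_mode": s.ion_mode,
                             "class": s.lipid_class, "genotype": a.genotype,
                             "pattern": s.pattern, "effect_size": s.effect_size,
                             "maturity_coupling": s.maturity_coupling,
                             "annotate": s.annotate, "truth_class": s.truth_class,
                             "discriminative": s.discriminative})
        return pd.DataFrame(rows)

    def annotation_table(self) -> pd.DataFrame:
        """Deduplicated annotation CSV (name, mz, ion_mode, class)."""
        df = self.species_table()
        df = df[df["annotate"]]
        return (df[["name", "mz", "ion_mode", "class"]]
                .drop_duplicates(subset=["name"])
                .reset_index(drop=True))


# ---------------------------------------------------------------------------
# kernels and spatial modulation
# ---------------------------------------------------------------------------

def _kernel_profiles(plaque: PlaqueTruth, dist_um: np.ndarray) -> dict[str, np.ndarray]:
    """The three spatial kernels evaluated at distances (in um) from a center."""
    r, rc = plaque.radius, plaque.core_radius
    sigma_w = r / 2.0
    # the dense fibrillar center: capped at half the radius so the core
    # kernel stays meaningfully tighter than the whole-plaque kernel even
    # for compact plaques (core_radius ~ radius)
    sigma_c = min(rc, 0.5 * r) / 2.2
    r_a = rc + 0.6 * (r - rc)
    sigma_a = 0.07 * r
    return {
        "whole": np.exp(-0.5 * (dist_um / sigma_w) ** 2),
        "core": np.exp(-0.5 * (dist_um / sigma_c) ** 2),
        "annulus": np.exp(-0.5 * ((dist_um - r_a) / sigma_a) ** 2),
    }


_PATTERN_KERNEL = {"depleted": "whole", "enriched_whole": "whole",
                   "enriched_core": "core", "enriched_periphery": "annulus"}


def _plaque_factor(species: SpeciesSpec, plaque: PlaqueTruth, kernel: np.ndarray,
                   jitter: float = 1.0) -> np.ndarray:
    """Multiplicative factor contributed by one plaque at given kernel values."""
    m = plaque.maturity
    if species.pattern == "background_only":
        return np.ones_like(kernel)
    if species.pattern == "depleted":
        return 1.0 - species.effect_size * kernel
    amp = (species.effect_size * (1.0 + species.maturity_coupling * m)
           * m ** species.maturity_exponent * jitter)
    return 1.0 + amp * kernel


def spatial_modulation(species: SpeciesSpec, plaques: list[PlaqueTruth],
                       pixel: tuple[int, int], pixel_pitch: float = 10.0) -> float:
    """Unitless abundance multiplier for one species at one pixel.

    A total function on the grid: pixels far from every plaque return 1.
    Factors of overlapping plaques compose multiplicatively (the generator's
    placement constraint keeps plaques disjoint in practice).
    """
    row, col = pixel
    factor = 1.0
    for p in plaques:
        d = pixel_pitch * math.hypot(row - p.center[0], col - p.center[1])
        kernels = _kernel_profiles(p, np.asarray([d]))
        k = kernels[_PATTERN_KERNEL.get(species.pattern, "whole")]
        factor *= float(_plaque_factor(species, p, k)[0])
    return factor


def _modulation_map(species: SpeciesSpec, plaques: list[PlaqueTruth],
                    grid: tuple[int, int], pixel_pitch: float,
                    jitters: np.ndarray | None,
                    supersample: int = 3) -> np.ndarray:
    """Vectorized per-pixel multiplier over the whole grid (patch-local).

    Kernels are rasterized area-averaged over each pixel (``supersample`` x
    ``supersample`` subpixel evaluation): the narrow peripheral annulus is
    thinner than a pixel, and point-sampling it at pixel centers would alias
    badly.
    """
    rows, cols = grid
    out = np.ones((rows, cols), dtype=np.float64)
    if species.pattern == "background_only":
        return out
    ss = max(1, int(supersample))
    offsets = (np.arange(ss) + 0.5) / ss - 0.5  # subpixel offsets in [-.5,.5)
    for i, p in enumerate(plaques):
        reach_px = int(math.ceil(4.0 * p.radius / pixel_pitch)) + 1
        r0 = max(0, p.center[0] - reach_px)
        r1 = min(rows, p.center[0] + reach_px + 1)
        c0 = max(0, p.center[1] - reach_px)
        c1 = min(cols, p.center[1] + reach_px + 1)
        rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                             np.arange(c0, c1, dtype=float), indexing="ij")
        kern = np.zeros(rr.shape)
        for dr in offsets:
            for dc in offsets:
                d = pixel_pitch * np.hypot(rr + dr - p.center[0],
                                           cc + dc - p.center[1])
                kern += _kernel_profiles(p, d)[_PATTERN_KERNEL[species.pattern]]
        kern /= ss * ss
        j = 1.0 if jitters is None else float(jitters[i])
        out[r0:r1, c0:c1] *= _plaque_factor(species, p, kern, j)
    return out


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def make_mz_axis(modality: str, spacing: float) -> np.ndarray:
    lo, hi = MODALITY_RANGES[modality]
    n = int(round((hi - lo) / spacing))
    return lo + spacing * np.arange(n + 1)


def peak_profile(mz: float, mz_axis: np.ndarray, resolution: float) -> np.ndarray:
    """Unit-amplitude Gaussian peak with FWHM = mz / resolution."""
    sigma = (mz / resolution) * FWHM_TO_SIGMA
    return np.exp(-0.5 * ((mz_axis - mz) / sigma) ** 2)


def synth_spectrum(species_amplitudes: dict[str, float], mz_axis: np.ndarray,
                   resolution: float, noise: NoiseSpec,
                   rng: np.random.Generator,
                   species_mz: dict[str, float] | None = None) -> np.ndarray:
    """Render one spectrum from species amplitudes.

    ``species_amplitudes`` maps species name to peak amplitude; ``species_mz``
    maps name to m/z (names of the form "<anything>@<mz>" are parsed when the
    map is omitted).  Noise: per-peak multiplicative log-normal with sigma
    ``noise.multiplicative_sigma``, plus additive Gaussian baseline with sigma
    ``noise.additive_sigma`` and offset ``noise.baseline``, both scaled by the
    largest amplitude.  The result is clipped at zero.
    """
    out = np.zeros_like(mz_axis, dtype=float)
    amax = max(species_amplitudes.values(), default=0.0)
    for name, amp in species_amplitudes.items():
        if amp < 0:
            raise ValueError(f"negative amplitude for species {name!r}")
        mz = species_mz[name] if species_mz else float(name.rsplit("@", 1)[1])
        if not (mz_axis[0] <= mz <= mz_axis[-1]):
            raise ValueError(f"species {name!r} m/z {mz} outside the axis range")
        if noise.multiplicative_sigma > 0:
            amp = amp * math.exp(noise.multiplicative_sigma * rng.standard_normal())
        out += amp * peak_profile(mz, mz_axis, resolution)
    if amax > 0 and (noise.additive_sigma > 0 or noise.baseline > 0):
        out += amax * noise.baseline
        out += amax * noise.additive_sigma * rng.standard_normal(out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _place_plaques(n: int, grid: tuple[int, int], pixel_pitch: float,
                   radius_range: tuple[float, float], rng: np.random.Generator,
                   max_attempts: int, separation_factor: float = 3.0
                   ) -> list[tuple[int, int]]:
    """Rejection-sample plaque centers, uniform over the grid interior, with
    pairwise separation > separation_factor x the maximum radius (the
    invariant requires > 2x; the default 3x keeps even dilated detected
    footprints of neighbouring plaques disjoint)."""
    rows, cols = grid
    margin = int(math.ceil(radius_range[1] / pixel_pitch)) + 1
    min_sep_px = max(2.0, separation_factor) * radius_range[1] / pixel_pitch
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise PlacementError(
            f"grid {grid} too small for plaque radius up to {radius_range[1]} um "
            f"at {pixel_pitch} um pitch (separation > {2 * radius_range[1]} um)")
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} plaques with center separation "
                f"> {min_sep_px * pixel_pitch} um in a {rows}x{cols} grid "
                f"after {max_attempts} attempts")
        r = int(rng.integers(margin, rows - margin))
        c = int(rng.integers(margin, cols - margin))
        if all(math.hypot(r - r0, c - c0) > min_sep_px for r0, c0 in centers):
            centers.append((r, c))
    return centers


def _sample_plaques(config: CohortConfig, phenotype: str,
                    rng: np.random.Generator) -> list[PlaqueTruth]:
    lo, hi = config.plaques_per_animal
    n = int(rng.integers(lo, hi + 1))
    centers = _place_plaques(n, config.grid, config.pixel_pitch,
                             config.radius_range, rng,
                             config.max_placement_attempts,
                             config.separation_factor)
    plaques = []
    for center in centers:
        radius = float(rng.uniform(*config.radius_range))
        if phenotype == "compact":
            ratio = float(rng.uniform(0.8, 0.95))
        else:
            ratio = float(rng.uniform(0.3, 0.5))
        maturity = float(rng.uniform(*config.maturity_range))
        plaques.append(PlaqueTruth(center=center, radius=radius,
                                   core_radius=ratio * radius,
                                   maturity=maturity, phenotype=phenotype))
    return plaques


def _texture_field(grid: tuple[int, int], sigma: float, length: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative tissue texture: 1 + correlated Gaussian field."""
    if sigma <= 0:
        return np.ones(grid)
    white = rng.standard_normal(grid)
    smooth = gaussian_filter(white, length)
    sd = smooth.std()
    if sd == 0:
        return np.ones(grid)
    return 1.0 + sigma * (smooth / sd)


def _generate_animal(config: CohortConfig, genotype: GenotypeSpec,
                     animal_id: str, rng: np.random.Generator) -> AnimalData:
    rows, cols = config.grid
    n_px = rows * cols
    coords = np.stack(np.meshgrid(np.arange(rows), np.arange(cols),
                                  indexing="ij"), axis=-1).reshape(-1, 2)

    plaques = _sample_plaques(config, genotype.phenotype, rng)

    datasets: dict[str, MSIDataset] = {}
    for modality in ("lipid_neg", "lipid_pos", "peptide"):
        ion_mode = MODALITY_ION_MODE[modality]
        species = [s for s in genotype.species if s.ion_mode == ion_mode]
        spacing = config.mz_spacing["peptide" if modality == "peptide" else "lipid"]
        axis = make_mz_axis(modality, spacing)

        # per-pixel, per-species amplitude maps (background x texture x plaques)
        amp = np.empty((n_px, len(species)), dtype=np.float32)
        for j, s in enumerate(species):
            texture = _texture_field(config.grid, config.texture_sigma,
                                     config.texture_length, rng)
            jitters = np.exp(s.plaque_jitter * rng.standard_normal(len(plaques)))
            mod = _modulation_map(s, plaques, config.grid, config.pixel_pitch,
                                  jitters)
            amp[:, j] = (s.base_abundance * texture * mod).reshape(-1)

        # per-pixel, per-peak multiplicative instrument noise
        if config.noise.multiplicative_sigma > 0:
            amp *= np.exp(config.noise.multiplicative_sigma
                          * rng.standard_normal(amp.shape).astype(np.float32))

        # accumulate each species' Gaussian peak within its +/-6 sigma window
        # (peaks are < 10 Da wide on a 2000+ Da axis; dense products waste
        # two orders of magnitude of work)
        cube = np.zeros((n_px, len(axis)), dtype=np.float32)
        for j, s in enumerate(species):
            sigma = (s.mz / config.resolution) * FWHM_TO_SIGMA
            lo = np.searchsorted(axis, s.mz - 6 * sigma)
            hi = np.searchsorted(axis, s.mz + 6 * sigma)
            window = np.exp(-0.5 * ((axis[lo:hi] - s.mz) / sigma) ** 2)
            cube[:, lo:hi] += amp[:, j:j + 1] * window.astype(np.float32)

        amax = max((s.base_abundance for s in species), default=0.0)
        if amax > 0 and config.noise.baseline > 0:
            cube += np.float32(amax * config.noise.baseline)
        if amax > 0 and config.noise.additive_sigma > 0:
            sigma = np.float32(amax * config.noise.additive_sigma)
            # chunked float32 noise: avoids a cube-sized float64 temporary
            step = max(1, 2**24 // cube.shape[1])
            for start in range(0, cube.shape[0], step):
                sl = slice(start, start + step)
                cube[sl] += sigma * rng.standard_normal(
                    cube[sl].shape, dtype=np.float32)
        np.clip(cube, 0.0, None, out=cube)

        datasets[modality] = MSIDataset(
            modality=modality, pixel_coords=coords,
            pixel_pitch=config.pixel_pitch, mz_axis=axis, intensities=cube)

    fluorescence = _render_fluorescence(config, plaques, rng)
    return AnimalData(animal_id=animal_id, genotype=genotype.label,
                      phenotype=genotype.phenotype, datasets=datasets,
                      fluorescence=fluorescence, plaques=plaques,
                      species=list(genotype.species))


def _render_fluorescence(config: CohortConfig, plaques: list[PlaqueTruth],
                         rng: np.random.Generator) -> FluorescenceImage:
    """q-FTAA follows each plaque's core kernel (scaled by maturity);
    h-FTAA follows the whole-plaque kernel."""
    rows, cols = config.grid
    q = np.zeros((rows, cols))
    h = np.zeros((rows, cols))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for p in plaques:
        d = config.pixel_pitch * np.hypot(rr - p.center[0], cc - p.center[1])
        kern = _kernel_profiles(p, d)
        q += p.maturity * kern["core"]
        h += kern["whole"]
    sigma = config.noise.additive_sigma
    if sigma > 0:
        q += sigma * rng.standard_normal(q.shape)
        h += sigma * rng.standard_normal(h.shape)
        q = np.clip(q, 0, None)
        h = np.clip(h, 0, None)
    return FluorescenceImage(channels={"qFTAA": q, "hFTAA": h},
                             pixel_size=config.pixel_pitch)


def generate_animal_ids(config: CohortConfig) -> list[tuple[str, str]]:
    """(animal_id, genotype label) pairs in generation order."""
    out = []
    for g in config.genotypes:
        for i in range(config.animals_per_genotype):
            out.append((f"{g.label}_{i + 1}", g.label))
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort.  Deterministic for a fixed ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    animals: list[AnimalData] = []
    streams = root.spawn(len(config.genotypes) * config.animals_per_genotype)
    k = 0
    for genotype in config.genotypes:
        for i in range(config.animals_per_genotype):
            rng = np.random.Generator(np.random.PCG64(streams[k]))
            k += 1
            animals.append(_generate_animal(config, genotype,
                                            f"{genotype.label}_{i + 1}", rng))
    return Cohort(config=config, animals=animals)


def iter_generate_cohort(config: CohortConfig):
    """Yield animals one at a time (same stream layout as generate_cohort).

    Memory-friendly variant: each animal's datacubes can be processed and
    dropped before the next animal is generated.
    """
    root = np.random.SeedSequence(config.seed)
    pairs = generate_animal_ids(config)
    streams = root.spawn(len(pairs))
    k = 0
    for genotype in config.genotypes:
        for _ in range(config.animals_per_genotype):
            rng = np.random.Generator(np.random.PCG64(streams[k]))
            aid = pairs[k][0]
            k += 1
            yield _generate_animal(config, genotype, aid, rng)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write each modality as continuous imzML, fluorescence as 2-channel
    TIFF, plaque truth as JSON and the species table as CSV."""
    from .msi_io import write_imzml, write_fluorescence_tiff

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.species_table().to_csv(out_dir / "species.csv", index=False)
    cohort.annotation_table().to_csv(out_dir / "annotations.csv", index=False)
    for animal in cohort.animals:
        adir = out_dir / animal.animal_id
        adir.mkdir(exist_ok=True)
        for modality, ds in animal.datasets.items():
            write_imzml(ds, adir / f"{modality}.imzML")
        write_fluorescence_tiff(animal.fluorescence, adir / "fluorescence.tiff")
        truth = {
            "animal_id": animal.animal_id,
            "genotype": animal.genotype,
            "phenotype": animal.phenotype,
            "plaques": [asdict(p) for p in animal.plaques],
        }
        (adir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir
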