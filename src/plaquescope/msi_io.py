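"""Reading, writing and spectrum-level preprocessing of MSI and microscopy data.

The pipeline's on-disk formats are the community standards: imzML (+ ibd) for
mass spectrometry imaging datacubes, multi-channel TIFF for fluorescence
microscopy, and CSV for annotation tables.  In memory, a modality lives in an
:class:`MSIDataset` (pixel coordinates + one shared m/z axis + a pixels x
channels intensity matrix); a single profile spectrum in a
:class:`MassSpectrum`.

Coordinates are 0-based ``(row, col)`` in row-major order throughout the
package; imzML's 1-based x/y convention is converted at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

MODALITY_RANGES: dict[str, tuple[float, float]] = {
    "lipid_neg": (400.0, 2500.0),
    "lipid_pos": (400.0, 2500.0),
    "peptide": (1500.0, 6000.0),
}

MODALITY_TAGS = {"lipid_neg": "LN", "lipid_pos": "LP", "peptide": "P"}

#: ion mode of each modality, as used in annotation tables
MODALITY_ION_MODE = {"lipid_neg": "neg", "lipid_pos": "pos", "peptide": "peptide"}

PROTON_MASS = 1.00727646688

# Residue (= amino acid minus water) masses for the 20 canonical residues.
# Monoisotopic values from the IUPAC 2021 atomic masses; average values from
# standard elemental compositions.
_RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_RESIDUE_AVG = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576,
    "N": 114.1026, "D": 115.0874, "Q": 128.1292, "K": 128.1723,
    "E": 129.1140, "M": 131.1961, "H": 137.1393, "F": 147.1739,
    "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}
_WATER_MONO = 18.01056
_WATER_AVG = 18.0153


class FormatError(ValueError):
    """Raised for ill-formed or inconsistent on-disk data."""


@dataclass
class MassSpectrum:
    """A single profile spectrum: strictly increasing m/z axis + intensities."""

    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.shape != self.intensities.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise FormatError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class MSIDataset:
    """One modality's datacube on a shared m/z axis.

    ``intensities[i]`` is the spectrum of pixel ``pixel_coords[i]`` (row, col).
    """

    modality: str
    pixel_coords: np.ndarray  # (n_pixels, 2) int, (row, col)
    pixel_pitch: float  # micrometres
    mz_axis: np.ndarray
    intensities: np.ndarray  # (n_pixels, n_channels)
    normalized: bool = False
    resampled: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_RANGES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=int)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.intensities.shape != (len(self.pixel_coords), len(self.mz_axis)):
            raise ValueError("intensity matrix shape does not match coords/axis")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise FormatError("m/z axis must be strictly increasing")
        uniq = {tuple(c) for c in self.pixel_coords}
        if len(uniq) != len(self.pixel_coords):
            raise ValueError("pixel coordinates must be unique")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (int(self.pixel_coords[:, 0].max()) + 1,
                int(self.pixel_coords[:, 1].max()) + 1)

    def spectrum(self, i: int) -> MassSpectrum:
        return MassSpectrum(self.mz_axis, self.intensities[i])

    def image(self, channel_values: np.ndarray) -> np.ndarray:
        """Scatter one value per pixel onto the 2-D grid (NaN where absent)."""
        img = np.full(self.grid_shape, np.nan)
        img[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = channel_values
        return img


@dataclass
class FluorescenceImage:
    """Co-registered LCO microscopy: q-FTAA (core) and h-FTAA (diffuse) channels."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 10.0  # micrometres

    CHANNEL_ORDER = ("qFTAA", "hFTAA")

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def infer_modality(polarity: str | None, mz_range: tuple[float, float]) -> str:
    """Guess the modality from polarity metadata and the recorded mass range."""
    lo, hi = mz_range
    if lo >= 1000.0:
        return "peptide"
    if polarity == "negative":
        return "lipid_neg"
    if polarity == "positive":
        return "lipid_pos"
    warnings.warn("polarity metadata missing; assuming negative-ion lipid modality")
    return "lipid_neg"


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a dataset as continuous-mode imzML (+ .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    polarity = {"lipid_neg": "negative", "lipid_pos": "positive",
                "peptide": "positive"}[dataset.modality]
    with ImzMLWriter(str(path), polarity=polarity, mode="continuous") as w:
        for (row, col), spec in zip(dataset.pixel_coords, dataset.intensities):
            # imzML is 1-based, x = column, y = row
            w.addSpectrum(dataset.mz_axis, spec, (int(col) + 1, int(row) + 1, 1))
    return path


def read_imzml(path: str | Path, modality: str | None = None,
               pixel_pitch: float = 10.0) -> MSIDataset:
    """Read an imzML file into an :class:`MSIDataset`.

    Continuous-mode files keep their recorded axis.  Processed-mode files
    (per-pixel axes) are resampled by linear interpolation onto the first
    spectrum's axis and flagged ``resampled=True``.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such imzML file: {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # ill-formed XML or missing ibd
        raise FormatError(f"cannot parse imzML/ibd pair at {path}: {exc}") from exc

    continuous = "continuous" in parser.metadata.file_description.param_by_name

    mzs0, ints0 = parser.getspectrum(0)
    mzs0 = np.asarray(mzs0, dtype=float)
    if np.any(np.diff(mzs0) <= 0):
        raise FormatError("non-monotone m/z axis in first spectrum")

    n = len(parser.coordinates)
    intensities = np.empty((n, len(mzs0)), dtype=np.float32)
    resampled = False
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        if continuous or (len(mzs) == len(mzs0) and np.array_equal(mzs, mzs0)):
            intensities[i] = ints
        else:
            if np.any(np.diff(mzs) <= 0):
                raise FormatError(f"non-monotone m/z axis in spectrum {i}")
            intensities[i] = np.interp(mzs0, mzs, ints, left=0.0, right=0.0)
            resampled = True

    coords = np.array([(y - 1, x - 1) for (x, y, *_z) in parser.coordinates], dtype=int)

    if modality is None:
        polarity = getattr(parser, "polarity", None) or None
        modality = infer_modality(polarity, (float(mzs0[0]), float(mzs0[-1])))

    return MSIDataset(modality=modality, pixel_coords=coords, pixel_pitch=pixel_pitch,
                      mz_axis=mzs0, intensities=intensities, resampled=resampled)


@dataclass
class TicReport:
    """Bookkeeping from TIC normalization."""

    n_pixels: int
    n_zero_tic: int
    zero_tic_indices: np.ndarray


def tic_normalize(dataset: MSIDataset, *, inplace: bool = False,
                  force: bool = False) -> tuple[MSIDataset, TicReport]:
    """Divide each pixel spectrum by its total ion current (sum over channels).

    Zero-TIC pixels are retained unchanged (all-zero) and counted in the
    report, so segmentation grids stay rectangular.  Re-normalizing an already
    normalized dataset is refused unless ``force=True`` (it would be a no-op
    up to floating point anyway).
    """
    if dataset.normalized and not force:
        raise ValueError("dataset is already TIC-normalized")
    tic = dataset.intensities.sum(axis=1)
    zero = tic == 0
    if zero.all():
        raise ValueError("all pixels have zero total ion current")
    denom = np.where(zero, 1.0, tic).astype(dataset.intensities.dtype)
    if inplace:
        dataset.intensities /= denom[:, None]
        out = replace(dataset, intensities=dataset.intensities, normalized=True)
    else:
        out = replace(dataset, intensities=dataset.intensities / denom[:, None],
                      normalized=True)
    report = TicReport(n_pixels=len(tic), n_zero_tic=int(zero.sum()),
                       zero_tic_indices=np.flatnonzero(zero))
    return out, report


def compute_peptide_mass(sequence: str, mode: str = "monoisotopic") -> float:
    """Neutral mass (Da) of a peptide from its one-letter sequence.

    mass = sum of residue masses + one water.  For the singly protonated ion
    add :data:`PROTON_MASS`.
    """
    if mode not in ("monoisotopic", "average"):
        raise ValueError("mode must be 'monoisotopic' or 'average'")
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = _RESIDUE_MONO if mode == "monoisotopic" else _RESIDUE_AVG
    water = _WATER_MONO if mode == "monoisotopic" else _WATER_AVG
    total = water
    for pos, aa in enumerate(sequence.upper(), start=1):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos}") from None
    return total


def recalibrate(dataset: MSIDataset, shift: float = 0.0) -> MSIDataset:
    """Constant-shift m/z correction hook (defaults to identity).

    External recalibration against spotted standards is out of scope; this
    hook lets a caller apply a known constant axis shift in Da.
    """
    from dataclasses import replace as _replace

    if shift == 0.0:
        return dataset
    return _replace(dataset, mz_axis=dataset.mz_axis + shift)


ABETA_1_42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
ABETA_1_40 = ABETA_1_42[:40]
ABETA_1_38 = ABETA_1_42[:38]


def write_fluorescence_tiff(image: FluorescenceImage, path: str | Path) -> Path:
    """Write channels as a (channel, row, col) TIFF stack in CHANNEL_ORDER."""
    path = Path(path)
    stack = np.stack([image.channels[name] for name in image.CHANNEL_ORDER])
    tifffile.imwrite(path, stack.astype(np.float32),
                     metadata={"axes": "CYX",
                               "channels": list(image.CHANNEL_ORDER),
                               "pixel_size_um": image.pixel_size})
    return path


def read_fluorescence_tiff(path: str | Path, pixel_size: float = 10.0) -> FluorescenceImage:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != len(FluorescenceImage.CHANNEL_ORDER):
        raise FormatError("expected a (2, rows, cols) fluorescence TIFF stack")
    channels = {name: np.asarray(stack[i], dtype=float)
                for i, name in enumerate(FluorescenceImage.CHANNEL_ORDER)}
    return FluorescenceImage(channels=channels, pixel_size=pixel_size)
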