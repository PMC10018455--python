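"""ROI average spectra, peak detection, common mass list and AUC integration.

The reduction from datacubes to one table works on TIC-normalized average
spectra of each ROI: peaks and their borders are detected per ROI, borders
are pooled into one common mass list (bins), and each ROI spectrum is
integrated (trapezoid AUC) within every bin.  Bins are annotated by accurate
mass against a species table.  The result is a :class:`BinTable` -- one row
per ROI, columns concatenated across modalities with LN/LP/P tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msi_io import MODALITY_ION_MODE, MODALITY_TAGS, MassSpectrum, MSIDataset
from .segmentation import ROI


@dataclass
class Peak:
    apex_mz: float
    apex_intensity: float
    left: float
    right: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left < self.apex_mz < self.right):
            raise ValueError("need left < apex < right")


@dataclass
class Bin:
    lo: float
    hi: float
    apex: float  # representative apex m/z (median of contributing peaks)

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValueError("need lo < hi")


@dataclass
class BinTable:
    """AUC intensities of every ROI (rows) in every common-mass-list bin.

    ``data`` columns are named ``{TAG}_{apex:.2f}`` and carry the annotation
    in ``columns_meta``; ``meta`` holds per-ROI metadata aligned on the index.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    columns_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rows(self, kind: str | None = None, genotype: str | None = None) -> pd.DataFrame:
        sel = pd.Series(True, index=self.meta.index)
        if kind is not None:
            sel &= self.meta["kind"] == kind
        if genotype is not None:
            sel &= self.meta["genotype"] == genotype
        return self.data.loc[sel[sel].index]

    def columns_for(self, modality_tags: tuple[str, ...] = ("LN", "LP")) -> list[str]:
        cm = self.columns_meta
        return list(cm.index[cm["tag"].isin(modality_tags)])

    def annotation_of(self, column: str) -> str:
        return str(self.columns_meta.loc[column, "annotation"])

    def column_by_annotation(self, name: str) -> str:
        hits = self.columns_meta.index[self.columns_meta["annotation"] == name]
        if len(hits) == 0:
            raise KeyError(f"no bin annotated as {name!r}")
        return str(hits[0])

    def to_csv(self, path) -> None:
        out = pd.concat([self.meta, self.data], axis=1)
        out.to_csv(path, index_label="roi_id")

    def write_pair(self, matrix_path, columns_path) -> None:
        """Two-file export: data matrix + column metadata."""
        self.to_csv(matrix_path)
        self.columns_meta.to_csv(columns_path, index_label="column")


def roi_average_spectrum(dataset: MSIDataset, roi: ROI) -> MassSpectrum:
    """Channel-wise arithmetic mean spectrum over the ROI's pixels."""
    coord_to_idx = getattr(dataset, "_coord_index", None)
    if coord_to_idx is None:
        coord_to_idx = {tuple(c): i for i, c in enumerate(dataset.pixel_coords)}
        dataset._coord_index = coord_to_idx  # cached; coords are immutable in use
    idx = [coord_to_idx[tuple(p)] for p in roi.pixels if tuple(p) in coord_to_idx]
    if not idx:
        raise ValueError(
            f"ROI {roi.roi_id!r} has no pixels in the dataset grid")
    idx = np.sort(np.asarray(idx))
    # chunked accumulation: large ROIs (e.g. background) would otherwise
    # materialise a near-cube-sized fancy-index copy
    total = np.zeros(dataset.intensities.shape[1], dtype=np.float64)
    for start in range(0, len(idx), 4096):
        total += dataset.intensities[idx[start:start + 4096]].sum(
            axis=0, dtype=np.float64)
    mean = total / len(idx)
    return MassSpectrum(dataset.mz_axis, np.clip(mean, 0, None))


def noise_level(intensities: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 x MAD of the first differences / sqrt(2)."""
    d = np.diff(intensities)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(spectrum: MassSpectrum, snr_threshold: float = 3.0,
                 border_fraction: float = 0.05) -> list[Peak]:
    """Local-maximum peaks with SNR- and width estimation.

    Apexes are local maxima whose height above the spectrum's median
    baseline is >= ``snr_threshold`` times the noise level.  Borders extend
    on each side to the first m/z where the above-baseline intensity falls
    below ``border_fraction`` x the apex height or to a local minimum,
    whichever comes first.  May return an empty list.
    """
    if not (0 < border_fraction < 1):
        raise ValueError("border_fraction must lie in (0, 1)")
    y = spectrum.intensities
    x = spectrum.mz
    if y.size < 3:
        return []
    sigma = noise_level(y)
    base = float(np.median(y))
    floor = base + snr_threshold * sigma if sigma > 0 else base

    apexes = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    if floor > 0:
        apexes = apexes[y[apexes] >= floor]
    else:
        apexes = apexes[y[apexes] > 0]

    peaks: list[Peak] = []
    for a in apexes:
        cutoff = base + border_fraction * (y[a] - base)
        left = a
        while left > 0 and y[left - 1] < y[left] and y[left] > cutoff:
            left -= 1
        if y[left] > cutoff and left > 0:
            # reached a local minimum above the cutoff
            pass
        right = a
        n = len(y)
        while right < n - 1 and y[right + 1] < y[right] and y[right] > cutoff:
            right += 1
        if left == a or right == a:
            continue  # apex on the edge of a plateau; skip degenerate width
        snr = (y[a] - base) / sigma if sigma > 0 else np.inf
        peaks.append(Peak(apex_mz=float(x[a]), apex_intensity=float(y[a]),
                          left=float(x[left]), right=float(x[right]), snr=snr))
    peaks.sort(key=lambda p: p.apex_mz)
    return peaks


def merge_bin_borders(peak_sets: list[list[Peak]],
                      min_overlap: float = 0.25) -> list[Bin]:
    """Pool per-ROI peaks into one disjoint, sorted common mass list.

    Intervals are merged when their overlap is at least ``min_overlap`` of
    the smaller interval (union of borders).  Touching-but-barely-overlapping
    intervals are truncated at the midpoint of their overlap so the result is
    disjoint.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    pooled = sorted((p for ps in peak_sets for p in ps), key=lambda p: p.apex_mz)
    if not pooled:
        return []

    intervals: list[list] = []  # [lo, hi, [apexes]]
    for p in pooled:
        if intervals:
            lo, hi, apexes = intervals[-1]
            overlap = min(hi, p.right) - max(lo, p.left)
            smaller = min(hi - lo, p.right - p.left)
            if overlap > 0 and smaller > 0 and overlap / smaller >= min_overlap:
                intervals[-1][0] = min(lo, p.left)
                intervals[-1][1] = max(hi, p.right)
                apexes.append(p.apex_mz)
                continue
        intervals.append([p.left, p.right, [p.apex_mz]])

    bins: list[Bin] = []
    for i, (lo, hi, apexes) in enumerate(intervals):
        if bins and lo < bins[-1].hi:  # small non-merged overlap: split at midpoint
            mid = 0.5 * (lo + bins[-1].hi)
            bins[-1] = Bin(bins[-1].lo, mid, bins[-1].apex)
            lo = mid
        if lo < hi:
            bins.append(Bin(float(lo), float(hi), float(np.median(apexes))))
    return bins


def integrate_bins(spectrum: MassSpectrum, bins: list[Bin]) -> np.ndarray:
    """Trapezoidal AUC of the spectrum over each bin.

    Borders falling between channels are handled by linear interpolation, so
    integration is exactly additive over a bin split at any interior m/z.
    """
    x, y = spectrum.mz, spectrum.intensities
    out = np.empty(len(bins))
    for i, b in enumerate(bins):
        if b.lo < x[0] or b.hi > x[-1]:
            raise ValueError(
                f"bin [{b.lo}, {b.hi}] outside the axis range "
                f"[{x[0]}, {x[-1]}]")
        inner = (x > b.lo) & (x < b.hi)
        xs = np.concatenate([[b.lo], x[inner], [b.hi]])
        ys = np.concatenate([[np.interp(b.lo, x, y)], y[inner],
                             [np.interp(b.hi, x, y)]])
        out[i] = np.trapezoid(ys, xs)
    return np.clip(out, 0, None)


def annotate_bins(bins: list[Bin], table: pd.DataFrame, tolerance: float = 0.3,
                  ion_mode: str | None = None) -> list[str]:
    """Annotate each bin with the nearest species within ``tolerance`` Da.

    ``table`` needs columns name, mz, ion_mode.  Ties on |dm| break
    alphabetically.  Unmatched bins get an m/z-only label.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    required = {"name", "mz", "ion_mode"}
    if not required.issubset(table.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            float(row.mz)
        except (TypeError, ValueError):
            raise ValueError(f"malformed annotation table row {i}: mz={row.mz!r}")
    sub = table if ion_mode is None else table[table["ion_mode"] == ion_mode]
    out = []
    for b in bins:
        if len(sub):
            dm = (sub["mz"].astype(float) - b.apex).abs()
            cand = sub.assign(_dm=dm)
            cand = cand[cand["_dm"] <= tolerance]
        else:
            cand = sub
        if len(cand):
            cand = cand.sort_values(["_dm", "name"])
            out.append(str(cand.iloc[0]["name"]))
        else:
            out.append(f"m/z {b.apex:.2f}")
    return out


def build_bin_table(roi_spectra: dict[str, dict[str, MassSpectrum]],
                    roi_meta: pd.DataFrame,
                    annotation_table: pd.DataFrame | None = None,
                    snr_threshold: float = 3.0, border_fraction: float = 0.05,
                    min_overlap: float = 0.25,
                    tolerance: float = 0.3,
                    tolerance_peptide: float | None = None) -> BinTable:
    """Assemble the common-mass-list table across modalities.

    ``roi_spectra`` maps modality -> {roi_id -> average spectrum}; all
    modalities must cover the same ROI ids.  Peak detection runs per ROI,
    borders are merged per modality, and AUC columns are concatenated with
    modality tags.
    """
    all_cols: list[pd.DataFrame] = []
    col_meta_rows = []
    roi_ids = list(roi_meta.index)
    for modality, spectra in roi_spectra.items():
        tag = MODALITY_TAGS[modality]
        peak_sets = [detect_peaks(spectra[rid], snr_threshold, border_fraction)
                     for rid in roi_ids]
        bins = merge_bin_borders(peak_sets, min_overlap)
        if not bins:
            continue
        values = np.stack([integrate_bins(spectra[rid], bins) for rid in roi_ids])
        if annotation_table is not None:
            tol = tolerance
            if modality == "peptide" and tolerance_peptide is not None:
                tol = tolerance_peptide
            labels = annotate_bins(bins, annotation_table, tol,
                                   ion_mode=MODALITY_ION_MODE[modality])
        else:
            labels = [f"m/z {b.apex:.2f}" for b in bins]
        names = [f"{tag}_{b.apex:.2f}" for b in bins]
        # de-duplicate column names from nearly coincident apexes
        seen: dict[str, int] = {}
        for i, n in enumerate(names):
            if n in seen:
                seen[n] += 1
                names[i] = f"{n}_{seen[n]}"
            else:
                seen[n] = 0
        all_cols.append(pd.DataFrame(values, index=roi_ids, columns=names))
        for n, b, lab in zip(names, bins, labels):
            col_meta_rows.append({"column": n, "tag": tag, "lo": b.lo,
                                  "hi": b.hi, "apex": b.apex, "annotation": lab})
    if not all_cols:
        raise ValueError("no peaks detected in any modality")
    data = pd.concat(all_cols, axis=1)
    columns_meta = pd.DataFrame(col_meta_rows).set_index("column")
    return BinTable(data=data, meta=roi_meta.copy(), columns_meta=columns_meta)
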