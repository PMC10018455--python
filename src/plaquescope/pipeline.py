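"""End-to-end pipeline: normalize -> segment -> register/validate -> ROI
spectra -> common mass list -> multivariate -> interplay.

The pipeline can run from a generated in-memory cohort (streaming one animal
at a time to bound memory) or from on-disk imzML/TIFF inputs.  Every stage
records its parameters and derived seed in a provenance dictionary; rerunning
with the same configuration and seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, interplay, multivariate, registration, segmentation
from .msi_io import tic_normalize
from .synthetic import AnimalData, Cohort, CohortConfig, iter_generate_cohort

log = logging.getLogger("plaquescope")


@dataclass
class PipelineParams:
    """Tunable parameters of the analysis stages (defaults documented in
    docs/methods.md)."""

    n_leaves: int = 8
    feature_bin_width_lipid: float = 1.0  # Da
    feature_bin_width_peptide: float = 5.0  # Da
    max_features: int = 60  # per modality, by spatial variance
    min_pixels: int = 4
    roi_dilation: int = 1  # px of halo captured around detected components
    center_mode: str = "geometric"  # geometric | qftaa (q-FTAA core mask)
    center_fraction: float = 0.35
    lco_validate: bool = True
    lco_dice_threshold: float = 0.3
    lco_threshold_method: str = "otsu"
    snr_threshold: float = 5.0
    border_fraction: float = 0.05
    min_overlap: float = 0.25
    annotation_tolerance: float = 0.3  # Da, lipid modalities
    annotation_tolerance_peptide: float = 2.0  # Da (linear-mode FWHM ~ 4 Da)
    k_top: int = 15
    n_orth: int = 1
    scaling: str = "autoscale"
    background_margin: int = 5
    seed: int = 0


@dataclass
class AnimalAnalysis:
    """Per-animal segmentation products and ROI spectra."""

    animal_id: str
    genotype: str
    phenotype: str
    rois: list
    spectra: dict  # modality -> {roi_id -> MassSpectrum}
    roi_meta: pd.DataFrame
    recovery: pd.DataFrame  # one row per truth plaque
    leaf_stats: dict
    lco_dice: dict  # roi_id -> dice vs amyloid mask


@dataclass
class CohortResult:
    params: PipelineParams
    bin_table: binning.BinTable
    recovery: pd.DataFrame
    oplsda_whole: multivariate.OplsdaModel | None
    vip_ranking: pd.DataFrame | None
    depletion_tests: pd.DataFrame | None
    assignment: pd.DataFrame | None
    interplay_report: dict | None
    recovery_report: dict | None
    provenance: list = field(default_factory=list)


def _stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed fan-out via SHA-256 of (seed, stage, i)."""
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def truth_disk_mask(plaque, grid_shape: tuple[int, int],
                    pixel_pitch: float) -> np.ndarray:
    """Pixels within the planted radius of a plaque center."""
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d = pixel_pitch * np.hypot(rr - plaque.center[0], cc - plaque.center[1])
    return d <= plaque.radius


def _lco_validation(animal: AnimalData, rois: list, grid_shape,
                    params: PipelineParams) -> tuple[list, dict, np.ndarray | None]:
    """Validate segmentation ROIs against the h-FTAA amyloid mask.

    Each ROI is scored by Dice against the amyloid-positive component(s) it
    overlaps; ROIs under the threshold are dropped.  Returns the surviving
    ROIs, the per-ROI dice map and the q-FTAA core mask (for center ROIs).
    """
    from skimage.measure import label as cc_label

    fluor = animal.fluorescence
    corners = [(0.0, 0.0), (grid_shape[1] - 1.0, 0.0),
               (0.0, grid_shape[0] - 1.0),
               (grid_shape[1] - 1.0, grid_shape[0] - 1.0)]
    transform, _rms = registration.affine_from_landmarks(
        [(c, c) for c in corners])
    channels = registration.resample_to_grid(fluor, transform, grid_shape)
    amyloid, core = registration.lco_masks(
        channels, method=params.lco_threshold_method)
    amyloid_cc = cc_label(amyloid, connectivity=2)

    kept, dice_map = [], {}
    from scipy.ndimage import binary_dilation

    for roi in rois:
        mask = roi.mask(grid_shape)
        overlap_labels = np.unique(amyloid_cc[mask])
        overlap_labels = overlap_labels[overlap_labels > 0]
        local_amyloid = np.isin(amyloid_cc, overlap_labels)
        if params.roi_dilation > 0 and overlap_labels.size:
            # ROIs carry a halo (roi_dilation); give the amyloid mask the
            # same halo so the Dice comparison is geometrically fair
            local_amyloid = binary_dilation(local_amyloid,
                                            iterations=params.roi_dilation)
        d = registration.dice(mask, local_amyloid) if overlap_labels.size else 0.0
        dice_map[roi.roi_id] = d
        if d >= params.lco_dice_threshold:
            kept.append(roi)
    return kept, dice_map, core


def process_animal(animal: AnimalData, params: PipelineParams) -> AnimalAnalysis:
    """Normalize, segment, validate and reduce one animal to ROI spectra."""
    grid_shape = next(iter(animal.datasets.values())).grid_shape

    features = []
    for modality in ("lipid_neg", "lipid_pos", "peptide"):
        ds = animal.datasets[modality]
        if not ds.normalized:
            ds, _rep = tic_normalize(ds, inplace=True)
            animal.datasets[modality] = ds
        width = (params.feature_bin_width_peptide if modality == "peptide"
                 else params.feature_bin_width_lipid)
        X, _centers = segmentation.build_feature_matrix(
            ds, width, max_features=params.max_features)
        features.append(X)
    X = np.concatenate(features, axis=1)
    # unit-variance feature scaling: clustering should weigh a faint plaque
    # bin and an abundant background bin equally
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    X /= np.where(sd == 0, 1.0, sd)

    seed = _stage_seed(params.seed, f"segment:{animal.animal_id}")
    tree = segmentation.bisecting_kmeans(X, params.n_leaves, seed=seed)
    coords = animal.datasets["lipid_neg"].pixel_coords
    rois, leaf_stats = segmentation.extract_plaque_rois(
        tree, coords, grid_shape, min_pixels=params.min_pixels,
        dilate=params.roi_dilation,
        animal_id=animal.animal_id, genotype=animal.genotype)

    core_mask = None
    lco_dice: dict = {}
    if params.lco_validate and animal.fluorescence is not None:
        rois, lco_dice, core_mask = _lco_validation(animal, rois, grid_shape,
                                                    params)
    elif params.lco_validate:
        log.warning("%s: no fluorescence available; skipping LCO validation, "
                    "centers derived geometrically", animal.animal_id)

    centers = []
    for roi in rois:
        if params.center_mode == "qftaa" and core_mask is not None:
            centers.append(segmentation.center_from_core_mask(roi, core_mask))
        else:
            centers.append(segmentation.derive_center_roi(
                roi, params.center_fraction))
    bg = segmentation.background_roi(rois, grid_shape,
                                     margin=params.background_margin,
                                     animal_id=animal.animal_id,
                                     genotype=animal.genotype)

    all_rois = rois + centers + [bg]
    spectra = {m: {roi.roi_id: binning.roi_average_spectrum(ds, roi)
                   for roi in all_rois}
               for m, ds in animal.datasets.items()}

    meta_rows = [{"roi_id": r.roi_id, "animal_id": animal.animal_id,
                  "genotype": animal.genotype, "phenotype": animal.phenotype,
                  "kind": r.kind, "n_pixels": len(r.pixels),
                  "lco_dice": lco_dice.get(r.roi_id, np.nan)}
                 for r in all_rois]
    roi_meta = pd.DataFrame(meta_rows).set_index("roi_id")

    pitch = animal.datasets["lipid_neg"].pixel_pitch
    rec_rows = []
    from scipy.ndimage import binary_erosion

    for i, plaque in enumerate(animal.plaques):
        disk = truth_disk_mask(plaque, grid_shape, pitch)
        best_d, best_roi = 0.0, None
        for roi in rois:
            mask = roi.mask(grid_shape)
            if params.roi_dilation > 0:
                # score detection on the footprint, not the integration halo
                eroded = binary_erosion(mask, iterations=params.roi_dilation)
                if eroded.any():
                    mask = eroded
            d = registration.dice(mask, disk)
            if d > best_d:
                best_d, best_roi = d, roi.roi_id
        rec_rows.append({"animal_id": animal.animal_id,
                         "genotype": animal.genotype, "plaque_index": i,
                         "maturity": plaque.maturity,
                         "radius_um": plaque.radius,
                         "best_dice": best_d, "matched_roi": best_roi})
    recovery = pd.DataFrame(rec_rows)

    return AnimalAnalysis(animal_id=animal.animal_id, genotype=animal.genotype,
                          phenotype=animal.phenotype, rois=all_rois,
                          spectra=spectra, roi_meta=roi_meta,
                          recovery=recovery, leaf_stats=leaf_stats,
                          lco_dice=lco_dice)


def analyze_cohort(source: Cohort | CohortConfig,
                   params: PipelineParams | None = None,
                   annotation_table: pd.DataFrame | None = None,
                   species_table: pd.DataFrame | None = None) -> CohortResult:
    """Run the full analysis over a cohort (streamed if a config is given)."""
    params = params or PipelineParams()
    provenance: list[dict] = []

    if isinstance(source, CohortConfig):
        animals_iter = iter_generate_cohort(source)
        config = source
    else:
        animals_iter = iter(source.animals)
        config = source.config
    genotypes = {g.label: g.phenotype for g in config.genotypes}

    analyses: list[AnimalAnalysis] = []
    spectra: dict[str, dict] = {}
    metas, recoveries = [], []
    for animal in animals_iter:
        t0 = time.time()
        if annotation_table is None or species_table is None:
            tmp = Cohort(config=config, animals=[animal])
            if annotation_table is None:
                annotation_table = tmp.annotation_table()
            if species_table is None:
                species_table = tmp.species_table()
        analysis = process_animal(animal, params)
        animal.datasets = {}  # free the datacubes
        for m, d in analysis.spectra.items():
            spectra.setdefault(m, {}).update(d)
        metas.append(analysis.roi_meta)
        recoveries.append(analysis.recovery)
        analysis.spectra = {}
        analyses.append(analysis)
        provenance.append({"stage": "animal", "animal": analysis.animal_id,
                           "n_rois": int((analysis.roi_meta["kind"]
                                          == "whole_plaque").sum()),
                           "seconds": round(time.time() - t0, 2)})
        log.info("processed %s: %d plaque ROIs", analysis.animal_id,
                 provenance[-1]["n_rois"])

    roi_meta = pd.concat(metas)
    recovery = pd.concat(recoveries, ignore_index=True)

    bin_table = binning.build_bin_table(
        spectra, roi_meta, annotation_table,
        snr_threshold=params.snr_threshold,
        border_fraction=params.border_fraction,
        min_overlap=params.min_overlap,
        tolerance=params.annotation_tolerance,
        tolerance_peptide=params.annotation_tolerance_peptide)
    provenance.append({"stage": "bins", "n_bins": bin_table.data.shape[1],
                       "n_rois": bin_table.data.shape[0]})

    # genotype discrimination on whole-plaque ROIs
    compact = [g for g, p in genotypes.items() if p == "compact"]
    cored = [g for g, p in genotypes.items() if p == "cored"]
    oplsda_model, vip_ranking, depletion = None, None, None
    assignment, report, recovery_report = None, None, None
    if compact and cored:
        g_a, g_b = compact[0], cored[0]
        whole = bin_table.rows(kind="whole_plaque")
        labels = bin_table.meta.loc[whole.index, "genotype"]
        if labels.nunique() == 2 and all(
                (labels == g).sum() >= 3 for g in (g_a, g_b)):
            oplsda_model = multivariate.oplsda(
                whole.to_numpy(), labels.to_numpy(), n_orth=params.n_orth,
                scaling=params.scaling,
                feature_names=list(whole.columns))
            vip, order = multivariate.vip_scores(oplsda_model)
            vip_ranking = pd.DataFrame({
                "column": [whole.columns[i] for i in order],
                "vip": vip[order],
                "annotation": [bin_table.annotation_of(whole.columns[i])
                               for i in order]})
            provenance.append({"stage": "oplsda", "n_orth": params.n_orth,
                               "seed": params.seed})

            # plaque vs background univariate screen (depletion direction)
            pb = bin_table.meta["kind"].isin(["whole_plaque", "background"])
            pb_rows = bin_table.data.loc[pb[pb].index]
            pb_labels = bin_table.meta.loc[pb_rows.index, "kind"]
            depletion = multivariate.compare_groups(
                pb_rows, pb_labels.to_numpy(), alternative="less")
            depletion["annotation"] = [bin_table.annotation_of(c)
                                       for c in depletion.index]

            quadruples, report = interplay.interplay_quadruples(
                bin_table, g_a, g_b, k=params.k_top)
            assignment = interplay.classify_interplay(quadruples)
            assignment["annotation"] = [bin_table.annotation_of(c)
                                        for c in assignment.index]
            if species_table is not None:
                recovery_report = interplay.interplay_recovery_report(
                    assignment, species_table)
            provenance.append({"stage": "interplay", "k": params.k_top})

    return CohortResult(params=params, bin_table=bin_table, recovery=recovery,
                        oplsda_whole=oplsda_model, vip_ranking=vip_ranking,
                        depletion_tests=depletion, assignment=assignment,
                        interplay_report=report,
                        recovery_report=recovery_report,
                        provenance=provenance)


def write_results(result: CohortResult, out_dir: str | Path) -> Path:
    """Export the cohort result as CSV/JSON artifacts with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.bin_table.write_pair(out / "bin_table.csv",
                                out / "bin_columns.csv")
    result.recovery.to_csv(out / "plaque_recovery.csv", index=False)
    if result.vip_ranking is not None:
        result.vip_ranking.to_csv(out / "vip_ranking.csv", index=False)
    if result.depletion_tests is not None:
        result.depletion_tests.to_csv(out / "plaque_vs_background.csv")
    if result.assignment is not None:
        result.assignment.to_csv(out / "interplay_assignment.csv")
    if result.recovery_report is not None:
        result.recovery_report["confusion"].to_csv(
            out / "interplay_confusion.csv")
    prov = {"params": asdict(result.params), "stages": result.provenance}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return out
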