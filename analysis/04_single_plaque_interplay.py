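"""Single-plaque lipid / A-beta interplay: correlation ranking and the
three-class membership classifier.

For each genotype and ROI type, ranks lipid bins by Pearson correlation
with the A-beta 1-40 bin across that genotype's plaques, forms top-15
membership quadruples, classifies them into plaque-growth (I), seeding/
fibrillation (II) and continuous-maturation (III) patterns, and scores the
assignment against the planted ground truth.

Run after 02:  python analysis/04_single_plaque_interplay.py
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from plaquescope import interplay  # noqa: E402
from plaquescope.cohorts import COMPACT_GENOTYPE, CORED_GENOTYPE  # noqa: E402
from plaquescope.multivariate import pearson_matrix  # noqa: E402

RESULTS = ROOT / "results"


def main() -> None:
    sys.path.insert(0, str(ROOT / "analysis"))
    loader = __import__("03_genotype_discrimination")
    table = loader.load_bin_table()
    species = pd.read_csv(RESULTS / "species_truth.csv")

    quadruples, report = interplay.interplay_quadruples(
        table, COMPACT_GENOTYPE, CORED_GENOTYPE, k=15)
    assignment = interplay.classify_interplay(quadruples)
    assignment["annotation"] = [table.annotation_of(c)
                                for c in assignment.index]
    assignment.to_csv(RESULTS / "interplay_assignment.csv")

    recovery = interplay.interplay_recovery_report(assignment, species)
    recovery["confusion"].to_csv(RESULTS / "interplay_confusion.csv")

    venn = assignment.groupby(
        ["whole_compact", "whole_cored", "center_compact", "center_cored"]
    ).size().rename("n_species")
    venn.to_csv(RESULTS / "interplay_venn_counts.csv")

    # per-genotype correlation heatmaps over plaque-center ROIs
    fig, axes = plt.subplots(1, 2, figsize=(12, 5))
    for ax, genotype in zip(axes, (COMPACT_GENOTYPE, CORED_GENOTYPE)):
        rows = table.rows(kind="plaque_center", genotype=genotype)
        corr, _ = pearson_matrix(rows)
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"{genotype} plaque centers (PCC)")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(RESULTS / "correlation_heatmaps.png", dpi=150)

    classed = assignment[assignment["interplay_class"] != "unclassified"]
    print(f"ranked lipids against {report['target_column']} "
          f"(A-beta 1-40) at k = {report['k']}")
    for cls, group in classed.groupby("interplay_class"):
        print(f"  {cls}: {', '.join(sorted(group['annotation']))}")
    recalls = {k.split('_')[0]: (f"{v:.2f}" if v is not None else "n/a")
               for k, v in recovery["recall"].items()}
    print(f"recall vs planted truth: {recalls}")
    print(f"wrote {RESULTS / 'interplay_assignment.csv'} and heatmaps")


if __name__ == "__main__":
    main()
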