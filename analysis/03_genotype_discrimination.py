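"""Genotype discrimination: PCA overview, OPLS-DA with VIP ranking, and the
plaque-vs-background univariate screen (sulfatide depletion).

Reads the bin table from results/, fits the two-genotype OPLS-DA on
whole-plaque ROIs, ranks species by VIP, tests every bin for plaque-
associated depletion/enrichment against the background ROIs (Welch + BH)
and writes tables + score/VIP figures.

Run after 02:  python analysis/03_genotype_discrimination.py
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from plaquescope import multivariate  # noqa: E402
from plaquescope.binning import BinTable  # noqa: E402

RESULTS = ROOT / "results"
META_COLS = ["animal_id", "genotype", "phenotype", "kind", "n_pixels",
             "lco_dice"]


def load_bin_table() -> BinTable:
    matrix = pd.read_csv(RESULTS / "bin_table.csv", index_col="roi_id")
    columns_meta = pd.read_csv(RESULTS / "bin_columns.csv",
                               index_col="column")
    meta = matrix[META_COLS]
    return BinTable(data=matrix.drop(columns=META_COLS), meta=meta,
                    columns_meta=columns_meta)


def main() -> None:
    table = load_bin_table()
    whole = table.rows(kind="whole_plaque")
    labels = table.meta.loc[whole.index, "genotype"]

    Xs, _ = multivariate.scale_matrix(whole.to_numpy())
    scores, _, expl = multivariate.pca(Xs, 2)
    model = multivariate.oplsda(whole.to_numpy(), labels.to_numpy(),
                                n_orth=1, feature_names=list(whole.columns))
    vip, order = multivariate.vip_scores(model)
    ranking = pd.DataFrame({
        "column": [whole.columns[i] for i in order],
        "annotation": [table.annotation_of(whole.columns[i]) for i in order],
        "vip": vip[order]})
    ranking.to_csv(RESULTS / "vip_ranking.csv", index=False)
    (RESULTS / "oplsda_model.json").write_text(json.dumps(model.to_json()))

    pb = table.meta["kind"].isin(["whole_plaque", "background"])
    rows = table.data.loc[pb[pb].index]
    tests = multivariate.compare_groups(
        rows, table.meta.loc[rows.index, "kind"].to_numpy(),
        alternative="two-sided")
    tests["annotation"] = [table.annotation_of(c) for c in tests.index]
    tests.to_csv(RESULTS / "plaque_vs_background.csv")

    enc = np.where(labels.to_numpy() == model.classes[1], 1, -1)
    mis = int((np.sign(model.scores * model.y_loading) != enc).sum())

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for g, color in zip(model.classes, ("tab:red", "tab:blue")):
        sel = labels.to_numpy() == g
        axes[0].scatter(scores[sel, 0], scores[sel, 1], label=str(g), c=color)
        axes[1].scatter(model.scores[sel], model.orth_scores[sel, 0],
                        label=str(g), c=color)
    axes[0].set_xlabel(f"PC1 ({expl[0]:.0%})")
    axes[0].set_ylabel(f"PC2 ({expl[1]:.0%})")
    axes[0].set_title("PCA, whole-plaque ROIs")
    axes[1].set_xlabel("predictive score t")
    axes[1].set_ylabel("orthogonal score t_o")
    axes[1].set_title("OPLS-DA")
    axes[1].legend()
    top15 = ranking.head(15)[::-1]
    axes[2].barh(top15["annotation"], top15["vip"], color="tab:gray")
    axes[2].set_xlabel("VIP score")
    axes[2].set_title("top 15 discriminative species")
    fig.tight_layout()
    fig.savefig(RESULTS / "genotype_discrimination.png", dpi=150)

    st = tests[tests["annotation"].str.startswith("ST(")]
    print(f"OPLS-DA separates the genotypes with {mis} misclassified of "
          f"{len(enc)} plaques (R2X predictive n/a, 1 orthogonal component)")
    print("top 5 VIP:", ", ".join(
        f"{r.annotation} ({r.vip:.2f})" for r in ranking.head(5).itertuples()))
    for r in st.itertuples():
        print(f"sulfatide {r.annotation}: plaque-background effect "
              f"{r.effect:+.2e}, q = {r.q:.2e}")
    print(f"wrote {RESULTS / 'vip_ranking.csv'} and figures")


if __name__ == "__main__":
    main()
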