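"""Single-plaque lipid / A-beta interplay classification.

For each genotype and each ROI type (whole plaque, plaque center), lipid
bins are ranked by their Pearson correlation with the A-beta 1-40 bin across
that genotype's plaques (plaques pooled over its animals).  A species'
membership in the four top-k lists forms a quadruple

    (whole x genotype A, whole x genotype B, center x A, center x B)

which the classifier maps to three mechanistic classes:

* class III (continuous maturation)   -- in all four lists;
* class II  (seeding / fibrillation)  -- in both center lists, in neither
  whole list;
* class I   (plaque growth)           -- in both whole lists and in the
  center list of the compact-phenotype genotype only.

Everything else is unclassified.  The rules are evaluated III -> II -> I and
are mutually exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinTable

CLASS_LABELS = {
    "I": "I_growth",
    "II": "II_seeding_fibrillation",
    "III": "III_continuous_maturation",
    "none": "unclassified",
}

LIPID_TAGS = ("LN", "LP")


@dataclass
class MembershipQuadruple:
    """Top-k membership of one species across the four ranked lists."""

    species: str
    whole_a: bool  # whole plaque, genotype A (compact by convention)
    whole_b: bool  # whole plaque, genotype B
    center_a: bool
    center_b: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.whole_a, self.whole_b, self.center_a, self.center_b)


def top_correlated(data: pd.DataFrame, target_column: str, k: int,
                   candidate_columns: list[str] | None = None,
                   rank_by: str = "signed") -> pd.DataFrame:
    """Rank candidate columns by Pearson correlation with the target.

    ``data`` holds one row per plaque ROI.  The target column (the A-beta
    1-40 bin) is excluded from the candidates, as is any peptide bin when
    ``candidate_columns`` is supplied by the caller.  Returns a frame with
    columns (column, r) sorted by descending signed r (or |r| when
    ``rank_by='magnitude'``), ties broken by ascending column order (i.e.
    ascending m/z for mass-ordered tables); at most ``k`` rows.
    """
    if target_column not in data.columns:
        raise KeyError(f"target column {target_column!r} not in table")
    target = data[target_column].to_numpy(dtype=float)
    if np.std(target) == 0:
        raise ValueError(
            f"target column {target_column!r} has zero variance; "
            "correlation ranking is undefined")
    if candidate_columns is None:
        candidate_columns = [c for c in data.columns if c != target_column]
    cands = [c for c in candidate_columns if c != target_column]

    rows = []
    tc = target - target.mean()
    tnorm = np.linalg.norm(tc)
    for idx, col in enumerate(cands):
        x = data[col].to_numpy(dtype=float)
        xc = x - x.mean()
        xnorm = np.linalg.norm(xc)
        if xnorm == 0:
            continue  # zero-variance candidate: excluded
        r = float(tc @ xc / (tnorm * xnorm))
        rows.append({"column": col, "r": r, "_idx": idx})
    ranked = pd.DataFrame(rows, columns=["column", "r", "_idx"])
    key = ranked["r"].abs() if rank_by == "magnitude" else ranked["r"]
    ranked = (ranked.assign(_key=-key)
              .sort_values(["_key", "_idx"], kind="mergesort")
              .drop(columns=["_key", "_idx"])
              .reset_index(drop=True))
    return ranked.head(k)


def interplay_quadruples(bin_table: BinTable, genotype_a: str, genotype_b: str,
                         k: int = 15, target_annotation: str = "Abeta1-40",
                         rank_by: str = "signed",
                         average_within_animal: bool = False
                         ) -> tuple[dict[str, MembershipQuadruple], dict]:
    """Build membership quadruples from the four top-k correlation lists.

    Genotype A must be the compact-phenotype genotype; correlations are
    computed per genotype over that genotype's plaque ROIs, pooled across
    its animals (or, with ``average_within_animal``, over per-animal mean
    signatures).  Species identity is the bin column; quadruples are keyed
    by column name with the bin annotation attached in the report.
    """
    target = bin_table.column_by_annotation(target_annotation)
    lipid_cols = bin_table.columns_for(LIPID_TAGS)

    lists: dict[tuple[str, str], list[str]] = {}
    rankings: dict[tuple[str, str], pd.DataFrame] = {}
    for kind in ("whole_plaque", "plaque_center"):
        for genotype in (genotype_a, genotype_b):
            rows = bin_table.rows(kind=kind, genotype=genotype)
            if average_within_animal:
                animals = bin_table.meta.loc[rows.index, "animal_id"]
                rows = rows.groupby(animals).mean()
            ranked = top_correlated(rows, target, k, lipid_cols, rank_by)
            key = (kind, genotype)
            lists[key] = list(ranked["column"])
            rankings[key] = ranked

    quadruples = {}
    for col in lipid_cols:
        quadruples[col] = MembershipQuadruple(
            species=col,
            whole_a=col in lists[("whole_plaque", genotype_a)],
            whole_b=col in lists[("whole_plaque", genotype_b)],
            center_a=col in lists[("plaque_center", genotype_a)],
            center_b=col in lists[("plaque_center", genotype_b)],
        )
    report = {"k": k, "target_column": target, "rankings": rankings}
    return quadruples, report


def classify_quadruple(q: MembershipQuadruple) -> str:
    """Map one membership quadruple to a class label (A = compact genotype).

    Evaluation order III -> II -> I; exactly one quadruple state maps to
    each class, everything else is unclassified.
    """
    whole_a, whole_b, center_a, center_b = q.as_tuple()
    if whole_a and whole_b and center_a and center_b:
        return CLASS_LABELS["III"]
    if center_a and center_b and not whole_a and not whole_b:
        return CLASS_LABELS["II"]
    if whole_a and whole_b and center_a and not center_b:
        return CLASS_LABELS["I"]
    return CLASS_LABELS["none"]


def classify_interplay(quadruples: dict[str, MembershipQuadruple]
                       ) -> pd.DataFrame:
    """Classify every species' quadruple; pure in the quadruples."""
    rows = []
    for col, q in quadruples.items():
        rows.append({"column": col, "whole_compact": q.whole_a,
                     "whole_cored": q.whole_b, "center_compact": q.center_a,
                     "center_cored": q.center_b,
                     "interplay_class": classify_quadruple(q)})
    return pd.DataFrame(rows).set_index("column")


def interplay_recovery_report(assignment: pd.DataFrame,
                              truth: pd.DataFrame) -> dict:
    """Confusion table and per-class recall against planted ground truth.

    ``assignment`` is the classify_interplay output with an ``annotation``
    column mapping bins to species names; ``truth`` is the species table
    with columns name and truth_class ('I', 'II', 'III' or 'none').
    """
    truth_map = (truth.drop_duplicates("name").set_index("name")["truth_class"]
                 .map(lambda c: CLASS_LABELS.get(str(c), CLASS_LABELS["none"]))
                 .to_dict())
    order = [CLASS_LABELS["I"], CLASS_LABELS["II"], CLASS_LABELS["III"],
             CLASS_LABELS["none"]]
    confusion = pd.DataFrame(0, index=order, columns=order)
    for _col, row in assignment.iterrows():
        name = row.get("annotation", _col)
        t = truth_map.get(name, CLASS_LABELS["none"])
        confusion.loc[t, row["interplay_class"]] += 1

    recall = {}
    for cls in order[:3]:
        planted = int(confusion.loc[cls].sum())
        recall[cls] = (confusion.loc[cls, cls] / planted) if planted else None
    n_off = int(confusion.to_numpy().sum()
                - np.trace(confusion.to_numpy()))
    return {"confusion": confusion, "recall": recall,
            "identity": n_off == 0,
            "n_species": int(confusion.to_numpy().sum())}
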