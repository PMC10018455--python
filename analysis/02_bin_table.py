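"""Build the common-mass-list bin table from the cached ROI spectra.

Detects peaks on every ROI average spectrum, merges their borders into one
common mass list per modality, integrates each ROI spectrum within every
bin (trapezoid AUC) and annotates the bins by accurate mass.  Writes the
ROI x bin table and the column metadata to results/.

Run after 01:  python analysis/02_bin_table.py
"""

import pickle
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from plaquescope.binning import build_bin_table  # noqa: E402

RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    with open(SCRATCH / "roi_spectra.pkl", "rb") as fh:
        cache = pickle.load(fh)
    params = cache["params"]
    annotation = pd.read_csv(RESULTS / "annotations.csv")

    table = build_bin_table(cache["spectra"], cache["roi_meta"], annotation,
                            snr_threshold=params.snr_threshold,
                            border_fraction=params.border_fraction,
                            min_overlap=params.min_overlap,
                            tolerance=params.annotation_tolerance)
    table.write_pair(RESULTS / "bin_table.csv", RESULTS / "bin_columns.csv")

    n_annotated = (~table.columns_meta["annotation"].str
                   .startswith("m/z")).sum()
    by_tag = table.columns_meta["tag"].value_counts().to_dict()
    print(f"common mass list: {table.data.shape[1]} bins "
          f"({by_tag}), {n_annotated} annotated by accurate mass")
    print(f"rows: {table.data.shape[0]} ROIs "
          f"({table.meta['kind'].value_counts().to_dict()})")
    print(f"wrote {RESULTS / 'bin_table.csv'}")


if __name__ == "__main__":
    main()
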