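#!/usr/bin/env python
"""Evaluate the differential calls against the generator's truth ledger.

Measures what the stoichiometry correction buys: recall of truly
upregulated sites, and the rate at which protein-confounded sites are
falsely called up with and without parent-protein correction.  Also draws
the volcano plot of the corrected site analysis.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kbhb_atlas import differential as diff
from kbhb_atlas import preprocess_quant as pq
from kbhb_atlas import plots
from kbhb_atlas import synthetic_data as synth
from kbhb_atlas.formats_io import read_site_table, site_records_to_frames, read_protein_table

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
RUN = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    design = synth.read_design(DATA / "design.tsv")
    truth = synth.SyntheticTruth.from_json(DATA / "truth.json")
    corrected = pd.read_csv(RUN / "site_differential.tsv", sep="\t", index_col=0)

    # the uncorrected alternative: same chain without the protein division
    records = read_site_table(DATA / "kbhb_sites.tsv", design)
    meta, intensities = site_records_to_frames(records, design)
    filtered, _ = pq.filter_features(intensities, design, site_meta=meta)
    site_rel, _ = pq.center_scale(filtered)
    uncorrected, _ = diff.differential_analysis(site_rel, design)

    up_true = set(truth.sites_of_class("up"))
    confounded = set(truth.sites_of_class("protein-confounded"))
    up_c = set(corrected.index[corrected["class"] == "up"])
    up_u = set(uncorrected.index[uncorrected["class"] == "up"])

    summary = {
        "true_up_sites": len(up_true),
        "confounded_sites": len(confounded),
        "recall_up_corrected_pct": round(100 * len(up_true & up_c) / len(up_true), 1),
        "confounded_called_up_corrected_pct":
            round(100 * len(confounded & up_c) / len(confounded), 1),
        "confounded_called_up_uncorrected_pct":
            round(100 * len(confounded & up_u) / len(confounded), 1),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "03_differential_evaluation.json").write_text(
        json.dumps(summary, indent=1))
    plots.volcano(corrected, RUN / "volcano_sites_corrected.png",
                  title="Kbhb sites, protein-abundance corrected")
    print(json.dumps(summary, indent=1))
    print("Without correction, protein-driven sites masquerade as modification "
          "changes; the parent-protein division removes almost all of them.")


if __name__ == "__main__":
    main()
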