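#!/usr/bin/env python
"""Summarize the modification landscape and flanking-sequence motifs.

Reports the sites-per-protein distribution, the subcellular breakdown of
all/up/down sites, the top two-sample position enrichments for
upregulated windows, and the motif-x patterns.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN = Path(__file__).resolve().parents[1] / "scratch" / "analysis" / "run"


def main() -> None:
    landscape = json.loads((RUN / "landscape.json").read_text())
    motifs = pd.read_csv(RUN / "motif_enrichment.tsv", sep="\t")
    patterns = json.loads((RUN / "motif_patterns.json").read_text())

    top = motifs.head(8)[["offset", "residue", "fg_freq", "bg_freq",
                          "p_value", "direction"]]
    summary = {
        "site_density_pct": landscape["site_density"]["percentages"],
        "compartment_pct": {k: v["percentages"]
                            for k, v in landscape["compartments"].items()},
        "top_position_enrichments": top.to_dict(orient="records"),
        "motif_x_patterns": [p["pattern"] for p in patterns],
    }
    (RESULTS / "04_landscape_motifs.json").write_text(json.dumps(summary, indent=1))
    print("sites-per-protein (%):", summary["site_density_pct"])
    print("compartments of all sites (%):", summary["compartment_pct"]["all"])
    print("top motif hits:")
    print(top.to_string(index=False))
    print("motif-x patterns:", summary["motif_x_patterns"])


if __name__ == "__main__":
    main()
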