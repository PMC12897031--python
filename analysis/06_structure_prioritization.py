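#!/usr/bin/env python
"""Prioritize modified lysines by spatial context and conservation.

Combines the four-way spatial/PTM-overlap classification (5 A cutoff)
with entropy-based conservation (> 0.85) to flag candidate regulatory
lysines, and demonstrates the distance mechanism on the synthetic
ADSS1-like fixture (K448 vs its annotated nucleotide pocket).
"""

from pathlib import Path

import pandas as pd

from kbhb_atlas import structure_conservation as sc
from kbhb_atlas import synthetic_data as synth

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    reports = pd.read_csv(RUN / "structure_reports.tsv", sep="\t")
    reports.to_csv(RESULTS / "06_structure_priorities.tsv", sep="\t", index=False)
    print(reports.to_string(index=False))
    flagged = reports[reports["priority"]]
    print(f"\n{len(flagged)} lysine(s) prioritized "
          f"(conservation > 0.85 and spatially implicated)")

    adss1 = synth.adss1_like_structure()
    d = sc.min_atomic_distance(adss1, 448, adss1.functional_residues)
    print(f"ADSS1-like fixture: K448 sits {d:.1f} A from the annotated "
          f"nucleotide-binding pocket")


if __name__ == "__main__":
    main()
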