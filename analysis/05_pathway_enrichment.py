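#!/usr/bin/env python
"""Pathway over-representation of proteins carrying upregulated Kbhb sites.

The universe is the quantified modified proteome; sites are mapped to
parent proteins and deduplicated before testing.  The planted pathway
should dominate; the decoy sets calibrate the BH-adjusted p-values.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    table = pd.read_csv(RUN / "enrichment.tsv", sep="\t")
    table.to_csv(RESULTS / "05_enrichment.tsv", sep="\t", index=False)
    print(table[["term", "k", "K", "n", "N", "p", "p_adjust", "significant"]]
          .to_string(index=False))
    sig = table[table["significant"]]
    print(f"\n{len(sig)} term(s) pass adjusted p < 0.05")


if __name__ == "__main__":
    main()
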