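# kbhb-atlas

Quantitative downstream analysis of lysine β-hydroxybutyrylation (Kbhb)
profiling experiments: label-free proteomics tables in, protein-abundance-
corrected differential modification calls, motif/landscape/pathway
summaries, and structure/conservation-based site prioritization out.

## The problem

Kbhb is an acyl modification of lysine ε-amines derived from the ketone
body β-hydroxybutyrate; during fasting it remodels extensively across the
skeletal-muscle proteome. Site-level MS intensities confound two signals:
a change in modification *stoichiometry* and a change in the parent
protein's *abundance*. A site on a protein that doubles under starvation
doubles its raw intensity with no change in modification level at all.
This package implements the two-layer normalization that separates them,
plus the downstream analyses a site-level PTM study needs, and a
synthetic-data generator with a full truth ledger so every stage is
testable without real data.

## Method

For the global proteome, log2 LFQ intensities are quantile-normalized
across samples. For sites, with `I[f,s]` the intensity of feature `f` in
sample `s`:

1. **Filtering** — keep features with valid intensities in ≥ 3 of 4
   replicates in at least one group; sites additionally need localization
   probability ≥ 0.90 and peptide length ≥ 7.
2. **Center-scale** — `R[f,s] = I[f,s] / mean_s' I[f,s']` (mean over valid
   samples; every row has mean 1).
3. **Stoichiometry correction** —
   `M[f,s] = R_site[f,s] / R_protein[parent(f), s]`, dividing each site's
   relative value by its parent protein's relative value from the proteome
   run of the same sample.
4. **Differential testing** — two-sample pooled-variance (Student) t-test
   on log2 values; fold change as the ratio of linear group means; class
   `up`/`down` when p < 0.05 and |log2FC| > 0.585 (fold change 1.5), with
   Benjamini–Hochberg adjusted p-values reported alongside.

Downstream: sites-per-protein density bins {1..5, >5}; subcellular
assignment with a mitochondria > nucleus > cytoplasm > other priority;
two-sample Fisher-exact position enrichment and greedy motif-x extraction
on ±7-residue windows; hypergeometric over-representation analysis with BH
adjustment; minimal heavy-atom distances from modified lysines to
annotated functional residues, the four-way classification (PTM-overlap ×
within-5 Å), entropy-based conservation (1 − H/log 20), and prioritization
of conserved (> 0.85), spatially implicated lysines.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with known ground truth (bulk outputs under `scratch/`, summaries
under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_run_pipeline.py
python analysis/03_differential_evaluation.py
```

With the default conditions (760 proteins, ~2,100 sites, 4 vs 4
replicates, CV 0.2, 10% of sites truly up at log2FC 1, ~10%
protein-confounded at protein log2FC 1, seed 2026) this prints:

```
201 up / 27 down Kbhb sites after protein-abundance correction
{
 "true_up_sites": 215,
 "confounded_sites": 209,
 "recall_up_corrected_pct": 93.5,
 "confounded_called_up_corrected_pct": 0.0,
 "confounded_called_up_uncorrected_pct": 87.1
}
```

i.e. 93.5% of truly upregulated sites are recovered, no protein-confounded
site survives the correction, and without the correction 87% of them would
be falsely called up. `04_landscape_and_motifs.py` then recovers the
planted D-at-+1 motif as the top enrichment hit
(p ≈ 5e-66, motif-x pattern `.......KD......`), `05_pathway_enrichment.py`
ranks the planted pathway first (adjusted p ≈ 2e-24, decoy sets at p ≈ 1),
and `06_structure_prioritization.py` flags the conserved lysines within
5 Å of functional residues.

The same machinery is scriptable (`kbhb-atlas simulate|run|report`) and
importable (`kbhb_atlas.preprocess_quant`, `kbhb_atlas.differential`, …)
against real MaxQuant-style tables: a tab-delimited sites table (accession,
1-based position, localization probability, 15-mer window, per-sample
intensities), a proteinGroups-style LFQ matrix, FASTA, a two-column
subcellular TSV, GMT gene sets, and PDB structures with a residue-label
TSV.

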