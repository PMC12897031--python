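# Methods

## Scope and data model

The package analyses two label-free quantification matrices from the same
two-group experiment (control vs starved, four biological replicates
each): a protein-level LFQ matrix and a Kbhb site-level intensity table
carrying, per site, the parent accession, the 1-based modified-lysine
position, a localization probability, and the ±7-residue sequence window
(15-mer, centre K, `_`-padded at termini). Positions follow the MaxQuant
1-based convention throughout. Missing intensities are represented as NaN
internally and accepted on disk as empty cells, `0` or `NaN`; they are
never imputed.

## Normalization and stoichiometry correction

The proteome matrix is log2-transformed and quantile-normalized across
samples: each column's sorted valid values are replaced by the
cross-column mean of sorted values, ties receiving the mean of the
reference values at their tied ranks, and columns with unequal valid
counts matched by linear interpolation on the quantile scale. The site
matrix is *not* quantile-normalized by default (a config flag enables it);
it is center-scaled on the linear scale — each feature divided by its mean
over valid samples — and then divided sample-wise by the parent protein's
center-scaled value computed from the back-transformed quantile-normalized
proteome. Sites whose parent protein is not quantified are flagged
`parent-missing` and excluded from the corrected matrix rather than passed
through uncorrected.

Filtering precedes normalization: a feature needs ≥ `min_valid` (default
3) valid values in at least one group; sites additionally need
localization probability ≥ 0.90 and peptide length ≥ 7 when that column is
present. Every dropped feature is logged with the failed rule, and
`features_in = features_out + features_rejected` holds exactly at each
filter.

## Differential testing

Per feature, a classical pooled-variance two-sample t-test on log2 values;
the fold change is the ratio of linear-scale group means (treatment over
reference). Classification uses strict thresholds: `up` when p < 0.05 and
log2FC > 0.585 (fold change 1.5), `down` symmetric, otherwise `ns`.
BH-adjusted p-values are reported but deliberately do not drive the
classification — the analysis is exploratory and prioritizes
large-magnitude changes; the adjusted column lets a reader apply FDR
control. Features with fewer than two valid values in a group cannot be
tested and are emitted in a separate presence/absence report instead of
being counted as up or down. Zero pooled variance yields t = 0, p = 1 for
equal means and a degenerate-flagged, underflowed p for unequal means.

## Landscape, motif and pathway summaries

Sites-per-protein density uses bins {1, 2, 3, 4, 5, >5} over distinct
(protein, position) pairs. Subcellular assignment resolves multi-annotated
proteins by a configurable priority, mitochondria > nucleus > cytoplasm >
other, favouring the most specific organelle; unannotated proteins fall in
`other`. Percentages are reported to two decimals.

Position-specific motif statistics compare foreground windows (by default
the upregulated sites) against all quantified windows with a two-sided
Fisher exact test per (offset, residue); padding never counts as a
residue. The exact test replaces the t-approximation of two-sample logo
displays because counts here are small. Note that for a 2×2 table the
enrichment of one residue and the depletion of its complement are the same
table, so complementary rows share a p-value. The motif-x iteration
greedily fixes the (offset, residue) with the smallest binomial tail
probability below 1e-6 among those with ≥ 20 foreground occurrences,
filters both sets to matching windows, and on convergence removes matched
windows and restarts; the thresholds follow the original motif-x defaults
and are exposed as parameters.

Over-representation analysis is an explicit hypergeometric upper tail,
P[X ≥ k] for k foreground hits of a K-member term in an n-of-N draw, BH
adjusted across tested terms. The universe is the quantified (post-filter)
feature space, restricted to annotated members as standard ORA tools do;
site-level foregrounds are mapped to parent proteins and deduplicated so a
protein with several regulated sites counts once.

## Structure and conservation

Distances are minimal heavy-atom pair distances (first model, altloc
blank/"A", hydrogens excluded) between a modified lysine and annotated
residue sets; functional and known-PTM residues are input annotations, not
computed. Each lysine is classified by (overlaps a known-PTM residue,
within 5 Å of a functional residue) into overlap+near / overlap-only /
near-only / neither; an absent distance (no annotation) counts as not
near. Conservation is scored per alignment column as 1 − H/log 20 with H
the Shannon entropy of non-gap residue frequencies; columns with > 50%
gaps are left unscored. This is a deliberately simple, exactly testable
monotone score standing in for ML rate estimation; the 0.85 prioritization
cutoff applies on this scale, and the scorer is swappable. Prioritized
lysines are those above the conservation cutoff in a spatially implicated
category, ranked by conservation then distance. Sequence-to-structure
numbering is assumed identical, with an offset parameter for tagged
constructs.

## The synthetic-data generator

The generator emulates the study design: two groups of four replicates,
log-normal intensities (log2 base mean 27, sd 2 — typical LFQ dynamic
range), a sites-per-protein distribution mirroring the observed landscape
(~41% single-site proteins, ~14% with more than five sites), a subcellular
composition of ~36% cytoplasm / 17% nucleus / 14% mitochondria, and an
up:down site ratio of about 8:1.

Noise has two layers. Biological replicate variation (CV 0.20) is drawn
once per protein per sample and *shared* between the proteome and the site
measurement of that sample, because both assays measure the same tissue
lysate; each assay then adds its own technical noise (CV 0.05). This
sharing is what makes the parent-protein correction genuinely informative
in simulation, exactly as in the real design where the proteome and PTM
runs come from the same samples. Per-feature CVs of real LFQ data are not
published for this design; both CVs are stated assumptions and
configurable.

True site classes: `up`/`down` sites change stoichiometry by
±`site_effect_log2fc` (default 1.0); `protein-confounded` sites keep
stoichiometry flat while their parent protein shifts by
`protein_effect_log2fc` — their raw intensities move although the
modification level does not. Because any flat-stoichiometry site on a
changed protein is by construction confounded, changed proteins are the
hosts of the confounded sites, and the number of changed proteins is
whatever covers the confounded-site quota, floored at
`frac_proteins_changed` of all proteins. Missingness is MCAR by default
(rate 0.05), with an optional intensity-dependent logistic mode, since the
≥3-of-4 validity filter only has bite under missingness. Windows are cut
from generated protein sequences (uniform residue background, centre K
forced); the motif specification plants residues at offsets with elevated
probability in the windows of a target class (default: D at +1 in 60% of
up sites). Gene sets comprise one pathway planted inside the up-regulated
proteins plus random decoys. Toy structures place lysines at exact planted
distances (3/9/4/12 Å) from a functional residue with alternating known-
PTM overlap, covering all four categories; accompanying gapless alignments
keep modified-lysine columns invariant so those sites score conservation
1.0. A separate ADSS1-like fixture places K448 exactly 14 Å from a
three-residue annotated pocket; it is a synthetic stand-in for
demonstrating the distance mechanism, not a predicted structure.

What the generator does not emulate: peptide-level effects (shared/razor
peptides, missed cleavages), intensity-dependent variance, correlated
missingness between the proteome and PTM runs, compositional distortions
of real LFQ, or realistic residue background frequencies. Passing tests
therefore demonstrate the correctness of the computations under the stated
generative model, not performance on real acquisitions.

## Numerical choices and degenerate inputs

Quantile normalization is idempotent and column-permutation-equivariant on
complete matrices; with missing values the interpolation step makes
idempotence approximate. All-missing columns are an error; all-missing
rows are dropped with a log entry at center-scale. BH adjustment enforces
step-up monotonicity and caps at 1. Fisher, hypergeometric, binomial and
t tail probabilities come from scipy's distributions; the t statistic is
computed in closed form so the zero-variance branches are explicit.
Tie-breaks are deterministic everywhere (stable sorts by p then offset/
residue/term), so a fixed seed reproduces every output byte-for-byte.

## Known limitations

Correcting against the *quantile-normalized* proteome leaves a small
systematic residual on confounded sites when the true abundance changes
are strongly one-sided (QN compresses a one-sided distributional shift):
at the default conditions the mean |corrected log2 ratio| of confounded
sites is ~0.13 instead of ~0.06, far below the 0.585 classification
threshold but visible as a false-positive rate of 0–2% among confounded
sites depending on the seed. Correcting against the merely center-scaled
proteome removes the residual entirely; both paths are available. Other
limitations: nominal-p classification inflates false positives by design
(the BH column is reported for stricter readings); the conservation score
ignores substitution chemistry and phylogeny; structures are reduced to
heavy-atom coordinates with input annotations; shared peptides are
assigned to their first listed accession.

## Problem sizes

Default simulations use 760 proteins (~2,100 sites), the scale at which
the recovery and calibration properties are measured with usefully tight
Monte-Carlo error while the full suite and the acceptance script each run
in well under a minute.
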