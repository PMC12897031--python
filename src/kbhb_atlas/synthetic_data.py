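"""Ground-truth generator for every input the pipeline consumes.

The generator emulates a label-free PTM-profiling experiment on two groups
of four biological replicates: a global proteome LFQ matrix, a Kbhb sites
table with localization probabilities and ±7 sequence windows, protein
FASTA sequences, subcellular annotation, GMT gene sets, toy PDB structures
and small multiple-sequence alignments — together with a ledger stating,
for every feature, what is actually true.

Intensity model.  Protein log2 abundance is Normal(base mean, base sd) per
protein.  Each sample adds a biological deviation drawn from the
replicate CV; because the proteome and the Kbhb enrichment assay the same
tissue lysate, this biological term is *shared* between the two
measurements of a sample, while each assay adds its own smaller technical
noise.  A site's intensity is parent-protein abundance x a site-specific
stoichiometry factor x technical noise.  "up"/"down" sites change their
stoichiometry by ±site_effect_log2fc in the starved group;
"protein-confounded" sites keep stoichiometry flat while their parent
protein changes — their raw intensities shift although the modification
level does not, which is exactly the artefact the parent-protein
correction removes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import formats_io as fio
from .formats_io import (
    AA_ALPHABET,
    CONTROL,
    STARVED,
    KbhbSiteRecord,
    Residue,
    ResidueGeometry,
    SampleDesign,
    two_group_design,
)

SITE_CLASSES = ("null", "up", "down", "protein-confounded")

#: sites-per-protein bins; ">5" draws uniformly from 6-8
SITE_BIN_KEYS = ("1", "2", "3", "4", "5", ">5")

_DEFAULT_SITE_DIST = {
    # mirrors the observed landscape: ~41% single-site proteins, ~14% with >5
    "1": 0.4138, "2": 0.20, "3": 0.12, "4": 0.08, "5": 0.0462, ">5": 0.14,
}

_DEFAULT_COMPARTMENTS = {
    # observed subcellular split of the modified proteome
    "cytoplasm": 0.359, "nucleus": 0.169, "mitochondria": 0.140, "other": 0.332,
}


class ConfigurationError(ValueError):
    """The generator configuration violates an invariant."""


def _check_probs(name: str, probs: Mapping[str, float]) -> None:
    if any(p < 0 for p in probs.values()):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {sum(probs.values())}, not 1")


def _cv_to_log2_sd(cv: float) -> float:
    """Log-normal sigma (in log2 units) for a linear-scale coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv)) / math.log(2.0)


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic experiment.

    Defaults are the study conditions: 4 replicates per group, biological
    CV 0.20, site effects of |log2FC| = 1, an up:down site ratio of about
    8:1 and a D-at-+1 motif planted in upregulated windows.
    """

    n_proteins: int = 760
    sites_per_protein_distribution: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SITE_DIST))
    n_replicates_per_group: int = 4
    base_intensity_log_mean: float = 27.0
    base_intensity_log_sd: float = 2.0
    replicate_cv: float = 0.20        # biological, shared between assays of a sample
    technical_cv: float = 0.05        # per-assay measurement noise
    missing_rate: float = 0.05
    missing_mode: str = "mcar"        # "mcar" or "intensity" (logistic in log2 intensity)
    frac_sites_up: float = 0.10
    frac_sites_down: float = 0.0125
    site_effect_log2fc: float = 1.0
    frac_proteins_changed: float = 0.10
    protein_effect_log2fc: float = 1.0
    frac_confounded_sites: float = 0.10
    frac_orphan_sites: float = 0.01   # sites whose parent is absent from the proteome table
    motif_spec: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {1: ("D", 0.6)})
    motif_target_class: str = "up"
    compartment_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPARTMENTS))
    low_locprob_rate: float = 0.02    # fraction of sites below the 0.90 localization cut
    short_peptide_rate: float = 0.01  # fraction of sites on sub-7-aa peptides
    seed: int = 0

    def validate(self) -> None:
        _check_probs("sites_per_protein_distribution", self.sites_per_protein_distribution)
        if set(self.sites_per_protein_distribution) != set(SITE_BIN_KEYS):
            raise ConfigurationError(f"site distribution keys must be {SITE_BIN_KEYS}")
        _check_probs("compartment_probs", self.compartment_probs)
        for name in ("missing_rate", "frac_sites_up", "frac_sites_down",
                     "frac_proteins_changed", "frac_confounded_sites",
                     "frac_orphan_sites", "low_locprob_rate", "short_peptide_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_sites_up + self.frac_sites_down + self.frac_confounded_sites > 1.0:
            raise ConfigurationError("site class fractions exceed 1")
        if self.n_proteins < 1 or self.n_replicates_per_group < 2:
            raise ConfigurationError("need >=1 protein and >=2 replicates per group")
        for offset, (residue, prob) in self.motif_spec.items():
            if offset == 0 or not -7 <= offset <= 7:
                raise ConfigurationError(f"motif offset {offset} outside ±7 (and not 0)")
            if residue not in AA_ALPHABET or not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"bad motif entry {offset}: {(residue, prob)}")
        if self.motif_target_class not in SITE_CLASSES:
            raise ConfigurationError(f"motif_target_class must be one of {SITE_CLASSES}")
        if self.missing_mode not in ("mcar", "intensity"):
            raise ConfigurationError("missing_mode must be 'mcar' or 'intensity'")


@dataclass
class SyntheticTruth:
    """What is actually true about every generated feature."""

    site_class: dict[str, str]                  # site_id -> class
    site_effect_log2fc: dict[str, float]        # signed stoichiometry effect (0 unless up/down)
    protein_class: dict[str, str]               # accession -> "null" | "changed"
    protein_effect_log2fc: dict[str, float]
    motif_planted: dict[str, list[list]]        # site_id -> [[offset, residue], ...] realized
    compartments: dict[str, str]                # accession -> planted compartment
    structure_distances: dict[str, dict[str, float]]  # structure id -> "resnum" -> planted min distance (Angstrom)
    orphan_sites: list[str]                     # sites whose parent is absent from the proteome table

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    def sites_of_class(self, cls_name: str) -> list[str]:
        return [s for s, c in self.site_class.items() if c == cls_name]


@dataclass
class SyntheticDataset:
    """Bundle of all generated pipeline inputs plus the truth ledger."""

    design: SampleDesign
    proteome: pd.DataFrame                      # accession x sample linear LFQ, NaN missing
    site_records: list[KbhbSiteRecord]
    sequences: dict[str, str]
    annotation: dict[str, list[str]]
    gene_sets: dict[str, set[str]]
    structures: dict[str, ResidueGeometry]
    alignments: dict[str, dict[str, str]]       # structure id -> MSA (id -> aligned seq)
    truth: SyntheticTruth

    def site_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return fio.site_records_to_frames(self.site_records, self.design)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_site_counts(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    keys = list(SITE_BIN_KEYS)
    probs = np.array([cfg.sites_per_protein_distribution[k] for k in keys])
    picks = rng.choice(len(keys), size=cfg.n_proteins, p=probs / probs.sum())
    counts = np.empty(cfg.n_proteins, dtype=int)
    for i, pick in enumerate(picks):
        counts[i] = int(keys[pick]) if keys[pick] != ">5" else int(rng.integers(6, 9))
    return counts


def _assign_classes(rng: np.random.Generator, cfg: GeneratorConfig,
                    proteins: list[str], site_counts: np.ndarray
                    ) -> tuple[dict[str, str], dict[str, str]]:
    """Per-protein pools; sites inherit their protein's pool.

    Changed proteins host the protein-confounded sites (a flat-stoichiometry
    site on a changed protein *is* confounded), so the number of changed
    proteins is whatever covers the confounded-site quota, floored at
    frac_proteins_changed of all proteins.
    """
    total_sites = int(site_counts.sum())
    order = rng.permutation(len(proteins))
    quota_conf = cfg.frac_confounded_sites * total_sites
    min_changed = math.ceil(cfg.frac_proteins_changed * len(proteins))
    quota_up = cfg.frac_sites_up * total_sites
    quota_down = cfg.frac_sites_down * total_sites

    protein_pool: dict[str, str] = {}
    covered_conf = covered_up = covered_down = 0
    n_changed = 0
    for idx in order:
        acc, n_sites = proteins[idx], int(site_counts[idx])
        if covered_conf < quota_conf or n_changed < min_changed:
            protein_pool[acc] = "confounded"
            covered_conf += n_sites
            n_changed += 1
        elif covered_up < quota_up:
            protein_pool[acc] = "up"
            covered_up += n_sites
        elif covered_down < quota_down:
            protein_pool[acc] = "down"
            covered_down += n_sites
        else:
            protein_pool[acc] = "null"
    site_class_of_pool = {"confounded": "protein-confounded", "up": "up",
                          "down": "down", "null": "null"}
    return protein_pool, site_class_of_pool


def _make_sequence(rng: np.random.Generator, length: int, positions: Sequence[int],
                   planted: Mapping[int, str]) -> str:
    seq = rng.choice(list(AA_ALPHABET), size=length)
    for pos in positions:
        seq[pos - 1] = "K"
    for pos1, res in planted.items():
        seq[pos1 - 1] = res
    return "".join(seq)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate every pipeline input with a known truth ledger.

    Deterministic in ``config.seed``: the same configuration yields
    bit-identical tables.
    """
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (rng_layout, rng_intensity, rng_missing, rng_seq, rng_annot,
     rng_struct, rng_misc) = [np.random.default_rng(s) for s in ss.spawn(7)]

    design = two_group_design(cfg.n_replicates_per_group)
    samples = design.samples
    n_samples = len(samples)
    starved_mask = np.array([design.groups[s] == STARVED for s in samples])

    proteins = [f"P{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    site_counts = _draw_site_counts(rng_layout, cfg)
    protein_pool, pool_to_class = _assign_classes(rng_layout, cfg, proteins, site_counts)

    sigma_bio = _cv_to_log2_sd(cfg.replicate_cv)
    sigma_tech = _cv_to_log2_sd(cfg.technical_cv)

    protein_class: dict[str, str] = {}
    protein_effect: dict[str, float] = {}
    site_class: dict[str, str] = {}
    site_effect: dict[str, float] = {}
    motif_planted: dict[str, list[list]] = {}
    sequences: dict[str, str] = {}
    annotation: dict[str, list[str]] = {}
    compartments: dict[str, str] = {}
    orphan_sites: list[str] = []

    comp_names = list(cfg.compartment_probs)
    comp_probs = np.array([cfg.compartment_probs[c] for c in comp_names])
    comp_probs = comp_probs / comp_probs.sum()

    proteome_log2 = np.empty((cfg.n_proteins, n_samples))
    site_rows: list[KbhbSiteRecord] = []
    orphan_parents: set[str] = set()

    for p_idx, acc in enumerate(proteins):
        n_sites = int(site_counts[p_idx])
        pool = protein_pool[acc]
        p_effect = cfg.protein_effect_log2fc if pool == "confounded" else 0.0
        protein_class[acc] = "changed" if pool == "confounded" else "null"
        protein_effect[acc] = p_effect

        base = rng_intensity.normal(cfg.base_intensity_log_mean, cfg.base_intensity_log_sd)
        bio = rng_intensity.normal(0.0, sigma_bio, size=n_samples)
        abundance = base + p_effect * starved_mask + bio           # true log2 abundance per sample
        proteome_log2[p_idx] = abundance + rng_intensity.normal(0.0, sigma_tech, size=n_samples)

        # site positions on a sequence long enough to hold them
        length = max(60, 25 * n_sites)
        positions = sorted(rng_seq.choice(np.arange(1, length + 1), size=n_sites,
                                          replace=False).tolist())

        planted: dict[int, str] = {}
        this_class = pool_to_class[pool]
        for pos in positions:
            sid = f"{acc}_K{pos}"
            site_class[sid] = this_class
            s_eff = 0.0
            if this_class == "up":
                s_eff = cfg.site_effect_log2fc
            elif this_class == "down":
                s_eff = -cfg.site_effect_log2fc
            site_effect[sid] = s_eff
            if this_class == cfg.motif_target_class:
                realized: list[list] = []
                for offset, (res, prob) in cfg.motif_spec.items():
                    tgt = pos + offset
                    if 1 <= tgt <= length and tgt not in positions and rng_seq.random() < prob:
                        planted[tgt] = res
                        realized.append([offset, res])
                if realized:
                    motif_planted[sid] = realized

        sequences[acc] = _make_sequence(rng_seq, length, positions, planted)

        comp = comp_names[int(rng_annot.choice(len(comp_names), p=comp_probs))]
        compartments[acc] = comp
        if comp != "other":                      # unannotated proteins resolve to "other"
            annotation[acc] = [comp]

        is_orphan = rng_misc.random() < cfg.frac_orphan_sites
        if is_orphan:
            orphan_parents.add(acc)

        stoich = rng_intensity.normal(-2.0, 0.8, size=n_sites)    # log2 site/protein ratio
        for s_idx, pos in enumerate(positions):
            sid = f"{acc}_K{pos}"
            log2_site = (abundance + site_effect[sid] * starved_mask + stoich[s_idx]
                         + rng_intensity.normal(0.0, sigma_tech, size=n_samples))
            intens = np.power(2.0, log2_site)
            if cfg.missing_mode == "mcar":
                miss = rng_missing.random(n_samples) < cfg.missing_rate
            else:
                # logistic in log2 intensity: low-abundance values vanish more often
                centre = cfg.base_intensity_log_mean - 2.0
                p_miss = cfg.missing_rate * 2.0 / (1.0 + np.exp((log2_site - centre) / 1.5))
                miss = rng_missing.random(n_samples) < np.clip(p_miss, 0.0, 1.0)
            loc_prob = (0.90 + 0.10 * rng_misc.random()
                        if rng_misc.random() >= cfg.low_locprob_rate
                        else 0.50 + 0.39 * rng_misc.random())
            pep_len = (int(rng_misc.integers(7, 26))
                       if rng_misc.random() >= cfg.short_peptide_rate
                       else int(rng_misc.integers(5, 7)))
            window = _window_from_sequence(sequences[acc], pos)
            site_rows.append(KbhbSiteRecord(
                protein=acc, position=pos, localization_prob=round(loc_prob, 4),
                window=window,
                intensities={s: (None if miss[j] else float(intens[j]))
                             for j, s in enumerate(samples)},
                peptide_length=pep_len))
            if is_orphan:
                orphan_sites.append(sid)

    # missing values in the proteome matrix
    prot_missing = rng_missing.random(proteome_log2.shape) < cfg.missing_rate
    proteome = pd.DataFrame(np.power(2.0, proteome_log2), index=proteins, columns=samples)
    proteome[prot_missing] = np.nan
    proteome = proteome.drop(index=sorted(orphan_parents))
    proteome.index.name = fio.COL_PROTEIN

    gene_sets = _make_gene_sets(rng_annot, proteins, protein_pool)
    structures, alignments, struct_distances = _make_structures(
        rng_struct, sequences, site_class)

    truth = SyntheticTruth(
        site_class=site_class, site_effect_log2fc=site_effect,
        protein_class=protein_class, protein_effect_log2fc=protein_effect,
        motif_planted=motif_planted, compartments=compartments,
        structure_distances=struct_distances, orphan_sites=orphan_sites)

    return SyntheticDataset(design=design, proteome=proteome, site_records=site_rows,
                            sequences=sequences, annotation=annotation,
                            gene_sets=gene_sets, structures=structures,
                            alignments=alignments, truth=truth)


def _window_from_sequence(seq: str, pos: int, flank: int = 7) -> str:
    left = seq[max(0, pos - 1 - flank):pos - 1]
    right = seq[pos:pos + flank]
    return "_" * (flank - len(left)) + left + seq[pos - 1] + right + "_" * (flank - len(right))


def _make_gene_sets(rng: np.random.Generator, proteins: list[str],
                    protein_pool: Mapping[str, str]) -> dict[str, set[str]]:
    """A planted pathway inside the up-regulated pool plus random decoys."""
    up_pool = [p for p in proteins if protein_pool[p] == "up"]
    gene_sets: dict[str, set[str]] = {}
    if up_pool:
        k = min(len(up_pool), 30)
        gene_sets["PLANTED_UP_PATHWAY"] = set(
            rng.choice(up_pool, size=k, replace=False).tolist())
    n_decoys = 6
    for i in range(1, n_decoys + 1):
        k = min(len(proteins), int(rng.integers(20, 50)))
        gene_sets[f"RANDOM_SET_{i}"] = set(rng.choice(proteins, size=k, replace=False).tolist())
    return gene_sets


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

# (distance to the functional residue in Angstrom, lysine is itself a known-PTM residue)
_CATEGORY_CYCLE = [(3.0, True), (9.0, True), (4.0, False), (12.0, False)]


def generate_toy_structure(spec: Sequence[tuple[str, int, Sequence[tuple[str, Sequence[float]]]]],
                           path: str | Path | None = None
                           ) -> tuple[ResidueGeometry, dict[tuple[int, int], float]]:
    """Build a minimal structure from explicit residue/atom coordinates.

    ``spec`` rows are ``(residue name, residue number, [(atom name, (x, y, z)), ...])``.
    Returns the geometry plus the exact pairwise minimal distances between
    all residue pairs (the ledger downstream distance tests check against).
    Duplicate residue numbers raise; written files are valid PDB subsets.
    """
    if not spec:
        raise ValueError("structure spec needs at least one residue")
    residues = []
    for resname, resnum, atoms in spec:
        if not atoms:
            raise ValueError(f"residue {resnum} has no atoms")
        coords = np.asarray([xyz for _, xyz in atoms], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"residue {resnum}: non-finite coordinates")
        residues.append(Residue("A", resnum, resname, [a for a, _ in atoms], coords))
    geometry = ResidueGeometry(residues)  # raises on duplicate residue numbers
    ledger: dict[tuple[int, int], float] = {}
    for i, a in enumerate(residues):
        for b in residues[i + 1:]:
            d = np.sqrt(((a.coords[:, None, :] - b.coords[None, :, :]) ** 2).sum(-1)).min()
            ledger[(a.resnum, b.resnum)] = float(d)
    if path is not None:
        fio.write_pdb(geometry, path)
    return geometry, ledger


def _make_structures(rng: np.random.Generator, sequences: Mapping[str, str],
                     site_class: Mapping[str, str]
                     ) -> tuple[dict[str, ResidueGeometry], dict[str, dict[str, str]],
                                dict[str, dict[str, float]]]:
    """Toy structures for up to four modified proteins, covering all four
    spatial/PTM-overlap categories, plus conserved-column MSAs."""
    by_protein: dict[str, list[int]] = {}
    for sid, cls in site_class.items():
        if cls != "up":
            continue
        acc, pos = sid.rsplit("_K", 1)
        by_protein.setdefault(acc, []).append(int(pos))
    chosen = sorted(by_protein)[:4]

    structures: dict[str, ResidueGeometry] = {}
    alignments: dict[str, dict[str, str]] = {}
    distances: dict[str, dict[str, float]] = {}
    for acc in chosen:
        positions = sorted(by_protein[acc])[:4]
        func_resnum = max(sequences[acc].__len__(), max(positions)) + 10
        spec: list[tuple[str, int, list[tuple[str, tuple[float, float, float]]]]] = [
            ("GLU", func_resnum, [("OE1", (0.0, 0.0, 0.0))])]
        ptm_set: set[int] = set()
        dist_ledger: dict[str, float] = {}
        directions = np.eye(3).tolist() + [[0.577350269, 0.577350269, 0.577350269]]
        for i, pos in enumerate(positions):
            d, overlaps = _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
            u = np.asarray(directions[i % len(directions)])
            u = u / np.linalg.norm(u)
            nz = tuple((d * u).tolist())
            ca = tuple((d * u + np.array([0.0, 0.0, 2.0])).tolist())
            spec.append(("LYS", pos, [("NZ", nz), ("CA", ca)]))
            if overlaps:
                ptm_set.add(pos)
            dist_ledger[str(pos)] = d
        geometry, _ = generate_toy_structure(spec)
        geometry.kbhb_lysines = set(positions)
        geometry.functional_residues = {func_resnum}
        geometry.ptm_residues = ptm_set
        structures[acc] = geometry
        distances[acc] = dist_ledger
        alignments[acc] = _make_alignment(rng, sequences[acc], positions)
    return structures, alignments, distances


def _make_alignment(rng: np.random.Generator, ref_seq: str, conserved: Sequence[int],
                    n_species: int = 8, mutation_rate: float = 0.3) -> dict[str, str]:
    """Gapless MSA: the reference plus relatives mutated away from it at
    non-conserved columns; planted lysine columns stay invariant."""
    msa = {"REF": ref_seq}
    keep = set(conserved)
    for s in range(1, n_species):
        chars = list(ref_seq)
        for i in range(len(chars)):
            if (i + 1) not in keep and rng.random() < mutation_rate:
                chars[i] = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        msa[f"SP{s}"] = "".join(chars)
    return msa


def adss1_like_structure() -> ResidueGeometry:
    """Synthetic stand-in for the adenylosuccinate synthetase (ADSS1) mapping.

    A toy geometry in which lysine 448 sits exactly 14 Angstrom from the
    nearest atom of a three-residue "GTP-binding pocket".  This is a
    synthetic fixture for exercising the distance machinery, not the
    predicted mouse ADSS1 model.
    """
    spec = [
        ("GLY", 100, [("CA", (0.0, 0.0, 0.0))]),
        ("ASP", 101, [("CA", (-2.0, 1.0, 0.0)), ("OD1", (-3.0, 1.5, 0.5))]),
        ("THR", 102, [("CA", (-1.5, 2.0, 1.0))]),
        ("LYS", 448, [("NZ", (14.0, 0.0, 0.0)), ("CA", (15.5, 0.5, 2.5))]),
    ]
    geometry, _ = generate_toy_structure(spec)
    geometry.kbhb_lysines = {448}
    geometry.functional_residues = {100, 101, 102}
    return geometry


# ---------------------------------------------------------------------------
# writing a dataset to disk
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in its on-disk format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sites"] = outdir / "kbhb_sites.tsv"
    fio.write_site_table(dataset.site_records, paths["sites"], dataset.design)
    paths["proteome"] = outdir / "proteome_lfq.tsv"
    fio.write_protein_table(dataset.proteome, paths["proteome"])
    paths["fasta"] = outdir / "proteins.fasta"
    fio.write_fasta(dataset.sequences, paths["fasta"])
    paths["annotation"] = outdir / "subcellular.tsv"
    fio.write_annotation(dataset.annotation, paths["annotation"])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    fio.write_gmt(dataset.gene_sets, paths["gene_sets"])
    paths["design"] = outdir / "design.tsv"
    with open(paths["design"], "w") as fh:
        for s, g in dataset.design.groups.items():
            fh.write(f"{s}\t{g}\n")

    struct_dir = outdir / "structures"
    struct_dir.mkdir(exist_ok=True)
    for acc, geometry in dataset.structures.items():
        fio.write_pdb(geometry, struct_dir / f"{acc}.pdb")
        fio.write_structure_labels(
            {"kbhb": geometry.kbhb_lysines, "functional": geometry.functional_residues,
             "ptm": geometry.ptm_residues},
            struct_dir / f"{acc}.labels.tsv")
    for acc, msa in dataset.alignments.items():
        fio.write_fasta(msa, struct_dir / f"{acc}.aln.fasta")
    paths["structures"] = struct_dir

    paths["truth"] = outdir / "truth.json"
    dataset.truth.to_json(paths["truth"])
    return paths


def read_design(path: str | Path) -> SampleDesign:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sample, group = line.rstrip("\n").split("\t")
                groups[sample] = group
    return SampleDesign(groups)
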