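"""End-to-end orchestration: simulate or load inputs, normalize, correct,
test, summarize, and write a report bundle with a run manifest.

Stage order mirrors the analysis: proteome normalization (log2 + quantile),
protein differential; site filtering, center-scale, parent-protein
correction, site differential; landscape, motif, enrichment, structural
prioritization; replicate QC (PCA and Pearson correlation).  Each stage
failure halts the run naming the stage; outputs written before the failure
are retained.  Row-count bookkeeping is exact at every filter:
features_in = features_out + features_rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import enrichment as enr
from . import formats_io as fio
from . import motif as mot
from . import preprocess_quant as pq
from . import site_landscape as land
from . import structure_conservation as sc
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def percent_change(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after``, one decimal.

    percent_change(29.3, 22.0) = 24.9 — the body-weight loss arithmetic.
    """
    if before <= 0:
        raise ValueError(f"baseline must be positive, got {before}")
    return round(100.0 * (before - after) / before, 1)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------


def pca_coordinates(matrix: pd.DataFrame, n_components: int = 2
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on features with no missing values (centered, unscaled).

    ``matrix`` is features x samples; returns (samples x PC coordinates,
    explained variance ratios).
    """
    complete = matrix.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("PCA needs at least two complete features")
    x = complete.T.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    coords = pd.DataFrame(u[:, :k] * s[:k], index=matrix.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    evr = (s ** 2) / (s ** 2).sum()
    return coords, evr[:k]


def pearson_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation over pairwise-complete features."""
    return matrix.corr(method="pearson")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Exactly one of ``simulate`` (generator settings) or ``inputs``
    (paths to on-disk tables) must be active."""

    simulate: synth.GeneratorConfig | None = None
    inputs: dict[str, str] | None = None      # sites, proteome, design, fasta,
                                              # annotation, gene_sets, structures
    alpha: float = diff.ALPHA
    fc_threshold: float = diff.FC_THRESHOLD
    loc_prob_min: float = 0.90
    min_valid: int = 3
    min_peptide_len: int = 7
    distance_cutoff: float = sc.DISTANCE_CUTOFF
    conservation_min: float = sc.CONSERVATION_MIN
    quantile_normalize_sites: bool = False    # alternative reading: QN the site matrix too
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate / inputs must be set")
        for name in ("alpha", "fc_threshold", "loc_prob_min", "distance_cutoff",
                     "conservation_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "motif_spec" in sim:
                sim["motif_spec"] = {int(k): (v[0], float(v[1]))
                                     for k, v in sim["motif_spec"].items()}
            sim = synth.GeneratorConfig(**sim)
        return cls(simulate=sim, **raw)


@dataclass
class PipelineResult:
    outdir: Path
    proteome_log2_qn: pd.DataFrame
    protein_relative: pd.DataFrame
    protein_differential: pd.DataFrame
    site_meta: pd.DataFrame                   # post-filter
    site_relative: pd.DataFrame
    site_corrected: pd.DataFrame
    site_differential: pd.DataFrame
    site_untestable: pd.DataFrame
    correction_status: pd.Series
    density: land.SiteDensitySummary
    compartments: dict[str, land.CompartmentSummary]
    motif_enrichment: pd.DataFrame
    motif_patterns: list[mot.MotifPattern]
    enrichment: pd.DataFrame
    structure_reports: dict[str, list[sc.LysineStructReport]]
    prioritized: dict[str, list[sc.LysineStructReport]]
    qc: dict[str, Any]
    manifest: dict[str, Any]
    truth: synth.SyntheticTruth | None = None


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict[str, int]] = {}
    written: list[str] = []

    def _write(frame: pd.DataFrame, name: str, **kwargs) -> None:
        frame.to_csv(outdir / name, sep="\t", **kwargs)
        written.append(name)

    # -- load ---------------------------------------------------------------
    stage = "load"
    try:
        truth = None
        structures: dict[str, fio.ResidueGeometry] = {}
        alignments: dict[str, dict[str, str]] = {}
        gene_set_path: Path | None = None
        gene_sets: dict[str, set[str]] | None = None
        if config.simulate is not None:
            gen_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            dataset = synth.generate_dataset(gen_cfg)
            design = dataset.design
            proteome = dataset.proteome
            site_meta_all, site_intensities = dataset.site_frames()
            sequences = dataset.sequences
            annotation = dataset.annotation
            gene_sets = dataset.gene_sets
            structures = dataset.structures
            alignments = dataset.alignments
            truth = dataset.truth
            truth.to_json(outdir / "truth.json")
            written.append("truth.json")
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()}
            design = synth.read_design(paths["design"])
            records = fio.read_site_table(paths["sites"], design)
            site_meta_all, site_intensities = fio.site_records_to_frames(records, design)
            proteome = fio.read_protein_table(paths["proteome"], design)
            sequences = fio.read_fasta(paths["fasta"]) if "fasta" in paths else {}
            annotation = fio.read_annotation(paths["annotation"]) if "annotation" in paths else {}
            gene_set_path = paths.get("gene_sets")
            if "structures" in paths:
                structures, alignments = _load_structures(paths["structures"])
        counts[stage] = {"proteins_in": len(proteome), "sites_in": len(site_intensities)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- proteome normalization ---------------------------------------------
    stage = "proteome_normalize"
    try:
        prot_filtered, prot_rejects = pq.filter_features(
            proteome, design, min_valid=config.min_valid)
        counts[stage] = {"in": len(proteome), "out": len(prot_filtered),
                         "rejected": len(prot_rejects)}
        proteome_log2_qn = pq.quantile_normalize(np.log2(prot_filtered))
        protein_linear_qn = np.power(2.0, proteome_log2_qn)
        protein_relative, _ = pq.center_scale(protein_linear_qn)
        _write(prot_rejects, "proteome_rejected.tsv", index=False)
        _write(proteome_log2_qn, "proteome_log2_quantile.tsv")
        _write(protein_relative, "protein_relative.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- protein differential -----------------------------------------------
    stage = "protein_differential"
    try:
        prot_diff, prot_untest = diff.differential_analysis(
            protein_linear_qn, design, alpha=config.alpha,
            fc_threshold=config.fc_threshold)
        counts[stage] = {"tested": len(prot_diff), "untestable": len(prot_untest)}
        _write(prot_diff, "protein_differential.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- site filtering ------------------------------------------------------
    stage = "site_filter"
    try:
        site_filtered, site_rejects = pq.filter_features(
            site_intensities, design, min_valid=config.min_valid,
            site_meta=site_meta_all, loc_prob_min=config.loc_prob_min,
            min_peptide_len=config.min_peptide_len)
        site_meta = site_meta_all.loc[site_filtered.index]
        counts[stage] = {"in": len(site_intensities), "out": len(site_filtered),
                         "rejected": len(site_rejects)}
        assert counts[stage]["in"] == counts[stage]["out"] + counts[stage]["rejected"]
        _write(site_rejects, "sites_rejected.tsv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- site normalization + correction ------------------------------------
    stage = "site_normalize"
    try:
        site_mat = site_filtered
        if config.quantile_normalize_sites:
            site_mat = np.power(2.0, pq.quantile_normalize(np.log2(site_mat)))
        site_relative, _ = pq.center_scale(site_mat)
        parent_map = site_meta["protein"].to_dict()
        correction = pq.protein_correct(site_relative, protein_relative, parent_map)
        counts[stage] = {
            "in": len(site_relative),
            "out": len(correction.corrected),
            "rejected": int((correction.status == "parent-missing").sum())}
        _write(site_relative, "site_relative.tsv")
        _write(correction.corrected, "site_corrected.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- site differential ---------------------------------------------------
    stage = "site_differential"
    try:
        site_diff, site_untest = diff.differential_analysis(
            correction.corrected, design, alpha=config.alpha,
            fc_threshold=config.fc_threshold)
        counts[stage] = {"tested": len(site_diff), "untestable": len(site_untest)}
        _write(site_diff, "site_differential.tsv")
        _write(site_untest, "site_presence_absence.tsv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    up_sites = site_diff.index[site_diff["class"] == diff.CLASS_UP].tolist() if len(site_diff) else []
    down_sites = site_diff.index[site_diff["class"] == diff.CLASS_DOWN].tolist() if len(site_diff) else []

    # -- landscape ------------------------------------------------------------
    stage = "landscape"
    try:
        density = land.site_density(zip(site_meta["protein"], site_meta["position"]))
        compartments = {
            "all": land.summarize_compartments(site_meta["protein"], annotation, "all"),
            "up": land.summarize_compartments(site_meta.loc[up_sites, "protein"],
                                              annotation, "up"),
            "down": land.summarize_compartments(site_meta.loc[down_sites, "protein"],
                                                annotation, "down"),
        }
        landscape_payload = {
            "site_density": dataclasses.asdict(density),
            "compartments": {k: dataclasses.asdict(v) for k, v in compartments.items()},
        }
        (outdir / "landscape.json").write_text(json.dumps(landscape_payload, indent=1))
        written.append("landscape.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- motif ----------------------------------------------------------------
    stage = "motif"
    try:
        background = site_meta["window"].tolist()
        foreground = site_meta.loc[up_sites, "window"].tolist()
        if foreground:
            motif_enrichment = mot.two_sample_position_test(foreground, background)
            motif_patterns = mot.motif_x_iterative(foreground, background)
        else:
            motif_enrichment = pd.DataFrame()
            motif_patterns = []
        counts[stage] = {"foreground": len(foreground), "background": len(background),
                         "significant": len(motif_enrichment)}
        _write(motif_enrichment, "motif_enrichment.tsv", index=False)
        (outdir / "motif_patterns.json").write_text(json.dumps(
            [dataclasses.asdict(p) for p in motif_patterns], indent=1, default=str))
        written.append("motif_patterns.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- enrichment -----------------------------------------------------------
    stage = "enrichment"
    try:
        if gene_sets is None:
            if gene_set_path is None:
                raise FileNotFoundError("no gene-set file configured")
            gene_sets = fio.read_gmt(gene_set_path)
        universe = set(site_meta["protein"])
        fg_proteins = set(site_meta.loc[up_sites, "protein"])  # dedup: protein counts once
        enrichment_table = enr.ora(fg_proteins, universe, gene_sets,
                                   alpha_adjusted=config.alpha)
        counts[stage] = {"foreground_proteins": len(fg_proteins),
                         "universe": len(universe), "terms_tested": len(enrichment_table)}
        _write(enrichment_table, "enrichment.tsv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- structure ------------------------------------------------------------
    stage = "structure"
    try:
        structure_reports: dict[str, list[sc.LysineStructReport]] = {}
        prioritized: dict[str, list[sc.LysineStructReport]] = {}
        rows = []
        for acc, geometry in structures.items():
            profile = None
            if acc in alignments:
                profile = sc.conservation_scores(alignments[acc], "REF")
            reports = sc.build_lysine_reports(geometry, profile,
                                              cutoff=config.distance_cutoff)
            structure_reports[acc] = reports
            prioritized[acc] = sc.prioritize(reports,
                                             conservation_min=config.conservation_min)
            for rep in reports:
                rows.append({"protein": acc, **dataclasses.asdict(rep)})
        _write(pd.DataFrame(rows), "structure_reports.tsv", index=False)
        counts[stage] = {"structures": len(structure_reports),
                         "prioritized": sum(len(v) for v in prioritized.values())}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- QC -------------------------------------------------------------------
    stage = "qc"
    try:
        pca_prot, evr_prot = pca_coordinates(proteome_log2_qn)
        corr_prot = pearson_correlation(proteome_log2_qn)
        corr_site = pearson_correlation(np.log2(correction.corrected))
        qc = {"pca_proteome": pca_prot, "pca_explained_variance": evr_prot,
              "pearson_proteome": corr_prot, "pearson_site_corrected": corr_site}
        _write(pca_prot, "qc_pca_proteome.tsv")
        _write(corr_prot, "qc_pearson_proteome.tsv")
        _write(corr_site, "qc_pearson_site_corrected.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- manifest -------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": _config_as_json(config),
        "stage_counts": counts,
        "outputs": written,
        "n_up_sites": len(up_sites),
        "n_down_sites": len(down_sites),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        outdir=outdir, proteome_log2_qn=proteome_log2_qn,
        protein_relative=protein_relative, protein_differential=prot_diff,
        site_meta=site_meta, site_relative=site_relative,
        site_corrected=correction.corrected, site_differential=site_diff,
        site_untestable=site_untest, correction_status=correction.status,
        density=density, compartments=compartments,
        motif_enrichment=motif_enrichment, motif_patterns=motif_patterns,
        enrichment=enrichment_table, structure_reports=structure_reports,
        prioritized=prioritized, qc=qc, manifest=manifest, truth=truth)


def _config_as_json(config: PipelineConfig) -> dict[str, Any]:
    raw = dataclasses.asdict(config)
    sim = raw.get("simulate")
    if sim is not None:
        sim["motif_spec"] = {str(k): list(v) for k, v in sim["motif_spec"].items()}
    return raw


def _load_structures(directory: Path) -> tuple[dict[str, fio.ResidueGeometry],
                                               dict[str, dict[str, str]]]:
    structures: dict[str, fio.ResidueGeometry] = {}
    alignments: dict[str, dict[str, str]] = {}
    for pdb_path in sorted(directory.glob("*.pdb")):
        acc = pdb_path.stem
        geometry = fio.read_pdb(pdb_path)
        label_path = directory / f"{acc}.labels.tsv"
        if label_path.exists():
            labels = fio.read_structure_labels(label_path)
            geometry.kbhb_lysines = labels["kbhb"]
            geometry.functional_residues = labels["functional"]
            geometry.ptm_residues = labels["ptm"]
            geometry.__post_init__()  # re-validate labels against the structure
        aln_path = directory / f"{acc}.aln.fasta"
        if aln_path.exists():
            alignments[acc] = fio.read_fasta(aln_path)
        structures[acc] = geometry
    return structures, alignments
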