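"""Filtering and the two-layer normalization.

The proteome LFQ matrix is log2-transformed and quantile-normalized across
samples.  The site table is center-scaled on the linear scale (each
feature divided by its mean over valid samples) and then divided,
sample-wise, by the parent protein's relative quantification value — the
stoichiometry correction that separates modification-level changes from
protein-expression changes.  Missing values are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .formats_io import SampleDesign

logger = logging.getLogger(__name__)

REASON_VALIDITY = "validity"
REASON_LOCALIZATION = "localization"
REASON_LENGTH = "length"


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    """Sample names disagree between the site and protein tables."""


def filter_features(intensities: pd.DataFrame, design: SampleDesign,
                    min_valid: int = 3,
                    site_meta: pd.DataFrame | None = None,
                    loc_prob_min: float = 0.90,
                    min_peptide_len: int = 7
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-validity (and, for sites, localization/length) filtering.

    A feature is retained when it has at least ``min_valid`` valid
    intensities within at least one experimental group.  When ``site_meta``
    is given (columns ``localization_prob`` and optionally
    ``peptide_length``, indexed like ``intensities``), rows below the
    localization-probability cut or shorter than ``min_peptide_len`` are
    dropped first.  Returns the retained matrix plus a rejection log with
    one row per dropped feature stating the failed rule.
    """
    for group in design.group_names:
        size = len(design.samples_in(group))
        if min_valid > size:
            raise ConfigurationError(
                f"min_valid={min_valid} exceeds size of group {group!r} ({size})")

    rejected: list[tuple[str, str]] = []
    keep_mask = pd.Series(True, index=intensities.index)

    if site_meta is not None:
        loc = site_meta.loc[intensities.index, "localization_prob"]
        bad_loc = loc < loc_prob_min
        for fid in intensities.index[bad_loc]:
            rejected.append((fid, REASON_LOCALIZATION))
        keep_mask &= ~bad_loc
        if "peptide_length" in site_meta.columns:
            peplen = site_meta.loc[intensities.index, "peptide_length"]
            bad_len = peplen.notna() & (peplen < min_peptide_len) & keep_mask
            for fid in intensities.index[bad_len]:
                rejected.append((fid, REASON_LENGTH))
            keep_mask &= ~bad_len

    group_cols = {g: design.samples_in(g) for g in design.group_names}
    valid_counts = pd.DataFrame(
        {g: intensities[cols].notna().sum(axis=1) for g, cols in group_cols.items()})
    passes_validity = (valid_counts >= min_valid).any(axis=1)
    bad_validity = ~passes_validity & keep_mask
    for fid in intensities.index[bad_validity]:
        rejected.append((fid, REASON_VALIDITY))
    keep_mask &= passes_validity

    log = pd.DataFrame(rejected, columns=["feature", "reason"])
    return intensities.loc[keep_mask], log


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across columns of a (log2-scale) matrix.

    Each column's sorted non-missing values are mapped onto the
    cross-column mean of sorted values; ranks within a column are
    preserved and tied values receive the mean of the reference values at
    their tied ranks.  Columns with differing numbers of valid values are
    matched through linear interpolation on the quantile scale.  Missing
    entries stay missing.
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one column")
    n_rows = matrix.shape[0]
    if n_rows == 0:
        return matrix.copy()
    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])

    col_sorted: dict[str, np.ndarray] = {}
    interpolated = np.empty((n_rows, matrix.shape[1]))
    for j, col in enumerate(matrix.columns):
        v = matrix[col].dropna().to_numpy()
        if v.size == 0:
            raise ValueError(f"column {col!r} has no valid values")
        v = np.sort(v)
        col_sorted[col] = v
        pos = np.linspace(0.0, 1.0, v.size) if v.size > 1 else np.array([0.5])
        interpolated[:, j] = np.interp(grid, pos, v)
    reference = interpolated.mean(axis=1)

    out = matrix.copy()
    for col in matrix.columns:
        valid = matrix[col].notna().to_numpy()
        values = matrix[col].to_numpy()[valid]
        m = values.size
        ranks = rankdata(values, method="average")  # 1..m, ties averaged
        pos = (ranks - 1.0) / (m - 1.0) if m > 1 else np.full(m, 0.5)
        mapped = np.interp(pos, grid, reference)
        new_col = np.full(n_rows, np.nan)
        new_col[valid] = mapped
        out[col] = new_col
    return out


def center_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Relative quantification: divide each feature by its mean over valid samples.

    Input must be on the linear intensity scale and positive where valid.
    Rows with no valid value are dropped (and returned in the log); every
    retained row has mean 1 over its valid entries.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] <= 0):
        raise ValueError("center_scale expects positive linear-scale intensities")
    finite = np.isfinite(values)
    counts = finite.sum(axis=1)
    row_means = np.where(counts > 0, np.where(finite, values, 0.0).sum(axis=1)
                         / np.maximum(counts, 1), np.nan)
    all_missing = counts == 0
    dropped = matrix.index[all_missing].tolist()
    if dropped:
        logger.info("center_scale: dropped %d all-missing row(s)", len(dropped))
    kept = matrix.loc[~all_missing]
    rel = kept.div(pd.Series(row_means[~all_missing], index=kept.index), axis=0)
    return rel, dropped


@dataclass
class CorrectionResult:
    """Stoichiometry-corrected site matrix plus per-site correction status."""

    corrected: pd.DataFrame            # site x sample, only sites with a quantified parent
    status: pd.Series                  # site -> "corrected" | "parent-missing"
    parent_map: dict[str, str]


def protein_correct(site_rel: pd.DataFrame, protein_rel: pd.DataFrame,
                    parent_map: dict[str, str]) -> CorrectionResult:
    """Divide each site's relative values by its parent protein's, sample-wise.

    Sites whose parent is absent from the protein table are flagged
    ``parent-missing`` and excluded from the corrected matrix.  The two
    matrices must carry the same sample set.
    """
    if set(site_rel.columns) != set(protein_rel.columns):
        raise AlignmentError(
            f"sample names differ between site table ({list(site_rel.columns)}) "
            f"and protein table ({list(protein_rel.columns)})")
    protein_rel = protein_rel[site_rel.columns]

    missing = {fid for fid in site_rel.index if parent_map[fid] not in protein_rel.index}
    if missing:
        logger.info("protein_correct: %d site(s) with unquantified parent excluded",
                    len(missing))
    kept = [fid for fid in site_rel.index if fid not in missing]
    parents = [parent_map[fid] for fid in kept]
    corrected = pd.DataFrame(
        site_rel.loc[kept].to_numpy() / protein_rel.loc[parents].to_numpy(),
        index=kept, columns=site_rel.columns)
    status = pd.Series(
        ["parent-missing" if fid in missing else "corrected" for fid in site_rel.index],
        index=site_rel.index, name="status")
    return CorrectionResult(corrected=corrected, status=status,
                            parent_map={fid: parent_map[fid] for fid in site_rel.index})
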