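"""Spatial and evolutionary prioritization of modified lysines.

Modified lysines are mapped onto a structure, their minimal heavy-atom
distances to annotated functional (catalytic/cofactor-binding) and
known-PTM residues computed, and each lysine placed in one of four
categories by whether it coincides with a known PTM residue and whether it
lies within 5 Angstrom of a functional residue.  Conservation is scored
per alignment column as 1 - normalized Shannon entropy (an exactly
testable monotone stand-in for ML rate estimation; columns over half gaps
are left unscored), and sites are prioritized when they are both highly
conserved and spatially implicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .formats_io import AA_ALPHABET, ResidueGeometry

DISTANCE_CUTOFF = 5.0       # Angstrom, "near a functional site"
CONSERVATION_MIN = 0.85

CAT_OVERLAP_NEAR = "overlap+near"   # orange: known-PTM residue within 5 A of a functional site
CAT_OVERLAP_ONLY = "overlap-only"   # green: known-PTM residue, not near functional sites
CAT_NEAR_ONLY = "near-only"         # red: within 5 A of a functional site only
CAT_NEITHER = "neither"             # yellow
CATEGORIES = (CAT_OVERLAP_NEAR, CAT_OVERLAP_ONLY, CAT_NEAR_ONLY, CAT_NEITHER)


def min_atomic_distance(geometry: ResidueGeometry, resnum: int,
                        residue_set: Iterable[int]) -> float | None:
    """Minimum heavy-atom pair distance from one residue to a residue set.

    Returns ``None`` (distance absent, not zero) for an empty set.
    """
    targets = list(residue_set)
    if not targets:
        return None
    source = geometry.residue(resnum).coords
    best = math.inf
    for other in targets:
        d = cdist(source, geometry.residue(other).coords).min()
        best = min(best, float(d))
    return best


def classify_lysine(overlaps_ptm: bool, min_dist_functional: float | None,
                    cutoff: float = DISTANCE_CUTOFF) -> str:
    """Four-way category from PTM overlap and proximity to functional residues.

    An absent distance (no annotated functional residues) counts as
    "not near".  Total: every input maps to exactly one category.
    """
    near = min_dist_functional is not None and min_dist_functional <= cutoff
    if overlaps_ptm:
        return CAT_OVERLAP_NEAR if near else CAT_OVERLAP_ONLY
    return CAT_NEAR_ONLY if near else CAT_NEITHER


@dataclass
class LysineStructReport:
    resnum: int
    min_dist_functional: float | None
    min_dist_ptm: float | None
    overlaps_ptm: bool
    category: str
    conservation: float | None = None
    priority: bool = False


@dataclass
class ConservationProfile:
    """Per-reference-residue conservation scores in [0, 1] (None = unscored)."""

    scores: dict[int, float | None]   # 1-based reference residue number -> score
    reference_id: str

    def score_at(self, resnum: int) -> float | None:
        return self.scores.get(resnum)


def conservation_scores(msa: Mapping[str, str], reference_id: str,
                        max_gap_frac: float = 0.5) -> ConservationProfile:
    """Column conservation = 1 - Shannon entropy / log(20), on reference numbering.

    Gaps are excluded from the frequency counts; columns with more than
    ``max_gap_frac`` gaps are scored absent.  Invariant columns score 1.0,
    a uniform column over all 20 residues scores 0.0.
    """
    if reference_id not in msa:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    if len(msa) < 3:
        raise ValueError("need at least three aligned sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must share one length")
    ref = msa[reference_id]
    n_seq = len(msa)
    log20 = math.log(len(AA_ALPHABET))

    scores: dict[int, float | None] = {}
    refpos = 0
    for col in range(len(ref)):
        if ref[col] == "-":
            continue
        refpos += 1
        residues = [s[col] for s in msa.values() if s[col] != "-"]
        if len(residues) < n_seq * (1.0 - max_gap_frac):
            scores[refpos] = None
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        total = len(residues)
        entropy = -sum((c / total) * math.log(c / total) for c in counts.values())
        scores[refpos] = 1.0 - entropy / log20
    return ConservationProfile(scores=scores, reference_id=reference_id)


def build_lysine_reports(geometry: ResidueGeometry,
                         conservation: ConservationProfile | None = None,
                         cutoff: float = DISTANCE_CUTOFF) -> list[LysineStructReport]:
    """One report per annotated Kbhb lysine of the structure.

    ``min_dist_ptm`` is the distance to the nearest *other* known-PTM
    residue; whether the lysine itself is a known-PTM residue is the
    separate ``overlaps_ptm`` flag.
    """
    reports = []
    for resnum in sorted(geometry.kbhb_lysines):
        d_func = min_atomic_distance(geometry, resnum, geometry.functional_residues)
        d_ptm = min_atomic_distance(geometry, resnum,
                                    geometry.ptm_residues - {resnum})
        overlaps = resnum in geometry.ptm_residues
        reports.append(LysineStructReport(
            resnum=resnum,
            min_dist_functional=d_func,
            min_dist_ptm=d_ptm,
            overlaps_ptm=overlaps,
            category=classify_lysine(overlaps, d_func, cutoff),
            conservation=None if conservation is None else conservation.score_at(resnum)))
    return reports


def prioritize(reports: Sequence[LysineStructReport],
               conservation_min: float = CONSERVATION_MIN,
               categories: Sequence[str] = (CAT_OVERLAP_NEAR, CAT_NEAR_ONLY)
               ) -> list[LysineStructReport]:
    """Flag and rank high-confidence candidate regulatory lysines.

    Flagged: conservation above ``conservation_min`` AND category among the
    functionally proximal ones.  Ranked by conservation descending, then
    functional distance ascending (absent distances last).
    """
    flagged = []
    for rep in reports:
        rep.priority = (rep.conservation is not None
                        and rep.conservation > conservation_min
                        and rep.category in categories)
        if rep.priority:
            flagged.append(rep)
    flagged.sort(key=lambda r: (-r.conservation,
                                r.min_dist_functional if r.min_dist_functional is not None
                                else math.inf,
                                r.resnum))
    return flagged
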