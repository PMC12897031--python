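"""Atlas summaries: sites-per-protein density and subcellular breakdowns."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DENSITY_BINS = ("1", "2", "3", "4", "5", ">5")
COMPARTMENTS = ("nucleus", "cytoplasm", "mitochondria", "other")

#: tie-break for multi-annotated proteins: most specific organelle first
DEFAULT_PRIORITY = ("mitochondria", "nucleus", "cytoplasm", "other")


@dataclass
class SiteDensitySummary:
    counts: dict[str, int]        # bin -> number of proteins
    percentages: dict[str, float]  # bin -> percent of modified proteins (2 dp)
    n_proteins: int


@dataclass
class CompartmentSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    scope: str
    n_features: int


def site_density(sites: Iterable[tuple[str, int]]) -> SiteDensitySummary:
    """Bin proteins by their number of distinct modified positions.

    Duplicate (protein, position) pairs are deduplicated with a warning.
    Percentages are over distinct modified proteins, reported to 2 decimals.
    """
    seen: set[tuple[str, int]] = set()
    per_protein: dict[str, int] = {}
    duplicates = 0
    for protein, position in sites:
        key = (protein, int(position))
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        per_protein[protein] = per_protein.get(protein, 0) + 1
    if duplicates:
        logger.warning("site_density: deduplicated %d repeated (protein, position) pair(s)",
                       duplicates)
    counts = {b: 0 for b in DENSITY_BINS}
    for n in per_protein.values():
        counts[str(n) if n <= 5 else ">5"] += 1
    total = len(per_protein)
    percentages = {b: (round(100.0 * c / total, 2) if total else 0.0)
                   for b, c in counts.items()}
    return SiteDensitySummary(counts=counts, percentages=percentages, n_proteins=total)


def assign_compartment(protein: str, annotation: Mapping[str, Sequence[str]],
                       priority: Sequence[str] = DEFAULT_PRIORITY) -> str:
    """Resolve a protein to one compartment by the stated priority.

    Labels outside the four canonical compartments, and unannotated
    proteins, resolve to ``other``.
    """
    labels = {c if c in COMPARTMENTS else "other" for c in annotation.get(protein, ())}
    for comp in priority:
        if comp in labels:
            return comp
    return "other"


def summarize_compartments(parents: Iterable[str],
                           annotation: Mapping[str, Sequence[str]],
                           scope: str = "all",
                           priority: Sequence[str] = DEFAULT_PRIORITY
                           ) -> CompartmentSummary:
    """Compartment counts/percentages over a scoped set of sites.

    ``parents`` holds one parent accession per site in the scope (a protein
    with several sites in scope is counted once per site, matching the
    site-level breakdowns of the differential analysis).
    """
    if scope not in ("all", "up", "down"):
        raise ValueError(f"scope must be all/up/down, got {scope!r}")
    counts = {c: 0 for c in COMPARTMENTS}
    n = 0
    for acc in parents:
        counts[assign_compartment(acc, annotation, priority)] += 1
        n += 1
    if n == 0:
        logger.warning("summarize_compartments: empty %r scope", scope)
    percentages = {c: (round(100.0 * v / n, 2) if n else 0.0) for c, v in counts.items()}
    return CompartmentSummary(counts=counts, percentages=percentages, scope=scope,
                              n_features=n)
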