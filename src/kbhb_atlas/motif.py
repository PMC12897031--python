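"""Sequence-motif statistics on ±7-residue windows around modified lysines.

Two complementary analyses: a per-(offset, residue) two-sample comparison
(foreground vs background windows, two-sided Fisher exact test — the exact
counterpart of a TwoSampleLogo display) and the classic greedy motif-x
iteration that extracts whole position-specific patterns with binomial
tail statistics.  Terminal ``_`` padding never counts as a residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import AA_ALPHABET, PAD, WINDOW_CENTER, WINDOW_WIDTH, validate_window

logger = logging.getLogger(__name__)

FLANK = 7
OFFSETS = tuple(o for o in range(-FLANK, FLANK + 1) if o != 0)


def extract_window(sequence: str, position: int, flank: int = FLANK) -> str:
    """±flank residues around a 1-based K position, ``_``-padded at termini."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "K":
        raise ValueError(f"residue at position {position} is "
                         f"{sequence[position - 1]!r}, not K")
    left = sequence[max(0, position - 1 - flank):position - 1]
    right = sequence[position:position + flank]
    return PAD * (flank - len(left)) + left + "K" + right + PAD * (flank - len(right))


def _column_counts(windows: Sequence[str], offset: int) -> tuple[dict[str, int], int]:
    """Residue counts at an offset, excluding padding; returns (counts, non-pad n)."""
    idx = WINDOW_CENTER + offset
    counts: dict[str, int] = {}
    n = 0
    for w in windows:
        ch = w[idx]
        if ch == PAD:
            continue
        counts[ch] = counts.get(ch, 0) + 1
        n += 1
    return counts, n


def two_sample_position_test(foreground: Sequence[str], background: Sequence[str],
                             alpha: float = 0.05,
                             return_all: bool = False) -> pd.DataFrame:
    """Two-sided Fisher exact test per (offset, residue).

    For every flanking offset and residue observed in either set, the 2x2
    table of presence at that offset in foreground vs background is
    tested.  Entries with p < ``alpha`` are returned (all tested entries
    with ``return_all=True``), sorted by p, with direction enriched or
    depleted by foreground vs background frequency.
    """
    for w in list(foreground) + list(background):
        validate_window(w)
    if not background:
        raise ValueError("background must be nonempty")
    if not foreground:
        logger.warning("two_sample_position_test: empty foreground")
        return pd.DataFrame(columns=["offset", "residue", "fg_count", "fg_n", "fg_freq",
                                     "bg_count", "bg_n", "bg_freq", "p_value", "direction"])
    rows = []
    for offset in OFFSETS:
        fg_counts, fg_n = _column_counts(foreground, offset)
        bg_counts, bg_n = _column_counts(background, offset)
        if fg_n == 0 or bg_n == 0:
            continue
        for residue in sorted(set(fg_counts) | set(bg_counts)):
            a = fg_counts.get(residue, 0)
            b = bg_counts.get(residue, 0)
            table = [[a, fg_n - a], [b, bg_n - b]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            fg_freq = a / fg_n
            bg_freq = b / bg_n
            rows.append({"offset": offset, "residue": residue,
                         "fg_count": a, "fg_n": fg_n, "fg_freq": fg_freq,
                         "bg_count": b, "bg_n": bg_n, "bg_freq": bg_freq,
                         "p_value": p,
                         "direction": "enriched" if fg_freq >= bg_freq else "depleted"})
    out = pd.DataFrame(rows).sort_values(["p_value", "offset", "residue"],
                                         kind="stable").reset_index(drop=True)
    if not return_all:
        out = out[out["p_value"] < alpha].reset_index(drop=True)
    return out


@dataclass
class MotifStep:
    offset: int
    residue: str
    fg_matches: int
    fg_total: int
    bg_freq: float
    binomial_p: float


@dataclass
class MotifPattern:
    """One extracted motif, e.g. ``.......KD......`` for D at +1."""

    pattern: str
    fixed: dict[int, str]
    steps: list[MotifStep] = field(default_factory=list)
    n_foreground_matches: int = 0

    def matches(self, window: str) -> bool:
        return all(window[WINDOW_CENTER + off] == res for off, res in self.fixed.items())


def _pattern_string(fixed: dict[int, str]) -> str:
    chars = ["."] * WINDOW_WIDTH
    chars[WINDOW_CENTER] = "K"
    for off, res in fixed.items():
        chars[WINDOW_CENTER + off] = res
    return "".join(chars)


def binomial_tail(k: int, n: int, p: float) -> float:
    """P[X >= k] for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))


def motif_x_iterative(foreground: Sequence[str], background: Sequence[str],
                      min_occurrences: int = 20,
                      binomial_p: float = 1e-6) -> list[MotifPattern]:
    """Greedy motif-x extraction.

    Repeatedly fix the (offset, residue) with the smallest binomial tail
    probability (foreground count vs current background frequency) that
    clears both the occurrence floor and the p threshold, restricting both
    sets to matching windows; when no further position qualifies, the
    accumulated pattern is emitted, its foreground matches removed, and
    the search restarts on the remainder.
    """
    for w in list(foreground) + list(background):
        validate_window(w)
    working_fg = list(foreground)
    working_bg = list(background)
    patterns: list[MotifPattern] = []

    while True:
        cur_fg = list(working_fg)
        cur_bg = list(working_bg)
        fixed: dict[int, str] = {}
        steps: list[MotifStep] = []
        while True:
            best: tuple[float, int, str, int, int, float] | None = None
            for offset in OFFSETS:
                if offset in fixed:
                    continue
                fg_counts, fg_n = _column_counts(cur_fg, offset)
                bg_counts, bg_n = _column_counts(cur_bg, offset)
                if fg_n == 0 or bg_n == 0:
                    continue
                for residue, k in fg_counts.items():
                    if k < min_occurrences:
                        continue
                    p0 = bg_counts.get(residue, 0) / bg_n
                    p_tail = binomial_tail(k, fg_n, p0)
                    if p_tail >= binomial_p:
                        continue
                    cand = (p_tail, offset, residue, k, fg_n, p0)
                    if best is None or cand[:3] < best[:3]:
                        best = cand
            if best is None:
                break
            p_tail, offset, residue, k, fg_n, p0 = best
            fixed[offset] = residue
            steps.append(MotifStep(offset, residue, k, fg_n, p0, p_tail))
            idx = WINDOW_CENTER + offset
            cur_fg = [w for w in cur_fg if w[idx] == residue]
            cur_bg = [w for w in cur_bg if w[idx] == residue]
        if not fixed:
            break
        pattern = MotifPattern(_pattern_string(fixed), fixed, steps, len(cur_fg))
        patterns.append(pattern)
        working_fg = [w for w in working_fg if not pattern.matches(w)]
        working_bg = [w for w in working_bg if not pattern.matches(w)]
        if not working_fg:
            break
    return patterns
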