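"""Minimal atomic distances vs brute force, the four-way lysine
classification, entropy-based conservation, and prioritization."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kbhb_atlas import structure_conservation as sc
from kbhb_atlas import synthetic_data as synth


def _geometry(*residues):
    spec = [(name, num, [(f"X{i}", tuple(xyz)) for i, xyz in enumerate(coords)])
            for name, num, coords in residues]
    geometry, _ = synth.generate_toy_structure(spec)
    return geometry


class TestMinAtomicDistance:
    def test_single_atom_pair(self):
        g = _geometry(("GLY", 1, [(0, 0, 0)]), ("LYS", 2, [(3, 4, 0)]))
        assert sc.min_atomic_distance(g, 2, [1]) == pytest.approx(5.0)

    def test_residue_vs_itself_zero(self):
        g = _geometry(("LYS", 2, [(3, 4, 0)]))
        assert sc.min_atomic_distance(g, 2, [2]) == 0.0

    def test_minimum_over_set(self):
        g = _geometry(("LYS", 1, [(0, 0, 0)]),
                      ("GLU", 2, [(7.1, 0, 0)]),
                      ("ASP", 3, [(0, 4.2, 0)]))
        assert sc.min_atomic_distance(g, 1, [2, 3]) == pytest.approx(4.2)

    def test_empty_set_is_absent_not_zero(self):
        g = _geometry(("LYS", 1, [(0, 0, 0)]))
        assert sc.min_atomic_distance(g, 1, []) is None

    def test_symmetric_and_matches_brute_force(self, small_dataset):
        for geometry in small_dataset.structures.values():
            nums = geometry.resnums
            for a in nums:
                for b in nums:
                    d_ab = sc.min_atomic_distance(geometry, a, [b])
                    d_ba = sc.min_atomic_distance(geometry, b, [a])
                    brute = min(
                        math.dist(p, q)
                        for p in geometry.residue(a).coords
                        for q in geometry.residue(b).coords)
                    assert d_ab == pytest.approx(d_ba, rel=1e-12)
                    assert d_ab == pytest.approx(brute, rel=1e-12)

    def test_planted_distances_recovered(self, small_dataset):
        truth = small_dataset.truth
        for acc, ledger in truth.structure_distances.items():
            geometry = small_dataset.structures[acc]
            functional = geometry.functional_residues
            for resnum_str, planted in ledger.items():
                d = sc.min_atomic_distance(geometry, int(resnum_str), functional)
                assert d == pytest.approx(planted, abs=1e-9)


class TestClassifyLysine:
    @pytest.mark.parametrize("overlaps, dist, expected", [
        (True, 4.2, "overlap+near"),
        (True, 7.0, "overlap-only"),
        (False, 3.0, "near-only"),
        (False, 12.0, "neither"),
        (True, 5.0, "overlap+near"),   # boundary: within 5 A inclusive
        (False, None, "neither"),
        (True, None, "overlap-only"),
    ])
    def test_legend_rules(self, overlaps, dist, expected):
        assert sc.classify_lysine(overlaps, dist) == expected

    @given(st.booleans(),
           st.one_of(st.none(), st.floats(min_value=0, max_value=100,
                                          allow_nan=False)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_function(self, overlaps, dist):
        assert sc.classify_lysine(overlaps, dist) in sc.CATEGORIES

    def test_all_four_categories_on_generated_toys(self, small_dataset):
        seen = set()
        for geometry in small_dataset.structures.values():
            for rep in sc.build_lysine_reports(geometry):
                seen.add(rep.category)
        assert seen == set(sc.CATEGORIES)


class TestConservation:
    def _msa(self, *seqs):
        return {f"S{i}": s for i, s in enumerate(seqs)}

    def test_invariant_column_scores_one(self):
        msa = self._msa(*["K"] * 10)
        profile = sc.conservation_scores(msa, "S0")
        assert profile.score_at(1) == pytest.approx(1.0)

    def test_uniform_twenty_residue_column_scores_zero(self):
        from kbhb_atlas.formats_io import AA_ALPHABET
        msa = self._msa(*list(AA_ALPHABET))
        profile = sc.conservation_scores(msa, "S0")
        assert profile.score_at(1) == pytest.approx(0.0, abs=1e-12)

    def test_half_half_column_value(self):
        msa = self._msa(*(["K"] * 5 + ["R"] * 5))
        profile = sc.conservation_scores(msa, "S0")
        assert profile.score_at(1) == pytest.approx(1 - math.log(2) / math.log(20),
                                                    rel=1e-12)

    def test_identical_sequences_fully_conserved(self):
        msa = self._msa(*["KARL"] * 4)
        profile = sc.conservation_scores(msa, "S0")
        assert all(profile.score_at(i) == pytest.approx(1.0) for i in range(1, 5))

    def test_gappy_column_unscored(self):
        msa = self._msa("KA", "K-", "K-", "K-")
        profile = sc.conservation_scores(msa, "S0")
        assert profile.score_at(1) == pytest.approx(1.0)
        assert profile.score_at(2) is None

    def test_reference_gaps_skipped_in_numbering(self):
        msa = self._msa("K-A", "KCA", "KCA")
        profile = sc.conservation_scores(msa, "S0")
        assert set(profile.scores) == {1, 2}  # reference has two residues

    def test_errors(self):
        with pytest.raises(ValueError, match="reference"):
            sc.conservation_scores(self._msa("KA", "KA", "KA"), "nope")
        with pytest.raises(ValueError, match="three"):
            sc.conservation_scores(self._msa("KA", "KA"), "S0")
        with pytest.raises(ValueError, match="length"):
            sc.conservation_scores(self._msa("KA", "KAA", "KA"), "S0")


class TestPrioritize:
    def _report(self, resnum, category, conservation, dist=4.0):
        return sc.LysineStructReport(resnum=resnum, min_dist_functional=dist,
                                     min_dist_ptm=None, overlaps_ptm=False,
                                     category=category, conservation=conservation)

    def test_flagging_rules(self):
        reports = [
            self._report(1, "near-only", 0.9),
            self._report(2, "near-only", 0.5),
            self._report(3, "neither", 0.99),
            self._report(4, "overlap+near", 0.95),
            self._report(5, "near-only", None),
        ]
        flagged = sc.prioritize(reports)
        assert [r.resnum for r in flagged] == [4, 1]
        assert reports[1].priority is False and reports[2].priority is False

    def test_tie_broken_by_distance(self):
        a = self._report(1, "near-only", 0.9, dist=4.0)
        b = self._report(2, "near-only", 0.9, dist=3.0)
        assert [r.resnum for r in sc.prioritize([a, b])] == [2, 1]

    def test_threshold_strict(self):
        exactly = self._report(1, "near-only", 0.85)
        assert sc.prioritize([exactly]) == []


def test_adss1_like_fixture_distance():
    """The synthetic ADSS1-like stand-in places K448 exactly 14 A from the
    nearest pocket atom."""
    g = synth.adss1_like_structure()
    d = sc.min_atomic_distance(g, 448, g.functional_residues)
    assert d == pytest.approx(14.0, abs=1e-9)
    assert sc.classify_lysine(448 in g.ptm_residues, d) == "neither"


def test_conserved_planted_lysines_prioritized(small_dataset):
    """Generated alignments keep modified-lysine columns invariant, so
    spatially implicated lysines clear the 0.85 conservation bar."""
    flagged_any = False
    for acc, geometry in small_dataset.structures.items():
        profile = sc.conservation_scores(small_dataset.alignments[acc], "REF")
        reports = sc.build_lysine_reports(geometry, profile)
        for rep in reports:
            if rep.category in ("overlap+near", "near-only"):
                assert rep.conservation == pytest.approx(1.0)
        flagged_any |= bool(sc.prioritize(reports))
    assert flagged_any
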