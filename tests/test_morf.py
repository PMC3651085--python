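"""Meta-ORF grouping: the 10%-of-shorter-ORF rule, transitive closure,
multi-call flagging and the optional anchored/containment modes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import morfpath as mp
from morfpath import Orf, PredictionSet, REFERENCE_SOURCE

from conftest import oracle_components, random_orfs


def _orf(left, right, strand="+", contig="chr1", source="x"):
    return Orf(contig, left, right, strand, source=source)


class TestPairCompatible:
    def test_matching_stops_group(self):
        # margin = 0.10 * 271 = 27.1; stop difference 0
        assert mp.pair_compatible(_orf(100, 400), _orf(130, 400))

    def test_small_overlap_beyond_margin_does_not_group(self):
        # min length 301, margin 30.1; start diff 290, stop diff 300
        assert not mp.pair_compatible(_orf(100, 400), _orf(390, 700))

    def test_opposite_strands_never_group(self):
        assert not mp.pair_compatible(_orf(100, 400, "+"),
                                      _orf(100, 400, "-"))

    def test_different_contigs_never_group(self):
        assert not mp.pair_compatible(_orf(100, 400, contig="c1"),
                                      _orf(100, 400, contig="c2"))

    def test_strict_inequality_at_margin(self):
        # both lengths 300 -> margin exactly 30.0; diff of 30 must fail
        assert not mp.pair_compatible(_orf(100, 399), _orf(130, 429))
        assert mp.pair_compatible(_orf(100, 399), _orf(129, 428))

    def test_pure_containment_needs_flag(self):
        outer, inner = _orf(100, 1300), _orf(600, 750)
        assert not mp.pair_compatible(outer, inner)
        assert mp.pair_compatible(outer, inner, containment=True)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry(self, data):
        left_a = data.draw(st.integers(1, 3000))
        left_b = data.draw(st.integers(1, 3000))
        len_a = data.draw(st.integers(20, 400)) * 3
        len_b = data.draw(st.integers(20, 400)) * 3
        strand = data.draw(st.sampled_from("+-"))
        a = _orf(left_a, left_a + len_a - 1, strand)
        b = _orf(left_b, left_b + len_b - 1, strand)
        assert mp.pair_compatible(a, b) == mp.pair_compatible(b, a)


class TestAssignMorfs:
    def test_three_sources_one_morf(self):
        sets = [PredictionSet("X", [_orf(100, 400, source="X")]),
                PredictionSet("Y", [_orf(130, 400, source="Y")])]
        ref = PredictionSet(REFERENCE_SOURCE,
                            [_orf(100, 400, source=REFERENCE_SOURCE)])
        morfs = mp.assign_morfs(sets, ref)
        assert len(morfs) == 1
        assert len(morfs[0].members) == 3
        assert morfs[0].reference_member is not None

    def test_incompatible_pair_two_morfs(self):
        sets = [PredictionSet("X", [_orf(100, 400, source="X")]),
                PredictionSet("Y", [_orf(390, 700, source="Y")])]
        assert len(mp.assign_morfs(sets)) == 2

    def test_chain_is_transitively_closed(self):
        """X-Y and Y-Z compatible via starts, X-Z via stops: one mORF."""
        sets = [PredictionSet("X", [_orf(100, 400, source="X")]),
                PredictionSet("Y", [_orf(115, 400, source="Y")]),
                PredictionSet("Z", [_orf(130, 400, source="Z")])]
        morfs = mp.assign_morfs(sets)
        assert len(morfs) == 1
        assert {frozenset(m.source for m in c.members) for c in morfs} == \
               {frozenset({"X", "Y", "Z"})}

    def test_partition_covers_all_orfs(self):
        rng = np.random.default_rng(7)
        orfs = random_orfs(rng, 40)
        morfs = mp.assign_morfs([PredictionSet("x", orfs)])
        recovered = sorted(o.coords_key for m in morfs for o in m.members)
        assert recovered == sorted(o.coords_key
                                   for o in PredictionSet("x", orfs))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        orfs = random_orfs(rng, int(rng.integers(5, 50)))
        pset = PredictionSet("x", orfs)  # dedupes
        morfs = mp.assign_morfs([pset])
        got = {frozenset(o.coords_key for o in m.members) for m in morfs}
        expected_idx = oracle_components(pset.orfs)
        expected = {frozenset(pset.orfs[i].coords_key for i in comp)
                    for comp in expected_idx}
        assert got == expected

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        orfs = random_orfs(rng, 30)
        base = mp.assign_morfs([PredictionSet("x", orfs)])
        shifted_orfs = [Orf(o.contig, o.leftmost + 10000,
                            o.rightmost + 10000, o.strand, o.source)
                        for o in orfs]
        shifted = mp.assign_morfs([PredictionSet("x", shifted_orfs)])
        norm = lambda morfs, delta: sorted(
            sorted((o.leftmost - delta, o.rightmost - delta, o.strand)
                   for o in m.members) for m in morfs)
        assert norm(base, 0) == norm(shifted, 10000)

    def test_deterministic_ids_ordered_by_position(self):
        sets = [PredictionSet("X", [_orf(5000, 5300, source="X"),
                                    _orf(100, 400, source="X")])]
        morfs = mp.assign_morfs(sets)
        assert [m.morf_id for m in morfs] == ["mORF_00001", "mORF_00002"]
        assert morfs[0].members[0].leftmost == 100

    def test_multicall_flag_and_resolution(self):
        """Two same-source ORFs in one mORF: kept, flagged, and the start
        closest to the reference is the scored member."""
        ref = PredictionSet(REFERENCE_SOURCE,
                            [_orf(100, 400, source=REFERENCE_SOURCE)])
        sets = [PredictionSet("X", [_orf(100, 400, source="X"),
                                    _orf(112, 400, source="X")])]
        morfs = mp.assign_morfs(sets, ref)
        assert len(morfs) == 1
        assert morfs[0].multi_call
        assert morfs[0].member("X").start_coord == 100

    def test_anchor_reference_mode(self):
        """Anchored grouping keeps two nearby reference ORFs in separate
        mORFs where single-linkage closure would merge them."""
        ref = PredictionSet(REFERENCE_SOURCE, [
            _orf(100, 700, source=REFERENCE_SOURCE),
            _orf(130, 730, source=REFERENCE_SOURCE)])
        sets = [PredictionSet("X", [_orf(100, 700, source="X")]),
                PredictionSet("Y", [_orf(130, 730, source="Y")])]
        assert len(mp.assign_morfs(sets, ref)) == 1  # closure merges
        morfs = mp.assign_morfs(sets, ref, anchor="reference")
        assert len(morfs) == 2
        assert all(m.reference_member is not None for m in morfs)
        with pytest.raises(mp.ConfigurationError):
            mp.assign_morfs(sets, None, anchor="reference")

    def test_containment_mode_groups_nested(self):
        outer = PredictionSet("X", [_orf(100, 1300, source="X")])
        inner = PredictionSet("Y", [_orf(600, 750, source="Y")])
        assert len(mp.assign_morfs([outer, inner])) == 2
        assert len(mp.assign_morfs([outer, inner], containment=True)) == 1
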