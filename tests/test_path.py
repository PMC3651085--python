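"""Greedy consensus-path training, impact ranking, the cross-genome
general path and path application to reference-free genomes."""

from __future__ import annotations

import numpy as np
import pytest

import morfpath as mp
from morfpath import Combination, Orf, PathSpec, PredictionSet, \
    REFERENCE_SOURCE
from morfpath.combine import score_combination, all_combinations
from morfpath.errors import ConfigurationError


def simulated_morfs(seed, n_orfs=120, shared=0.4):
    ref = mp.generate_reference(n_orfs, seed=seed)
    sets = mp.simulate_panel(ref, mp.default_panel_profiles(),
                             mp.CorrelationSpec(shared), seed=seed)
    return mp.assign_morfs(sets, ref), [s.source for s in sets]


class TestImpact:
    def test_identity_point(self):
        assert mp.impact(1.0, 1.0, 1) == 1.0

    def test_zero_specificity_zero_impact(self):
        for sens, rank in [(0.0, 1), (0.5, 2), (1.0, 7)]:
            assert mp.impact(0.0, sens, rank) == 0.0

    def test_strictly_decreasing_in_rank(self):
        assert mp.impact(0.9, 0.5, 2) < mp.impact(0.9, 0.5, 1)

    def test_strictly_increasing_in_spec_and_sens(self):
        assert mp.impact(0.8, 0.5, 3) < mp.impact(0.9, 0.5, 3)
        assert mp.impact(0.8, 0.5, 3) < mp.impact(0.8, 0.6, 3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mp.impact(0.5, 0.5, 0)
        with pytest.raises(ValueError):
            mp.impact(1.5, 0.5, 1)
        with pytest.raises(ValueError):
            mp.impact(0.5, 0.5, 1, form="nope")


class TestRunPath:
    def test_perfect_engine_reaches_specificity_one(self):
        """A is a perfect copy of the reference, B is shifted everywhere:
        round 1 must achieve specificity 1.0 with a combination
        containing A."""
        ref = mp.generate_reference(20, seed=4)
        copy_a = PredictionSet("A", list(ref))
        shifted = [Orf(o.contig,
                       o.leftmost + (3 if o.strand == "+" else 0),
                       o.rightmost + (0 if o.strand == "+" else -3),
                       o.strand, "B")
                   for o in ref]
        set_b = PredictionSet("B", shifted)
        morfs = mp.assign_morfs([copy_a, set_b], ref)
        rounds = mp.run_path(morfs, ["A", "B"])
        assert rounds[0].specificity == 1.0
        assert "A" in rounds[0].combination.engines

    def test_max_rounds_limits_path(self):
        morfs, panel = simulated_morfs(seed=0)
        rounds = mp.run_path(morfs, panel, max_rounds=1)
        assert len(rounds) <= 1

    def test_terminates_when_remaining_empties(self):
        """Two engines in perfect agreement with the reference: round 1
        calls every mORF and the path stops regardless of max_rounds."""
        ref = mp.generate_reference(15, seed=9)
        sets = [PredictionSet(name, list(ref)) for name in ("A", "B")]
        morfs = mp.assign_morfs(sets, ref)
        rounds = mp.run_path(morfs, ["A", "B"], max_rounds=5)
        assert len(rounds) == 1
        assert rounds[0].n_new == len(morfs)

    def test_called_morfs_disjoint_across_rounds(self):
        morfs, panel = simulated_morfs(seed=3)
        rounds = mp.run_path(morfs, panel)
        all_called = [m for r in rounds for m in r.called_morfs]
        assert len(all_called) == len(set(all_called))
        assert sum(r.n_new for r in rounds) == len(set(all_called))

    def test_combination_selected_at_most_once(self):
        morfs, panel = simulated_morfs(seed=5)
        rounds = mp.run_path(morfs, panel)
        keys = [r.combination.key for r in rounds]
        assert len(keys) == len(set(keys))
        assert [r.round_index for r in rounds] == \
            list(range(1, len(rounds) + 1))

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_selection_matches_exhaustive_oracle(self, seed):
        """Each round's winner attains the maximum specificity over an
        independent exhaustive scan (scalar scoring route)."""
        morfs, panel = simulated_morfs(seed=seed, n_orfs=80)
        rounds = mp.run_path(morfs, panel)
        remaining = {m.morf_id: m for m in morfs}
        selected = set()
        for r in rounds:
            best_spec = -1.0
            for combo in all_combinations(panel):
                if combo.key in selected:
                    continue
                counts = score_combination(remaining.values(), combo)
                if counts.predictions == 0:
                    continue
                best_spec = max(best_spec, mp.specificity(counts))
            assert r.specificity == pytest.approx(best_spec)
            selected.add(r.combination.key)
            for morf_id in r.called_morfs:
                del remaining[morf_id]

    def test_requires_reference(self):
        ref = mp.generate_reference(10, seed=1)
        sets = [PredictionSet("A", list(ref))]
        morfs = mp.assign_morfs(sets)  # no reference members
        with pytest.raises(ConfigurationError):
            mp.run_path(morfs, ["A"])


class TestGeneralPath:
    def test_single_genome_equals_own_greedy_path(self):
        morfs, panel = simulated_morfs(seed=7)
        rounds, tables = mp.run_path(morfs, panel, record_tables=True)
        path = mp.general_path({"g1": tables})
        assert [c.key for c in path.combinations] == \
            [r.combination.key for r in rounds][:len(path)]
        # with one genome, projected confidence is that genome's own
        # round specificity
        for conf, r in zip(path.projected_confidence, rounds):
            assert conf == pytest.approx(r.specificity)

    def test_identical_genomes_share_path_and_confidence(self):
        morfs, panel = simulated_morfs(seed=8)
        _, tables = mp.run_path(morfs, panel, record_tables=True)
        single = mp.general_path({"g1": tables})
        double = mp.general_path({"g1": tables, "g2": tables})
        assert [c.key for c in single.combinations] == \
            [c.key for c in double.combinations]
        assert double.projected_confidence == \
            pytest.approx(single.projected_confidence)

    def test_full_panel_everywhere_wins_round_one(self):
        """Three genomes engineered so the full-panel consensus is the
        most specific combination in each: independent wrong starts from
        a tiny offset alphabet make chance agreement on a wrong start
        decay with combination size, so specificity rises from pairs
        (~0.75) to the full panel (~0.95); the general path must open
        with the full panel."""
        tables = {}
        panel = ["A", "B", "C", "D"]
        for seed in (21, 22, 23):
            ref = mp.generate_reference(800, seed=seed)
            profiles = [mp.EngineProfile(name=n, p_wrong_start=0.45,
                                         offset_choices=(-3, 3),
                                         p_fn_short=0.02, p_fn_long=0.01,
                                         fp_rate=2.0) for n in panel]
            sets = mp.simulate_panel(ref, profiles,
                                     mp.CorrelationSpec(0.0), seed=seed)
            morfs = mp.assign_morfs(sets, ref)
            _, tables[f"g{seed}"] = mp.run_path(morfs, panel,
                                                record_tables=True)
        path = mp.general_path(tables)
        assert path.combinations[0].key == "A+B+C+D"

    def test_inconsistent_panels_rejected(self):
        t1 = [{"A": (0.9, 0.5), "B": (0.8, 0.6)}]
        t2 = [{"A": (0.9, 0.5), "C": (0.8, 0.6)}]
        with pytest.raises(ConfigurationError):
            mp.general_path({"g1": t1, "g2": t2}, panel=["A", "B"])

    def test_zero_call_genomes_drag_average_impact(self):
        """A combination evaluable in only one of two genomes gets half
        the single-genome impact."""
        t_evaluable = [{"A+B": (1.0, 0.5)}]
        t_empty = [{"A": (0.6, 0.5)}]  # A+B made no call here
        path = mp.general_path({"g1": t_evaluable, "g2": t_empty})
        # A+B avg impact = (1.0*0.5/1 + 0)/2 = 0.25 > A's (0.3/2=0.15)
        assert path.combinations[0].key == "A+B"
        assert path.average_impact[0] == pytest.approx(0.25)
        assert path.projected_confidence[0] == pytest.approx(1.0)


class TestApplyPath:
    @staticmethod
    def _world():
        """Three loci: all four engines agree on locus 1; only C+D agree
        on locus 2; total disagreement on locus 3."""
        def orf(e, start):
            return Orf("chr1", start, start + 299, "+", source=e)
        sets = [
            PredictionSet("A", [orf("A", 1000), orf("A", 3000)]),
            PredictionSet("B", [orf("B", 1000), orf("B", 3030)]),
            PredictionSet("C", [orf("C", 1000), orf("C", 2000),
                                orf("C", 3060)]),
            PredictionSet("D", [orf("D", 1000), orf("D", 2000),
                                orf("D", 3090)]),
        ]
        path = PathSpec(
            combinations=[Combination.of("A", "B", "C", "D"),
                          Combination.of("C", "D")],
            projected_confidence=[0.95, 0.60])
        return sets, path

    def test_round_assignment_walkthrough(self):
        sets, path = self._world()
        morfs = mp.assign_morfs(sets)
        calls = mp.apply_path(morfs, path)
        by_start = {}
        for morf in morfs:
            anchor = min(m.leftmost for m in morf.members)
            by_start[anchor] = calls[morf.morf_id]
        assert by_start[1000] == (1000, 1, 0.95)
        assert by_start[2000] == (2000, 2, 0.60)
        assert by_start[3000] == (None, None, None)

    def test_missing_engine_is_config_error(self):
        sets, path = self._world()
        morfs = mp.assign_morfs(sets[:2])  # only A and B supplied
        with pytest.raises(ConfigurationError):
            mp.apply_path(morfs, path)


class TestPathSpec:
    def test_json_and_yaml_round_trip(self, tmp_path):
        path = PathSpec(
            combinations=[Combination.of("A", "B"), Combination.of("A")],
            projected_confidence=[0.9, 0.7],
            average_impact=[0.45, 0.2],
            metadata={"n_training_genomes": 2})
        for name in ("path.json", "path.yaml"):
            target = tmp_path / name
            path.save(target)
            back = PathSpec.load(target)
            assert [c.key for c in back.combinations] == ["A+B", "A"]
            assert back.projected_confidence == \
                pytest.approx([0.9, 0.7])
            assert back.impact_form == path.impact_form

    def test_validation(self):
        with pytest.raises(ValueError):
            PathSpec(combinations=[Combination.of("A")],
                     projected_confidence=[0.9, 0.8])
        with pytest.raises(ValueError):
            PathSpec(combinations=[Combination.of("A"),
                                   Combination.of("A")],
                     projected_confidence=[0.9, 0.8])

    def test_four_engine_preset_shape(self):
        preset = mp.default_four_engine_path()
        assert [c.key for c in preset.combinations] == [
            "BASys+ISGA+RAST+xBASE", "ISGA+RAST+xBASE",
            "BASys+ISGA+RAST", "ISGA+RAST", "BASys+RAST+xBASE"]
        assert all(0.0 <= c <= 1.0 for c in preset.projected_confidence)
        # confidences are ordered from reliable to speculative rounds
        assert preset.projected_confidence == \
            sorted(preset.projected_confidence, reverse=True)
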