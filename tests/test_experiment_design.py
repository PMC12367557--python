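"""Session layouts and trial sequences reproduce the published designs."""

from collections import Counter

import pytest

from mimicaxis import (
    chick_trial_sequence,
    enumerate_trait_combinations,
    invertebrate_sequence,
    layout_discrimination,
    layout_generalization,
    layout_multiple_models,
)
from mimicaxis.experiment_design import (
    DISCRIMINATION_TEST_PHENOTYPES,
    DesignError,
    MULTIMODEL_MIMICS,
    format_trait_code,
    ALL_PERFECT,
    ALL_POOR,
)

SEEDS = range(20)


class TestDiscriminationLayout:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_training_counts(self, seed):
        counts = layout_discrimination("training", seed).counts()
        assert counts["M100"] == 15
        assert counts["V100"] == 15
        assert counts["empty"] == 19

    @pytest.mark.parametrize("seed", SEEDS)
    def test_testing_counts(self, seed):
        layout = layout_discrimination("testing", seed)
        counts = layout.counts()
        assert len(layout.dishes) == 49
        assert counts["V100"] == 17
        assert counts["M100"] == 10
        for code in DISCRIMINATION_TEST_PHENOTYPES:
            assert counts[code] == 2
        assert sum(1 for d in layout.dishes if not d.rewarded and d.stimulus != "empty") == 17

    def test_models_never_rewarded(self):
        for d in layout_discrimination("testing", 3).dishes:
            if d.stimulus in ("V100", "A100"):
                assert not d.rewarded
            elif d.stimulus != "empty":
                assert d.rewarded

    def test_seeded_determinism(self):
        assert layout_discrimination("testing", 11).dishes == layout_discrimination(
            "testing", 11
        ).dishes
        a = [d.stimulus for d in layout_discrimination("testing", 1).dishes]
        b = [d.stimulus for d in layout_discrimination("testing", 2).dishes]
        assert a != b and Counter(a) == Counter(b)

    def test_unknown_phase(self):
        with pytest.raises(DesignError):
            layout_discrimination("warmup", 0)


class TestMultipleModelsLayout:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_training_counts(self, seed):
        one = layout_multiple_models("training", "1M", seed).counts()
        assert one["M100"] == 25 and one["V100"] == 24
        two = layout_multiple_models("training", "2M", seed).counts()
        assert two["M100"] == 25 and two["V100"] == 12 and two["A100"] == 12

    @pytest.mark.parametrize("seed", SEEDS)
    def test_testing_counts(self, seed):
        one = layout_multiple_models("testing", "1M", seed).counts()
        assert one["V100"] == 20 and one["M100"] == 10
        two = layout_multiple_models("testing", "2M", seed).counts()
        assert two["V100"] == 10 and two["A100"] == 10 and two["M100"] == 10

    @pytest.mark.parametrize("seed", SEEDS)
    def test_largest_remainder_mimic_allocation(self, seed):
        """19 mimics over 7 types: five types get 3, two get 2."""
        counts = layout_multiple_models("testing", "2M", seed).counts()
        mimic_counts = sorted(counts[c] for c in MULTIMODEL_MIMICS)
        assert mimic_counts == [2, 2, 3, 3, 3, 3, 3]

    def test_unknown_treatment(self):
        with pytest.raises(DesignError):
            layout_multiple_models("testing", "3M", 0)


class TestGeneralizationLayout:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_training_counts(self, seed):
        counts = layout_generalization("training", seed).counts()
        assert counts["M100"] == 12 and counts["V100"] == 12 and counts["empty"] == 25

    @pytest.mark.parametrize("seed", SEEDS)
    def test_half_of_each_species_is_real(self, seed):
        layout = layout_generalization("testing", seed)
        for code in ("M100", "V100"):
            dishes = [d for d in layout.dishes if d.stimulus == code]
            assert len(dishes) == 12
            assert sum(d.real_specimen for d in dishes) == 6

    def test_reward_follows_species_not_material(self):
        for d in layout_generalization("testing", 5).dishes:
            if d.stimulus == "M100":
                assert d.rewarded
            elif d.stimulus == "V100":
                assert not d.rewarded


def test_edge_flags_mark_exactly_the_perimeter():
    """Brute-force check of all 49 cells of the 7x7 grid."""
    layout = layout_discrimination("testing", 0)
    for dish in layout.dishes:
        r, c = dish.position
        assert dish.edge == (r in (0, 6) or c in (0, 6))
    assert sum(d.edge for d in layout.dishes) == 24


class TestChickTrials:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_testing_composition(self, seed):
        seq = chick_trial_sequence("testing", seed=seed)
        assert len(seq.presentations) == 16
        fly = [p for p in seq.presentations
               if p.stimulus == format_trait_code(ALL_POOR) and not p.probe]
        wasp = [p for p in seq.presentations
                if p.stimulus == format_trait_code(ALL_PERFECT) and not p.probe]
        probes = [p for p in seq.presentations if p.probe]
        assert (len(fly), len(wasp), len(probes)) == (6, 6, 4)
        assert all(p.rewarded for p in fly)
        assert not any(p.rewarded for p in wasp)

    def test_probes_rewarded_and_distinct(self):
        for seed in SEEDS:
            probes = [p for p in chick_trial_sequence("testing", seed=seed).presentations
                      if p.probe]
            assert all(p.rewarded for p in probes)  # even the perfect mimic
            assert len({p.stimulus for p in probes}) == 4

    def test_perfect_mimic_probe_is_rewarded(self):
        """The all-perfect probe (identical to the wasp) still carries a reward."""
        perfect = format_trait_code(ALL_PERFECT)
        found = False
        for seed in range(200):
            for p in chick_trial_sequence("testing", seed=seed).presentations:
                if p.probe and p.stimulus == perfect:
                    assert p.rewarded
                    found = True
        assert found

    def test_training_is_sixteen_binary_choices(self):
        seq = chick_trial_sequence("training", seed=0)
        assert len(seq.presentations) == 16
        assert all(p.stimulus.startswith("choice:") for p in seq.presentations)

    def test_small_pool_rejected(self):
        with pytest.raises(DesignError):
            chick_trial_sequence("testing", probe_pool=enumerate_trait_combinations()[:3])


class TestInvertebrateSequence:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_alternating_structure(self, seed):
        seq = invertebrate_sequence(seed)
        assert len(seq.presentations) == 9
        probes = [p.stimulus for k, p in enumerate(seq.presentations) if k % 2 == 0]
        reinforcement = [p.stimulus for k, p in enumerate(seq.presentations) if k % 2 == 1]
        assert sorted(probes) == sorted(
            ["M100", "M75/V25", "M50/V50", "M25/V75", "V100"]
        )
        assert Counter(reinforcement) == Counter({"M100": 2, "V100": 2})
        assert all(p.probe for k, p in enumerate(seq.presentations) if k % 2 == 0)
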