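"""Certainty bands, stacking, propagation-threshold routing, traffic lights."""

import numpy as np
import pytest

from depcascade.cohort import CohortTable
from depcascade.evaluation import make_fold_plan, metric_triple
from depcascade.exceptions import LeakageError
from depcascade.models import ModalityModelSpec, load_registry, predict_proba, train_base_model
from depcascade.sequential import (
    OOFMatrix,
    RoutingResult,
    SequentialPolicy,
    StackSpec,
    assign_band,
    evaluate_sequential_nested,
    format_count_cell,
    format_percentage,
    optimize_policy,
    route_cases,
    route_from_probabilities,
    traffic_light_report,
    train_stacker,
)

from conftest import make_separable_table


class TestBands:
    @pytest.mark.parametrize("p,colour,level", [
        (0.70, "red", "medium"),
        (0.50, "yellow", "low"),
        (0.10, "green", "high"),
        (0.67, "red", "medium"),      # boundary inclusive upward
        (0.33, "yellow", "low"),      # certainty 0.67 - eps
        (0.83, "red", "high"),
        (0.17, "green", "high"),
        (0.55, "yellow", "low"),
    ])
    def test_band_assignments(self, p, colour, level):
        b = assign_band(p)
        assert (b.colour, b.level) == (colour, level)

    def test_certainty_is_symmetric(self):
        assert assign_band(0.10).certainty == pytest.approx(0.90)
        assert assign_band(0.90).certainty == pytest.approx(0.90)

    def test_partition_property(self):
        """Every probability maps to exactly one colour; counts sum to n."""
        ps = np.linspace(0, 1, 401)
        colours = [assign_band(float(p)).colour for p in ps]
        assert set(colours) <= {"green", "yellow", "red"}
        assert len(colours) == 401

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_band(1.01)
        with pytest.raises(ValueError):
            assign_band(-0.01)


class TestStacker:
    def _oof(self, probs, names=("m1", "m2"), oof=True):
        return OOFMatrix(member_names=list(names), probabilities=np.asarray(probs),
                         out_of_fold=oof)

    def test_two_perfect_members_reproduced(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 300)
        p = np.clip(y + rng.normal(0, 0.05, 300), 0, 1)
        stack = train_stacker(StackSpec(("m1", "m2")), self._oof(np.column_stack([p, p])), y)
        held_y = rng.integers(0, 2, 200)
        held_p = np.clip(held_y + rng.normal(0, 0.05, 200), 0, 1)
        pred = (stack.predict_proba(np.column_stack([held_p, held_p])) > 0.5).astype(int)
        assert metric_triple(held_y, pred).balanced_accuracy >= 0.98

    def test_perfect_and_antiperfect_members(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        good = np.clip(y + rng.normal(0, 0.1, 400), 0, 1)
        anti = 1.0 - good
        stack = train_stacker(StackSpec(("good", "anti")),
                              self._oof(np.column_stack([good, anti]), ("good", "anti")), y)
        pred = (stack.predict_proba(np.column_stack([good, anti])) > 0.5).astype(int)
        assert metric_triple(y, pred).balanced_accuracy >= 0.95

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            StackSpec(("only",))

    def test_in_fold_probabilities_rejected(self):
        y = np.array([0, 1] * 20)
        probs = np.column_stack([y, y]).astype(float)
        with pytest.raises(LeakageError):
            train_stacker(StackSpec(("a", "b")), self._oof(probs, ("a", "b"), oof=False), y)


class TestRouting:
    def test_policy_validation(self):
        with pytest.raises(ValueError):
            SequentialPolicy(step_names=("a", "b"), taus=(1.01,))
        with pytest.raises(ValueError):
            SequentialPolicy(step_names=("a",), taus=())
        with pytest.raises(ValueError):
            route_from_probabilities([np.array([0.5]), np.array([0.5])], [0.4])

    def test_all_confident_cases_decided_at_step_one(self):
        p1 = np.array([0.95, 0.02, 0.99, 0.01])
        p2 = np.array([0.5, 0.5, 0.5, 0.5])
        r = route_from_probabilities([p1, p2], [0.9])
        assert r.propagated_fraction == [0.0]
        assert np.array_equal(r.step_index, np.zeros(4, dtype=int))
        assert np.array_equal(r.labels, (p1 > 0.5).astype(int))

    def test_degenerate_tau_one_equals_final_model(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.01, 0.99, 200)
        p2 = rng.uniform(0.01, 0.99, 200)
        r = route_from_probabilities([p1, p2], [1.0])
        assert np.array_equal(r.labels, (p2 > 0.5).astype(int))
        assert r.propagated_fraction == [1.0]

    def test_low_tau_below_all_certainties_equals_step_one(self):
        rng = np.random.default_rng(3)
        p1 = np.where(rng.integers(0, 2, 100) == 1,
                      rng.uniform(0.8, 0.99, 100), rng.uniform(0.01, 0.2, 100))
        p2 = rng.uniform(0, 1, 100)
        r = route_from_probabilities([p1, p2], [0.5])
        assert np.array_equal(r.labels, (p1 > 0.5).astype(int))

    def test_propagated_fraction_monotone_in_tau(self):
        rng = np.random.default_rng(4)
        p1 = rng.uniform(0, 1, 500)
        p2 = rng.uniform(0, 1, 500)
        fracs = [route_from_probabilities([p1, p2], [t]).propagated_fraction[0]
                 for t in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_step_counts_sum_to_n(self):
        rng = np.random.default_rng(5)
        r = route_from_probabilities([rng.uniform(0, 1, 300), rng.uniform(0, 1, 300)], [0.8])
        counts = np.bincount(r.step_index, minlength=2)
        assert counts.sum() == 300 and counts[1] > 0


def _two_step_specs(table):
    feats = list(table.dictionary)
    perfect = [f for f in feats if f.startswith("inf")]
    noise = [f for f in feats if f.startswith("noise")][:3]
    spec_noise = ModalityModelSpec(name="noisy step", modalities="synthetic",
                                   features=tuple(noise), feature_count=len(noise),
                                   pipeline="P1")
    spec_perfect = ModalityModelSpec(name="strong step", modalities="synthetic",
                                     features=tuple(perfect), feature_count=len(perfect),
                                     pipeline="P1")
    return spec_noise, spec_perfect


class TestOptimizePolicy:
    def test_empty_grid_rejected(self, clean_cohort):
        reg = load_registry()
        plan = make_fold_plan(clean_cohort.labels, seed=0)
        with pytest.raises(ValueError, match="empty"):
            optimize_policy([reg["Clinical 15"], reg["Clinical 15"]], clean_cohort,
                            plan.inner[0], tau_grid=[], seed=0)

    def test_better_final_step_propagates_everyone(self):
        t = make_separable_table(n=250, shift=3.0, seed=6)
        spec_noise, spec_perfect = _two_step_specs(t)
        plan = make_fold_plan(t.labels, seed=1)
        policy = optimize_policy([spec_noise, spec_perfect], t, plan.inner[0],
                                 tau_grid=(0.5, 0.75, 1.0), seed=1)
        assert policy.taus == (1.0,)

    def test_perfect_first_step_takes_minimal_tau(self):
        # wide separation so every inner fold scores BAC 1.0 at every tau and
        # the tie-breaks (fewest propagations, then smaller tau) decide
        t = make_separable_table(n=250, shift=6.0, seed=7)
        spec_noise, spec_perfect = _two_step_specs(t)
        plan = make_fold_plan(t.labels, seed=2)
        policy = optimize_policy([spec_perfect, spec_perfect], t, plan.inner[0],
                                 tau_grid=(0.5, 0.75, 1.0), seed=2)
        assert policy.taus == (0.5,)


class TestTrafficLight:
    def test_printed_percentage_arithmetic(self):
        assert format_percentage(55, 59) == 93.2
        assert format_percentage(436, 491) == 88.8
        assert format_count_cell(436, 491) == "436/491 (88.8%)"

    def test_counts_and_undefined_cells(self):
        probs = np.array([0.95, 0.90, 0.05, 0.55, 0.45, 0.10])
        r = route_from_probabilities([probs], [])
        y = np.array([1, 0, 0, 1, 0, 1])
        rep = traffic_light_report(r, y)
        assert rep.cells[("red", 1)] == {"correct": 1, "total": 1}   # 0.95 depressed
        assert rep.cells[("red", 0)] == {"correct": 0, "total": 1}   # 0.90 control
        assert rep.cells[("yellow", 1)] == {"correct": 1, "total": 1}
        assert rep.cells[("green", 1)] == {"correct": 0, "total": 1}  # 0.10 depressed
        assert sum(c["total"] for c in rep.cells.values()) == 6
        # no all-green cohort cell -> percentage undefined, not 0
        empty = traffic_light_report(
            route_from_probabilities([np.array([0.9, 0.95])], []), np.array([1, 1]))
        assert empty.percentage("green", 0) is None

    def test_length_mismatch_rejected(self):
        r = route_from_probabilities([np.array([0.9])], [])
        with pytest.raises(ValueError):
            traffic_light_report(r, np.array([1, 0]))


class TestSequentialNested:
    def test_cascade_on_reference_cohort(self, missing_cohort):
        """End-to-end two-step cascade: fold fractions account for everyone,
        and the high-certainty bands outperform the yellow band."""
        reg = load_registry()
        plan = make_fold_plan(missing_cohort.labels, seed=1)
        rep, routing, light, policies = evaluate_sequential_nested(
            missing_cohort, plan, reg["Clinical 15"], tau_grid=(0.5, 0.7, 0.9, 1.0))
        assert rep.mean_balanced_accuracy > 0.75
        assert len(policies) == 5
        y = missing_cohort.labels
        colours = np.array([b.colour for b in routing.bands])
        assert np.bincount(routing.step_index, minlength=2).sum() == missing_cohort.n
        hi = colours != "yellow"
        if (~hi).sum() >= 4 and len(set(y[~hi])) > 1:
            hi_bac = metric_triple(y[hi], routing.labels[hi]).balanced_accuracy
            lo_bac = metric_triple(y[~hi], routing.labels[~hi]).balanced_accuracy
            assert hi_bac >= lo_bac
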