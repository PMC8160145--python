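"""Tests for scenario enumeration, domination logic and Pareto filtering."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from mhsd import (
    best_per_outcome,
    dominates,
    enumerate_sets,
    pareto_front,
    percent_reduction,
)
from mhsd.engine import ScenarioOutcome
from mhsd.scenarios import OUTCOMES, OutcomeTable, _pareto_mask

import reference_outcomes as ref


def make_table(triplets: dict[str, tuple], region="PHN") -> OutcomeTable:
    rows = [
        {"scenario_id": sid, "region_id": region,
         "suicides": t[0], "ed_presentations": t[1], "disengagements": t[2]}
        for sid, t in triplets.items()
    ]
    return OutcomeTable(df=pd.DataFrame(rows), window=(10.0, 20.0))


def brute_force_front(values: np.ndarray) -> set[int]:
    """Independent O(n^2) all-pairs oracle."""
    n = len(values)
    keep = set(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (all(values[i, k] <= values[j, k] for k in range(3))
                    and any(values[i, k] < values[j, k] for k in range(3))):
                keep.discard(j)
    return keep


class TestEnumerateSets:
    @pytest.mark.parametrize("k,expected", [(4, 495), (5, 792), (0, 1),
                                            (1, 12), (12, 1)])
    def test_counts(self, k, expected):
        sets = enumerate_sets(k=k)
        assert len(sets) == expected == comb(12, k)

    def test_no_duplicates_and_deterministic_order(self):
        a = enumerate_sets(k=3)
        b = enumerate_sets(k=3)
        labels = [s.label() for s in a]
        assert len(set(labels)) == len(labels)
        assert labels == [s.label() for s in b]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_sets(k=13)


class TestPercentReduction:
    @pytest.mark.parametrize("base,scen,expected", [
        (1778.0, 1532.0, 13.8),
        (155_901.0, 138_444.0, 11.2),
        (155_901.0, 137_573.0, 11.8),
        (544_972.0, 483_846.0, 11.2),
    ])
    def test_reference_table_arithmetic(self, base, scen, expected):
        assert round(percent_reduction(base, scen), 1) == expected

    def test_identity_is_zero(self):
        assert percent_reduction(42.0, 42.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestDominates:
    def out(self, tri):
        return ScenarioOutcome("s", "R", (0.0, 1.0), *tri)

    def test_strictly_better_on_some_never_worse(self):
        assert dominates(self.out((10, 10, 10)), self.out((11, 10, 12)))

    def test_not_dominating_when_other_wins_somewhere(self):
        assert not dominates(self.out((10, 10, 10)), self.out((9, 20, 20)))

    def test_never_dominates_itself(self):
        a = self.out((10, 10, 10))
        assert not dominates(a, a)

    def test_mismatched_region_rejected(self):
        b = ScenarioOutcome("s", "other", (0.0, 1.0), 1, 1, 1)
        with pytest.raises(ValueError):
            dominates(self.out((1, 1, 1)), b)


class TestParetoFront:
    def test_three_point_example(self):
        table = make_table({
            "x": (10, 10, 10), "y": (12, 9, 11), "z": (13, 13, 13),
        })
        res = pareto_front(table, "PHN")
        assert set(res.non_dominated) == {"x", "y"}
        assert res.dominated == [("z", "x")]

    def test_single_scenario_is_the_front(self):
        res = pareto_front(make_table({"only": (1, 2, 3)}), "PHN")
        assert res.non_dominated == ["only"]

    def test_identical_triplets_all_retained(self):
        table = make_table({"t1": (5, 5, 5), "t2": (5, 5, 5), "w": (9, 9, 9)})
        res = pareto_front(table, "PHN")
        assert set(res.non_dominated) == {"t1", "t2"}

    def test_reference_seventeen_mutually_non_dominated(self):
        res = pareto_front(make_table(ref.NON_DOMINATED_PHN), "PHN")
        assert len(res.non_dominated) == 17

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Vectorised front equals the all-pairs oracle on >=1000 random
        outcome tables, including ones with many ties."""
        rng = np.random.default_rng(2021)
        for trial in range(1000):
            n = int(rng.integers(1, 25))
            vals = rng.integers(0, 6, size=(n, 3)).astype(float)
            mask, witness = _pareto_mask(vals)
            expected = brute_force_front(vals)
            assert set(np.flatnonzero(mask)) == expected, f"trial {trial}"
            # every dominated entry names a genuine dominator
            for j in np.flatnonzero(~mask):
                w = witness[j]
                assert (vals[w] <= vals[j]).all() and (vals[w] < vals[j]).any()

    def test_front_invariant_to_row_order_and_affine_rescaling(self):
        rng = np.random.default_rng(5)
        tri = {f"s{i}": tuple(rng.uniform(0, 100, 3)) for i in range(40)}
        base = set(pareto_front(make_table(tri), "PHN").non_dominated)
        items = list(tri.items())
        rng.shuffle(items)
        shuffled = dict(items)
        assert set(pareto_front(make_table(shuffled), "PHN").non_dominated) == base
        rescaled = {k: (v[0] * 3.5 + 11.0, v[1], v[2]) for k, v in tri.items()}
        assert set(pareto_front(make_table(rescaled), "PHN").non_dominated) == base


@pytest.fixture(scope="module")
def ref_table():
    rows = dict(ref.NON_DOMINATED_PHN)
    rows["baseline"] = ref.BASELINE_PHN
    return make_table(rows)


class TestBestPerOutcome:

    def test_reference_argmins(self, ref_table):
        assert best_per_outcome(ref_table, "PHN", "suicides") == "a"
        assert best_per_outcome(ref_table, "PHN", "ed_presentations") == "o"
        assert best_per_outcome(ref_table, "PHN", "disengagements") == "q"

    def test_best_is_on_the_front(self, ref_table):
        front = set(pareto_front(ref_table, "PHN").non_dominated)
        for outcome in OUTCOMES:
            assert best_per_outcome(ref_table, "PHN", outcome) in front

    def test_tie_broken_lexicographically(self):
        table = make_table({"bb": (1, 2, 3), "aa": (1, 5, 6), "cc": (4, 4, 4)})
        assert best_per_outcome(table, "PHN", "suicides") == "aa"

    def test_unknown_outcome_rejected(self, ref_table):
        with pytest.raises(KeyError):
            best_per_outcome(ref_table, "PHN", "happiness")
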