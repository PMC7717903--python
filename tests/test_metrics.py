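import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinesurvival import (
    classify_fates,
    classify_size,
    fraction_sp_positive,
    interval_loss,
    match_pairs_by_size,
    turnover_metrics,
)
from spinesurvival.metrics import size_class_counts
from tests.conftest import make_table

DAYS = (-1, 0, 3, 6, 9, 12)


def random_table(rng, n_spines=20):
    """Random (not necessarily biological) trajectory table."""
    traj = {}
    for i in range(n_spines):
        states = []
        pruned = False
        started = rng.random() > 0.3
        for _ in DAYS:
            if pruned:
                states.append(None)
            elif not started:
                states.append(None)
                started = rng.random() > 0.5
            else:
                states.append(bool(rng.random() < 0.3))
                pruned = rng.random() < 0.2
        traj[f"s{i}"] = states
    return make_table(traj, days=DAYS)


class TestTurnover:
    def test_static_population(self):
        table = make_table({f"s{i}": [False] * 6 for i in range(10)})
        m = turnover_metrics(table, -1, 12)
        assert m.turnover_ratio == m.formation_ratio == m.loss_ratio == 0.0

    def test_worked_example(self):
        # 7 initial, 3 gained later, 2 of all 10 absent at the end
        traj = {f"i{k}": [False] * 6 for k in range(5)}
        traj["i5"] = [False, False, False, False, False, None]
        traj["i6"] = [False, False, False, False, None, None]
        traj["g0"] = [None, False, False, False, False, False]
        traj["g1"] = [None, None, False, False, False, False]
        traj["g2"] = [None, None, None, False, False, False]
        m = turnover_metrics(make_table(traj), -1, 12)
        assert m.n_initial == 7 and m.n_total == 10 and m.n_final == 8
        assert m.formation_ratio == pytest.approx(0.3)
        assert m.loss_ratio == pytest.approx(0.2)
        assert m.turnover_ratio == pytest.approx(0.25)

    def test_missing_day_rejected(self):
        table = make_table({"s0": [False] * 6})
        with pytest.raises(ValueError):
            turnover_metrics(table, -1, 13)

    @pytest.mark.parametrize("seed", range(25))
    def test_turnover_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        m = turnover_metrics(random_table(rng), -1, 12)
        assert m.turnover_ratio == pytest.approx(
            (m.formation_ratio + m.loss_ratio) / 2.0
        )
        for r in (m.turnover_ratio, m.formation_ratio, m.loss_ratio):
            assert 0.0 <= r <= 1.0


class TestSizeClasses:
    @pytest.mark.parametrize(
        "area,label",
        [
            (0.29, "very_small"),
            (0.3, "small"),       # boundary goes upward
            (0.54, "small"),
            (0.55, "medium"),
            (0.79, "medium"),
            (0.8, "large"),
            (0.801, "large"),     # the mean SP+ head size sits in 'large'
            (5.0, "large"),
        ],
    )
    def test_boundaries(self, area, label):
        assert classify_size(area) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_size(0.0)

    @given(st.lists(st.floats(1e-6, 10.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_partition(self, areas):
        counts = size_class_counts(areas)
        assert sum(counts.values()) == len(areas)


class TestMatching:
    def test_identical_multisets_pair_perfectly(self):
        a = [(f"a{i}", v) for i, v in enumerate([0.2, 0.5, 0.9])]
        b = [(f"b{i}", v) for i, v in enumerate([0.9, 0.2, 0.5])]
        pairs = match_pairs_by_size(a, b)
        assert len(pairs) == 3
        np.testing.assert_allclose(pairs["diff"], 0.0)

    def test_nearest_neighbor_within_caliper(self):
        pairs = match_pairs_by_size([("a", 0.8)], [("b0", 0.81), ("b1", 2.0)])
        assert list(pairs["id_b"]) == ["b0"]

    def test_caliper_discards_distant_pairs(self):
        pairs = match_pairs_by_size([("a", 0.2)], [("b", 0.5)], caliper=0.1)
        assert pairs.empty

    def test_matched_means_close_on_synthetic_cohorts(self):
        rng = np.random.default_rng(0)
        a = [(f"a{i}", float(v)) for i, v in enumerate(rng.lognormal(-0.35, 0.5, 40))]
        b = [(f"b{i}", float(v)) for i, v in enumerate(rng.lognormal(-1.14, 0.5, 400))]
        pairs = match_pairs_by_size(a, b, caliper=0.1)
        assert len(pairs) > 0
        mean_a = pairs["area_a"].mean()
        assert abs(mean_a - pairs["area_b"].mean()) < 0.1 * mean_a


class TestFates:
    def test_pruned_via_sp_neg(self):
        table = make_table({"s": [True, True, True, False, None, None]})
        fates = classify_fates(table)
        assert fates["s"].outcome == "pruned_via_sp_neg"
        assert not fates["s"].undulating

    def test_pruned_direct(self):
        table = make_table({"s": [True, True, None, None, None, None]})
        assert classify_fates(table)["s"].outcome == "pruned_direct"

    def test_undulating_flag(self):
        table = make_table({"s": [True, True, False, True, False, False]})
        f = classify_fates(table)["s"]
        assert f.outcome == "survived"
        assert f.undulating
        assert f.transitions == (3, 6, 9)

    def test_fraction_via_sp_neg_worked_example(self):
        # 34 via the SP- state, 2 apparently direct -> ~94%
        traj = {}
        for i in range(34):
            traj[f"v{i}"] = [True, True, False, None, None, None]
        for i in range(2):
            traj[f"d{i}"] = [True, True, None, None, None, None]
        fates = classify_fates(make_table(traj))
        via = sum(f.outcome == "pruned_via_sp_neg" for f in fates.values())
        assert 100.0 * via / len(fates) == pytest.approx(94.44, abs=0.01)

    def test_partition_property(self):
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            table = random_table(rng)
            day0_present = table[(table["day"] == 0) & table["present"]]
            if day0_present.empty:
                continue
            fates = classify_fates(table)
            assert len(fates) == len(day0_present)
            outcomes = {"survived", "pruned_via_sp_neg", "pruned_direct"}
            assert all(f.outcome in outcomes for f in fates.values())

    def test_inconsistent_rows_rejected(self):
        table = make_table({"s": [True] * 6})
        table.loc[table["day"] == 3, "sp_positive"] = pd.NA
        with pytest.raises(ValueError):
            classify_fates(table)


class TestFractions:
    def test_sp_positive_fraction_counts(self):
        traj = {f"p{i}": [True] * 6 for i in range(87)}
        traj.update({f"n{i}": [False] * 6 for i in range(1021)})
        frac, n_pos, n_present = fraction_sp_positive(make_table(traj), 0)
        assert n_pos == 87 and n_present == 1108
        assert frac == pytest.approx(7.852, abs=0.01)

    def test_zero_sp_positive(self):
        frac, _, _ = fraction_sp_positive(make_table({"n": [False] * 6}), 0)
        assert frac == 0.0

    def test_interval_loss_worked_example(self):
        traj = {f"k{i}": [False] * 6 for i in range(391)}
        traj.update({f"l{i}": [False, None, None, None, None, None] for i in range(72)})
        pct, n_lost, n_from = interval_loss(make_table(traj), -1, 0)
        assert (n_lost, n_from) == (72, 463)
        assert pct == pytest.approx(15.55, abs=0.01)

    def test_no_spines_present_error(self):
        table = make_table({"s": [None, False, False, False, False, False]})
        with pytest.raises(ValueError):
            fraction_sp_positive(table, -1)
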