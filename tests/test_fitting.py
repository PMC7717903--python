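import numpy as np
import pytest

from spinesurvival import (
    SimulationConfig,
    SinglePhaseDecay,
    SurvivalTable,
    TwoStageDecay,
    build_survival_table,
    fit_single_phase,
    fit_two_stage,
    simulate_population,
)
from spinesurvival.fitting import weighted_sse
from spinesurvival.models import survival_single, survival_two_stage
from tests.conftest import make_table

DAYS = np.array([0.0, 3.0, 6.0, 9.0, 12.0])


def table_from_model(model, days=DAYS, n_initial=1000, label="t"):
    """Noiseless survival table sampled from a model (rounded counts)."""
    if isinstance(model, SinglePhaseDecay):
        y = survival_single(model, days)
    else:
        y = survival_two_stage(model, days)
    n = np.round(n_initial * y / 100.0).astype(int)
    return SurvivalTable(cohort_label=label, days=days, n_surviving=n,
                         n_initial=n_initial)


def exact_table(model, days=DAYS, label="t"):
    """SurvivalTable whose fractions equal the model exactly (via n=10^6)."""
    if isinstance(model, SinglePhaseDecay):
        y = survival_single(model, days)
    else:
        y = survival_two_stage(model, days)
    n_initial = 10**6
    return SurvivalTable(
        cohort_label=label,
        days=days,
        n_surviving=np.round(n_initial * y / 100.0).astype(int),
        n_initial=n_initial,
    )


class TestBuildSurvivalTable:
    def test_all_present_is_flat_100(self):
        table = make_table({f"s{i}": [False] * 6 for i in range(5)})
        st = build_survival_table(table, "sp_neg")
        np.testing.assert_allclose(st.fraction_percent, 100.0)
        assert st.n_initial == 5

    def test_single_loss_trajectory(self):
        # one of four spines absent from day 3 onward
        traj = {f"s{i}": [False] * 6 for i in range(3)}
        traj["s3"] = [False, False, None, None, None, None]
        st = build_survival_table(make_table(traj), "sp_neg")
        np.testing.assert_allclose(st.fraction_percent, [100, 75, 75, 75, 75])
        np.testing.assert_allclose(st.days, [0, 3, 6, 9, 12])

    def test_reappearance_counts_as_surviving_by_default(self):
        traj = {
            "a": [False, False, None, False, None, None],  # miss at day 3, back day 6
            "b": [False] * 6,
        }
        st = build_survival_table(make_table(traj), "sp_neg")
        np.testing.assert_allclose(st.fraction_percent, [100, 100, 100, 50, 50])
        strict = build_survival_table(make_table(traj), "sp_neg", strict=True)
        np.testing.assert_allclose(strict.fraction_percent, [100, 50, 50, 50, 50])

    def test_cohort_by_sp_state_and_predicate(self):
        traj = {
            "p0": [True, True, True, None, None, None],
            "n0": [False] * 6,
            "n1": [False] * 6,
        }
        table = make_table(traj)
        assert build_survival_table(table, "sp_pos").n_initial == 1
        assert build_survival_table(table, "sp_neg").n_initial == 2
        # "timed SP+" style predicate: SP- at day -1 handled via callable
        st = build_survival_table(
            table, lambda day0: day0["sp_positive"].astype(bool)
        )
        assert st.n_initial == 1

    def test_errors(self):
        table = make_table({"s0": [False] * 6})
        with pytest.raises(ValueError):
            build_survival_table(table, "sp_pos")  # empty cohort
        with pytest.raises(ValueError):
            build_survival_table(table, "sp_neg", cohort_day=1)

    def test_large_synthetic_matches_exponential(self, big_sp_neg_table):
        st = build_survival_table(big_sp_neg_table, "sp_neg")
        expected = 100.0 * np.exp(-st.days / 9.8)
        np.testing.assert_allclose(st.fraction_percent, expected, atol=1.0)


class TestFitSinglePhase:
    def test_noiseless_self_consistency(self):
        fit = fit_single_phase(exact_table(SinglePhaseDecay(9.8)))
        assert fit.model.tau_spine == pytest.approx(9.8, abs=1e-3)
        assert fit.model.offset == pytest.approx(0.0, abs=1e-2)
        assert fit.weighted_sse < 1e-6

    def test_noiseless_with_offset(self):
        truth = SinglePhaseDecay(5.0, offset=1.0)
        fit = fit_single_phase(exact_table(truth))
        assert fit.model.tau_spine == pytest.approx(5.0, abs=5e-3)
        assert fit.model.offset == pytest.approx(1.0, abs=5e-3)

    def test_objective_matches_independent_recomputation(self):
        st = table_from_model(SinglePhaseDecay(7.0), n_initial=500)
        fit = fit_single_phase(st)
        sse = weighted_sse(fit.model, st.days, st.fraction_percent)
        assert fit.weighted_sse == pytest.approx(sse, rel=1e-8)

    def test_grid_search_oracle(self):
        st = table_from_model(SinglePhaseDecay(9.8), n_initial=392)
        fit = fit_single_phase(st)
        taus = np.arange(0.5, 50.0, 0.1)
        offset = fit.model.offset
        grid_sse = [
            weighted_sse(SinglePhaseDecay(tau, offset), st.days, st.fraction_percent)
            for tau in taus
        ]
        assert min(grid_sse) >= fit.weighted_sse - 1e-6

    def test_zero_fraction_points_excluded(self):
        st = SurvivalTable(
            cohort_label="t",
            days=np.array([0.0, 3.0, 6.0, 9.0, 12.0]),
            n_surviving=np.array([100, 37, 14, 5, 0]),
            n_initial=100,
        )
        fit = fit_single_phase(st)
        assert fit.n_points == 4
        assert np.isfinite(fit.weighted_sse)

    def test_too_few_points(self):
        st = SurvivalTable(
            cohort_label="t",
            days=np.array([0.0, 3.0]),
            n_surviving=np.array([10, 5]),
            n_initial=10,
        )
        with pytest.raises(ValueError):
            fit_single_phase(st)

    def test_parameter_recovery_across_seeds(self):
        taus = []
        for seed in range(10):
            config = SimulationConfig(
                n_spines_sp_pos=0, n_spines_sp_neg=392,
                observation_days=(0, 3, 6, 9, 12), seed=seed,
            )
            st = build_survival_table(simulate_population(config), "sp_neg")
            taus.append(fit_single_phase(st).model.tau_spine)
        assert abs(np.mean(taus) - 9.8) / 9.8 < 0.10


class TestFitTwoStage:
    def test_noiseless_self_consistency(self):
        st = exact_table(TwoStageDecay(11.1, 9.8))
        fit = fit_two_stage(st, tau_spine_fixed=9.8)
        assert fit.model.tau_sp == pytest.approx(11.1, abs=1e-3)
        assert fit.fixed_parameters == ("tau_spine",)

    def test_wrong_fixed_tau_spine_costs_more(self):
        st = exact_table(TwoStageDecay(11.1, 9.8))
        good = fit_two_stage(st, tau_spine_fixed=9.8)
        bad = fit_two_stage(st, tau_spine_fixed=19.6)
        assert bad.weighted_sse > good.weighted_sse

    def test_cofit_mode_recovers_both(self):
        # the survival curve is symmetric in (tau_sp, tau_spine), so the
        # co-fit recovers the pair only up to a swap
        st = exact_table(TwoStageDecay(11.1, 9.8))
        fit = fit_two_stage(st, fit_tau_spine=True)
        pair = sorted([fit.model.tau_sp, fit.model.tau_spine])
        assert pair[0] == pytest.approx(9.8, abs=0.05)
        assert pair[1] == pytest.approx(11.1, abs=0.05)
        assert fit.fixed_parameters == ()

    def test_requires_tau_spine_when_not_cofitting(self):
        st = exact_table(TwoStageDecay(11.1, 9.8))
        with pytest.raises(ValueError):
            fit_two_stage(st)
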