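import dataclasses

import numpy as np
import pytest

from anacap import (
    PLACEBO,
    compute_maod,
    default_caffeine,
    fit_demand_line,
    group_trials,
    maod_matrix,
    simulate_crossover_study,
    supramaximal_demand,
)


def normal_equation_ols(x, y):
    """Independent closed-form two-parameter OLS oracle."""
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return slope, intercept


class TestDemandLine:
    def test_collinear_points_fit_exactly(self):
        pts = [(100, 1.5), (150, 2.0), (200, 2.5)]
        line = fit_demand_line(pts)
        assert line.slope == pytest.approx(0.01)
        assert line.intercept == pytest.approx(0.5)
        assert line.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_on_noisy_points(self):
        rng = np.random.default_rng(4)
        x = np.array([120.0, 150.0, 190.0, 205.0, 230.0])
        y = 0.5 + 0.0103 * x + rng.normal(0, 0.05, 5)
        line = fit_demand_line(list(zip(x, y)))
        slope, intercept = normal_equation_ols(x, y)
        assert line.slope == pytest.approx(slope, abs=1e-10)
        assert line.intercept == pytest.approx(intercept, abs=1e-10)
        assert 0 <= line.r2 <= 1

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_demand_line([(100, 1.5)])

    def test_identical_powers_rejected(self):
        with pytest.raises(ValueError, match="powers"):
            fit_demand_line([(100, 1.5), (100, 1.7)])


class TestSupramaximalDemand:
    def test_direct_evaluation(self):
        line = fit_demand_line([(100, 1.5), (200, 2.7)])  # slope 0.012, intercept 0.3
        assert supramaximal_demand(line, 300.0, 131.0) == pytest.approx(
            (0.012 * 300 + 0.3) * 131 / 60, rel=1e-9
        )

    def test_sixty_seconds_equals_rate(self):
        line = fit_demand_line([(100, 1.5), (200, 2.5)])
        assert supramaximal_demand(line, 250.0, 60.0) == pytest.approx(line.demand_at(250.0))

    def test_zero_duration_rejected(self):
        line = fit_demand_line([(100, 1.5), (200, 2.5)])
        with pytest.raises(ValueError):
            supramaximal_demand(line, 300.0, 0.0)


class TestComputeMaod:
    def test_store_correction_and_energy_conversion(self):
        # 7.88 L demand, 4.38 L accumulated → 3.50 L deficit → 10% store
        # correction → 3.15 L → 65.8 kJ at 20.9 kJ/L
        est = compute_maod(7.88, 4.38)
        assert est.total_kj == pytest.approx((7.88 - 4.38) * 0.9 * 20.9, rel=1e-12)
        assert est.total_kj == pytest.approx(65.80, rel=0.005)
        assert est.extras["deficit_l"] == pytest.approx(3.50)

    def test_zero_deficit(self):
        assert compute_maod(5.0, 5.0).total_kj == 0.0

    def test_identity_parameters_return_raw_deficit(self):
        est = compute_maod(7.0, 4.0, store_correction=0.0, energy_equiv=1.0)
        assert est.total_kj == pytest.approx(3.0)

    def test_negative_deficit_rejected(self):
        with pytest.raises(ValueError, match="negative deficit"):
            compute_maod(4.0, 5.0)

    def test_linear_in_energy_equiv_affine_in_correction(self):
        base = compute_maod(8.0, 5.0, store_correction=0.1, energy_equiv=20.9).total_kj
        doubled = compute_maod(8.0, 5.0, store_correction=0.1, energy_equiv=41.8).total_kj
        assert doubled == pytest.approx(2 * base)
        c0 = compute_maod(8.0, 5.0, store_correction=0.0).total_kj
        c5 = compute_maod(8.0, 5.0, store_correction=0.5).total_kj
        assert c5 == pytest.approx(0.5 * c0)


@pytest.fixture(scope="module")
def participant_trials():
    trials = simulate_crossover_study(2, seed=17)
    return group_trials(trials)[0]


class TestMaodMatrix:
    def test_three_variants_produced(self, participant_trials):
        out = maod_matrix(participant_trials)
        assert set(out) == {"CAF-CAF", "CAF-PLA", "PLA-PLA"}
        for est in out.values():
            assert est.total_kj > 0

    def test_demand_and_supra_conditions_recorded(self, participant_trials):
        out = maod_matrix(participant_trials)
        assert out["CAF-PLA"].condition == "caffeine"
        assert out["CAF-PLA"].demand_condition == "placebo"
        assert out["PLA-PLA"].demand_condition == "placebo"

    def test_variants_share_supra_bout_when_conditions_match(self, participant_trials):
        # CAF-CAF and CAF-PLA integrate the same supramaximal bout; they can
        # differ only through the demand line (generator submax is
        # condition-independent up to noise).
        out = maod_matrix(participant_trials)
        a, b = out["CAF-CAF"], out["CAF-PLA"]
        assert a.extras["accumulated_l"] == pytest.approx(b.extras["accumulated_l"])
        assert a.extras["total_demand_l"] != b.extras["total_demand_l"]

    def test_identical_submax_degenerate_equality(self, participant_trials):
        # replace the placebo submax bouts with the caffeine ones: the two
        # caffeine-bout variants must coincide exactly
        tm = dict(participant_trials)
        for wl in ("d10", "d20", "d40", "d50", "d80"):
            tm[(wl, "placebo")] = tm[(wl, "caffeine")]
        out = maod_matrix(tm)
        assert out["CAF-CAF"].total_kj == pytest.approx(out["CAF-PLA"].total_kj, rel=1e-12)

    def test_missing_bout_named(self, participant_trials):
        tm = dict(participant_trials)
        del tm[("d40", "caffeine")]
        with pytest.raises(ValueError, match="d40"):
            maod_matrix(tm)


def test_maod_recovers_generator_oxygen_deficit():
    """On a noiseless supramaximal bout with a known demand line, the MAOD
    kJ value equals the true integrated O2 deficit x 0.9 x 20.9 within 2%."""
    from anacap import accumulated_vo2, make_participant, simulate_constant_load, workload_power

    truth = make_participant(3, overrides={"noise_sd": 0.0, "slow_amp": 0.0})
    power = workload_power(truth, "p120")
    tr = simulate_constant_load(truth, PLACEBO, power, to_exhaustion=True, seed=1)
    tte = tr.time_to_exhaustion
    demand_l = (truth.demand_intercept + truth.demand_slope * power) * tte / 60.0
    acc = accumulated_vo2(tr.breaths, tr.breaths.t[0], tr.breaths.t[-1])
    est = compute_maod(demand_l, acc)
    # truth-side deficit: demand minus the capped first-order response,
    # integrated in closed form
    d = truth.demand(power)
    cap = min(d, truth.vo2peak)
    integral_vo2 = cap * (tte - truth.tau_on * (1 - np.exp(-tte / truth.tau_on)))
    true_deficit_l = (d * tte - integral_vo2) / 60.0
    assert est.total_kj == pytest.approx(true_deficit_l * 0.9 * 20.9, rel=0.02)
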