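"""Likelihood machinery: cost, multistart fit, profiles, LRT, reduction."""

import numpy as np
import pytest
from dataclasses import replace

from her2traffic import (
    ModelBParameters,
    pulse_chase_schedule,
    reference_parameters,
    simulate,
)
from her2traffic.errors import FitFailureError, RefitNeededError, \
    ValidationError
from her2traffic.inference import (
    ArrayObjective,
    ConditionData,
    Dataset,
    ReductionCandidate,
    SolutionFilters,
    TraffickingObjective,
    check_scaling_symmetry,
    fit,
    likelihood_ratio_test,
    minus2_log_likelihood,
    profile,
    reduce_model,
)
from conftest import signal_dataset
from oracles import gaussian_profile_ci

B_FREE = ["k_act_R_T0", "k_act_F_T0", "k_diss", "k_int_RT", "k_int_FT",
          "k_off", "s_c", "N_F0"]


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def test_cost_zero_on_noise_free_data(model_b_truth,
                                      noise_free_main_dataset):
    obj = TraffickingObjective("B", model_b_truth,
                               noise_free_main_dataset, B_FREE)
    assert obj.cost(obj.theta_from(model_b_truth)) <= 1e-10


def test_cost_single_condition_arithmetic():
    """One condition with prediction 3, datum 1, sigma 1 costs 4."""
    p = ModelBParameters(k_act_R_T0=0.4, k_act_F_T0=0.4, k_diss=0.05,
                        k_int_RT=49, k_int_FT=0.0126, k_on_A0=4.0,
                        k_off=0.0, N_F0=1.0, N_R0=0.0, s_c=3.0)
    sched = pulse_chase_schedule("before_experiment", drug_min=0)
    # label saturates within the 10-min window (k_on*A0 = 4/min)
    data = Dataset((ConditionData("control", sched, 1.0, 1.0),))
    obj = TraffickingObjective("B", p, data, ["s_c"])
    assert obj.cost(obj.theta_from(p)) == pytest.approx(4.0, abs=1e-10)


def test_cost_equals_residual_recomputation(model_b_truth, main_schedules):
    data = signal_dataset(model_b_truth, "B", main_schedules, seed=5)
    obj = TraffickingObjective("B", model_b_truth, data, B_FREE)
    theta = obj.theta_from(model_b_truth) + 0.07
    res = obj.residuals(theta)
    # independent loop over exported per-condition residuals
    params = obj.params_from(theta)
    manual = 0.0
    for cond in data.conditions:
        traj = simulate("B", params, cond.schedule,
                        output_times=[cond.schedule.measurement_time])
        manual += ((traj.observed[-1] - cond.y) / cond.sigma) ** 2
    assert obj.cost(theta) == pytest.approx(float(res @ res), rel=1e-12)
    assert obj.cost(theta) == pytest.approx(manual, rel=1e-9)
    assert minus2_log_likelihood(params, data, "B") == \
        pytest.approx(manual, rel=1e-12)


def test_cost_is_infinite_when_simulation_fails(model_b_truth,
                                                noise_free_main_dataset):
    obj = TraffickingObjective("B", model_b_truth,
                               noise_free_main_dataset, ["k_int_RT"])
    theta = np.array([np.log10(model_b_truth.k_int_RT)])
    assert np.isfinite(obj.cost(theta))
    res = obj.residuals(np.array([np.nan]))
    assert np.all(res == 1e6)  # optimizers stay safe


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def test_refit_from_optimum_is_a_fixed_point(model_b_truth,
                                             main_schedules):
    data = signal_dataset(model_b_truth, "B", main_schedules, seed=8)
    obj = TraffickingObjective("B", model_b_truth, data, B_FREE)
    first = fit(obj, n_starts=2, seed=0,
                extra_starts=[obj.theta_from(model_b_truth)])
    again = fit(obj, n_starts=1, seed=1,
                extra_starts=[first.theta_log10])
    assert abs(again.minus2LL - first.minus2LL) < 1e-6
    assert first.minus2LL == pytest.approx(obj.cost(first.theta_log10))
    assert np.all(np.diff([s.cost for s in first.ensemble]) >= 0)


def test_filtered_start_excluded_even_if_it_has_lowest_cost():
    """Double-well cost with the deeper/equal basin outside the accepted
    region: the winner must come from the accepted set."""

    class GatedObjective(ArrayObjective):
        def accepts(self, theta):
            ok = theta[0] > 0
            return ok, "" if ok else "negative branch excluded"

    obj = GatedObjective(lambda x: np.array([(x[0] ** 2 - 4.0) / 2.0]),
                         [(-6.0, 6.0)])
    res = fit(obj, n_starts=4, seed=3, extra_starts=[np.array([-2.1]),
                                                     np.array([1.5])])
    assert res.theta_log10[0] == pytest.approx(2.0, abs=1e-6)
    rejected = [s for s in res.ensemble if not s.accepted and s.success]
    assert any(abs(s.theta[0] + 2.0) < 1e-6 for s in rejected)


def test_solution_filters_on_parameters(model_b_truth, main_schedules,
                                        model_a_truth):
    data = signal_dataset(model_b_truth, "B", main_schedules)
    obj_b = TraffickingObjective("B", model_b_truth, data,
                                 ["k_on_A0", "s_c"])
    ok, _ = obj_b.accepts(np.log10([1.0, 535.0]))
    assert ok
    bad, reason = obj_b.accepts(np.log10([6.0, 535.0]))
    assert not bad and "k_on_A0" in reason

    data_a = signal_dataset(model_a_truth, "A", main_schedules)
    obj_a = TraffickingObjective("A", replace(model_a_truth, k_rec=0.1),
                                 data_a, ["N_i0", "s_c"])
    assert obj_a.accepts(np.log10([0.025, 529.0]))[0]
    assert not obj_a.accepts(np.log10([0.2, 529.0]))[0]


def test_fit_failure_carries_ensemble():
    class Hopeless(ArrayObjective):
        def accepts(self, theta):
            return False, "never"

    obj = Hopeless(lambda x: np.array([x[0]]), [(-1.0, 1.0)])
    with pytest.raises(FitFailureError) as err:
        fit(obj, n_starts=3, seed=0)
    assert len(err.value.ensemble) == 3


def test_sigma_rescaling_scales_cost_not_optimum(model_b_truth,
                                                 main_schedules):
    data = signal_dataset(model_b_truth, "B", main_schedules, seed=13)
    kappa = 2.5
    data2 = Dataset(tuple(
        ConditionData(c.name, c.schedule, c.y, kappa * c.sigma)
        for c in data.conditions))
    o1 = TraffickingObjective("B", model_b_truth, data, B_FREE)
    o2 = TraffickingObjective("B", model_b_truth, data2, B_FREE)
    f1 = fit(o1, n_starts=1, seed=0,
             extra_starts=[o1.theta_from(model_b_truth)])
    f2 = fit(o2, n_starts=1, seed=0,
             extra_starts=[o2.theta_from(model_b_truth)])
    assert f2.minus2LL == pytest.approx(f1.minus2LL / kappa ** 2, rel=1e-4)
    np.testing.assert_allclose(f2.theta_log10, f1.theta_log10, atol=2e-3)


def test_region_label_canonicalization(model_b_truth,
                                       noise_free_main_dataset):
    obj = TraffickingObjective("B", model_b_truth,
                               noise_free_main_dataset, B_FREE)
    theta = obj.theta_from(model_b_truth)
    # swapped labels: fast internalization assigned to the flat pool
    swapped = theta.copy()
    i = {n: k for k, n in enumerate(B_FREE)}
    swapped[[i["k_act_R_T0"], i["k_act_F_T0"]]] = \
        theta[[i["k_act_F_T0"], i["k_act_R_T0"]]]
    swapped[[i["k_int_RT"], i["k_int_FT"]]] = \
        theta[[i["k_int_FT"], i["k_int_RT"]]]
    swapped[i["N_F0"]] = np.log10(1 - 10 ** theta[i["N_F0"]])
    assert obj.cost(swapped) == pytest.approx(obj.cost(theta), abs=1e-9)
    restored = obj.canonicalize(swapped)
    np.testing.assert_allclose(restored, theta, atol=1e-12)
    # already-canonical vectors pass through untouched
    np.testing.assert_allclose(obj.canonicalize(theta), theta)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_quadratic_cost_profile_matches_gaussian_oracle():
    """Correlated linear-Gaussian problem: profile interval ends equal the
    closed-form hat +- 1.96 sigma to 1%."""
    rng = np.random.default_rng(31)
    A = rng.normal(size=(20, 3))
    sigma = 0.7
    x_true = np.array([0.5, -1.0, 2.0])
    y = A @ x_true + rng.normal(0, sigma, 20)
    obj = ArrayObjective(lambda x: (A @ x - y) / sigma,
                         [(-30, 30)] * 3, names=["a", "b", "c"])
    res = fit(obj, n_starts=2, seed=0, extra_starts=[x_true])
    cov = sigma ** 2 * np.linalg.inv(A.T @ A)
    for j, name in enumerate(obj.free):
        pc = profile(obj, res, name)
        lo, hi = gaussian_profile_ci(res.theta_log10, cov, j)
        width = hi - lo
        assert pc.ci_lower == pytest.approx(lo, abs=0.01 * width)
        assert pc.ci_upper == pytest.approx(hi, abs=0.01 * width)
        assert pc.minus2LL.min() >= res.minus2LL - 1e-9
        assert pc.ci_lower <= res.theta_log10[j] <= pc.ci_upper


def test_structurally_dead_parameter_has_flat_profile(model_a_truth,
                                                      main_schedules):
    """Degradation of an absorbing internal pool never reaches the
    observable: its profile is flat and the interval unbounded both ways."""
    truth = replace(model_a_truth, k_rec_T=0.0)
    data = signal_dataset(truth, "A", main_schedules)
    obj = TraffickingObjective("A", truth, data, ["k_deg_T"])
    res = fit(obj, n_starts=2, seed=0,
              extra_starts=[np.array([np.log10(truth.k_deg_T)])])
    pc = profile(obj, res, "k_deg_T")
    assert pc.lower_unbounded and pc.upper_unbounded
    assert pc.ci_natural == (0.0, np.inf)
    assert np.max(pc.minus2LL) - pc.minimum < 1e-6


# ---------------------------------------------------------------------------
# likelihood-ratio testing and reduction
# ---------------------------------------------------------------------------

def test_lrt_basic_values():
    a = _dummy_fit(10.0)
    assert likelihood_ratio_test(a, _dummy_fit(10.0), df=1) == \
        (0.0, pytest.approx(1.0))
    stat, p = likelihood_ratio_test(a, _dummy_fit(13.841458820694124), df=1)
    assert p == pytest.approx(0.05, abs=1e-4)
    with pytest.raises(RefitNeededError):
        likelihood_ratio_test(_dummy_fit(10.0), _dummy_fit(9.0), df=1)
    with pytest.raises(ValidationError):
        likelihood_ratio_test(a, a, df=0)


def _dummy_fit(minus2ll):
    from her2traffic.inference import FitResult
    return FitResult(free_names=[], theta_log10=np.empty(0), theta={},
                     minus2LL=minus2ll)


def _model_a_objective(truth, schedules, free, sigma_rel=0.01):
    data = signal_dataset(truth, "A", schedules, sigma_rel=sigma_rel)
    return TraffickingObjective("A", truth, data, free)


A_FULL_FREE = ["k_prod", "k_rec", "N_i0", "k_act_T0", "k_diss",
               "k_int_T", "k_rec_T", "k_deg_T", "k_off", "s_c"]


def test_reduction_removes_absent_constitutive_processes(model_a_truth,
                                                         main_schedules):
    """Data simulated without production/degradation and without basal
    trafficking: both removals are accepted, echoing the published chain."""
    truth = replace(model_a_truth, N_i0=0.025)
    obj = _model_a_objective(truth, main_schedules, A_FULL_FREE)
    start = obj.theta_from(replace(truth, k_prod=1e-5, k_rec=1e-4,
                                   N_i0=0.025))
    res = fit(obj, n_starts=2, seed=0, extra_starts=[start], max_nfev=60)
    report = reduce_model(
        obj, res,
        [ReductionCandidate("production_and_degradation", ("k_prod",)),
         ReductionCandidate("basal_internalization_and_recycling",
                            ("k_rec",))],
        n_starts=2, seed=0)
    assert report.removed == ["production_and_degradation",
                              "basal_internalization_and_recycling"]
    assert set(report.objective.free) == set(A_FULL_FREE) - {"k_prod",
                                                             "k_rec"}


def test_reduction_rejects_removal_of_strong_basal_recycling(
        model_a_truth, main_schedules):
    truth = replace(model_a_truth, k_rec=0.5, N_i0=0.04, k_int_T=2.0,
                    k_rec_T=0.0, k_deg_T=0.0)
    free = ["k_rec", "N_i0", "k_act_T0", "k_diss", "k_int_T", "k_off",
            "s_c"]
    obj = _model_a_objective(truth, main_schedules, free)
    res = fit(obj, n_starts=2, seed=0, extra_starts=[obj.theta_from(truth)],
              max_nfev=60)
    report = reduce_model(
        obj, res,
        [ReductionCandidate("basal_recycling", ("k_rec",))],
        n_starts=4, seed=0)
    assert report.removed == []
    assert not report.steps[-1].accepted
    assert report.steps[-1].p_value < 0.05


def test_reduction_with_no_candidates_returns_input(model_b_truth,
                                                    noise_free_main_dataset):
    obj = TraffickingObjective("B", model_b_truth,
                               noise_free_main_dataset, B_FREE)
    res = fit(obj, n_starts=1, seed=0,
              extra_starts=[obj.theta_from(model_b_truth)])
    report = reduce_model(obj, res, [])
    assert report.fit is res and report.steps == [] and report.removed == []


# ---------------------------------------------------------------------------
# scaling symmetry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", ["A", "B"])
def test_freedom_of_scale_leaves_observable_invariant(model):
    params = reference_parameters(model)
    sched = pulse_chase_schedule("before_experiment", drug_min=20,
                                 chase_min=60)
    report = check_scaling_symmetry(model, params, sched)
    assert report["invariant"]
    assert max(report["max_relative_deviation"].values()) <= 1e-10


def test_scale_only_perturbation_is_detected(model_b_truth):
    """Negative control: changing s_c without rescaling the initial
    amounts is not a symmetry."""
    sched = pulse_chase_schedule("before_experiment", drug_min=20)
    base = simulate("B", model_b_truth, sched)
    bumped = simulate("B", replace(model_b_truth, s_c=2 * model_b_truth.s_c),
                      sched, output_times=base.times)
    dev = np.max(np.abs(bumped.observed - base.observed)) / \
        np.max(np.abs(base.observed))
    assert dev > 0.1
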