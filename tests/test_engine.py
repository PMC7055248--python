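"""Engine: prediction errors, free-energy gradients, action, integration."""

import math

import numpy as np
import pytest

from phasematch.engine import (
    AgentState,
    DivergenceError,
    IntegratorOptions,
    ModelSpec,
    PrecisionSpec,
    WorldState,
    action_derivative,
    belief_derivative,
    embed_process_sensory,
    free_energy,
    generalized_predictions,
    integrate_trial,
    prediction_errors,
)
from phasematch.generalized import shift_operator, smoothness_precision
from phasematch.task_model import CONDITION_REGISTRY, build_condition

ORDER = 4


def _generic_model(log_prec=(2.0, 1.5, 2.5), log_px=1.0, prior_mean=0.1):
    """A small nonlinear model exercised through the numerical-derivative path."""

    def flow(x, v, params, a=0.0):
        return np.array([0.3 * x[1] - 0.1 * x[0] + 0.2 * v, -0.25 * x[0] + a])

    def obs(x, v, params):
        return np.array([np.sin(x[0]), np.tanh(x[1]), np.sin(x[1] - v) * 0.8])

    precision = PrecisionSpec(
        log_prec_sensory={"target": log_prec[0], "proprioception": log_prec[1], "vision": log_prec[2]},
        log_prec_states=log_px,
        log_prec_cause_prior=0.5,
        smoothness=0.7,
    )
    return ModelSpec(flow=flow, obs=obs, cause_prior_mean=prior_mean, params={}, precision=precision)


def _random_state(rng, order=ORDER):
    return AgentState(
        {"x_t": rng.normal(0, 0.4, order), "x_h": rng.normal(0, 0.4, order)},
        rng.normal(0, 0.3, order),
    )


def _flat(beliefs):
    return np.concatenate([beliefs.mu_x["x_t"], beliefs.mu_x["x_h"], beliefs.mu_v])


def _unflat(flat, order=ORDER):
    return AgentState({"x_t": flat[:order], "x_h": flat[order : 2 * order]}, flat[2 * order :])


class TestPredictionErrors:
    def test_zero_at_self_generated_input(self, rng):
        """Beliefs that generate the sensory input exactly leave no error."""
        model = _generic_model(prior_mean=0.0)
        beliefs = _random_state(rng)
        G, Fp = generalized_predictions(model, beliefs)
        sensory = {c: G[i] for i, c in enumerate(model.channel_names)}
        # make the state-motion and prior errors vanish too
        D = shift_operator(ORDER)
        for i, s in enumerate(model.state_names):
            beliefs.mu_x[s][1:] = 0.0
        beliefs.mu_v[:] = 0.0
        G, Fp = generalized_predictions(model, beliefs)
        sensory = {c: G[i] for i, c in enumerate(model.channel_names)}
        errors = prediction_errors(model, beliefs, sensory)
        for c in model.channel_names:
            np.testing.assert_allclose(errors.eps_v[c], 0.0, atol=1e-14)

    def test_cause_prior_error_is_offset_from_prior_mean(self):
        cond = build_condition("VH", "incong")
        model = cond.model()  # prior mean 0
        beliefs = cond.initial_agent(ORDER)  # mu_v starts at 0.35
        sensory = {c: np.zeros(ORDER) for c in model.channel_names}
        errors = prediction_errors(model, beliefs, sensory)
        assert errors.eps_prior[0] == pytest.approx(0.35)

    def test_matches_directly_coded_error_equations(self, rng):
        """Independent direct evaluation of the error definitions."""
        model = _generic_model()
        beliefs = _random_state(rng)
        sensory = {c: rng.normal(0, 0.5, ORDER) for c in model.channel_names}
        errors = prediction_errors(model, beliefs, sensory)

        # oracle: direct first-order generalized evaluation, coded separately
        mu_x = np.array([beliefs.mu_x["x_t"], beliefs.mu_x["x_h"]])
        mu_v = beliefs.mu_v
        x0, v0 = mu_x[:, 0], mu_v[0]
        h = 1e-7

        def jac(f, x):
            return np.column_stack(
                [(f(x + dx) - f(x - dx)) / (2 * h) for dx in (h * np.eye(x.size))]
            )

        g0 = model.obs(x0, v0, {})
        f0 = model.flow(x0, v0, {})
        Jgx = jac(lambda xx: model.obs(xx, v0, {}), x0)
        Jgv = (model.obs(x0, v0 + h, {}) - model.obs(x0, v0 - h, {})) / (2 * h)
        Jfx = jac(lambda xx: model.flow(xx, v0, {}), x0)
        Jfv = (model.flow(x0, v0 + h, {}) - model.flow(x0, v0 - h, {})) / (2 * h)
        for i, c in enumerate(model.channel_names):
            pred = np.concatenate(
                [[g0[i]], Jgx[i] @ mu_x[:, 1:] + Jgv[i] * mu_v[1:]]
            )
            np.testing.assert_allclose(errors.eps_v[c], sensory[c] - pred, atol=1e-6)
        D = shift_operator(ORDER)
        for i, s in enumerate(model.state_names):
            pred = np.concatenate([[f0[i]], Jfx[i] @ mu_x[:, 1:] + Jfv[i] * mu_v[1:]])
            np.testing.assert_allclose(errors.eps_x[s], D @ mu_x[i] - pred, atol=1e-6)
        exp_prior = mu_v.copy()
        exp_prior[0] -= model.cause_prior_mean
        np.testing.assert_allclose(errors.eps_prior, exp_prior)

    def test_order_mismatch_rejected(self, rng):
        model = _generic_model()
        beliefs = _random_state(rng)
        sensory = {c: np.zeros(ORDER + 1) for c in model.channel_names}
        with pytest.raises(ValueError, match="order"):
            prediction_errors(model, beliefs, sensory)


class TestBeliefDerivative:
    def test_pure_prediction_at_zero_errors(self, rng):
        """With all errors zero the update reduces to the shift prediction."""
        # static hidden states (zero flow) admit an exact fixed point
        model = _generic_model(prior_mean=0.0)
        model.flow = lambda x, v, params, a=0.0: np.zeros(2)
        model.jac_flow_x = lambda x, v, params: np.zeros((2, 2))
        model.jac_flow_v = lambda x, v, params: np.zeros(2)
        beliefs = _random_state(rng)
        beliefs.mu_v[:] = 0.0
        for s in model.state_names:
            beliefs.mu_x[s][1:] = 0.0
        G, _ = generalized_predictions(model, beliefs)
        sensory = {c: G[i] for i, c in enumerate(model.channel_names)}
        errors = prediction_errors(model, beliefs, sensory)
        assert max(np.abs(e).max() for e in errors.eps_x.values()) < 1e-14
        dmu_x, dmu_v = belief_derivative(model, beliefs, errors)
        D = shift_operator(ORDER)
        for s in model.state_names:
            np.testing.assert_allclose(dmu_x[s], D @ beliefs.mu_x[s], atol=1e-10)
        np.testing.assert_allclose(dmu_v, D @ beliefs.mu_v, atol=1e-10)

    def test_precision_weighting_is_linear_in_errors(self, rng):
        """Doubling one channel's precision doubles its additive contribution."""
        beliefs = _random_state(rng)
        base = _generic_model()
        boosted = _generic_model(log_prec=(2.0 + math.log(2), 1.5, 2.5))
        sensory = {c: rng.normal(0, 0.5, ORDER) for c in base.channel_names}
        err = prediction_errors(base, beliefs, sensory)
        # zero out everything except the target channel to isolate its term
        for c in ("proprioception", "vision"):
            err.eps_v[c] = np.zeros(ORDER)
        for s in base.state_names:
            err.eps_x[s] = np.zeros(ORDER)
        err.eps_prior = np.zeros(ORDER)
        D = shift_operator(ORDER)

        def error_part(model):
            dmu_x, dmu_v = belief_derivative(model, beliefs, err)
            return np.concatenate(
                [dmu_x[s] - D @ beliefs.mu_x[s] for s in model.state_names]
                + [dmu_v - D @ beliefs.mu_v]
            )

        np.testing.assert_allclose(error_part(boosted), 2 * error_part(base), rtol=1e-10)

    @pytest.mark.parametrize("which", ["generic", "task"])
    def test_equals_negative_free_energy_gradient(self, rng, which):
        """Error-driven part equals -dF/dmu by central finite differences."""
        if which == "generic":
            model = _generic_model()
            sensory = {c: rng.normal(0, 0.5, ORDER) for c in model.channel_names}
        else:
            cond = build_condition("VH", "incong", "HA")
            model = cond.model()
            world = WorldState(x=rng.normal(0, 0.5, 2), v_true=0.35, a=0.1)
            sensory = embed_process_sensory(cond.process(), world, ORDER)
        beliefs = _random_state(rng)
        errors = prediction_errors(model, beliefs, sensory)
        dmu_x, dmu_v = belief_derivative(model, beliefs, errors)
        D = shift_operator(ORDER)
        err_part = np.concatenate(
            [dmu_x[s] - D @ beliefs.mu_x[s] for s in model.state_names]
            + [dmu_v - D @ beliefs.mu_v]
        )
        flat0 = _flat(beliefs)
        grad = np.zeros_like(flat0)
        h = 1e-6
        for i in range(flat0.size):
            up, dn = flat0.copy(), flat0.copy()
            up[i] += h
            dn[i] -= h
            Fu = free_energy(prediction_errors(model, _unflat(up), sensory), model)
            Fd = free_energy(prediction_errors(model, _unflat(dn), sensory), model)
            grad[i] = (Fu - Fd) / (2 * h)
        np.testing.assert_allclose(err_part, -grad, rtol=1e-5, atol=1e-7 * np.abs(grad).max())


class TestActionDerivative:
    def test_zero_without_sensory_error(self):
        cond = build_condition("VH", "cong")
        proc, model = cond.process(), cond.model()
        world = WorldState(x=np.array([0.3, 0.3]), v_true=0.0, a=0.05)
        errors = prediction_errors(
            model, cond.initial_agent(ORDER), embed_process_sensory(proc, world, ORDER)
        )
        for c in model.channel_names:
            errors.eps_v[c] = np.zeros(ORDER)
        assert action_derivative(proc, model, errors, world) == 0.0

    def test_target_channel_is_not_controllable(self, rng):
        """Errors confined to the target channel cannot drive action."""
        cond = build_condition("RH", "incong")
        proc, model = cond.process(), cond.model()
        world = WorldState(x=rng.normal(0, 0.5, 2), v_true=0.35, a=0.02)
        errors = prediction_errors(
            model, _random_state(rng), embed_process_sensory(proc, world, ORDER)
        )
        errors.eps_v["proprioception"] = np.zeros(ORDER)
        errors.eps_v["vision"] = np.zeros(ORDER)
        assert action_derivative(proc, model, errors, world) == pytest.approx(0.0, abs=1e-12)

    def test_matches_free_energy_gradient_through_process(self, rng):
        cond = build_condition("VH", "incong", "HD")
        proc, model = cond.process(), cond.model()
        world = WorldState(x=rng.normal(0, 0.5, 2), v_true=0.35, a=0.07)
        beliefs = _random_state(rng)
        errors = prediction_errors(model, beliefs, embed_process_sensory(proc, world, ORDER))
        da = action_derivative(proc, model, errors, world)
        h = 1e-6

        def F_at(a):
            w = WorldState(x=world.x, v_true=world.v_true, a=a)
            return free_energy(
                prediction_errors(model, beliefs, embed_process_sensory(proc, w, ORDER)), model
            )

        fd = (F_at(world.a + h) - F_at(world.a - h)) / (2 * h)
        assert da == pytest.approx(-fd, rel=1e-6)


class TestFreeEnergy:
    def test_zero_iff_no_errors(self, rng):
        model = _generic_model()
        zero = {
            "eps_v": {c: np.zeros(ORDER) for c in model.channel_names},
            "eps_x": {s: np.zeros(ORDER) for s in model.state_names},
        }
        from phasematch.engine import ErrorSet

        errors = ErrorSet(zero["eps_v"], zero["eps_x"], np.zeros(ORDER))
        assert free_energy(errors, model) == 0.0
        errors.eps_v["target"] = np.array([0.1, 0, 0, 0])
        assert free_energy(errors, model) > 0

    def test_single_scalar_error_is_half_precision_times_square(self):
        model = _generic_model()
        from phasematch.engine import ErrorSet

        e = 0.3
        errors = ErrorSet(
            {c: np.zeros(1) for c in model.channel_names},
            {s: np.zeros(1) for s in model.state_names},
            np.zeros(1),
        )
        errors.eps_v["target"] = np.array([e])
        p = math.exp(2.0) * smoothness_precision(1, 0.7)[0, 0]
        assert free_energy(errors, model) == pytest.approx(0.5 * p * e**2)

    def test_quadratic_scaling(self, rng):
        model = _generic_model()
        beliefs = _random_state(rng)
        sensory = {c: rng.normal(0, 0.5, ORDER) for c in model.channel_names}
        errors = prediction_errors(model, beliefs, sensory)
        F1 = free_energy(errors, model)
        for c in model.channel_names:
            errors.eps_v[c] = 2 * errors.eps_v[c]
        for s in model.state_names:
            errors.eps_x[s] = 2 * errors.eps_x[s]
        errors.eps_prior = 2 * errors.eps_prior
        assert free_energy(errors, model) == pytest.approx(4 * F1)


class TestIntegrateTrial:
    def test_zero_duration_echoes_initial_conditions(self):
        cond = build_condition("VH", "cong")
        trace = integrate_trial(
            cond.process(), cond.initial_world(), cond.model(), cond.initial_agent(), 0.0, 1.0
        )
        assert len(trace) == 1
        assert trace.data["x_t"].iloc[0] == 0.0
        assert trace.data["a"].iloc[0] == 0.0

    def test_record_count_is_duration_over_dt_plus_one(self):
        cond = build_condition("VH", "cong")
        trace = integrate_trial(
            cond.process(), cond.initial_world(), cond.model(), cond.initial_agent(),
            duration=2.0, dt=1.0 / 120.0,
        )
        assert len(trace) == 241

    def test_non_multiple_duration_rejected(self):
        cond = build_condition("VH", "cong")
        with pytest.raises(ValueError, match="multiple"):
            integrate_trial(
                cond.process(), cond.initial_world(), cond.model(), cond.initial_agent(), 1.05, 0.5
            )

    def test_determinism_is_bitwise(self):
        cond = build_condition("RH", "incong", "HA")
        args = (cond.process(), cond.initial_world(), cond.model(), cond.initial_agent())
        t1 = integrate_trial(*args, duration=120.0, dt=1.0)
        t2 = integrate_trial(*args, duration=120.0, dt=1.0)
        assert t1.data.equals(t2.data)

    def test_divergence_guard_names_the_step(self):
        cond = build_condition("VH", "cong")
        world = WorldState(x=np.zeros(2), v_true=0.0, a=1e7)  # beyond the guard
        with pytest.raises(DivergenceError, match="step 0"):
            integrate_trial(cond.process(), world, cond.model(), cond.initial_agent(), 10.0, 1.0)

    def test_euler_fallback_runs(self):
        # explicit Euler needs a small effective step for these stiff
        # precision-weighted dynamics; a tiny gain keeps it in its domain
        cond = build_condition("VH", "cong")
        opts = IntegratorOptions(integrator="euler", update_gain=1e-4, action_gain=1e-4)
        trace = integrate_trial(
            cond.process(), cond.initial_world(), cond.model(), cond.initial_agent(),
            duration=30.0, dt=1.0, options=opts,
        )
        assert len(trace) == 31
        assert np.all(np.isfinite(trace.data["F"]))


class TestTraceSerialization:
    def test_csv_round_trip(self, tmp_path, condition_traces):
        trace = condition_traces("vh_cong")["vh_cong"]
        p = tmp_path / "trace.csv"
        trace.to_csv(p)
        back = type(trace).from_csv(p)
        np.testing.assert_allclose(
            back.data["mu_xh"].to_numpy(), trace.data["mu_xh"].to_numpy(), rtol=1e-12
        )

    def test_hdf5_round_trip_preserves_metadata(self, tmp_path, condition_traces):
        trace = condition_traces("vh_cong")["vh_cong"]
        p = tmp_path / "trace.h5"
        trace.to_hdf5(p)
        back = type(trace).from_hdf5(p)
        assert back.meta["condition"]["instruction"] == "VH"
        np.testing.assert_allclose(back.data["F"].to_numpy(), trace.data["F"].to_numpy())
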