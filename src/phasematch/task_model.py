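"""Generative process and model of the hand-target phase-matching task.

The world has two hidden states: the target state ``x_t``, driven at a
constant rate so that its sensory mapping ``sin(x_t)`` oscillates at about
0.5 Hz, and the hand state ``x_h``, driven by action through a short motor
time constant.  Sensory input has three channels: the target's size
(``sin(x_t)``), the felt (proprioceptive) hand posture (``sin(x_h)``) and the
seen (visual) hand posture (``sin(x_h - v)``), where the hidden cause ``v``
is the visuo-proprioceptive displacement (0 when seen and felt hands are
congruent, 0.35 rad when vision is delayed).

The agent's generative model has the same sensory form with the believed
cause in place of the true one, no action, and a hand state driven by the
hand-target displacement: ``x_t - x_h`` under the real-hand instruction and
``x_t - (x_h - v)`` under the virtual-hand instruction (the perceived visual
delay must then also be compensated).  Attention is modelled as a +1 shift
of the log-precision of the instructed (high attention, HA) or of the
non-instructed (high distraction, HD) hand modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .engine import AgentState, IntegratorOptions, ModelSpec, PrecisionSpec, SimulationTrace, WorldState, integrate_trial
from .generalized import taylor_jacobian, taylor_shift_scale, taylor_sin_cos

__all__ = [
    "TaskParams",
    "ConditionSpec",
    "process_equations",
    "model_equations",
    "build_condition",
    "run_condition",
    "CONDITION_REGISTRY",
    "IDEAL_CONDITIONS",
    "REALISTIC_INCONG_CONDITIONS",
    "DEFAULT_LOG_PREC_STATES",
    "DEFAULT_LOG_PREC_TARGET",
    "DEFAULT_SMOOTHNESS_BINS",
    "DEFAULT_ORDER",
]

# Model-side constants that the task description leaves open.  The state
# motion log-precision sets how strongly the agent holds on to its believed
# dynamics (the task instruction); the target channel keeps the default
# visual log-precision and is never touched by the attention presets.  The
# smoothness of the assumed fluctuations is half a time bin (the classical
# generalized-filtering default), and belief/action updates run at a quarter
# of a free-energy gradient unit per bin -- fast enough for tight tracking,
# slow enough that the motion prior carries beliefs through the momentarily
# ambiguous peaks of the sinusoidal sensory mapping.
DEFAULT_LOG_PREC_STATES = 3.0
DEFAULT_LOG_PREC_TARGET = 4.0
DEFAULT_SMOOTHNESS_BINS = 0.5
DEFAULT_ORDER = 4
DEFAULT_UPDATE_GAIN = 0.25

INSTRUCTIONS = ("VH", "RH")
CONGRUENCES = ("cong", "incong")
ATTENTIONS = ("default", "HA", "HD")
BELIEF_PRESETS = ("congruent_prior", "ideal_incongruent_prior")


@dataclass
class TaskParams:
    """Constants of the simulated task, in the units the task is stated in.

    ``t_t`` is the target drive rate in radians per time bin, ``t_a`` the
    motor time constant in seconds, ``dt`` the time bin in seconds,
    ``v_true`` the visuo-proprioceptive displacement in radians and
    ``a_rate`` the nominal (stationary) action scale per time bin, used only
    for normalizing and plotting action.
    """

    t_t: float = 1.0 / 40.0
    t_a: float = 1.0 / 60.0
    dt: float = 1.0 / 120.0
    v_true: float = 0.0
    a_rate: float = 0.05
    trial_duration: float = 14.0

    def __post_init__(self):
        if min(self.t_t, self.t_a, self.dt, self.a_rate, self.trial_duration) <= 0:
            raise ValueError("task rate/time constants must be positive")
        if self.v_true < 0:
            raise ValueError("v_true must be non-negative")

    @property
    def t_a_bins(self) -> float:
        """Motor time constant in time bins (the engine's time unit)."""
        return self.t_a / self.dt

    @property
    def omega(self) -> float:
        """Angular frequency of the target oscillation in rad/s."""
        return self.t_t / self.dt

    @property
    def f_target(self) -> float:
        """Target oscillation frequency in Hz (~0.48 Hz for the defaults)."""
        return self.omega / (2 * math.pi)

    @property
    def displacement_seconds(self) -> float:
        """The true displacement expressed as a temporal delay in seconds."""
        return self.v_true / self.omega


def _sin_embed(phase_rows):
    """Exact generalized embedding of sinusoidal channels (Taylor series)."""
    return np.array([taylor_sin_cos(u)[0] for u in phase_rows])


def process_equations(params: TaskParams) -> ModelSpec:
    """The generative process: true world dynamics and sensory mapping.

    Flows are expressed per time bin: the target advances at ``t_t`` and the
    hand at ``a / (t_a/dt)``; the sensory mapping is
    ``(sin(x_t), sin(x_h), sin(x_h - v))`` with ``v`` the true displacement.
    Random fluctuations are suppressed (log-precision 16 on all process error
    terms), so generation is noise-free -- the single simulated movement
    stands in for an average over realizations.
    """
    p = {"t_t": params.t_t, "t_a_bins": params.t_a_bins}

    def flow(x, v, par, a=0.0):
        return np.array([par["t_t"], a / par["t_a_bins"]])

    def obs(x, v, par):
        return np.array([math.sin(x[0]), math.sin(x[1]), math.sin(x[1] - v)])

    def obs_embed(X, v, par):
        return _sin_embed([X[0], X[1], taylor_shift_scale(X[1], offset=-v)])

    precision = PrecisionSpec(
        log_prec_sensory={"target": 16.0, "proprioception": 16.0, "vision": 16.0},
        log_prec_states=16.0,
        log_prec_cause_prior=16.0,
        smoothness=DEFAULT_SMOOTHNESS_BINS,
    )
    return ModelSpec(
        flow=flow,
        obs=obs,
        cause_prior_mean=0.0,
        params=p,
        precision=precision,
        jac_flow_x=lambda x, v, par: np.zeros((2, 2)),
        jac_flow_v=lambda x, v, par: np.zeros(2),
        jac_obs_x=_sin_jac_x,
        jac_obs_v=_sin_jac_v,
        hess_obs_xx=_sin_hess_xx,
        hess_obs_xv=_sin_hess_xv,
        hess_obs_vv=_sin_hess_vv,
        hess_flow_xx=lambda x, v, par: np.zeros((2, 2, 2)),
        hess_flow_xv=lambda x, v, par: np.zeros((2, 2)),
        hess_flow_vv=lambda x, v, par: np.zeros(2),
        obs_embed=obs_embed,
        flow_da=lambda x, v, par, a=0.0: np.array([0.0, 1.0 / par["t_a_bins"]]),
    )


# Channel phases: u_target = x_t, u_prop = x_h, u_vis = x_h - v.
# alpha maps states to phases, beta maps the cause.
_ALPHA = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
_BETA = np.array([0.0, 0.0, -1.0])


def _phases(x, v):
    return _ALPHA @ np.asarray(x, float) + _BETA * v


def _sin_jac_x(x, v, par):
    return np.cos(_phases(x, v))[:, None] * _ALPHA


def _sin_jac_v(x, v, par):
    return np.cos(_phases(x, v)) * _BETA


def _sin_hess_xx(x, v, par):
    s = np.sin(_phases(x, v))
    return -s[:, None, None] * np.einsum("ci,cj->cij", _ALPHA, _ALPHA)


def _sin_hess_xv(x, v, par):
    s = np.sin(_phases(x, v))
    return -s[:, None] * _ALPHA * _BETA[:, None]


def _sin_hess_vv(x, v, par):
    return -np.sin(_phases(x, v)) * _BETA**2


def model_equations(
    params: TaskParams,
    instruction: str,
    precision: Optional[PrecisionSpec] = None,
    cause_prior_mean: float = 0.0,
) -> ModelSpec:
    """The agent's generative model under one task instruction.

    Under 'RH' the believed hand state is driven by ``x_t - x_h``; under
    'VH' by ``x_t - (x_h - v)`` so that a perceived visual delay is
    compensated to keep the seen hand on target.  The sensory form matches
    the process with the believed cause in place of the true displacement.
    """
    if instruction not in INSTRUCTIONS:
        raise ValueError(f"unknown instruction {instruction!r}; expected one of {INSTRUCTIONS}")
    p = {"t_t": params.t_t}
    vh = instruction == "VH"

    def flow(x, v, par, a=0.0):
        drive = x[0] - x[1] + (v if vh else 0.0)
        return np.array([par["t_t"], drive])

    def obs(x, v, par):
        return np.array([math.sin(x[0]), math.sin(x[1]), math.sin(x[1] - v)])

    if precision is None:
        precision = default_precisions("default", instruction)
    jac_flow_x = lambda x, v, par: np.array([[0.0, 0.0], [1.0, -1.0]])
    jac_flow_v = lambda x, v, par: np.array([0.0, 1.0 if vh else 0.0])

    def obs_embed_mu(mu_x, mu_v, par):
        # exact generalized predictions: sinusoid series of the channel
        # phases u_t = mu_xt, u_p = mu_xh, u_v = mu_xh - mu_v
        phases = (mu_x[0], mu_x[1], mu_x[1] - mu_v)
        return np.array([taylor_sin_cos(u)[0] for u in phases])

    def obs_embed_mu_jac(mu_x, mu_v, par):
        n = mu_v.size
        A = np.zeros((3 * n, 3 * n))
        phases = (mu_x[0], mu_x[1], mu_x[1] - mu_v)
        # phase composition per channel: (state coefficients, cause coefficient)
        comp = (((1.0, 0.0), 0.0), ((0.0, 1.0), 0.0), ((0.0, 1.0), -1.0))
        for c, (u, (alphas, beta)) in enumerate(zip(phases, comp)):
            T = taylor_jacobian(taylor_sin_cos(u)[1])  # multiplier cos(u)
            rows = slice(c * n, (c + 1) * n)
            for j, alpha in enumerate(alphas):
                if alpha:
                    A[rows, j * n : (j + 1) * n] = alpha * T
            if beta:
                A[rows, 2 * n : 3 * n] = beta * T
        return A

    return ModelSpec(
        flow=flow,
        obs=obs,
        cause_prior_mean=cause_prior_mean,
        params=p,
        precision=precision,
        jac_flow_x=jac_flow_x,
        jac_flow_v=jac_flow_v,
        jac_obs_x=_sin_jac_x,
        jac_obs_v=_sin_jac_v,
        hess_obs_xx=_sin_hess_xx,
        hess_obs_xv=_sin_hess_xv,
        hess_obs_vv=_sin_hess_vv,
        hess_flow_xx=lambda x, v, par: np.zeros((2, 2, 2)),
        hess_flow_xv=lambda x, v, par: np.zeros((2, 2)),
        hess_flow_vv=lambda x, v, par: np.zeros(2),
        obs_embed_mu=obs_embed_mu,
        obs_embed_mu_jac=obs_embed_mu_jac,
    )


def default_precisions(attention: str, instruction: str) -> PrecisionSpec:
    """Sensory log-precisions (prop, vis) = (3, 4) with attentional shifts.

    'HA' adds +1 to the instructed hand modality's channel, 'HD' adds +1 to
    the non-instructed one; the target channel is never modified.
    """
    if attention not in ATTENTIONS:
        raise ValueError(f"unknown attention preset {attention!r}")
    if instruction not in INSTRUCTIONS:
        raise ValueError(f"unknown instruction {instruction!r}")
    log_prop, log_vis = 3.0, 4.0
    instructed = "vision" if instruction == "VH" else "proprioception"
    boosted = None
    if attention == "HA":
        boosted = instructed
    elif attention == "HD":
        boosted = "proprioception" if instructed == "vision" else "vision"
    if boosted == "vision":
        log_vis += 1.0
    elif boosted == "proprioception":
        log_prop += 1.0
    return PrecisionSpec(
        log_prec_sensory={
            "target": DEFAULT_LOG_PREC_TARGET,
            "proprioception": log_prop,
            "vision": log_vis,
        },
        log_prec_states=DEFAULT_LOG_PREC_STATES,
        log_prec_cause_prior=3.0,
        smoothness=DEFAULT_SMOOTHNESS_BINS,
    )


@dataclass
class ConditionSpec:
    """Full parameterization of one simulated condition."""

    instruction: str
    congruence: str
    attention: str = "default"
    belief_preset: str = "congruent_prior"
    params: TaskParams = field(default_factory=TaskParams)
    precisions: PrecisionSpec = None  # filled by build_condition
    mu_v_init: float = 0.0
    name: Optional[str] = None

    def process(self) -> ModelSpec:
        return process_equations(self.params)

    def model(self) -> ModelSpec:
        prior_mean = self.params.v_true if self.belief_preset == "ideal_incongruent_prior" else 0.0
        return model_equations(self.params, self.instruction, self.precisions, prior_mean)

    def initial_world(self) -> WorldState:
        return WorldState(x=np.zeros(2), v_true=self.params.v_true, a=0.0)

    def initial_agent(self, order: int = DEFAULT_ORDER) -> AgentState:
        """Beliefs at the prior means with flow-consistent motion.

        Order 0 sits at the prior means (states at 0, cause at the
        condition's initial value); the velocity order is set to the model's
        believed flow there, so the agent starts out expecting the task
        dynamics it is familiar with (the world still starts at rest, which
        produces the initiation transient).
        """
        mu_v = np.zeros(order)
        mu_v[0] = self.mu_v_init
        mu_x = {"x_t": np.zeros(order), "x_h": np.zeros(order)}
        if order > 1:
            f0 = self.model()._flow(np.zeros(2), self.mu_v_init)
            mu_x["x_t"][1] = f0[0]
            mu_x["x_h"][1] = f0[1]
        return AgentState(mu_x, mu_v)

    def to_dict(self) -> dict:
        return {
            "instruction": self.instruction,
            "congruence": self.congruence,
            "attention": self.attention,
            "belief_preset": self.belief_preset,
            "mu_v_init": self.mu_v_init,
            "name": self.name,
            "params": {
                "t_t": self.params.t_t,
                "t_a": self.params.t_a,
                "dt": self.params.dt,
                "v_true": self.params.v_true,
                "a_rate": self.params.a_rate,
                "trial_duration": self.params.trial_duration,
            },
            "precisions": {
                "log_prec_sensory": dict(self.precisions.log_prec_sensory),
                "log_prec_states": self.precisions.log_prec_states,
                "log_prec_cause_prior": self.precisions.log_prec_cause_prior,
                "smoothness": self.precisions.smoothness,
            },
        }

    @staticmethod
    def from_dict(d: dict) -> "ConditionSpec":
        params = TaskParams(**d["params"])
        prec = PrecisionSpec(**d["precisions"])
        return ConditionSpec(
            instruction=d["instruction"],
            congruence=d["congruence"],
            attention=d["attention"],
            belief_preset=d["belief_preset"],
            params=params,
            precisions=prec,
            mu_v_init=d["mu_v_init"],
            name=d.get("name"),
        )


def build_condition(
    instruction: str,
    congruence: str,
    attention: str = "default",
    belief_preset: str = "congruent_prior",
    params: Optional[TaskParams] = None,
    name: Optional[str] = None,
) -> ConditionSpec:
    """Assemble a fully parameterized condition from the factorial design.

    ``v_true = 0.35`` iff incongruent; the initial cause belief carries the
    condition information (0 congruent, 0.35 incongruent); the ideal belief
    preset moves the cause-prior mean onto the true displacement.
    """
    if congruence not in CONGRUENCES:
        raise ValueError(f"unknown congruence {congruence!r}")
    if belief_preset not in BELIEF_PRESETS:
        raise ValueError(f"unknown belief preset {belief_preset!r}")
    v_true = 0.35 if congruence == "incong" else 0.0
    base = params or TaskParams()
    task = replace(base, v_true=v_true)
    prec = default_precisions(attention, instruction)
    mu_v_init = 0.35 if congruence == "incong" else 0.0
    return ConditionSpec(
        instruction=instruction,
        congruence=congruence,
        attention=attention,
        belief_preset=belief_preset,
        params=task,
        precisions=prec,
        mu_v_init=mu_v_init,
        name=name,
    )


def _registry() -> Dict[str, ConditionSpec]:
    reg: Dict[str, ConditionSpec] = {}

    def add(name, *args, **kw):
        reg[name] = build_condition(*args, name=name, **kw)

    for instr in INSTRUCTIONS:
        low = instr.lower()
        add(f"{low}_cong", instr, "cong")
        add(f"{low}_incong", instr, "incong")
        add(f"{low}_incong_ha", instr, "incong", attention="HA")
        add(f"{low}_incong_hd", instr, "incong", attention="HD")
        # ideal-belief conditions: congruent ones coincide with the realistic
        # congruent conditions; incongruent ones adopt the ideal prior
        add(f"{low}_cong_ideal", instr, "cong")
        add(f"{low}_incong_ideal", instr, "incong", belief_preset="ideal_incongruent_prior")
    return reg


CONDITION_REGISTRY: Dict[str, ConditionSpec] = _registry()
IDEAL_CONDITIONS: Tuple[str, ...] = (
    "vh_cong_ideal", "rh_cong_ideal", "vh_incong_ideal", "rh_incong_ideal",
)
REALISTIC_INCONG_CONDITIONS: Tuple[str, ...] = (
    "vh_incong", "rh_incong", "vh_incong_ha", "rh_incong_ha", "vh_incong_hd", "rh_incong_hd",
)


def run_condition(
    condition: ConditionSpec,
    order: int = DEFAULT_ORDER,
    duration: Optional[float] = None,
    options: Optional[IntegratorOptions] = None,
) -> SimulationTrace:
    """Simulate one trial of a condition; time in the trace is in seconds."""
    params = condition.params
    dur_s = params.trial_duration if duration is None else duration
    n_bins = round(dur_s / params.dt)
    opts = options or IntegratorOptions(update_gain=DEFAULT_UPDATE_GAIN, action_gain=DEFAULT_UPDATE_GAIN)
    opts = replace(opts, time_unit_seconds=params.dt)
    trace = integrate_trial(
        condition.process(),
        condition.initial_world(),
        condition.model(),
        condition.initial_agent(order),
        duration=float(n_bins),
        dt=1.0,
        options=opts,
    )
    trace.meta.update(
        condition=condition.to_dict(),
        f_target=params.f_target,
        fs=1.0 / params.dt,
        displacement_seconds=params.displacement_seconds,
    )
    return trace
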