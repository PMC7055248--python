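"""Generalized-coordinate predictive-coding engine with an action channel.

The engine integrates the coupled dynamics of a *generative process* (the
world: hidden states driven by action, emitting noise-free sensory input) and
an *agent* whose beliefs follow a gradient descent on variational free energy
(generalized filtering / predictive coding), while action descends the free
energy gradient through the true sensory mapping.

Conventions
-----------
* All dynamical quantities live in generalized coordinates of motion: a
  variable is a vector of its temporal derivatives up to the embedding order.
* Time units are those of the model's flow functions: ``duration`` and ``dt``
  passed to :func:`integrate_trial` must use the same unit.  The
  ``time_unit_seconds`` integrator option only rescales the time column of
  the recorded trace.
* Free energy is reported as the sum of precision-weighted squared errors,
  ``F = 1/2 * sum(eps' Pi eps)``; the log-determinant terms are constant with
  respect to beliefs and action under fixed precisions and are omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .generalized import shift_operator, smoothness_precision

__all__ = [
    "PrecisionSpec",
    "ModelSpec",
    "WorldState",
    "AgentState",
    "ErrorSet",
    "SimulationTrace",
    "IntegratorOptions",
    "DivergenceError",
    "NumericalError",
    "prediction_errors",
    "generalized_predictions",
    "belief_derivative",
    "action_derivative",
    "free_energy",
    "embed_process_sensory",
    "integrate_trial",
]

_FD_STEP = 1e-6


class DivergenceError(RuntimeError):
    """Raised when the integrated system leaves the admissible range."""


class NumericalError(RuntimeError):
    """Raised on singular or non-finite Jacobians during belief updating."""


# ---------------------------------------------------------------------------
# Specifications and state containers


@dataclass
class PrecisionSpec:
    """Log-precisions of the model's error terms and the assumed smoothness.

    Parameters
    ----------
    log_prec_sensory
        Log-precision per sensory channel.
    log_prec_states
        Log-precision of the motion of hidden states.
    log_prec_cause_prior
        Log-precision of the static Gaussian prior on the hidden cause.
    smoothness
        Temporal correlation length of the assumed fluctuations, in the
        model's time unit; expands scalar precisions over generalized orders.
    """

    log_prec_sensory: Dict[str, float]
    log_prec_states: float
    log_prec_cause_prior: float
    smoothness: float

    def sensory_precision(self, channel: str) -> float:
        return math.exp(self.log_prec_sensory[channel])

    def _key(self, channels: Tuple[str, ...]) -> tuple:
        return (
            tuple((c, float(self.log_prec_sensory[c])) for c in channels),
            float(self.log_prec_states),
            float(self.log_prec_cause_prior),
            float(self.smoothness),
        )


@dataclass
class ModelSpec:
    """A single-level generative model (or process) with one hidden cause.

    ``flow(x, v, params, a=0.0)`` returns the state velocities and
    ``obs(x, v, params)`` the sensory values; both must be differentiable at
    every evaluated point.  Closed-form Jacobians/Hessians may be supplied;
    otherwise central finite differences are used.  ``obs_embed`` optionally
    provides an exact generalized (Taylor) embedding of the sensory mapping
    along a state trajectory; the default embedding is first order.
    """

    flow: Callable[..., np.ndarray]
    obs: Callable[..., np.ndarray]
    cause_prior_mean: float
    params: Dict[str, float]
    precision: PrecisionSpec
    state_names: Tuple[str, ...] = ("x_t", "x_h")
    channel_names: Tuple[str, ...] = ("target", "proprioception", "vision")
    jac_flow_x: Optional[Callable] = None
    jac_flow_v: Optional[Callable] = None
    jac_obs_x: Optional[Callable] = None
    jac_obs_v: Optional[Callable] = None
    hess_obs_xx: Optional[Callable] = None
    hess_obs_xv: Optional[Callable] = None
    hess_obs_vv: Optional[Callable] = None
    hess_flow_xx: Optional[Callable] = None
    hess_flow_xv: Optional[Callable] = None
    hess_flow_vv: Optional[Callable] = None
    obs_embed: Optional[Callable] = None
    flow_da: Optional[Callable] = None
    #: exact generalized sensory prediction from generalized beliefs
    #: ``obs_embed_mu(mu_x (nx, n), mu_v (n,), params) -> (nc, n)`` and its
    #: analytic Jacobian w.r.t. the flat belief vector (states then cause),
    #: ``obs_embed_mu_jac(mu_x, mu_v, params) -> (nc*n, (nx+1)*n)``; when
    #: absent, predictions use the first-order chain-rule expansion around
    #: the order-0 beliefs with exact (Hessian-corrected) gradients
    obs_embed_mu: Optional[Callable] = None
    obs_embed_mu_jac: Optional[Callable] = None

    # -- derivative accessors (closed form if given, else finite differences)

    def _flow(self, x, v, a=0.0):
        return np.asarray(self.flow(x, v, self.params, a), dtype=float)

    def _obs(self, x, v):
        return np.asarray(self.obs(x, v, self.params), dtype=float)

    def flow_jac_x(self, x, v, a=0.0):
        if self.jac_flow_x is not None:
            return np.asarray(self.jac_flow_x(x, v, self.params), dtype=float)
        return _fd_jac(lambda xx: self._flow(xx, v, a), np.asarray(x, float))

    def flow_jac_v(self, x, v, a=0.0):
        if self.jac_flow_v is not None:
            return np.asarray(self.jac_flow_v(x, v, self.params), dtype=float)
        return _fd_scalar(lambda vv: self._flow(x, vv, a), v)

    def obs_jac_x(self, x, v):
        if self.jac_obs_x is not None:
            return np.asarray(self.jac_obs_x(x, v, self.params), dtype=float)
        return _fd_jac(lambda xx: self._obs(xx, v), np.asarray(x, float))

    def obs_jac_v(self, x, v):
        if self.jac_obs_v is not None:
            return np.asarray(self.jac_obs_v(x, v, self.params), dtype=float)
        return _fd_scalar(lambda vv: self._obs(x, vv), v)

    def obs_hess(self, x, v):
        """Second derivatives of obs: (d2/dxdx, d2/dxdv, d2/dvdv)."""
        x = np.asarray(x, float)
        nx = x.size
        if self.hess_obs_xx is not None:
            hxx = np.asarray(self.hess_obs_xx(x, v, self.params), float)
        else:
            cols = [_fd_jac(lambda xx: self.obs_jac_x(xx, v)[:, j], x) for j in range(nx)]
            hxx = np.stack(cols, axis=1)  # (nc, j, i) -> symmetric
        if self.hess_obs_xv is not None:
            hxv = np.asarray(self.hess_obs_xv(x, v, self.params), float)
        else:
            hxv = _fd_jac(lambda xx: self.obs_jac_v(xx, v), x)
        if self.hess_obs_vv is not None:
            hvv = np.asarray(self.hess_obs_vv(x, v, self.params), float)
        else:
            hvv = _fd_scalar(lambda vv: self.obs_jac_v(x, vv), v)
        return hxx, hxv, hvv

    def flow_hess(self, x, v):
        x = np.asarray(x, float)
        nx = x.size
        if self.hess_flow_xx is not None:
            hxx = np.asarray(self.hess_flow_xx(x, v, self.params), float)
        else:
            cols = [_fd_jac(lambda xx: self.flow_jac_x(xx, v)[:, j], x) for j in range(nx)]
            hxx = np.stack(cols, axis=1)
        if self.hess_flow_xv is not None:
            hxv = np.asarray(self.hess_flow_xv(x, v, self.params), float)
        else:
            hxv = _fd_jac(lambda xx: self.flow_jac_v(xx, v), x)
        if self.hess_flow_vv is not None:
            hvv = np.asarray(self.hess_flow_vv(x, v, self.params), float)
        else:
            hvv = _fd_scalar(lambda vv: self.flow_jac_v(x, vv), v)
        return hxx, hxv, hvv


@dataclass
class WorldState:
    """True state of the generative process: hidden states, cause and action."""

    x: np.ndarray
    v_true: float
    a: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(self.x)) or not np.isfinite(self.v_true):
            raise ValueError("world state must be finite")


@dataclass
class AgentState:
    """Conditional expectations over hidden states and the cause."""

    mu_x: Dict[str, np.ndarray]
    mu_v: np.ndarray

    def __post_init__(self):
        self.mu_x = {k: np.asarray(v, dtype=float) for k, v in self.mu_x.items()}
        self.mu_v = np.asarray(self.mu_v, dtype=float)
        orders = {v.size for v in self.mu_x.values()} | {self.mu_v.size}
        if len(orders) != 1:
            raise ValueError("all generalized vectors must share one embedding order")

    @property
    def order(self) -> int:
        return self.mu_v.size


@dataclass
class ErrorSet:
    """Sensory, state-motion and cause-prior prediction errors."""

    eps_v: Dict[str, np.ndarray]
    eps_x: Dict[str, np.ndarray]
    eps_prior: np.ndarray


@dataclass
class IntegratorOptions:
    """Numerical options for :func:`integrate_trial`.

    ``update_gain`` and ``action_gain`` scale the free-energy gradient terms
    of the belief and action updates (the prediction term ``D mu`` is not
    scaled); a gain of 1 performs one unit of gradient descent per unit of
    model time.  The default integrator is local linearization (a
    matrix-exponential update of the joint belief/action/world system over
    each step); ``"euler"`` selects an explicit Euler fallback.
    """

    integrator: str = "ll"
    update_gain: float = 1.0
    action_gain: float = 1.0
    divergence_limit: float = 1e6
    time_unit_seconds: float = 1.0
    #: steps between finite-difference refreshes of the joint Jacobian used
    #: by the local-linearization update (the drift f is always current)
    jacobian_refresh: int = 10
    #: sub-steps of the local-linearization update within each recorded step;
    #: keeps each matrix-exponential jump inside the linearization's validity
    substeps: int = 1
    #: largest admissible change of any variable within one LL sub-step;
    #: larger proposed jumps trigger adaptive step halving
    max_jump: float = 0.5


# ---------------------------------------------------------------------------
# Finite differences


def _fd_jac(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, h: float = _FD_STEP) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    cols = []
    for j in range(x.size):
        dx = np.zeros_like(x)
        dx[j] = h
        cols.append((np.asarray(f(x + dx), float) - np.asarray(f(x - dx), float)) / (2 * h))
    return np.stack(cols, axis=-1)


def _fd_scalar(f: Callable[[float], np.ndarray], v: float, h: float = _FD_STEP) -> np.ndarray:
    return (np.asarray(f(v + h), float) - np.asarray(f(v - h), float)) / (2 * h)


# ---------------------------------------------------------------------------
# Precision structure (cached on primitive keys)


@lru_cache(maxsize=64)
def _precision_blocks(key: tuple, order: int) -> tuple:
    sens, log_px, log_pp, smooth = key
    S = smoothness_precision(order, smooth)
    pi_v = {c: math.exp(lp) * S for c, lp in sens}
    pi_x = math.exp(log_px) * S
    pi_p = math.exp(log_pp) * S
    return pi_v, pi_x, pi_p


def _precisions(model: ModelSpec, order: int):
    return _precision_blocks(model.precision._key(model.channel_names), order)


def _stack(d: Mapping[str, np.ndarray], names: Sequence[str]) -> np.ndarray:
    return np.concatenate([np.asarray(d[k], float) for k in names])


@lru_cache(maxsize=16)
def _shift_blocks(nx: int, n: int) -> tuple:
    D = shift_operator(n)
    return np.kron(np.eye(nx + 1), D), np.kron(np.eye(nx), D)


# ---------------------------------------------------------------------------
# Generalized predictions and errors


def _beliefs_arrays(model: ModelSpec, beliefs: AgentState) -> Tuple[np.ndarray, np.ndarray]:
    mu_x = np.array([beliefs.mu_x[s] for s in model.state_names], dtype=float)
    return mu_x, beliefs.mu_v.astype(float)


def generalized_predictions(model: ModelSpec, beliefs: AgentState) -> Tuple[np.ndarray, np.ndarray]:
    """Generalized sensory and flow predictions ``(g_tilde, f_tilde)``.

    Order 0 evaluates the nonlinear maps at the order-0 beliefs; orders k >= 1
    use the first-order chain-rule expansion around the order-0 beliefs.
    Returns arrays of shape ``(n_channels, order)`` and ``(n_states, order)``.
    """
    mu_x, mu_v = _beliefs_arrays(model, beliefs)
    n = beliefs.order
    x0, v0 = mu_x[:, 0], mu_v[0]
    Fp = np.empty((len(model.state_names), n))
    Fp[:, 0] = model._flow(x0, v0)
    if n > 1:
        Jfx = model.flow_jac_x(x0, v0)
        Jfv = model.flow_jac_v(x0, v0)
        Fp[:, 1:] = Jfx @ mu_x[:, 1:] + np.outer(Jfv, mu_v[1:])
    if model.obs_embed_mu is not None:
        G = np.asarray(model.obs_embed_mu(mu_x, mu_v, model.params), dtype=float)
        return G, Fp
    G = np.empty((len(model.channel_names), n))
    G[:, 0] = model._obs(x0, v0)
    if n > 1:
        Jx = model.obs_jac_x(x0, v0)
        Jv = model.obs_jac_v(x0, v0)
        G[:, 1:] = Jx @ mu_x[:, 1:] + np.outer(Jv, mu_v[1:])
    return G, Fp


def prediction_errors(model: ModelSpec, beliefs: AgentState, sensory: Mapping[str, np.ndarray]) -> ErrorSet:
    """Prediction errors on sensory input, state motion and the cause prior.

    ``eps_v = s_tilde - g_tilde``, ``eps_x = D mu_x - f_tilde`` and
    ``eps_prior = mu_v - prior mean`` (the prior mean enters at order 0 only,
    so higher orders of the prior error equal the cause-belief derivatives).
    """
    n = beliefs.order
    for c in model.channel_names:
        if np.asarray(sensory[c]).size != n:
            raise ValueError(
                f"sensory channel {c!r} has order {np.asarray(sensory[c]).size}, beliefs have {n}"
            )
    mu_x, mu_v = _beliefs_arrays(model, beliefs)
    G, Fp = generalized_predictions(model, beliefs)
    D = shift_operator(n)
    S = np.array([np.asarray(sensory[c], float) for c in model.channel_names])
    ev = S - G
    ex = mu_x @ D.T - Fp
    ep = mu_v.copy()
    ep[0] -= model.cause_prior_mean
    return ErrorSet(
        eps_v={c: ev[i] for i, c in enumerate(model.channel_names)},
        eps_x={s: ex[i] for i, s in enumerate(model.state_names)},
        eps_prior=ep,
    )


def _error_jacobians(model: ModelSpec, beliefs: AgentState):
    """Jacobians of the stacked generalized predictions w.r.t. flat beliefs.

    The flat belief vector concatenates each state's generalized vector and
    the cause's.  Because higher-order predictions are linearized around the
    order-0 beliefs, the Jacobians carry second-derivative (Hessian)
    corrections in their order-0 columns; including them keeps the belief
    update an exact gradient of the implemented free energy.
    """
    mu_x, mu_v = _beliefs_arrays(model, beliefs)
    n = beliefs.order
    nx, nc = len(model.state_names), len(model.channel_names)
    m = (nx + 1) * n
    x0, v0 = mu_x[:, 0], mu_v[0]
    Jfx = model.flow_jac_x(x0, v0)
    Jfv = model.flow_jac_v(x0, v0)
    if not np.all(np.isfinite(Jfx)):
        raise NumericalError("non-finite Jacobian of flow at current beliefs")
    Gxx, Gxv, Gvv = model.flow_hess(x0, v0)
    idx = np.arange(n)

    B = np.zeros((nx * n, m))  # d f_tilde / d mu
    if model.obs_embed_mu_jac is not None:
        A = np.asarray(model.obs_embed_mu_jac(mu_x, mu_v, model.params), dtype=float)
        if A.shape != (nc * n, m):
            raise NumericalError(f"obs_embed_mu_jac returned shape {A.shape}, expected {(nc * n, m)}")
    else:
        Jx = model.obs_jac_x(x0, v0)
        Jv = model.obs_jac_v(x0, v0)
        if not np.all(np.isfinite(Jx)):
            raise NumericalError("non-finite Jacobian of obs at current beliefs")
        Hxx, Hxv, Hvv = model.obs_hess(x0, v0)
        A = np.zeros((nc * n, m))  # d g_tilde / d mu
        for c in range(nc):
            rows = slice(c * n, (c + 1) * n)
            for j in range(nx):
                blk = A[rows, j * n : (j + 1) * n]
                blk[idx, idx] = Jx[c, j]
                if n > 1:
                    blk[1:, 0] += Hxx[c, j, :] @ mu_x[:, 1:] + Hxv[c, j] * mu_v[1:]
            blk = A[rows, nx * n :]
            blk[idx, idx] = Jv[c]
            if n > 1:
                blk[1:, 0] += Hxv[c, :] @ mu_x[:, 1:] + Hvv[c] * mu_v[1:]
    for i in range(nx):
        rows = slice(i * n, (i + 1) * n)
        for j in range(nx):
            blk = B[rows, j * n : (j + 1) * n]
            blk[idx, idx] = Jfx[i, j]
            if n > 1:
                blk[1:, 0] += Gxx[i, j, :] @ mu_x[:, 1:] + Gxv[i, j] * mu_v[1:]
        blk = B[rows, nx * n :]
        blk[idx, idx] = Jfv[i]
        if n > 1:
            blk[1:, 0] += Gxv[i, :] @ mu_x[:, 1:] + Gvv[i] * mu_v[1:]
    return A, B


def belief_derivative(model: ModelSpec, beliefs: AgentState, errors: ErrorSet) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Time derivative of beliefs: ``D mu - dF/dmu``.

    Expands to the predictive-coding update: state beliefs are driven by
    precision-weighted sensory and state-motion errors through the transposed
    Jacobians of the sensory and flow maps (minus the transported-error term
    ``D' Pi_x eps_x``); cause beliefs additionally feel the static prior.
    """
    n = beliefs.order
    nx = len(model.state_names)
    mu_x, mu_v = _beliefs_arrays(model, beliefs)
    mu_flat = np.concatenate([mu_x.ravel(), mu_v])
    Dblk_all, Dblk_x = _shift_blocks(nx, n)

    A, B = _error_jacobians(model, beliefs)
    pi_v, pi_x, pi_p = _precisions(model, n)

    ev = _stack(errors.eps_v, model.channel_names)
    ex = _stack(errors.eps_x, model.state_names)
    ep = errors.eps_prior

    wev = np.concatenate([pi_v[c] @ errors.eps_v[c] for c in model.channel_names])
    wex = np.concatenate([pi_x @ errors.eps_x[s] for s in model.state_names])
    wep = pi_p @ ep

    # dF/dmu = (d eps_v/d mu)' Pi ev + (d eps_x/d mu)' Pi ex + (d eps_p/d mu)' Pi ep
    Dblk_x_pad = np.hstack([Dblk_x, np.zeros((nx * n, n))])
    grad = -A.T @ wev + (Dblk_x_pad - B).T @ wex
    grad[nx * n :] += wep
    dmu = Dblk_all @ mu_flat - grad
    dmu_x = dmu[: nx * n].reshape(nx, n)
    return {s: dmu_x[i] for i, s in enumerate(model.state_names)}, dmu[nx * n :]


def free_energy(errors: ErrorSet, model: ModelSpec) -> float:
    """Sum of precision-weighted squared prediction errors (times one half).

    Non-negative, and zero exactly when all errors vanish; constant
    log-determinant terms are omitted (they do not affect gradients).
    """
    n = errors.eps_prior.size
    pi_v, pi_x, pi_p = _precisions(model, n)
    F = 0.0
    for c in model.channel_names:
        e = errors.eps_v[c]
        F += 0.5 * float(e @ pi_v[c] @ e)
    for s in model.state_names:
        e = errors.eps_x[s]
        F += 0.5 * float(e @ pi_x @ e)
    F += 0.5 * float(errors.eps_prior @ pi_p @ errors.eps_prior)
    return F


# ---------------------------------------------------------------------------
# The generative process: sensory embedding and the action gradient


def _embed_sensory(process: ModelSpec, x: np.ndarray, v: float, a: float, order: int) -> np.ndarray:
    """Generalized sensory input from the process along its own trajectory.

    State derivatives follow the process flow (action held constant within
    the embedding); derivative orders >= 2 are propagated through the flow
    Jacobian, which is exact for flows that are linear in the states.
    """
    x = np.asarray(x, dtype=float)
    nx = x.size
    X = np.zeros((nx, order))
    X[:, 0] = x
    if order > 1:
        X[:, 1] = process._flow(x, v, a)
        if order > 2:
            Jfx = process.flow_jac_x(x, v, a)
            for k in range(2, order):
                X[:, k] = Jfx @ X[:, k - 1]
    if process.obs_embed is not None:
        return np.asarray(process.obs_embed(X, v, process.params), dtype=float)
    S = np.empty((len(process.channel_names), order))
    S[:, 0] = process._obs(x, v)
    if order > 1:
        S[:, 1:] = process.obs_jac_x(x, v) @ X[:, 1:]
    return S


def embed_process_sensory(process: ModelSpec, world: WorldState, order: int) -> Dict[str, np.ndarray]:
    """Noise-free generalized sensory input generated by the process."""
    S = _embed_sensory(process, world.x, world.v_true, world.a, order)
    return {c: S[i] for i, c in enumerate(process.channel_names)}


def _embed_sensory_da(process: ModelSpec, x, v, a, order, h: float = _FD_STEP) -> np.ndarray:
    """Derivative of the generalized sensory embedding w.r.t. action."""
    return (_embed_sensory(process, x, v, a + h, order) - _embed_sensory(process, x, v, a - h, order)) / (2 * h)


def action_derivative(process: ModelSpec, model: ModelSpec, errors: ErrorSet, world: WorldState) -> float:
    """Action update ``da/dt = -dF/da = -(d eps_v/d a)' Pi_v eps_v``.

    The sensitivity of the sensory error to action is propagated through the
    true generative process: action enters the velocity of the hand state, so
    it perturbs orders >= 1 of the sensory embedding of the hand-dependent
    channels; channels that do not depend on the hand contribute zero.
    Precisions are the agent's (the model's) sensory precisions.
    """
    n = errors.eps_prior.size
    dS = _embed_sensory_da(process, world.x, world.v_true, world.a, n)
    pi_v, _, _ = _precisions(model, n)
    da = 0.0
    for i, c in enumerate(model.channel_names):
        da -= float(dS[i] @ pi_v[c] @ errors.eps_v[c])
    return da


# ---------------------------------------------------------------------------
# Trial integration


@dataclass
class SimulationTrace:
    """Per-step record of a simulated trial (tidy table plus metadata)."""

    data: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)

    CSV_COLUMNS = [
        "t", "x_t", "x_h", "a", "s_target", "s_prop", "s_vis",
        "pred_target", "pred_prop", "pred_vis",
        "eps_target", "eps_prop", "eps_vis",
        "mu_xt", "mu_xh", "mu_v", "F", "a_dot",
    ]

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        cols = [c for c in self.CSV_COLUMNS if c in self.data.columns]
        self.data[cols].to_csv(path, index=False, float_format="%.17g", lineterminator="\n")

    @staticmethod
    def from_csv(path, meta: Optional[dict] = None) -> "SimulationTrace":
        return SimulationTrace(pd.read_csv(path), meta or {})

    def to_hdf5(self, path) -> None:
        import json

        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("trace")
            for col in self.data.columns:
                grp.create_dataset(col, data=self.data[col].to_numpy())
            f.attrs["meta"] = json.dumps(self.meta, default=str)

    @staticmethod
    def from_hdf5(path) -> "SimulationTrace":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            grp = f["trace"]
            data = pd.DataFrame({k: grp[k][()] for k in grp.keys()})
            meta = json.loads(f.attrs.get("meta", "{}"))
        return SimulationTrace(data, meta)


_CHANNEL_SHORT = {"target": "target", "proprioception": "prop", "vision": "vis"}


def _short(name: str) -> str:
    return _CHANNEL_SHORT.get(name, name)


def integrate_trial(
    process: ModelSpec,
    world0: WorldState,
    model: ModelSpec,
    agent0: AgentState,
    duration: float,
    dt: float,
    options: Optional[IntegratorOptions] = None,
) -> SimulationTrace:
    """Integrate the coupled world/agent system and record every step.

    Alternates (conceptually) between generating noise-free sensory input
    from the process under the current action, and updating beliefs and
    action by the free-energy gradients, using locally linearized
    (matrix-exponential) integration of the joint system over each step.

    ``duration`` must be a non-negative multiple of ``dt`` (both in the
    model's time unit); the trace has ``duration/dt + 1`` records.
    """
    opts = options or IntegratorOptions()
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n_steps_f = duration / dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or duration < 0:
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")

    order = agent0.order
    nx = len(process.state_names)
    n_mu = (nx + 1) * order
    state_names = model.state_names
    channel_names = model.channel_names
    v_true = world0.v_true

    def unpack(z):
        x = z[:nx]
        a = z[nx]
        mu_x = z[nx + 1 : nx + 1 + nx * order].reshape(nx, order)
        mu_v = z[nx + 1 + nx * order :]
        return x, a, mu_x, mu_v

    def make_agent(mu_x, mu_v):
        return AgentState({s: mu_x[i] for i, s in enumerate(state_names)}, mu_v)

    def evaluate(z, want_record=False):
        x, a, mu_x, mu_v = unpack(z)
        world = WorldState(x=x, v_true=v_true, a=a)
        sensory = embed_process_sensory(process, world, order)
        beliefs = make_agent(mu_x, mu_v)
        errors = prediction_errors(model, beliefs, sensory)
        dmu_x, dmu_v = belief_derivative(model, beliefs, errors)
        D = shift_operator(order)
        # apply the update gain to the gradient part only (D mu is a prediction)
        g = opts.update_gain
        dmu_x_arr = np.array([dmu_x[s] for s in state_names])
        dmu_v_arr = np.asarray(dmu_v)
        pred_x = mu_x @ D.T
        pred_v = D @ mu_v
        dmu_x_arr = pred_x + g * (dmu_x_arr - pred_x)
        dmu_v_arr = pred_v + g * (dmu_v_arr - pred_v)
        da = opts.action_gain * action_derivative(process, model, errors, world)
        dx = process._flow(x, v_true, a)
        dz = np.concatenate([dx, [da], dmu_x_arr.ravel(), dmu_v_arr])
        if not want_record:
            return dz, None
        G, _ = generalized_predictions(model, beliefs)
        rec = {"a": a, "a_dot": da, "F": free_energy(errors, model)}
        for i, s in enumerate(state_names):
            rec[s] = x[i]
            rec["mu_" + s.replace("_", "")] = mu_x[i, 0]
        rec["mu_v"] = mu_v[0]
        for i, c in enumerate(channel_names):
            sc = _short(c)
            rec["s_" + sc] = sensory[c][0]
            rec["pred_" + sc] = G[i, 0]
            rec["eps_" + sc] = errors.eps_v[c][0]
        return dz, rec

    z = np.concatenate(
        [
            world0.x,
            [world0.a],
            np.array([agent0.mu_x[s] for s in state_names]).ravel(),
            agent0.mu_v,
        ]
    )
    d = z.size
    records = []
    jac_h = 1e-6
    J_cache = None
    for step in range(n_steps + 1):
        if np.any(np.abs(z) > opts.divergence_limit) or not np.all(np.isfinite(z)):
            raise DivergenceError(f"divergence at step {step} (t = {step * dt:g})")
        dz, rec = evaluate(z, want_record=True)
        rec["t"] = step * dt * opts.time_unit_seconds
        records.append(rec)
        if step == n_steps:
            break
        if opts.integrator == "euler":
            z = z + dt * dz
        elif opts.integrator == "ll":
            # local linearization: z += (expm(h J) - I) J^-1 f, via the
            # augmented-matrix form that handles singular J; the step is
            # halved adaptively whenever the proposed jump leaves the
            # trust region of the linearization
            if J_cache is None or step % max(1, opts.jacobian_refresh) == 0:
                J_cache = np.empty((d, d))
                for j in range(d):
                    pz = z.copy()
                    pz[j] += jac_h
                    J_cache[:, j] = (evaluate(pz)[0] - dz) / jac_h
            remaining = dt
            h = dt / max(1, opts.substeps)
            guard = 0
            while remaining > 1e-12 * dt:
                h = min(h, remaining)
                M = np.zeros((d + 1, d + 1))
                M[1:, 0] = dz * h
                M[1:, 1:] = J_cache * h
                with np.errstate(over="ignore", invalid="ignore"):
                    jump = expm(M)[1:, 0]
                if (np.max(np.abs(jump)) > opts.max_jump or not np.all(np.isfinite(jump))) and h > dt / 1024:
                    h /= 2
                    guard += 1
                    continue
                z = z + jump
                remaining -= h
                if not np.all(np.isfinite(z)):
                    raise DivergenceError(f"divergence at step {step} (t = {step * dt:g})")
                if remaining > 1e-12 * dt:
                    dz = evaluate(z)[0]
                    h *= 2
        else:
            raise ValueError(f"unknown integrator {opts.integrator!r}")

    df = pd.DataFrame(records)
    cols = [c for c in SimulationTrace.CSV_COLUMNS if c in df.columns]
    df = df[cols + [c for c in df.columns if c not in cols]]
    meta = {
        "dt": dt,
        "duration": duration,
        "order": order,
        "v_true": v_true,
        "integrator": opts.integrator,
        "time_unit_seconds": opts.time_unit_seconds,
    }
    return SimulationTrace(df, meta)
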