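"""Behavioural analysis chain: preprocessing, wavelet phase lag, statistics.

Implements the analysis applied to data-glove trajectories from the
phase-matching experiment: averaging of the four non-thumb finger channels,
continuous-wavelet-transform (complex Morlet) estimation of the phase lag
between grasp and target oscillations, per-participant circular aggregation,
the 2x2 within-subject ANOVA on lags with Bonferroni-corrected paired
post-hoc t-tests, and the nonparametric tests (Friedman, Wilcoxon signed
rank) used for the ordinal questionnaire ratings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import stats

__all__ = [
    "TrialTrajectory",
    "UndefinedPhaseError",
    "CONDITION_LABELS",
    "preprocess_trial",
    "normalize_trajectory",
    "cwt_phase_lag",
    "wavelet_name",
    "edge_margin_samples",
    "virtual_from_real",
    "aggregate_lags",
    "rm_anova_2x2",
    "posthoc_paired_tests",
    "friedman_test",
    "wilcoxon_pairs",
]

# Complex Morlet with the classical centre-frequency parameter 6: in the
# PyWavelets cmorB-C parameterization this is bandwidth B = 2 (Gaussian
# envelope exp(-t^2/2) at scale 1) and centre frequency C = 6/(2 pi).
MORLET_OMEGA0 = 6.0
_MORLET_B = 2.0
_MORLET_C = MORLET_OMEGA0 / (2 * math.pi)

CONDITION_LABELS = ("vh_cong", "vh_incong", "rh_cong", "rh_incong")

#: Role of the five glove sensors; the thumb is excluded from the grasp
#: average (four-finger averaging).
FINGER_COLUMNS = ("f1", "f2", "f3", "f4", "f5")
THUMB_COLUMN = "f1"


class UndefinedPhaseError(ValueError):
    """Raised when a signal's oscillatory amplitude is too small for a phase."""


@dataclass
class TrialTrajectory:
    """One behavioural trial: time, five glove channels, target phase, labels."""

    t: np.ndarray
    fingers: np.ndarray  # shape (5, n_samples), values in [0, 1]
    target_phase: np.ndarray
    labels: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.fingers = np.asarray(self.fingers, float)
        self.target_phase = np.asarray(self.target_phase, float)
        if self.fingers.shape != (5, self.t.size):
            raise ValueError(f"expected 5 finger channels x {self.t.size} samples")

    @property
    def condition(self) -> str:
        return f"{str(self.labels['instruction']).lower()}_{self.labels['congruence']}"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "target_phase": self.target_phase})
        for i, col in enumerate(FINGER_COLUMNS):
            df[col] = self.fingers[i]
        for k, v in self.labels.items():
            df[k] = v
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "TrialTrajectory":
        label_cols = [c for c in df.columns if c not in ("t", "target_phase") + FINGER_COLUMNS]
        labels = {c: df[c].iloc[0] for c in label_cols}
        return TrialTrajectory(
            t=df["t"].to_numpy(),
            fingers=np.array([df[c].to_numpy() for c in FINGER_COLUMNS]),
            target_phase=df["target_phase"].to_numpy(),
            labels=labels,
        )


def preprocess_trial(trial: TrialTrajectory) -> np.ndarray:
    """Scalar grasp signal: mean of the four non-thumb finger channels."""
    idx = [i for i, c in enumerate(FINGER_COLUMNS) if c != THUMB_COLUMN]
    if trial.fingers.shape[0] < 5:
        raise ValueError("expected 5 glove channels (thumb + 4 fingers)")
    return trial.fingers[idx].mean(axis=0)


def normalize_trajectory(signal: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-peak version of a trajectory (display only).

    Normalization cannot change the phase, so the lag estimator consumes the
    un-normalized average; this helper exists for condition-average plots.
    """
    s = np.asarray(signal, float) - np.mean(signal)
    peak = np.max(np.abs(s))
    if peak == 0:
        raise UndefinedPhaseError("flat signal cannot be normalized")
    return s / peak


def wavelet_name(bandwidth: float = _MORLET_B, center: float = _MORLET_C) -> str:
    return f"cmor{bandwidth:.6f}-{center:.8f}"


def edge_margin_samples(f0: float, fs: float, edge_sigmas: float = 2.0) -> int:
    """Samples excluded at each edge (one wavelet-support length).

    The Morlet envelope at the scale matching ``f0`` has temporal standard
    deviation ``sigma_t = C / f0`` seconds; one support length is taken as
    ``edge_sigmas * sigma_t`` (default two standard deviations), the cone of
    influence within which coefficients are contaminated by the edges.
    """
    sigma_t = _MORLET_C / f0
    return int(math.ceil(edge_sigmas * sigma_t * fs))


def _cwt_single(signal: np.ndarray, f0: float, fs: float) -> np.ndarray:
    # the mean is removed first: the complex Morlet is only approximately
    # admissible, so a DC offset would otherwise leak into the phase
    scale = _MORLET_C * fs / f0
    sig = np.asarray(signal, float)
    coeffs, _ = pywt.cwt(sig - sig.mean(), [scale], wavelet_name(), sampling_period=1.0 / fs)
    return coeffs[0]


def cwt_phase_lag(
    signal: np.ndarray,
    reference: np.ndarray,
    f0: float,
    fs: float,
    edge_sigmas: float = 2.0,
) -> float:
    """Phase lag of ``signal`` behind ``reference`` at ``f0``, in seconds.

    Both series are transformed with a complex Morlet wavelet at the scale
    matching ``f0``; the per-sample angular difference of the coefficients is
    averaged circularly over a window that excludes one wavelet-support
    length at each edge, and converted to time: ``lag = dphi / (2 pi f0)``.
    Positive values mean the signal lags the reference.  The result lies in
    ``(-T/2, T/2]`` for period ``T = 1/f0``.
    """
    signal = np.asarray(signal, float)
    reference = np.asarray(reference, float)
    if signal.shape != reference.shape:
        raise ValueError("signal and reference must have equal length")
    if f0 >= fs / 2:
        raise ValueError(f"f0 = {f0} must lie below the Nyquist frequency {fs / 2}")
    margin = edge_margin_samples(f0, fs, edge_sigmas)
    n_min = 2 * margin + int(math.ceil(fs / f0))
    if signal.size < n_min:
        raise ValueError(
            f"series too short: {signal.size} samples, need >= {n_min} "
            f"(edge margins plus one period at {f0} Hz)"
        )
    w_sig = _cwt_single(signal, f0, fs)[margin:-margin]
    w_ref = _cwt_single(reference, f0, fs)[margin:-margin]
    amp_floor = 1e-12 * max(1.0, float(np.max(np.abs(reference)) + np.max(np.abs(signal))))
    if np.median(np.abs(w_sig)) < amp_floor or np.median(np.abs(w_ref)) < amp_floor:
        raise UndefinedPhaseError("oscillatory amplitude too small for a phase estimate")
    # phase of ref relative to signal: positive when the signal trails
    dphi = np.angle(w_ref * np.conj(w_sig))
    mean_angle = np.angle(np.mean(np.exp(1j * dphi)))
    return mean_angle / (2 * math.pi * f0)


def virtual_from_real(signal: np.ndarray, delay: float, fs: float) -> np.ndarray:
    """Seen-hand trace: the real grasp delayed by the rendering delay.

    The first ``delay`` seconds hold the initial posture (as the renderer
    would); that edge falls inside the wavelet exclusion margin.
    """
    k = int(round(delay * fs))
    if k == 0:
        return np.asarray(signal, float).copy()
    out = np.empty_like(np.asarray(signal, float))
    out[:k] = signal[0]
    out[k:] = signal[: signal.size - k]
    return out


def _circular_mean_lag(lags: Sequence[float], f0: float) -> float:
    phasors = np.exp(1j * 2 * math.pi * f0 * np.asarray(lags, float))
    return float(np.angle(np.mean(phasors)) / (2 * math.pi * f0))


def aggregate_lags(
    trials: Iterable[TrialTrajectory],
    f0: float,
    fs: float,
    visual_delay: float = 0.5,
) -> pd.DataFrame:
    """Participant x condition phase-lag table (circular means, seconds).

    For each trial the grasp signal is the four-finger average; the real-hand
    lag is estimated against the target reference (grasp closing mapped to a
    shrinking target), and the virtual-hand lag against the same reference
    after delaying the grasp by the rendering delay in incongruent trials
    (the seen hand equals the real hand in congruent trials).  Participants
    missing a condition are excluded from the table with a warning.
    """
    per_cell: Dict[Tuple[object, str], Dict[str, List[float]]] = {}
    for trial in trials:
        sig = preprocess_trial(trial)
        # closing the hand (flexion up) when the dot shrinks: the reference
        # for flexion is the negated target size modulation
        ref = -np.sin(trial.target_phase)
        lag_r = cwt_phase_lag(sig, ref, f0, fs)
        if trial.labels["congruence"] == "incong":
            lag_v = cwt_phase_lag(virtual_from_real(sig, visual_delay, fs), ref, f0, fs)
        else:
            lag_v = lag_r
        key = (trial.labels["participant"], trial.condition)
        cell = per_cell.setdefault(key, {"real": [], "virtual": []})
        cell["real"].append(lag_r)
        cell["virtual"].append(lag_v)

    rows = []
    participants = sorted({k[0] for k in per_cell})
    for pid in participants:
        missing = [c for c in CONDITION_LABELS if (pid, c) not in per_cell]
        if missing:
            warnings.warn(
                f"participant {pid!r} is missing conditions {missing}; excluded from the lag table"
            )
            continue
        for cond in CONDITION_LABELS:
            cell = per_cell[(pid, cond)]
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "lag_real": _circular_mean_lag(cell["real"], f0),
                    "lag_virtual": _circular_mean_lag(cell["virtual"], f0),
                }
            )
    return pd.DataFrame(rows)


def _pivot(table: pd.DataFrame, dependent: str) -> pd.DataFrame:
    wide = table.pivot(index="participant", columns="condition", values=dependent)
    missing = [c for c in CONDITION_LABELS if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"incomplete crossed design (missing {missing or 'cells'})")
    return wide[list(CONDITION_LABELS)]


def rm_anova_2x2(table: pd.DataFrame, dependent: str = "lag_virtual") -> Dict[str, Dict[str, float]]:
    """2x2 repeated-measures ANOVA (factors: task VH/RH, congruence).

    With two-level within factors each effect's F equals the squared paired
    t-statistic of the corresponding contrast on subject means, with
    degrees of freedom (1, n-1); the three effects are computed from those
    contrasts directly.
    """
    wide = _pivot(table, dependent)
    vh_c, vh_i = wide["vh_cong"].to_numpy(), wide["vh_incong"].to_numpy()
    rh_c, rh_i = wide["rh_cong"].to_numpy(), wide["rh_incong"].to_numpy()
    n = wide.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")

    def effect(contrast: np.ndarray) -> Dict[str, float]:
        mean = contrast.mean()
        se = contrast.std(ddof=1) / math.sqrt(n)
        t = mean / se if se > 0 else (0.0 if mean == 0 else math.inf)
        F = t**2
        p = float(stats.f.sf(F, 1, n - 1)) if math.isfinite(F) else 0.0
        return {"F": float(F), "df": (1, n - 1), "p": p}

    return {
        "task": effect((vh_c + vh_i) / 2 - (rh_c + rh_i) / 2),
        "congruence": effect((vh_i + rh_i) / 2 - (vh_c + rh_c) / 2),
        "interaction": effect((vh_i - vh_c) - (rh_i - rh_c)),
    }


def posthoc_paired_tests(
    table: pd.DataFrame,
    comparisons: Sequence[Tuple[str, str]],
    dependent: str = "lag_virtual",
    correction: str = "bonferroni",
) -> List[Dict[str, object]]:
    """Two-tailed paired t-tests with Bonferroni-corrected p-values."""
    wide = _pivot(table, dependent)
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        n = xa.size
        if n < 2:
            raise ValueError("paired t-test needs at least two pairs")
        diff = xa - xb
        degenerate = bool(np.all(diff == diff[0]) and diff[0] != 0)
        if degenerate:
            t, p = math.inf, 0.0
        else:
            res = stats.ttest_rel(xa, xb)
            t, p = float(res.statistic), float(res.pvalue)
            if math.isnan(t):  # identical vectors
                t, p = 0.0, 1.0
        p_corr = min(1.0, p * m) if correction == "bonferroni" else p
        out.append(
            {
                "comparison": (a, b),
                "t": t,
                "df": n - 1,
                "p": p,
                "p_corrected": p_corr,
                "degenerate": degenerate,
            }
        )
    return out


def _ratings_wide(ratings: pd.DataFrame, question: str) -> pd.DataFrame:
    sub = ratings[ratings["question"] == question]
    wide = sub.pivot(index="participant", columns="condition", values="rating")
    missing = [c for c in CONDITION_LABELS if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"incomplete ratings design for {question} (missing {missing or 'cells'})")
    return wide[list(CONDITION_LABELS)]


def friedman_test(ratings: pd.DataFrame, question: str) -> Dict[str, float]:
    """Friedman test over the four related condition samples of one question."""
    wide = _ratings_wide(ratings, question)
    arrays = [wide[c].to_numpy() for c in CONDITION_LABELS]
    stacked = np.column_stack(arrays)
    if np.all(np.ptp(stacked, axis=1) == 0):
        if np.all(stacked == stacked[0, 0]):
            raise ValueError("all-tied ratings: Friedman statistic undefined")
        return {"chi2": 0.0, "df": len(CONDITION_LABELS) - 1, "p": 1.0}
    chi2, p = stats.friedmanchisquare(*arrays)
    return {"chi2": float(chi2), "df": len(CONDITION_LABELS) - 1, "p": float(p)}


def wilcoxon_pairs(
    ratings: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]],
    question: str,
    correction: str = "bonferroni",
) -> List[Dict[str, object]]:
    """Wilcoxon signed-rank tests with a normal-approximation z statistic.

    Zero differences are dropped, ties receive mid-ranks (with the usual tie
    correction of the variance) and a continuity correction is applied --
    the large-sample convention for cohorts of a few dozen participants.
    """
    wide = _ratings_wide(ratings, question)
    m = len(pairs)
    out = []
    for a, b in pairs:
        d = wide[a].to_numpy(float) - wide[b].to_numpy(float)
        d = d[d != 0]
        n = d.size
        if n < 2:
            raise ValueError(f"too few non-zero differences for pair ({a}, {b})")
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        mu = n * (n + 1) / 4
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = np.sum(counts**3 - counts) / 48
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - tie_corr
        if sigma2 <= 0:
            raise ValueError("degenerate ranks: zero variance")
        delta = w_plus - mu
        z = (delta - 0.5 * np.sign(delta)) / math.sqrt(sigma2)
        p = 2 * float(stats.norm.sf(abs(z)))
        p_corr = min(1.0, p * m) if correction == "bonferroni" else p
        out.append(
            {
                "comparison": (a, b),
                "W": w_plus,
                "z": float(z),
                "n": n,
                "p": p,
                "p_corrected": p_corr,
            }
        )
    return out
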