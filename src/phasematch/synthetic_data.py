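"""Synthetic data-glove cohorts with the study's design and known ground truth.

Emulates the behavioural experiment's structure -- 24 participants, four
conditions (virtual-hand/real-hand instruction x congruent/incongruent), six
trials per condition (two runs of three), 32-second trials of 0.5 Hz grasp
cycles sampled at 60 Hz, a 500 ms rendering delay of the seen hand in
incongruent trials, and 7-point ratings for two questionnaire items -- so
the analysis chain can be exercised end to end with recoverable truth.

The noise model is deliberately simple: per-participant condition lags are
Gaussian around condition means, trials jitter around the participant lag,
finger channels share the grasp waveform up to per-finger gains and additive
Gaussian sensor noise.  All parameters are exposed on :class:`CohortSpec`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .phase_analysis import CONDITION_LABELS, FINGER_COLUMNS, TrialTrajectory

__all__ = [
    "CohortSpec",
    "Cohort",
    "make_target",
    "generate_participant",
    "generate_cohort",
    "generate_ratings",
    "draw_lag_table",
    "RATING_QUESTIONS",
]

RATING_QUESTIONS = ("Q1", "Q2")

#: Condition means of the real-hand lag (seconds, positive = hand behind the
#: target) for the effect preset.  The pattern mirrors the behavioural
#: findings: in the virtual-hand incongruent condition the real hand leads by
#: most of the 0.5 s delay (so the seen hand is close to the target), while
#: in the real-hand incongruent condition the real hand is dragged only
#: partway by the delayed visual feedback.
EFFECT_LAG_MEANS = {
    "vh_cong": 0.04,
    "rh_cong": 0.04,
    "vh_incong": -0.38,
    "rh_incong": -0.12,
}

# Latent shifts (in latent-sd units) of the two ordinal questions:
# Q1 (difficulty) rises under incongruence, most for the virtual-hand task;
# Q2 (attention focus, real -> virtual) follows the instructed modality.
EFFECT_RATING_SHIFTS = {
    "Q1": {"vh_cong": -0.8, "rh_cong": -0.8, "vh_incong": 1.2, "rh_incong": 0.3},
    "Q2": {"vh_cong": 1.5, "vh_incong": 1.5, "rh_cong": -1.5, "rh_incong": -1.5},
}


@dataclass
class CohortSpec:
    """Design constants and noise parameters of a synthetic cohort."""

    n_participants: int = 24
    trials_per_condition: int = 6
    trial_duration: float = 32.0
    f0: float = 0.5
    fs: float = 60.0
    visual_delay: float = 0.5
    condition_lag_means: Dict[str, float] = field(default_factory=lambda: dict(EFFECT_LAG_MEANS))
    between_subject_sd: float = 0.06
    within_trial_sd: float = 0.03
    noise_sd: float = 0.02
    amplitude_range: Tuple[float, float] = (0.1, 0.9)
    rating_preset: str = "effect"
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * self.f0:
            raise ValueError("sampling rate must exceed twice the grasp frequency")
        half_period = 0.5 / self.f0
        for cond, lag in self.condition_lag_means.items():
            if abs(lag) > half_period:
                raise ValueError(f"lag mean for {cond} beyond half a period ({lag} s)")
        if not (0 <= self.amplitude_range[0] < self.amplitude_range[1] <= 1):
            raise ValueError("amplitude_range must be an increasing sub-interval of [0, 1]")

    @classmethod
    def effect_preset(cls, seed: int = 0, **kw) -> "CohortSpec":
        return cls(seed=seed, **kw)

    @classmethod
    def null_preset(cls, seed: int = 0, **kw) -> "CohortSpec":
        means = {c: 0.04 for c in CONDITION_LABELS}
        return cls(condition_lag_means=means, rating_preset="null", seed=seed, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplitude_range"] = list(self.amplitude_range)
        return d

    @staticmethod
    def from_dict(d: dict) -> "CohortSpec":
        d = dict(d)
        d["amplitude_range"] = tuple(d["amplitude_range"])
        d["condition_lag_means"] = dict(d["condition_lag_means"])
        return CohortSpec(**d)


def make_target(duration: float, f0: float, fs: float) -> pd.DataFrame:
    """Target oscillation: sinusoidal size signal and its phase.

    The size modulation follows the 12% convention: the ratio of the largest
    to the smallest dot size is 1.12, i.e. ``size = 1 + m sin(phase)`` with
    ``(1+m)/(1-m) = 1.12``.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = 2 * math.pi * f0 * t
    m = 0.12 / 2.12
    size = 1 + m * np.sin(phase)
    return pd.DataFrame({"t": t, "phase": phase, "size": size})


def _grasp_waveform(t: np.ndarray, f0: float, lag: float, amplitude_range: Tuple[float, float]) -> np.ndarray:
    """Flexion trace of a grasp lagging the target by ``lag`` seconds.

    The hand closes (flexion rises) as the dot shrinks, so flexion is in
    anti-phase with the target size modulation.
    """
    lo, hi = amplitude_range
    mid, amp = (hi + lo) / 2, (hi - lo) / 2
    return mid - amp * np.sin(2 * math.pi * f0 * (t - lag))


def _participant_rng(spec: CohortSpec, participant: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1, participant])


def generate_participant(
    spec: CohortSpec, participant: int
) -> Tuple[List[TrialTrajectory], pd.DataFrame]:
    """Trials and hidden-truth records for one participant.

    Per condition the participant's real-hand lag is drawn around the
    condition mean; each trial jitters around it.  Five finger channels are
    built from the grasp waveform with per-participant finger gains (the
    thumb moves least) and additive sensor noise, clipped to the glove range.
    In incongruent conditions the seen hand is the real hand delayed by the
    rendering delay, so the true virtual lag is the real lag plus the delay.
    """
    rng = _participant_rng(spec, participant)
    n = int(round(spec.trial_duration * spec.fs))
    t = np.arange(n) / spec.fs
    phase = 2 * math.pi * spec.f0 * t
    gains = np.concatenate([[rng.uniform(0.3, 0.5)], rng.uniform(0.8, 1.0, size=4)])
    half_period = 0.5 / spec.f0
    trials: List[TrialTrajectory] = []
    truth_rows = []
    for cond in CONDITION_LABELS:
        instruction, congruence = cond.split("_")
        p_lag = spec.condition_lag_means[cond] + rng.normal(0, spec.between_subject_sd)
        for trial_idx in range(spec.trials_per_condition):
            lag = p_lag + rng.normal(0, spec.within_trial_sd)
            if abs(lag) > half_period:
                raise ValueError(f"drawn lag {lag:.3f} s beyond half a period")
            grasp = _grasp_waveform(t, spec.f0, lag, spec.amplitude_range)
            mid = sum(spec.amplitude_range) / 2
            fingers = mid + gains[:, None] * (grasp - mid)[None, :]
            fingers = fingers + rng.normal(0, spec.noise_sd, size=fingers.shape)
            np.clip(fingers, 0.0, 1.0, out=fingers)
            run = 1 + trial_idx // (spec.trials_per_condition // 2 or 1)
            trials.append(
                TrialTrajectory(
                    t=t,
                    fingers=fingers,
                    target_phase=phase,
                    labels={
                        "participant": participant,
                        "run": run,
                        "trial": trial_idx,
                        "instruction": instruction.upper(),
                        "congruence": congruence,
                    },
                )
            )
            lag_virtual = lag + (spec.visual_delay if congruence == "incong" else 0.0)
            truth_rows.append(
                {
                    "participant": participant,
                    "condition": cond,
                    "trial": trial_idx,
                    "true_lag_real": lag,
                    "true_lag_virtual": lag_virtual,
                    "participant_lag": p_lag,
                }
            )
    return trials, pd.DataFrame(truth_rows)


def generate_ratings(spec: CohortSpec, preset: Optional[str] = None) -> pd.DataFrame:
    """Ordinal 1-7 ratings from a shifted-latent-Gaussian model.

    Each participant has a latent offset; condition shifts are applied under
    the effect preset and absent under the null preset; the latent value is
    thresholded at fixed cutpoints into the 7-point scale.
    """
    preset = preset or spec.rating_preset
    if preset not in ("effect", "null"):
        raise ValueError(f"unknown rating preset {preset!r}")
    cuts = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
    rows = []
    for pid in range(spec.n_participants):
        rng = np.random.default_rng([spec.seed, 2, pid])
        offsets = {q: rng.normal(0, 0.8) for q in RATING_QUESTIONS}
        for q in RATING_QUESTIONS:
            for cond in CONDITION_LABELS:
                shift = EFFECT_RATING_SHIFTS[q][cond] if preset == "effect" else 0.0
                latent = offsets[q] + shift + rng.normal(0, 1.0)
                rating = int(np.digitize(latent, cuts)) + 1
                rows.append(
                    {"participant": pid, "condition": cond, "question": q, "rating": rating}
                )
    return pd.DataFrame(rows)


def draw_lag_table(spec: CohortSpec, cohort_index: int = 0) -> pd.DataFrame:
    """Participant x condition lag table drawn from the generator's lag layer.

    Produces the table that perfect lag estimation on ``trials_per_condition``
    trials would recover (participant lag plus the mean of the trial
    jitters), without synthesizing waveforms.  Used for repeated-cohort
    calibration studies of the group statistics.
    """
    rows = []
    for pid in range(spec.n_participants):
        rng = np.random.default_rng([spec.seed, 3, cohort_index, pid])
        for cond in CONDITION_LABELS:
            p_lag = spec.condition_lag_means[cond] + rng.normal(0, spec.between_subject_sd)
            jitter = rng.normal(0, spec.within_trial_sd, size=spec.trials_per_condition).mean()
            lag = p_lag + jitter
            lag_virtual = lag + (spec.visual_delay if cond.endswith("incong") else 0.0)
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "lag_real": lag,
                    "lag_virtual": lag_virtual,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """An in-memory synthetic cohort: trials, ratings, manifest and truth."""

    spec: CohortSpec
    trials: List[TrialTrajectory]
    ratings: pd.DataFrame
    truth: pd.DataFrame

    @property
    def manifest(self) -> dict:
        return {
            "fs": self.spec.fs,
            "f0": self.spec.f0,
            "visual_delay": self.spec.visual_delay,
            "trial_duration": self.spec.trial_duration,
            "n_participants": self.spec.n_participants,
            "trials_per_condition": self.spec.trials_per_condition,
            "conditions": list(CONDITION_LABELS),
            "spec": self.spec.to_dict(),
        }

    def trials_frame(self) -> pd.DataFrame:
        return pd.concat([tr.to_frame() for tr in self.trials], ignore_index=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials_frame().to_csv(out / "trials.csv", index=False, float_format="%.8g")
        self.ratings.to_csv(out / "ratings.csv", index=False)
        # ground truth lives in a clearly separated sidecar, not analysis input
        self.truth.to_csv(out / "truth_synthetic.csv", index=False, float_format="%.8g")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    @staticmethod
    def read(in_dir) -> "Cohort":
        path = Path(in_dir)
        manifest = json.loads((path / "manifest.json").read_text())
        spec = CohortSpec.from_dict(manifest["spec"])
        frame = pd.read_csv(path / "trials.csv")
        trials = [
            TrialTrajectory.from_frame(g)
            for _, g in frame.groupby(["participant", "instruction", "congruence", "trial"], sort=True)
        ]
        ratings_path = path / "ratings.csv"
        ratings = pd.read_csv(ratings_path) if ratings_path.exists() else pd.DataFrame()
        truth_path = path / "truth_synthetic.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
        return Cohort(spec=spec, trials=trials, ratings=ratings, truth=truth)


def generate_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Generate a full cohort (deterministic under ``spec.seed``)."""
    trials: List[TrialTrajectory] = []
    truths = []
    for pid in range(spec.n_participants):
        p_trials, p_truth = generate_participant(spec, pid)
        trials.extend(p_trials)
        truths.append(p_truth)
    cohort = Cohort(
        spec=spec,
        trials=trials,
        ratings=generate_ratings(spec),
        truth=pd.concat(truths, ignore_index=True),
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
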