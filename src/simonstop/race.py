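"""Independent horse-race simulation of Simon stop-signal behavior.

A go process (ex-Gaussian finishing time, congruency-dependent) races an
independent stop process (Gaussian latency starting at the stop-signal delay).
On stop trials the response escapes iff the go process finishes before
SSD + stop latency. Choice errors, misses and stop-trigger failures are
modeled as independent lapses.

Default calibration targets the behavioral profile of a healthy adult cohort
on this task: go RT 507 +/- 169 ms (congruent) vs 532 +/- 162 ms (incongruent),
stop-process latency 266 ms (congruent) vs 277 ms (incongruent), choice-error
rates 2.8% / 6.3%, and staircase tracking toward p(respond | stop) = 0.5.
The ex-Gaussian exponential share (tau = 60 ms) is kept modest so that the
mean-method SSRT estimator, which is biased by RT skew, remains close to the
implanted stop latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .design import DesignConfig, StaircaseState, TrialSpec, next_ssd, speedup_triggered

__all__ = [
    "RaceModelParams",
    "BehavioralRecord",
    "sample_go_rt",
    "simulate_subject",
    "records_to_frame",
    "frame_to_records",
]

_CONGRUENCIES = ("congruent", "incongruent")


def _per_congruency(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {c: float(value[c]) for c in _CONGRUENCIES}
    return {c: float(value) for c in _CONGRUENCIES}


@dataclass
class RaceModelParams:
    """Race-model parameters; scalar values apply to both congruencies.

    go_mu/go_sigma/go_tau parameterize the ex-Gaussian go finishing time
    (mean = mu + tau, var = sigma^2 + tau^2). stop_latency_* parameterize the
    Gaussian stop-process latency. All times in ms.
    """

    go_mu: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 447.0, "incongruent": 472.0}
    )
    go_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 158.0, "incongruent": 150.5}
    )
    go_tau: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 60.0, "incongruent": 60.0}
    )
    stop_latency_mean: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 266.0, "incongruent": 277.0}
    )
    stop_latency_sd: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 30.0, "incongruent": 30.0}
    )
    choice_error_prob: Mapping[str, float] = field(
        default_factory=lambda: {"congruent": 0.028, "incongruent": 0.063}
    )
    miss_prob: float = 0.005
    trigger_failure_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("go_mu", "go_sigma", "go_tau", "stop_latency_mean", "stop_latency_sd", "choice_error_prob"):
            setattr(self, name, _per_congruency(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        for c in _CONGRUENCIES:
            if self.go_sigma[c] < 0 or self.go_tau[c] < 0 or self.stop_latency_sd[c] < 0:
                raise ValueError("go_sigma, go_tau and stop_latency_sd must be >= 0")
            if not 0.0 <= self.choice_error_prob[c] <= 1.0:
                raise ValueError("choice_error_prob must lie in [0, 1]")
        if not 0.0 <= self.miss_prob <= 1.0 or not 0.0 <= self.trigger_failure_prob <= 1.0:
            raise ValueError("miss_prob and trigger_failure_prob must lie in [0, 1]")


@dataclass(frozen=True)
class BehavioralRecord:
    """Realized outcome of one trial."""

    trial: TrialSpec
    ssd_used: float | None  # ms; None on go trials
    response: str  # "left" | "right" | "none"
    rt: float | None  # ms from target onset; None iff response == "none"
    label: str  # correct | incorrect | miss | correct_rejection | failure_to_stop


def sample_go_rt(params: RaceModelParams, congruency: str, rng: np.random.Generator) -> float:
    """Draw one ex-Gaussian go finishing time, truncated below at 1 ms."""
    draw = rng.normal(params.go_mu[congruency], params.go_sigma[congruency])
    tau = params.go_tau[congruency]
    if tau > 0:
        draw += rng.exponential(tau)
    return max(draw, 1.0)


def _stop_latency(params: RaceModelParams, congruency: str, rng: np.random.Generator) -> float:
    # Per-trial stop latency, Gaussian truncated below at 1 ms.
    return max(rng.normal(params.stop_latency_mean[congruency], params.stop_latency_sd[congruency]), 1.0)


def simulate_subject(
    params: RaceModelParams,
    sequence: Sequence[TrialSpec],
    config: DesignConfig,
    seed: int,
) -> tuple[list[BehavioralRecord], StaircaseState]:
    """Simulate one subject through a trial sequence.

    Go trials: with miss_prob the trial is a miss; otherwise the subject
    responds at the go RT (or misses if it exceeds the display window), with
    the wrong hand at the congruency's choice-error rate. Stop trials: the
    response escapes iff the go RT beats SSD + stop latency (always, on a
    trigger failure); the staircase advances after every stop trial.

    The speed-up prompt is evaluated after every responded trial over the last
    ``config.speedup_window`` responded RTs and logged on the staircase-free
    side (returned records are unaffected, the prompt has no behavioral
    consequence in this model).
    """
    rng = substream(seed, "behavior")
    staircase = StaircaseState.from_config(config)
    records: list[BehavioralRecord] = []
    responded_rts: list[float] = []

    for trial in sequence:
        cong = trial.congruency
        correct_hand = config.letter_hand_map[trial.letter]
        wrong_hand = "left" if correct_hand == "right" else "right"

        # Lapse and process draws are made unconditionally so that the random
        # stream consumed per trial is fixed and runs are reproducible even
        # when parameters change branch frequencies.
        u_miss = rng.random()
        go_rt = sample_go_rt(params, cong, rng)
        u_choice = rng.random()
        responds_hand = wrong_hand if u_choice < params.choice_error_prob[cong] else correct_hand

        if trial.trial_type == "go":
            if u_miss < params.miss_prob or go_rt > config.go_display:
                rec = BehavioralRecord(trial, None, "none", None, "miss")
            else:
                label = "correct" if responds_hand == correct_hand else "incorrect"
                rec = BehavioralRecord(trial, None, responds_hand, go_rt, label)
        else:
            ssd = staircase.current_ssd
            u_trigger = rng.random()
            stop_finish = ssd + _stop_latency(params, cong, rng)
            goes = go_rt < stop_finish or u_trigger < params.trigger_failure_prob
            if u_miss < params.miss_prob or go_rt > config.go_display:
                goes = False  # no go process finished -> nothing to stop
            if goes:
                rec = BehavioralRecord(trial, ssd, responds_hand, go_rt, "failure_to_stop")
                staircase = next_ssd(staircase, "failure_to_stop", trial.index)
            else:
                rec = BehavioralRecord(trial, ssd, "none", None, "correct_rejection")
                staircase = next_ssd(staircase, "correct_rejection", trial.index)

        records.append(rec)
        if rec.rt is not None:
            responded_rts.append(rec.rt)
            speedup_triggered(responded_rts, config)  # logged event only
    return records, staircase


def records_to_frame(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    """Flatten behavioral records to a tidy table (one row per trial)."""
    return pd.DataFrame(
        {
            "index": [r.trial.index for r in records],
            "block": [r.trial.block for r in records],
            "trial_type": [r.trial.trial_type for r in records],
            "letter": [r.trial.letter for r in records],
            "side": [r.trial.side for r in records],
            "congruency": [r.trial.congruency for r in records],
            "ssd_used": [r.ssd_used for r in records],
            "response": [r.response for r in records],
            "rt": [r.rt for r in records],
            "label": [r.label for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[BehavioralRecord]:
    """Inverse of :func:`records_to_frame` (NaN -> None for ssd_used/rt)."""
    out = []
    for row in frame.itertuples(index=False):
        trial = TrialSpec(
            index=int(row.index),
            block=int(row.block),
            trial_type=row.trial_type,
            letter=row.letter,
            side=row.side,
            congruency=row.congruency,
        )
        ssd = None if pd.isna(row.ssd_used) else float(row.ssd_used)
        rt = None if pd.isna(row.rt) else float(row.rt)
        out.append(BehavioralRecord(trial, ssd, row.response, rt, row.label))
    return out
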