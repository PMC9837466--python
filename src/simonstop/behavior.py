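"""Behavioral summaries, mean-method SSRT estimation, and subject exclusion.

SSRT (stop-signal reaction time) is estimated by the mean method: mean correct
go RT minus mean realized SSD, valid when staircase tracking holds the
probability of responding on stop trials near 0.5. SSRT is computed per
congruency from that congruency's correct go RTs and the realized SSDs of its
stop trials (the staircase itself is global).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_LETTER_HAND_MAP
from .race import BehavioralRecord

__all__ = [
    "SubjectSummary",
    "ExclusionReport",
    "classify_trial",
    "estimate_ssrt_mean",
    "summarize_subject",
    "apply_exclusions",
    "summaries_to_frame",
]

_SIDES = ("left", "right")
_CONGRUENCIES = ("congruent", "incongruent")


@dataclass
class SubjectSummary:
    """Per-subject behavioral summary.

    Go measures are per (position x congruency) cell; stop measures per
    congruency. Units: accuracy in %, times in ms, p_respond as a proportion.
    Cells with no trials hold NaN and are listed in ``starved_cells``.
    """

    subject_id: str
    go_accuracy: dict = field(default_factory=dict)  # (side, congruency) -> %
    go_mean_rt: dict = field(default_factory=dict)  # (side, congruency) -> ms
    p_respond: dict = field(default_factory=dict)  # congruency -> proportion
    mean_ssd: dict = field(default_factory=dict)  # congruency -> ms
    ssrt: dict = field(default_factory=dict)  # congruency -> ms
    fts_mean_rt: dict = field(default_factory=dict)  # congruency -> ms (failures to stop)
    n_trials: dict = field(default_factory=dict)  # cell key -> count
    p_respond_overall: float = float("nan")
    starved_cells: list = field(default_factory=list)


@dataclass
class ExclusionReport:
    """Outcome of the subject-level exclusion rules."""

    subject_id: str
    p_respond_overall: float
    ssrt_congruent: float
    ssrt_incongruent: float
    ssrt_diff: float  # congruent - incongruent
    excluded: bool
    reasons: list


def classify_trial(
    record: BehavioralRecord,
    letter_hand_map: Mapping[str, str] = DEFAULT_LETTER_HAND_MAP,
) -> str:
    """Classify a trial outcome from its design cell and response.

    Go trials: correct iff the response hand matches the letter's mapped hand,
    miss when no response. Stop trials: correct rejection when no response,
    failure to stop otherwise.
    """
    trial = record.trial
    if record.response not in ("left", "right", "none"):
        raise ValueError(f"malformed response: {record.response!r}")
    if (record.rt is None) != (record.response == "none"):
        raise ValueError("rt must be present iff a response was given")
    if trial.trial_type == "stop":
        return "correct_rejection" if record.response == "none" else "failure_to_stop"
    if trial.trial_type == "go":
        if record.response == "none":
            return "miss"
        return "correct" if record.response == letter_hand_map[trial.letter] else "incorrect"
    raise ValueError(f"malformed trial_type: {trial.trial_type!r}")


def estimate_ssrt_mean(go_rts: Sequence[float], realized_ssds: Sequence[float]) -> float:
    """Mean-method SSRT: mean(go RTs) - mean(realized SSDs)."""
    if len(go_rts) == 0:
        raise ValueError("no go RTs available for SSRT estimation (starved go cell)")
    if len(realized_ssds) == 0:
        raise ValueError("no realized SSDs available for SSRT estimation (starved stop cell)")
    return float(np.mean(go_rts) - np.mean(realized_ssds))


def summarize_subject(
    records: Sequence[BehavioralRecord],
    subject_id: str = "S00",
    letter_hand_map: Mapping[str, str] = DEFAULT_LETTER_HAND_MAP,
    include_choice_errors_in_ssrt: bool = False,
) -> SubjectSummary:
    """Compute the full behavioral summary for one subject.

    Misses are excluded from all RT means. The go RTs entering SSRT are the
    correct go responses only, unless ``include_choice_errors_in_ssrt`` pools
    all responded go trials (consensus-guideline variant).
    """
    s = SubjectSummary(subject_id=subject_id)
    labels = [classify_trial(r, letter_hand_map) for r in records]

    for side in _SIDES:
        for cong in _CONGRUENCIES:
            cell = [
                (r, lab)
                for r, lab in zip(records, labels)
                if r.trial.trial_type == "go" and r.trial.side == side and r.trial.congruency == cong
            ]
            key = (side, cong)
            s.n_trials[("go",) + key] = len(cell)
            scored = [(r, lab) for r, lab in cell if lab != "miss"]
            if not cell or not scored:
                s.go_accuracy[key] = float("nan")
                s.go_mean_rt[key] = float("nan")
                s.starved_cells.append(("go",) + key)
                continue
            s.go_accuracy[key] = 100.0 * sum(lab == "correct" for _, lab in scored) / len(scored)
            rts = [r.rt for r, lab in scored if lab == "correct"]
            s.go_mean_rt[key] = float(np.mean(rts)) if rts else float("nan")

    stop_any = [r for r in records if r.trial.trial_type == "stop"]
    for cong in _CONGRUENCIES:
        stop = [(r, lab) for r, lab in zip(records, labels) if r.trial.trial_type == "stop" and r.trial.congruency == cong]
        s.n_trials[("stop", cong)] = len(stop)
        if not stop:
            for d in (s.p_respond, s.mean_ssd, s.ssrt, s.fts_mean_rt):
                d[cong] = float("nan")
            s.starved_cells.append(("stop", cong))
            continue
        fts = [r for r, lab in stop if lab == "failure_to_stop"]
        s.p_respond[cong] = len(fts) / len(stop)
        s.mean_ssd[cong] = float(np.mean([r.ssd_used for r, _ in stop]))
        s.fts_mean_rt[cong] = float(np.mean([r.rt for r in fts])) if fts else float("nan")
        if not fts:
            s.starved_cells.append(("failure_to_stop", cong))
        go_ok = [
            r.rt
            for r, lab in zip(records, labels)
            if r.trial.trial_type == "go"
            and r.trial.congruency == cong
            and (lab == "correct" or (include_choice_errors_in_ssrt and lab == "incorrect"))
        ]
        try:
            s.ssrt[cong] = estimate_ssrt_mean(go_ok, [r.ssd_used for r, _ in stop])
        except ValueError:
            s.ssrt[cong] = float("nan")
            s.starved_cells.append(("ssrt", cong))

    if stop_any:
        s.p_respond_overall = sum(lab == "failure_to_stop" for lab in labels) / len(stop_any)
    else:
        s.starved_cells.append(("stop", "overall"))
    return s


def apply_exclusions(
    summaries: Sequence[SubjectSummary],
    p_lo: float = 0.25,
    p_hi: float = 0.75,
    ssrt_diff_cut: float = 50.0,
) -> list[ExclusionReport]:
    """Apply the subject exclusion rules.

    A subject is excluded when the overall probability of responding on stop
    trials falls outside [p_lo, p_hi] (staircase tracking failed and the race
    model's SSRT estimate is unreliable), or when SSRT(congruent) exceeds
    SSRT(incongruent) by strictly more than ``ssrt_diff_cut`` ms (the effect
    direction is implausibly reversed).
    """
    reports = []
    for s in summaries:
        ssrt_c = s.ssrt.get("congruent", float("nan"))
        ssrt_i = s.ssrt.get("incongruent", float("nan"))
        diff = ssrt_c - ssrt_i
        reasons = []
        if not (p_lo <= s.p_respond_overall <= p_hi):
            reasons.append(
                f"stop-response probability {s.p_respond_overall:.3f} outside [{p_lo}, {p_hi}]"
            )
        if diff > ssrt_diff_cut:
            reasons.append(
                f"SSRT difference (congruent - incongruent) {diff:.1f} ms > {ssrt_diff_cut} ms"
            )
        reports.append(
            ExclusionReport(
                subject_id=s.subject_id,
                p_respond_overall=s.p_respond_overall,
                ssrt_congruent=ssrt_c,
                ssrt_incongruent=ssrt_i,
                ssrt_diff=diff,
                excluded=bool(reasons),
                reasons=reasons,
            )
        )
    return reports


def summaries_to_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    """Flatten summaries to a tidy table; units are ms, %, and proportions."""
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id, "p_respond_overall": s.p_respond_overall}
        for (side, cong), v in s.go_accuracy.items():
            row[f"go_accuracy_pct_{side}_{cong}"] = v
        for (side, cong), v in s.go_mean_rt.items():
            row[f"go_mean_rt_ms_{side}_{cong}"] = v
        for cong in _CONGRUENCIES:
            row[f"p_respond_{cong}"] = s.p_respond.get(cong)
            row[f"mean_ssd_ms_{cong}"] = s.mean_ssd.get(cong)
            row[f"ssrt_ms_{cong}"] = s.ssrt.get(cong)
            row[f"fts_mean_rt_ms_{cong}"] = s.fts_mean_rt.get(cong)
        rows.append(row)
    return pd.DataFrame(rows)
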