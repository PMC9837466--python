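"""Trial-sequence generation and adaptive stop-signal staircase.

The task crosses a Simon (spatial stimulus-response) manipulation with a stop
signal: a letter (A or B) appears left or right of fixation and maps to a left
or right key press irrespective of its side. On a minority of trials the letter
turns red after the stop-signal delay (SSD) and the response must be withheld.
The SSD is tracked with a one-up/one-down 50 ms staircase so that stopping
succeeds on roughly half of the stop trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from ._rng import substream

__all__ = [
    "DesignConfig",
    "TrialSpec",
    "StaircaseState",
    "generate_trial_sequence",
    "next_ssd",
    "speedup_triggered",
    "sequence_to_frame",
]

TrialType = Literal["go", "stop"]
Side = Literal["left", "right"]

#: Letter-to-hand assignment used in the task: A -> left key, B -> right key.
DEFAULT_LETTER_HAND_MAP: Mapping[str, str] = {"A": "left", "B": "right"}


@dataclass(frozen=True)
class DesignConfig:
    """Session design parameters.

    Defaults give the full session: 9 blocks of 80 go + 24 stop trials
    (936 total, 720 go / 216 stop), SSD staircase starting at 250 ms with
    50 ms steps clamped to [50, 1000] ms, 1700 ms stimulus displays, 1300 ms
    inter-trial interval, and a speed-up prompt when the mean RT of the last
    50 responded trials falls below 450 ms.
    """

    n_blocks: int = 9
    go_per_block: int = 80
    stop_per_block: int = 24
    letter_hand_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LETTER_HAND_MAP)
    )
    initial_ssd: float = 250.0
    ssd_step: float = 50.0
    ssd_min: float = 50.0
    ssd_max: float = 1000.0
    go_display: float = 1700.0
    stop_display: float = 1700.0
    iti: float = 1300.0
    speedup_window: int = 50
    speedup_rt_threshold: float = 450.0
    rng_seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * (self.go_per_block + self.stop_per_block)

    def validate(self) -> None:
        if self.n_blocks < 1 or self.go_per_block < 0 or self.stop_per_block < 0:
            raise ValueError("trial counts must be nonnegative and n_blocks >= 1")
        hands = sorted(self.letter_hand_map.values())
        if sorted(self.letter_hand_map) != ["A", "B"] or hands != ["left", "right"]:
            raise ValueError("letter_hand_map must be a bijection {A,B} -> {left,right}")
        if self.go_per_block % 2 or self.stop_per_block % 2:
            raise ValueError(
                "go_per_block and stop_per_block must be even for an exact "
                "congruent/incongruent balance within each trial type"
            )
        if not (self.ssd_min <= self.initial_ssd <= self.ssd_max):
            raise ValueError("initial_ssd outside [ssd_min, ssd_max]")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's design cell."""

    index: int
    block: int
    trial_type: TrialType
    letter: str
    side: Side
    congruency: str  # "congruent" iff the letter's response hand equals the side

    @staticmethod
    def derive_congruency(letter: str, side: str, letter_hand_map: Mapping[str, str]) -> str:
        return "congruent" if letter_hand_map[letter] == side else "incongruent"


@dataclass
class StaircaseState:
    """Current SSD tracker with bounds, step and full update history."""

    current_ssd: float
    step: float
    min: float
    max: float
    history: list = field(default_factory=list)  # (trial index, ssd used, outcome)

    @classmethod
    def from_config(cls, config: DesignConfig) -> "StaircaseState":
        return cls(
            current_ssd=config.initial_ssd,
            step=config.ssd_step,
            min=config.ssd_min,
            max=config.ssd_max,
        )


def generate_trial_sequence(config: DesignConfig, seed: int) -> list[TrialSpec]:
    """Generate the randomized trial sequence for one session.

    Each block contains exactly ``go_per_block`` go and ``stop_per_block``
    stop trials, with congruent and incongruent trials balanced within each
    trial type (per block, hence also over the session). Letters are split as
    evenly as possible within each congruency cell. Order within a block is
    randomized by the ``design`` substream of ``seed``; the same seed always
    reproduces the identical sequence.
    """
    config.validate()
    rng = substream(seed, "design")

    def cell_stimuli(congruency: str, count: int) -> list[tuple[str, str]]:
        # Congruent cells: letter shown on its own response side; incongruent:
        # on the opposite side. Split the two letters as evenly as possible.
        out = []
        for i in range(count):
            letter = "A" if i % 2 == 0 else "B"
            hand = config.letter_hand_map[letter]
            side = hand if congruency == "congruent" else ("left" if hand == "right" else "right")
            out.append((letter, side))
        return out

    trials: list[TrialSpec] = []
    index = 0
    for block in range(config.n_blocks):
        cells: list[tuple[str, str, str]] = []
        for trial_type, count in (("go", config.go_per_block), ("stop", config.stop_per_block)):
            for congruency in ("congruent", "incongruent"):
                for letter, side in cell_stimuli(congruency, count // 2):
                    cells.append((trial_type, letter, side))
        order = rng.permutation(len(cells))
        for k in order:
            trial_type, letter, side = cells[k]
            trials.append(
                TrialSpec(
                    index=index,
                    block=block,
                    trial_type=trial_type,  # type: ignore[arg-type]
                    letter=letter,
                    side=side,  # type: ignore[arg-type]
                    congruency=TrialSpec.derive_congruency(letter, side, config.letter_hand_map),
                )
            )
            index += 1
    return trials


def next_ssd(
    state: StaircaseState,
    outcome: Literal["correct_rejection", "failure_to_stop"],
    trial_index: int | None = None,
) -> StaircaseState:
    """Advance the staircase after a stop trial.

    A correct rejection makes stopping harder (+step); a failure to stop makes
    it easier (-step). The result is clamped to [min, max] and the transition
    is appended to the history.
    """
    if outcome == "correct_rejection":
        new = state.current_ssd + state.step
    elif outcome == "failure_to_stop":
        new = state.current_ssd - state.step
    else:
        raise ValueError(f"unknown stop-trial outcome: {outcome!r}")
    new = min(max(new, state.min), state.max)
    history = state.history + [(trial_index, state.current_ssd, outcome)]
    return StaircaseState(current_ssd=new, step=state.step, min=state.min, max=state.max, history=history)


def speedup_triggered(recent_rts: Sequence[float], config: DesignConfig) -> bool:
    """True iff the speed-up prompt fires: at least ``speedup_window`` responded
    trials exist and the mean RT of the last ``speedup_window`` of them is
    strictly below ``speedup_rt_threshold``."""
    w = config.speedup_window
    if len(recent_rts) < w:
        return False
    window = list(recent_rts)[-w:]
    return sum(window) / w < config.speedup_rt_threshold


def sequence_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Serialize a trial sequence as a tidy table (CSV-ready)."""
    return pd.DataFrame(
        {
            "index": [t.index for t in trials],
            "block": [t.block for t in trials],
            "trial_type": [t.trial_type for t in trials],
            "letter": [t.letter for t in trials],
            "side": [t.side for t in trials],
            "congruency": [t.congruency for t in trials],
        }
    )
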