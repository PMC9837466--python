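"""Synthetic epoched EEG with known component ground truth.

Each epoch is the sum of stimulus-locked components (P1, N1 over the lateral
posterior channels; N2 frontocentral) and a latency-jittered late positivity
("C" component, the P3 carrier, with frontocentral-plus-parietal topography),
scaled per condition cell, plus sensor noise. The C component's default
condition map implants a congruency x response interaction: its amplitude is
boosted on incongruent stop trials only, emulating a conflict effect that is
specific to stopping.

Ground truth (per-trial C latencies and component amplitudes) is returned
separately and must never feed the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .epochs import EEGEpochs
from .race import BehavioralRecord

__all__ = [
    "ComponentTemplate",
    "EEGSimSpec",
    "GroundTruth",
    "default_templates",
    "generate_epochs",
    "DEFAULT_CHANNELS",
]

#: Default montage: the four quantification electrodes plus neighbors that
#: give the components a plausible (non-degenerate) topography.
DEFAULT_CHANNELS = ["Fz", "FCz", "Cz", "C3", "C4", "Pz", "P7", "P8", "O1", "O2"]

REQUIRED_CHANNELS = ("P7", "P8", "FCz", "Pz")


@dataclass(frozen=True)
class ComponentTemplate:
    """One component: a Hann-lobe waveform over [onset, offset] ms scaled by
    ``amplitude`` (uV, signed) and projected through per-channel topography
    weights (channels absent from the map get weight 0)."""

    name: str
    onset: float  # ms
    offset: float  # ms
    amplitude: float  # uV at the peak of the lobe, at topography weight 1
    topography: Mapping[str, float]

    def waveform(self, times: np.ndarray) -> np.ndarray:
        """Sample the component's time course (topography weight 1)."""
        w = np.zeros_like(times, dtype=float)
        inside = (times >= self.onset) & (times <= self.offset)
        phase = (times[inside] - self.onset) / (self.offset - self.onset)
        w[inside] = self.amplitude * np.sin(np.pi * phase) ** 2
        return w

    def topography_vector(self, channel_labels: Sequence[str]) -> np.ndarray:
        return np.array([float(self.topography.get(ch, 0.0)) for ch in channel_labels])


def default_templates() -> list[ComponentTemplate]:
    """P1/N1 (posterior), N2 (frontocentral) and the late C positivity."""
    return [
        ComponentTemplate("P1", 80.0, 140.0, 3.0, {"P7": 1.0, "P8": 1.0, "O1": 0.6, "O2": 0.6}),
        ComponentTemplate("N1", 140.0, 200.0, -4.0, {"P7": 1.0, "P8": 1.0, "O1": 0.5, "O2": 0.5}),
        ComponentTemplate("N2", 260.0, 350.0, -3.0, {"FCz": 1.0, "Fz": 0.7, "Cz": 0.6}),
        ComponentTemplate("C", 390.0, 790.0, 5.0, {"FCz": 1.0, "Cz": 0.8, "Pz": 0.9, "Fz": 0.5}),
    ]


def _default_condition_map() -> dict:
    # Multiplier per (component, response, congruency); unlisted cells are 1.
    # The C boost on incongruent stop trials is the implanted interaction:
    # +20% of a 5 uV peak = +1 uV.
    return {("C", "stop", "incongruent"): 1.2}


@dataclass
class EEGSimSpec:
    """Synthetic-EEG generation parameters.

    Defaults: 256 Hz sampling, epochs spanning -2000..2000 ms around target
    onset, 50 ms SD Gaussian jitter on the C component's single-trial latency
    (clipped at 3 SD), and 5 uV white sensor noise.
    """

    channel_labels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    srate: float = 256.0
    epoch_span: tuple = (-2000.0, 2000.0)
    component_templates: list = field(default_factory=default_templates)
    c_latency_jitter_sd: float = 50.0  # ms
    condition_amplitude_map: dict = field(default_factory=_default_condition_map)
    noise_sd: float = 5.0  # uV
    noise_spectrum: str = "white"  # "white" | "one_over_f"
    jittered_component: str = "C"
    rng_seed: int = 0

    def validate(self) -> None:
        missing = [ch for ch in REQUIRED_CHANNELS if ch not in self.channel_labels]
        if missing:
            raise ValueError(f"channel_labels must include quantification electrodes; missing {missing}")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise_spectrum {self.noise_spectrum!r}")
        if self.noise_sd < 0 or self.c_latency_jitter_sd < 0:
            raise ValueError("noise_sd and c_latency_jitter_sd must be >= 0")

    def times(self) -> np.ndarray:
        n = int(round((self.epoch_span[1] - self.epoch_span[0]) / 1000.0 * self.srate))
        return self.epoch_span[0] + np.arange(n) * 1000.0 / self.srate


@dataclass
class GroundTruth:
    """Generator-side truth, kept out of the analysis path.

    per_trial: one row per generated epoch with the true C latency offset (ms)
    and realized amplitude multiplier/peak per component.
    """

    per_trial: pd.DataFrame
    templates: list
    condition_amplitude_map: dict
    subject_params: dict = field(default_factory=dict)


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    out = np.fft.irfft(spec, n=shape[-1], axis=-1)
    out *= sd / out.std()
    return out


def generate_epochs(
    spec: EEGSimSpec,
    records: Sequence[BehavioralRecord],
    seed: int,
) -> tuple[EEGEpochs, GroundTruth]:
    """Synthesize epochs for the analyzable trials of one subject.

    Only correct go responses and correct rejections receive an epoch (the
    segmentation used by the analysis). Per epoch: each stimulus-locked
    template is added at its nominal latency; the jittered component is
    shifted by a per-trial integer-sample latency drawn from N(0, jitter_sd);
    every component is scaled by its (component, response, congruency)
    multiplier; sensor noise is added last. Deterministic per seed.
    """
    spec.validate()
    rng = substream(seed, "eeg")
    times = spec.times()
    n_samples = times.size
    n_channels = len(spec.channel_labels)

    keep = [r for r in records if r.label in ("correct", "correct_rejection")]
    n_trials = len(keep)
    meta = pd.DataFrame(
        {
            "trial_index": [r.trial.index for r in keep],
            "response": [r.trial.trial_type for r in keep],
            "congruency": [r.trial.congruency for r in keep],
        }
    )

    dt_ms = 1000.0 / spec.srate
    max_shift = int(np.ceil(3.0 * spec.c_latency_jitter_sd / dt_ms))
    jitter_samples = np.zeros(n_trials, dtype=int)
    if spec.c_latency_jitter_sd > 0:
        raw = rng.normal(0.0, spec.c_latency_jitter_sd, size=n_trials) / dt_ms
        jitter_samples = np.clip(np.round(raw), -max_shift, max_shift).astype(int)

    data = np.zeros((n_trials, n_channels, n_samples))
    truth_rows: dict = {"trial_index": meta["trial_index"], "response": meta["response"], "congruency": meta["congruency"]}

    for tpl in spec.component_templates:
        wave = tpl.waveform(times)
        topo = tpl.topography_vector(spec.channel_labels)
        mult = np.array(
            [
                float(spec.condition_amplitude_map.get((tpl.name, resp, cong), 1.0))
                for resp, cong in zip(meta["response"], meta["congruency"])
            ]
        )
        if tpl.name == spec.jittered_component:
            # guard against the shifted lobe leaving the epoch
            if tpl.onset - max_shift * dt_ms < times[0] or tpl.offset + max_shift * dt_ms > times[-1]:
                raise ValueError("jittered component support exceeds the epoch span at 3 SD")
            idx = np.arange(n_samples)[None, :] - jitter_samples[:, None]
            shifted = wave[np.clip(idx, 0, n_samples - 1)]  # support margin checked above
            data += mult[:, None, None] * topo[None, :, None] * shifted[:, None, :]
            truth_rows["c_latency_ms"] = jitter_samples * dt_ms
        else:
            data += (mult[:, None, None] * topo[None, :, None]) * wave[None, None, :]
        truth_rows[f"amplitude_{tpl.name}"] = mult * tpl.amplitude

    if spec.noise_sd > 0:
        if spec.noise_spectrum == "white":
            data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        else:
            data += _one_over_f_noise(rng, data.shape, spec.noise_sd)

    if "c_latency_ms" not in truth_rows:
        truth_rows["c_latency_ms"] = np.zeros(n_trials)

    epochs = EEGEpochs(
        data=data,
        srate=spec.srate,
        times=times,
        channel_labels=list(spec.channel_labels),
        metadata=meta,
    )
    truth = GroundTruth(
        per_trial=pd.DataFrame(truth_rows),
        templates=list(spec.component_templates),
        condition_amplitude_map=dict(spec.condition_amplitude_map),
    )
    return epochs, truth
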