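"""Residue-iteration temporal decomposition of epoched ERPs.

Single-trial epochs are decomposed into a stimulus-locked cluster (S, fixed
latency, window -200..600 ms) and a latency-variable cluster (C, window
200..800 ms) whose single-trial latency is estimated and refined iteratively:

1. initialize C latencies by cross-correlating each trial with the
   stimulus-locked average restricted to the C window;
2. S-step: S = pointwise median over trials of (trial - C shifted to the
   trial's latency), restricted to the S window;
3. C-step: C = pointwise median over trials of (trial - S) back-aligned by
   the trial's latency, restricted to the C window;
4. re-estimate latencies against the updated C waveform; repeat.

Pointwise medians are the L1-norm waveform estimators; they make the cluster
waveforms robust to outlier trials. Steps 2-3 are alternated to their own
fixed point between latency updates (the waveform split inside the S/C window
overlap relaxes geometrically, so a single pass per latency update would stop
far from the stationary split). A response-locked cluster is not modeled:
response-locked variance is absorbed by C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epochs import EEGEpochs

__all__ = [
    "RideConfig",
    "RideResult",
    "estimate_latency",
    "aligned_median_waveform",
    "ride_decompose",
    "shift_waveform",
]


@dataclass
class RideConfig:
    """RIDE parameters (all times in ms).

    latency_search_halfwidth bounds the per-trial latency offsets; the
    convergence tolerance is in samples of the epoch's sampling rate.
    """

    s_window: tuple = (-200.0, 600.0)
    c_window: tuple = (200.0, 800.0)
    latency_search_halfwidth: float = 300.0
    max_outer_iterations: int = 10
    latency_convergence_tol: int = 1  # samples
    max_inner_iterations: int = 4
    inner_rel_tol: float = 1e-3  # waveform change, relative to max |C|
    taper_frac: float = 0.1  # cosine taper share of the template edges
    model_r: bool = False  # reserved; response-locked cluster not modeled
    min_trials: int = 10
    dtype: str = "float32"  # working precision of the iteration


@dataclass
class RideResult:
    """Decomposition of one subject x condition cell.

    s_waveform / c_waveform are (channels, samples) in uV on the epoch's time
    axis (zero outside their windows); c_latencies_ms are per-trial offsets
    with median 0 by construction. For every trial,
    ``trial = s_waveform + shift(c_waveform, latency) + residual`` exactly.
    """

    s_waveform: np.ndarray
    c_waveform: np.ndarray
    c_latencies_ms: np.ndarray
    n_iterations: int
    converged: bool
    residual_rms: np.ndarray  # per trial
    times: np.ndarray
    channel_labels: list
    latency_update_history: list = field(default_factory=list)  # total |update| per outer iter


def shift_waveform(waveform: np.ndarray, shift_samples: int) -> np.ndarray:
    """Shift (channels, samples) right by ``shift_samples``, zero-padding."""
    out = np.zeros_like(waveform)
    s = int(shift_samples)
    if s == 0:
        out[:] = waveform
    elif s > 0:
        out[:, s:] = waveform[:, :-s]
    else:
        out[:, :s] = waveform[:, -s:]
    return out


def _tapered_mask(n_window: int, taper_frac: float) -> np.ndarray:
    from scipy.signal.windows import tukey

    if taper_frac <= 0:
        return np.ones(n_window)
    return tukey(n_window, alpha=min(2.0 * taper_frac, 1.0))


def _shift_order(halfwidth_samples: int) -> np.ndarray:
    """Candidate shifts ordered by |shift| (ties: negative first) so that an
    argmax over equal scores lands on the smallest absolute shift."""
    shifts = np.arange(-halfwidth_samples, halfwidth_samples + 1)
    return shifts[np.lexsort((shifts, np.abs(shifts)))]


def _batch_latencies(
    data: np.ndarray,
    template: np.ndarray,
    window_idx: np.ndarray,
    halfwidth_samples: int,
    taper_frac: float,
    subtract: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial shifts (samples) maximizing the cross-correlation, summed
    over channels, between each trial and the template restricted to the
    window. data: (n, ch, s); template: (ch, s)."""
    n, n_ch, n_samp = data.shape
    tpl = np.zeros_like(template)
    tpl[:, window_idx] = template[:, window_idx] * _tapered_mask(window_idx.size, taper_frac)
    if not np.any(tpl):
        raise ValueError("latency template is all zero within the search window")

    i0, i1 = window_idx[0], window_idx[-1] + 1
    lo = max(i0 - halfwidth_samples, 0)
    hi = min(i1 + halfwidth_samples, n_samp)
    shifts = _shift_order(halfwidth_samples)

    core = tpl[:, i0:i1]  # (ch, L)
    width = hi - lo
    bank = np.zeros((shifts.size, n_ch, width))
    for k, s in enumerate(shifts):
        a = i0 + s - lo
        src_lo = max(0, -a)
        src_hi = core.shape[1] - max(0, a + core.shape[1] - width)
        if src_hi > src_lo:
            bank[k, :, a + src_lo : a + src_hi] = core[:, src_lo:src_hi]

    seg = data[:, :, lo:hi]
    if subtract is not None:
        seg = seg - subtract[None, :, lo:hi]
    scores = seg.reshape(n, -1) @ bank.reshape(shifts.size, -1).T  # (n, n_shifts)
    return shifts[np.argmax(scores, axis=1)]


def estimate_latency(
    residual_trial: np.ndarray,
    template: np.ndarray,
    window: tuple,
    halfwidth: float,
    times: np.ndarray,
    srate: float,
    taper_frac: float = 0.1,
) -> float:
    """Latency (ms) of ``template`` within one trial.

    Returns the shift in [-halfwidth, +halfwidth] ms maximizing the
    channel-summed cross-correlation restricted to ``window``; ties break
    toward the smallest absolute shift.
    """
    trial = np.atleast_2d(np.asarray(residual_trial, dtype=float))
    template = np.atleast_2d(np.asarray(template, dtype=float))
    idx = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    h = int(round(halfwidth / 1000.0 * srate))
    shift = _batch_latencies(trial[None, ...], template, idx, h, taper_frac)[0]
    return float(shift * 1000.0 / srate)


def aligned_median_waveform(trials: np.ndarray, latencies_ms: np.ndarray, srate: float) -> np.ndarray:
    """Back-shift each (ch, s) trial by its latency and take the pointwise
    median across trials (the L1-norm waveform)."""
    trials = np.asarray(trials, dtype=float)
    shifts = np.round(np.asarray(latencies_ms) / 1000.0 * srate).astype(int)
    aligned = np.stack([shift_waveform(t, -s) for t, s in zip(trials, shifts)])
    return np.median(aligned, axis=0)


def _gather_waveform(full: np.ndarray, pos: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """full: (ch, s); pos/valid: (n, L) precomputed clipped sample indices.
    Returns (n, ch, L) with out-of-range samples zeroed."""
    out = np.transpose(full[:, pos], (1, 0, 2))
    return out * valid[:, None, :]


def _shift_positions(idx: np.ndarray, shifts: np.ndarray, n_samp: int, sign: int) -> tuple:
    """Clipped index matrix idx + sign*shift_i and its validity mask."""
    pos = idx[None, :] + sign * shifts[:, None]
    valid = (pos >= 0) & (pos < n_samp)
    return np.clip(pos, 0, n_samp - 1), valid


def ride_decompose(epochs: EEGEpochs, config: RideConfig | None = None) -> RideResult:
    """Decompose the kept trials of one condition cell into S and C clusters."""
    cfg = config or RideConfig()
    if cfg.model_r:
        raise NotImplementedError("the response-locked cluster is not modeled")
    data64 = epochs.kept().data
    data = data64.astype(cfg.dtype)
    n, n_ch, n_samp = data.shape
    if n < cfg.min_trials:
        raise ValueError(f"need at least {cfg.min_trials} kept trials, got {n}")
    times = epochs.times
    srate = epochs.srate

    s_idx = np.flatnonzero((times >= cfg.s_window[0]) & (times <= cfg.s_window[1]))
    c_idx = np.flatnonzero((times >= cfg.c_window[0]) & (times <= cfg.c_window[1]))
    if s_idx.size == 0 or c_idx.size == 0:
        raise ValueError("S/C windows lie outside the epoch span")
    h = int(round(cfg.latency_search_halfwidth / 1000.0 * srate))

    # (1) initial latencies from the stimulus-locked average
    avg = data.mean(axis=0)
    shifts = _batch_latencies(data, avg, c_idx, h, cfg.taper_frac)
    shifts = shifts - int(np.round(np.median(shifts)))

    S = np.zeros((n_ch, n_samp), dtype=data.dtype)
    C = np.zeros((n_ch, n_samp), dtype=data.dtype)
    converged = False
    n_outer = 0
    history: list = []

    data_s = np.ascontiguousarray(data[:, :, s_idx])
    arange_n = np.arange(n)[:, None, None]
    arange_ch = np.arange(n_ch)[None, :, None]

    for outer in range(cfg.max_outer_iterations):
        n_outer = outer + 1
        # positions are fixed while latencies are fixed; precompute per outer
        pos_s, valid_s = _shift_positions(s_idx, shifts, n_samp, sign=-1)
        pos_c, valid_c = _shift_positions(c_idx, shifts, n_samp, sign=+1)
        data_c = data[arange_n, arange_ch, pos_c[:, None, :]] * valid_c[:, None, :]

        # (2)+(3) alternate S- and C-steps toward the stationary split at the
        # current latencies (the relaxation continues across outer iterations
        # through the warm-started S and C)
        for _ in range(cfg.max_inner_iterations):
            c_on_s = _gather_waveform(C, pos_s, valid_s)
            S_new = np.zeros_like(S)
            S_new[:, s_idx] = np.median(data_s - c_on_s, axis=0)

            s_on_c = _gather_waveform(S_new, pos_c, valid_c)
            C_new = np.zeros_like(C)
            C_new[:, c_idx] = np.median(data_c - s_on_c, axis=0)

            scale = max(np.abs(C_new).max(), np.abs(S_new).max(), 1e-12)
            delta_wave = max(np.abs(C_new - C).max(), np.abs(S_new - S).max())
            S, C = S_new, C_new
            if delta_wave <= cfg.inner_rel_tol * scale:
                break

        # (4) re-estimate latencies against the updated C waveform
        new_shifts = _batch_latencies(data, C, c_idx, h, cfg.taper_frac, subtract=S)
        new_shifts = new_shifts - int(np.round(np.median(new_shifts)))
        move = np.abs(new_shifts - shifts)
        history.append(int(move.sum()))
        shifts = new_shifts
        if move.max() <= cfg.latency_convergence_tol:
            converged = True
            break

    if not converged:
        warnings.warn("RIDE latency estimation did not converge; returning last iterate")

    S = S.astype(float)
    C = C.astype(float)
    resid = data64 - S[None, :, :] - np.stack([shift_waveform(C, s) for s in shifts])
    return RideResult(
        s_waveform=S,
        c_waveform=C,
        c_latencies_ms=shifts * 1000.0 / srate,
        n_iterations=n_outer,
        converged=converged,
        residual_rms=np.sqrt((resid**2).mean(axis=(1, 2))),
        times=times,
        channel_labels=list(epochs.channel_labels),
        latency_update_history=history,
    )
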