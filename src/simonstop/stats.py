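"""ERP quantification and the within-subject statistical battery.

Components are quantified as mean amplitudes in fixed windows at fixed
electrodes on the decomposed cluster waveforms. Condition effects are tested
with 2x2 repeated-measures ANOVAs (factors response: go vs stop, and
congruency), validated by a BIC-approximated posterior probability of the
null hypothesis, with paired t or Wilcoxon post hocs and sensor-level
sign-flip permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream

__all__ = [
    "ComponentDef",
    "AnovaResult",
    "BayesResult",
    "PosthocResult",
    "DEFAULT_COMPONENTS",
    "quantify_amplitude",
    "rm_anova_2x2",
    "posthoc_tests",
    "masson_pbic",
    "permutation_paired_test",
    "grand_average_and_difference",
    "effect_table",
]


@dataclass(frozen=True)
class ComponentDef:
    """Mean-amplitude quantification rule for one ERP component."""

    name: str
    cluster: str  # "S" | "C"
    electrodes: tuple
    window: tuple  # ms

    def label(self) -> str:
        return f"{self.name}_{'_'.join(self.electrodes)}"


#: Canonical component set: P1/N1 over lateral posterior electrodes, N2
#: frontocentral (all in the stimulus-locked cluster), and the P3 on the
#: C-cluster quantified at FCz and Pz separately.
DEFAULT_COMPONENTS = [
    ComponentDef("P1", "S", ("P7", "P8"), (100.0, 120.0)),
    ComponentDef("N1", "S", ("P7", "P8"), (160.0, 180.0)),
    ComponentDef("N2", "S", ("FCz",), (290.0, 320.0)),
    ComponentDef("P3", "C", ("FCz",), (530.0, 650.0)),
    ComponentDef("P3", "C", ("Pz",), (530.0, 650.0)),
]


@dataclass
class AnovaResult:
    """One effect of a 2x2 within-subject ANOVA."""

    effect: str
    F: float
    df: tuple
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class BayesResult:
    """BIC-approximated posterior probability of the null hypothesis.

    delta_bic compares the effect model against the null on the within-subject
    sums of squares; p_h0_given_d = BF01 / (1 + BF01) with
    BF01 = exp(delta_bic / 2). ``n_used`` records which sample size entered
    the approximation (subjects, by the within-subject contrast convention).
    """

    p_h0_given_d: float
    delta_bic: float
    n_used: int
    convention: str = "n = number of subjects (within-subject contrast)"

    @property
    def evidence(self) -> str:
        p = self.p_h0_given_d
        if p < 0.5:
            return "favors alternative"
        if p < 0.75:
            return "weak evidence for null"
        if p < 0.95:
            return "positive evidence for null"
        if p < 0.99:
            return "strong evidence for null"
        return "very strong evidence for null"


@dataclass
class PosthocResult:
    method: str  # "paired_t" | "wilcoxon"
    statistic: float
    df: int | None
    p: float
    degenerate: bool = False


def quantify_amplitude(
    cluster_waveform: np.ndarray,
    definition: ComponentDef,
    channel_labels: Sequence[str],
    times: np.ndarray,
) -> float:
    """Mean amplitude (uV) over the component's window, averaged across its
    electrodes, on a (channels, samples) cluster waveform."""
    missing = [e for e in definition.electrodes if e not in channel_labels]
    if missing:
        raise KeyError(f"electrode(s) {missing} not in channel labels {list(channel_labels)}")
    idx = np.flatnonzero((times >= definition.window[0]) & (times <= definition.window[1]))
    if idx.size == 0:
        raise ValueError(f"window {definition.window} outside the time axis")
    rows = [list(channel_labels).index(e) for e in definition.electrodes]
    return float(np.asarray(cluster_waveform)[rows][:, idx].mean())


def effect_table(values: Mapping, factor_a: str = "response", factor_b: str = "congruency") -> pd.DataFrame:
    """Build a tidy subject x cell table from {subject: {(a_level, b_level): value}}.

    Subjects with incomplete cells are dropped (with their ids recorded in
    ``frame.attrs['dropped']``).
    """
    rows, dropped = [], []
    levels_a, levels_b = set(), set()
    for subj, cells in values.items():
        for a, b in cells:
            levels_a.add(a)
            levels_b.add(b)
    for subj, cells in values.items():
        if any((a, b) not in cells or not np.isfinite(cells[(a, b)]) for a in levels_a for b in levels_b):
            dropped.append(subj)
            continue
        for (a, b), v in cells.items():
            rows.append({"subject": subj, factor_a: a, factor_b: b, "value": float(v)})
    frame = pd.DataFrame(rows)
    frame.attrs["dropped"] = dropped
    frame.attrs["factors"] = (factor_a, factor_b)
    return frame


def _table_to_cube(table: pd.DataFrame, factor_a: str, factor_b: str) -> tuple:
    la = sorted(table[factor_a].unique())
    lb = sorted(table[factor_b].unique())
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("rm_anova_2x2 requires exactly two levels per factor")
    pivot = table.pivot_table(index="subject", columns=[factor_a, factor_b], values="value")
    if pivot.isna().any().any():
        raise ValueError("incomplete cells; drop affected subjects first")
    cube = np.empty((len(pivot), 2, 2))
    for i, a in enumerate(la):
        for j, b in enumerate(lb):
            cube[:, i, j] = pivot[(a, b)].to_numpy()
    return cube, la, lb


def rm_anova_2x2(
    table: pd.DataFrame,
    factor_a: str = "response",
    factor_b: str = "congruency",
) -> dict:
    """Two-by-two within-subject ANOVA.

    Returns {effect: AnovaResult} for the two main effects and the
    interaction, each tested against its own subject-by-effect error term
    with df = (1, n-1). With two levels per factor, sphericity holds
    trivially (the Greenhouse-Geisser correction is identically 1) and each
    F equals the square of the paired t on the corresponding within-subject
    contrast. Partial eta squared = SS_effect / (SS_effect + SS_error).
    """
    cube, la, lb = _table_to_cube(table, factor_a, factor_b)
    n = cube.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete subjects")

    grand = cube.mean()
    m_subj = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ia = cube.mean(axis=2)
    m_ib = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    results = {}
    specs = {
        factor_a: (
            2 * n * ((m_a - grand) ** 2).sum(),
            2 * ((m_ia - m_subj[:, None] - m_a[None, :] + grand) ** 2).sum(),
        ),
        factor_b: (
            2 * n * ((m_b - grand) ** 2).sum(),
            2 * ((m_ib - m_subj[:, None] - m_b[None, :] + grand) ** 2).sum(),
        ),
        f"{factor_a} x {factor_b}": (
            n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum(),
            (
                (
                    cube
                    - m_ia[:, :, None]
                    - m_ib[:, None, :]
                    - m_ab[None, :, :]
                    + m_subj[:, None, None]
                    + m_a[None, :, None]
                    + m_b[None, None, :]
                    - grand
                )
                ** 2
            ).sum(),
        ),
    }
    for effect, (ss_eff, ss_err) in specs.items():
        df = (1, n - 1)
        if ss_err <= 0:
            raise ZeroDivisionError(f"zero error variance for effect {effect!r}; F undefined")
        F = (ss_eff / df[0]) / (ss_err / df[1])
        results[effect] = AnovaResult(
            effect=effect,
            F=float(F),
            df=df,
            p=float(sps.f.sf(F, *df)),
            partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )
    return results


def posthoc_tests(
    cond_a: Sequence[float],
    cond_b: Sequence[float],
    normality: bool | None = None,
    alpha_normality: float = 0.05,
) -> PosthocResult:
    """Paired post hoc comparison.

    Uses a paired t test when the paired differences are compatible with
    normality, a Wilcoxon signed-rank test otherwise (exact when sample size
    permits). ``normality=None`` decides via a Kolmogorov-Smirnov test on the
    standardized differences.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.allclose(d, 0.0):
        return PosthocResult("degenerate", 0.0, len(d) - 1, 1.0, degenerate=True)
    if normality is None:
        sd = d.std(ddof=1)
        normality = bool(sps.kstest((d - d.mean()) / sd, "norm").pvalue > alpha_normality) if sd > 0 else False
    if normality:
        t, p = sps.ttest_rel(a, b)
        return PosthocResult("paired_t", float(t), len(d) - 1, float(p))
    method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
    res = sps.wilcoxon(a, b, method=method)
    return PosthocResult("wilcoxon", float(res.statistic), None, float(res.pvalue))


def masson_pbic(
    ss_effect: float,
    ss_error: float,
    n_observations: int,
    extra_params: int = 1,
) -> BayesResult:
    """BIC-based posterior probability of the null for one ANOVA effect.

    delta_bic = n * ln(SSE1 / SSE0) + k * ln(n), where SSE0 (null) =
    ss_error + ss_effect, SSE1 (effect model) = ss_error and k is the number
    of extra parameters of the effect model. BF01 = exp(delta_bic / 2);
    P(H0|D) = BF01 / (1 + BF01).
    """
    if ss_effect < 0 or ss_error <= 0:
        raise ValueError("ss_effect must be >= 0 and ss_error > 0")
    if n_observations < 2:
        raise ValueError("need n_observations >= 2")
    n = int(n_observations)
    sse0 = ss_error + ss_effect
    sse1 = ss_error
    delta_bic = n * np.log(sse1 / sse0) + extra_params * np.log(n)
    bf01 = np.exp(delta_bic / 2.0)
    return BayesResult(
        p_h0_given_d=float(bf01 / (1.0 + bf01)),
        delta_bic=float(delta_bic),
        n_used=n,
    )


def permutation_paired_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 2500,
    seed: int = 0,
    statistic: str = "mean",
    alpha: float = 0.05,
) -> dict:
    """Sign-flip permutation test of paired condition differences, per channel.

    cond_a/cond_b: (n_subjects,) or (n_subjects, n_channels). The observed
    statistic is the mean paired difference (or the paired t with
    statistic="t"); the null distribution flips each subject's difference
    sign at random. Two-sided p = (#{|perm| >= |obs|} + 1) / (n_perm + 1).
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(cond_b, dtype=float).T).T
    if a.shape != b.shape:
        raise ValueError("condition arrays must be subject-matched")
    d = a - b  # (n, ch)
    n = d.shape[0]
    rng = substream(seed, "permutation")

    def stat(x: np.ndarray) -> np.ndarray:
        if statistic == "mean":
            return x.mean(axis=0)
        if statistic == "t":
            sd = x.std(axis=0, ddof=1)
            return np.divide(x.mean(axis=0), sd / np.sqrt(n), out=np.zeros(x.shape[1]), where=sd > 0)
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat(d)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = np.abs(np.stack([stat(d * s[:, None]) for s in signs]))
    p = (np.sum(perm >= np.abs(obs)[None, :], axis=0) + 1.0) / (n_perm + 1.0)
    return {"statistic": obs, "p": p, "significant": p < alpha, "n_perm": n_perm}


def grand_average_and_difference(cell_waveforms: Mapping) -> dict:
    """Group waveforms and congruency difference waves.

    cell_waveforms: {(response, congruency): array (n_subjects, channels,
    samples)}. Returns per-cell grand averages plus, per response level, the
    incongruent - congruent difference wave.
    """
    grand = {cell: np.asarray(w).mean(axis=0) for cell, w in cell_waveforms.items()}
    diffs = {}
    for resp in sorted({r for r, _ in grand}):
        if (resp, "incongruent") in grand and (resp, "congruent") in grand:
            diffs[resp] = grand[(resp, "incongruent")] - grand[(resp, "congruent")]
    return {"grand_average": grand, "difference_waves": diffs}
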