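"""End-to-end pipeline: simulate a cohort, preprocess, decompose, test.

Library functions behind the command-line interface. A run directory has a
fixed layout::

    run/
      manifest.json
      behavior/sub-XX.csv        simulated behavioral logs
      ground_truth/sub-XX.csv    generator truth (never read by analysis)
      epochs/sub-XX.h5           raw synthetic epochs
      preprocessed/sub-XX.h5     after reference/rejection/baseline
      ride/sub-XX_<cell>_latencies.csv, sub-XX.h5
      stats/results.json, report.txt

Every random draw derives from the manifest seed through named substreams
(design, behavior, eeg, permutation) and a per-subject spawn, so reruns with
the same seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import apply_exclusions, summaries_to_frame, summarize_subject
from .design import DesignConfig, generate_trial_sequence
from .eegsim import EEGSimSpec, generate_epochs
from .epochs import EEGEpochs
from .preprocess import PreprocessConfig, preprocess_epochs
from .race import RaceModelParams, frame_to_records, records_to_frame, simulate_subject
from .ride import RideConfig, RideResult, ride_decompose
from .stats import (
    DEFAULT_COMPONENTS,
    effect_table,
    masson_pbic,
    permutation_paired_test,
    posthoc_tests,
    quantify_amplitude,
    rm_anova_2x2,
)

__all__ = [
    "CohortConfig",
    "subject_seed",
    "simulate_cohort_behavior",
    "subject_cell_decompositions",
    "subject_component_amplitudes",
    "cohort_erp_analysis",
    "run_simulate",
    "run_preprocess",
    "run_ride",
    "run_stats",
    "run_all",
    "load_config",
]

CELLS = [("go", "congruent"), ("go", "incongruent"), ("stop", "congruent"), ("stop", "incongruent")]


@dataclass
class CohortConfig:
    """Study-level configuration: cohort size plus per-stage parameter sets."""

    n_subjects: int = 27
    design: DesignConfig = field(default_factory=DesignConfig)
    race: RaceModelParams = field(default_factory=RaceModelParams)
    eeg: EEGSimSpec = field(default_factory=EEGSimSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ride: RideConfig = field(default_factory=RideConfig)
    components: list = field(default_factory=lambda: list(DEFAULT_COMPONENTS))


def subject_seed(seed: int, subject: int) -> int:
    """Stable per-subject seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(subject),))
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path) -> CohortConfig:
    """Read a YAML config whose sections mirror the stage dataclasses."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = CohortConfig()
    if "n_subjects" in raw:
        cfg.n_subjects = int(raw["n_subjects"])
    for section in ("design", "race", "eeg", "preprocess", "ride"):
        options = raw.get(section) or {}
        obj = getattr(cfg, section)
        for key in options:
            if not hasattr(obj, key):
                raise KeyError(f"unknown {section} option {key!r}")
        if options:
            setattr(cfg, section, dataclasses.replace(obj, **options))
    return cfg


# -- simulation -------------------------------------------------------------


def simulate_cohort_behavior(config: CohortConfig, seed: int) -> list:
    """Simulate behavior for every subject; returns a list of record lists."""
    out = []
    for i in range(config.n_subjects):
        s = subject_seed(seed, i)
        seq = generate_trial_sequence(config.design, s)
        records, _ = simulate_subject(config.race, seq, config.design, s)
        out.append(records)
    return out


# -- ERP analysis -----------------------------------------------------------


def subject_cell_decompositions(
    epochs: EEGEpochs, ride_config: RideConfig | None = None
) -> dict[tuple, RideResult]:
    """RIDE-decompose each (response, congruency) cell of one subject."""
    results = {}
    for resp, cong in CELLS:
        mask = ((epochs.metadata["response"] == resp) & (epochs.metadata["congruency"] == cong)).to_numpy()
        results[(resp, cong)] = ride_decompose(epochs.select(mask), ride_config)
    return results


def subject_component_amplitudes(
    decompositions: dict[tuple, RideResult],
    components: Sequence = DEFAULT_COMPONENTS,
) -> dict[str, dict[tuple, float]]:
    """Quantify every component in every cell: {component label: {cell: uV}}."""
    out: dict[str, dict[tuple, float]] = {c.label(): {} for c in components}
    for cell, res in decompositions.items():
        for comp in components:
            wave = res.s_waveform if comp.cluster == "S" else res.c_waveform
            out[comp.label()][cell] = quantify_amplitude(wave, comp, res.channel_labels, res.times)
    return out


def cohort_erp_analysis(
    amplitudes_per_subject: Sequence[dict],
    seed: int = 0,
    n_perm: int = 2500,
) -> dict:
    """Run the 2x2 response x congruency battery on cohort amplitudes.

    amplitudes_per_subject: one dict per subject as returned by
    :func:`subject_component_amplitudes`. Returns per component: the effect
    table, ANOVA results, the interaction's null posterior probability, and
    stop-condition post hocs.
    """
    results = {}
    if not amplitudes_per_subject:
        raise ValueError("no subjects to analyze")
    for label in amplitudes_per_subject[0]:
        table = effect_table({i: amps[label] for i, amps in enumerate(amplitudes_per_subject)})
        anova = rm_anova_2x2(table)
        inter = anova["response x congruency"]
        bayes = masson_pbic(inter.ss_effect, inter.ss_error, n_observations=table["subject"].nunique())
        pivot = table.pivot_table(index="subject", columns=["response", "congruency"], values="value")
        posthoc_stop = posthoc_tests(pivot[("stop", "incongruent")], pivot[("stop", "congruent")])
        posthoc_go = posthoc_tests(pivot[("go", "incongruent")], pivot[("go", "congruent")])
        results[label] = {
            "table": table,
            "anova": anova,
            "interaction_p_h0": bayes,
            "posthoc_stop_incongruent_vs_congruent": posthoc_stop,
            "posthoc_go_incongruent_vs_congruent": posthoc_go,
        }
    results["_seed"] = seed
    results["_n_perm"] = n_perm
    return results


# -- run directory stages ---------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_snapshot(config: CohortConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    snap = {"n_subjects": config.n_subjects}
    for name in ("design", "race", "eeg", "preprocess", "ride"):
        obj = getattr(config, name)
        d = dataclasses.asdict(obj)
        if name == "eeg":
            d["component_templates"] = [dataclasses.asdict(t) for t in obj.component_templates]
            d["condition_amplitude_map"] = {str(k): v for k, v in d["condition_amplitude_map"].items()}
        snap[name] = enc(d)
    snap["components"] = [dataclasses.asdict(c) for c in config.components]
    return snap


def _write_manifest(run_dir: Path, seed: int, config: CohortConfig, stage: str) -> None:
    path = run_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "seed": seed,
        "config": _config_snapshot(config),
        "substreams": ["design", "behavior", "eeg", "permutation"],
        "stages": {},
        "files": {},
    }
    manifest["stages"][stage] = {"completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(run_dir))] = _digest(f)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _sub_id(i: int) -> str:
    return f"sub-{i:02d}"


def run_simulate(out_dir, seed: int, config: CohortConfig | None = None) -> Path:
    """Simulate the full cohort: behavioral logs, epochs, ground truth."""
    config = config or CohortConfig()
    run = Path(out_dir)
    for sub in ("behavior", "ground_truth", "epochs"):
        (run / sub).mkdir(parents=True, exist_ok=True)
    for i in range(config.n_subjects):
        s = subject_seed(seed, i)
        seq = generate_trial_sequence(config.design, s)
        records, _ = simulate_subject(config.race, seq, config.design, s)
        records_to_frame(records).to_csv(run / "behavior" / f"{_sub_id(i)}.csv", index=False)
        ep, truth = generate_epochs(config.eeg, records, s)
        ep.save_h5(run / "epochs" / f"{_sub_id(i)}.h5")
        truth.per_trial.to_csv(run / "ground_truth" / f"{_sub_id(i)}.csv", index=False)
    _write_manifest(run, seed, config, "simulate")
    return run


def _subject_ids(run: Path, stage: str) -> list:
    return sorted(p.stem for p in (run / stage).glob("sub-*.h5")) or sorted(
        p.stem for p in (run / "behavior").glob("sub-*.csv")
    )


def run_preprocess(run_dir, config: CohortConfig | None = None, seed: int = 0) -> Path:
    config = config or CohortConfig()
    run = Path(run_dir)
    (run / "preprocessed").mkdir(exist_ok=True)
    for sid in _subject_ids(run, "epochs"):
        ep = EEGEpochs.load_h5(run / "epochs" / f"{sid}.h5")
        preprocess_epochs(ep, config.preprocess).save_h5(run / "preprocessed" / f"{sid}.h5")
    _write_manifest(run, seed, config, "preprocess")
    return run


def run_ride(run_dir, config: CohortConfig | None = None, seed: int = 0) -> Path:
    import h5py

    config = config or CohortConfig()
    run = Path(run_dir)
    (run / "ride").mkdir(exist_ok=True)
    for sid in _subject_ids(run, "preprocessed"):
        ep = EEGEpochs.load_h5(run / "preprocessed" / f"{sid}.h5")
        dec = subject_cell_decompositions(ep, config.ride)
        with h5py.File(run / "ride" / f"{sid}.h5", "w") as f:
            for (resp, cong), res in dec.items():
                g = f.create_group(f"{resp}_{cong}")
                g.create_dataset("s_waveform", data=res.s_waveform)
                g.create_dataset("c_waveform", data=res.c_waveform)
                g.create_dataset("c_latencies_ms", data=res.c_latencies_ms)
                g.create_dataset("times", data=res.times)
                g.attrs["channel_labels"] = json.dumps(res.channel_labels)
                g.attrs["converged"] = res.converged
                g.attrs["n_iterations"] = res.n_iterations
        for (resp, cong), res in dec.items():
            pd.DataFrame(
                {"trial": np.arange(res.c_latencies_ms.size), "latency_ms": res.c_latencies_ms}
            ).to_csv(run / "ride" / f"{sid}_{resp}_{cong}_latencies.csv", index=False)
    _write_manifest(run, seed, config, "ride")
    return run


def _behavioral_battery(summaries) -> dict:
    """Position x congruency ANOVAs on go measures and the congruency SSRT test."""
    out: dict = {}
    frames = {
        "go_accuracy_pct": lambda s: {(side, cong): s.go_accuracy[(side, cong)] for side, cong in s.go_accuracy},
        "go_mean_rt_ms": lambda s: {(side, cong): s.go_mean_rt[(side, cong)] for side, cong in s.go_mean_rt},
    }
    for name, getter in frames.items():
        table = effect_table({s.subject_id: getter(s) for s in summaries}, factor_a="position", factor_b="congruency")
        try:
            out[name] = rm_anova_2x2(table, factor_a="position", factor_b="congruency")
        except (ValueError, ZeroDivisionError) as exc:
            out[name] = {"error": str(exc)}
    ssrt_c = [s.ssrt["congruent"] for s in summaries]
    ssrt_i = [s.ssrt["incongruent"] for s in summaries]
    ok = [i for i in range(len(ssrt_c)) if np.isfinite(ssrt_c[i]) and np.isfinite(ssrt_i[i])]
    out["ssrt_congruency_posthoc"] = posthoc_tests([ssrt_c[i] for i in ok], [ssrt_i[i] for i in ok])
    out["ssrt_means"] = {
        "congruent": float(np.nanmean(ssrt_c)),
        "incongruent": float(np.nanmean(ssrt_i)),
    }
    return out


def run_stats(run_dir, config: CohortConfig | None = None, seed: int = 0, n_perm: int = 2500) -> Path:
    """Behavioral summaries + exclusions + ERP battery + permutation map.

    Reads only the behavior logs and RIDE outputs — never the ground truth.
    """
    import h5py

    config = config or CohortConfig()
    run = Path(run_dir)
    (run / "stats").mkdir(exist_ok=True)

    summaries = []
    for sid in sorted(p.stem for p in (run / "behavior").glob("sub-*.csv")):
        records = frame_to_records(pd.read_csv(run / "behavior" / f"{sid}.csv"))
        summaries.append(summarize_subject(records, sid, config.design.letter_hand_map))
    summaries_to_frame(summaries).to_csv(run / "stats" / "behavior_summaries.csv", index=False)
    exclusions = apply_exclusions(summaries)
    pd.DataFrame([dataclasses.asdict(e) for e in exclusions]).to_csv(
        run / "stats" / "exclusions.csv", index=False
    )
    behavioral = _behavioral_battery(summaries)

    amps = []
    c_waves_by_cell: dict[tuple, list] = {cell: [] for cell in CELLS}
    channel_labels: list = []
    times = None
    for sid in sorted(p.stem for p in (run / "ride").glob("sub-*.h5")):
        dec = {}
        with h5py.File(run / "ride" / f"{sid}.h5", "r") as f:
            for resp, cong in CELLS:
                g = f[f"{resp}_{cong}"]
                res = RideResult(
                    s_waveform=g["s_waveform"][()],
                    c_waveform=g["c_waveform"][()],
                    c_latencies_ms=g["c_latencies_ms"][()],
                    n_iterations=int(g.attrs["n_iterations"]),
                    converged=bool(g.attrs["converged"]),
                    residual_rms=np.array([]),
                    times=g["times"][()],
                    channel_labels=json.loads(g.attrs["channel_labels"]),
                )
                dec[(resp, cong)] = res
                c_waves_by_cell[(resp, cong)].append(res.c_waveform)
                channel_labels = res.channel_labels
                times = res.times
        amps.append(subject_component_amplitudes(dec, config.components))

    report: dict = {"behavioral": behavioral, "excluded": [e.subject_id for e in exclusions if e.excluded]}
    starved = [s.subject_id for s in summaries if s.starved_cells]
    if starved:
        report["warnings"] = [f"starved cells for {sid}" for sid in starved]
    if amps:
        try:
            erp = cohort_erp_analysis(amps, seed=seed, n_perm=n_perm)
            report["erp"] = erp
        except ValueError as exc:
            report.setdefault("warnings", []).append(f"ERP battery not testable: {exc}")
            amps = []
    if amps:
        # sensor-level permutation map: stop incongruent vs congruent mean
        # C-cluster amplitude in the P3 window, per channel
        win = next(c for c in config.components if c.cluster == "C").window
        idx = np.flatnonzero((times >= win[0]) & (times <= win[1]))
        a = np.stack([w[:, idx].mean(axis=1) for w in c_waves_by_cell[("stop", "incongruent")]])
        b = np.stack([w[:, idx].mean(axis=1) for w in c_waves_by_cell[("stop", "congruent")]])
        perm = permutation_paired_test(a, b, n_perm=n_perm, seed=seed)
        report["permutation_stop_incongruent_vs_congruent"] = {
            "channels": channel_labels,
            "mean_difference_uV": perm["statistic"].tolist(),
            "p": perm["p"].tolist(),
            "significant": perm["significant"].tolist(),
        }

    (run / "stats" / "results.json").write_text(json.dumps(_jsonable(report), indent=2))
    (run / "stats" / "report.txt").write_text(format_report(report))
    _write_manifest(run, seed, config, "stats")
    return run


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items() if k != "table"}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return None
    return obj


def _fmt_anova(effects: dict) -> str:
    if "error" in effects:
        return f"  (not testable: {effects['error']})\n"
    lines = []
    for name, r in effects.items():
        lines.append(
            f"  {name}: F({r.df[0]}, {r.df[1]}) = {r.F:.2f}, P = {r.p:.3f}, partial eta^2 = {r.partial_eta_sq:.2f}"
        )
    return "\n".join(lines) + "\n"


def format_report(report: dict) -> str:
    """Human-readable summary mirroring the analysis battery's structure."""
    out = ["== Behavioral results ==", ""]
    b = report["behavioral"]
    for name in ("go_accuracy_pct", "go_mean_rt_ms"):
        out.append(f"{name} (position x congruency ANOVA):")
        out.append(_fmt_anova(b[name]))
    m = b["ssrt_means"]
    ph = b["ssrt_congruency_posthoc"]
    out.append(
        f"SSRT (mean method): congruent {m['congruent']:.0f} ms, incongruent {m['incongruent']:.0f} ms; "
        f"{ph.method}: stat = {ph.statistic:.2f}, P = {ph.p:.3f}"
    )
    out.append(f"Excluded subjects: {report['excluded'] or 'none'}")
    for w in report.get("warnings", []):
        out.append(f"warning: {w}")
    if "erp" in report:
        out += ["", "== ERP results (response x congruency) =="]
        for label, res in report["erp"].items():
            if label.startswith("_"):
                continue
            out.append(f"\n{label}:")
            out.append(_fmt_anova(res["anova"]))
            bayes = res["interaction_p_h0"]
            out.append(f"  interaction P(H0|D) = {bayes.p_h0_given_d:.3f} ({bayes.evidence})")
            for key in ("posthoc_stop_incongruent_vs_congruent", "posthoc_go_incongruent_vs_congruent"):
                ph = res[key]
                out.append(f"  {key}: {ph.method} stat = {ph.statistic:.2f}, P = {ph.p:.3f}")
    if "permutation_stop_incongruent_vs_congruent" in report:
        pm = report["permutation_stop_incongruent_vs_congruent"]
        sig = [ch for ch, s in zip(pm["channels"], pm["significant"]) if s]
        out += ["", "== Sensor-level permutation map (stop: incongruent vs congruent) =="]
        out.append(f"significant channels (P < 0.05): {sig or 'none'}")
    return "\n".join(out) + "\n"


def run_all(out_dir, seed: int, config: CohortConfig | None = None, n_perm: int = 2500) -> Path:
    config = config or CohortConfig()
    run = run_simulate(out_dir, seed, config)
    run_preprocess(run, config, seed)
    run_ride(run, config, seed)
    return run_stats(run, config, seed, n_perm=n_perm)
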