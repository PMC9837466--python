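# simonstop

Simulation and EEG analysis pipeline for a combined **Simon / stop-signal
task** — a paradigm that asks how stimulus–response conflict affects the
ability to cancel an already-initiated response.

In the task, a letter (A or B) shown left or right of fixation maps to a
left- or right-hand key press irrespective of its side; trials are
*congruent* when side and response hand coincide. On 23% of trials the letter
turns red after an adaptively tracked stop-signal delay (SSD) and the
response must be withheld. The package is written for cognitive
neurophysiologists who want a fully testable, ground-truth-equipped version
of this analysis chain:

- **Task design** — trial sequences (9 × (80 go + 24 stop) = 936 trials,
  congruency balanced within trial type) and the one-up/one-down SSD
  staircase (start 250 ms, ±50 ms, clamped to 50–1000 ms), which tracks
  p(respond | stop) ≈ 0.5.
- **Race model** — behavior from the independent horse-race model: an
  ex-Gaussian go process races a Gaussian stop process launched at the SSD;
  a response escapes iff go finishes before SSD + stop latency. SSRT (stop
  signal reaction time) is estimated by the *mean method*,
  `SSRT = mean(go RT) − mean(SSD)`, valid near the 0.5 tracking point.
- **Synthetic EEG** — epoched data (−2000..2000 ms, 256 Hz) built from known
  components: stimulus-locked P1/N1/N2 and a latency-jittered late
  positivity ("C", the P3 carrier) whose amplitude carries a congruency ×
  response interaction confined to stop trials. Ground truth is kept out of
  the analysis path.
- **Preprocessing** — zero-phase 0.5–40 Hz band-pass (order 8) + 50 Hz
  notch, polyphase resampling to 256 Hz, common average reference,
  ±100 μV / flatline artifact rejection in −200..200 ms, −200..0 ms
  baseline. BrainVision and EDF+ readers provide real-data entry points.
- **RIDE** — residue iteration decomposition of each subject × condition
  cell into a stimulus-locked S-cluster (−200..600 ms) and a
  latency-variable C-cluster (200..800 ms) via iterated L1 (pointwise
  median) waveforms and single-trial cross-correlation latency estimation.
- **Statistics** — component mean amplitudes (P1/N1 at P7/P8, N2 at FCz, P3
  at FCz and Pz); 2×2 within-subject ANOVA with partial η²; the
  BIC-approximated posterior null probability
  `P(H0|D) = BF01/(1+BF01)`, `BF01 = exp(ΔBIC/2)`,
  `ΔBIC = n·ln(SSE1/SSE0) + ln n`; paired-t/Wilcoxon post hocs; sensor-level
  sign-flip permutation tests (2500 permutations).

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Run a small synthetic study (8 subjects, 3 blocks) end to end:

```bash
cat > example.yaml <<'EOF'
n_subjects: 8
design:
  n_blocks: 3
EOF
simonstop all --seed 7 --config example.yaml --out example_run
```

This simulates behavior and EEG, preprocesses, decomposes, and prints the
report (`example_run/stats/report.txt`). Excerpts from that exact run:

```
SSRT (mean method): congruent 269 ms, incongruent 288 ms; paired_t: stat = -1.59, P = 0.156

P3_FCz:
  response: F(1, 7) = 958.87, P = 0.000, partial eta^2 = 0.99
  congruency: F(1, 7) = 4.35, P = 0.075, partial eta^2 = 0.38
  response x congruency: F(1, 7) = 4.88, P = 0.063, partial eta^2 = 0.41

  interaction P(H0|D) = 0.254 (favors alternative)
  posthoc_stop_incongruent_vs_congruent: paired_t stat = 2.76, P = 0.028

== Sensor-level permutation map (stop: incongruent vs congruent) ==
significant channels (P < 0.05): ['FCz', 'O1', 'O2']
```

Reading it: the simulated SSRT is longer on incongruent trials (stopping is
harder under conflict, though 8 subjects give little power for the paired
test), and the implanted C-cluster boost on incongruent stop trials surfaces
exactly where it should — a congruency effect at P3-FCz that is specific to
the stop condition (post hoc P = 0.028), with the BIC posterior favoring the
interaction. At full cohort size (27 subjects, the default) the interaction
itself is reliably significant. The large "response" main effect is a
decomposition artifact of unequal cell sizes, discussed in the methods note.

The stages are also available separately (`simonstop simulate / preprocess /
ride / stats / report`), and everything is callable as a library:

```python
from simonstop import (DesignConfig, RaceModelParams, generate_trial_sequence,
                       simulate_subject, summarize_subject)

cfg = DesignConfig()
seq = generate_trial_sequence(cfg, seed=1)
records, staircase = simulate_subject(RaceModelParams(), seq, cfg, seed=1)
print(summarize_subject(records).ssrt)
# {'congruent': 284.5..., 'incongruent': 299.2...}
```

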