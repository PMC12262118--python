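# erplearn

Learning-dynamics analysis for passive-oddball EEG.

When a listener is passively exposed to a repetitive "standard" sound with
rare "deviant" sounds, the brain's automatic change detection shows up in the
deviant-minus-standard event-related potential (ERP) as a fronto-central
negativity around 150–250 ms (the mismatch negativity, MMN) followed by a
positivity around 250–350 ms (P3a). Over hours and days of exposure these
components change — the signature of passive perceptual learning. `erplearn`
implements a complete, testable pipeline for quantifying those learning
dynamics at three timescales:

1. **Day-wise ERP effects** — balanced deviant/standard epoch pairs, a
   grand-average-driven definition of the MMN/P3a analysis windows
   (±35 ms around the most negative / most positive post-stimulus peak), and
   linear mixed-effects models `amplitude ~ day + (day | participant)` fitted
   by maximum likelihood with Satterthwaite degrees of freedom.
2. **Multivariate decoding** — a shrinkage-regularized linear discriminant
   trained independently at every epoch timepoint on the three frontal
   channels (F3, Fz, F4) of single-trial differential responses, labelled by
   exposure day; performance is the cross-validated ROC AUC (stratified
   5-fold, 100 repeats), with group inference by a one-tailed sign-flip
   permutation *t* test against chance (AUC = 0.5), Bonferroni-corrected.
3. **Within-session dynamics** — sliding averages of per-trial component
   amplitudes over overlapping bins of 100 trials in one-trial steps, with a
   linear trend fit; a "clear trend" is a significant slope (*p* < 0.05)
   combined with *R²* > 0.5.

Because raw human recordings of this kind are rarely shareable, the package
ships a **synthetic session generator**: 21-channel, 500 Hz multi-day
oddball sessions (11,000 stimuli per session, 80/10/10 composition, deviants
separated by ≥2 standards, ISI uniform in 440–520 ms) with cosine-bell
MMN/P3a templates whose amplitudes and latencies drift across days and
within sessions by known amounts. Every analysis stage can therefore be
tested against ground truth, end to end, without any data download.

## Worked example

```bash
python examples/01_build_sequence.py
```

```
total stimuli:       11000
standards:           8800
small deviants:      1100
large deviants:      1100
separation violations (min 2 standards between deviants): 0
SOA range:           640.0 - 720.0 ms
session duration:    124.7 min
```

Counts are exact (randomization is over order only) and the exhaustive scan
confirms every consecutive deviant pair is buffered by at least two
standards. `examples/04_sliding_trends.py` runs the within-session stage on
a 508-trial simulated day:

```
trials: 508  ->  sliding windows: 400
slope: 0.925 nV per window step
t = 25.5, p = 6.81e-86, R^2 = 0.62
clear trend: True
```

i.e. the programmed MMN attenuation is detected as a clear positive trend
(the negative component moves toward zero). The other examples cover the
data-driven window selection (`02`), temporal decoding with exact
permutation inference (`03`), mixed models (`05`), and the one-config
pipeline (`06`).

The pipeline is also exposed as a thin CLI over the same functions:

```bash
erplearn init-config run.yaml
erplearn run-all --config run.yaml
```

Stages (`simulate`, `preprocess`, `erp`, `decode`, `slide`, `lmm`) can be
run individually; artifacts land in the configured output directory with a
manifest recording the config hash and seed.

## Layout

- `src/erplearn/sequences.py` — constrained oddball sequence construction
- `src/erplearn/simulate.py` — synthetic multi-day EEG with programmed drift
- `src/erplearn/preprocess.py` — filtering, artifact handling, epoching,
  deviant–standard pairing, pair rejection, linked-mastoid re-referencing
- `src/erplearn/erp.py` — differential ERPs, window selection, measures
- `src/erplearn/decoding.py` — per-timepoint LDA, CV AUC, permutation tests
- `src/erplearn/sliding.py` — sliding averages and trend statistics
- `src/erplearn/mixed.py` — day-wise mixed models with Satterthwaite df
- `src/erplearn/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats,
  configuration and orchestration

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
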