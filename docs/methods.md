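# Methods

This note documents the models, defaults and numerical choices behind
`erplearn`, and what the synthetic generator does and does not emulate.

## Paradigm and synthetic data

**Sequences.** A session is 11,000 stimuli: 80% standards and 10% of each of
two deviant magnitudes, with at least two standards between consecutive
deviants, 200 ms stimulus duration and an offset-to-onset ISI drawn uniformly
from 440–520 ms. Counts are exact — the proportions define counts of a fixed
total, and randomization is over order only. Construction is rejection-free:
the standards surplus (after reserving the minimum per between-deviant gap)
is distributed over the gaps as a uniform random composition (stars and
bars), which makes every admissible ordering equally likely and guarantees
termination; deviant types are then shuffled uniformly over the deviant
slots. ISIs are sampled as continuous milliseconds and onsets rounded to the
sample grid when epochs are cut.

**Evoked model.** Every stimulus evokes a shared obligatory response
(N1-like at 100 ms, P2-like at 180 ms); deviants additionally evoke an
MMN-like negativity and a P3a-like positivity. Deflections are truncated
cosine bells `a · ½(1 + cos(π(t−c)/w))` on `|t−c| ≤ w` — smooth, compactly
supported, and analytically integrable, so window means have closed forms
the tests use as oracles. Default deviant components: small deviant
MMN −1.30 μV / P3a +1.19 μV, large deviant MMN −2.00 μV / P3a +1.05 μV,
centred at 220 ms and 320 ms with 50 ms half-width. The scalp topography is
frontal-maximal (gain 1.0 at F3/Fz/F4, decreasing posteriorly); the mastoid
A2 carries no evoked signal, so linked-mastoid re-referencing shifts only
noise, which keeps amplitude ground truth exact.

**Learning dynamics.** Per component and deviant type, a drift specification
programs (i) additive per-day amplitude offsets (day 1 = 0 by definition;
defaults follow the day-wise effect sizes of the study this emulates, e.g.
+0.72 μV for the large-deviant MMN on day 4), (ii) a linear within-session
amplitude slope in μV per deviant trial (defaults 1–1.5 nV/trial), and
(iii) a per-day latency shift (MMN latencies shorten by 4–5 ms/day).
A per-participant Gaussian amplitude offset (SD 0.8 μV) adds the
between-subject variability the mixed models' random intercepts absorb.

**Noise and artifacts.** Additive Gaussian noise, default white with
σ = 10 μV per sample (typical of filtered scalp EEG; it yields
trial-averaged standard errors of the same order as the emulated study's
reported SEs), optionally 1/f-shaped via spectral weighting. Artifact
transients (default 3% of trials, ±300 μV cosine bumps) exercise the
±200 μV pair rejection; the rate is only loosely calibrated, since the
emulated study reports just the minimum number of surviving trials (508).

**What the generator does not emulate:** acoustic stimulus structure,
realistic ocular/muscle artifact topographies (the muscle detector is
exercised with spectral bursts instead), non-stationary drift of electrode
impedances, and correlated cross-channel noise. Passing tests therefore
demonstrate correctness of the analysis machinery and its statistical
calibration under the stated model, not robustness to every failure mode of
real recordings.

## Preprocessing

Order: muscle-artifact detection on the raw 500 Hz data → zero-phase
filtering → anti-aliased downsampling to 250 Hz → epoching →
baseline correction → deviant–standard pairing → pair rejection →
linked-mastoid re-referencing. Detection runs first because the 35–128 Hz
detection band exceeds the Nyquist frequency of 250 Hz data; windows (0.5 s)
whose band power exceeds the per-channel **median** window spectrum by 10 dB
are flagged (the median is the robust baseline the threshold needs a
reference for), and epochs overlapping flagged spans are dropped.

Filters are 4th-order Butterworth applied forward–backward (`sosfiltfilt`):
a 30 Hz low-pass and a 50 ± 2 Hz band-stop notch; DC is preserved.
Downsampling uses polyphase FIR resampling. Epochs live on the **closed**
grid [−100, +600] ms — both endpoints on the sample grid, 176 samples at
250 Hz — and baseline correction subtracts the per-trial, per-channel mean
of [−100, 0] ms.

Pairing keeps only the standard immediately preceding each deviant
(balancing counts by construction) and uses original sequence indices, so
dropped epochs can never mis-pair neighbours; a deviant whose predecessor
was dropped contributes no pair. Rejection removes the **whole pair** when
either member exceeds ±200 μV on the analysis channels (F3, Fz, F4 plus A2
by default — the channel set is configurable since conventions differ).
With a left-mastoid online reference, linked-mastoid re-referencing is
`x − A2/2`; applying it twice is a hard error because the identity only
holds for left-mastoid-referenced input. An externally supplied
component-removal (unmixing) matrix can be hooked in before epoching;
no decomposition is implemented.

## ERP windows and measures

The grand-average differential (unweighted mean over participants, days and
deviant types of the frontal-mean deviant-minus-standard traces) defines the
component windows: MMN = ±35 ms around the most negative **post-stimulus**
(0–600 ms) sample, P3a likewise around the most positive. The post-stimulus
restriction exists because baseline extrema are noise artifacts. Windows
closer than twice the half-width raise a diagnostic error (the waveform then
lacks two separable deflections); windows at the epoch edge are clipped with
a warning; flat stretches tie-break to the earliest sample. Amplitude is the
window-mean voltage, latency the within-window extreme sample (earliest on
ties). Latency is milliseconds throughout; the mixed-model reporting layer
can emit seconds.

## Temporal decoding

The single-trial "differential response" is defined as deviant epoch minus
its paired preceding standard — consistent with the balanced pairing (the
construction is not otherwise canonical). Features are the three frontal
channels, anti-alias downsampled to 50 Hz (36 timepoints per epoch). At each
timepoint a binary LDA is trained: weights `S_λ⁻¹ (m₁ − m₀)` with the pooled
within-class covariance shrunk toward scaled identity,
`S_λ = (1−λ)S + λ·(tr S / p)·I`; λ defaults to the analytic Ledoit–Wolf
estimate from the training fold. Cross-validation is stratified 5-fold,
reshuffled each of 100 repeats; AUC (rank-based, ties ½) is averaged over
folds, then repeats. Day pairs are decoded separately per deviant type.

Group inference on window-mean AUCs: one-sample *t* on (AUC − 0.5), null
distribution by sign-flips of the centred values — all 2ⁿ patterns
enumerated when 2ⁿ ≤ n_perm (exact p), otherwise 10,000 random flips with
add-one smoothing; one-tailed (greater), Bonferroni family size 3 (the three
day-1-vs-later comparisons) by default and configurable, since other family
conventions are defensible. Sign-flipping was chosen over within-CV label
permutation because the group-level statistic is the participant mean. A
day-2-vs-day-4 comparison can be added through the config's comparison list.

## Sliding trends

Per-trial window amplitudes (frontal-mean differential voltage in a
component window) are averaged over bins of 100 trials advancing one trial
per step, truncated to 400 windows to match the emulated study's convention
(508 trials would otherwise give 409; the cap is configurable and can be
disabled). By linearity the per-trial shortcut equals re-averaging full ERPs
per bin, to float tolerance — the tests assert this identity. The trend is
OLS amplitude-on-window-index; `clear_trend = (p < 0.05) AND (R² > 0.5)`.

Two group readings are reported side by side, because the single-series OLS
p-value is anticonservative (adjacent windows share 99 trials; the test
suite demonstrates the inflation by simulation): a one-sample *t* test of
per-participant slopes against zero — one slope per series is a valid
block-level unit — and the OLS fit on the participant-averaged series,
whose R² describes the strength of the mean trajectory. The clear-trend flag
combines the group slope test's p with the averaged-series R².

## Mixed models

Per component × deviant type × response (amplitude in μV, latency in ms),
the model is `response ~ day` (categorical, day 1 the reference) with
by-participant random intercepts and day slopes, estimated by maximum
likelihood via statsmodels' MixedLM. Satterthwaite degrees of freedom are
computed in-package: for each fixed effect, `df = 2f²/(gᵀA g)` where
`f(θ) = [(Σᵢ XᵢᵀVᵢ⁻¹Xᵢ)⁻¹]ⱼⱼ`, `g` is its finite-difference gradient in the
variance parameters, and `A` is the pseudo-inverse observed information of
the profiled ML log-likelihood (central-difference Hessian). df is clamped
to [1, n − k]. The implementation reproduces R lmerTest's estimates, SEs,
df and p on a shared fixture to ≲0.1% (an oracle test runs Rscript when
available).

Full random-slope covariances routinely fail to converge with 14
participants (the random-effect count then equals the observation count), so
the structure simplifies on failure — full → diagonal → intercept-only —
each step logged; if every mixed structure fails (e.g. zero residual
variance), pooled OLS is the final fallback. In the balanced complete design
the fixed-effect estimates equal day-mean contrasts regardless of the
variance parameters, which the degenerate-variance test asserts exactly.
Nominal 95% CI coverage is verified by a 200-replicate simulation (±3 pp).

## Problem sizes and tolerances

The test suite runs scaled-down studies chosen to keep the full run at a few
minutes while leaving every statistical check adequately powered: unit
fixtures use 300–600-stimulus sessions; parameter recovery uses 8
participants × 2 days × 1,100 stimuli; the end-to-end smoke run uses 2
participants × 4 days × 1,100 stimuli at full analysis defaults (100
decoding repeats, 10,000 permutations); decoder null calibration uses 200
replicates of 14 participants with small feature tensors. Exact identities
(pair balance, linearity, cumulative-sum moving averages, rank-AUC vs pair
counting) are asserted at 1e-10–1e-12; Monte-Carlo quantities carry 2-SEM or
stated relative tolerances; the null decoder must sit within ±0.02 of
AUC 0.5 and the permutation test within ±2 pp of the 5% nominal rate.

## Known limitations

- The EDF writer quantizes to 16 bits over the per-file physical range
  (round-trip error ≤ range/32767); the BrainVision writer (float32) is
  exact. Recordings are zero-padded to whole 1 s EDF records.
- Muscle detection assumes a stationary baseline spectrum per channel;
  slowly varying broadband power would shift the median reference.
- The sliding-stage cap of 400 windows discards trailing windows rather
  than re-binning; sessions with fewer than `bin_size` trials per deviant
  type are skipped with a logged warning.
- Satterthwaite df at variance boundaries (singular information) falls back
  to the residual df; this matches the degenerate limit but is approximate
  just off the boundary.
- The decoder assumes exactly two classes and three feature channels per
  the paradigm; no temporal generalization or other classifiers.
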