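"""Synthetic multi-day oddball EEG with known learning dynamics.

The generator emulates a passive-oddball exposure study: a 21-channel montage
sampled at 500 Hz, sessions of 11,000 stimuli (80% standards, 10% each
deviant, deviants separated by at least two standards, ISI uniform in
440-520 ms), and deviant-specific change-detection components — a fronto-
central negativity (MMN-like, near 220 ms) followed by a positivity
(P3a-like, near 320 ms).  Component amplitudes and latencies drift across
days and within a session according to a :class:`DriftSpec`, giving every
downstream analysis stage a known ground truth to recover.

All stimuli evoke a shared obligatory auditory response (N1/P2-like), which
cancels exactly in the deviant-minus-standard differential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import MONTAGE_21, ContinuousRecording, epoch_grid
from .sequences import (DEV_LARGE, DEV_SMALL, STANDARD, SequenceSpec,
                        StimulusSequence, build_sequence)

MMN = "MMN"
P3A = "P3a"

#: Relative scalp gain of the evoked components per electrode
#: (frontal-maximal topography; the mastoid carries no evoked signal so the
#: linked-mastoid re-reference leaves component amplitudes untouched).
DEFAULT_TOPOGRAPHY = {
    "Fp1": 0.7, "Fp2": 0.7, "F3": 1.0, "F4": 1.0, "F7": 0.7, "F8": 0.7,
    "Fz": 1.0, "C3": 0.5, "C4": 0.5, "Cz": 0.6, "P3": 0.25, "P4": 0.25,
    "Pz": 0.3, "T3": 0.3, "T4": 0.3, "T5": 0.15, "T6": 0.15,
    "O1": 0.1, "O2": 0.1, "Oz": 0.1, "A2": 0.0,
}


@dataclass(frozen=True)
class ComponentTemplate:
    """A smooth evoked deflection: truncated cosine bell.

    ``amplitude_uv`` is the signed peak at unit-gain channels; the deflection
    spans ``center_ms +/- width_ms`` and is identically zero outside.
    """

    name: str
    center_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def evaluate(self, times_ms: np.ndarray, amplitude_uv: float | None = None,
                 center_ms: float | None = None) -> np.ndarray:
        amp = self.amplitude_uv if amplitude_uv is None else amplitude_uv
        ctr = self.center_ms if center_ms is None else center_ms
        x = (times_ms - ctr) / self.width_ms
        out = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
        return amp * out

    def window_mean(self, start_ms: float, end_ms: float,
                    amplitude_uv: float | None = None) -> float:
        """Analytic mean of the deflection over [start, end] ms (oracle use)."""
        amp = self.amplitude_uv if amplitude_uv is None else amplitude_uv
        a = np.clip((start_ms - self.center_ms) / self.width_ms, -1.0, 1.0)
        b = np.clip((end_ms - self.center_ms) / self.width_ms, -1.0, 1.0)
        # integral of 0.5(1+cos(pi x)) from a to b, in units of width_ms
        integ = 0.5 * (b - a) + (np.sin(np.pi * b) - np.sin(np.pi * a)) / (2 * np.pi)
        return amp * integ * self.width_ms / (end_ms - start_ms)


@dataclass(frozen=True)
class TemplateSet:
    """Evoked templates: shared obligatory response plus per-deviant components."""

    common: tuple[ComponentTemplate, ...]
    deviant: dict[str, tuple[ComponentTemplate, ...]]

    def components_for(self, label: str) -> tuple[ComponentTemplate, ...]:
        if label == STANDARD:
            return self.common
        if label not in self.deviant:
            raise ValueError(f"unknown trial label {label!r}")
        return self.common + self.deviant[label]


def default_templates() -> TemplateSet:
    """Study-condition templates.

    Deviant component amplitudes follow the day-1 (reference) levels of the
    study this generator emulates: small-deviant MMN -1.30 uV / P3a +1.19 uV,
    large-deviant MMN -2.00 uV / P3a +1.05 uV, centred at 220 ms (MMN) and
    320 ms (P3a).
    """
    common = (
        ComponentTemplate("N1", center_ms=100.0, width_ms=40.0, amplitude_uv=-1.0),
        ComponentTemplate("P2", center_ms=180.0, width_ms=50.0, amplitude_uv=0.8),
    )
    deviant = {
        DEV_SMALL: (
            ComponentTemplate(MMN, 220.0, 50.0, -1.30),
            ComponentTemplate(P3A, 320.0, 50.0, 1.19),
        ),
        DEV_LARGE: (
            ComponentTemplate(MMN, 220.0, 50.0, -2.00),
            ComponentTemplate(P3A, 320.0, 50.0, 1.05),
        ),
    }
    return TemplateSet(common=common, deviant=deviant)


@dataclass(frozen=True)
class ComponentDrift:
    """Learning dynamics of one component of one deviant type.

    ``day_offsets_uv[d-1]`` is added to the template amplitude on day ``d``
    (day 1 is the reference, offset 0 by definition); the within-day slope
    adds ``slope * trial_index`` uV where ``trial_index`` counts that deviant
    type's trials within the session; latencies shift by
    ``latency_shift_ms_per_day * (day - 1)``.
    """

    day_offsets_uv: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    within_day_slope_uv_per_trial: float = 0.0
    latency_shift_ms_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.day_offsets_uv and self.day_offsets_uv[0] != 0.0:
            raise ValueError("day 1 is the reference day; its offset must be 0")
        vals = (*self.day_offsets_uv, self.within_day_slope_uv_per_trial,
                self.latency_shift_ms_per_day)
        if not np.all(np.isfinite(vals)):
            raise ValueError("drift values must be finite")

    def amplitude_offset(self, day: int, trial_index: int) -> float:
        off = self.day_offsets_uv[day - 1] if day - 1 < len(self.day_offsets_uv) else 0.0
        return off + self.within_day_slope_uv_per_trial * trial_index

    def latency_offset(self, day: int) -> float:
        return self.latency_shift_ms_per_day * (day - 1)


@dataclass(frozen=True)
class DriftSpec:
    """Drift per (deviant type, component): keys ``(label, component_name)``."""

    components: dict[tuple[str, str], ComponentDrift] = field(default_factory=dict)

    def get(self, label: str, component: str) -> ComponentDrift:
        return self.components.get((label, component), ComponentDrift())


def default_drift() -> DriftSpec:
    """Study-condition drift: per-day amplitude offsets matching the emulated
    study's day-wise fixed-effect estimates, latency shortening for the MMN,
    and modest within-session trends (MMN attenuating, P3a growing)."""
    return DriftSpec(components={
        (DEV_SMALL, MMN): ComponentDrift((0.0, 0.31, 0.27, 0.25), 0.0015, -5.0),
        (DEV_SMALL, P3A): ComponentDrift((0.0, 0.04, 0.26, 0.24), 0.0015, 0.0),
        (DEV_LARGE, MMN): ComponentDrift((0.0, 0.15, 0.28, 0.72), 0.0010, -4.0),
        (DEV_LARGE, P3A): ComponentDrift((0.0, 0.41, 0.84, 1.00), 0.0, 0.0),
    })


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: Gaussian with optional 1/f^a spectral shaping, plus
    rare high-amplitude transients emulating movement artifacts."""

    sigma_uv: float = 10.0
    spectral_exponent: float = 0.0
    artifact_rate: float = 0.03
    artifact_amplitude_uv: float = 300.0

    def __post_init__(self) -> None:
        if self.sigma_uv < 0:
            raise ValueError("sigma_uv must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")


def _colored_noise(rng: np.random.Generator, shape: tuple[int, ...],
                   sigma: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, std = sigma."""
    white = rng.standard_normal(shape)
    if sigma == 0.0:
        return np.zeros(shape)
    if exponent == 0.0:
        return sigma * white
    n = shape[-1]
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sigma * shaped / std


def _evoked_trial(label: str, templates: TemplateSet, day: int, trial_index: int,
                  drift: DriftSpec, times_ms: np.ndarray) -> np.ndarray:
    """Noise-free single-channel (unit gain) evoked trace for one trial."""
    trace = np.zeros_like(times_ms)
    for tpl in templates.components_for(label):
        if label == STANDARD or tpl in templates.common:
            trace += tpl.evaluate(times_ms)
        else:
            d = drift.get(label, tpl.name)
            amp = tpl.amplitude_uv + d.amplitude_offset(day, trial_index)
            ctr = tpl.center_ms + d.latency_offset(day)
            trace += tpl.evaluate(times_ms, amplitude_uv=amp, center_ms=ctr)
    return trace


def simulate_epoch(label: str, templates: TemplateSet, day: int, trial_index: int,
                   drift: DriftSpec, noise: NoiseSpec, rng: np.random.Generator,
                   fs: float = 500.0,
                   channel_names: tuple[str, ...] = MONTAGE_21,
                   topography: dict[str, float] | None = None) -> np.ndarray:
    """One trial on the [-100, 600] ms grid: channels x timepoints, uV.

    Standard trials carry the obligatory response only; deviant trials add
    the MMN-like and P3a-like deflections scaled/shifted by the drift for
    (day, trial_index).  Noise and artifact transients follow ``noise``.
    """
    topo = DEFAULT_TOPOGRAPHY if topography is None else topography
    times = epoch_grid(fs)
    trace = _evoked_trial(label, templates, day, trial_index, drift, times)
    gains = np.array([topo.get(c, 0.0) for c in channel_names])
    data = gains[:, None] * trace[None, :]
    data = data + _colored_noise(rng, (len(channel_names), len(times)),
                                 noise.sigma_uv, noise.spectral_exponent)
    if noise.artifact_rate > 0 and rng.uniform() < noise.artifact_rate:
        data += _artifact_transient(rng, len(channel_names), times, noise)
    return data


def _artifact_transient(rng: np.random.Generator, n_channels: int,
                        times_ms: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    center = rng.uniform(times_ms[0] + 50.0, times_ms[-1] - 50.0)
    sign = rng.choice([-1.0, 1.0])
    bump = ComponentTemplate("artifact", center, 60.0,
                             sign * noise.artifact_amplitude_uv)
    return np.tile(bump.evaluate(times_ms), (n_channels, 1))


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Study conditions for the multi-day simulation.

    Defaults are the emulated study's: 14 participants, 4 daily sessions of
    11,000 stimuli at 500 Hz.  ``participant_sd_uv`` is the SD of a stable
    per-participant amplitude offset applied to every deviant component
    (between-subject variability, the random intercept the day-wise mixed
    model absorbs).
    """

    n_participants: int = 14
    n_days: int = 4
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fs: float = 500.0
    participant_sd_uv: float = 0.8
    seed: int = 0

    def templates(self) -> TemplateSet:
        return default_templates()

    def drift(self) -> DriftSpec:
        return default_drift()


@dataclass
class SimulatedSession:
    """One participant-day: continuous recording + event table + truth."""

    recording: ContinuousRecording
    events: "object"  # pandas DataFrame: onset, duration, trial_type
    sequence: StimulusSequence
    participant: str
    day: int


def simulate_session(config: StudyConfig, participant_idx: int, day: int,
                     rng: np.random.Generator,
                     participant_offset_uv: float = 0.0) -> SimulatedSession:
    """Synthesize one continuous session with its BIDS-styled event table."""
    import pandas as pd

    templates = config.templates()
    drift = config.drift()
    seq_seed = int(rng.integers(2**31))
    seq = build_sequence(
        SequenceSpec(**{**asdict(config.sequence), "seed": seq_seed}))
    fs = config.fs
    times = epoch_grid(fs)
    n_rel = len(times)
    rel0 = round(-100.0 * fs / 1000.0)  # sample offset of epoch start vs onset

    lead_in = int(round(1.0 * fs))  # 1 s of pre-stimulus recording
    onset_samples = np.round(seq.onsets_ms * fs / 1000.0).astype(int) + lead_in
    n_samples = int(onset_samples[-1] + round(0.8 * fs) + n_rel)
    n_ch = len(MONTAGE_21)
    data = _colored_noise(rng, (n_ch, n_samples), config.noise.sigma_uv,
                          config.noise.spectral_exponent).astype(np.float32)

    gains = np.array([DEFAULT_TOPOGRAPHY[c] for c in MONTAGE_21], dtype=np.float32)
    type_counters: dict[str, int] = {DEV_SMALL: 0, DEV_LARGE: 0}
    # evoked traces are pure functions of (label, day, trial_index); deviant
    # traces vary per trial through the within-day slope, standards do not
    std_trace = _evoked_trial(STANDARD, templates, day, 0, drift, times)
    for s, lab in zip(onset_samples, seq.labels):
        if lab == STANDARD:
            trace = std_trace
        else:
            k = type_counters[lab]
            type_counters[lab] = k + 1
            trace = _evoked_trial(lab, templates, day, k, drift, times)
            trace = trace + participant_offset_uv * _deviant_indicator(
                templates, lab, times)
        a = s + rel0
        data[:, a : a + n_rel] += (gains[:, None] * trace[None, :]).astype(np.float32)

    if config.noise.artifact_rate > 0:
        hit = rng.uniform(size=len(onset_samples)) < config.noise.artifact_rate
        for s in onset_samples[hit]:
            a = s + rel0
            data[:, a : a + n_rel] += _artifact_transient(
                rng, n_ch, times, config.noise).astype(np.float32)

    rec = ContinuousRecording(data=data.astype(float), fs=fs,
                              channel_names=MONTAGE_21,
                              reference_note="left mastoid")
    events = pd.DataFrame({
        "onset": onset_samples / fs,
        "duration": np.full(len(seq), 0.2),
        "trial_type": seq.labels.astype(str),
    })
    pid = f"sub-{participant_idx + 1:02d}"
    return SimulatedSession(recording=rec, events=events, sequence=seq,
                            participant=pid, day=day)


def _deviant_indicator(templates: TemplateSet, label: str,
                       times_ms: np.ndarray) -> np.ndarray:
    """Unit-amplitude sum of the deviant components' shapes, used to apply a
    per-participant amplitude offset coherently to both components."""
    out = np.zeros_like(times_ms)
    for tpl in templates.deviant[label]:
        out += tpl.evaluate(times_ms, amplitude_uv=np.sign(tpl.amplitude_uv))
    return out


def ground_truth(config: StudyConfig) -> dict:
    """Generator parameters downstream stages should recover (sidecar content)."""
    templates = config.templates()
    drift = config.drift()
    truth: dict = {"seed": config.seed, "fs": config.fs,
                   "n_participants": config.n_participants,
                   "n_days": config.n_days,
                   "noise_sigma_uv": config.noise.sigma_uv,
                   "participant_sd_uv": config.participant_sd_uv,
                   "components": {}}
    for label, tpls in templates.deviant.items():
        for tpl in tpls:
            d = drift.get(label, tpl.name)
            truth["components"][f"{label}/{tpl.name}"] = {
                "amplitude_uv": tpl.amplitude_uv,
                "center_ms": tpl.center_ms,
                "width_ms": tpl.width_ms,
                "day_offsets_uv": list(d.day_offsets_uv),
                "within_day_slope_uv_per_trial": d.within_day_slope_uv_per_trial,
                "latency_shift_ms_per_day": d.latency_shift_ms_per_day,
            }
    return truth


def simulate_study(config: StudyConfig, out_dir: str | Path | None = None,
                   fmt: str = "edf"):
    """Simulate every participant x day session.

    With ``out_dir`` set, writes one recording (EDF by default, or a
    BrainVision triplet), one tab-separated event table per session, and a
    ground-truth JSON sidecar; returns the manifest of written paths.
    Without ``out_dir``, yields :class:`SimulatedSession` objects lazily
    (sessions are large; hold one at a time).

    Reproducible: the root seed is fanned out deterministically per
    participant and day.
    """
    if out_dir is None:
        return _iter_sessions(config)
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sessions": [], "ground_truth": "ground_truth.json"}
    (out_dir / "ground_truth.json").write_text(
        json.dumps(ground_truth(config), indent=1))
    for sess in _iter_sessions(config):
        base = f"{sess.participant}_day-{sess.day}"
        if fmt == "edf":
            rec_path = out_dir / f"{base}_eeg.edf"
            _io.write_edf(sess.recording, rec_path)
        elif fmt == "brainvision":
            rec_path = out_dir / f"{base}_eeg.vhdr"
            _io.write_brainvision(sess.recording, rec_path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        ev_path = out_dir / f"{base}_events.tsv"
        _io.write_events(sess.events, ev_path)
        manifest["sessions"].append({
            "participant": sess.participant, "day": sess.day,
            "recording": rec_path.name, "events": ev_path.name,
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _iter_sessions(config: StudyConfig):
    root = np.random.SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)
    for p in range(config.n_participants):
        offset_rng = np.random.default_rng(part_seeds[p].spawn(1)[0])
        offset = float(offset_rng.normal(0.0, config.participant_sd_uv))
        day_seeds = part_seeds[p].spawn(config.n_days + 1)[1:]
        for d in range(1, config.n_days + 1):
            rng = np.random.default_rng(day_seeds[d - 1])
            yield simulate_session(config, p, d, rng, participant_offset_uv=offset)
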