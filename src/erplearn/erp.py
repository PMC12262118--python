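"""Differential ERPs, data-driven component windows, amplitude/latency measures.

The deviant-minus-standard differential isolates change-related activity.
Component windows are not fixed a priori: the grand-average differential
(pooled over participants, days and deviant types) defines the MMN peak as its
most negative post-stimulus sample and the P3a peak as its most positive, and
the analysis windows are +/- a half-width around those peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FRONTAL_CHANNELS, PairedEpochSet

MMN = "MMN"
P3A = "P3a"


@dataclass(frozen=True)
class ErpWaveform:
    """Averaged (single-trace) waveform with its averaging provenance."""

    values: np.ndarray
    times_ms: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        if self.values.shape != self.times_ms.shape:
            raise ValueError("values and times_ms must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform contains non-finite values")


@dataclass(frozen=True)
class AnalysisWindow:
    """Component analysis window, centred on a grand-average peak."""

    component: str
    start_ms: float
    end_ms: float
    peak_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms <= self.peak_ms <= self.end_ms:
            raise ValueError("peak must lie inside the window")
        if self.start_ms < 0:
            raise ValueError("window must be post-stimulus (start >= 0)")

    @property
    def width_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class ComponentMeasure:
    """Per participant x day x deviant type x component measurement."""

    participant: str
    day: int
    deviant_type: str
    component: str
    amplitude_uv: float
    latency_ms: float
    n_trials: int = 0


def average_differential(pairs: PairedEpochSet,
                         channels=FRONTAL_CHANNELS) -> ErpWaveform:
    """Deviant-average minus standard-average, then mean over channels.

    By linearity this equals the mean of single-trial differentials, so the
    trace is identical whichever order averaging is done in.
    """
    if pairs.n_pairs == 0:
        raise ValueError("no pairs to average")
    idx = [pairs.channel_index(c) for c in channels]
    diff = pairs.deviants[:, idx, :].mean(axis=0) - pairs.standards[:, idx, :].mean(axis=0)
    return ErpWaveform(
        values=diff.mean(axis=0), times_ms=pairs.times_ms,
        provenance={"participant": pairs.participant, "day": pairs.day,
                    "deviant_types": sorted(set(pairs.deviant_types.tolist())),
                    "n_trials": pairs.n_pairs, "channels": tuple(channels)},
    )


def grand_average(waveforms) -> ErpWaveform:
    """Unweighted mean of differential traces (participants x days x types)."""
    waveforms = list(waveforms)
    if not waveforms:
        raise ValueError("no waveforms to average")
    times = waveforms[0].times_ms
    for w in waveforms[1:]:
        if not np.array_equal(w.times_ms, times):
            raise ValueError("waveforms are not on a common time grid")
    values = np.mean([w.values for w in waveforms], axis=0)
    return ErpWaveform(values=values, times_ms=times,
                       provenance={"n_inputs": len(waveforms)})


def select_windows(grand: ErpWaveform,
                   half_width_ms: float = 35.0) -> tuple[AnalysisWindow, AnalysisWindow]:
    """Data-driven MMN and P3a windows from the grand-average differential.

    The MMN peak is the most negative post-stimulus (0-600 ms) sample, the
    P3a peak the most positive; each window is peak +/- half_width, clipped
    to the epoch with a warning if a peak sits near an edge.  Flat stretches
    break ties to the earliest sample.  Overlapping windows (peaks closer
    than 2x half-width) raise: that indicates the grand average does not show
    two separable deflections.
    """
    post = grand.times_ms >= 0.0
    if not post.any():
        raise ValueError("no post-stimulus samples")
    t = grand.times_ms[post]
    v = grand.values[post]
    if np.ptp(v) == 0.0:
        warnings.warn("flat grand average; peaks tied to earliest sample")
    mmn_peak = float(t[np.argmin(v)])
    p3a_peak = float(t[np.argmax(v)])
    if mmn_peak != p3a_peak and abs(p3a_peak - mmn_peak) < 2 * half_width_ms:
        raise ValueError(
            f"MMN ({mmn_peak:g} ms) and P3a ({p3a_peak:g} ms) windows would "
            f"overlap (< {2 * half_width_ms:g} ms apart)")

    def _window(component: str, peak: float) -> AnalysisWindow:
        start, end = peak - half_width_ms, peak + half_width_ms
        lo, hi = max(grand.times_ms[0], 0.0), grand.times_ms[-1]
        if start < lo or end > hi:
            warnings.warn(f"{component} window clipped to the epoch")
            start, end = max(start, lo), min(end, hi)
        return AnalysisWindow(component, start, end, peak)

    return _window(MMN, mmn_peak), _window(P3A, p3a_peak)


def _window_mask(times_ms: np.ndarray, window: AnalysisWindow) -> np.ndarray:
    m = (times_ms >= window.start_ms - 1e-9) & (times_ms <= window.end_ms + 1e-9)
    if not m.any():
        raise ValueError("window contains no samples of this waveform")
    return m


def mean_amplitude(waveform: ErpWaveform, window: AnalysisWindow) -> float:
    """Mean voltage (uV) over the window samples."""
    return float(waveform.values[_window_mask(waveform.times_ms, window)].mean())


def peak_latency(waveform: ErpWaveform, window: AnalysisWindow,
                 polarity: str | None = None) -> float:
    """Latency (ms) of the window's extreme sample.

    ``polarity`` is "negative" (MMN-style) or "positive" (P3a-style); when
    omitted it follows the window's component.  Ties break to the earliest
    sample (argmin/argmax convention).
    """
    if polarity is None:
        polarity = "negative" if window.component == MMN else "positive"
    m = _window_mask(waveform.times_ms, window)
    v = waveform.values[m]
    t = waveform.times_ms[m]
    if polarity == "negative":
        return float(t[np.argmin(v)])
    if polarity == "positive":
        return float(t[np.argmax(v)])
    raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")


def measure_components(pairs_by_session, windows,
                       channels=FRONTAL_CHANNELS) -> list[ComponentMeasure]:
    """Extract amplitude and latency per session, deviant type and component.

    ``pairs_by_session`` is an iterable of PairedEpochSets (one per
    participant x day); each is split by deviant type, averaged to a
    differential trace, and measured in every window.
    """
    out: list[ComponentMeasure] = []
    for pairs in pairs_by_session:
        for dtype in sorted(set(pairs.deviant_types.tolist())):
            sub = pairs.select_type(dtype)
            wave = average_differential(sub, channels=channels)
            for win in windows:
                out.append(ComponentMeasure(
                    participant=pairs.participant, day=pairs.day,
                    deviant_type=dtype, component=win.component,
                    amplitude_uv=mean_amplitude(wave, win),
                    latency_ms=peak_latency(wave, win),
                    n_trials=sub.n_pairs,
                ))
    return out
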