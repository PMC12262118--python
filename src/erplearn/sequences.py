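"""Oddball stimulus sequences.

A passive-oddball session is a long sequence of frequent "standard" sounds with
rare "deviant" sounds (two deviance magnitudes) interspersed.  The trial-type
proportions are exact counts of a fixed total — randomisation is over order
only — and consecutive deviants must be separated by a minimum number of
standards so that each deviant is preceded by a re-established standard context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD = "standard"
DEV_SMALL = "dev_small"
DEV_LARGE = "dev_large"

TRIAL_TYPES = (STANDARD, DEV_SMALL, DEV_LARGE)

#: Stimulus duration in ms (offset-to-onset ISI is added on top of this).
STIMULUS_DURATION_MS = 200.0


class InfeasibleSequenceError(ValueError):
    """Raised when no ordering can satisfy the deviant-separation constraint."""


@dataclass(frozen=True)
class SequenceSpec:
    """Composition and timing of one oddball session.

    Proportions must multiply ``n_total`` to integers: counts are exact, not
    sampled.  ``min_separation`` is the minimum number of standards between any
    two consecutive deviants (of either type).  ``isi_range_ms`` is the
    offset-to-onset interval range, sampled uniformly per trial.
    """

    n_total: int = 11_000
    p_standard: float = 0.8
    p_small: float = 0.1
    p_large: float = 0.1
    min_separation: int = 2
    isi_range_ms: tuple[float, float] = (440.0, 520.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        props = (self.p_standard, self.p_small, self.p_large)
        if any(p < 0 for p in props):
            raise ValueError("proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(props)}")
        for name, p in zip(("p_standard", "p_small", "p_large"), props):
            cnt = p * self.n_total
            if abs(cnt - round(cnt)) > 1e-6:
                raise ValueError(
                    f"{name} * n_total = {cnt} is not an integer; counts are exact"
                )
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        lo, hi = self.isi_range_ms
        if lo > hi:
            raise ValueError("isi_range_ms low must be <= high")

    @property
    def counts(self) -> dict[str, int]:
        return {
            STANDARD: round(self.p_standard * self.n_total),
            DEV_SMALL: round(self.p_small * self.n_total),
            DEV_LARGE: round(self.p_large * self.n_total),
        }


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered trial labels with onset times (ms from session start)."""

    labels: np.ndarray = field(repr=False)  # array of str codes
    onsets_ms: np.ndarray = field(repr=False)
    spec: SequenceSpec | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.onsets_ms):
            raise ValueError("labels and onsets_ms must have equal length")
        if len(self.onsets_ms) > 1 and not np.all(np.diff(self.onsets_ms) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def separation_violations(self, min_separation: int) -> int:
        """Exhaustively count consecutive-deviant pairs with too few standards."""
        dev_pos = np.flatnonzero(self.labels != STANDARD)
        if len(dev_pos) < 2:
            return 0
        gaps = np.diff(dev_pos) - 1  # standards between consecutive deviants
        return int(np.sum(gaps < min_separation))


def _random_composition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random weak composition of ``total`` into ``parts`` parts.

    Classic stars-and-bars: choose ``parts - 1`` divider positions among
    ``total + parts - 1`` slots uniformly without replacement.
    """
    if parts == 1:
        return np.array([total])
    dividers = rng.choice(total + parts - 1, size=parts - 1, replace=False)
    dividers.sort()
    bounds = np.concatenate(([-1], dividers, [total + parts - 1]))
    return np.diff(bounds) - 1


def build_sequence(spec: SequenceSpec) -> StimulusSequence:
    """Build a randomised oddball sequence honouring the separation constraint.

    Construction is rejection-free: the gaps of standards around the deviants
    are drawn as a uniform random composition of the surplus standards (after
    reserving ``min_separation`` per between-deviant gap), which makes every
    admissible ordering equally likely; deviant types are then shuffled
    uniformly over the deviant slots.

    Onsets accumulate stimulus duration (200 ms) plus a per-trial ISI drawn
    uniformly from ``spec.isi_range_ms``.
    """
    counts = spec.counts
    n_std = counts[STANDARD]
    n_dev = counts[DEV_SMALL] + counts[DEV_LARGE]
    rng = np.random.default_rng(spec.seed)

    required = max(n_dev - 1, 0) * spec.min_separation
    if n_dev > 0 and n_std < required:
        raise InfeasibleSequenceError(
            f"{n_dev} deviants need at least {required} standards for "
            f"min_separation={spec.min_separation}, only {n_std} available"
        )

    labels = np.empty(spec.n_total, dtype=object)
    if n_dev == 0:
        labels[:] = STANDARD
    else:
        surplus = n_std - required
        free = _random_composition(surplus, n_dev + 1, rng)
        gaps = free.copy()
        gaps[1:-1] += spec.min_separation  # interior gaps carry the reserve
        dev_labels = np.array(
            [DEV_SMALL] * counts[DEV_SMALL] + [DEV_LARGE] * counts[DEV_LARGE],
            dtype=object,
        )
        rng.shuffle(dev_labels)
        pos = 0
        for i, g in enumerate(gaps):
            labels[pos : pos + g] = STANDARD
            pos += g
            if i < n_dev:
                labels[pos] = dev_labels[i]
                pos += 1
        assert pos == spec.n_total

    isi = rng.uniform(*spec.isi_range_ms, size=spec.n_total)
    # SOA of trial i = duration + ISI_i; first onset at 0.
    soa = STIMULUS_DURATION_MS + isi
    onsets = np.concatenate(([0.0], np.cumsum(soa[:-1])))
    return StimulusSequence(labels=labels, onsets_ms=onsets, spec=spec)
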