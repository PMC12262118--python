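"""Run configuration: one structured file drives every pipeline stage.

Stage defaults are the analysis settings of the emulated study: 250 Hz
analysis rate, 30 Hz low-pass, 50 Hz notch, ±200 μV pair rejection,
−100..600 ms epochs, ±35 ms component windows, 5-fold × 100-repeat decoding
with 10,000 permutations, and 100-trial sliding bins capped at 400 windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SequenceBlock:
    n_total: int = 11_000
    p_standard: float = 0.8
    p_small: float = 0.1
    p_large: float = 0.1
    min_separation: int = 2
    isi_range_ms: tuple[float, float] = (440.0, 520.0)


@dataclass
class SimulateBlock:
    n_participants: int = 14
    n_days: int = 4
    fs: float = 500.0
    sigma_uv: float = 10.0
    spectral_exponent: float = 0.0
    artifact_rate: float = 0.03
    artifact_amplitude_uv: float = 300.0
    participant_sd_uv: float = 0.8
    format: str = "edf"


@dataclass
class PreprocessBlock:
    target_fs: float = 250.0
    lowpass_hz: float = 30.0
    notch_hz: float = 50.0
    muscle_band_hz: tuple[float, float] = (35.0, 128.0)
    muscle_threshold_db: float = 10.0
    reject_uv: float = 200.0
    tmin_ms: float = -100.0
    tmax_ms: float = 600.0


@dataclass
class ErpBlock:
    half_width_ms: float = 35.0
    channels: tuple[str, ...] = ("F3", "Fz", "F4")


@dataclass
class DecodeBlock:
    target_fs: float = 50.0
    folds: int = 5
    repeats: int = 100
    n_permutations: int = 10_000
    bonferroni_m: int = 3
    shrinkage: float | None = None
    comparisons: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (1, 4))


@dataclass
class SlideBlock:
    bin_size: int = 100
    step: int = 1
    window_cap: int = 400
    alpha: float = 0.05
    r2_min: float = 0.5


@dataclass
class LmmBlock:
    latency_in_seconds: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "results"
    sequence: SequenceBlock = field(default_factory=SequenceBlock)
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    erp: ErpBlock = field(default_factory=ErpBlock)
    decode: DecodeBlock = field(default_factory=DecodeBlock)
    slide: SlideBlock = field(default_factory=SlideBlock)
    lmm: LmmBlock = field(default_factory=LmmBlock)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list)
            .encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        blocks = {f.name: f.type for f in dataclasses.fields(cls)}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(_BLOCK_TYPES.get(f.name)) and isinstance(val, dict):
                val = _coerce_block(_BLOCK_TYPES[f.name], val)
            kwargs[f.name] = val
        unknown = set(raw) - set(blocks)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


_BLOCK_TYPES = {
    "sequence": SequenceBlock, "simulate": SimulateBlock,
    "preprocess": PreprocessBlock, "erp": ErpBlock, "decode": DecodeBlock,
    "slide": SlideBlock, "lmm": LmmBlock,
}


def _coerce_block(block_cls, val: dict):
    names = {f.name for f in dataclasses.fields(block_cls)}
    unknown = set(val) - names
    if unknown:
        raise ValueError(f"unknown keys in {block_cls.__name__}: {sorted(unknown)}")
    out = {}
    for k, v in val.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return block_cls(**out)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_plain(v) for v in obj]
    return obj
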