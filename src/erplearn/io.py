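"""File formats: EDF / BrainVision recordings, BIDS-styled event tables,
HDF5 epoch containers and tidy CSV result tables.

Reading continuous recordings goes through MNE.  Writing uses two small
writers of our own: 16-bit EDF (quantized to the file's physical range) and
a BrainVision triplet with IEEE float32 samples (exact round-trip).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording, EpochSet, PairedEpochSet

EVENT_COLUMNS = ("onset", "duration", "trial_type")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

class EventFileError(ValueError):
    """Malformed event table (message carries the offending line number)."""


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False,
                  columns=list(EVENT_COLUMNS), float_format="%.6f")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated event table (onset s, duration s, trial_type)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise EventFileError(f"{path}: cannot parse as TSV ({err})") from err
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventFileError(f"{path}:1: missing columns {missing}")
    for col in ("onset", "duration"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise EventFileError(
                f"{path}:{line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise EventFileError(f"{path}:{line}: missing value in {col!r}")
        df[col] = coerced
    if not df["onset"].is_monotonic_increasing:
        first = int(np.flatnonzero(np.diff(df["onset"]) < 0)[0]) + 3
        raise EventFileError(f"{path}:{first}: onsets must be non-decreasing")
    return df


# ---------------------------------------------------------------------------
# EDF writer (16-bit, 1-second records)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: ContinuousRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic") -> Path:
    """Write an EDF file (one data record per second, int16 samples).

    The recording is zero-padded to a whole number of records; samples are
    quantized to the per-file symmetric physical range, so the round-trip
    error is bounded by range/32767.  A fixed header date keeps output
    byte-deterministic for a given recording.
    """
    path = Path(path)
    if rec.fs != int(rec.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rec.fs)  # samples per 1 s record
    n_ch = rec.data.shape[0]
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    phys_max = float(np.max(np.abs(data)))
    phys_max = max(phys_max * 1.0001, 1.0)
    # quantize against the exact (truncated) value the header will carry
    phys_max = float(f"{phys_max:.6g}"[:7])
    dig_max = 32767
    # digital range symmetric (+/-32767) so cal = phys_max / dig_max exactly
    scaled = np.clip(np.round(data / phys_max * dig_max),
                     -dig_max, dig_max).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(patient_id, 80),
        _edf_field(recording_id, 80),
        _edf_field("01.01.01", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(c, 16) for c in rec.channel_names),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"-{phys_max:.6g}"[:8], 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{phys_max:.6g}"[:7], 8) for _ in range(n_ch)),
        b"".join(_edf_field(-dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: per record, per signal, spr int16 samples
        rec_view = scaled.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view).tobytes())
    return path


# ---------------------------------------------------------------------------
# BrainVision writer (vhdr/vmrk/eeg, float32 multiplexed)
# ---------------------------------------------------------------------------

def write_brainvision(rec: ContinuousRecording, vhdr_path: str | Path) -> Path:
    vhdr_path = Path(vhdr_path)
    if vhdr_path.suffix != ".vhdr":
        raise ValueError("pass the .vhdr path; companions are derived from it")
    base = vhdr_path.with_suffix("")
    eeg_path = base.with_suffix(".eeg")
    vmrk_path = base.with_suffix(".vmrk")

    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV"
        for i, name in enumerate(rec.channel_names))
    vhdr = f"""Brain Vision Data Exchange Header File Version 1.0
; synthetic recording

[Common Infos]
Codepage=UTF-8
DataFile={eeg_path.name}
MarkerFile={vmrk_path.name}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={len(rec.channel_names)}
SamplingInterval={1e6 / rec.fs:.6f}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{ch_lines}
"""
    vmrk = f"""Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={eeg_path.name}

[Marker Infos]
Mk1=New Segment,,1,1,0,20000101000000000000
"""
    vhdr_path.write_text(vhdr, encoding="utf-8")
    vmrk_path.write_text(vmrk, encoding="utf-8")
    rec.data.T.astype("<f4").tofile(eeg_path)
    return vhdr_path


# ---------------------------------------------------------------------------
# readers (MNE-backed)
# ---------------------------------------------------------------------------

def read_raw(path: str | Path,
             expected_channels: tuple[str, ...] | None = None) -> ContinuousRecording:
    """Read an EDF or BrainVision recording into microvolts.

    ``expected_channels``, when given, is validated against the file's
    channel names (order-sensitive) — a mismatch against the configured
    montage is an error, not a silent reorder.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r}")
    names = tuple(raw.ch_names)
    if expected_channels is not None and names != tuple(expected_channels):
        raise ValueError(
            f"{path}: channel names {names} do not match the configured "
            f"montage {tuple(expected_channels)}")
    data_uv = raw.get_data() * 1e6
    return ContinuousRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                               channel_names=names)


# ---------------------------------------------------------------------------
# HDF5 epoch containers
# ---------------------------------------------------------------------------

def write_pairs_h5(pairs: PairedEpochSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("deviants", data=pairs.deviants)
        f.create_dataset("standards", data=pairs.standards)
        f.create_dataset("deviant_types",
                         data=np.array(pairs.deviant_types, dtype="S"))
        f.create_dataset("deviant_trial_ids", data=pairs.deviant_trial_ids)
        f.create_dataset("standard_trial_ids", data=pairs.standard_trial_ids)
        f.create_dataset("times_ms", data=pairs.times_ms)
        f.attrs["channel_names"] = list(pairs.channel_names)
        f.attrs["participant"] = pairs.participant
        f.attrs["day"] = pairs.day
        f.attrs["reference"] = pairs.reference
    return path


def read_pairs_h5(path: str | Path) -> PairedEpochSet:
    with h5py.File(path, "r") as f:
        return PairedEpochSet(
            deviants=f["deviants"][()],
            standards=f["standards"][()],
            deviant_types=np.array([s.decode() for s in f["deviant_types"][()]],
                                   dtype=object),
            deviant_trial_ids=f["deviant_trial_ids"][()],
            standard_trial_ids=f["standard_trial_ids"][()],
            times_ms=f["times_ms"][()],
            channel_names=tuple(f.attrs["channel_names"]),
            participant=str(f.attrs["participant"]),
            day=int(f.attrs["day"]),
            reference=str(f.attrs["reference"]),
        )


def write_epochs_h5(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("labels", data=np.array(epochs.labels, dtype="S"))
        f.create_dataset("trial_ids", data=epochs.trial_ids)
        f.attrs["channel_names"] = list(epochs.channel_names)
        f.attrs["participant"] = epochs.participant
        f.attrs["day"] = epochs.day
        f.attrs["reference"] = epochs.reference
        f.attrs["baseline_corrected"] = epochs.baseline_corrected
    return path


def read_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            epochs=f["epochs"][()], times_ms=f["times_ms"][()],
            labels=np.array([s.decode() for s in f["labels"][()]], dtype=object),
            trial_ids=f["trial_ids"][()],
            channel_names=tuple(f.attrs["channel_names"]),
            participant=str(f.attrs["participant"]),
            day=int(f.attrs["day"]),
            reference=str(f.attrs["reference"]),
            baseline_corrected=bool(f.attrs["baseline_corrected"]),
        )


# ---------------------------------------------------------------------------
# tidy CSV outputs
# ---------------------------------------------------------------------------

def measures_to_frame(measures) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant": m.participant, "day": m.day,
        "deviant_type": m.deviant_type, "component": m.component,
        "amplitude_uv": m.amplitude_uv, "latency_ms": m.latency_ms,
        "n_trials": m.n_trials,
    } for m in measures])


def curve_to_frame(curve) -> pd.DataFrame:
    return pd.DataFrame({
        "participant": curve.participant,
        "comparison": f"day{curve.comparison[0]}_vs_day{curve.comparison[1]}",
        "time_ms": curve.times_ms,
        "auc": curve.auc_per_timepoint,
    })


def window_stats_to_frame(stats_list) -> pd.DataFrame:
    return pd.DataFrame([{
        "component": s.component,
        "comparison": f"day{s.comparison[0]}_vs_day{s.comparison[1]}",
        "mean_auc": s.mean_auc, "t": s.t, "p": s.p,
        "p_bonferroni": s.p_adjusted, "n_permutations": s.n_permutations,
    } for s in stats_list])
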