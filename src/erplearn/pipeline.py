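"""Stage orchestration: simulate -> preprocess -> erp -> decode -> slide -> lmm.

Each stage reads its inputs from the artifact directory written by the stage
before it and appends its outputs to a manifest carrying the config hash and
root seed, so a finished run is self-describing and reruns with the same
config are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import RunConfig
from .decoding import (group_permutation_ttest, make_features,
                       temporal_decoding, window_mean_auc)
from .erp import (AnalysisWindow, average_differential, grand_average,
                  measure_components, select_windows)
from .mixed import build_measure_table, fit_all
from .preprocess import preprocess_session
from .sequences import DEV_LARGE, DEV_SMALL, SequenceSpec
from .simulate import NoiseSpec, StudyConfig, simulate_study
from .sliding import group_trend, sliding_series, trial_window_amplitudes
from .erp import ComponentMeasure

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "erp", "decode", "slide", "lmm")


class MissingArtifactError(RuntimeError):
    """An upstream stage's output is required but absent."""


def _require(path: Path, needed_by: str, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {needed_by!r} requires {path.name}, which is produced by "
            f"stage {produced_by!r}; run that stage first")
    return path


def _stage_seed(config: RunConfig, stage: str) -> int:
    child = np.random.SeedSequence(config.seed, spawn_key=(STAGES.index(stage),))
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, stages=STAGES) -> Path:
    """Run the requested stages in dependency order; returns the out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest.setdefault("config_hash", config.hash())
    manifest.setdefault("seed", config.seed)
    manifest.setdefault("files", {})
    config.save(out_dir / "config.yaml")

    runners = {
        "simulate": _run_simulate, "preprocess": _run_preprocess,
        "erp": _run_erp, "decode": _run_decode, "slide": _run_slide,
        "lmm": _run_lmm,
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("pipeline: running stage %s", stage)
        produced = runners[stage](config, out_dir)
        manifest["files"][stage] = sorted(str(p.name) for p in produced)
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def _run_simulate(config: RunConfig, out_dir: Path):
    data_dir = Path(config.data_dir)
    sc = StudyConfig(
        n_participants=config.simulate.n_participants,
        n_days=config.simulate.n_days,
        sequence=SequenceSpec(
            n_total=config.sequence.n_total,
            p_standard=config.sequence.p_standard,
            p_small=config.sequence.p_small,
            p_large=config.sequence.p_large,
            min_separation=config.sequence.min_separation,
            isi_range_ms=tuple(config.sequence.isi_range_ms),
            seed=0,
        ),
        noise=NoiseSpec(
            sigma_uv=config.simulate.sigma_uv,
            spectral_exponent=config.simulate.spectral_exponent,
            artifact_rate=config.simulate.artifact_rate,
            artifact_amplitude_uv=config.simulate.artifact_amplitude_uv,
        ),
        fs=config.simulate.fs,
        participant_sd_uv=config.simulate.participant_sd_uv,
        seed=_stage_seed(config, "simulate"),
    )
    simulate_study(sc, out_dir=data_dir, fmt=config.simulate.format)
    return [data_dir / "manifest.json"]


def _sessions(config: RunConfig) -> list[dict]:
    data_dir = Path(config.data_dir)
    mf = _require(data_dir / "manifest.json", "preprocess", "simulate")
    return json.loads(mf.read_text())["sessions"]


def _run_preprocess(config: RunConfig, out_dir: Path):
    data_dir = Path(config.data_dir)
    pairs_dir = out_dir / "pairs"
    pairs_dir.mkdir(exist_ok=True)
    written = []
    for sess in _sessions(config):
        rec = _io.read_raw(data_dir / sess["recording"])
        events = _io.read_events(data_dir / sess["events"])
        pairs = preprocess_session(
            rec, events,
            target_fs=config.preprocess.target_fs,
            lowpass_hz=config.preprocess.lowpass_hz,
            notch_hz=config.preprocess.notch_hz,
            muscle_band_hz=tuple(config.preprocess.muscle_band_hz),
            muscle_threshold_db=config.preprocess.muscle_threshold_db,
            reject_uv=config.preprocess.reject_uv,
            participant=sess["participant"], day=sess["day"],
        )
        logger.info("preprocess %s day %s: %d balanced pairs",
                    sess["participant"], sess["day"], pairs.n_pairs)
        p = pairs_dir / f"{sess['participant']}_day-{sess['day']}_pairs.h5"
        _io.write_pairs_h5(pairs, p)
        written.append(p)
    return written


def _load_pairs(config: RunConfig, out_dir: Path, needed_by: str):
    pairs_dir = _require(out_dir / "pairs", needed_by, "preprocess")
    files = sorted(pairs_dir.glob("*_pairs.h5"))
    if not files:
        raise MissingArtifactError(
            f"stage {needed_by!r} found no paired epochs; run 'preprocess'")
    return [_io.read_pairs_h5(f) for f in files]


def _run_erp(config: RunConfig, out_dir: Path):
    all_pairs = _load_pairs(config, out_dir, "erp")
    channels = tuple(config.erp.channels)
    diffs = []
    for pairs in all_pairs:
        for dtype in (DEV_SMALL, DEV_LARGE):
            sub = pairs.select_type(dtype)
            if sub.n_pairs:
                diffs.append(average_differential(sub, channels=channels))
    grand = grand_average(diffs)
    windows = select_windows(grand, half_width_ms=config.erp.half_width_ms)
    (out_dir / "windows.json").write_text(json.dumps({
        w.component: {"start_ms": w.start_ms, "end_ms": w.end_ms,
                      "peak_ms": w.peak_ms} for w in windows}, indent=1))
    logger.info("erp: windows %s", [(w.component, w.start_ms, w.end_ms)
                                    for w in windows])
    measures = measure_components(all_pairs, windows, channels=channels)
    frame = _io.measures_to_frame(measures)
    frame.to_csv(out_dir / "component_measures.csv", index=False)
    pd.DataFrame({"time_ms": grand.times_ms, "amplitude_uv": grand.values}) \
        .to_csv(out_dir / "grand_average.csv", index=False)
    return [out_dir / "windows.json", out_dir / "component_measures.csv",
            out_dir / "grand_average.csv"]


def _load_windows(out_dir: Path, needed_by: str) -> list[AnalysisWindow]:
    wf = _require(out_dir / "windows.json", needed_by, "erp")
    raw = json.loads(wf.read_text())
    return [AnalysisWindow(component=k, start_ms=v["start_ms"],
                           end_ms=v["end_ms"], peak_ms=v["peak_ms"])
            for k, v in raw.items()]


def _run_decode(config: RunConfig, out_dir: Path):
    all_pairs = _load_pairs(config, out_dir, "decode")
    windows = _load_windows(out_dir, "decode")
    by_part: dict[str, dict[int, object]] = {}
    for p in all_pairs:
        by_part.setdefault(p.participant, {})[p.day] = p
    seed0 = _stage_seed(config, "decode")
    curve_frames, stats_rows = [], []
    for dtype in (DEV_SMALL, DEV_LARGE):
        for ci, (a, b) in enumerate(config.decode.comparisons):
            per_part_curves = []
            for part, days in sorted(by_part.items()):
                if a not in days or b not in days:
                    continue
                feats = make_features({a: days[a], b: days[b]},
                                      target_fs=config.decode.target_fs,
                                      channels=tuple(config.erp.channels),
                                      deviant_type=dtype)
                part_key = int(hashlib.sha1(part.encode()).hexdigest()[:6], 16)
                curve = temporal_decoding(
                    feats, folds=config.decode.folds,
                    repeats=config.decode.repeats,
                    seed=(seed0 + 1000 * ci + part_key) % (2**31),
                    shrinkage=config.decode.shrinkage)
                per_part_curves.append(curve)
                frame = _io.curve_to_frame(curve)
                frame.insert(0, "deviant_type", dtype)
                curve_frames.append(frame)
            if not per_part_curves:
                continue
            for win in windows:
                values = np.array([window_mean_auc(c, win)
                                   for c in per_part_curves])
                if len(values) >= 2:
                    stat = group_permutation_ttest(
                        values, n_perm=config.decode.n_permutations,
                        m_comparisons=config.decode.bonferroni_m,
                        seed=seed0 + ci, component=win.component,
                        comparison=(a, b))
                    row = _io.window_stats_to_frame([stat])
                    row.insert(0, "deviant_type", dtype)
                    stats_rows.append(row)
    out = [out_dir / "decoding_curves.csv"]
    pd.concat(curve_frames, ignore_index=True).to_csv(out[0], index=False)
    if stats_rows:
        p = out_dir / "decoding_window_stats.csv"
        pd.concat(stats_rows, ignore_index=True).to_csv(p, index=False)
        out.append(p)
    return out


def _run_slide(config: RunConfig, out_dir: Path):
    all_pairs = _load_pairs(config, out_dir, "slide")
    windows = _load_windows(out_dir, "slide")
    rows, trend_rows = [], []
    by_cell: dict[tuple, list] = {}
    for pairs in all_pairs:
        for dtype in (DEV_SMALL, DEV_LARGE):
            sub = pairs.select_type(dtype)
            if sub.n_pairs < config.slide.bin_size:
                logger.warning("slide: %s day %s %s has %d < %d trials; skipped",
                               pairs.participant, pairs.day, dtype,
                               sub.n_pairs, config.slide.bin_size)
                continue
            for win in windows:
                amps = trial_window_amplitudes(
                    sub, win, channels=tuple(config.erp.channels))
                series = sliding_series(
                    amps, bin_size=config.slide.bin_size,
                    step=config.slide.step, window_cap=config.slide.window_cap,
                    participant=pairs.participant, day=pairs.day,
                    deviant_type=dtype, component=win.component)
                by_cell.setdefault((pairs.day, dtype, win.component),
                                   []).append(series)
                rows.append(pd.DataFrame({
                    "participant": pairs.participant, "day": pairs.day,
                    "deviant_type": dtype, "component": win.component,
                    "window_index": np.arange(len(series)),
                    "amplitude_uv": series.values,
                }))
    for (day, dtype, comp), series_list in sorted(by_cell.items()):
        if min(len(s) for s in series_list) < 3:
            logger.warning("slide: day %s %s %s has too few windows for a "
                           "trend fit; skipped", day, dtype, comp)
            continue
        res = group_trend(series_list, alpha=config.slide.alpha,
                          r2_min=config.slide.r2_min)
        trend_rows.append({
            "day": day, "deviant_type": dtype, "component": comp,
            "mean_slope": float(np.mean(res.participant_slopes)),
            "slope_t": res.slope_t, "slope_p": res.slope_p,
            "avg_series_slope": res.averaged_fit.slope,
            "avg_series_p": res.averaged_fit.p,
            "r_squared": res.averaged_fit.r_squared,
            "clear_trend": res.clear_trend,
        })
    out = []
    if rows:
        p = out_dir / "sliding_series.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        out.append(p)
    if trend_rows:
        p = out_dir / "sliding_trends.csv"
        pd.DataFrame(trend_rows).to_csv(p, index=False)
        out.append(p)
    return out


def _run_lmm(config: RunConfig, out_dir: Path):
    mfile = _require(out_dir / "component_measures.csv", "lmm", "erp")
    frame = pd.read_csv(mfile)
    measures = [ComponentMeasure(
        participant=r.participant, day=int(r.day), deviant_type=r.deviant_type,
        component=r.component, amplitude_uv=r.amplitude_uv,
        latency_ms=r.latency_ms, n_trials=int(r.n_trials))
        for r in frame.itertuples()]
    table = build_measure_table(measures)
    results = fit_all(table, latency_in_seconds=config.lmm.latency_in_seconds)
    p = out_dir / "lmm_results.csv"
    results.to_csv(p, index=False)
    return [p]
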