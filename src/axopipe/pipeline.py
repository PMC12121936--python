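"""End-to-end orchestration: smooth -> select -> motion -> transients -> cluster.

Each stage writes its artifacts to the output directory and contributes a
section to a JSON run manifest (configuration hash, per-stage ROI/frame
counts, chosen cluster count). The manifest contains no timestamps, so a
rerun with the same inputs, configuration and seed is byte-identical —
reproducibility is checked by diffing manifests.

Stages are individually skippable; each also exists as a standalone CLI
subcommand operating on the previous stage's CSV outputs, so the pipeline
works with or without upstream segmentation software.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import motion as _motion
from . import selection as _selection
from . import smoothing as _smoothing
from . import transients as _transients
from .io import Channel, TraceMatrix, read_trace_csv, write_trace_csv

log = logging.getLogger("axopipe")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    traces_path: str | None = None
    static_path: str | None = None
    frame_rate_hz: float = 15.49
    out_dir: str = "axopipe_out"
    seed: int = 0

    smoothing: _smoothing.SmoothingParams = field(default_factory=_smoothing.SmoothingParams)
    selection: _selection.SelectionParams = field(default_factory=_selection.SelectionParams)
    auto_band: bool = False
    exemplar_ids: list[str] = field(default_factory=list)
    motion: _motion.SegmentationParams = field(default_factory=_motion.SegmentationParams)
    motion_mode: _motion.MaskMode = _motion.MaskMode.DROP
    verify_with_static: bool = True
    baseline: _transients.BaselineParams = field(default_factory=_transients.BaselineParams)
    peaks: _transients.PeakParams = field(default_factory=_transients.PeakParams)
    subtract_only: bool = False
    cluster: _cluster.ClusterParams = field(default_factory=_cluster.ClusterParams)
    use_masked: bool = True

    skip_smoothing: bool = False
    skip_selection: bool = False
    skip_motion: bool = False
    skip_transients: bool = False
    skip_clustering: bool = False

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/output dir excluded)."""
        payload = _as_jsonable(self)
        for key in ("traces_path", "static_path", "out_dir"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value
    return obj


_CONFIG_KEYS = {
    "smoothing": ("smoothing", _smoothing.SmoothingParams),
    "motion": ("motion", _motion.SegmentationParams),
}


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file of dotted config keys.

    Recognized sections: ``smoothing`` (window_frames, polyorder),
    ``selection`` (band_low_hz, band_high_hz, filter_order,
    power_threshold, auto_band, exemplar_ids), ``motion`` (n_change_points,
    min_artifact_duration_s, deviation_k, mode, verify_with_static),
    ``transients`` (window_s, percentile, min_amplitude, min_duration_s,
    min_prominence, subtract_only), ``cluster`` (prefilter_r, k_min,
    k_max_fraction, method, linkage, seed, use_masked) plus top-level
    ``frame_rate_hz``, ``seed`` and paths.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key in ("traces_path", "static_path", "frame_rate_hz", "out_dir", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "smoothing" in raw:
        cfg.smoothing = _smoothing.SmoothingParams(**raw["smoothing"])
    if "selection" in raw:
        sel = dict(raw["selection"])
        cfg.auto_band = sel.pop("auto_band", cfg.auto_band)
        cfg.exemplar_ids = sel.pop("exemplar_ids", cfg.exemplar_ids)
        low = sel.pop("band_low_hz", None)
        high = sel.pop("band_high_hz", None)
        band = cfg.selection.band
        if low is not None or high is not None:
            band = _selection.FrequencyBand(
                low if low is not None else band.low_hz,
                high if high is not None else band.high_hz,
            )
        cfg.selection = _selection.SelectionParams(band=band, **sel)
    if "motion" in raw:
        mot = dict(raw["motion"])
        cfg.motion_mode = _motion.MaskMode(mot.pop("mode", cfg.motion_mode.value))
        cfg.verify_with_static = mot.pop("verify_with_static", cfg.verify_with_static)
        cfg.motion = _motion.SegmentationParams(**mot)
    if "transients" in raw:
        tr = dict(raw["transients"])
        cfg.subtract_only = tr.pop("subtract_only", cfg.subtract_only)
        cfg.baseline = _transients.BaselineParams(
            window_s=tr.pop("window_s", cfg.baseline.window_s),
            percentile=tr.pop("percentile", cfg.baseline.percentile),
        )
        cfg.peaks = _transients.PeakParams(
            min_amplitude_dff=tr.pop("min_amplitude", cfg.peaks.min_amplitude_dff),
            min_duration_s=tr.pop("min_duration_s", cfg.peaks.min_duration_s),
            min_prominence_dff=tr.pop("min_prominence", cfg.peaks.min_prominence_dff),
        )
        if tr:
            raise ValueError(f"unknown transients config keys: {sorted(tr)}")
    if "cluster" in raw:
        cl = dict(raw["cluster"])
        cfg.use_masked = cl.pop("use_masked", cfg.use_masked)
        cfg.cluster = _cluster.ClusterParams(**cl)
    return cfg


def run_pipeline(
    config: RunConfig,
    traces: TraceMatrix | None = None,
    static: TraceMatrix | None = None,
) -> dict:
    """Execute the full preprocessing flow and write a run manifest.

    Inputs may be passed in memory (``traces``/``static``) or read from the
    CSV paths in ``config``. Returns the manifest dict (also written to
    ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traces is None:
        if config.traces_path is None:
            raise PipelineError("input: no traces given (traces_path unset)")
        traces = read_trace_csv(config.traces_path, config.frame_rate_hz)
    if static is None and config.static_path is not None:
        static = read_trace_csv(config.static_path, config.frame_rate_hz, Channel.STATIC)

    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input": {"n_rois": traces.n_rois, "n_frames": traces.n_frames,
                  "frame_rate_hz": traces.frame_rate_hz},
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)

    # 1. smoothing -------------------------------------------------------
    stage("smoothing")
    try:
        smoothed = traces if config.skip_smoothing else _smoothing.smooth_traces(
            traces, config.smoothing
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"smoothing: {exc}") from exc
    manifest["stages"]["smoothing"] = {"skipped": config.skip_smoothing}

    # 2. band-power selection -------------------------------------------
    stage("selection")
    try:
        if config.skip_selection:
            selected = smoothed
            manifest["stages"]["selection"] = {"skipped": True}
        else:
            sel_params = config.selection
            if config.auto_band:
                spectra = {
                    r: _selection.power_spectrum(row, smoothed.sampling)
                    for r, row in zip(smoothed.roi_ids, smoothed.values)
                }
                exemplars = [spectra[r] for r in config.exemplar_ids]
                band = _selection.estimate_band_of_interest(
                    exemplars, list(spectra.values())
                )
                sel_params = dataclasses.replace(sel_params, band=band)
            result = _selection.select_rois(smoothed, sel_params)
            _selection.band_power_table(result).to_csv(out / "band_power.csv", index=False)
            keep = np.flatnonzero(result.selected)
            manifest["stages"]["selection"] = {
                "skipped": False,
                "band_hz": [sel_params.band.low_hz, sel_params.band.high_hz],
                "threshold": sel_params.power_threshold,
                "n_in": traces.n_rois,
                "n_selected": result.n_selected,
                "n_discarded": result.n_discarded,
            }
            if result.n_selected == 0:
                manifest["status"] = "stopped: no ROI exceeded the band-power threshold"
                _write_manifest(manifest, out)
                return manifest
            selected = smoothed.subset_rois(keep)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"selection: {exc}") from exc

    # 3. motion artifacts ------------------------------------------------
    stage("motion")
    try:
        if config.skip_motion:
            cleaned_pieces = [(selected, np.arange(selected.n_frames))]
            manifest["stages"]["motion"] = {"skipped": True}
        else:
            intervals, pc = _motion.detect_artifacts(selected, config.motion)
            verification = None
            if static is not None and config.verify_with_static and intervals.intervals:
                static_sel = static.subset_rois(
                    [static.roi_ids.index(r) for r in selected.roi_ids]
                )
                verification = _motion.verify_with_static_channel(
                    static_sel, intervals, config.motion
                )
            if verification is not None:
                # only static-confirmed periods are removed; unconfirmed ones
                # are likely population coactivity and stay in the data
                removable = _motion.ArtifactIntervals(
                    [iv for iv, ok in zip(intervals.intervals, verification.confirmed) if ok],
                    intervals.source,
                )
            else:
                removable = intervals
            rows = []
            for j, (s, e) in enumerate(intervals.intervals):
                rows.append({
                    "start_frame": s, "end_frame": e,
                    "start_s": s / selected.frame_rate_hz,
                    "end_s": e / selected.frame_rate_hz,
                    "confirmed_by_static": (
                        verification.confirmed[j] if verification else None
                    ),
                })
            pd.DataFrame(
                rows, columns=["start_frame", "end_frame", "start_s", "end_s",
                               "confirmed_by_static"],
            ).to_csv(out / "artifact_intervals.csv", index=False)
            manifest["stages"]["motion"] = {
                "skipped": False,
                "n_change_points": config.motion.n_change_points,
                "explained_variance_ratio": round(pc.explained_variance_ratio, 6),
                "intervals": [list(iv) for iv in intervals.intervals],
                "frames_flagged": removable.total_frames(),
                "static_confirmed": (
                    verification.confirmed if verification else None
                ),
                "mode": config.motion_mode.value,
            }
            if removable.intervals:
                cleaned_pieces = _motion.apply_artifact_mask(
                    selected, removable, config.motion_mode
                )
            else:
                cleaned_pieces = [(selected, np.arange(selected.n_frames))]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"motion: {exc}") from exc

    # downstream stages run on the longest clean piece (split mode keeps all on disk)
    for i, (piece, fmap) in enumerate(cleaned_pieces):
        write_trace_csv(piece, out / f"cleaned_traces_{i}.csv")
        np.savetxt(out / f"cleaned_frame_map_{i}.csv", fmap, fmt="%d")
    piece, frame_map = max(cleaned_pieces, key=lambda p: p[0].n_frames)
    manifest["stages"]["motion_output"] = {
        "n_pieces": len(cleaned_pieces),
        "frames_kept_total": int(sum(p[0].n_frames for p in cleaned_pieces)),
        "analyzed_piece_frames": piece.n_frames,
    }

    # 4. transient extraction -------------------------------------------
    stage("transients")
    try:
        if config.skip_transients:
            manifest["stages"]["transients"] = {"skipped": True}
            _write_manifest(manifest, out)
            return manifest
        tset = _transients.extract_transients(
            piece, config.baseline, config.peaks, config.subtract_only
        )
        peak_rows = [
            {
                "roi_id": roi,
                "peak_frame": p.frame,
                "time_s": p.frame / piece.frame_rate_hz,
                "amplitude": p.amplitude,
                "prominence": p.prominence,
                "width_s": p.width_s,
                "extent_start": p.extent[0],
                "extent_end": p.extent[1],
            }
            for roi in tset.roi_ids
            for p in tset.peaks[roi]
        ]
        pd.DataFrame(
            peak_rows,
            columns=["roi_id", "peak_frame", "time_s", "amplitude", "prominence",
                     "width_s", "extent_start", "extent_end"],
        ).to_csv(out / "peaks.csv", index=False)
        write_trace_csv(tset.masked_dff, out / "masked_dff.csv")
        manifest["stages"]["transients"] = {
            "skipped": False,
            "n_peaks_total": tset.n_peaks(),
            "n_rois_with_peaks": sum(1 for r in tset.roi_ids if tset.peaks[r]),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"transients: {exc}") from exc

    # 5. clustering ------------------------------------------------------
    stage("clustering")
    try:
        if config.skip_clustering:
            manifest["stages"]["clustering"] = {"skipped": True}
            _write_manifest(manifest, out)
            return manifest
        source = tset.masked_dff if config.use_masked else tset.dff
        cluster_section: dict[str, Any] = {"skipped": False}
        if source.n_rois < 2:
            cluster_section["note"] = "fewer than 2 ROIs; all singletons"
            labels = {r: i for i, r in enumerate(source.roi_ids)}
        else:
            corr, forced = _cluster.correlation_matrix(source)
            cand_idx, single_idx = _cluster.prefilter_singletons(
                corr, config.cluster.prefilter_r
            )
            singleton_ids = [corr.roi_ids[i] for i in single_idx] + forced
            cluster_section["n_candidates"] = len(cand_idx)
            cluster_section["n_singletons"] = len(singleton_ids)
            if len(cand_idx) < 4:
                cluster_section["note"] = (
                    "fewer than 4 clustering candidates; every ROI kept separate"
                )
                labels = {r: i for i, r in enumerate(source.roi_ids)}
            else:
                sub = corr.submatrix(cand_idx)
                results = _cluster.scan_k(sub, config.cluster, singleton_ids=singleton_ids)
                scan_rows = [
                    {"k": k, "method": m, "silhouette": s}
                    for m, res in results.items()
                    for k, s in sorted(res.silhouette_by_k.items())
                ]
                pd.DataFrame(scan_rows).to_csv(out / "k_scan.csv", index=False)
                primary = results.get("hierarchical") or next(iter(results.values()))
                labels = primary.full_partition()
                cluster_section["chosen_k"] = {m: r.k for m, r in results.items()}
                cluster_section["max_silhouette"] = {
                    m: round(max(r.silhouette_by_k.values()), 6) for m, r in results.items()
                }
                for m, r in results.items():
                    if r.warning:
                        cluster_section.setdefault("warnings", []).append(f"{m}: {r.warning}")
        pd.DataFrame(
            {
                "roi_id": list(labels),
                "group_id": [labels[r] for r in labels],
                "is_singleton": [
                    sum(1 for v in labels.values() if v == labels[r]) == 1 for r in labels
                ],
            }
        ).to_csv(out / "labels.csv", index=False)
        manifest["stages"]["clustering"] = cluster_section
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"clustering: {exc}") from exc

    manifest["status"] = "ok"
    # ROI bookkeeping: discarded + singleton + clustered == input
    if not config.skip_selection and "clustering" in manifest["stages"]:
        sel = manifest["stages"]["selection"]
        manifest["roi_accounting"] = {
            "input": traces.n_rois,
            "discarded_by_power": sel["n_discarded"],
            "selected": sel["n_selected"],
        }
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
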