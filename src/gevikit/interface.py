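"""File I/O, run configuration and the end-to-end analysis pipeline.

Movies travel as multi-page grayscale TIFF with a JSON sidecar carrying
acquisition metadata (frame rate, pixel size, camera offset); traces as
two-column CSV (time_s, value); reports as JSON with floats fixed to 9
significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .activation_segmentation import (
    ROIMask,
    activation_map,
    delta_f_sequence,
    preprocess_map_sequence,
    roi_timecourse,
    segment_soma,
)
from .dff_core import (
    DEFAULT_CAMERA_OFFSET,
    DEFAULT_PIXEL_SIZE_UM,
    FluorTrace,
    Movie,
    average_trials,
    compute_dff,
    pixel_bleach_fit,
)
from .signal_metrics import snr_report
from .synthetic_scene import Pulse, StimProtocol

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_movie",
    "save_movie",
    "load_trials",
    "save_trace",
    "load_trace",
    "dump_json",
    "load_protocol",
    "run_pipeline",
]


def _json_ready(obj):
    """Round floats to 9 significant digits for stable serialization."""
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.9g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    return obj


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_json_ready(obj), indent=1, sort_keys=True) + "\n")


def save_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as multi-page float TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float64), photometric="minisblack")
    sidecar = {
        "frame_rate": movie.frame_rate,
        "pixel_size": movie.pixel_size,
        "camera_offset": movie.camera_offset,
        "meta": _json_ready(movie.meta),
    }
    dump_json(sidecar, path.with_suffix(".json"))


def load_movie(path: str | Path, **overrides) -> Movie:
    """Read a multi-page grayscale TIFF movie, bit-exact.

    Metadata is resolved from the JSON sidecar (``<stem>.json`` next to
    the TIFF) and then from keyword overrides (``frame_rate``,
    ``pixel_size``, ``camera_offset``). A missing frame rate is an error,
    never guessed.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        axes = tif.series[0].axes
        data = tif.series[0].asarray()
    if "S" in axes or (data.ndim == 3 and axes in ("YXS",)) or data.ndim > 3:
        raise ValueError(f"unsupported TIFF layout {axes!r} (RGB/multi-sample not supported)")
    if data.ndim == 2:
        raise ValueError("movie TIFF must contain multiple pages")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frame_rate = overrides.get("frame_rate", meta.get("frame_rate"))
    if frame_rate is None:
        raise ValueError(f"frame rate for {path} not found in sidecar and not overridden")
    return Movie(
        data,
        float(frame_rate),
        float(overrides.get("pixel_size", meta.get("pixel_size", DEFAULT_PIXEL_SIZE_UM))),
        float(overrides.get("camera_offset", meta.get("camera_offset", DEFAULT_CAMERA_OFFSET))),
        meta.get("meta", {}),
    )


def load_trials(pattern: str, **overrides) -> list[Movie]:
    """Load every movie matching a glob pattern, in lexicographic order."""
    paths = sorted(_glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no movies match {pattern!r}")
    return [load_movie(p, **overrides) for p in paths]


def save_trace(path: str | Path, trace: FluorTrace, value_name: str = "dff_fraction") -> None:
    arr = np.column_stack([trace.times, trace.values])
    np.savetxt(path, arr, delimiter=",", header=f"time_s,{value_name}", comments="")


def load_trace(path: str | Path, rate: float, convention: str = "raw") -> FluorTrace:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return FluorTrace(arr[:, 1], rate, convention)


def load_protocol(path: str | Path) -> StimProtocol:
    """Read a stimulation protocol from YAML/JSON.

    Expected layout::

        trial_count: 4
        pulses:
          - {onset: 1.0, duration: 0.1, kind: long_depol}
    """
    raw = yaml.safe_load(Path(path).read_text())
    pulses = [Pulse(float(p["onset"]), float(p["duration"]), str(p["kind"]))
              for p in raw.get("pulses", [])]
    return StimProtocol(pulses, int(raw.get("trial_count", 1)))


@dataclass
class RunConfig:
    """Everything one end-to-end analysis run needs.

    Either ``movie_glob`` (trial TIFFs on disk) or ``movies`` (in-memory)
    must be supplied; ``protocol`` is required whenever signal metrics are
    requested.
    """

    out_dir: str
    movie_glob: str | None = None
    movies: list = field(default_factory=list)
    protocol: StimProtocol | None = None
    frame_rate: float | None = None
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    camera_offset: float = DEFAULT_CAMERA_OFFSET
    poly_order: int = 3
    yen_bins: int = 256
    exclude_stim_from_bleach_fit: bool = True
    snr_convention: str = "sqrt"
    compute_metrics: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        proto = raw.pop("protocol", None)
        cfg = cls(**raw)
        if proto is not None:
            pulses = [Pulse(float(p["onset"]), float(p["duration"]), str(p["kind"]))
                      for p in proto.get("pulses", [])]
            cfg.protocol = StimProtocol(pulses, int(proto.get("trial_count", 1)))
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "movies"}
        if self.protocol is not None:
            payload["protocol"] = [
                (p.onset, p.duration, p.kind) for p in self.protocol.pulses
            ]
        return hashlib.sha256(
            json.dumps(_json_ready(payload), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: RunConfig) -> dict:
    """Run trial averaging -> bleach fit -> dF/F -> map -> ROI -> metrics.

    Writes every intermediate into ``config.out_dir`` and returns a result
    bundle. Deterministic and idempotent for a fixed config: rerunning
    produces byte-identical JSON outputs. A stage failure raises
    :class:`PipelineError` after writing a partial-results manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    manifest: list[str] = []
    log: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                dump_json({"completed_stages": manifest, **bundle}, out / "manifest.json")
                raise PipelineError(name, exc) from exc
        return wrap

    if config.compute_metrics and config.protocol is None:
        raise PipelineError("metrics", ValueError("protocol required for signal metrics"))

    def _load():
        if config.movies:
            return list(config.movies)
        if config.movie_glob is None:
            raise ValueError("RunConfig needs movie_glob or movies")
        over = {}
        if config.frame_rate is not None:
            over["frame_rate"] = config.frame_rate
        over["pixel_size"] = config.pixel_size
        over["camera_offset"] = config.camera_offset
        return load_trials(config.movie_glob, **over)

    movies = stage("load")(_load)
    avg = stage("average_trials")(lambda: average_trials(movies))
    n_trials = len(movies)

    rate = avg.frame_rate
    stim = (config.protocol.stim_frames(rate, avg.n_frames)
            if config.protocol is not None else np.array([], dtype=int))
    fit_frames = (np.setdiff1d(np.arange(avg.n_frames), stim)
                  if config.exclude_stim_from_bleach_fit else None)
    log.append(f"bleach fit frames: {'non-stimulus' if config.exclude_stim_from_bleach_fit else 'all'}")

    bleach = stage("bleach_fit")(lambda: pixel_bleach_fit(avg, fit_frames))
    manifest.append("bleach_fit")
    dff = stage("dff")(lambda: compute_dff(avg, bleach))
    manifest.append("dff")

    def _map():
        seq = delta_f_sequence(avg, bleach)
        seq50, rate50 = preprocess_map_sequence(seq, rate, mode="visualization")
        if config.protocol is None:
            raise ValueError("protocol required to place stimulus windows")
        win = [config.protocol.stim_frames(rate50, seq50.shape[0])]
        return activation_map(seq50, win, avg.pixel_size,
                              provenance={"filter": "visualization"})

    amap = stage("activation_map")(_map)
    manifest.append("activation_map")
    roi: ROIMask = stage("segmentation")(lambda: segment_soma(amap, nbins=config.yen_bins))
    manifest.append("segmentation")
    trace = stage("roi_timecourse")(lambda: roi_timecourse(dff, roi, rate))
    manifest.append("roi_timecourse")

    rate_map = bleach.rate_map()
    bleach_rate = float(np.nanmedian(rate_map[roi.mask]))

    tifffile.imwrite(out / "activation_map.tif", amap.data.astype(np.float32))
    tifffile.imwrite(out / "roi_mask.tif", roi.mask.astype(np.uint8))
    tifffile.imwrite(out / "dff.tif", dff.astype(np.float32))
    save_trace(out / "roi_trace.csv", trace)

    bundle.update(
        n_trials=n_trials,
        roi_pixels=roi.pixel_count,
        roi_centroid_um=list(roi.centroid_um),
        bleach_rate_pct_s=bleach_rate,
    )

    if config.compute_metrics:
        def _metrics():
            reports = []
            for k, pulse in enumerate(config.protocol.pulses):
                onset = int(np.floor(pulse.onset * rate + 0.5))
                spike_idx = sum(
                    1 for p in config.protocol.pulses[:k] if p.kind == "spike"
                ) if pulse.kind == "spike" else 0
                rep = snr_report(
                    trace, onset, pulse.kind,
                    bleach_rate_pct_s=bleach_rate,
                    stim_duration_s=pulse.duration,
                    spike_index=spike_idx,
                    trial_count=n_trials,
                    convention=config.snr_convention,
                )
                reports.append(rep.to_dict())
            return reports

        bundle["snr_reports"] = stage("metrics")(_metrics)
        manifest.append("metrics")
        log.append(f"snr correction convention: {config.snr_convention}")

    bundle["log"] = log
    dump_json(bundle, out / "report.json")
    dump_json({"completed_stages": manifest, **{k: bundle[k] for k in ("version", "config_hash", "seed")}},
              out / "manifest.json")
    return bundle
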