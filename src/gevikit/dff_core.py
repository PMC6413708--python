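"""Trial averaging, per-pixel bleach correction and dF/F0 computation.

Wide-field voltage-imaging movies bleach measurably within a single trial
(0.2--1 %/s is typical for the FRET-based indicators this package targets),
so the baseline F0 of every pixel is estimated from a straight-line fit to
that pixel's own time course rather than from a fixed pre-stimulus frame.
The fractional fluorescence change of pixel ``p_i`` at frame ``n`` is then

    dF/F0[i, n] = (p_i[n] - f_i[n]) / (f_i[n] - offset)

where ``f_i`` is the fitted line and ``offset`` is the camera's dark offset
(1,600 counts for the 4x4-binned sCMOS acquisition this convention comes
from).  Depolarization makes the donor emission *decrease*, so raw dF/F is
negative-going; traces can be flipped to the "depol_positive" convention
for display and peak-finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CAMERA_OFFSET",
    "Movie",
    "FluorTrace",
    "BleachField",
    "average_trials",
    "pixel_bleach_fit",
    "compute_dff",
    "flatten_trace",
]

DEFAULT_CAMERA_OFFSET = 1600.0
DEFAULT_PIXEL_SIZE_UM = 1.04


@dataclass
class Movie:
    """A frames x rows x cols stack of camera counts with acquisition metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, n_rows, n_cols)``, camera counts. Stored
        as float64 (trial averages are generally non-integer).
    frame_rate
        Acquisition rate in Hz.
    pixel_size
        Pixel pitch at the sample plane, micrometres.
    camera_offset
        Dark offset in counts, subtracted in all fractional-change math.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    camera_offset: float = DEFAULT_CAMERA_OFFSET
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"movie data must be 3-D (frames, rows, cols), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ValueError("movie must contain at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.camera_offset < 0:
            raise ValueError("camera_offset must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in seconds."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass
class FluorTrace:
    """A 1-D fluorescence time course with an explicit sign convention.

    ``convention`` is ``"raw"`` when depolarization drives the values down
    (donor-emission polarity, the native output of :func:`compute_dff`) and
    ``"depol_positive"`` after the sign flip used for plotting and
    peak-finding.
    """

    values: np.ndarray
    rate: float
    convention: str = "raw"
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.convention not in ("raw", "depol_positive"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) / self.rate

    def to_raw(self) -> "FluorTrace":
        if self.convention == "raw":
            return self
        return FluorTrace(-self.values, self.rate, "raw", dict(self.origin))

    def to_depol_positive(self) -> "FluorTrace":
        if self.convention == "depol_positive":
            return self
        return FluorTrace(-self.values, self.rate, "depol_positive", dict(self.origin))


@dataclass
class BleachField:
    """Per-pixel straight-line baseline fits f_i[n] = intercept + slope * n.

    Pixels whose fitted value ever drops to or below the camera offset have
    an undefined fractional change; they are flagged here and excluded from
    dF/F and from the bleach-rate map (NaN) downstream.
    """

    slope: np.ndarray  # counts / frame
    intercept: np.ndarray  # counts at frame 0
    frame_rate: float
    camera_offset: float
    n_frames: int
    flagged: np.ndarray  # bool, True where the fit is unusable
    fit_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def evaluate(self, frames: np.ndarray | None = None) -> np.ndarray:
        """Fitted baseline stack, evaluated at every frame by default."""
        if frames is None:
            frames = np.arange(self.n_frames)
        frames = np.asarray(frames, dtype=np.float64)
        return self.intercept[None] + self.slope[None] * frames[:, None, None]

    def rate_map(self) -> np.ndarray:
        """Bleach-rate map in %/s relative to the offset-subtracted intercept.

        Defined as ``-slope / (intercept - offset) * frame_rate * 100`` and
        NaN on flagged pixels.
        """
        denom = self.intercept - self.camera_offset
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = -self.slope / denom * self.frame_rate * 100.0
        rate[self.flagged] = np.nan
        return rate


def average_trials(movies: Sequence[Movie]) -> Movie:
    """Element-wise mean of repeated imaging trials.

    All trials must share shape, frame rate, pixel size and offset; the
    result's metadata records the trial count.
    """
    if len(movies) == 0:
        raise ValueError("need at least one movie to average")
    ref = movies[0]
    for i, m in enumerate(movies[1:], start=1):
        if m.data.shape != ref.data.shape:
            raise ValueError(
                f"trial {i} has shape {m.data.shape}, expected {ref.data.shape}"
            )
        if m.frame_rate != ref.frame_rate:
            raise ValueError(f"trial {i} has frame rate {m.frame_rate}, expected {ref.frame_rate}")
    mean = np.mean([m.data for m in movies], axis=0)
    meta = dict(ref.meta)
    meta["n_trials_averaged"] = len(movies)
    return Movie(mean, ref.frame_rate, ref.pixel_size, ref.camera_offset, meta)


def pixel_bleach_fit(movie: Movie, fit_frames: np.ndarray | None = None) -> BleachField:
    """Ordinary-least-squares line per pixel, used as the bleaching baseline.

    Parameters
    ----------
    movie
        Input counts movie.
    fit_frames
        Frame indices the line is fitted over (e.g. all frames outside the
        stimulus windows). Defaults to every frame. The fitted line is
        always *evaluated* at every frame.
    """
    if fit_frames is None:
        fit_frames = np.arange(movie.n_frames)
    fit_frames = np.asarray(sorted(set(int(f) for f in np.asarray(fit_frames).ravel())))
    if fit_frames.size and (fit_frames[0] < 0 or fit_frames[-1] >= movie.n_frames):
        raise ValueError("fit_frames outside movie range")
    if fit_frames.size < 10:
        raise ValueError(
            f"need at least 10 frames for a per-pixel bleach fit, got {fit_frames.size}"
        )
    t = fit_frames.astype(np.float64)
    y = movie.data[fit_frames].reshape(fit_frames.size, -1)
    design = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope = coef[0].reshape(movie.spatial_shape)
    intercept = coef[1].reshape(movie.spatial_shape)
    # A pixel is unusable when the fitted value touches the offset anywhere
    # in the movie (the dF/F denominator would be <= 0).
    ends = np.stack([intercept, intercept + slope * (movie.n_frames - 1)])
    flagged = ends.min(axis=0) <= movie.camera_offset
    return BleachField(
        slope=slope,
        intercept=intercept,
        frame_rate=movie.frame_rate,
        camera_offset=movie.camera_offset,
        n_frames=movie.n_frames,
        flagged=flagged,
        fit_frames=fit_frames,
    )


def compute_dff(
    movie: Movie, bleach: BleachField, camera_offset: float | None = None
) -> np.ndarray:
    """Per-pixel fractional change (p_i[n] - f_i[n]) / (f_i[n] - offset).

    Returns a float array of the movie's shape, negative-going on
    depolarization ("raw" convention). Flagged pixels are NaN throughout
    and must be excluded from any downstream averaging.
    """
    if bleach.slope.shape != movie.spatial_shape:
        raise ValueError("bleach field shape does not match movie")
    if camera_offset is None:
        camera_offset = bleach.camera_offset
    fitted = bleach.evaluate(np.arange(movie.n_frames))
    flagged = bleach.flagged | (fitted.min(axis=0) <= camera_offset)
    if flagged.all():
        raise ValueError("camera offset >= fitted baseline on every pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie.data - fitted) / (fitted - camera_offset)
    dff[:, flagged] = np.nan
    return dff


def flatten_trace(
    trace: FluorTrace, signal_mask: np.ndarray, poly_order: int = 3
) -> FluorTrace:
    """Divide out slow drift using a polynomial fitted to signal-free frames.

    The polynomial is fitted by least squares only to frames *outside*
    ``signal_mask`` (the voltage-signal windows), the whole trace is divided
    by it, and the result is returned as the deviation from 1. Used before
    downsampling analyses so that residual bleaching does not inflate the
    noise estimate of long averaging windows.
    """
    mask = np.zeros(len(trace), dtype=bool)
    mask[np.asarray(signal_mask, dtype=int)] = True
    n_free = int((~mask).sum())
    needed = 5 * (poly_order + 1)
    if n_free < needed:
        raise ValueError(
            f"need at least {needed} signal-free frames for order-{poly_order} "
            f"flattening, got {n_free}"
        )
    t = np.arange(len(trace), dtype=np.float64)
    poly = np.polynomial.Polynomial.fit(t[~mask], trace.values[~mask], deg=poly_order)
    baseline = poly(t)
    if np.any(np.abs(baseline) < 1e-12):
        raise ValueError("fitted baseline crosses zero; cannot flatten by division")
    flat = trace.values / baseline - 1.0
    origin = dict(trace.origin)
    origin["flattened"] = {"poly_order": poly_order, "n_free_frames": n_free}
    return FluorTrace(flat, trace.rate, trace.convention, origin)
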