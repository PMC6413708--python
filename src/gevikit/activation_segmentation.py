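"""Stimulus-evoked activation maps and automatic somatic ROI segmentation.

An activation map is the per-pixel sum of the bleach-corrected dF sequence
over the frames collected during stimulation: pixels carrying signal go
negative (donor-emission polarity) while pure-noise pixels average to
zero, so the map reveals the active cell's anatomy. The somatic ROI is
found by Yen's automatic threshold on the sign-corrected map, one round of
binary closing then dilation, and selection of the largest connected
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_yen
from skimage.measure import label

from .dff_core import BleachField, FluorTrace, Movie

__all__ = [
    "ActivationMap",
    "ROIMask",
    "NoActiveCellError",
    "delta_f_sequence",
    "preprocess_map_sequence",
    "activation_map",
    "segment_soma",
    "roi_timecourse",
]

MAP_RATE_HZ = 50.0
_FOOTPRINT = np.ones((3, 3), dtype=bool)  # smallest symmetric structuring element


class NoActiveCellError(ValueError):
    """Raised when an activation map contains no credible active cell."""


@dataclass
class ActivationMap:
    """2-D per-pixel stimulus-evoked response image.

    ``convention`` is ``"raw"`` when active pixels are negative and
    ``"depol_positive"`` after sign correction; ``provenance`` records the
    stimulus windows and filter mode that produced the map.
    """

    data: np.ndarray
    pixel_size: float
    convention: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("activation map contains non-finite values")

    def sign_corrected(self) -> np.ndarray:
        """Map with active pixels positive."""
        return self.data if self.convention == "depol_positive" else -self.data


@dataclass
class ROIMask:
    """A single-connected-component binary region of interest."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("ROI mask must be a non-empty 2-D binary image")
        if label(self.mask, connectivity=2).max() != 1:
            raise ValueError("ROI mask must be a single connected component")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid_um(self) -> tuple[float, float]:
        r, c = np.nonzero(self.mask)
        return (float((r.mean() + 0.5) * self.pixel_size),
                float((c.mean() + 0.5) * self.pixel_size))


def delta_f_sequence(movie: Movie, bleach: BleachField) -> np.ndarray:
    """Per-pixel, per-frame difference from the fitted bleach line (counts)."""
    if bleach.slope.shape != movie.spatial_shape:
        raise ValueError("bleach field shape does not match movie")
    return movie.data - bleach.evaluate(np.arange(movie.n_frames))


def preprocess_map_sequence(
    seq: np.ndarray, rate: float, mode: str = "visualization"
) -> tuple[np.ndarray, float]:
    """Downsample a dF sequence to 50 Hz and filter it for map building.

    ``mode="visualization"`` applies a spatiotemporal Gaussian with sigma
    of one 50 Hz frame (20 ms) and one pixel; ``mode="spread"`` applies
    only a 3-point temporal median filter, leaving the spatial structure
    untouched for autocorrelation analysis. Returns ``(sequence, 50.0)``.
    """
    seq = np.asarray(seq, dtype=np.float64)
    if rate < MAP_RATE_HZ:
        raise ValueError(f"input rate {rate} Hz is below the 50 Hz map rate")
    ratio = rate / MAP_RATE_HZ
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"input rate {rate} Hz is not an integer multiple of 50 Hz")
    n = int(round(ratio))
    usable = (seq.shape[0] // n) * n
    down = seq[:usable].reshape(-1, n, *seq.shape[1:]).mean(axis=1)
    if mode == "visualization":
        out = ndimage.gaussian_filter(down, sigma=(1.0, 1.0, 1.0))
    elif mode == "spread":
        out = ndimage.median_filter(down, size=(3, 1, 1), mode="nearest")
    else:
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    return out, MAP_RATE_HZ


def activation_map(
    seq: np.ndarray,
    stim_windows: list,
    pixel_size: float,
    provenance: dict | None = None,
) -> ActivationMap:
    """Sum the filtered dF sequence over all stimulation frames."""
    seq = np.asarray(seq, dtype=np.float64)
    frames = np.unique(np.concatenate([np.asarray(w, dtype=int).ravel() for w in stim_windows])) \
        if stim_windows else np.array([], dtype=int)
    if frames.size == 0:
        raise ValueError("stimulus window set is empty")
    if frames.min() < 0 or frames.max() >= seq.shape[0]:
        raise ValueError("stimulus windows fall outside the sequence")
    prov = dict(provenance or {})
    prov["stim_frames"] = frames.tolist()
    return ActivationMap(seq[frames].sum(axis=0), pixel_size, "raw", prov)


def segment_soma(
    amap: ActivationMap,
    nbins: int = 256,
    min_foreground_sigma: float = 3.5,
) -> ROIMask:
    """Automatically segment the somatic ROI from an activation map.

    Yen's threshold is computed on a 256-bin histogram of the min-max
    scaled, sign-corrected map. To reject maps that contain nothing but
    noise (where a histogram threshold always "succeeds"), the *mean of
    the suprathreshold foreground* must exceed the map median by
    ``min_foreground_sigma`` robust standard deviations, else
    :class:`NoActiveCellError` is raised. The 3.5-sigma default sits well
    above this statistic's null distribution on pure-noise maps (max 2.5
    over 300 null draws, smoothed or not) while a genuine soma scores far
    higher; pass 0 to disable the gate when a cell is known to be present.
    One round of 3x3 binary closing then dilation is applied and the
    largest 8-connected component is returned; equal-size ties are broken
    toward the component with larger summed activation.
    """
    x = amap.sign_corrected()
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise NoActiveCellError("no active cell detected: constant activation map")
    scaled = (x - lo) / (hi - lo)
    thr = threshold_yen(scaled, nbins=nbins)
    fg = scaled > thr
    if not fg.any():
        raise NoActiveCellError("no active cell detected: empty foreground")
    med = float(np.median(x))
    sigma = 1.4826 * float(np.median(np.abs(x - med)))
    if sigma > 0 and float(x[fg].mean()) < med + min_foreground_sigma * sigma:
        raise NoActiveCellError(
            "no active cell detected: foreground within the noise floor of the map"
        )
    fg = ndimage.binary_closing(fg, structure=_FOOTPRINT)
    fg = ndimage.binary_dilation(fg, structure=_FOOTPRINT)
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoActiveCellError("no active cell detected: empty foreground after morphology")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, labels.max() + 1))
    best = sizes.max()
    candidates = np.nonzero(sizes == best)[0] + 1
    if len(candidates) > 1:
        sums = ndimage.sum_labels(x, labels, index=candidates)
        chosen = candidates[int(np.argmax(sums))]
    else:
        chosen = candidates[0]
    return ROIMask(labels == chosen, amap.pixel_size)


def roi_timecourse(dff: np.ndarray, mask: ROIMask, frame_rate: float) -> FluorTrace:
    """Unweighted mean time course of the pixels inside an ROI.

    Pixels flagged as undefined (NaN) by the bleach fit are excluded from
    the mean; it is an error for the ROI to contain no valid pixel.
    """
    dff = np.asarray(dff, dtype=np.float64)
    if dff.shape[1:] != mask.mask.shape:
        raise ValueError("dF/F movie and ROI mask shapes differ")
    pix = dff[:, mask.mask]
    valid = ~np.isnan(pix).all(axis=0)
    if not valid.any():
        raise ValueError("ROI lies entirely on flagged (undefined) pixels")
    if not valid.all():
        warnings.warn(f"excluding {int((~valid).sum())} flagged pixels from ROI mean")
    values = np.nanmean(pix[:, valid], axis=1)
    return FluorTrace(
        values, frame_rate, "raw",
        origin={"roi_pixels": int(valid.sum())},
    )
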