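"""Synthetic wide-field voltage-imaging movies with ground truth.

Emulates sparse "Golgi-staining-like" expression of a membrane-localized
FRET-donor voltage indicator in an acute-slice field of view:

* neurons render as bright membrane annuli (darker interior) plus
  line-segment dendrites, optionally blurred by a Gaussian to model
  defocus / scattering;
* depolarization produces a *negative* fractional change in donor
  emission, low-pass filtered by first-order indicator kinetics with decay
  constant ``gevi_tau``;
* the camera integrates the underlying waveform over the whole frame
  period, adds photon shot noise (Poisson, variance = expected photons),
  Gaussian read noise, and a fixed dark offset;
* fluorescence bleaches as a single effective exponential (the product of
  excitation intensity and bleaching quantum yield is not separable from
  an imaging experiment, so a single rate constant stands in for it);
* a spatially uniform background contributes a configurable fraction
  ``background_fraction`` of all collected fluorescence, modelling
  non-signaling structures and autofluorescence.

Every simulation returns a :class:`GroundTruth` bundle (masks, noiseless
traces, bleach decay) so downstream stages can be tested as parameter
recovery problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dff_core import Movie

__all__ = [
    "NeuronGeometry",
    "SceneConfig",
    "Pulse",
    "StimProtocol",
    "GroundTruth",
    "VoltageTrace",
    "render_neurons",
    "simulate_movie",
    "simulate_trials",
    "simulate_ephys",
    "dff_waveform",
    "ap_attenuation",
    "table1_config",
    "table1_geometries",
    "table1_protocol",
    "scatter_pair_scene",
]


@dataclass
class NeuronGeometry:
    """Geometry of one membrane-labelled neuron, all lengths in micrometres.

    ``dendrites`` is a list of ``((r0, c0), (r1, c1), width)`` line
    segments; ``defocus_sigma`` is the Gaussian blur applied to this
    neuron's rendered map (depth of the cell relative to the focal plane,
    plus scattering).
    """

    soma_center: tuple[float, float]
    soma_radius: float
    membrane_thickness: float = 2.0
    dendrites: list = field(default_factory=list)
    defocus_sigma: float = 2.0
    dendrite_defocus_sigma: float | None = None

    def __post_init__(self) -> None:
        if not self.soma_radius > 0:
            raise ValueError("soma_radius must be positive")
        if not 0 < self.membrane_thickness < self.soma_radius:
            raise ValueError("membrane_thickness must be in (0, soma_radius)")
        if self.dendrite_defocus_sigma is None:
            # processes rarely stay in the focal plane of the soma; by
            # default they carry three times the somatic defocus
            self.dendrite_defocus_sigma = 3.0 * self.defocus_sigma


@dataclass
class SceneConfig:
    """Acquisition and indicator parameters for a simulated movie.

    Defaults reflect the 4x4-binned sCMOS acquisition this package is
    calibrated against: 1.04 um pixels, 1,600-count dark offset, 100 Hz.
    ``gevi_tau`` defaults to 25 ms (room-temperature indicator kinetics;
    use 12 ms for recordings near 34 C). ``bleach_rate`` is an effective
    initial fractional loss per second. Amplitudes are peak -dF/F
    fractions before kinetic attenuation by the camera frame integration.

    ``interior_brightness`` and ``dendrite_brightness`` are relative to
    the soma rim: wide-field imaging integrates over depth, so a
    spherical membrane shell projects to a bright rim with an interior of
    roughly 0.45x the rim density, and micron-scale dendrites are dimmer
    than the soma rim once defocus is included.
    """

    fov: tuple[int, int] = (96, 96)
    pixel_size: float = 1.04
    frame_rate: float = 100.0
    n_frames: int = 300
    camera_offset: float = 1600.0
    baseline_photons: float = 8000.0
    bleach_rate: float = 0.0052
    background_fraction: float = 0.2
    gevi_tau: float = 0.025
    ap_amplitude: float = 0.0017
    depol_amplitude: float = 0.006
    read_noise_sd: float = 2.0
    interior_brightness: float = 0.45
    dendrite_brightness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if not self.gevi_tau > 0:
            raise ValueError("gevi_tau must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.camera_offset < 0:
            raise ValueError("camera_offset must be non-negative")
        for name in ("ap_amplitude", "depol_amplitude"):
            amp = getattr(self, name)
            if not (0 < amp <= 0.05):
                raise ValueError(f"{name} must be in (0, 0.05]")

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class Pulse:
    onset: float  # s
    duration: float  # s
    kind: str  # "long_depol" | "spike"

    def __post_init__(self) -> None:
        if self.kind not in ("long_depol", "spike"):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("pulse onset must be >= 0 and duration > 0")


@dataclass
class StimProtocol:
    """A sorted, non-overlapping list of stimulation pulses."""

    pulses: list
    trial_count: int = 1

    def __post_init__(self) -> None:
        if self.trial_count < 1:
            raise ValueError("trial_count must be >= 1")
        onsets = [p.onset for p in self.pulses]
        if onsets != sorted(onsets):
            raise ValueError("pulses must be sorted by onset")
        for a, b in zip(self.pulses, self.pulses[1:]):
            if a.onset + a.duration > b.onset:
                raise ValueError("pulses must not overlap")

    @property
    def end_time(self) -> float:
        if not self.pulses:
            return 0.0
        last = self.pulses[-1]
        return last.onset + last.duration

    def frame_windows(self, rate: float, spike_window: float = 0.05) -> list[np.ndarray]:
        """Frame indices covered by each pulse at a given frame rate.

        A spike's optical transient outlasts the (sub-ms) current pulse, so
        spike windows span ``spike_window`` seconds (default 50 ms) from
        onset; long depolarizations use their own duration.
        """
        windows = []
        for p in self.pulses:
            dur = p.duration if p.kind == "long_depol" else spike_window
            first = int(math.floor(p.onset * rate + 0.5))
            n = max(1, int(math.floor(dur * rate + 0.5)))
            windows.append(np.arange(first, first + n))
        return windows

    def stim_frames(self, rate: float, n_frames: int, spike_window: float = 0.05) -> np.ndarray:
        """All stimulus frame indices (union of windows), clipped to range."""
        if not self.pulses:
            return np.array([], dtype=int)
        frames = np.concatenate(self.frame_windows(rate, spike_window))
        return np.unique(frames[(frames >= 0) & (frames < n_frames)])


@dataclass
class GroundTruth:
    """Per-neuron ground truth accompanying a simulated movie."""

    membrane_masks: list  # bool arrays, whole labelled structure per neuron
    soma_masks: list  # bool arrays, filled soma disc per neuron
    dff_traces: np.ndarray  # (n_neurons, n_frames) frame-integrated -going dF/F
    bleach_decay: np.ndarray  # (n_frames,) multiplicative decay factor
    brightness_maps: list  # blurred expected-photon maps per neuron
    background_per_pixel: float
    config: SceneConfig = None
    geometries: list = field(default_factory=list)


@dataclass
class VoltageTrace:
    """Simultaneous patch-clamp companion trace, mV versus seconds."""

    values_mv: np.ndarray
    rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values_mv)) / self.rate


# ---------------------------------------------------------------------------
# rendering

def _render_single(geom: NeuronGeometry, config: SceneConfig, index: int,
                   blur: bool = True) -> np.ndarray:
    rows, cols = config.fov
    if rows <= 0 or cols <= 0:
        raise ValueError(f"field of view must be positive, got {config.fov}")
    ps = config.pixel_size
    ss = 3  # subpixel sampling per axis for anti-aliasing
    r_um = (np.arange(rows * ss) + 0.5) * ps / ss
    c_um = (np.arange(cols * ss) + 0.5) * ps / ss
    rr, cc = np.meshgrid(r_um, c_um, indexing="ij")

    extent = (rows * ps, cols * ps)
    outer = geom.soma_radius + geom.membrane_thickness / 2
    cr, ccen = geom.soma_center
    if not (0 <= cr - outer and cr + outer <= extent[0] and
            0 <= ccen - outer and ccen + outer <= extent[1]):
        raise ValueError(f"neuron {index}: soma extends outside the field of view")

    dist = np.hypot(rr - cr, cc - ccen)
    inner = geom.soma_radius - geom.membrane_thickness / 2
    soma_img = np.zeros_like(dist)
    soma_img[dist < inner] = config.interior_brightness
    soma_img[(dist >= inner) & (dist <= outer)] = 1.0

    dend_img = np.zeros_like(dist)
    for (p0, p1, width) in geom.dendrites:
        for pt in (p0, p1):
            if not (0 <= pt[0] <= extent[0] and 0 <= pt[1] <= extent[1]):
                raise ValueError(f"neuron {index}: dendrite endpoint {pt} outside the field of view")
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        dr = rr - p0[0]
        dc = cc - p0[1]
        if seg_len2 == 0:
            d = np.hypot(dr, dc)
        else:
            t = np.clip((dr * seg[0] + dc * seg[1]) / seg_len2, 0.0, 1.0)
            d = np.hypot(dr - t * seg[0], dc - t * seg[1])
        dend_img = np.maximum(dend_img, config.dendrite_brightness * (d <= width / 2))

    # average the subpixel samples back onto the camera grid, then apply
    # each compartment's own defocus (dendrites sit further from the focal
    # plane than the soma and blur more)
    soma_img = soma_img.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    dend_img = dend_img.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    if blur:
        if geom.defocus_sigma > 0:
            soma_img = ndimage.gaussian_filter(soma_img, geom.defocus_sigma / ps)
        if geom.dendrite_defocus_sigma > 0:
            dend_img = ndimage.gaussian_filter(dend_img, geom.dendrite_defocus_sigma / ps)
    return soma_img + dend_img


def render_neurons(
    geometries: Sequence[NeuronGeometry],
    config: SceneConfig,
    separate: bool = False,
    blur: bool = True,
):
    """Render membrane-brightness maps (relative units, membrane = 1).

    With ``separate=True`` a list of per-neuron maps is returned, otherwise
    their sum.
    """
    if len(geometries) == 0:
        raise ValueError("need at least one neuron geometry")
    maps = [_render_single(g, config, i, blur=blur) for i, g in enumerate(geometries)]
    if separate:
        return maps
    return np.sum(maps, axis=0)


# ---------------------------------------------------------------------------
# indicator kinetics and frame integration

def _continuous_waveform(protocol: StimProtocol, config: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Noiseless -going dF/F(t): stimulus convolved with exponential kinetics."""
    tau = config.gevi_tau
    w = np.zeros_like(t)
    for p in protocol.pulses:
        dt = t - p.onset
        if p.kind == "spike":
            w -= config.ap_amplitude * np.exp(-np.maximum(dt, 0) / tau) * (dt >= 0)
        else:  # long_depol: box convolved with normalized exponential decay
            rise = (1.0 - np.exp(-np.clip(dt, 0, None) / tau)) * (dt >= 0)
            after = dt - p.duration
            plateau = 1.0 - np.exp(-p.duration / tau)
            decay = plateau * np.exp(-np.clip(after, 0, None) / tau) * (after >= 0)
            w -= config.depol_amplitude * np.where(after < 0, rise, decay)
    return w


def dff_waveform(protocol: StimProtocol, config: SceneConfig) -> np.ndarray:
    """Frame-integrated noiseless dF/F per frame (negative-going).

    The underlying waveform is supersampled at >= 10x the frame rate (and
    at >= 10 samples per indicator time constant) and averaged within each
    frame period, realizing full-frame photon integration.
    """
    n_sub = max(10, math.ceil(10.0 / (config.frame_rate * config.gevi_tau)))
    dt = 1.0 / (config.frame_rate * n_sub)
    t = (np.arange(config.n_frames * n_sub) + 0.5) * dt
    w = _continuous_waveform(protocol, config, t)
    return w.reshape(config.n_frames, n_sub).mean(axis=1)


def ap_attenuation(tau: float, frame_rate: float) -> float:
    """Peak attenuation of a single-AP transient by full-frame integration.

    For an instantaneous-rise exponential transient starting at a frame
    boundary, the brightest frame averages ``exp(-t/tau)`` over one frame
    period ``T = 1/frame_rate``, giving ``(tau/T) * (1 - exp(-T/tau))``.
    """
    s = tau * frame_rate
    return s * (1.0 - math.exp(-1.0 / s))


# ---------------------------------------------------------------------------
# movie simulation

def simulate_movie(
    geometries: Sequence[NeuronGeometry],
    config: SceneConfig,
    protocol: StimProtocol,
    active: Sequence[bool] | None = None,
    trial: int = 0,
) -> tuple[Movie, GroundTruth]:
    """Simulate one trial of a wide-field voltage-imaging acquisition.

    Expected counts per pixel per frame are

        offset + decay[n] * (sum_i photons_i * (1 + dff_i[n]) + background)

    with Poisson shot noise on the photon term and additive Gaussian read
    noise. The RNG is seeded once per call with ``config.seed + trial`` so
    trials are independent but reproducible.
    """
    if active is None:
        active = [True] * len(geometries)
    if len(active) != len(geometries):
        raise ValueError("one activity flag per neuron required")
    if protocol.end_time > config.duration:
        raise ValueError(
            f"protocol ends at {protocol.end_time:.3f} s but the movie lasts "
            f"{config.duration:.3f} s"
        )

    blurred = render_neurons(geometries, config, separate=True, blur=True)
    unblurred = render_neurons(geometries, config, separate=True, blur=False)
    photon_maps = [config.baseline_photons * m for m in blurred]

    rows, cols = config.fov
    total0 = float(np.sum([m.sum() for m in photon_maps]))
    fb = config.background_fraction
    bg_per_px = fb / (1.0 - fb) * total0 / (rows * cols) if total0 > 0 else 0.0

    w = dff_waveform(protocol, config)
    t_frames = (np.arange(config.n_frames) + 0.5) / config.frame_rate
    decay = np.exp(-config.bleach_rate * t_frames)

    inactive_maps = [m for m, a in zip(photon_maps, active) if not a]
    active_maps = [m for m, a in zip(photon_maps, active) if a]
    static = bg_per_px + (np.sum(inactive_maps, axis=0) if inactive_maps else 0.0)
    dynamic = np.sum(active_maps, axis=0) if active_maps else np.zeros((rows, cols))

    expected_photons = decay[:, None, None] * (
        static + dynamic[None] * (1.0 + w[:, None, None])
    )
    rng = np.random.default_rng(config.seed + trial)
    counts = config.camera_offset + rng.poisson(expected_photons).astype(np.float64)
    if config.read_noise_sd > 0:
        counts += rng.normal(0.0, config.read_noise_sd, size=counts.shape)
    counts = np.clip(counts, 0.0, None)

    movie = Movie(
        counts,
        config.frame_rate,
        config.pixel_size,
        config.camera_offset,
        meta={"seed": config.seed, "trial": trial, "synthetic": True},
    )

    soma_masks = []
    ps = config.pixel_size
    rr = (np.arange(rows) + 0.5) * ps
    cc = (np.arange(cols) + 0.5) * ps
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    for g in geometries:
        d = np.hypot(grid_r - g.soma_center[0], grid_c - g.soma_center[1])
        soma_masks.append(d <= g.soma_radius + g.membrane_thickness / 2)
    membrane_masks = [m > 0.05 for m in unblurred]

    truth = GroundTruth(
        membrane_masks=membrane_masks,
        soma_masks=soma_masks,
        dff_traces=np.array([w if a else np.zeros_like(w) for a in active]),
        bleach_decay=decay,
        brightness_maps=photon_maps,
        background_per_pixel=bg_per_px,
        config=config,
        geometries=list(geometries),
    )
    return movie, truth


def simulate_trials(
    geometries: Sequence[NeuronGeometry],
    config: SceneConfig,
    protocol: StimProtocol,
    active: Sequence[bool] | None = None,
) -> tuple[list[Movie], GroundTruth]:
    """Simulate ``protocol.trial_count`` independent trials (seeds seed+k)."""
    movies = []
    truth = None
    for k in range(protocol.trial_count):
        m, truth = simulate_movie(geometries, config, protocol, active, trial=k)
        movies.append(m)
    return movies, truth


# ---------------------------------------------------------------------------
# companion electrophysiology

def simulate_ephys(
    protocol: StimProtocol,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
    duration: float | None = None,
    resting_mv: float = -70.0,
) -> VoltageTrace:
    """Stereotyped patch-clamp trace matching a stimulation protocol.

    Spike pulses produce template action potentials (difference of
    exponentials peaking ~+30 mV); long depolarizations produce plateau
    steps with a 10 ms membrane time constant. This is plumbing for
    figures and tests, not a biophysical model.
    """
    if sampling_rate < 1000:
        raise ValueError("ephys sampling rate must be >= 1 kHz")
    if duration is None:
        duration = protocol.end_time + 0.2
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    v = np.full(n, resting_mv)
    for p in protocol.pulses:
        dt = t - p.onset
        if p.kind == "spike":
            shape = np.exp(-np.clip(dt, 0, None) / 0.0015) - np.exp(
                -np.clip(dt, 0, None) / 0.0002
            )
            shape[dt < 0] = 0.0
            peak = shape.max() if shape.max() > 0 else 1.0
            v += 100.0 * shape / peak
        else:
            tau_m = 0.010
            rise = (1.0 - np.exp(-np.clip(dt, 0, None) / tau_m)) * (dt >= 0)
            after = dt - p.duration
            level = 1.0 - np.exp(-p.duration / tau_m)
            fall = level * np.exp(-np.clip(after, 0, None) / tau_m) * (after >= 0)
            v += 25.0 * np.where(after < 0, rise, fall)
    rng = np.random.default_rng(seed)
    v += rng.normal(0.0, 0.2, size=n)
    return VoltageTrace(v, sampling_rate)


# ---------------------------------------------------------------------------
# calibration preset

def table1_config(seed: int = 0, **overrides) -> SceneConfig:
    """Calibration preset reproducing the magnitudes of typical slice data.

    100 Hz, 3 s movies; single-AP optical signal ~0.14 % and 100 ms
    depolarization ~0.59 % after frame integration and background
    dilution; pre-stimulus noise ~0.04-0.07 % after 4-trial averaging;
    bleach rate 0.52 %/s. Room-temperature kinetics (tau = 25 ms).
    """
    params = dict(
        fov=(96, 96),
        pixel_size=1.04,
        frame_rate=100.0,
        n_frames=300,
        camera_offset=1600.0,
        baseline_photons=8000.0,
        bleach_rate=0.0052,
        background_fraction=0.2,
        gevi_tau=0.025,
        ap_amplitude=0.0017,
        depol_amplitude=0.006,
        read_noise_sd=2.0,
        seed=seed,
    )
    params.update(overrides)
    return SceneConfig(**params)


def table1_geometries(config: SceneConfig | None = None) -> list[NeuronGeometry]:
    """Two pyramidal-like cells: one to be driven, one silent neighbour.

    Both somata sit in the focal plane (1 um defocus -- the calibration
    preset represents the in-focus superficial recordings that make it
    into a summary table); their dendrites leave the plane and blur more.
    """
    return [
        NeuronGeometry(
            soma_center=(50.0, 30.0),
            soma_radius=10.0,
            membrane_thickness=2.0,
            dendrites=[
                ((50.0, 40.5), (50.0, 78.0), 2.0),  # apical
                ((42.0, 24.0), (18.0, 14.0), 2.0),  # basal
            ],
            defocus_sigma=1.0,
        ),
        NeuronGeometry(
            soma_center=(20.0, 75.0),
            soma_radius=9.0,
            membrane_thickness=2.0,
            dendrites=[((28.5, 79.0), (60.0, 92.0), 2.0)],
            defocus_sigma=1.0,
        ),
    ]


def scatter_pair_scene(
    separation_um: float,
    seed: int = 0,
    halo_sigma: float = 80.0,
    trial_count: int = 4,
) -> tuple[list[NeuronGeometry], SceneConfig, StimProtocol]:
    """Two identical deep cells with heavy scattering halos, for mixing tests.

    Models the regime where signal crosstalk actually matters: recordings
    tens of micrometres deep, where scattering broadens each cell's
    functional signal into a halo. The default 80 um halo matches the
    upper end of observed activation-map autocorrelation widths (50 %
    cutoffs up to ~135 um). Pixels are 2.08 um (8x8 binning) and photon
    counts are high so that validation probes the signal-mixing geometry
    rather than shot noise. The second cell sits ``separation_um`` along
    the column axis.
    """
    rows, cols = 230, 300
    ps = 2.08
    config = SceneConfig(
        fov=(rows, cols),
        pixel_size=ps,
        frame_rate=100.0,
        n_frames=100,
        baseline_photons=1e5,
        bleach_rate=0.0052,
        background_fraction=0.2,
        gevi_tau=0.025,
        depol_amplitude=0.006,
        read_noise_sd=2.0,
        seed=seed,
    )
    c0 = (cols * ps - separation_um) / 2.0
    r0 = rows * ps / 2.0
    geometries = [
        NeuronGeometry((r0, c0), 10.0, 2.0, [], defocus_sigma=halo_sigma),
        NeuronGeometry((r0, c0 + separation_um), 10.0, 2.0, [], defocus_sigma=halo_sigma),
    ]
    protocol = StimProtocol([Pulse(0.3, 0.5, "long_depol")], trial_count=trial_count)
    return geometries, config, protocol


def table1_protocol(kind: str = "depol", trial_count: int = 4) -> StimProtocol:
    """Standard stimulation protocols used with the calibration preset.

    ``"depol"``: one 100 ms depolarizing step at t = 1 s (the Table-row
    stimulus). ``"spikes"``: three brief current pulses at 20 Hz starting
    at t = 1 s. ``"map"``: one 500 ms depolarization, the long mapping
    stimulus used when anatomy-quality activation maps are wanted (up to
    ~30 summed frames at the 50 Hz map rate).
    """
    if kind == "depol":
        pulses = [Pulse(1.0, 0.100, "long_depol")]
    elif kind == "map":
        pulses = [Pulse(1.0, 0.500, "long_depol")]
    elif kind == "spikes":
        pulses = [Pulse(1.0 + k * 0.05, 0.002, "spike") for k in range(3)]
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return StimProtocol(pulses, trial_count=trial_count)
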