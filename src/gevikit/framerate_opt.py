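"""Frame-rate analysis: phase downsampling, power-law fits, aliasing model.

A 500 Hz trace containing AP-evoked transients is downsampled by block
averaging with integer factors n, keeping all n phase-shifted versions.
Signal size decays slowly with effective rate x (the indicator's
exponential kinetics low-pass the transient already) while the noise SD
grows as ~x^0.5 (shot noise), so the detection SNR

    SNR(x) = (1 - A1 * x**b1) / (A2 * x**b2)

has an interior maximum: the ideal imaging speed for spike detection. The
aliasing model treats the optical signal as a decaying exponential
(Lorentzian power spectrum) sampled by a camera that integrates the whole
frame period (sinc^2 frequency response); the aliased fraction of sampled
power fixes the minimum useful frame rate at about 2/tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .dff_core import FluorTrace

__all__ = [
    "PowerLawFit",
    "DownsampleTable",
    "phase_downsample",
    "downsample_metrics",
    "fit_power_laws",
    "optimal_rate",
    "aliased_power_fraction",
    "min_alias_free_rate",
    "noise_scaling_exponent",
    "SEVERE_ALIASING_FRACTION",
    "AliasFreeRate",
]

DEFAULT_FACTORS = (1, 2, 3, 4, 5, 10, 20)

#: Aliased power fraction at a sampling period of half the indicator decay
#: constant -- the calibration point of the "period <= tau/2" rule. The
#: Lorentzian x sinc^2 model depends only on the product rate*tau, so this
#: number is scale invariant; it is computed once at import from the same
#: integral the module exposes (see ``_severe_fraction`` below).
SEVERE_ALIASING_FRACTION: float


@dataclass
class PowerLawFit:
    """A log-log-linear fit y = A * x**b against effective frame rate."""

    A: float
    b: float
    r2: float
    orientation: str = "vs_rate"
    form: str = "noise"  # "noise" (A2 x^b2) or "one_minus_signal" (A1 x^b1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must be in [0, 1]")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(x, dtype=float) ** self.b


@dataclass
class DownsampleTable:
    """Per-factor, per-phase signal/noise plus per-factor jitter."""

    base_rate: float
    frame: pd.DataFrame  # columns: factor, phase, eff_rate_hz, signal_pct, noise_pct
    jitter: pd.DataFrame  # columns: factor, eff_rate_hz, jitter_s

    def mean_by_factor(self) -> pd.DataFrame:
        """Phase-mean signal and noise per factor (what the fits consume)."""
        g = self.frame.groupby("factor", as_index=False).agg(
            eff_rate_hz=("eff_rate_hz", "first"),
            signal_pct=("signal_pct", "mean"),
            noise_pct=("noise_pct", "mean"),
        )
        return g.merge(self.jitter[["factor", "jitter_s"]], on="factor")


def phase_downsample(values: np.ndarray, n: int) -> list[np.ndarray]:
    """All n phase-shifted block-average downsamples of a trace.

    Phase k averages frames {k..k+n-1}, {k+n..k+2n-1}, ...; a trailing
    partial block is dropped.
    """
    values = np.asarray(values, dtype=np.float64)
    if n < 1:
        raise ValueError("downsampling factor must be >= 1")
    if n > len(values) // 2:
        raise ValueError(f"factor {n} too large for a trace of {len(values)} frames")
    out = []
    for k in range(n):
        tail = values[k:]
        m = len(tail) // n
        out.append(tail[: m * n].reshape(m, n).mean(axis=1))
    return out


def downsample_metrics(
    trace: FluorTrace,
    stim_onset_s: float,
    factors: Sequence[int] = DEFAULT_FACTORS,
    stim_window_s: float = 0.05,
) -> DownsampleTable:
    """Signal, noise and timing jitter versus downsampling factor.

    The trace should be flattened (see :func:`gevikit.dff_core.flatten_trace`)
    beforehand. Per factor n and phase: noise is the SD of the
    ``floor(100/n)`` signal-free samples immediately preceding the
    stimulus; signal is the sign-corrected peak within the stimulus window
    minus the median of the ``floor(20/n)`` preceding samples. Jitter is
    the spread (max - min), across phases, of the time of the block
    containing the optical peak; with a single phase (n = 1) it is zero by
    construction. Factors whose baseline or window becomes too short are
    omitted with a warning.
    """
    v = trace.to_depol_positive().values
    rate = trace.rate
    onset_frame = int(math.floor(stim_onset_s * rate + 0.5))
    win_frames = max(1, int(math.floor(stim_window_s * rate + 0.5)))
    if onset_frame + win_frames > len(v):
        raise ValueError("stimulus window extends past end of trace")
    if onset_frame < 100:
        raise ValueError("need >= 100 signal-free frames before the stimulus at base rate")

    rows = []
    jit_rows = []
    for n in sorted(set(int(f) for f in factors)):
        n_noise = 100 // n
        n_base = 20 // n
        if n_noise < 2 or n_base < 1 or win_frames // n < 1:
            warnings.warn(f"downsampling factor {n} omitted: too few samples")
            continue
        peak_times = []
        for k, ds in enumerate(phase_downsample(v, n)):
            # downsampled sample j covers original frames [k + j*n, k + (j+1)*n)
            j_base_end = (onset_frame - k) // n  # blocks fully before onset
            j_win_start = max(0, (onset_frame - k - n) // n + 1)  # first overlap
            j_win_end = min(len(ds), math.ceil((onset_frame + win_frames - k) / n))
            if j_base_end < 1 or j_win_end <= j_win_start:
                continue
            baseline_all = ds[:j_base_end]
            if len(baseline_all) < max(n_noise, n_base):
                continue
            noise = float(np.std(baseline_all[-n_noise:], ddof=1)) * 100.0
            base = float(np.median(baseline_all[-n_base:]))
            win = ds[j_win_start:j_win_end]
            idx = int(np.argmax(win))  # ties resolve toward the earlier frame
            signal = (float(win[idx]) - base) * 100.0
            peak_times.append((k + (j_win_start + idx) * n) / rate)
            rows.append(
                dict(factor=n, phase=k, eff_rate_hz=rate / n,
                     signal_pct=signal, noise_pct=noise)
            )
        if not peak_times:
            warnings.warn(f"downsampling factor {n} omitted: no usable phase")
            continue
        jit_rows.append(
            dict(factor=n, eff_rate_hz=rate / n,
                 jitter_s=float(max(peak_times) - min(peak_times)))
        )
    if not rows:
        raise ValueError("no usable downsampling factor")
    return DownsampleTable(rate, pd.DataFrame(rows), pd.DataFrame(jit_rows))


def _loglog_fit(x: np.ndarray, y: np.ndarray, form: str) -> PowerLawFit:
    keep = y > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} non-positive value(s) dropped from "
                      f"the {form} log-log fit")
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 positive points for the {form} fit, got {len(x)}")
    lx, ly = np.log(x), np.log(y)
    b, loga = np.polyfit(lx, ly, 1)
    pred = loga + b * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(A=float(np.exp(loga)), b=float(b), r2=min(max(r2, 0.0), 1.0),
                       orientation="vs_rate", form=form)


def fit_power_laws(
    table: DownsampleTable, normalize_signal: bool = True
) -> tuple[PowerLawFit, PowerLawFit]:
    """Least-squares log-log fits of noise and 1 - signal vs effective rate.

    With ``normalize_signal=True`` (the pipeline default, where signal
    columns carry % dF/F units) the phase-mean signal is first normalized
    to its full-rate (factor 1) value; that point then sits at exactly
    zero and is dropped from the log fit. Pass ``False`` when the signal
    column is already on the 0..1 scale whose complement follows the
    power law. Returns ``(noise_fit, signal_fit)`` where the signal fit
    parameterizes ``1 - signal = A1 * x**b1``.
    """
    m = table.mean_by_factor().sort_values("factor")
    x = m["eff_rate_hz"].to_numpy()
    noise_fit = _loglog_fit(x, m["noise_pct"].to_numpy(), "noise")
    sig = m["signal_pct"].to_numpy()
    if normalize_signal:
        ref_rows = m[m["factor"] == 1]
        ref = float(ref_rows["signal_pct"].iloc[0]) if len(ref_rows) else float(sig[0])
        if ref <= 0:
            raise ValueError("full-rate signal is non-positive; cannot normalize")
        sig = sig / ref
    one_minus = 1.0 - sig
    signal_fit = _loglog_fit(x, one_minus, "one_minus_signal")
    return noise_fit, signal_fit


def optimal_rate(
    noise_fit: PowerLawFit,
    signal_fit: PowerLawFit,
    rate_range: tuple[float, float] = (25.0, 500.0),
    n_grid: int = 4000,
) -> float:
    """Frame rate maximizing SNR(x) = (1 - A1 x^b1) / (A2 x^b2).

    The stationary point has the closed form
    ``x* = (b2 / (A1 * (b2 - b1))) ** (1 / b1)``; it is returned when it
    lies inside ``rate_range`` (a dense log-grid search is used as a
    cross-check and for ranges without an interior maximum, in which case
    the better boundary is returned with a warning).
    """
    A1, b1 = signal_fit.A, signal_fit.b
    A2, b2 = noise_fit.A, noise_fit.b
    if not (b2 > 0 > b1):
        raise ValueError("expect a positive noise exponent and negative signal exponent")
    lo, hi = rate_range
    grid = np.geomspace(lo, hi, n_grid)
    snr = (1.0 - A1 * grid ** b1) / (A2 * grid ** b2)
    x_grid = float(grid[int(np.argmax(snr))])
    x_star = (b2 / (A1 * (b2 - b1))) ** (1.0 / b1)
    if lo <= x_star <= hi and (1.0 - A1 * x_star ** b1) > 0:
        return float(x_star)
    warnings.warn("no interior SNR maximum in the requested range; returning boundary")
    return x_grid


# ---------------------------------------------------------------------------
# aliasing model

def _alias_integrals(s: float, rtol: float = 1e-9) -> tuple[float, float]:
    """(aliased, total) power integrals in units of u = f * tau.

    Integrand: Lorentzian 1/(1 + (2 pi u)^2) times the squared frequency
    response sinc^2(u / s) of a full-period integrator, with s = rate*tau
    samples per time constant. Integrated piecewise between the sinc zeros
    (u = j*s) so the oscillatory tail converges cleanly; the remainder
    beyond the last piece is bounded analytically with the half-mean of
    sin^2.
    """

    def g(u: float) -> float:
        return np.sinc(u / s) ** 2 / (1.0 + (2.0 * np.pi * u) ** 2)

    def piece(a: float, b: float) -> float:
        val, _ = integrate.quad(g, a, b, limit=200)
        return val

    u_nyq = s / 2.0
    total = piece(0.0, u_nyq)
    aliased = 0.0
    a = u_nyq
    b = s  # first sinc zero
    j = 1
    while True:
        seg = piece(a, b)
        aliased += seg
        a, b = b, b + s
        j += 1
        if seg < rtol * (total + aliased) and j > 3:
            break
        if j > 10_000:  # pragma: no cover - safety net
            break
    # analytic tail bound: sinc^2 ~ (s/(pi u))^2 * sin^2, <sin^2> = 1/2
    tail = (s ** 2) / (8.0 * np.pi ** 4) / (3.0 * a ** 3)
    aliased += tail
    total += aliased
    return aliased, total


def aliased_power_fraction(tau: float, frame_rate: float) -> float:
    """Fraction of sampled signal power folded above the Nyquist frequency.

    The optical signal is modelled as a decaying exponential with time
    constant ``tau`` (Lorentzian power spectrum) sampled by integrating
    over the whole frame period. Depends only on the product
    ``frame_rate * tau``; strictly decreasing in the frame rate.
    """
    if tau <= 0 or frame_rate <= 0:
        raise ValueError("tau and frame_rate must be positive")
    aliased, total = _alias_integrals(frame_rate * tau)
    return aliased / total


def _severe_fraction() -> float:
    aliased, total = _alias_integrals(2.0)  # sampling period = tau/2
    return aliased / total


SEVERE_ALIASING_FRACTION = _severe_fraction()


class AliasFreeRate(NamedTuple):
    rate_hz: int
    aliased_fraction: float


def min_alias_free_rate(tau: float) -> AliasFreeRate:
    """Minimum frame rate avoiding severe aliasing: the half-tau rule.

    Severe aliasing sets in when the sampling period exceeds about half
    the indicator decay constant, so the rule of thumb is 2/tau, rounded
    to the nearest integer Hz (12 ms -> 167 Hz). The aliased power
    fraction remaining at that rate is returned alongside.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rate = 2.0 / tau
    return AliasFreeRate(int(round(rate)), aliased_power_fraction(tau, rate))


def noise_scaling_exponent(
    values: np.ndarray,
    base_rate: float,
    factors: Sequence[int] = DEFAULT_FACTORS,
) -> PowerLawFit:
    """Exponent of noise SD versus effective rate for a signal-free trace.

    Downsamples by block averaging at each factor (all phases, all
    samples), fits log(SD) against log(effective rate) and returns the
    fit; for independent shot noise the exponent is 0.5.
    """
    values = np.asarray(values, dtype=np.float64)
    x, y = [], []
    for n in sorted(set(int(f) for f in factors)):
        sds = [np.std(ds, ddof=1) for ds in phase_downsample(values, n)]
        x.append(base_rate / n)
        y.append(float(np.mean(sds)))
    return _loglog_fit(np.asarray(x), np.asarray(y), "noise")
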