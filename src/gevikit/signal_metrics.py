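"""Signal size, noise, SNR and photon-budget metrics for ROI traces.

All amplitude rules operate on the native negative-going ("raw") trace
convention and report magnitudes as positive percentages:

* long depolarization -- 5th percentile of the trace during the stimulus
  period, referenced to the median of the previous 10 time points;
* first spike of a train -- extreme value in the 50 ms after the stimulus,
  referenced to the median of the preceding 10 time points;
* subsequent spikes -- extreme of the 50 ms following the stimulus,
  referenced to the *extreme* (not median) of the 20 ms before it.

The first-spike and later-spike baselines deliberately differ (median of a
fixed point count versus extremum of a fixed time span): the later spikes
of a train ride on the decaying tail of their predecessors, where a median
is a biased baseline. Noise is the standard deviation of exactly the 20
samples preceding the stimulus.

Shot-noise bookkeeping: a fractional change dF/F measured against n
detected photons has SNR = (dF/F) * sqrt(n), so 10,000 photons are needed
for a 1 % signal to reach SNR 1. Background fluorescence occupying a
fraction f_b of the collected light dilutes the signal to (1-f_b) * dF/F
and, at fixed total photon count, scales the SNR by sqrt(1-f_b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dff_core import FluorTrace

__all__ = [
    "SnrReport",
    "signal_amplitude",
    "noise_level",
    "snr_report",
    "photon_budget",
    "background_degradation",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SnrReport:
    """Signal/noise/SNR summary for one cell and stimulus, Table-style."""

    signal_pct: float
    noise_pct: float
    snr: float
    bleach_rate_pct_s: float | None
    bleach_corrected_snr: float | None
    stimulus_kind: str
    trial_count: int = 1
    correction_convention: str = "snr_per_sqrt_pct_per_s"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.noise_pct > 0:
            raise ValueError("noise must be positive")
        if abs(self.snr - self.signal_pct / self.noise_pct) > 1e-9 * max(1.0, self.snr):
            raise ValueError("snr must equal signal/noise")

    def to_dict(self) -> dict:
        return {
            "signal_pct": self.signal_pct,
            "noise_pct": self.noise_pct,
            "snr": self.snr,
            "bleach_rate_pct_s": self.bleach_rate_pct_s,
            "bleach_corrected_snr": self.bleach_corrected_snr,
            "stimulus_kind": self.stimulus_kind,
            "trial_count": self.trial_count,
            "correction_convention": self.correction_convention,
            **self.extra,
        }


def signal_amplitude(
    trace: FluorTrace,
    onset_frame: int,
    kind: str,
    stim_duration_s: float | None = None,
    spike_index: int = 0,
    spike_window_s: float = 0.05,
) -> float:
    """Stimulus-evoked signal size in % dF/F (positive magnitude).

    Parameters
    ----------
    trace
        ROI-mean fluorescence trace (either convention; converted to raw
        internally).
    onset_frame
        Frame index of stimulus onset.
    kind
        ``"long_depol"`` or ``"spike"``.
    stim_duration_s
        Required for ``"long_depol"``: length of the depolarizing step.
    spike_index
        Position of the spike within its train; index 0 uses the
        median-baseline rule, later spikes the extremum-baseline rule.
    """
    v = trace.to_raw().values
    rate = trace.rate
    n = len(v)
    if kind == "long_depol":
        if stim_duration_s is None:
            raise ValueError("stim_duration_s required for long_depol amplitude")
        if onset_frame < 10:
            raise ValueError("need at least 10 pre-stimulus frames, got "
                             f"{onset_frame}")
        n_stim = max(1, _round_half_up(stim_duration_s * rate))
        if onset_frame + n_stim > n:
            raise ValueError("stimulus window extends past end of trace")
        stim = v[onset_frame:onset_frame + n_stim]
        base = float(np.median(v[onset_frame - 10:onset_frame]))
        amp = base - float(np.percentile(stim, 5))
    elif kind == "spike":
        n_win = max(1, _round_half_up(spike_window_s * rate))
        if onset_frame + n_win > n:
            raise ValueError("spike window extends past end of trace")
        win = v[onset_frame:onset_frame + n_win]
        if spike_index == 0:
            if onset_frame < 10:
                raise ValueError("need at least 10 pre-stimulus frames, got "
                                 f"{onset_frame}")
            base = float(np.median(v[onset_frame - 10:onset_frame]))
        else:
            n_pre = max(1, _round_half_up(0.020 * rate))
            if onset_frame < n_pre:
                raise ValueError(f"need at least {n_pre} pre-stimulus frames "
                                 f"(20 ms), got {onset_frame}")
            base = float(np.max(v[onset_frame - n_pre:onset_frame]))
        amp = base - float(np.min(win))
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return 100.0 * amp


def noise_level(trace: FluorTrace, onset_frame: int) -> float:
    """SD of the 20 samples immediately preceding the stimulus, in %."""
    if onset_frame < 20:
        raise ValueError(f"need at least 20 pre-stimulus frames, got {onset_frame}")
    seg = trace.values[onset_frame - 20:onset_frame]
    return 100.0 * float(np.std(seg, ddof=1))


def snr_report(
    trace: FluorTrace,
    onset_frame: int,
    kind: str,
    bleach_rate_pct_s: float | None = None,
    stim_duration_s: float | None = None,
    spike_index: int = 0,
    trial_count: int = 1,
    convention: str = "sqrt",
) -> SnrReport:
    """Assemble signal, noise, SNR and bleach-corrected SNR for one stimulus.

    ``convention="sqrt"`` normalizes as SNR / sqrt(bleach rate in %/s):
    under shot noise, SNR scales with the square root of the illumination
    intensity while the bleach rate scales linearly with it, so dividing
    by sqrt(rate) removes the illumination dependence. The alternative
    ``"linear"`` (SNR / rate) is selectable; the convention string is
    stored in every report. A non-positive bleach rate leaves the
    corrected field unavailable (None) rather than fabricated.
    """
    signal = signal_amplitude(trace, onset_frame, kind, stim_duration_s, spike_index)
    noise = noise_level(trace, onset_frame)
    snr = signal / noise
    if bleach_rate_pct_s is not None and bleach_rate_pct_s > 0:
        if convention == "sqrt":
            corrected = snr / math.sqrt(bleach_rate_pct_s)
            conv_str = "snr_per_sqrt_pct_per_s"
        elif convention == "linear":
            corrected = snr / bleach_rate_pct_s
            conv_str = "snr_per_pct_per_s"
        else:
            raise ValueError(f"unknown bleach-correction convention {convention!r}")
    else:
        corrected = None
        conv_str = f"unavailable ({convention})"
    return SnrReport(
        signal_pct=signal,
        noise_pct=noise,
        snr=snr,
        bleach_rate_pct_s=bleach_rate_pct_s,
        bleach_corrected_snr=corrected,
        stimulus_kind=kind,
        trial_count=trial_count,
        correction_convention=conv_str,
    )


def photon_budget(
    dff: float,
    photons: float | None = None,
    target_snr: float | None = None,
) -> float:
    """Shot-noise photon budget: SNR = dF/F * sqrt(n).

    Forward (``photons`` given): returns the SNR. Inverse (``target_snr``
    given): returns the photon count required, ``(target_snr / dff)**2``.
    """
    if (photons is None) == (target_snr is None):
        raise ValueError("give exactly one of photons or target_snr")
    if photons is not None:
        if photons < 0:
            raise ValueError("photon count must be non-negative")
        if dff <= 0:
            raise ValueError("dff must be positive")
        return dff * math.sqrt(photons)
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    if dff <= 0:
        raise ValueError("cannot invert the photon budget at dff = 0 "
                         "(infinite photons required)")
    return (target_snr / dff) ** 2


def background_degradation(
    f_b: float,
    snr0: float,
    dff0: float,
    convention: str = "sqrt",
) -> tuple[float, float]:
    """Signal and SNR degradation from non-signaling background fluorescence.

    A background fraction ``f_b`` dilutes the fractional change to
    ``(1 - f_b) * dff0``. Under shot noise at fixed total photon flux the
    SNR falls by ``sqrt(1 - f_b)`` (default); the linear convention
    ``(1 - f_b) * snr0`` is selectable for comparison with sources that
    quote it. Returns ``(degraded_dff, degraded_snr)``.
    """
    if not (0 <= f_b < 1):
        raise ValueError("f_b must be in [0, 1)")
    dff = (1.0 - f_b) * dff0
    if convention == "sqrt":
        snr = math.sqrt(1.0 - f_b) * snr0
    elif convention == "linear":
        snr = (1.0 - f_b) * snr0
    else:
        raise ValueError(f"unknown background convention {convention!r}")
    return dff, snr
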