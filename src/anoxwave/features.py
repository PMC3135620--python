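"""Quantitative signatures of a membrane-voltage trace.

The oxygen-glucose-deprivation trace has a characteristic anatomy: a slow
(convex) subthreshold depolarization, a ~7 s burst of action potentials of
rising frequency and collapsing amplitude, and a depolarized quiescent
plateau (depolarization block).  The functions here measure each piece:
spike times and instantaneous firing rate, the depolarization slope, the
excitation threshold read from the pre-spike baseline, and the post-block
voltages.

Everything is deterministic: given a trace and parameters the report is a
pure function of its input.  Times are in seconds, voltages in mV, rates
in Hz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "FeatureReport",
    "detect_spikes",
    "instantaneous_rate",
    "pre_spike_slope",
    "peak_depolarization_rate",
    "excitation_threshold",
    "mean_membrane_potential",
    "block_diagnostics",
    "analyze_trace",
]

#: spike detector defaults: upward crossing level (mV), dead time (ms) and
#: the minimum peak voltage for a deflection to count as an action
#: potential (the classic overshoot criterion).  The peak requirement
#: matters at the end of an anoxic burst, where the spike amplitude decays
#: to zero and bare threshold crossings would count damped subthreshold
#: oscillations as spikes.
SPIKE_THRESHOLD_MV = -30.0
SPIKE_REFRACTORY_MS = 1.0
SPIKE_MIN_PEAK_MV = 0.0


@dataclass
class FeatureReport:
    """Summary measures of one trace.  Fields are ``None`` when the trace
    has no spikes (rather than fabricating values)."""

    spike_times: list
    onset_time: Optional[float]
    last_spike_time: Optional[float]
    oscillation_duration: Optional[float]
    initial_rate: Optional[float]
    max_rate: Optional[float]
    pre_spike_slope: Optional[float]
    peak_depolarization_rate: Optional[float]
    excitation_threshold: Optional[float]
    mean_V_after_block: Optional[float]
    V_final: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _as_arrays(t, v):
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("t and v must be 1-D arrays of equal length")
    return t, v


def detect_spikes(t, v, threshold: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = SPIKE_REFRACTORY_MS,
                  min_peak: Optional[float] = SPIKE_MIN_PEAK_MV) -> np.ndarray:
    """Action-potential times: upward crossings of ``threshold`` separated
    by at least ``refractory_ms``, whose subsequent peak reaches
    ``min_peak``.

    Pass ``min_peak=None`` to count every threshold crossing regardless of
    amplitude.  Emits a warning when the sampling is too coarse to resolve
    the spike waveform (estimated width < 3 samples).
    """
    t, v = _as_arrays(t, v)
    idx = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    if idx.size == 0:
        return np.array([])

    # estimated spike width: consecutive samples above threshold per event
    above = v >= threshold
    widths = []
    for i in idx[: min(idx.size, 50)]:
        j = i + 1
        while j < above.size and above[j]:
            j += 1
        widths.append(j - (i + 1))
    if np.median(widths) < 3:
        warnings.warn(
            "sampling too coarse to resolve spike waveforms "
            f"(median width {np.median(widths):.0f} samples); spike times and "
            "peak amplitudes may be unreliable",
            stacklevel=2,
        )

    bounds = np.append(idx, v.size - 1)
    times = []
    last = -np.inf
    for k, i in enumerate(idx):
        ti = t[i]
        if ti - last < refractory_ms / 1000.0:
            continue
        if min_peak is not None and v[i: bounds[k + 1] + 1].max() < min_peak:
            continue
        times.append(ti)
        last = ti
    return np.array(times)


def instantaneous_rate(spike_times) -> tuple[np.ndarray, np.ndarray]:
    """Reciprocal interspike intervals (Hz), stamped at interval midpoints.

    Fewer than two spikes yields empty arrays.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        return np.array([]), np.array([])
    isi = np.diff(st)
    return st[:-1] + isi / 2.0, 1.0 / isi


def mean_membrane_potential(t, v, window: float = 0.3) -> np.ndarray:
    """Centered moving average with a flat (boxcar) window of ``window`` s.

    Requires a uniform time grid.  At the trace ends the window is
    truncated to the available samples (no padding), so a constant input is
    returned unchanged.
    """
    t, v = _as_arrays(t, v)
    dt = np.diff(t)
    if dt.size == 0:
        return v.copy()
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("mean_membrane_potential requires a uniform time grid")
    w = int(round(window / dt[0]))
    if w < 1:
        raise ValueError(
            f"window ({window} s) must exceed the sample spacing ({dt[0]:.3g} s)"
        )
    cs = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def pre_spike_slope(t, v, onset_time: float) -> float:
    """Least-squares slope (mV/s) of the voltage over ``[0, onset - 1 s]``.

    This is the average rate of rise of the whole subthreshold
    depolarization phase.  Because that phase is convex (the rise
    accelerates as the threshold nears), the average is substantially lower
    than the terminal rate of rise; see
    :func:`peak_depolarization_rate` for the latter.
    """
    t, v = _as_arrays(t, v)
    if onset_time <= 2.0:
        raise ValueError(f"onset must exceed 2 s, got {onset_time:.3g} s")
    t_hi = onset_time - 1.0
    if t_hi < 5.0:
        warnings.warn(
            f"pre-spike window is only {t_hi:.2f} s long; slope estimate may "
            "be unreliable", stacklevel=2,
        )
    sel = (t >= 0.0) & (t <= t_hi)
    return float(np.polyfit(t[sel], v[sel], 1)[0])


def peak_depolarization_rate(t, v, onset_time: float,
                             window: float = 0.3, fs: float = 100.0) -> float:
    """Maximum rate of rise (mV/s) of the smoothed subthreshold ramp.

    The voltage is resampled to ``fs``, smoothed with a ``window``-second
    boxcar, differentiated, and the maximum over ``[window, onset - 1 s]``
    taken (the half-window edge region is excluded).  On a convex ramp this
    is the rate of rise with which the membrane reaches the excitation
    threshold just before spiking starts.
    """
    t, v = _as_arrays(t, v)
    t_hi = onset_time - 1.0
    if t_hi <= 2 * window:
        raise ValueError("subthreshold window too short for a smoothed slope")
    grid = np.arange(0.0, t_hi, 1.0 / fs)
    smooth = mean_membrane_potential(grid, np.interp(grid, t, v), window)
    dvdt = np.gradient(smooth, grid)
    return float(dvdt[grid >= window].max())


def excitation_threshold(t, v, onset_time: float,
                         window: float = 0.3, gap: float = 0.05) -> float:
    """Membrane voltage (mV) at which spiking begins, read from the
    pre-spike baseline: the ``window``-averaged voltage in the window
    ending ``gap`` seconds before the first spike.

    Reading the baseline rather than the spike waveform makes the estimate
    invariant to spike amplitude.
    """
    t, v = _as_arrays(t, v)
    grid = np.arange(onset_time - gap - window, onset_time - gap, 1e-4)
    return float(np.interp(grid, t, v).mean())


def block_diagnostics(t, v, last_spike_time: Optional[float],
                      window: float = 0.3):
    """Voltages after the depolarization block.

    Returns ``(mean_V_after_block, V_final)``: the ``window``-averaged
    voltage one second after the last spike, and the voltage at the end of
    the trace.  Without a detected last spike the plateau average is
    ``None`` - absence is reported, not fabricated.
    """
    t, v = _as_arrays(t, v)
    v_final = float(v[-1])
    if last_spike_time is None:
        return None, v_final
    center = last_spike_time + 1.0
    grid = np.arange(center - window / 2, center + window / 2, 1e-4)
    return float(np.interp(grid, t, v).mean()), v_final


def analyze_trace(trace, threshold: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = SPIKE_REFRACTORY_MS,
                  min_peak: Optional[float] = SPIKE_MIN_PEAK_MV) -> FeatureReport:
    """Full feature report for a simulation trace."""
    t, v = trace.t, trace.V
    spikes = detect_spikes(t, v, threshold, refractory_ms, min_peak)
    if spikes.size == 0:
        return FeatureReport(
            spike_times=[], onset_time=None, last_spike_time=None,
            oscillation_duration=None, initial_rate=None, max_rate=None,
            pre_spike_slope=None, peak_depolarization_rate=None,
            excitation_threshold=None, mean_V_after_block=None,
            V_final=float(v[-1]),
        )
    onset, last = float(spikes[0]), float(spikes[-1])
    _, rates = instantaneous_rate(spikes)
    slope = float(pre_spike_slope(t, v, onset)) if onset > 2.0 else None
    try:
        peak_rate = peak_depolarization_rate(t, v, onset)
    except ValueError:
        peak_rate = None
    mean_after, v_final = block_diagnostics(t, v, last)
    return FeatureReport(
        spike_times=[float(s) for s in spikes],
        onset_time=onset,
        last_spike_time=last,
        oscillation_duration=last - onset,
        initial_rate=float(rates[0]) if rates.size else None,
        max_rate=float(rates.max()) if rates.size else None,
        pre_spike_slope=slope,
        peak_depolarization_rate=peak_rate,
        excitation_threshold=float(excitation_threshold(t, v, onset)),
        mean_V_after_block=mean_after,
        V_final=v_final,
    )
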