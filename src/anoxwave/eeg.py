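"""EEG forward model: population averaging and high-pass filtering.

During anoxia synaptic transmission has failed, so a cortical population
behaves as an ensemble of identical, uncoupled neurons whose anoxic
depolarizations are spread over a few hundred milliseconds.  The raw EEG is
then proportional to the ensemble-mean membrane potential, i.e. the
single-cell voltage convolved with the onset-jitter distribution (a flat
300 ms window by default).  A recording amplifier's high-pass filter (0.1 Hz
Butterworth) turns the step-like anoxic depolarization into a single slow
transient - the wave seen on the EEG about half a minute after circulatory
arrest.

Both operations are linear; amplitudes of the filtered signal are reported
in arbitrary units (no dipole/volume-conduction calibration is attempted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .features import mean_membrane_potential
from .model import ModelParameters
from .protocols import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    SimulationTrace,
    find_resting_state,
    run_ogd,
    run_rest,
)

__all__ = [
    "EEGTrace",
    "population_average",
    "highpass_filter",
    "simulate_wave",
    "wave_support",
]

#: sampling rate used to resolve spikes before averaging (Hz)
RAW_FS = 10_000.0
#: decimated rate at which the 0.1 Hz filter is applied (Hz); a 0.1 Hz
#: corner at 10 kHz would put the filter poles pathologically close to z=1
FILTER_FS = 200.0


@dataclass
class EEGTrace:
    """Simulated EEG on a uniform grid: the population-averaged membrane
    potential (``raw_eeg``, mV) and its high-pass-filtered version
    (``filtered_eeg``, arbitrary units)."""

    t: np.ndarray
    raw_eeg: np.ndarray
    filtered_eeg: np.ndarray
    filter_spec: dict = field(default_factory=dict)

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame({
            "t_s": self.t,
            "raw_eeg_mV": self.raw_eeg,
            "filtered_eeg_au": self.filtered_eeg,
        }).to_csv(path, index=False, float_format="%.10g", encoding="utf-8")
        if sidecar:
            path.with_suffix(".meta.json").write_text(
                json.dumps(self.filter_spec, indent=2, sort_keys=True),
                encoding="utf-8",
            )


def population_average(trace: SimulationTrace, jitter_width: float = 0.3,
                       fs: float = RAW_FS):
    """Ensemble-mean membrane potential of identical neurons whose onset
    times are uniformly spread over ``jitter_width`` seconds.

    Equals the single-cell voltage convolved with a normalized boxcar, i.e.
    the same centered moving average used for trace smoothing.  Returns
    ``(t, raw_eeg)`` on a uniform ``fs`` grid.
    """
    if jitter_width <= 0:
        raise ValueError("jitter_width must be positive")
    t = np.arange(trace.t[0], trace.t[-1], 1.0 / fs)
    v = trace.sample_voltage(t)
    return t, mean_membrane_potential(t, v, jitter_width)


def highpass_filter(x, fs: float, cutoff: float = 0.1, order: int = 2) -> np.ndarray:
    """Causal Butterworth high-pass, applied once in the forward direction
    (as a recording amplifier would).

    The filter state is initialized for a constant input at ``x[0]``, so a
    stationary signal produces no spurious startup transient.
    """
    if cutoff >= fs / 2:
        raise ValueError(
            f"cutoff ({cutoff} Hz) must be below the Nyquist frequency ({fs / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def _decimate(x, fs_in: float, fs_out: float):
    q = int(round(fs_in / fs_out))
    if abs(fs_in / fs_out - q) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    # linear-extrapolation padding: zero padding would inject an edge step
    # that the high-pass filter turns into a large spurious transient
    return signal.resample_poly(x, 1, q, padtype="line")


def simulate_wave(p: Optional[ModelParameters] = None, *,
                  trace: Optional[SimulationTrace] = None,
                  t_end: float = 60.0,
                  jitter_width: float = 0.3,
                  cutoff: float = 0.1, order: int = 2,
                  ogd: bool = True,
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> EEGTrace:
    """End-to-end EEG wave: resting state -> OGD run -> population average
    -> high-pass filter.

    A precomputed ``trace`` may be supplied to skip the simulation.  With
    ``ogd=False`` the neuron keeps its homeostasis and the filtered EEG
    stays flat - the wave is specific to the anoxic depolarization.
    """
    if trace is None:
        p = p or ModelParameters()
        x0 = find_resting_state(p)
        runner = run_ogd if ogd else run_rest
        trace = runner(p, x0, t_end, rtol=rtol, atol=atol)
    t_raw, raw = population_average(trace, jitter_width, fs=RAW_FS)
    dec = _decimate(raw, RAW_FS, FILTER_FS)
    t = t_raw[0] + np.arange(dec.size) / FILTER_FS
    filtered = highpass_filter(dec, FILTER_FS, cutoff, order)
    return EEGTrace(
        t=t, raw_eeg=dec, filtered_eeg=filtered,
        filter_spec={"design": "butterworth-highpass", "cutoff_hz": cutoff,
                     "order": order, "fs_hz": FILTER_FS,
                     "jitter_width_s": jitter_width, "causal": True},
    )


def wave_support(t, x, frac: float = 0.1, min_gap: float = 2.0):
    """Contiguous intervals where ``|x|`` exceeds ``frac`` of its maximum.

    Intervals separated by gaps shorter than ``min_gap`` seconds are merged:
    a biphasic wave passes through zero, and sample-level contiguity would
    split one physiological transient at each zero crossing.  The default
    gap equals the timescale of the fast terminal depolarization (~2 s), so
    ripple during the spike burst and the main deflection it feeds count as
    one event.  Returns a list of ``(t_start, t_end)`` pairs.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    level = frac * np.abs(x).max()
    above = np.abs(x) > level
    if not above.any():
        return []
    idx = np.where(above)[0]
    intervals = []
    start = prev = idx[0]
    for i in idx[1:]:
        if t[i] - t[prev] > min_gap:
            intervals.append((t[start], t[prev]))
            start = i
        prev = i
    intervals.append((t[start], t[prev]))
    return intervals
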