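"""Simulation protocols: resting state, current injection, oxygen-glucose deprivation.

All public time arguments and trace time stamps are in seconds; the
integrator works in milliseconds internally (Hodgkin-Huxley convention).
The system is stiff - millisecond action potentials ride on minutes of
concentration drift - so integration uses an adaptive stiff-capable solver
(LSODA by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import ConvergenceError, InvalidParameterError, SolverError
from .model import (
    STATE_FIELDS,
    ModelParameters,
    NeuronState,
    _rhs,
    _unpack_params,
    nernst_potential,
    steady_state_gating,
)

__all__ = [
    "SimulationTrace",
    "InjectionProtocol",
    "find_resting_state",
    "run_rest",
    "run_injection",
    "run_ogd",
    "find_rheobase",
    "load_trace_csv",
]

logger = logging.getLogger(__name__)

_MS = 1000.0
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: sampling rate (Hz) of the fine grid around the spiking window
FINE_FS = 10_000.0
#: sampling rate (Hz) of the coarse grid elsewhere
COARSE_FS = 100.0

#: seed used to start the relaxation towards the physiological fixed point
_PHYSIOLOGICAL_SEED = dict(
    V=-68.0, Na_i=20.0, Na_o=144.0, K_i=139.0, K_o=3.8, Cl_i=6.0, Cl_o=130.0
)

_CSV_COLUMNS = ["t_s", "V_mV", "h", "n", "Na_i", "Na_o", "K_i", "K_o",
                "Cl_i", "Cl_o", "E_Na", "E_K", "E_Cl"]


@dataclass
class SimulationTrace:
    """Time-stamped record of a simulation.

    ``t`` is in seconds and strictly increasing; ``y`` has one row per
    sample in the packed state order (V, h, n, Na_i, Na_o, K_i, K_o, Cl_i,
    Cl_o).  The first sample equals the supplied initial state.
    """

    t: np.ndarray
    y: np.ndarray
    mode: str
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.t.size, len(STATE_FIELDS)):
            raise ValueError(
                f"trace shape mismatch: t has {self.t.size} samples, "
                f"y has shape {self.y.shape}"
            )
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time stamps must be strictly increasing")

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    def column(self, name: str) -> np.ndarray:
        return self.y[:, STATE_FIELDS.index(name)]

    def state(self, i: int) -> NeuronState:
        return NeuronState.from_array(self.y[i])

    @property
    def final_state(self) -> NeuronState:
        return self.state(-1)

    def sample_voltage(self, t_s: np.ndarray) -> np.ndarray:
        """Membrane voltage linearly interpolated at the given times (s)."""
        return np.interp(t_s, self.t, self.V)

    def nernst_potentials(self, p: ModelParameters) -> dict:
        return {
            "E_Na": np.array([nernst_potential(1, a, b, p.T, "Na")
                              for a, b in zip(self.column("Na_i"), self.column("Na_o"))]),
            "E_K": np.array([nernst_potential(1, a, b, p.T, "K")
                             for a, b in zip(self.column("K_i"), self.column("K_o"))]),
            "E_Cl": np.array([nernst_potential(-1, a, b, p.T, "Cl")
                              for a, b in zip(self.column("Cl_i"), self.column("Cl_o"))]),
        }

    def to_csv(self, path, p: Optional[ModelParameters] = None,
               sidecar: bool = True) -> None:
        """Write the trace as CSV ('.' decimal, UTF-8) plus a JSON sidecar.

        Nernst potential columns are computed from the concentrations using
        ``p`` (defaults to the standard parameter set).
        """
        path = Path(path)
        p = p or ModelParameters()
        df = pd.DataFrame({"t_s": self.t})
        for i, name in enumerate(STATE_FIELDS):
            col = "V_mV" if name == "V" else name
            df[col] = self.y[:, i]
        for name, values in self.nernst_potentials(p).items():
            df[name] = values
        df = df[_CSV_COLUMNS]
        df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")
        if sidecar:
            meta = {"mode": self.mode, **self.solver_meta}
            path.with_suffix(".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
            )


def load_trace_csv(path) -> SimulationTrace:
    """Read back a trace written by :meth:`SimulationTrace.to_csv`."""
    df = pd.read_csv(path)
    y = np.column_stack(
        [df["V_mV" if name == "V" else name].to_numpy() for name in STATE_FIELDS]
    )
    meta_path = Path(path).with_suffix(".meta.json")
    meta = {}
    mode = "unknown"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        mode = meta.pop("mode", "unknown")
    return SimulationTrace(t=df["t_s"].to_numpy(), y=y, mode=mode, solver_meta=meta)


@dataclass
class InjectionProtocol:
    """A rectangular current pulse delivered through an electrode.

    ``amplitude`` in uA/cm2 (positive = depolarizing), ``onset`` and
    ``duration`` in seconds.
    """

    amplitude: float
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError(
                f"injection duration must be positive, got {self.duration!r}"
            )
        if self.onset < 0:
            raise InvalidParameterError(
                f"injection onset must be non-negative, got {self.onset!r}"
            )


def _solve(p, y0, t_span_ms, ogd, rtol, atol, method="LSODA",
           dense=True, inject_uA=0.0):
    pv = _unpack_params(p)
    if inject_uA:
        def fun(t, y):
            d = list(_rhs(t, y, pv, ogd))
            d[0] += inject_uA / p.C_m
            return d
    else:
        def fun(t, y):
            return _rhs(t, y, pv, ogd)
    sol = solve_ivp(fun, t_span_ms, y0, method=method, rtol=rtol, atol=atol,
                    dense_output=dense)
    if not sol.success:
        raise SolverError(
            f"ODE solver failed: {sol.message}",
            last_state=NeuronState.from_array(sol.y[:, -1]) if sol.y.size else None,
            last_time_s=float(sol.t[-1]) / _MS if sol.t.size else None,
        )
    return sol


def _meta(sol, rtol, atol, method="LSODA", **extra) -> dict:
    return {
        "method": method, "rtol": rtol, "atol": atol,
        "nfev": int(sol.nfev), "njev": int(sol.njev), "nlu": int(sol.nlu),
        "n_steps": int(sol.t.size), **extra,
    }


def _seed_state(V: float = -68.0) -> NeuronState:
    _, h_inf, n_inf = steady_state_gating(V)
    return NeuronState(V=V, h=h_inf, n=n_inf, **{
        k: v for k, v in _PHYSIOLOGICAL_SEED.items() if k != "V"
    })


def find_resting_state(p: ModelParameters,
                       relax_time: float = 2000.0,
                       tol: float = 1e-9) -> NeuronState:
    """Physiological fixed point of the model (all derivatives ~ 0).

    A long relaxation from a physiological seed brings the system close to
    the stable resting state; a damped Newton iteration then polishes the
    residual.  The polish works in the reduced coordinates
    (V, h, n, Na_i, K_i, K_o): total sodium is conserved and chloride is
    clamped under physiological conditions, so the full 9-dimensional
    Jacobian is singular by construction.

    Parameters
    ----------
    relax_time : float
        Relaxation horizon in seconds of simulated time.
    tol : float
        Acceptance threshold on the largest right-hand-side component
        (per-ms units: mV/ms and mM/ms).

    Raises
    ------
    ConvergenceError
        If the residual norm cannot be brought below ``tol``; carries the
        final norm.
    """
    seed = _seed_state()
    sol = _solve(p, seed.to_array(), (0.0, relax_time * _MS), ogd=False,
                 rtol=1e-10, atol=1e-12, dense=False)
    y = sol.y[:, -1].copy()

    pv = _unpack_params(p)
    na_total = y[3] + y[4] / p.beta  # conserved: Na_i + Na_o/beta
    reduced_idx = [0, 1, 2, 3, 5, 6]  # V, h, n, Na_i, K_i, K_o

    def residual(r):
        full = y.copy()
        full[reduced_idx] = r
        full[4] = (na_total - full[3]) * p.beta  # Na_o from conservation
        d = np.asarray(_rhs(0.0, full, pv, False))
        return d[reduced_idx], full

    r = y[reduced_idx].copy()
    f, full = residual(r)
    norm = np.max(np.abs(f))
    for _ in range(60):
        if norm < tol * 1e-3:  # polish well below the acceptance threshold
            break
        # finite-difference Jacobian of the reduced residual
        J = np.empty((len(r), len(r)))
        for j in range(len(r)):
            step = 1e-7 * max(1.0, abs(r[j]))
            rp = r.copy(); rp[j] += step
            fp, _ = residual(rp)
            J[:, j] = (fp - f) / step
        try:
            delta = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            break
        lam, improved = 1.0, False
        for _ in range(20):
            rn = r + lam * delta
            fn, fulln = residual(rn)
            if np.max(np.abs(fn)) < norm:
                r, f, full, norm = rn, fn, fulln, np.max(np.abs(fn))
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    if norm >= tol:
        raise ConvergenceError(
            f"resting-state search did not converge: max |dstate/dt| = {norm:.3e} "
            f"(tolerance {tol:.1e}) after {relax_time} s of relaxation",
            residual_norm=float(norm),
        )
    state = NeuronState.from_array(full)
    state.validate()
    logger.info("resting state: V = %.3f mV (residual %.2e)", state.V, norm)
    return state


def _grid_with_fine_window(t_end_ms, t_steps_ms, V_steps,
                           spike_level=-30.0, pad_ms=2000.0):
    """Piecewise-uniform output grid: coarse everywhere, fine where it spikes.

    The solver's own (adaptive) steps are used to locate the window in which
    the voltage crosses the spike level; that window, padded, is sampled at
    ``FINE_FS`` and the remainder at ``COARSE_FS``.
    """
    coarse = np.arange(0.0, t_end_ms, _MS / COARSE_FS)
    crossings = np.where((V_steps[:-1] < spike_level) & (V_steps[1:] >= spike_level))[0]
    if crossings.size == 0:
        return np.append(coarse, t_end_ms)
    w0 = max(0.0, t_steps_ms[crossings[0]] - pad_ms)
    w1 = min(t_end_ms, t_steps_ms[crossings[-1]] + pad_ms)
    fine = np.arange(w0, w1, _MS / FINE_FS)
    grid = np.union1d(coarse, fine)
    return np.append(grid[grid < t_end_ms], t_end_ms)


def run_ogd(p: ModelParameters, x0: NeuronState, t_end: float,
            rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> SimulationTrace:
    """Oxygen-glucose deprivation from ``t = 0``: pump, glial buffering and
    blood diffusion off, chloride free.

    ``t_end`` is in seconds; use >= 60 s to capture the depolarization wave
    and >= 600 s for the final voltage asymptote.  The returned trace is
    sampled at 10 kHz in a 2 s-padded window around the spike burst and at
    100 Hz elsewhere.
    """
    x0.validate()
    sol = _solve(p, x0.to_array(), (0.0, t_end * _MS), ogd=True,
                 rtol=rtol, atol=atol, dense=True)
    grid_ms = _grid_with_fine_window(t_end * _MS, sol.t, sol.y[0])
    y = sol.sol(grid_ms).T
    y[0] = x0.to_array()  # the first sample is the supplied initial state
    return SimulationTrace(
        t=grid_ms / _MS, y=y, mode="ogd",
        solver_meta=_meta(sol, rtol, atol, t_end_s=t_end),
    )


def run_rest(p: ModelParameters, x0: NeuronState, t_end: float,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> SimulationTrace:
    """Physiological (homeostasis intact) run, sampled like :func:`run_ogd`."""
    x0.validate()
    sol = _solve(p, x0.to_array(), (0.0, t_end * _MS), ogd=False,
                 rtol=rtol, atol=atol, dense=True)
    grid_ms = _grid_with_fine_window(t_end * _MS, sol.t, sol.y[0])
    y = sol.sol(grid_ms).T
    y[0] = x0.to_array()
    return SimulationTrace(
        t=grid_ms / _MS, y=y, mode="rest",
        solver_meta=_meta(sol, rtol, atol, t_end_s=t_end),
    )


def run_injection(p: ModelParameters, x0: NeuronState, proto: InjectionProtocol,
                  t_end: float, mode: str = "physiological",
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  fs: float = FINE_FS) -> SimulationTrace:
    """Current-injection protocol: a rectangular electrode current is added
    to the voltage equation during ``[onset, onset + duration]``.

    The electrode current does not enter the concentration equations (ion
    species carried by the electrode are not modelled).  Set
    ``mode='ogd'`` to stimulate a neuron whose homeostasis has failed, e.g.
    to probe excitability after depolarization block.  The trace is sampled
    uniformly at ``fs``.
    """
    x0.validate()
    if mode not in ("physiological", "ogd"):
        raise ValueError(f"mode must be 'physiological' or 'ogd', got {mode!r}")
    ogd = mode == "ogd"
    edges_ms = sorted({0.0, proto.onset * _MS,
                       min((proto.onset + proto.duration) * _MS, t_end * _MS),
                       t_end * _MS})
    y0 = x0.to_array()
    ts, ys = [], []
    nfev = 0
    for a, b in zip(edges_ms[:-1], edges_ms[1:]):
        if b <= a:
            continue
        amp = proto.amplitude if proto.onset * _MS <= a < (proto.onset + proto.duration) * _MS else 0.0
        sol = _solve(p, y0, (a, b), ogd=ogd, rtol=rtol, atol=atol,
                     dense=True, inject_uA=amp)
        grid = np.arange(a, b, _MS / fs)
        if ts and grid.size and grid[0] <= ts[-1][-1]:
            grid = grid[1:]
        ts.append(grid)
        ys.append(sol.sol(grid).T)
        y0 = sol.y[:, -1]
        nfev += int(sol.nfev)
    t_ms = np.concatenate(ts + [[t_end * _MS]])
    y = np.vstack(ys + [y0[None, :]])
    y[0] = x0.to_array()
    return SimulationTrace(
        t=t_ms / _MS, y=y, mode="inject",
        solver_meta={"method": "LSODA", "rtol": rtol, "atol": atol,
                     "nfev": nfev, "t_end_s": t_end,
                     "amplitude_uA_per_cm2": proto.amplitude,
                     "onset_s": proto.onset, "duration_s": proto.duration},
    )


def find_rheobase(p: ModelParameters, x0: NeuronState,
                  lo: float = 0.0, hi: float = 10.0, tol: float = 0.1,
                  t_test: float = 3.0, min_spikes: int = 5) -> float:
    """Minimum sustained current (uA/cm2) that elicits repetitive firing,
    located by bisection to ``tol``.

    Firing is judged by at least ``min_spikes`` upward crossings of -30 mV
    during a ``t_test``-second step of current.
    """
    from .features import detect_spikes

    def fires(amp: float) -> bool:
        proto = InjectionProtocol(amplitude=amp, onset=0.1, duration=t_test)
        tr = run_injection(p, x0, proto, t_end=t_test + 0.2)
        return detect_spikes(tr.t, tr.V).size >= min_spikes

    if not fires(hi):
        raise ConvergenceError(
            f"no repetitive firing up to {hi} uA/cm2; cannot bracket rheobase"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
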