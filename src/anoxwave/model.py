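"""Single-neuron membrane and ion-concentration dynamics.

The model couples Hodgkin-Huxley sodium/potassium channel dynamics to the
intra- and extracellular concentrations of Na+, K+ and Cl-.  Two compartments
(intracellular, extracellular) exchange ions through the gated channels and
leaks; homeostasis is provided by an ATP-driven Na/K pump (3 Na+ out, 2 K+ in
per cycle), glial buffering of extracellular potassium, and diffusion of
potassium between the extracellular space and the blood.

Two right-hand-side variants are provided:

* :func:`rhs_physiological` - pump, glia and blood diffusion active, chloride
  concentrations clamped (homeostatic mechanism not modelled explicitly).
* :func:`rhs_ogd` - oxygen-glucose deprivation: pump, glial uptake and blood
  diffusion are all zero and chloride is free to redistribute, making the
  two-compartment system closed for every ion species.

Units follow the Hodgkin-Huxley convention: mV, ms, uA/cm2, mS/cm2, uF/cm2,
mM.  Rates quoted per second (pump turnover expressed through gamma, glial
buffering, diffusion) are converted to per-ms inside the right-hand sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.constants import e as _ELEMENTARY_CHARGE
from scipy.constants import k as _BOLTZMANN

from .exceptions import InvalidParameterError, InvalidStateError

__all__ = [
    "ModelParameters",
    "NeuronState",
    "FluxBreakdown",
    "thermal_voltage",
    "nernst_potential",
    "gating_rates",
    "steady_state_gating",
    "membrane_currents",
    "homeostasis_fluxes",
    "rhs_physiological",
    "rhs_ogd",
]

#: index order of the packed state vector used by the integrators
STATE_FIELDS = ("V", "h", "n", "Na_i", "Na_o", "K_i", "K_o", "Cl_i", "Cl_o")

_MS_PER_S = 1000.0


def thermal_voltage(temperature_K: float) -> float:
    """k_B*T/e in mV (about 26.7 mV at 310 K)."""
    return _MS_PER_S * _BOLTZMANN * temperature_K / _ELEMENTARY_CHARGE


@dataclass
class ModelParameters:
    """Biophysical constants of the neuron model.

    Defaults are the values used throughout: a mammalian pyramidal cell at
    body temperature with an intra/extracellular volume ratio of 2.

    Attributes
    ----------
    C_m : float
        Specific membrane capacitance, uF/cm2.
    g_Na, g_K : float
        Maximal conductance of the gated Na+/K+ channels, mS/cm2.
    g_NaL, g_KL, g_ClL : float
        Leak conductances, mS/cm2.
    phi : float
        Dimensionless multiplier on the gating rate functions (channel
        kinetics speed-up).
    gamma : float
        Conversion factor from membrane current density to rate of change
        of intracellular concentration, A/(F*V_i): mM/s per uA/cm2.
    beta : float
        Ratio of intracellular to extracellular volume (dimensionless).
    rho : float
        Maximal Na/K-pump current density, uA/cm2.
    G_glia : float
        Maximal glial buffering rate of extracellular K+, mM/s.
    eps : float
        Diffusion rate of extracellular K+ to/from the blood, 1/s.
    k_bath : float
        Potassium concentration in the blood, mM.
    T : float
        Absolute temperature, K.
    """

    C_m: float = 1.0
    g_Na: float = 100.0
    g_NaL: float = 0.0175
    g_K: float = 40.0
    g_KL: float = 0.05
    g_ClL: float = 0.05
    phi: float = 3.0
    gamma: float = 0.044
    beta: float = 2.0
    rho: float = 28.1
    G_glia: float = 66.0
    eps: float = 1.3
    k_bath: float = 4.0
    T: float = 310.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0.0:
                raise InvalidParameterError(
                    f"parameter {f.name} must be finite and strictly positive, "
                    f"got {value!r}"
                )

    @property
    def thermal_voltage_mV(self) -> float:
        return thermal_voltage(self.T)


@dataclass
class NeuronState:
    """Dynamical state: membrane voltage, gating fractions, ion concentrations.

    Voltages in mV, concentrations in mM.  ``h`` is the fraction of
    non-inactivated Na+ channels, ``n`` the fraction of activated K+
    channels; the Na+ activation ``m`` is not a state variable because it is
    taken to follow the voltage instantaneously.
    """

    V: float
    h: float
    n: float
    Na_i: float
    Na_o: float
    K_i: float
    K_o: float
    Cl_i: float
    Cl_o: float

    def validate(self) -> None:
        if not np.isfinite(self.V):
            raise InvalidStateError(f"membrane voltage must be finite, got {self.V!r}")
        for name in ("h", "n"):
            q = getattr(self, name)
            if not 0.0 <= q <= 1.0:
                raise InvalidStateError(
                    f"gating variable {name} must lie in [0, 1], got {q!r}"
                )
        for name in ("Na_i", "Na_o", "K_i", "K_o", "Cl_i", "Cl_o"):
            c = getattr(self, name)
            if not np.isfinite(c) or c <= 0.0:
                raise InvalidStateError(
                    f"concentration {name} must be strictly positive, got {c!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        if len(y) != len(STATE_FIELDS):
            raise InvalidStateError(
                f"state vector must have {len(STATE_FIELDS)} components, got {len(y)}"
            )
        return cls(*(float(v) for v in y))


@dataclass
class FluxBreakdown:
    """Per-evaluation decomposition of membrane currents and homeostasis fluxes.

    Currents are positive outward (uA/cm2); ``I_glia`` and ``I_diff`` are
    rates of change of extracellular K+ (mM/s), not electrical currents.
    """

    I_Na: float
    I_K: float
    I_Cl: float
    E_Na: float
    E_K: float
    E_Cl: float
    I_pump: float
    I_glia: float
    I_diff: float
    m_inf: float


def nernst_potential(z: int, c_in: float, c_out: float, T: float, ion: str = "ion") -> float:
    """Nernst (reversal) potential in mV for valence ``z``.

    E = (k_B*T / z*e) * ln(c_out / c_in)

    Parameters
    ----------
    z : int
        Ion valence, +1 (Na+, K+) or -1 (Cl-).
    c_in, c_out : float
        Intra- and extracellular concentrations, mM (strictly positive).
    T : float
        Absolute temperature, K.
    ion : str
        Name used in error messages.
    """
    if z not in (-1, 1):
        raise ValueError(f"valence must be +1 or -1, got {z}")
    if c_in <= 0.0 or c_out <= 0.0:
        raise InvalidStateError(
            f"non-positive concentration for {ion}: c_in={c_in!r}, c_out={c_out!r}"
        )
    return thermal_voltage(T) / z * math.log(c_out / c_in)


def _x_over_one_minus_exp_neg(x):
    """x / (1 - exp(-x)) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    # limit value 1 + x/2 near 0; -expm1(-x) is accurate for small |x|
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 + x / 2.0, safe / (-np.expm1(-safe)))
    return out if out.ndim else float(out)


def gating_rates(V):
    """Voltage-dependent opening/closing rates of the gating variables, 1/ms.

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.  Accepts
    scalars or arrays.  The removable singularities of the alpha_m and
    alpha_n forms are evaluated by their analytic limits.
    """
    V = np.asarray(V, dtype=float)
    alpha_m = _x_over_one_minus_exp_neg(0.1 * (V + 30.0))
    beta_m = 4.0 * np.exp(-(V + 55.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 44.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-0.1 * (V + 14.0)))
    alpha_n = 0.1 * _x_over_one_minus_exp_neg(0.1 * (V + 34.0))
    beta_n = 0.125 * np.exp(-(V + 44.0) / 80.0)
    if V.ndim == 0:
        return tuple(float(r) for r in (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n))
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_state_gating(V):
    """Voltage-clamp fixed points ``(m_inf, h_inf, n_inf)`` of the gates."""
    am, bm, ah, bh, an, bn = gating_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def membrane_currents(state: NeuronState, p: ModelParameters) -> FluxBreakdown:
    """All membrane currents, Nernst potentials and homeostasis fluxes.

    Currents are positive outward.  The gated sodium current uses the
    instantaneous activation m_inf(V)^3 together with the inactivation state
    ``h``; the gated potassium current uses n^4.
    """
    state.validate()
    E_Na = nernst_potential(1, state.Na_i, state.Na_o, p.T, "Na")
    E_K = nernst_potential(1, state.K_i, state.K_o, p.T, "K")
    E_Cl = nernst_potential(-1, state.Cl_i, state.Cl_o, p.T, "Cl")
    m_inf, _, _ = steady_state_gating(state.V)
    I_Na = (p.g_Na * m_inf**3 * state.h + p.g_NaL) * (state.V - E_Na)
    I_K = (p.g_K * state.n**4 + p.g_KL) * (state.V - E_K)
    I_Cl = p.g_ClL * (state.V - E_Cl)
    I_pump, I_glia, I_diff = homeostasis_fluxes(state, p)
    return FluxBreakdown(
        I_Na=I_Na, I_K=I_K, I_Cl=I_Cl,
        E_Na=E_Na, E_K=E_K, E_Cl=E_Cl,
        I_pump=I_pump, I_glia=I_glia, I_diff=I_diff,
        m_inf=m_inf,
    )


def homeostasis_fluxes(state: NeuronState, p: ModelParameters):
    """Na/K-pump current, glial K+ uptake and K+ diffusion to the blood.

    The pump current (uA/cm2) depends sigmoidally on intracellular Na+ and
    extracellular K+ and starves when either substrate is depleted.  Glial
    uptake (mM/s) saturates at ``G_glia`` for high extracellular K+;
    diffusion (mM/s) is linear in the gradient to the blood concentration.
    """
    I_pump = p.rho / (
        (1.0 + math.exp((25.0 - state.Na_i) / 3.0))
        * (1.0 + math.exp(5.5 - state.K_o))
    )
    I_glia = p.G_glia / (1.0 + math.exp((18.0 - state.K_o) / 2.5))
    I_diff = p.eps * (state.K_o - p.k_bath)
    return I_pump, I_glia, I_diff


def _unpack_params(p: ModelParameters):
    return (
        p.C_m, p.g_Na, p.g_NaL, p.g_K, p.g_KL, p.g_ClL, p.phi,
        p.gamma, p.beta, p.rho, p.G_glia, p.eps, p.k_bath,
        thermal_voltage(p.T),
    )


def _rhs(t, y, pv, ogd: bool):
    """Packed right-hand side, time in ms.  Not validated; used by solvers."""
    (C_m, g_Na, g_NaL, g_K, g_KL, g_ClL, phi,
     gamma, beta, rho, G_glia, eps, k_bath, VT) = pv
    V, h, n, Na_i, Na_o, K_i, K_o, Cl_i, Cl_o = y

    E_Na = VT * math.log(Na_o / Na_i)
    E_K = VT * math.log(K_o / K_i)
    E_Cl = -VT * math.log(Cl_o / Cl_i)

    x = 0.1 * (V + 30.0)
    alpha_m = 1.0 + x / 2.0 if abs(x) < 1e-7 else x / (-math.expm1(-x))
    beta_m = 4.0 * math.exp(-(V + 55.0) / 18.0)
    alpha_h = 0.07 * math.exp(-(V + 44.0) / 20.0)
    beta_h = 1.0 / (1.0 + math.exp(-0.1 * (V + 14.0)))
    xn = 0.1 * (V + 34.0)
    alpha_n = 0.1 * (1.0 + xn / 2.0) if abs(xn) < 1e-7 else 0.1 * xn / (-math.expm1(-xn))
    beta_n = 0.125 * math.exp(-(V + 44.0) / 80.0)
    m_inf = alpha_m / (alpha_m + beta_m)

    I_Na = (g_Na * m_inf**3 * h + g_NaL) * (V - E_Na)
    I_K = (g_K * n**4 + g_KL) * (V - E_K)
    I_Cl = g_ClL * (V - E_Cl)

    if ogd:
        I_pump = I_glia = I_diff = 0.0
    else:
        I_pump = rho / ((1.0 + math.exp((25.0 - Na_i) / 3.0))
                        * (1.0 + math.exp(5.5 - K_o)))
        I_glia = G_glia / (1.0 + math.exp((18.0 - K_o) / 2.5))
        I_diff = eps * (K_o - k_bath)

    dV = -(I_Na + I_K + I_Cl) / C_m
    dh = phi * (alpha_h * (1.0 - h) - beta_h * h)
    dn = phi * (alpha_n * (1.0 - n) - beta_n * n)

    # concentration fluxes are per second; time unit here is ms
    g = gamma / _MS_PER_S
    dNa_i = -g * I_Na - 3.0 * g * I_pump
    dNa_o = -beta * dNa_i
    dK_i = -g * I_K + 2.0 * g * I_pump
    dK_o = -beta * dK_i - (I_glia + I_diff) / _MS_PER_S
    if ogd:
        # outward (positive) chloride current carries Cl- inward
        dCl_i = g * I_Cl
        dCl_o = -beta * dCl_i
    else:
        dCl_i = dCl_o = 0.0

    return (dV, dh, dn, dNa_i, dNa_o, dK_i, dK_o, dCl_i, dCl_o)


def _rhs_validated(t_ms: float, state: NeuronState, p: ModelParameters, ogd: bool):
    state.validate()
    return np.array(_rhs(t_ms, state.to_array(), _unpack_params(p), ogd))


def rhs_physiological(t_ms: float, state: NeuronState, p: ModelParameters) -> np.ndarray:
    """Time derivative of the state under intact homeostasis (per ms).

    Chloride concentrations are held constant; extracellular potassium is
    buffered by glia and exchanged with the blood; the pump keeps the sodium
    and potassium gradients.  Total sodium (Na_i + Na_o/beta) is conserved.
    """
    return _rhs_validated(t_ms, state, p, ogd=False)


def rhs_ogd(t_ms: float, state: NeuronState, p: ModelParameters) -> np.ndarray:
    """Time derivative of the state under oxygen-glucose deprivation (per ms).

    Pump, glial buffering and blood diffusion are zero and chloride is
    released, so each ion species is conserved across the two compartments
    and the membrane charge balance gives
    gamma*C_m*dV = d(Na_i + K_i - Cl_i) (with the uF*mV -> uC conversion).
    """
    return _rhs_validated(t_ms, state, p, ogd=True)
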