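"""Independent re-implementation of the model equations, used as an oracle.

Written directly from the equation list in a deliberately different style
from the package (dict-based state, R/F instead of k_B/e for the thermal
voltage, no shared helpers) so that agreement is evidence of correctness
rather than of shared code.
"""

from math import exp, log

from scipy.constants import R, physical_constants

F = physical_constants["Faraday constant"][0]

KEYS = ("V", "h", "n", "Na_i", "Na_o", "K_i", "K_o", "Cl_i", "Cl_o")


def nernst_mV(z, inside, outside, T):
    return 1000.0 * R * T / (z * F) * log(outside / inside)


def _rate_alpha_m(V):
    u = V + 30.0
    if abs(u) < 1e-6:
        return 1.0 + 0.05 * u
    return 0.1 * u / (1.0 - exp(-0.1 * u))


def _rate_alpha_n(V):
    u = V + 34.0
    if abs(u) < 1e-6:
        return 0.1 + 0.005 * u
    return 0.01 * u / (1.0 - exp(-0.1 * u))


def derivatives(state: dict, p: dict, ogd: bool) -> dict:
    """d(state)/dt per millisecond, straight from the equations."""
    V = state["V"]
    ENa = nernst_mV(+1, state["Na_i"], state["Na_o"], p["T"])
    EK = nernst_mV(+1, state["K_i"], state["K_o"], p["T"])
    ECl = nernst_mV(-1, state["Cl_i"], state["Cl_o"], p["T"])

    a_m = _rate_alpha_m(V)
    b_m = 4.0 * exp(-(V + 55.0) / 18.0)
    a_h = 0.07 * exp(-(V + 44.0) / 20.0)
    b_h = 1.0 / (1.0 + exp(-0.1 * (V + 14.0)))
    a_n = _rate_alpha_n(V)
    b_n = 0.125 * exp(-(V + 44.0) / 80.0)
    m = a_m / (a_m + b_m)

    I_Na = p["g_Na"] * m ** 3 * state["h"] * (V - ENa) + p["g_NaL"] * (V - ENa)
    I_K = p["g_K"] * state["n"] ** 4 * (V - EK) + p["g_KL"] * (V - EK)
    I_Cl = p["g_ClL"] * (V - ECl)

    if ogd:
        pump = glia = diff = 0.0
    else:
        pump = p["rho"] / (
            (1.0 + exp((25.0 - state["Na_i"]) / 3.0))
            * (1.0 + exp(5.5 - state["K_o"]))
        )
        glia = p["G_glia"] / (1.0 + exp((18.0 - state["K_o"]) / 2.5))
        diff = p["eps"] * (state["K_o"] - p["k_bath"])

    out = {}
    out["V"] = -(I_Na + I_K + I_Cl) / p["C_m"]
    out["h"] = p["phi"] * (a_h * (1.0 - state["h"]) - b_h * state["h"])
    out["n"] = p["phi"] * (a_n * (1.0 - state["n"]) - b_n * state["n"])
    # concentration balance: gamma converts uA/cm2 to mM/s, hence /1000 per ms
    out["Na_i"] = (-p["gamma"] * I_Na - 3.0 * p["gamma"] * pump) / 1000.0
    out["Na_o"] = -p["beta"] * out["Na_i"]
    out["K_i"] = (-p["gamma"] * I_K + 2.0 * p["gamma"] * pump) / 1000.0
    out["K_o"] = -p["beta"] * out["K_i"] - (glia + diff) / 1000.0
    if ogd:
        out["Cl_i"] = p["gamma"] * I_Cl / 1000.0
        out["Cl_o"] = -p["beta"] * out["Cl_i"]
    else:
        out["Cl_i"] = 0.0
        out["Cl_o"] = 0.0
    return out


def derivatives_array(y, p: dict, ogd: bool):
    state = dict(zip(KEYS, y))
    d = derivatives(state, p, ogd)
    return [d[k] for k in KEYS]
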