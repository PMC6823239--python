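"""Physical constants and small helper formulas shared across modules.

Units follow instrument-log conventions throughout the package: areas in
cm^2, flow in umol air s^-1, CO2 mole fractions in umol mol^-1 (ppm), H2O
mole fractions in mmol mol^-1, pressure in kPa, temperature in degrees C.
"""

from __future__ import annotations

import math

import numpy as np

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.31446

#: Ratio of diffusivities of water vapour to CO2 in air. Used to convert
#: total conductance to water into total conductance to CO2. Standard
#: constant; override via function arguments where exposed.
DIFF_RATIO_H2O_CO2 = 1.6

#: Zero Celsius in Kelvin.
T0_KELVIN = 273.15


def saturation_vapor_pressure(t_celsius):
    """Saturation vapour pressure of water in kPa (Buck-type formula).

    e_s(T) = 0.61365 * exp(17.502 * T / (240.97 + T))

    This is the common instrument default; accurate to a fraction of a
    percent over the 0-50 degC range relevant to leaf cuvettes.
    """
    t = np.asarray(t_celsius, dtype=float)
    es = 0.61365 * np.exp(17.502 * t / (240.97 + t))
    if es.ndim == 0:
        return float(es)
    return es


def leaf_saturation_mole_fraction(t_leaf_celsius, pressure_kpa):
    """Water mole fraction (mmol mol^-1) of saturated air at leaf temperature.

    W_leaf = 1000 * e_s(T_leaf) / P, the humidity assumed inside the leaf
    when computing total conductance to water.
    """
    es = saturation_vapor_pressure(t_leaf_celsius)
    w = 1000.0 * np.asarray(es, dtype=float) / np.asarray(pressure_kpa, dtype=float)
    if w.ndim == 0:
        return float(w)
    return w


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + T0_KELVIN


def polyval(coefficients, x):
    """Evaluate a polynomial given coefficients in ascending order.

    ``coefficients[0]`` is the constant term, matching how empty-chamber
    models store their fit.
    """
    c = np.asarray(coefficients, dtype=float)
    result = np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), c)
    if np.ndim(x) == 0:
        return float(result)
    return result


def isclose(a: float, b: float, rel: float = 1e-9, abs_: float = 1e-12) -> bool:
    return math.isclose(a, b, rel_tol=rel, abs_tol=abs_)
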