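"""Farquhar-von Caemmerer-Berry (FvCB) C3 photosynthesis model and fitting.

Net assimilation is the minimum of a Rubisco-limited and an
RuBP-regeneration-limited rate, minus day respiration:

    Ac = Vcmax * (Ci - Gamma*) / (Ci + Km),     Km = Kc * (1 + O / Ko)
    Aj = J * (Ci - Gamma*) / (4 Ci + 8 Gamma*)
    A  = min(Ac, Aj) - Rd

with J the electron transport rate from a non-rectangular hyperbola in
incident light. Kinetic constants default to widely used 25 degC values
(Gamma* = 42.75 umol mol-1, Kc = 404.9 umol mol-1, Ko = 278.4 mmol mol-1,
O = 210 mmol mol-1, theta = 0.85, alpha = 0.24); no temperature scaling is
applied -- all quantities refer to measurements at 25 degC.

Fitting minimises the sum of squared A residuals over (Vcmax, Jmax) with Rd
either fixed at an independently measured value (the recommended workflow)
or estimated as a third parameter. Multi-start nonlinear least squares
guards against local minima from branch reassignment. Branches are combined
with a hard minimum; triose-phosphate limitation is not modelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .curve import Curve
from .errors import NonConvergenceError, TooFewPointsError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FvcbParams:
    """FvCB kinetic parameters at 25 degC.

    vcmax, jmax, rd are in umol m-2 s-1; gamma_star and kc in umol mol-1;
    ko and o2 in mmol mol-1; theta and alpha dimensionless; ppfd in
    umol m-2 s-1 (the fixed measurement light level).
    """

    vcmax: float
    jmax: float
    rd: float = 1.5
    gamma_star: float = 42.75
    kc: float = 404.9
    ko: float = 278.4
    o2: float = 210.0
    theta: float = 0.85
    alpha: float = 0.24
    ppfd: float = 1200.0

    def __post_init__(self):
        for name in ("vcmax", "jmax", "gamma_star", "kc", "ko", "o2", "ppfd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rd < 0:
            raise ValueError("rd must be non-negative")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def km(self) -> float:
        """Effective Michaelis-Menten constant Kc * (1 + O / Ko), umol mol-1."""
        return self.kc * (1.0 + self.o2 / self.ko)


#: Neutral kinetic template used when the caller supplies none; vcmax/jmax
#: placeholders are overwritten by the fit.
DEFAULT_KINETICS = FvcbParams(vcmax=50.0, jmax=100.0)


@dataclass
class FitResult:
    """Outcome of an A-Ci fit."""

    params: FvcbParams
    rd_fixed: bool
    rmse: float  # umol m-2 s-1, on the fitted range
    ci_transition: float  # umol mol-1; NaN if one limitation never expressed
    ci_range_used: Tuple[float, float]
    n_points: int
    converged: bool
    rss: float = math.nan

    def to_dict(self) -> dict:
        return {
            "vcmax": self.params.vcmax,
            "jmax": self.params.jmax,
            "rd": self.params.rd,
            "rd_fixed": self.rd_fixed,
            "rmse": self.rmse,
            "rss": self.rss,
            "ci_transition": self.ci_transition,
            "ci_range_used": list(self.ci_range_used),
            "n_points": self.n_points,
            "converged": self.converged,
        }


def electron_transport(
    ppfd: float, jmax: float, theta: float = 0.85, alpha: float = 0.24
) -> float:
    """Electron transport rate J from the non-rectangular hyperbola.

    Smaller root of theta J^2 - (alpha Q + Jmax) J + alpha Q Jmax = 0.
    Saturates at Jmax for bright light and vanishes in darkness.
    """
    q = alpha * ppfd
    b = q + jmax
    disc = b * b - 4.0 * theta * q * jmax
    if disc < 0:
        if disc > -1e-9 * b * b:  # numerical round-off at the double root
            disc = 0.0
        else:
            raise ValueError("negative discriminant in electron transport solve")
    return (b - math.sqrt(disc)) / (2.0 * theta)


def rubisco_limited(ci, params: FvcbParams):
    """Rubisco-limited gross carboxylation rate Ac (umol m-2 s-1)."""
    ci = np.asarray(ci, dtype=float)
    ac = params.vcmax * (ci - params.gamma_star) / (ci + params.km)
    return float(ac) if ac.ndim == 0 else ac


def rubp_limited(ci, params: FvcbParams):
    """RuBP-regeneration-limited rate Aj (umol m-2 s-1)."""
    ci = np.asarray(ci, dtype=float)
    j = electron_transport(params.ppfd, params.jmax, params.theta, params.alpha)
    aj = j * (ci - params.gamma_star) / (4.0 * ci + 8.0 * params.gamma_star)
    return float(aj) if aj.ndim == 0 else aj


def fvcb_A(ci, params: FvcbParams):
    """Net assimilation A = min(Ac, Aj) - Rd at the given Ci (umol mol-1)."""
    ac = rubisco_limited(ci, params)
    aj = rubp_limited(ci, params)
    a = np.minimum(ac, aj) - params.rd
    return float(a) if np.ndim(a) == 0 else a


def ci_transition(params: FvcbParams, lo: float = 1e-2, hi: float = 1e5) -> float:
    """Ci (umol mol-1) where the Rubisco- and RuBP-limited rates intersect.

    Solved numerically; returns NaN when one limitation is never expressed
    (the two branch curves do not cross for positive Ci).
    """
    j = electron_transport(params.ppfd, params.jmax, params.theta, params.alpha)

    def diff(ci):
        # Ac - Aj with the common (ci - gamma_star) factor removed, so the
        # trivial intersection at the photocompensation point is excluded
        return params.vcmax / (ci + params.km) - (j / 4.0) / (
            ci + 2.0 * params.gamma_star
        )

    f_lo, f_hi = diff(lo), diff(hi)
    if not np.isfinite(f_lo) or not np.isfinite(f_hi) or f_lo * f_hi > 0:
        return math.nan
    return float(optimize.brentq(diff, lo, hi, xtol=1e-10))


def co2_compensation_point(params: FvcbParams, include_rd: bool = True) -> float:
    """CO2 compensation point (umol mol-1).

    Without Rd this is the photocompensation point Gamma* itself. With Rd,
    it is the Ci at which net assimilation crosses zero on the
    Rubisco-limited branch, available in closed form:

        Ci = (Gamma* Vcmax + Rd Km) / (Vcmax - Rd)

    Raises ``ValueError`` when Rd >= Vcmax (net uptake can never reach zero
    from below in that regime).
    """
    if not include_rd:
        return params.gamma_star
    if params.rd >= params.vcmax:
        raise ValueError(
            f"no compensation point: rd={params.rd} >= vcmax={params.vcmax}"
        )
    return (params.gamma_star * params.vcmax + params.rd * params.km) / (
        params.vcmax - params.rd
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

#: Multi-start grid: vcmax starting guesses; jmax starts at 1.9 x vcmax and
#: rd at 1 umol m-2 s-1 when free.
VCMAX_STARTS = (25.0, 50.0, 100.0)


def _extract_aci(data) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(data, Curve):
        df = data.data
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        raise TypeError("fit_aci expects a Curve or DataFrame with A and Ci")
    if "A" not in df.columns or "Ci" not in df.columns:
        raise ValueError("data must carry A and Ci columns")
    a = df["A"].to_numpy(dtype=float)
    ci = df["Ci"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(ci)
    return ci[ok], a[ok]


def fit_aci(
    data: Union[Curve, pd.DataFrame],
    rd_measured: Optional[float] = None,
    ci_range: Optional[Sequence[float]] = None,
    kinetics: FvcbParams = DEFAULT_KINETICS,
) -> FitResult:
    """Fit Vcmax and Jmax (and optionally Rd) to an A-Ci curve.

    Parameters
    ----------
    data
        Corrected curve (or frame) with A and Ci columns.
    rd_measured
        Independently measured dark respiration (umol m-2 s-1). When given,
        Rd is fixed at this value; otherwise it is a third fit parameter.
    ci_range
        Optional (lo, hi) restriction in umol mol-1, e.g. (200, 800) for a
        partial-range fit.
    kinetics
        Template carrying the kinetic constants (gamma_star, kc, ko, o2,
        theta, alpha, ppfd); its vcmax/jmax/rd entries are ignored.

    Raises
    ------
    TooFewPointsError
        Fewer than 8 usable points after restriction.
    NonConvergenceError
        Every start of the multi-start optimisation failed.
    """
    ci, a_obs = _extract_aci(data)
    if ci_range is not None:
        lo, hi = float(ci_range[0]), float(ci_range[1])
        if lo > hi:
            raise ValueError(f"invalid ci_range: {ci_range}")
        mask = (ci >= lo) & (ci <= hi)
        ci, a_obs = ci[mask], a_obs[mask]
    n = len(ci)
    n_free = 2 if rd_measured is not None else 3
    if n < max(8, n_free + 5):
        raise TooFewPointsError(
            f"need at least {max(8, n_free + 5)} points to fit, got {n}"
        )

    def unpack(x) -> FvcbParams:
        rd = rd_measured if rd_measured is not None else x[2]
        return replace(kinetics, vcmax=x[0], jmax=x[1], rd=rd)

    def residuals(x):
        return fvcb_A(ci, unpack(x)) - a_obs

    best = None
    messages = []
    for v0 in VCMAX_STARTS:
        x0 = [v0, 1.9 * v0] + ([] if rd_measured is not None else [1.0])
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=([1e-3] * len(x0), [np.inf] * len(x0)),
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - defensive
            messages.append(f"start {x0}: {exc}")
            continue
        messages.append(f"start {x0}: status={res.status} cost={res.cost:.6g}")
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise NonConvergenceError(
            "FvCB fit failed from every start:\n" + "\n".join(messages)
        )

    params = unpack(best.x)
    rss = float(np.sum(best.fun**2))
    rmse = math.sqrt(rss / n)
    return FitResult(
        params=params,
        rd_fixed=rd_measured is not None,
        rmse=rmse,
        ci_transition=ci_transition(params),
        ci_range_used=(float(ci.min()), float(ci.max())),
        n_points=n,
        converged=True,
        rss=rss,
    )
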