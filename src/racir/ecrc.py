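"""Empty-chamber response curve (ECRC) models and RACiR correction.

A rapid ramp measured with an empty chamber should show zero assimilation;
what it actually shows is the apparent-flux artifact produced by chamber
mixing lag, IRGA match offsets and residual time delays. That artifact is
smooth in reference CO2, so it is captured by a low-order polynomial of
apparent A on co2_ref (degrees 1-3), the best degree chosen by the Bayesian
information criterion, and subtracted from leaf measurements taken under
the same chamber settings.

BIC uses the Gaussian concentrated-likelihood form

    BIC = n * ln(RSS / n) + k * ln(n),        k = degree + 1

whose additive constants cancel in comparisons. An exact fit (RSS below
1e-12 * n) makes the log undefined; such models are marked exact and the
lowest exact degree wins on parsimony grounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from .constants import polyval
from .curve import Curve
from .errors import DomainMismatchError, TooFewPointsError
from . import gasx

logger = logging.getLogger(__name__)

#: RSS per point below which a polynomial fit is treated as exact.
EXACT_RSS_PER_POINT = 1e-12


@dataclass(frozen=True)
class EcrcModel:
    """A fitted empty-chamber polynomial.

    ``coefficients`` are in ascending order (constant term first).
    ``co2_ref_domain`` is the observed reference-CO2 range of the fit;
    the model must never be evaluated outside it (no extrapolation).
    """

    degree: int
    coefficients: tuple
    co2_ref_domain: tuple  # (min, max) umol mol-1
    n_points: int
    rss: float
    bic: float
    exact: bool = False

    def __post_init__(self):
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        lo, hi = self.co2_ref_domain
        if not lo < hi:
            raise ValueError("co2_ref_domain must satisfy min < max")

    def predict(self, co2_ref):
        """Apparent-A offset (umol m-2 s-1) at the given reference CO2."""
        return polyval(self.coefficients, co2_ref)

    def contains(self, co2_ref) -> np.ndarray:
        lo, hi = self.co2_ref_domain
        x = np.asarray(co2_ref, dtype=float)
        return (x >= lo) & (x <= hi)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "co2_ref_domain": list(self.co2_ref_domain),
            "n_points": self.n_points,
            "rss": self.rss,
            "bic": self.bic,
            "exact": self.exact,
        }


def fit_ecrc(
    ecrc_curve: Curve,
    degrees: Iterable[int] = (1, 2, 3),
    nominal_area: float = 36.0,
) -> List[EcrcModel]:
    """Fit polynomials of each requested degree to an empty-chamber curve.

    The curve should already be restricted to its quasi-linear portion
    (see :mod:`racir.filtering`). Apparent assimilation is regressed on
    reference CO2 by ordinary least squares; if the curve carries no A
    column it is computed here with ``nominal_area`` (the chamber aperture,
    36 cm^2 for a large needle chamber) standing in for leaf area.
    """
    degrees = sorted(set(int(d) for d in degrees))
    if any(d not in (1, 2, 3) for d in degrees):
        raise ValueError(f"degrees must be a subset of {{1, 2, 3}}, got {degrees}")
    if "A" not in ecrc_curve.data.columns:
        ecrc_curve = gasx.compute_derived(ecrc_curve, area=nominal_area)

    x = ecrc_curve["co2_ref"]
    y = ecrc_curve["A"]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]

    models = []
    for d in degrees:
        n = len(x)
        if n <= d + 2:
            raise TooFewPointsError(
                f"degree-{d} polynomial needs more than {d + 2} points, got {n}"
            )
        # fit in a scaled domain for conditioning, then convert to raw coefs
        poly = np.polynomial.Polynomial.fit(x, y, deg=d)
        coefs = poly.convert().coef
        if len(coefs) < d + 1:  # numpy trims trailing zeros on conversion
            coefs = np.pad(coefs, (0, d + 1 - len(coefs)))
        rss = float(np.sum((y - poly(x)) ** 2))
        exact = rss < EXACT_RSS_PER_POINT * n
        bic = -math.inf if exact else n * math.log(rss / n) + (d + 1) * math.log(n)
        models.append(
            EcrcModel(
                degree=d,
                coefficients=tuple(float(c) for c in coefs),
                co2_ref_domain=(float(x.min()), float(x.max())),
                n_points=n,
                rss=rss,
                bic=bic,
                exact=exact,
            )
        )
    return models


def select_best_bic(models: Sequence[EcrcModel]) -> EcrcModel:
    """Model with minimal BIC; ties (including exact fits) break to lowest degree."""
    models = list(models)
    if not models:
        raise ValueError("no candidate models to select from")
    return min(models, key=lambda m: (m.bic, m.degree))


def correct_racir(
    racir_curve: Curve,
    model: EcrcModel,
    min_inside_fraction: float = 0.2,
    offset_scale: float = 1.0,
) -> Curve:
    """Subtract the empty-chamber artifact from a leaf ramp and recompute Ci.

    Records whose reference CO2 falls outside the model's fitted domain are
    dropped (the polynomial is never extrapolated); if fewer than
    ``min_inside_fraction`` of records survive, the chamber settings likely
    differ from the ECRC's and a :class:`DomainMismatchError` advises
    measuring a new one. Ci is recomputed from the corrected flux rather
    than corrected additively, because Ci depends nonlinearly on A.

    The artifact is a chamber-level flux: when the leaf curve's A was
    computed with a leaf area different from the nominal aperture the ECRC
    used, pass ``offset_scale = nominal_area / leaf_area`` so the
    subtraction is done on the same per-area basis.
    """
    if "A" not in racir_curve.data.columns:
        raise ValueError("correct_racir needs derived A; run gasx.compute_derived")
    racir_curve.require_nonempty()

    x = racir_curve["co2_ref"]
    inside = model.contains(x)
    frac = inside.mean()
    if frac < min_inside_fraction:
        raise DomainMismatchError(
            f"only {frac:.0%} of records fall inside the ECRC domain "
            f"{model.co2_ref_domain}; measure a new empty-chamber curve under "
            "the current chamber settings"
        )
    n_trimmed = int((~inside).sum())
    if n_trimmed:
        logger.info("trimmed %d records outside ECRC domain %s",
                    n_trimmed, model.co2_ref_domain)

    df = racir_curve.data.loc[inside].reset_index(drop=True)
    a_corr = df["A"].to_numpy(dtype=float) - offset_scale * model.predict(
        df["co2_ref"].to_numpy(dtype=float)
    )
    df["A"] = a_corr

    # recompute Ci from the corrected flux; conductances are unaffected
    if "gtc" in df.columns and "E" in df.columns:
        gtc = df["gtc"].to_numpy(dtype=float)
        e = df["E"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ci = np.where(
                np.isfinite(gtc) & (gtc > 0),
                ((gtc - e / 2.0) * df["co2_sam"].to_numpy(dtype=float) - a_corr)
                / (gtc + e / 2.0),
                np.nan,
            )
        df["Ci"] = ci

    return racir_curve.with_data(
        df, ecrc_model=model, n_domain_trimmed=n_trimmed
    )
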