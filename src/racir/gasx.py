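"""Open-system gas-exchange bookkeeping.

Computes net assimilation, transpiration, conductances and intercellular
CO2 from raw IRGA quantities, and recomputes everything after a
post-measurement leaf-area change (needed for non-flat conifer shoots whose
true silhouette area is only known after scanning).

The equation set is the standard open-chamber system used by commercial
instruments, with boundary-layer conductance folded into a single lumped
total conductance:

    A   = flow * (c_r - c_s * (1000 - w_r) / (1000 - w_s)) / (100 * S)
    E   = flow * (w_s - w_r) / (100 * S * (1000 - w_s))
    gtw = E * (1000 - (W_leaf + w_s) / 2) / (W_leaf - w_s)
    gtc = gtw / 1.6
    Ci  = ((gtc - E/2) * c_s - A) / (gtc + E/2)

with CO2 in umol mol-1, H2O in mmol mol-1, flow in umol s-1, S in cm^2,
A in umol m-2 s-1 and E, gtw, gtc in mol m-2 s-1. W_leaf is the saturation
water mole fraction at leaf temperature (Buck formula, see
:mod:`racir.constants`).

Two parallel implementations exist on purpose: scalar functions operating
on a single :class:`~racir.curve.GasExchangeRecord` (the reference path)
and a vectorised curve-level path (:func:`compute_derived`). Tests assert
both agree, which guards the leaf-area rescaling round trip.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np

from .constants import DIFF_RATIO_H2O_CO2, leaf_saturation_mole_fraction
from .curve import Curve, GasExchangeRecord
from .errors import InvalidAreaError, InvalidHumidityError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# record-level reference implementation
# ---------------------------------------------------------------------------

def compute_assimilation(record: GasExchangeRecord) -> float:
    """Net CO2 assimilation (umol m-2 s-1) from raw IRGA draw-down.

    Raises :class:`InvalidAreaError` for non-positive leaf area and
    :class:`InvalidHumidityError` for physically impossible water mole
    fractions -- never returns a silent NaN for those cases.
    """
    if record.leaf_area is None or record.leaf_area <= 0:
        raise InvalidAreaError(
            f"leaf_area must be positive, got {record.leaf_area!r}"
        )
    if record.h2o_sam >= 1000 or record.h2o_ref >= 1000:
        raise InvalidHumidityError(
            f"water mole fraction out of range: h2o_ref={record.h2o_ref}, "
            f"h2o_sam={record.h2o_sam} (must be < 1000 mmol mol-1)"
        )
    dilution = (1000.0 - record.h2o_ref) / (1000.0 - record.h2o_sam)
    a = record.flow * (record.co2_ref - record.co2_sam * dilution) / (
        100.0 * record.leaf_area
    )
    record.A = a
    return a


def compute_transpiration_and_conductances(
    record: GasExchangeRecord,
) -> Tuple[float, float, float]:
    """Transpiration E and total conductances to water and CO2.

    A record with no outward vapour gradient (W_leaf <= h2o_sam, or
    non-positive E) is flagged rather than erroring: its conductances are
    NaN and it is excluded from Ci computation downstream.
    """
    if record.leaf_area is None or record.leaf_area <= 0:
        raise InvalidAreaError(
            f"leaf_area must be positive, got {record.leaf_area!r}"
        )
    e = record.flow * (record.h2o_sam - record.h2o_ref) / (
        100.0 * record.leaf_area * (1000.0 - record.h2o_sam)
    )
    record.E = e
    w_leaf = leaf_saturation_mole_fraction(record.t_leaf, record.pressure)
    if e <= 0 or w_leaf <= record.h2o_sam:
        record.flag("no_vapor_gradient")
        record.gtw = None
        record.gtc = None
        logger.warning(
            "record at t=%.1fs flagged: no usable vapour gradient "
            "(E=%.3g, W_leaf=%.2f, h2o_sam=%.2f)",
            record.elapsed_s, e, w_leaf, record.h2o_sam,
        )
        return e, math.nan, math.nan
    gtw = e * (1000.0 - (w_leaf + record.h2o_sam) / 2.0) / (w_leaf - record.h2o_sam)
    gtc = gtw / DIFF_RATIO_H2O_CO2
    record.gtw = gtw
    record.gtc = gtc
    return e, gtw, gtc


def compute_ci(record: GasExchangeRecord) -> float:
    """Intercellular CO2 (umol mol-1) from A, E and total CO2 conductance.

    Negative Ci is permitted (it can arise from noisy humidity control)
    but the record is flagged as suspect.
    """
    if record.A is None or record.E is None:
        raise ValueError("compute A and E before Ci")
    if record.gtc is None or not math.isfinite(record.gtc) or record.gtc <= 0:
        record.flag("no_conductance")
        record.Ci = math.nan
        return math.nan
    ci = ((record.gtc - record.E / 2.0) * record.co2_sam - record.A) / (
        record.gtc + record.E / 2.0
    )
    if ci < 0:
        record.flag("negative_ci")
    record.Ci = ci
    return ci


def compute_record(record: GasExchangeRecord) -> GasExchangeRecord:
    """Run the full derivation chain A -> (E, gtw, gtc) -> Ci on one record."""
    compute_assimilation(record)
    compute_transpiration_and_conductances(record)
    compute_ci(record)
    return record


# ---------------------------------------------------------------------------
# curve-level vectorised path
# ---------------------------------------------------------------------------

def compute_derived(curve: Curve, area: Optional[float] = None) -> Curve:
    """Compute A, E, gtw, gtc and Ci for every record of a curve.

    Parameters
    ----------
    curve
        Input curve carrying the raw IRGA fields.
    area
        Optional override for leaf area in cm^2. Empty-chamber curves log
        a leaf area of zero; pass the nominal chamber aperture here to
        obtain the *apparent* assimilation signal those curves carry.

    Returns
    -------
    Curve
        A new curve with derived columns and a string ``flag`` column
        (semicolon-separated quality flags, empty when clean).
    """
    df = curve.data.copy()
    if area is not None:
        if area <= 0:
            raise InvalidAreaError(f"area must be positive, got {area!r}")
        s = np.full(len(df), float(area))
    else:
        s = df["leaf_area"].to_numpy(dtype=float)
        if (s <= 0).any():
            raise InvalidAreaError(
                "curve contains non-positive leaf_area; pass an explicit "
                "nominal area for empty-chamber curves"
            )

    flow = df["flow"].to_numpy(dtype=float)
    c_r = df["co2_ref"].to_numpy(dtype=float)
    c_s = df["co2_sam"].to_numpy(dtype=float)
    w_r = df["h2o_ref"].to_numpy(dtype=float)
    w_s = df["h2o_sam"].to_numpy(dtype=float)
    if (w_s >= 1000).any() or (w_r >= 1000).any():
        raise InvalidHumidityError("water mole fraction >= 1000 mmol mol-1")

    a = flow * (c_r - c_s * (1000.0 - w_r) / (1000.0 - w_s)) / (100.0 * s)
    e = flow * (w_s - w_r) / (100.0 * s * (1000.0 - w_s))
    w_leaf = leaf_saturation_mole_fraction(
        df["t_leaf"].to_numpy(dtype=float), df["pressure"].to_numpy(dtype=float)
    )

    no_gradient = (e <= 0) | (w_leaf <= w_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        gtw = np.where(
            no_gradient,
            np.nan,
            e * (1000.0 - (w_leaf + w_s) / 2.0) / (w_leaf - w_s),
        )
    gtc = gtw / DIFF_RATIO_H2O_CO2

    bad_g = no_gradient | ~np.isfinite(gtc) | (gtc <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(
            bad_g, np.nan, ((gtc - e / 2.0) * c_s - a) / (gtc + e / 2.0)
        )

    flags = np.array([""] * len(df), dtype=object)
    flags[no_gradient] = "no_vapor_gradient"
    neg = np.isfinite(ci) & (ci < 0)  # disjoint from no_gradient by construction
    flags[neg] = "negative_ci"
    n_flagged = int(no_gradient.sum() + neg.sum())
    if n_flagged:
        logger.warning("flagged %d of %d records during derivation", n_flagged, len(df))

    df["A"] = a
    df["E"] = e
    df["gtw"] = gtw
    df["gtc"] = gtc
    df["Ci"] = ci
    df["flag"] = flags
    return curve.with_data(df)


def rescale_leaf_area(curve: Curve, new_area: float) -> Curve:
    """Replace leaf area and recompute every derived quantity from raw fields.

    Raw IRGA fields are untouched; A and E scale exactly inversely with
    area while Ci responds nonlinearly through the recomputation.
    """
    if new_area is None or new_area <= 0:
        raise InvalidAreaError(f"new_area must be positive, got {new_area!r}")
    df = curve.data.copy()
    df["leaf_area"] = float(new_area)
    rescaled = curve.with_data(df, leaf_area_rescaled_to=float(new_area))
    return compute_derived(rescaled)
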