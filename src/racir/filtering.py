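"""Quasi-linear segment selection and outlier removal for ramp data.

A rapid CO2 ramp only yields interpretable assimilation values once the
chamber mixing has reached a moving steady state. The filter implements the
delta-threshold rule used in practice: consecutive-point changes in net
assimilation, delta_i = A_i - A_(i-1), must stay within +/- 0.05
umol m-2 s-1 (configurable). Points before the first sufficiently long run
of in-threshold deltas form the initial *lag block*; after that, isolated
points that jump away from the accepted trace are *outliers*.

Two outlier-reference conventions exist in the wild, so both are provided:
compare each candidate to the last *kept* point (default; idempotent on its
own output) or to its raw predecessor (monotone in the threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

from .curve import Curve
from .errors import InvalidWindowError, NoSteadyStateError, TooFewPointsError

logger = logging.getLogger(__name__)


@dataclass
class FilterSettings:
    """Parameters of the delta-threshold filter.

    delta_threshold
        Largest |A_i - A_(i-1)| (umol m-2 s-1) still considered steady.
    min_run_length
        Number of consecutive in-threshold deltas that ends the lag block
        (default 10 = 20 s of 2 s logging, well under observed lag times).
    direction
        Which ramp direction the filter is meant for; informational.
    compare_to
        ``"last_kept"`` (default) or ``"predecessor"`` -- the reference
        point for the outlier test after the lag block.
    lag_pad
        Extra points dropped after the detected lag block, for signals where
        a slow transient may still be decaying when deltas first fall inside
        the threshold. Default 0 (the bare rule).
    min_kept_fraction
        Sanity guard on lag detection: if fewer than this fraction of the
        post-lag remainder survives the outlier test, the detected run is
        treated as spurious (a transient can momentarily have near-zero
        deltas while passing through a turning point) and the search
        continues from the next candidate run. Set 0 to disable.
    """

    delta_threshold: float = 0.05
    min_run_length: int = 10
    direction: str = "up"
    compare_to: str = "last_kept"
    lag_pad: int = 0
    min_kept_fraction: float = 0.5

    def __post_init__(self):
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be at least 2")
        if self.compare_to not in ("last_kept", "predecessor"):
            raise ValueError("compare_to must be 'last_kept' or 'predecessor'")
        if self.lag_pad < 0:
            raise ValueError("lag_pad must be non-negative")
        if not 0 <= self.min_kept_fraction < 1:
            raise ValueError("min_kept_fraction must be in [0, 1)")


@dataclass
class FilterResult:
    """Partition of input indices into kept / lag / outlier classes."""

    kept_indices: np.ndarray
    outlier_indices: np.ndarray
    lag_indices: np.ndarray

    def __post_init__(self):
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.outlier_indices = np.asarray(self.outlier_indices, dtype=int)
        self.lag_indices = np.asarray(self.lag_indices, dtype=int)

    @property
    def n_total(self) -> int:
        return len(self.kept_indices) + len(self.outlier_indices) + len(self.lag_indices)


def compute_deltas(a_series: Sequence[float]) -> np.ndarray:
    """First differences delta_i = a_i - a_(i-1) for i >= 1 (length n-1)."""
    a = np.asarray(a_series, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise TooFewPointsError("need at least 2 values to compute deltas")
    return np.diff(a)


def _a_values(curve_or_values: Union[Curve, Sequence[float]]) -> np.ndarray:
    if isinstance(curve_or_values, Curve):
        if "A" not in curve_or_values.data.columns:
            raise ValueError("curve has no A column; run gasx.compute_derived first")
        return curve_or_values["A"]
    return np.asarray(curve_or_values, dtype=float)


def select_quasi_linear(
    curve_or_values: Union[Curve, Sequence[float]],
    settings: FilterSettings = FilterSettings(),
) -> FilterResult:
    """Partition a ramp into lag block, kept points and outliers.

    The lag block ends at the point *preceding* the first run of
    ``min_run_length`` consecutive in-threshold deltas (that point is the
    anchor the run's deltas are measured against, so it belongs to the
    steady segment). Within the remainder, a point whose delta from the
    reference (last kept point, by default) exceeds the threshold in
    absolute value is an outlier.

    Raises :class:`NoSteadyStateError` when no qualifying run exists.
    """
    a = _a_values(curve_or_values)
    if len(a) < 2:
        raise TooFewPointsError("need at least 2 points to filter")
    thr = settings.delta_threshold
    m = settings.min_run_length

    deltas = np.diff(a)
    in_thr = np.abs(deltas) <= thr
    longest = _longest_run(in_thr)

    search_from = 1  # delta positions are 1-based point indices
    while True:
        run_start = _next_run(in_thr, m, search_from)
        if run_start is None:
            raise NoSteadyStateError(thr, m, longest)
        # the point preceding the run anchors its first delta, so the steady
        # segment starts one point before the run (plus any configured pad)
        start = run_start - 1 + settings.lag_pad
        if start >= len(a) - 1:
            raise NoSteadyStateError(thr, m, longest)

        kept = [start]
        outliers = []
        for i in range(start + 1, len(a)):
            ref = a[kept[-1]] if settings.compare_to == "last_kept" else a[i - 1]
            if abs(a[i] - ref) > thr:
                outliers.append(i)
            else:
                kept.append(i)

        remainder = len(a) - start
        if len(kept) >= settings.min_kept_fraction * remainder:
            break
        logger.debug(
            "run at %d rejected as spurious (%d of %d kept); searching on",
            run_start, len(kept), remainder,
        )
        search_from = run_start + 1

    lag = list(range(start))
    logger.debug(
        "filter: %d kept, %d lag, %d outliers (threshold %.3g)",
        len(kept), len(lag), len(outliers), thr,
    )
    return FilterResult(
        kept_indices=np.array(kept, dtype=int),
        outlier_indices=np.array(outliers, dtype=int),
        lag_indices=np.array(lag, dtype=int),
    )


def _longest_run(mask: np.ndarray) -> int:
    longest = run = 0
    for ok in mask:
        run = run + 1 if ok else 0
        longest = max(longest, run)
    return longest


def _next_run(mask: np.ndarray, m: int, search_from: int):
    """First 1-based position >= search_from starting m consecutive True deltas."""
    run = 0
    for j in range(search_from, len(mask) + 1):
        if mask[j - 1]:
            run += 1
            if run == m:
                return j - m + 1
        else:
            run = 0
    return None


def apply_filter(
    curve: Curve, settings: FilterSettings = FilterSettings()
) -> Tuple[Curve, FilterResult]:
    """Run :func:`select_quasi_linear` on a curve and return the kept subset."""
    result = select_quasi_linear(curve, settings)
    df = curve.data.iloc[result.kept_indices].reset_index(drop=True)
    filtered = curve.with_data(
        df,
        filter_settings=settings,
        n_lag=len(result.lag_indices),
        n_outliers=len(result.outlier_indices),
    )
    return filtered, result


def exclude_ci_window(curve: Curve, ci_lo: float, ci_hi: float) -> Curve:
    """Drop records whose Ci falls inside [ci_lo, ci_hi].

    Used to remove localized erroneous dips in net assimilation (e.g. the
    ~450-600 ppm Ci artifacts seen in some rapid conifer curves) before
    model fitting. The number of removals is logged and recorded in curve
    metadata; silence is never an option.
    """
    if ci_lo > ci_hi:
        raise InvalidWindowError(f"invalid Ci window: lo={ci_lo} > hi={ci_hi}")
    if "Ci" not in curve.data.columns:
        raise ValueError("curve has no Ci column; run gasx.compute_derived first")
    ci = curve["Ci"]
    inside = np.isfinite(ci) & (ci >= ci_lo) & (ci <= ci_hi)
    n_removed = int(inside.sum())
    logger.info("excluding %d records with Ci in [%.1f, %.1f]", n_removed, ci_lo, ci_hi)
    df = curve.data.loc[~inside].reset_index(drop=True)
    prior = curve.meta.get("n_ci_excluded", 0)
    return curve.with_data(df, n_ci_excluded=prior + n_removed)
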