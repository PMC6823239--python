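"""Gas-exchange equations: hand-derived values, error handling, scaling laws."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from racir import (
    Curve,
    CurveRole,
    GasExchangeRecord,
    InvalidAreaError,
    InvalidHumidityError,
    compute_assimilation,
    compute_ci,
    compute_derived,
    compute_record,
    compute_transpiration_and_conductances,
    rescale_leaf_area,
)
from conftest import make_leaf_frame


def record(**kw):
    base = dict(
        elapsed_s=0.0, co2_ref=420.0, co2_sam=400.0, h2o_ref=22.0,
        h2o_sam=24.0, flow=600.0, leaf_area=36.0,
    )
    base.update(kw)
    return GasExchangeRecord(**base)


class TestAssimilation:
    def test_no_drawdown_gives_zero(self):
        assert compute_assimilation(record(co2_sam=420.0, h2o_sam=22.0)) == 0.0

    def test_hand_value(self):
        # flow 600, area 36, equal humidities: A = 600 * 20 / 3600
        a = compute_assimilation(record(h2o_sam=22.0))
        assert a == pytest.approx(600 * 20 / 3600, rel=1e-12)

    def test_halving_area_doubles_a(self):
        a36 = compute_assimilation(record(h2o_sam=22.0))
        a18 = compute_assimilation(record(h2o_sam=22.0, leaf_area=18.0))
        assert a18 == pytest.approx(2 * a36, rel=1e-12)
        assert a18 == pytest.approx(20 / 3.0, rel=1e-6)

    @pytest.mark.parametrize("area", [0.0, -1.0])
    def test_invalid_area(self, area):
        with pytest.raises(InvalidAreaError):
            compute_assimilation(record(leaf_area=area))

    def test_invalid_humidity(self):
        rec = record()
        rec.h2o_sam = 1000.0
        with pytest.raises(InvalidHumidityError):
            compute_assimilation(rec)


class TestTranspiration:
    def test_hand_value(self):
        # E = 600 * 4 / (100 * 36 * 976)
        rec = record(h2o_ref=20.0, h2o_sam=24.0)
        e, gtw, gtc = compute_transpiration_and_conductances(rec)
        assert e == pytest.approx(600 * 4 / (100 * 36 * 976), rel=1e-12)
        assert gtc == pytest.approx(gtw / 1.6, rel=1e-12)

    def test_zero_flux_flags_record(self):
        rec = record(h2o_ref=22.0, h2o_sam=22.0)
        e, gtw, gtc = compute_transpiration_and_conductances(rec)
        assert e == 0.0
        assert math.isnan(gtw) and math.isnan(gtc)
        assert "no_vapor_gradient" in rec.flags

    def test_halving_area_doubles_e(self):
        e1, _, _ = compute_transpiration_and_conductances(record(h2o_ref=20.0))
        e2, _, _ = compute_transpiration_and_conductances(
            record(h2o_ref=20.0, leaf_area=18.0)
        )
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestCi:
    def test_hand_value(self):
        rec = record()
        rec.A, rec.E, rec.gtc = 10.0, 0.0, 0.1
        assert compute_ci(rec) == pytest.approx((0.1 * 400 - 10) / 0.1, rel=1e-12)

    def test_no_flux_means_ci_equals_sample(self):
        rec = record()
        rec.A, rec.E, rec.gtc = 0.0, 0.0, 0.1
        assert compute_ci(rec) == pytest.approx(400.0, rel=1e-12)

    def test_uptake_draws_ci_below_sample(self):
        rec = record()
        rec.A, rec.E, rec.gtc = 5.0, 0.0, 0.1
        assert compute_ci(rec) < rec.co2_sam

    def test_negative_ci_is_flagged_not_raised(self):
        rec = record()
        rec.A, rec.E, rec.gtc = 50.0, 0.0, 0.1
        ci = compute_ci(rec)
        assert ci < 0
        assert "negative_ci" in rec.flags

    def test_no_conductance_flags(self):
        rec = record()
        rec.A, rec.E, rec.gtc = 5.0, 0.0, None
        assert math.isnan(compute_ci(rec))
        assert "no_conductance" in rec.flags


@given(
    area=st.floats(1.0, 100.0),
    scale=st.floats(0.1, 10.0),
    co2_sam=st.floats(10.0, 1500.0),
    h2o_sam=st.floats(22.5, 35.0),
)
def test_fluxes_inversely_proportional_to_area(area, scale, co2_sam, h2o_sam):
    """A and E scale exactly as 1/area for fixed raw fields."""
    r1 = record(leaf_area=area, co2_sam=co2_sam, h2o_sam=h2o_sam)
    r2 = record(leaf_area=area * scale, co2_sam=co2_sam, h2o_sam=h2o_sam)
    a1, a2 = compute_assimilation(r1), compute_assimilation(r2)
    e1 = compute_transpiration_and_conductances(r1)[0]
    e2 = compute_transpiration_and_conductances(r2)[0]
    assert a1 == pytest.approx(a2 * scale, rel=1e-12, abs=1e-15)
    assert e1 == pytest.approx(e2 * scale, rel=1e-12, abs=1e-15)


def test_symmetric_channels_give_zero_fluxes():
    rec = record(co2_sam=420.0, h2o_sam=22.0)
    compute_assimilation(rec)
    compute_transpiration_and_conductances(rec)
    assert rec.A == 0.0 and rec.E == 0.0


class TestCurveLevel:
    def test_vectorised_matches_record_path(self, leaf_curve):
        derived = compute_derived(leaf_curve)
        recs = [compute_record(r) for r in leaf_curve.records()]
        for col in ("A", "E", "gtw", "gtc", "Ci"):
            vec = derived[col]
            scalar = np.array([getattr(r, col) for r in recs], dtype=float)
            np.testing.assert_allclose(vec, scalar, rtol=1e-12)

    def test_rescale_identity(self, leaf_curve):
        derived = compute_derived(leaf_curve)
        same = rescale_leaf_area(leaf_curve, 36.0)
        for col in ("A", "E", "Ci"):
            np.testing.assert_allclose(same[col], derived[col], rtol=1e-12)

    def test_rescale_halving_doubles_fluxes(self, leaf_curve):
        derived = compute_derived(leaf_curve)
        half = rescale_leaf_area(leaf_curve, 18.0)
        np.testing.assert_allclose(half["A"], 2 * derived["A"], rtol=1e-12)
        np.testing.assert_allclose(half["E"], 2 * derived["E"], rtol=1e-12)

    def test_rescale_ci_round_trip_with_record_path(self, leaf_curve):
        """Ci after rescaling equals Ci computed from scratch at the new area."""
        rescaled = rescale_leaf_area(leaf_curve, 24.0)
        fresh = make_leaf_frame(leaf_area=24.0)
        recs = [compute_record(r) for r in Curve(fresh).records()]
        np.testing.assert_allclose(
            rescaled["Ci"],
            [r.Ci for r in recs],
            rtol=1e-12,
        )

    def test_rescale_rejects_bad_area(self, leaf_curve):
        with pytest.raises(InvalidAreaError):
            rescale_leaf_area(leaf_curve, 0.0)

    def test_ecrc_needs_explicit_area(self, leaf_frame):
        leaf_frame["leaf_area"] = 0.0
        ecrc = Curve(leaf_frame, role=CurveRole.ECRC)
        with pytest.raises(InvalidAreaError):
            compute_derived(ecrc)
        derived = compute_derived(ecrc, area=36.0)
        assert np.isfinite(derived["A"]).all()
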