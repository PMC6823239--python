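"""FvCB model values, compensation points, and the A-Ci fitting machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from racir import (
    FvcbParams,
    TooFewPointsError,
    ci_transition,
    co2_compensation_point,
    electron_transport,
    fit_aci,
    fvcb_A,
)
from racir.fvcb import rubisco_limited, rubp_limited

TRUTH = FvcbParams(vcmax=60.0, jmax=120.0, rd=2.0)


def synthetic_aci(params, ci, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = fvcb_A(ci, params) + rng.normal(0.0, noise_sd, np.size(ci))
    return pd.DataFrame({"Ci": ci, "A": a})


class TestElectronTransport:
    def test_dark_limit(self):
        assert electron_transport(0.0, 120.0) == pytest.approx(0.0, abs=1e-12)

    def test_saturation_limit(self):
        j = electron_transport(1e9, 120.0)
        assert j == pytest.approx(120.0, rel=1e-3)
        assert j <= 120.0

    def test_double_root_at_theta_one(self):
        # theta = 1 and alpha*ppfd = jmax make J = jmax exactly
        jmax = 120.0
        j = electron_transport(jmax / 0.24, jmax, theta=1.0, alpha=0.24)
        assert j == pytest.approx(jmax, rel=1e-9)

    def test_below_jmax_at_study_light(self):
        j = electron_transport(1200.0, 120.0)
        assert 0 < j < 120.0


class TestFvcbA:
    def test_gross_zero_at_gamma_star(self):
        assert fvcb_A(TRUTH.gamma_star, TRUTH) == pytest.approx(-TRUTH.rd, abs=1e-12)

    def test_high_ci_asymptote_is_j_over_four(self):
        j = electron_transport(TRUTH.ppfd, TRUTH.jmax, TRUTH.theta, TRUTH.alpha)
        assert fvcb_A(1e7, TRUTH) == pytest.approx(j / 4 - TRUTH.rd, rel=1e-4)

    def test_rubisco_branch_hand_value(self):
        # Km = 404.9 * (1 + 210/278.4) = 710.32; Ac = 60 * 257.25 / 1010.32
        p = FvcbParams(vcmax=60.0, jmax=120.0, rd=0.0)
        assert p.km == pytest.approx(710.3203, abs=1e-3)
        assert rubisco_limited(300.0, p) == pytest.approx(15.2773, abs=1e-3)

    def test_min_rule(self):
        ci = np.linspace(10, 2000, 200)
        a = fvcb_A(ci, TRUTH)
        assert np.all(a <= rubisco_limited(ci, TRUTH) - TRUTH.rd + 1e-12)
        assert np.all(a <= rubp_limited(ci, TRUTH) - TRUTH.rd + 1e-12)

    def test_continuity_across_transition(self):
        t = ci_transition(TRUTH)
        assert np.isfinite(t)
        eps = 1e-6
        assert fvcb_A(t - eps, TRUTH) == pytest.approx(fvcb_A(t + eps, TRUTH),
                                                       abs=1e-4)


class TestCompensationPoint:
    def test_without_rd_is_gamma_star(self):
        assert co2_compensation_point(TRUTH, include_rd=False) == TRUTH.gamma_star

    def test_rd_zero_returns_gamma_star_exactly(self):
        p = FvcbParams(vcmax=60.0, jmax=120.0, rd=0.0)
        assert co2_compensation_point(p, include_rd=True) == pytest.approx(
            p.gamma_star, rel=1e-12
        )

    def test_closed_form_hand_value(self):
        # (42.75*60 + 2*Km) / 58 with Km = 710.32
        value = co2_compensation_point(TRUTH, include_rd=True)
        assert value == pytest.approx(
            (42.75 * 60 + 2 * TRUTH.km) / 58, rel=1e-12
        )
        assert value == pytest.approx(68.72, abs=0.01)

    def test_monotone_in_rd(self):
        values = [
            co2_compensation_point(
                FvcbParams(vcmax=60.0, jmax=120.0, rd=rd), include_rd=True
            )
            for rd in (0.5, 1.0, 2.0, 5.0)
        ]
        assert values == sorted(values)
        assert len(set(values)) == len(values)

    def test_rd_above_vcmax_errors(self):
        p = FvcbParams(vcmax=5.0, jmax=120.0, rd=6.0)
        with pytest.raises(ValueError):
            co2_compensation_point(p, include_rd=True)


class TestFitAci:
    def test_noise_free_recovery(self):
        ci = np.linspace(50, 1500, 30)
        fit = fit_aci(synthetic_aci(TRUTH, ci))
        assert fit.params.vcmax == pytest.approx(60.0, rel=1e-3)
        assert fit.params.jmax == pytest.approx(120.0, rel=1e-3)
        assert fit.params.rd == pytest.approx(2.0, rel=1e-3)
        assert fit.rmse < 1e-6
        assert fit.converged

    def test_rd_fixed_uses_given_value(self):
        ci = np.linspace(50, 1500, 30)
        fit = fit_aci(synthetic_aci(TRUTH, ci), rd_measured=2.0)
        assert fit.rd_fixed
        assert fit.params.rd == 2.0
        assert fit.params.vcmax == pytest.approx(60.0, rel=1e-4)

    def test_fixing_rd_at_truth_never_beats_free_rd_on_clean_data(self):
        ci = np.linspace(50, 1500, 30)
        data = synthetic_aci(TRUTH, ci)
        fixed = fit_aci(data, rd_measured=2.0)
        free = fit_aci(data)
        assert fixed.rmse <= free.rmse + 1e-9

    def test_ci_range_restriction(self):
        ci = np.linspace(50, 1500, 60)
        fit = fit_aci(synthetic_aci(TRUTH, ci), rd_measured=2.0,
                      ci_range=(200.0, 800.0))
        lo, hi = fit.ci_range_used
        assert lo >= 200.0 and hi <= 800.0
        assert fit.params.vcmax == pytest.approx(60.0, rel=1e-3)

    def test_transition_point_matches_branch_equality(self):
        ci = np.linspace(50, 1500, 30)
        fit = fit_aci(synthetic_aci(TRUTH, ci))
        t = fit.ci_transition
        assert rubisco_limited(t, fit.params) == pytest.approx(
            rubp_limited(t, fit.params), abs=1e-6
        )
        lo, hi = fit.ci_range_used
        assert lo <= t <= hi

    def test_too_few_points(self):
        ci = np.linspace(100, 800, 5)
        with pytest.raises(TooFewPointsError):
            fit_aci(synthetic_aci(TRUTH, ci))

    def test_grid_search_oracle_single_instance(self):
        """NLS optimum matches a dense 2-D grid search within one grid step."""
        ci = np.linspace(50, 1500, 30)
        data = synthetic_aci(TRUTH, ci, noise_sd=0.5, seed=11)
        fit = fit_aci(data, rd_measured=2.0)
        vc_grid = np.arange(48.0, 72.0 + 1e-9, 0.1)
        j_grid = np.arange(96.0, 144.0 + 1e-9, 0.1)
        best = grid_search(data, vc_grid, j_grid, rd=2.0)
        assert abs(fit.params.vcmax - best[0]) <= 0.1 + 1e-9
        assert abs(fit.params.jmax - best[1]) <= 0.1 + 1e-9


def grid_search(data, vc_grid, j_grid, rd):
    """Brute-force RSS minimisation over a (vcmax, jmax) grid."""
    ci = data["Ci"].to_numpy()
    a = data["A"].to_numpy()
    base = FvcbParams(vcmax=50.0, jmax=100.0, rd=rd)
    km = base.km
    gs = base.gamma_star
    # Ac for every vcmax at once: (n_vc, n_ci)
    ac_mat = vc_grid[:, None] * ((ci - gs) / (ci + km))[None, :]
    best = (None, None, np.inf)
    for jm in j_grid:
        j = electron_transport(base.ppfd, jm, base.theta, base.alpha)
        aj = j * (ci - gs) / (4 * ci + 8 * gs)
        resid = np.minimum(ac_mat, aj[None, :]) - rd - a[None, :]
        rss = np.einsum("ij,ij->i", resid, resid)
        i = int(np.argmin(rss))
        if rss[i] < best[2]:
            best = (float(vc_grid[i]), float(jm), float(rss[i]))
    return best


def test_ci_transition_nan_when_one_branch_dominates():
    # vcmax so large that RuBP regeneration limits at every Ci: no crossing
    p = FvcbParams(vcmax=150.0, jmax=40.0, rd=0.5)
    assert math.isnan(ci_transition(p))
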