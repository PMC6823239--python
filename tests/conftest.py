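"""Shared fixtures: simulated curves are expensive enough to share per session."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from racir import (
    Curve,
    CurveRole,
    PipelineSettings,
    preset,
    simulate_ecrc,
    simulate_ramp,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_setup():
    """(chamber, ramp, leaf) of the study-like scenario."""
    return preset("paper-racir")


@pytest.fixture(scope="session")
def sim_pair(paper_setup):
    """One simulated (ecrc, racir) curve pair at fixed seeds."""
    chamber, ramp, leaf = paper_setup
    ecrc = simulate_ecrc(chamber, ramp, seed=101)
    racir_curve = simulate_ramp(chamber, ramp, leaf=leaf, seed=202)
    return ecrc, racir_curve


@pytest.fixture(scope="session")
def pipeline_result(sim_pair):
    from racir import correct_and_fit

    ecrc, racir_curve = sim_pair
    return correct_and_fit(
        racir_curve,
        ecrc,
        PipelineSettings(rd_measured=2.0, partial_ci_range=(200.0, 800.0)),
    )


def make_leaf_frame(
    n=20,
    co2_ref=420.0,
    co2_sam=400.0,
    h2o_ref=22.0,
    h2o_sam=24.0,
    flow=600.0,
    leaf_area=36.0,
):
    """A small synthetic raw frame with constant conditions."""
    return pd.DataFrame(
        {
            "elapsed_s": np.arange(n, dtype=float) * 2.0,
            "co2_ref": co2_ref,
            "co2_sam": co2_sam,
            "h2o_ref": h2o_ref,
            "h2o_sam": h2o_sam,
            "flow": flow,
            "leaf_area": leaf_area,
            "t_leaf": 25.0,
            "t_air": 25.0,
            "ppfd": 1200.0,
            "pressure": 101.325,
        }
    )


@pytest.fixture
def leaf_frame():
    return make_leaf_frame()


@pytest.fixture
def leaf_curve(leaf_frame):
    return Curve(leaf_frame, role=CurveRole.RACIR)
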