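"""Shared fixtures.

The cohort-simulation fixtures are session-scoped at populations of 6e6
with 10 replicates — the scale at which the Monte-Carlo standard error on
the youngest-cohort MAF difference drops below 1e-3, which the published
3-decimal MAF-difference values require.  They dominate the suite's run
time (about ten minutes on one CPU).
"""

from __future__ import annotations

import numpy as np
import pytest

from lodsim import build_architecture, config_from_preset
from lodsim.analysis import aggregate_cohort_runs
from lodsim.engine import run_cohort

SIM_N = 6_000_000
SIM_REPLICATES = 10
SIM_SEED = 1234

#: largest-effect tracked allele (MAF 0.5, OR 1.15)
TOP_VARIANT = "s1_m5_o1"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def scenario_a_arch():
    return build_architecture("A", target_h2=0.31)


def _cohort_aggregate(preset: str):
    cfg = config_from_preset(
        preset, n_population=SIM_N, mode="cohort", seed=SIM_SEED
    )
    runs = [run_cohort(cfg, replicate=i) for i in range(SIM_REPLICATES)]
    return cfg, runs, aggregate_cohort_runs(runs)


@pytest.fixture(scope="session")
def lung_cohort():
    return _cohort_aggregate("lung")


@pytest.fixture(scope="session")
def breast_cohort():
    return _cohort_aggregate("breast")


@pytest.fixture(scope="session")
def stroke_cohort():
    return _cohort_aggregate("stroke")
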