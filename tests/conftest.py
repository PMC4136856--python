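"""Shared fixtures: small generated landscapes and the constructed valley
scenario case used across connectivity, scenario and end-to-end tests."""

from __future__ import annotations

import pytest

import corridorscape as cs
from corridorscape import scenarios as scen
from corridorscape.benchmarks import valley_scenario_case


@pytest.fixture(scope="session")
def small_landscape():
    cfg = cs.LandscapeConfig(n_rows=40, n_cols=50, seed=3)
    stack, features = cs.generate_landscape(cfg)
    return cfg, stack, features


@pytest.fixture(scope="session")
def valley_case():
    return valley_scenario_case(seed=11)


@pytest.fixture(scope="session")
def valley_matrix(valley_case):
    return scen.scenario_costs(
        valley_case["stack"], valley_case["features"],
        valley_case["scenarios"], valley_case["avg"], valley_case["paths"])
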