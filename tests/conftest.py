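"""Shared fixtures: calibrated scenario runs are expensive (tens of seconds)
and deterministic, so they are computed once per session."""

from __future__ import annotations

from dataclasses import replace

import pytest

from sizecheck import (CellGeometry, Mesh, MTParams, ScenarioConfig,
                       run_scenario, simulate_mt)


@pytest.fixture(scope="session")
def geom():
    return CellGeometry()


@pytest.fixture(scope="session")
def mesh():
    return Mesh(100)


@pytest.fixture(scope="session")
def mt_traj_wt():
    """Calibrated wild-type MT subsystem on a 0.1-min grid."""
    return simulate_mt(MTParams(), CellGeometry(), t_end=100.0, sample_dt=0.1)


@pytest.fixture(scope="session")
def wt_result():
    return run_scenario(ScenarioConfig.preset("wt"))


@pytest.fixture(scope="session")
def lat_a_result():
    return run_scenario(ScenarioConfig.preset("lat_a"))


@pytest.fixture(scope="session")
def mbc_result():
    return run_scenario(ScenarioConfig.preset("mbc"))


@pytest.fixture(scope="session")
def pom1_oe2_result():
    return run_scenario(ScenarioConfig.preset("pom1_oe", pom1_oe_factor=2.0))


@pytest.fixture(scope="session")
def pom1_oe3_result():
    return run_scenario(ScenarioConfig.preset("pom1_oe", pom1_oe_factor=3.0))


@pytest.fixture(scope="session")
def single_step_result():
    """Wild type with the single-step (n_sites = 0) expulsion variant."""
    cfg = ScenarioConfig.preset("wt")
    return run_scenario(replace(cfg, kinetics=replace(cfg.kinetics, n_sites=0)))


@pytest.fixture(scope="session")
def newborn_result():
    """Wild type started from the asymmetric newborn profile."""
    cfg = ScenarioConfig.preset("wt")
    return run_scenario(replace(cfg, profile_kind="newborn"))


@pytest.fixture(scope="session")
def feeds_off_result():
    """Wild type with all production terms off (conservation check)."""
    cfg = ScenarioConfig.preset("wt")
    cfg = replace(cfg, t_end=100.0,
                  kinetics=replace(cfg.kinetics, feed_P=0.0, feed_C=0.0))
    return run_scenario(cfg)
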