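"""Shared fixtures: small-bounds constraints and reusable simulation batches."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from isodom.assignment import AssignmentConstraints, ElementBounds
from isodom.pipeline import run_incubation
from isodom.simulate import (
    SimConfig,
    evaluate_recovery,
    generate_world,
    render_peaklists,
    simulate_kinetics,
)
from isodom.timeseries import build_timeseries, mean_labeling, summed_intensity

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

#: seeds of the multi-seed benchmark batches, fixed once
BATCH_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def small_constraints() -> AssignmentConstraints:
    """Bounds small enough for the brute-force reference to be fast."""
    return AssignmentConstraints(
        bounds=ElementBounds(c_max=12, h_max=26, n_max=2, o_max=8,
                             p_max=1, s_max=1),
        isotope_mode="mixed")


def _run_scenario(config: SimConfig) -> dict:
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    runs, truth = render_peaklists(traj, config)
    result = run_incubation(runs, config.constraints)
    table = build_timeseries(result.samples)
    t0, t_end = config.timepoints[0], config.timepoints[-1]
    medians = {
        k: table.loc[table["heteroatom_class"] == k, "n_timepoints"].median()
        for k in ("CHO", "N", "P")}
    return {
        "config": config,
        "world": world,
        "trajectory": traj,
        "runs": runs,
        "truth": truth,
        "result": result,
        "table": table,
        "recovery": evaluate_recovery(truth, result),
        "drop_pipeline": mean_labeling(table, t0) - mean_labeling(table, t_end),
        "drop_expected": (traj.expected_mean_labeling(t0)
                          - traj.expected_mean_labeling(t_end)),
        "summed_ratio": summed_intensity(table, t_end) / summed_intensity(table, t0),
        "class_medians": medians,
    }


@pytest.fixture(scope="session")
def default_batch() -> list[dict]:
    """The default scenario (decay + fragments + recombination), 20 seeds."""
    return [_run_scenario(SimConfig(seed=seed)) for seed in BATCH_SEEDS]


@pytest.fixture(scope="session")
def breakdown_batch() -> list[dict]:
    """Decay-only scenario for persistence ordering: recombination switched
    off so presence groups reflect class kinetics, not formula relabeling."""
    return [_run_scenario(SimConfig(seed=seed, recombination_prob=0.0))
            for seed in BATCH_SEEDS]


@pytest.fixture(scope="session")
def default_scenario(default_batch) -> dict:
    """One fully materialized default-scenario run for detailed checks."""
    return default_batch[0]


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A miniature world for fast structural tests."""
    return SimConfig(seed=5, n_ambient=40, n_substrate=12, n_precursors=2)
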