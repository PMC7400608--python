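"""Generator determinism, world structure, kinetics and the 13C ledger."""

import dataclasses
import math

import numpy as np
import pytest

from isodom.formulas import heteroatom_class, ion_mz, labeling_percent
from isodom.pipeline import write_peak_table
from isodom.simulate import (
    SimConfig,
    expected_consensus_survival,
    generate_world,
    render_peaklists,
    render_tracer_series,
    simulate_kinetics,
    write_simulation,
)


def test_world_is_deterministic_under_seed(tiny_config):
    w1 = generate_world(tiny_config)
    w2 = generate_world(tiny_config)
    assert [(s.formula, s.a0, s.k) for s in w1.species] \
        == [(s.formula, s.a0, s.k) for s in w2.species]


def test_rendered_files_byte_identical(tiny_config, tmp_path):
    for sub in ("a", "b"):
        world = generate_world(tiny_config)
        traj = simulate_kinetics(world, tiny_config)
        runs, _ = render_peaklists(traj, tiny_config)
        write_peak_table(runs, tmp_path / f"{sub}.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_class_allocation_is_deterministic():
    config = SimConfig(seed=2, n_ambient=30, n_substrate=60, n_precursors=0)
    world = generate_world(config)
    counts = {}
    for sp in world.species:
        if sp.kind == "substrate":
            counts[sp.klass] = counts.get(sp.klass, 0) + 1
    assert counts == {"CHO": 24, "N": 18, "P": 12, "NP": 6}


def test_substrate_is_two_percent_of_total(tiny_config):
    world = generate_world(tiny_config)
    labeled = sum(sp.a0 for sp in world.species if sp.labeled)
    total = sum(sp.a0 for sp in world.species)
    assert labeled / total == pytest.approx(0.02, rel=1e-9)


def test_world_formulas_screened_unique(tiny_config):
    """Every labeled world formula is fully 13C and pairwise separated by
    more than the assignment tolerance."""
    world = generate_world(tiny_config)
    labeled = [sp for sp in world.species if sp.labeled]
    assert all(sp.formula.c12 == 0 for sp in labeled)
    mzs = sorted(ion_mz(sp.formula) for sp in world.species)
    gaps_ppm = np.diff(mzs) / np.array(mzs[:-1]) * 1e6
    assert gaps_ppm.min() > tiny_config.screen_ppm


def test_ambiguity_pair_on_request(tiny_config):
    config = dataclasses.replace(tiny_config, include_ambiguity_pair=True)
    world = generate_world(config)
    f1, f2 = world.ambiguity_pair
    mz1, mz2 = ion_mz(f1), ion_mz(f2)
    assert abs(mz2 - mz1) / mz1 * 1e6 < 0.3


def test_infeasible_request_raises():
    from isodom.assignment import AssignmentConstraints, ElementBounds
    tiny_space = AssignmentConstraints(bounds=ElementBounds(
        c_max=8, h_max=18, n_max=0, o_max=5, p_max=0, s_max=0))
    config = SimConfig(seed=0, n_ambient=10_000, n_substrate=1, n_precursors=0,
                       constraints=tiny_space)
    with pytest.raises(ValueError, match="exhausted"):
        generate_world(config)


def test_null_kinetics_constant_abundance(tiny_config):
    config = dataclasses.replace(tiny_config, k_cho=0.0, k_n=0.0, k_p=0.0,
                                 recombination_prob=0.0,
                                 remineralized_share=0.0)
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    for i, sp in enumerate(world.species):
        if sp.kind != "fragment":
            assert np.allclose(traj.abundance[i], sp.a0)
    assert traj.remineralized13[-1] == 0.0


def test_exponential_decay_closed_form(tiny_config):
    """k = ln2 / 3h: 40% remaining after 4 h (half-life 3 h)."""
    k = math.log(2) / 0.125  # per day
    config = dataclasses.replace(tiny_config, k_p=k, recombination_prob=0.0)
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    j = traj.times.index(4.0)
    for i, sp in enumerate(world.species):
        if sp.kind == "substrate" and sp.klass == "P":
            assert traj.abundance[i, j] / sp.a0 == pytest.approx(
                math.exp(-k * 4 / 24), rel=1e-12)
            assert traj.abundance[i, j] / sp.a0 == pytest.approx(0.397, abs=0.001)


def test_mass_ledger_conserves_13c(default_batch):
    for scenario in default_batch[:5]:
        traj = scenario["trajectory"]
        total = (traj.remaining13 + traj.remineralized13
                 + traj.transformed13 + traj.exchanged13)
        assert total == pytest.approx(traj.init13, rel=1e-9)


def test_recombination_expected_labeling_closed_form():
    """Simulated mean labeling matches the closed-form expectation."""
    drops_sim, drops_exp = [], []
    for seed in range(25):
        config = SimConfig(seed=seed, n_ambient=30, n_substrate=30,
                           n_precursors=0, k_cho=0.0, k_n=0.0, k_p=0.0,
                           dropout=0.0)
        world = generate_world(config)
        traj = simulate_kinetics(world, config)
        labs = [labeling_percent(traj.formula_at(i, 28.0))
                for i, sp in enumerate(world.species) if sp.kind == "substrate"]
        drops_sim.append(100.0 - float(np.mean(labs)))
        drops_exp.append(100.0 - traj.expected_mean_labeling(28.0))
    se = np.std(drops_sim, ddof=1) / np.sqrt(len(drops_sim))
    assert abs(np.mean(drops_sim) - np.mean(drops_exp)) < 3 * se + 0.5


def test_expected_survival_closed_form_values():
    assert expected_consensus_survival(0.4) == pytest.approx(0.648)
    assert expected_consensus_survival(0.0) == 1.0
    assert expected_consensus_survival(1.0) == 0.0


def test_tracer_series_shapes_and_flat_when_zero(tiny_config):
    config = dataclasses.replace(tiny_config, k_cho=0.0, k_n=0.0, k_p=0.0,
                                 remineralized_share=0.5,
                                 fixation_rate_um_per_day=0.0,
                                 tracer_noise_um=0.0, tracer_noise_atpercent=0.0)
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    tracer = render_tracer_series(traj, config)
    dic = tracer[(tracer["analyte"] == "DIC")]
    assert dic["value"].abs().max() == pytest.approx(0.0)
    poc = tracer[(tracer["analyte"] == "POC")
                 & (tracer["kind"] == "atom_percent_13c")]
    assert poc["value"].std() == pytest.approx(0.0)


def test_write_simulation_outputs(tiny_config, tmp_path):
    artifacts = write_simulation(tmp_path, tiny_config)
    for name in ("peaks.tsv", "truth.tsv", "tracer.tsv", "config.yaml"):
        assert (tmp_path / name).exists()
    assert len(artifacts["runs"]) == 4 * 3 + 1 * 3  # DO13C + control at t0
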