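"""Diversification metrics: presence groups, class composition, ratios."""

import numpy as np
import pandas as pd
import pytest

from isodom.formulas import MolecularFormula, ion_mz
from isodom.simulate import SimConfig, generate_world, render_peaklists, simulate_kinetics
from isodom.pipeline import run_incubation
from isodom.timeseries import (
    build_timeseries,
    class_composition,
    mean_labeling,
    presence_patterns,
    ratio_summary,
    summary_table,
    summed_intensity,
)


def _table(rows):
    """rows: list of (formula, class, labeling, intensities-at-4-timepoints)."""
    data = {}
    for f, klass, lab, intens in rows:
        data[str(f)] = {
            "formula": f, "heteroatom_class": klass, "labeling_percent": lab,
            "ion_mz": ion_mz(f),
            **{f"intensity_{t:g}": v for t, v in zip((0, 4, 16, 28), intens)},
        }
    table = pd.DataFrame.from_dict(data, orient="index")
    cols = [c for c in table.columns if c.startswith("intensity_")]
    table["n_timepoints"] = (table[cols] > 0).sum(axis=1)
    return table


F1 = MolecularFormula(c13=6, h=12, o=6)
F2 = MolecularFormula(c13=5, c12=5, h=14, o=4)
F3 = MolecularFormula(c13=8, h=11, n=1, o=3)
F4 = MolecularFormula(c13=6, h=13, o=6, p=1)


def test_summed_intensity_and_empty_timepoint():
    table = _table([(F1, "CHO", 100, (0.01, 0, 0, 0)),
                    (F2, "CHO", 50, (0.02, 0, 0, 0))])
    assert summed_intensity(table, 0) == pytest.approx(0.03)
    assert summed_intensity(table, 16) == 0.0


def test_mean_labeling_unweighted_and_weighted():
    table = _table([(F1, "CHO", 100, (0.03, 0, 0, 0)),
                    (F2, "CHO", 60, (0.01, 0, 0, 0))])
    assert mean_labeling(table, 0) == pytest.approx(80.0)
    assert mean_labeling(table, 0, intensity_weighted=True) == pytest.approx(90.0)
    assert np.isnan(mean_labeling(table, 28))


def test_presence_groups_partition_table():
    table = _table([(F1, "CHO", 100, (1, 1, 1, 1)),
                    (F2, "CHO", 50, (1, 0, 1, 0)),
                    (F3, "N", 100, (0, 1, 0, 0)),
                    (F4, "P", 100, (1, 1, 0, 0))])
    groups = presence_patterns(table)
    assert groups["n_formulas"].sum() == len(table)
    assert groups.set_index("group")["n_formulas"].to_dict() == \
        {4: 1, 3: 0, 2: 2, 1: 1}


def test_class_composition_fractions():
    table = _table([(F1, "CHO", 100, (1, 1, 1, 1)),
                    (F2, "CHO", 50, (1, 1, 1, 1)),
                    (F3, "N", 100, (1, 1, 1, 1)),
                    (F4, "P", 100, (1, 1, 1, 1))])
    comp = class_composition(table)
    assert comp == {"CHO": 0.5, "N": 0.25, "P": 0.25, "NP": 0.0}
    assert sum(comp.values()) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty group"):
        class_composition(table.iloc[0:0])


def test_ratio_summary_single_and_weighted_mass():
    glucose_like = MolecularFormula(c13=6, h=12, o=6)
    table = _table([(glucose_like, "CHO", 100, (0.01, 0, 0, 0))])
    ratios = ratio_summary(table, 0)
    assert ratios["mean_hc"] == pytest.approx(2.0)
    assert ratios["mean_oc"] == pytest.approx(1.0)

    light = MolecularFormula(c13=4, h=8, o=2)
    heavy = MolecularFormula(c13=14, h=22, o=6)
    table2 = _table([(light, "CHO", 100, (0.01, 0, 0, 0)),
                     (heavy, "CHO", 100, (0.01, 0, 0, 0))])
    expected = (ion_mz(light) + ion_mz(heavy)) / 2
    assert ratio_summary(table2, 0)["weighted_mean_mass"] == pytest.approx(expected)


def test_build_timeseries_union_and_groups(default_scenario):
    samples = default_scenario["result"].samples
    table = default_scenario["table"]
    all_formulas = set().union(*(s.table["formula_str"] for s in samples.values()))
    assert set(table.index) == all_formulas
    assert (table["n_timepoints"] >= 1).all()
    # distinct-formula count close to the generator's detectable ground truth
    truth = default_scenario["truth"]
    truth_count = truth.loc[truth["detectable"], "formula_str"].nunique()
    assert abs(len(table) - truth_count) <= 0.2 * truth_count


def test_headline_dynamics_on_default_scenario(default_batch):
    """Summed intensity and mean labeling decline over the incubation."""
    for scenario in default_batch[:10]:
        assert scenario["summed_ratio"] < 1.0
        assert scenario["drop_pipeline"] > 0.0


def test_summary_table_columns(default_scenario):
    summary = summary_table(default_scenario["table"])
    assert list(summary["timepoint_h"]) == [0.0, 4.0, 16.0, 28.0]
    assert (summary["n_formulas"] > 0).all()


def test_stationary_ratios_without_class_bias():
    """With equal decay rates and no recombination, mean H:C drifts < 5%."""
    config = SimConfig(seed=3, n_ambient=150, n_substrate=40, n_precursors=0,
                       k_n=1.386, k_p=1.386, recombination_prob=0.0)
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    runs, _ = render_peaklists(traj, config)
    result = run_incubation(runs, config.constraints)
    table = build_timeseries(result.samples)
    hc = [ratio_summary(table, t)["mean_hc"] for t in (0, 4, 16, 28)]
    assert max(hc) / min(hc) - 1 < 0.05
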