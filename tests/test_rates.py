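"""Tracer rate arithmetic: APE clamping, OLS slopes, fixation, C:N."""

import numpy as np
import pytest

from isodom.rates import (
    NATURAL_BASELINE_PERCENT,
    atom_percent_excess,
    cn_ratio,
    co2_fixation_rate,
    dom_remineralization_rate,
    linear_rate,
    remineralized_fraction,
)
from isodom.simulate import simulate_tracer_linear


@pytest.mark.parametrize("at, baseline, expected", [
    (1.1, 1.1, 0.0),
    (11.1, 1.1, 10.0),
    (0.9, 1.1, 0.0),    # below baseline clamps to zero, never negative
])
def test_atom_percent_excess(at, baseline, expected):
    assert atom_percent_excess(at, baseline) == pytest.approx(expected)


def test_natural_baseline_matches_mass_table():
    assert NATURAL_BASELINE_PERCENT == pytest.approx(1.07)


def test_excess_concentration_scaling():
    from isodom.rates import excess_concentration
    # 0.1 atom-percent excess of a 2,000 uM DIC pool is 2 uM excess 13C
    assert excess_concentration(1.17, 2000.0) == pytest.approx(2.0)
    assert excess_concentration(0.9, 2000.0) == 0.0
    with pytest.raises(ValueError):
        excess_concentration(2.0, 0.0)


def test_linear_rate_two_point_line():
    est = linear_rate([0.0, 24.0], [0.0, 0.5])
    assert est.slope_um_per_day == pytest.approx(0.5)
    assert est.n_points == 2


def test_linear_rate_flat_series():
    est = linear_rate([0, 4, 16, 28], [0.2, 0.2, 0.2, 0.2])
    assert est.slope_um_per_day == pytest.approx(0.0, abs=1e-12)


def test_linear_rate_unit_coherence():
    """Hour-spaced inputs give a per-day slope 24x the per-hour slope."""
    t = np.array([0.0, 4.0, 16.0, 28.0])
    y = 0.02 * t  # 0.02 uM per hour
    est = linear_rate(t, y)
    assert est.slope_um_per_day == pytest.approx(0.48)


def test_linear_rate_requires_spread():
    with pytest.raises(ValueError):
        linear_rate([4.0, 4.0], [0.1, 0.2])
    with pytest.raises(ValueError):
        linear_rate([0.0], [0.1])


def test_linear_rate_unbiased_over_seeds():
    """Mean slope estimate over 100 noisy series is within 1 SE of truth."""
    slopes, ses = [], []
    for seed in range(100):
        t, y = simulate_tracer_linear(0.5, noise_um=0.02, seed=seed)
        est = linear_rate(t, y)
        slopes.append(est.slope_um_per_day)
        ses.append(est.stderr_um_per_day)
    se_of_mean = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 0.5) < max(se_of_mean, 1e-3)


@pytest.mark.parametrize("slope, fraction, expected", [
    (0.495, 0.99, 0.5),
    (0.7, 1.0, 0.7),
    (0.0, 0.99, 0.0),
])
def test_dom_remineralization_rate_label_correction(slope, fraction, expected):
    est = dom_remineralization_rate([0.0, 24.0], [0.0, slope], fraction)
    assert est.slope_um_per_day == pytest.approx(expected)


@pytest.mark.parametrize("rate, added, expected", [
    (0.5, 2.0, 25.0),
    (0.0, 5.0, 0.0),
    (2.0, 2.0, 100.0),
])
def test_remineralized_fraction(rate, added, expected):
    assert remineralized_fraction(rate, added) == pytest.approx(expected)


def test_remineralized_fraction_requires_positive_addition():
    with pytest.raises(ValueError):
        remineralized_fraction(0.5, 0.0)


def test_co2_fixation_rate_ape_ratio():
    # APE_POC 1%, APE_DIC 10%, 6 uM POC over one day -> 0.6 uM/d
    rate = co2_fixation_rate(poc_at_percent_t=2.1, poc_at_percent_0=1.1,
                             dic_label_at_percent=11.1, poc_um=6.0, dt_h=24.0,
                             baseline_percent=1.1)
    assert rate == pytest.approx(0.6)
    assert co2_fixation_rate(1.1, 1.1, 11.1, 6.0, 24.0,
                             baseline_percent=1.1) == 0.0
    with pytest.raises(ValueError):
        co2_fixation_rate(2.1, 1.1, 1.1, 6.0, 24.0, baseline_percent=1.1)


def test_cn_ratio():
    assert cn_ratio(17.0, 1.0) == pytest.approx(17.0)
    assert cn_ratio(106.0, 16.0) == pytest.approx(6.625)
    with pytest.raises(ValueError):
        cn_ratio(10.0, 0.0)
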