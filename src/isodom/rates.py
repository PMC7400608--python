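"""Bulk isotope-tracer rate arithmetic.

Rates are derived from bulk measurements that accompany the molecular data:
the 13CO2 (excess dissolved inorganic 13C) production curve gives the
substrate remineralization rate, and 13C incorporation into particulate
organic carbon gives the CO2 fixation rate via the standard atom-percent-
excess (APE) tracer equation

    rate = (APE_POC / APE_DIC) x [POC] / dt,

where APE is the measured 13C atom percent minus the natural-abundance
baseline (1.1 atom%).  Hour-spaced inputs are converted to per-day rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formulas import DEFAULT_MASSES

__all__ = [
    "RateEstimate",
    "NATURAL_BASELINE_PERCENT",
    "atom_percent_excess",
    "excess_concentration",
    "linear_rate",
    "dom_remineralization_rate",
    "remineralized_fraction",
    "co2_fixation_rate",
    "cn_ratio",
]

HOURS_PER_DAY = 24.0

#: Natural 13C abundance baseline on the atom-percent scale.
NATURAL_BASELINE_PERCENT = 100.0 * DEFAULT_MASSES.natural_13c_fraction


@dataclass(frozen=True)
class RateEstimate:
    """An ordinary-least-squares rate: slope and SE in µM per day."""

    slope_um_per_day: float
    stderr_um_per_day: float
    intercept_um: float
    n_points: int


def atom_percent_excess(at_percent: float,
                        baseline_percent: float = NATURAL_BASELINE_PERCENT
                        ) -> float:
    """13C atom percent above the natural baseline, clamped at zero.

    Measurements scattering below the baseline are noise, not negative
    enrichment, hence the clamp.
    """
    return max(at_percent - baseline_percent, 0.0)


def excess_concentration(at_percent: float, pool_um: float,
                         baseline_percent: float = NATURAL_BASELINE_PERCENT
                         ) -> float:
    """Convert a pool's 13C atom percent into excess-13C concentration (µM).

    For dissolved inorganic carbon a typical surface-seawater pool is
    ~2,000 µM; measurements reported as atom percent are converted with
    excess = APE x pool / 100 before regression.
    """
    if pool_um <= 0:
        raise ValueError("pool concentration must be positive")
    return atom_percent_excess(at_percent, baseline_percent) * pool_um / 100.0


def linear_rate(time_h, excess_um) -> RateEstimate:
    """OLS slope of excess tracer concentration (µM) vs time, in µM per day.

    Replicate values are passed as repeated time points; all points enter
    the regression individually.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(excess_um, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need at least two (time, value) points")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical; slope undefined")
    fit = stats.linregress(t, y)
    return RateEstimate(
        slope_um_per_day=fit.slope * HOURS_PER_DAY,
        stderr_um_per_day=float(fit.stderr) * HOURS_PER_DAY,
        intercept_um=fit.intercept,
        n_points=int(t.size),
    )


def dom_remineralization_rate(time_h, excess_13co2_um,
                              substrate_label_fraction: float = 0.99
                              ) -> RateEstimate:
    """Substrate remineralization rate from the excess 13CO2 curve.

    The OLS slope is divided by the substrate's 13C label fraction so the
    rate refers to total substrate carbon, not only its labeled part.
    """
    if not (0 < substrate_label_fraction <= 1):
        raise ValueError("substrate_label_fraction must be in (0, 1]")
    est = linear_rate(time_h, excess_13co2_um)
    return RateEstimate(
        slope_um_per_day=est.slope_um_per_day / substrate_label_fraction,
        stderr_um_per_day=est.stderr_um_per_day / substrate_label_fraction,
        intercept_um=est.intercept_um,
        n_points=est.n_points,
    )


def remineralized_fraction(rate_um_per_day: float, added_um: float) -> float:
    """Percent of the added substrate carbon remineralized per day."""
    if added_um <= 0:
        raise ValueError("added substrate concentration must be positive")
    return 100.0 * rate_um_per_day / added_um


def co2_fixation_rate(poc_at_percent_t: float,
                      poc_at_percent_0: float,
                      dic_label_at_percent: float,
                      poc_um: float,
                      dt_h: float,
                      baseline_percent: float = NATURAL_BASELINE_PERCENT
                      ) -> float:
    """CO2 fixation rate (µM C per day) from 13C incorporation into biomass.

    ``poc_at_percent_0`` is the biomass 13C atom percent at the start of the
    incubation (the incorporation baseline); ``dic_label_at_percent`` is the
    labeling of the dissolved inorganic carbon pool.
    """
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    ape_dic = dic_label_at_percent - baseline_percent
    if ape_dic <= 0:
        raise ValueError("DIC labeling is at or below natural abundance; "
                         "fixation rate undefined")
    ape_poc = max(poc_at_percent_t - poc_at_percent_0, 0.0)
    return (ape_poc / ape_dic) * poc_um / (dt_h / HOURS_PER_DAY)


def cn_ratio(c_um: float, n_um: float) -> float:
    """Molar carbon-to-nitrogen ratio."""
    if n_um == 0:
        raise ValueError("nitrogen concentration is zero; C:N undefined")
    return c_um / n_um
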