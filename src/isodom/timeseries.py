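"""Time-series diversification metrics for labeled-molecule tables.

Given the final labeled tables at the four incubation time points, these
functions compute the quantities used to describe molecular diversification:
distinct-formula counts, summed normalized intensity, the mean labeling
percentage of the detected molecules, presence-pattern groups (detected at
4, 3, 2 or 1 time points), per-group heteroatom-class composition, and
elemental-ratio (H:C, O:C) summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import AssignedSample

__all__ = [
    "build_timeseries",
    "timepoint_columns",
    "summed_intensity",
    "mean_labeling",
    "presence_patterns",
    "class_composition",
    "ratio_summary",
    "summary_table",
]

CLASSES = ("CHO", "N", "P", "NP")


def timepoint_columns(table: pd.DataFrame) -> dict[float, str]:
    """Map time point (h) -> intensity column name of a time-series table."""
    out = {}
    for col in table.columns:
        if col.startswith("intensity_"):
            out[float(col.split("_", 1)[1])] = col
    return dict(sorted(out.items()))


def build_timeseries(samples: dict[float, AssignedSample]) -> pd.DataFrame:
    """Union the per-time-point tables into one per-formula time series.

    One row per distinct formula; ``intensity_<t>`` columns hold the mean
    normalized intensity at each time point (0 where not detected).  The
    heteroatom class, labeling percentage and ion mass derive from the
    formula and are constant per row.  ``n_timepoints`` counts time points
    with non-zero intensity (the presence group).
    """
    if not samples:
        raise ValueError("no samples supplied")
    times = sorted(samples)
    rows: dict[str, dict] = {}
    for t in times:
        for rec in samples[t].table.itertuples():
            row = rows.setdefault(rec.formula_str, {
                "formula": rec.formula,
                "heteroatom_class": rec.heteroatom_class,
                "labeling_percent": rec.labeling_percent,
                "ion_mz": rec.ion_mz,
                **{f"intensity_{u:g}": 0.0 for u in times},
            })
            row[f"intensity_{t:g}"] = rec.intensity
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "formula_str"
    intensity_cols = [f"intensity_{u:g}" for u in times]
    table["n_timepoints"] = (table[intensity_cols] > 0).sum(axis=1)
    return table.sort_index()


def _column(table: pd.DataFrame, timepoint: float) -> str:
    col = f"intensity_{timepoint:g}"
    if col not in table.columns:
        raise KeyError(f"no time point {timepoint} in table")
    return col


def summed_intensity(table: pd.DataFrame, timepoint: float) -> float:
    """Summed normalized intensity of all labeled molecules at a time point."""
    return float(table[_column(table, timepoint)].sum())


def mean_labeling(table: pd.DataFrame, timepoint: float,
                  intensity_weighted: bool = False) -> float:
    """Average labeling percentage over molecules detected at a time point.

    Unweighted by default (every detected molecule counts equally); the
    intensity-weighted variant is available as an option.
    """
    col = _column(table, timepoint)
    detected = table[table[col] > 0]
    if detected.empty:
        return float("nan")
    if intensity_weighted:
        return float(np.average(detected["labeling_percent"],
                                weights=detected[col]))
    return float(detected["labeling_percent"].mean())


def presence_patterns(table: pd.DataFrame) -> pd.DataFrame:
    """Partition formulas by the number of time points at which they appear.

    Returns one row per presence group (4, 3, 2, 1) with the member count
    and the heteroatom-class composition fractions; groups partition the
    table, so the counts sum to the number of rows.
    """
    n_times = len(timepoint_columns(table))
    records = []
    for group in range(n_times, 0, -1):
        members = table[table["n_timepoints"] == group]
        rec = {"group": group, "n_formulas": len(members)}
        if len(members):
            comp = class_composition(members)
        else:
            comp = {k: float("nan") for k in CLASSES}
        rec.update({f"frac_{k}": comp[k] for k in CLASSES})
        records.append(rec)
    return pd.DataFrame(records)


def class_composition(members: pd.DataFrame) -> dict[str, float]:
    """Heteroatom-class fractions of a set of formulas (rows)."""
    if len(members) == 0:
        raise ValueError("empty group has no class composition")
    counts = members["heteroatom_class"].value_counts()
    return {k: float(counts.get(k, 0)) / len(members) for k in CLASSES}


def ratio_summary(table: pd.DataFrame, timepoint: float) -> dict[str, float]:
    """Mean H:C, mean O:C and intensity-weighted mean ion mass at a time point."""
    col = _column(table, timepoint)
    detected = table[table[col] > 0]
    if detected.empty:
        return {"mean_hc": float("nan"), "mean_oc": float("nan"),
                "weighted_mean_mass": float("nan")}
    formulas = detected["formula"]
    hc = np.array([f.h / f.c_total for f in formulas])
    oc = np.array([f.o / f.c_total for f in formulas])
    return {
        "mean_hc": float(hc.mean()),
        "mean_oc": float(oc.mean()),
        "weighted_mean_mass": float(np.average(detected["ion_mz"],
                                               weights=detected[col])),
    }


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point summary: count, summed intensity, labeling, ratios."""
    records = []
    for t in timepoint_columns(table):
        ratios = ratio_summary(table, t)
        col = _column(table, t)
        records.append({
            "timepoint_h": t,
            "n_formulas": int((table[col] > 0).sum()),
            "summed_intensity": summed_intensity(table, t),
            "mean_labeling_percent": mean_labeling(table, t),
            **ratios,
        })
    return pd.DataFrame(records)
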