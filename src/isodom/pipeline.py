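"""Replicate peak tables -> consensus, normalized, formula-assigned samples.

The processing chain per sample (one treatment x time point, measured in
triplicate across five quadrupole mass windows):

1. merge peaks duplicated across overlapping mass windows (keep the more
   intense record, so window overlap cannot double-count intensity);
2. normalize every replicate run to its summed intensity over all windows;
3. two-pass formula assignment — pass 1 considers only 12C formulas, pass 2
   opens the 13C dimension for the peaks pass 1 could not uniquely explain;
4. replicate consensus — a formula is retained only when uniquely assigned
   within tolerance in at least 2 of 3 runs, at the mean of its normalized
   intensities over the runs where it was found;
5. labeled-molecule filtering (labeling >= 50%, ion m/z inside 90-391) and
   subtraction of anything also present in the unlabeled-control table.

Steps 3-5 implement a deliberately conservative scheme: every surviving
record is uniquely assigned, replicate-confirmed, highly labeled and inside
the unambiguous mass range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assignment import AssignmentConstraints, PeakAssignment, assign_peak
from .formulas import (
    DEFAULT_MASSES,
    ElementMassTable,
    MolecularFormula,
    heteroatom_class,
    ion_mz,
    labeling_percent,
)

logger = logging.getLogger("isodom.pipeline")

__all__ = [
    "Peak",
    "ReplicateRun",
    "AssignedPeak",
    "AssignedSample",
    "read_peak_table",
    "write_peak_table",
    "merge_window_overlaps",
    "normalize_run",
    "assign_run",
    "consensus_assignments",
    "subtract_control",
    "filter_labeled",
    "process_sample",
    "run_incubation",
    "IncubationResult",
]

PEAK_TABLE_COLUMNS = ["sample_id", "treatment", "timepoint_h", "replicate",
                      "window", "mz", "intensity"]

TREATMENTS = ("DO13C", "DI13C_control")


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    window: str

    def __post_init__(self) -> None:
        if not (0 < self.mz < 2000):
            raise ValueError(f"peak m/z {self.mz} outside (0, 2000)")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class ReplicateRun:
    """One replicate measurement of one sample (all mass windows)."""

    sample_id: str
    treatment: str
    timepoint_h: float
    replicate: int
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz)))

    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.peaks))


@dataclass(frozen=True)
class AssignedPeak:
    """A peak together with its (possibly empty) formula assignment."""

    mz: float
    intensity: float
    window: str
    assignment: PeakAssignment


@dataclass
class AssignedSample:
    """Consensus per-formula table for one sample.

    ``table`` columns: formula (object), formula_str, ion_mz,
    labeling_percent, heteroatom_class, intensity (mean normalized),
    n_replicates, mean_error_ppm, pass_number.
    """

    sample_id: str
    treatment: str
    timepoint_h: float
    table: pd.DataFrame
    log: dict = field(default_factory=dict)

    def formulas(self) -> set[MolecularFormula]:
        return set(self.table["formula"])


def read_peak_table(path) -> list[ReplicateRun]:
    """Read a delimited peak table (TSV or CSV) into validated runs.

    Malformed rows raise ``ValueError`` naming the offending line (1-based,
    counting the header as line 1).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    for col in ("mz", "intensity", "timepoint_h"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"non-numeric {col!r} at line {line}")
        df[col] = coerced
    if (df["intensity"] < 0).any():
        line = int((df["intensity"] < 0).idxmax()) + 2
        raise ValueError(f"negative intensity at line {line}")
    dup_key = ["sample_id", "treatment", "timepoint_h", "replicate", "window", "mz"]
    dups = df.duplicated(subset=dup_key)
    if dups.any():
        line = int(dups.idxmax()) + 2
        raise ValueError(f"duplicate (replicate, window, mz) record at line {line}")

    runs = []
    group_cols = ["sample_id", "treatment", "timepoint_h", "replicate"]
    for (sample_id, treatment, timepoint, replicate), grp in df.groupby(
            group_cols, sort=True):
        peaks = tuple(Peak(float(r.mz), float(r.intensity), str(r.window))
                      for r in grp.itertuples())
        runs.append(ReplicateRun(str(sample_id), str(treatment),
                                 float(timepoint), int(replicate), peaks))
    return runs


def write_peak_table(runs: list[ReplicateRun], path) -> None:
    records = [
        (run.sample_id, run.treatment, run.timepoint_h, run.replicate,
         p.window, p.mz, p.intensity)
        for run in runs for p in run.peaks
    ]
    pd.DataFrame(records, columns=PEAK_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def merge_window_overlaps(run: ReplicateRun, link_ppm: float = 0.5) -> ReplicateRun:
    """Collapse peaks reported by two overlapping windows into one record.

    Two peaks from *different* windows closer than ``link_ppm`` are treated
    as one physical ion measured twice; the more intense record wins.
    Without this, window overlap would double-count intensity in the
    run-level normalization.
    """
    peaks = sorted(run.peaks, key=lambda p: p.mz)
    merged: list[Peak] = []
    for peak in peaks:
        if merged:
            prev = merged[-1]
            if (peak.window != prev.window
                    and (peak.mz - prev.mz) / prev.mz * 1e6 < link_ppm):
                if peak.intensity > prev.intensity:
                    merged[-1] = peak
                continue
        merged.append(peak)
    return replace(run, peaks=tuple(merged))


def normalize_run(run: ReplicateRun) -> ReplicateRun:
    """Divide every intensity by the run's total over all windows."""
    total = run.total_intensity()
    if total <= 0:
        raise ValueError(f"run {run.sample_id}/r{run.replicate} has zero "
                         "total intensity; cannot normalize")
    peaks = tuple(Peak(p.mz, p.intensity / total, p.window) for p in run.peaks)
    return replace(run, peaks=peaks)


def assign_run(run: ReplicateRun,
               constraints: AssignmentConstraints,
               masses: ElementMassTable = DEFAULT_MASSES) -> list[AssignedPeak]:
    """Two-pass assignment of every peak in a replicate run.

    Pass 1 enumerates 12C-only formulas; peaks it assigns uniquely never
    reach pass 2.  Pass 2 opens c13 in 0..C for the remaining peaks.  No
    peak ever carries assignments from both passes.
    """
    pass1 = constraints.with_mode("c12_only")
    pass2 = constraints.with_mode("mixed")
    out: list[AssignedPeak] = []
    for peak in run.peaks:
        result = assign_peak(peak.mz, pass1, masses)
        if result.status != "unique":
            result = assign_peak(peak.mz, pass2, masses)
        out.append(AssignedPeak(peak.mz, peak.intensity, peak.window, result))
    n1 = sum(1 for a in out if a.assignment.status == "unique"
             and a.assignment.pass_number == 1)
    n2 = sum(1 for a in out if a.assignment.status == "unique"
             and a.assignment.pass_number == 2)
    namb = sum(1 for a in out if a.assignment.status == "ambiguous")
    logger.info("%s/r%d: %d peaks, %d pass-1 unique, %d pass-2 unique, "
                "%d ambiguous, %d unassigned", run.sample_id, run.replicate,
                len(out), n1, n2, namb, len(out) - n1 - n2 - namb)
    return out


def consensus_assignments(run_assignments: list[list[AssignedPeak]],
                          sample_id: str = "",
                          treatment: str = "",
                          timepoint_h: float = 0.0,
                          masses: ElementMassTable = DEFAULT_MASSES,
                          min_replicates: int = 2) -> AssignedSample:
    """Replicate consensus: keep formulas uniquely assigned in >=2 of 3 runs.

    Replicates are linked by identical formula, not by m/z clustering, which
    sidesteps peak-alignment ambiguity entirely.  The retained intensity is
    the mean of the normalized intensities over the runs where the formula
    was detected.
    """
    if len(run_assignments) < 2:
        raise ValueError("consensus needs at least 2 replicate runs")
    per_formula: dict[MolecularFormula, list[AssignedPeak]] = {}
    for run in run_assignments:
        seen: dict[MolecularFormula, AssignedPeak] = {}
        for ap in run:
            if ap.assignment.status != "unique":
                continue
            f = ap.assignment.formula
            if f not in seen or ap.intensity > seen[f].intensity:
                seen[f] = ap
        for f, ap in seen.items():
            per_formula.setdefault(f, []).append(ap)

    records = []
    for f, hits in sorted(per_formula.items()):
        if len(hits) < min_replicates:
            continue
        records.append({
            "formula": f,
            "formula_str": str(f),
            "ion_mz": ion_mz(f, masses),
            "labeling_percent": labeling_percent(f),
            "heteroatom_class": heteroatom_class(f),
            "intensity": float(np.mean([h.intensity for h in hits])),
            "n_replicates": len(hits),
            "mean_error_ppm": float(np.mean([h.assignment.error_ppm for h in hits])),
            "pass_number": max(h.assignment.pass_number for h in hits),
        })
    table = pd.DataFrame(records, columns=[
        "formula", "formula_str", "ion_mz", "labeling_percent",
        "heteroatom_class", "intensity", "n_replicates", "mean_error_ppm",
        "pass_number"])
    return AssignedSample(sample_id, treatment, timepoint_h, table,
                          log={"n_formulas_any": len(per_formula),
                               "n_formulas_consensus": len(records)})


def subtract_control(sample: AssignedSample,
                     control_t0: AssignedSample) -> tuple[AssignedSample, int]:
    """Remove formulas that also occur in the control's 0 h table.

    A safeguard against ambient molecules leaking into the labeled table;
    with a >=50% labeling filter upstream it is expected to remove nothing,
    and the number actually removed is logged.
    """
    control_formulas = control_t0.formulas()
    mask = ~sample.table["formula"].isin(control_formulas)
    removed = int((~mask).sum())
    logger.info("%s: control subtraction removed %d formulas",
                sample.sample_id, removed)
    out = AssignedSample(sample.sample_id, sample.treatment,
                         sample.timepoint_h,
                         sample.table[mask].reset_index(drop=True),
                         log={**sample.log, "control_removed": removed})
    return out, removed


def filter_labeled(sample: AssignedSample,
                   min_percent: float = 50.0,
                   mass_window: tuple[float, float] = (90.0, 391.0)
                   ) -> AssignedSample:
    """Keep records with labeling >= ``min_percent`` and ion m/z in the window.

    Both bounds of the mass window are inclusive; the window restricts the
    analysis to the range where isotopologue assignment stays unambiguous.
    """
    t = sample.table
    mask = (t["labeling_percent"] >= min_percent) \
        & (t["ion_mz"] >= mass_window[0]) & (t["ion_mz"] <= mass_window[1])
    kept = t[mask].reset_index(drop=True)
    logger.info("%s: labeled filter kept %d of %d formulas",
                sample.sample_id, len(kept), len(t))
    return AssignedSample(sample.sample_id, sample.treatment,
                          sample.timepoint_h, kept,
                          log={**sample.log,
                               "labeled_kept": len(kept),
                               "labeled_dropped": int(len(t) - len(kept))})


def process_sample(runs: list[ReplicateRun],
                   constraints: AssignmentConstraints,
                   masses: ElementMassTable = DEFAULT_MASSES) -> AssignedSample:
    """Merge windows, normalize, assign and build the consensus table."""
    if not runs:
        raise ValueError("no runs supplied")
    ids = {(r.sample_id, r.treatment, r.timepoint_h) for r in runs}
    if len(ids) != 1:
        raise ValueError(f"runs from different samples: {sorted(ids)}")
    prepared = [normalize_run(merge_window_overlaps(run)) for run in runs]
    for run in prepared:
        assert abs(run.total_intensity() - 1.0) < 1e-9
    assignments = [assign_run(run, constraints, masses) for run in prepared]
    sample_id, treatment, timepoint = next(iter(ids))
    return consensus_assignments(assignments, sample_id, treatment,
                                 timepoint, masses)


@dataclass
class IncubationResult:
    """Final labeled tables per time point, plus the control and a log."""

    samples: dict[float, AssignedSample]
    control_t0: AssignedSample
    log: dict


def run_incubation(runs: list[ReplicateRun],
                   constraints: AssignmentConstraints,
                   min_labeling_percent: float = 50.0,
                   mass_window: tuple[float, float] = (90.0, 391.0),
                   masses: ElementMassTable = DEFAULT_MASSES
                   ) -> IncubationResult:
    """Full pipeline over a mixed list of runs from both treatments.

    Amended (DO13C) samples at every time point are processed, filtered to
    labeled molecules and compared against the unlabeled-control 0 h table.
    """
    by_sample: dict[tuple[str, float], list[ReplicateRun]] = {}
    for run in runs:
        by_sample.setdefault((run.treatment, run.timepoint_h), []).append(run)

    control_key = ("DI13C_control", 0.0)
    if control_key not in by_sample:
        raise ValueError("no DI13C_control runs at 0 h found")
    control_t0 = process_sample(by_sample[control_key], constraints, masses)

    samples: dict[float, AssignedSample] = {}
    log: dict = {"control_removed": {}}
    for (treatment, timepoint), sample_runs in sorted(by_sample.items()):
        if treatment != "DO13C":
            continue
        assigned = process_sample(sample_runs, constraints, masses)
        labeled = filter_labeled(assigned, min_labeling_percent, mass_window)
        final, removed = subtract_control(labeled, control_t0)
        samples[timepoint] = final
        log["control_removed"][timepoint] = removed
    return IncubationResult(samples, control_t0, log)
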