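"""Candidate enumeration and peak assignment over bounded CHNOPS space.

The assignment problem: given an observed [M-H]- ion m/z, find every
molecular formula (optionally including mixed 12C/13C isotopologues) whose
theoretical ion m/z lies within a ppm tolerance, subject to element bounds
and chemical feasibility rules.  A peak is *uniquely* assigned when exactly
one candidate matches; peaks with several candidates are flagged ambiguous
and discarded downstream — the conservative rule appropriate for tracer
work, where a single wrong formula is worse than a missing one.

Implementation: all 12C-only formulas satisfying the bounds and rules are
materialized once per constraint set into mass-sorted numpy arrays.  A
mixed-isotopologue query with c13 = k is a 12C-only query shifted down by
k x (13C - 12C), so enumeration is a handful of binary searches.  The
independent brute-force reference in :mod:`isodom.reference` checks this
index-based path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .formulas import (
    DEFAULT_MASSES,
    ElementMassTable,
    MolecularFormula,
    mass_error_ppm,
)

__all__ = [
    "ElementBounds",
    "AssignmentConstraints",
    "CandidateAssignment",
    "PeakAssignment",
    "enumerate_candidates",
    "assign_peak",
    "find_near_degenerate_pair",
]


@dataclass(frozen=True)
class ElementBounds:
    """Inclusive per-element atom-count bounds for candidate enumeration.

    ``c`` bounds apply to total carbon (12C + 13C).  Defaults cover typical
    solid-phase-extracted DOM assignments below m/z ~515.
    """

    c_min: int = 1
    c_max: int = 40
    h_min: int = 1
    h_max: int = 80
    n_min: int = 0
    n_max: int = 5
    o_min: int = 0
    o_max: int = 30
    p_min: int = 0
    p_max: int = 2
    s_min: int = 0
    s_max: int = 2

    def __post_init__(self) -> None:
        for name in ("c_min", "c_max", "h_min", "h_max", "n_min", "n_max",
                     "o_min", "o_max", "p_min", "p_max", "s_min", "s_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"bound {name!r} must be non-negative")
        if self.c_max < 1:
            raise ValueError("c_max must be at least 1")
        for lo, hi in (("c_min", "c_max"), ("h_min", "h_max"), ("n_min", "n_max"),
                       ("o_min", "o_max"), ("p_min", "p_max"), ("s_min", "s_max")):
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"{lo} exceeds {hi}")


@dataclass(frozen=True)
class AssignmentConstraints:
    """Tolerance, bounds, isotope mode and chemical rules for assignment.

    ``isotope_mode`` is ``"c12_only"`` (first assignment pass) or ``"mixed"``
    (second pass, c13 free in 0..C).  The chemical rules are the standard
    feasibility filters: non-negative integer DBE for the neutral molecule,
    the valence cap H <= 2C + 2 + N, and an O/C ratio cap.
    """

    tolerance_ppm: float = 0.3
    bounds: ElementBounds = field(default_factory=ElementBounds)
    isotope_mode: str = "c12_only"
    mz_min: float = 90.0
    mz_max: float = 515.0
    require_integer_dbe: bool = True
    require_nonnegative_dbe: bool = True
    require_valence_cap: bool = True
    oc_ratio_max: float = 1.2

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if self.isotope_mode not in ("c12_only", "mixed"):
            raise ValueError("isotope_mode must be 'c12_only' or 'mixed'")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be below mz_max")

    def with_mode(self, mode: str) -> "AssignmentConstraints":
        return AssignmentConstraints(
            tolerance_ppm=self.tolerance_ppm, bounds=self.bounds,
            isotope_mode=mode, mz_min=self.mz_min, mz_max=self.mz_max,
            require_integer_dbe=self.require_integer_dbe,
            require_nonnegative_dbe=self.require_nonnegative_dbe,
            require_valence_cap=self.require_valence_cap,
            oc_ratio_max=self.oc_ratio_max)

    def with_tolerance(self, tolerance_ppm: float) -> "AssignmentConstraints":
        return AssignmentConstraints(
            tolerance_ppm=tolerance_ppm, bounds=self.bounds,
            isotope_mode=self.isotope_mode, mz_min=self.mz_min, mz_max=self.mz_max,
            require_integer_dbe=self.require_integer_dbe,
            require_nonnegative_dbe=self.require_nonnegative_dbe,
            require_valence_cap=self.require_valence_cap,
            oc_ratio_max=self.oc_ratio_max)


@dataclass(frozen=True)
class CandidateAssignment:
    """One formula candidate for an observed peak."""

    formula: MolecularFormula
    theoretical_mz: float
    error_ppm: float
    pass_number: int


@dataclass(frozen=True)
class PeakAssignment:
    """Outcome of assigning one peak: status plus the winning candidate.

    ``status`` is ``unique`` (exactly one candidate within tolerance),
    ``ambiguous`` (two or more; ``formula`` is None — ambiguity is never
    broken heuristically) or ``unassigned`` (none).
    """

    status: str
    formula: MolecularFormula | None
    theoretical_mz: float | None
    error_ppm: float | None
    pass_number: int
    n_candidates: int


_SPACE_CACHE: dict[tuple, SimpleNamespace] = {}


def _space_key(constraints: AssignmentConstraints,
               masses: ElementMassTable) -> tuple:
    b = constraints.bounds
    return (
        (b.c_min, b.c_max, b.h_min, b.h_max, b.n_min, b.n_max,
         b.o_min, b.o_max, b.p_min, b.p_max, b.s_min, b.s_max),
        (constraints.require_integer_dbe, constraints.require_nonnegative_dbe,
         constraints.require_valence_cap, round(constraints.oc_ratio_max, 9)),
        round(constraints.mz_max, 6),
        (masses.h, masses.c12, masses.c13, masses.n, masses.o, masses.p,
         masses.s, masses.electron),
    )


def _formula_space(constraints: AssignmentConstraints,
                   masses: ElementMassTable) -> SimpleNamespace:
    """Mass-sorted arrays of every 12C-only formula within bounds and rules."""
    key = _space_key(constraints, masses)
    cached = _SPACE_CACHE.get(key)
    if cached is not None:
        return cached

    b = constraints.bounds
    mass_limit = constraints.mz_max + masses.proton + 1.0

    c, n, o, p, s = (g.ravel() for g in np.meshgrid(
        np.arange(b.c_min, b.c_max + 1),
        np.arange(b.n_min, b.n_max + 1),
        np.arange(b.o_min, b.o_max + 1),
        np.arange(b.p_min, b.p_max + 1),
        np.arange(b.s_min, b.s_max + 1),
        indexing="ij"))
    heavy = (c * masses.c12 + n * masses.n + o * masses.o
             + p * masses.p + s * masses.s)
    keep = heavy + b.h_min * masses.h <= mass_limit
    if constraints.oc_ratio_max is not None:
        keep &= o <= constraints.oc_ratio_max * c
    c, n, o, p, s, heavy = c[keep], n[keep], o[keep], p[keep], s[keep], heavy[keep]

    # Hydrogen range per heavy-atom combination.  DBE >= 0 and the valence
    # cap both reduce to h <= 2c + n + 2; integer DBE forces h = n (mod 2).
    h_hi = np.full(c.shape, b.h_max)
    if constraints.require_valence_cap or constraints.require_nonnegative_dbe:
        h_hi = np.minimum(h_hi, 2 * c + n + 2)
    h_hi = np.minimum(h_hi, np.floor((mass_limit - heavy) / masses.h).astype(int))
    h_lo = np.full(c.shape, b.h_min)
    if constraints.require_integer_dbe:
        step = 2
        h_lo = h_lo + ((n - h_lo) % 2)
    else:
        step = 1
    n_h = np.maximum(0, (h_hi - h_lo) // step + 1)
    n_h[h_hi < h_lo] = 0

    total = int(n_h.sum())
    rows = np.repeat(np.arange(c.size), n_h)
    offsets = np.arange(total) - np.repeat(np.cumsum(n_h) - n_h, n_h)
    h = h_lo[rows] + step * offsets

    c, n, o, p, s, heavy = c[rows], n[rows], o[rows], p[rows], s[rows], heavy[rows]
    neutral = heavy + h * masses.h
    order = np.argsort(neutral, kind="stable")

    space = SimpleNamespace(
        c=c[order].astype(np.int16), h=h[order].astype(np.int16),
        n=n[order].astype(np.int16), o=o[order].astype(np.int16),
        p=p[order].astype(np.int16), s=s[order].astype(np.int16),
        neutral_mass=neutral[order],
        ion_mz=neutral[order] - masses.proton,
    )
    _SPACE_CACHE[key] = space
    return space


def _candidate_sort_key(cand: CandidateAssignment):
    return (abs(cand.error_ppm), cand.formula)


def enumerate_candidates(mz: float,
                         constraints: AssignmentConstraints,
                         masses: ElementMassTable = DEFAULT_MASSES
                         ) -> list[CandidateAssignment]:
    """Every formula whose [M-H]- m/z is within tolerance of ``mz``.

    In ``c12_only`` mode all candidates have c13 = 0; in ``mixed`` mode c13
    ranges over 0..C.  Candidates are sorted by |error_ppm|, ties broken by
    lexicographic atom counts.  An empty list means no match (not an error).
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    space = _formula_space(constraints, masses)
    tol = constraints.tolerance_ppm
    # |1e6 (obs - theo) / theo| < tol  <=>  theo in (obs/(1+tol e-6), obs/(1-tol e-6))
    theo_lo = mz / (1 + tol * 1e-6)
    theo_hi = mz / (1 - tol * 1e-6)

    pass_number = 1 if constraints.isotope_mode == "c12_only" else 2
    c13_values = (0,) if constraints.isotope_mode == "c12_only" else \
        range(0, constraints.bounds.c_max + 1)

    delta = masses.c13_delta
    out: list[CandidateAssignment] = []
    ion = space.ion_mz
    for c13 in c13_values:
        lo = np.searchsorted(ion, theo_lo - c13 * delta, side="left")
        hi = np.searchsorted(ion, theo_hi - c13 * delta, side="right")
        for i in range(lo, hi):
            c_total = int(space.c[i])
            if c13 > c_total:
                continue
            theo = float(ion[i]) + c13 * delta
            err = mass_error_ppm(mz, theo)
            if abs(err) >= tol:
                continue
            formula = MolecularFormula(
                c12=c_total - c13, c13=c13, h=int(space.h[i]), n=int(space.n[i]),
                o=int(space.o[i]), p=int(space.p[i]), s=int(space.s[i]))
            out.append(CandidateAssignment(formula, theo, err, pass_number))
    out.sort(key=_candidate_sort_key)
    return out


def assign_peak(mz: float,
                constraints: AssignmentConstraints,
                masses: ElementMassTable = DEFAULT_MASSES) -> PeakAssignment:
    """Assign one peak: unique iff exactly one candidate is within tolerance."""
    candidates = enumerate_candidates(mz, constraints, masses)
    pass_number = 1 if constraints.isotope_mode == "c12_only" else 2
    if not candidates:
        return PeakAssignment("unassigned", None, None, None, pass_number, 0)
    if len(candidates) > 1:
        return PeakAssignment("ambiguous", None, None, None, pass_number,
                              len(candidates))
    best = candidates[0]
    return PeakAssignment("unique", best.formula, best.theoretical_mz,
                          best.error_ppm, pass_number, 1)


def find_near_degenerate_pair(constraints: AssignmentConstraints,
                              max_ppm: float = 0.3,
                              mz_min: float | None = None,
                              mz_max: float | None = None,
                              masses: ElementMassTable = DEFAULT_MASSES,
                              max_c13: int = 6,
                              ) -> tuple[MolecularFormula, MolecularFormula] | None:
    """Find two distinct formulas whose ion m/z differ by less than ``max_ppm``.

    Scans the (optionally isotopologue-expanded) formula space for the
    closest adjacent pair inside the m/z range; used to construct ambiguity
    fixtures.  Returns None when the space holds no such pair.
    """
    space = _formula_space(constraints, masses)
    lo = mz_min if mz_min is not None else constraints.mz_min
    hi = mz_max if mz_max is not None else constraints.mz_max
    delta = masses.c13_delta

    if constraints.isotope_mode == "mixed":
        shifts = range(0, max_c13 + 1)
    else:
        shifts = (0,)
    mzs, idxs, c13s = [], [], []
    for c13 in shifts:
        mask = (space.c >= c13) & (space.ion_mz + c13 * delta >= lo) \
            & (space.ion_mz + c13 * delta <= hi)
        mzs.append(space.ion_mz[mask] + c13 * delta)
        idxs.append(np.nonzero(mask)[0])
        c13s.append(np.full(int(mask.sum()), c13))
    mz_all = np.concatenate(mzs)
    if mz_all.size < 2:
        return None
    idx_all = np.concatenate(idxs)
    c13_all = np.concatenate(c13s)
    order = np.argsort(mz_all, kind="stable")
    mz_all, idx_all, c13_all = mz_all[order], idx_all[order], c13_all[order]
    gaps_ppm = np.diff(mz_all) / mz_all[:-1] * 1e6
    j = int(np.argmin(gaps_ppm))
    if gaps_ppm[j] >= max_ppm:
        return None

    def _formula(i: int, c13: int) -> MolecularFormula:
        return MolecularFormula(
            c12=int(space.c[i]) - c13, c13=c13, h=int(space.h[i]),
            n=int(space.n[i]), o=int(space.o[i]), p=int(space.p[i]),
            s=int(space.s[i]))

    first = _formula(int(idx_all[j]), int(c13_all[j]))
    second = _formula(int(idx_all[j + 1]), int(c13_all[j + 1]))
    if first == second:
        return None
    return first, second
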