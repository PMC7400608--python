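"""Brute-force reference enumeration, independent of the indexed fast path.

This module re-solves the candidate-enumeration problem with plain nested
loops over every element tuple, computing each candidate mass by direct
summation.  It shares nothing with :mod:`isodom.assignment` except the
domain types and the sort order, so agreement between the two is a real
cross-check rather than a tautology.  It is deliberately simple and slow;
use it for validation at small bounds, not in the pipeline.
"""

from __future__ import annotations

from .assignment import AssignmentConstraints, CandidateAssignment, _candidate_sort_key
from .formulas import DEFAULT_MASSES, ElementMassTable, MolecularFormula

__all__ = ["enumerate_reference"]


def enumerate_reference(mz: float,
                        constraints: AssignmentConstraints,
                        masses: ElementMassTable = DEFAULT_MASSES
                        ) -> list[CandidateAssignment]:
    """Exhaustive-loop equivalent of :func:`isodom.assignment.enumerate_candidates`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    b = constraints.bounds
    tol = constraints.tolerance_ppm
    upper = mz * (1 + tol * 1e-6) + masses.proton  # neutral-mass cutoff
    pass_number = 1 if constraints.isotope_mode == "c12_only" else 2

    out: list[CandidateAssignment] = []
    for c in range(b.c_min, b.c_max + 1):
        if c * masses.c12 + b.h_min * masses.h > upper:
            break
        c13_range = range(0, c + 1) if constraints.isotope_mode == "mixed" else (0,)
        for c13 in c13_range:
            for s in range(b.s_min, b.s_max + 1):
                for p in range(b.p_min, b.p_max + 1):
                    for n in range(b.n_min, b.n_max + 1):
                        for o in range(b.o_min, b.o_max + 1):
                            if (constraints.oc_ratio_max is not None
                                    and o > constraints.oc_ratio_max * c):
                                break
                            heavy = ((c - c13) * masses.c12 + c13 * masses.c13
                                     + n * masses.n + o * masses.o
                                     + p * masses.p + s * masses.s)
                            if heavy + b.h_min * masses.h > upper:
                                break
                            for h in range(b.h_min, b.h_max + 1):
                                neutral = heavy + h * masses.h
                                if neutral > upper:
                                    break
                                if constraints.require_integer_dbe and (h - n) % 2:
                                    continue
                                dbe_value = c - h / 2 + n / 2 + 1
                                if constraints.require_nonnegative_dbe and dbe_value < 0:
                                    continue
                                if constraints.require_valence_cap and h > 2 * c + 2 + n:
                                    continue
                                theo = neutral - masses.proton
                                err = 1e6 * (mz - theo) / theo
                                if abs(err) >= tol:
                                    continue
                                formula = MolecularFormula(
                                    c12=c - c13, c13=c13, h=h, n=n, o=o, p=p, s=s)
                                out.append(CandidateAssignment(
                                    formula, theo, err, pass_number))
    out.sort(key=_candidate_sort_key)
    return out
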