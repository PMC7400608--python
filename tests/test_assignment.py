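"""Candidate enumeration and peak assignment against the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodom.assignment import (
    AssignmentConstraints,
    ElementBounds,
    assign_peak,
    enumerate_candidates,
    find_near_degenerate_pair,
)
from isodom.formulas import MolecularFormula, ion_mz, labeling_percent
from isodom.reference import enumerate_reference

GLUCOSE = MolecularFormula(c12=6, h=12, o=6)


def test_exact_glucose_is_found_c12_only():
    cons = AssignmentConstraints(isotope_mode="c12_only")
    cands = enumerate_candidates(ion_mz(GLUCOSE), cons)
    assert GLUCOSE in [c.formula for c in cands]
    match = next(c for c in cands if c.formula == GLUCOSE)
    assert match.error_ppm == pytest.approx(0.0, abs=1e-9)
    assert match.pass_number == 1


def test_mixed_mode_is_superset_of_c12_only():
    mz = ion_mz(GLUCOSE)
    c12 = enumerate_candidates(mz, AssignmentConstraints(isotope_mode="c12_only"))
    mixed = enumerate_candidates(mz, AssignmentConstraints(isotope_mode="mixed"))
    assert set(c.formula for c in c12) <= set(c.formula for c in mixed)
    assert all(c.formula.c13 == 0 for c in c12)


def test_tolerance_monotonicity():
    cons = AssignmentConstraints(isotope_mode="mixed")
    mz = ion_mz(GLUCOSE)
    narrow = {c.formula for c in enumerate_candidates(mz, cons)}
    wide = {c.formula for c in enumerate_candidates(mz, cons.with_tolerance(1.0))}
    wider = {c.formula for c in enumerate_candidates(mz, cons.with_tolerance(5.0))}
    assert narrow <= wide <= wider


def test_bound_monotonicity():
    mz = ion_mz(MolecularFormula(c12=10, h=16, n=2, o=5))
    small = AssignmentConstraints(
        isotope_mode="mixed", tolerance_ppm=5.0,
        bounds=ElementBounds(c_max=15, n_max=2, o_max=10))
    large = AssignmentConstraints(
        isotope_mode="mixed", tolerance_ppm=5.0,
        bounds=ElementBounds(c_max=25, n_max=4, o_max=20))
    assert {c.formula for c in enumerate_candidates(mz, small)} \
        <= {c.formula for c in enumerate_candidates(mz, large)}


def test_assign_far_peak_unassigned():
    cons = AssignmentConstraints(isotope_mode="mixed",
                                 bounds=ElementBounds(c_max=10, n_max=1,
                                                      o_max=5, p_max=0, s_max=0))
    mz = ion_mz(GLUCOSE) * (1 + 5e-6)  # 5 ppm off everything
    result = assign_peak(mz, cons)
    assert result.status == "unassigned"
    assert result.formula is None


def test_ambiguous_peak_from_near_degenerate_pair():
    """A peak between two formulas closer than the tolerance is ambiguous."""
    cons = AssignmentConstraints(isotope_mode="mixed")
    pair = find_near_degenerate_pair(cons, max_ppm=0.3)
    assert pair is not None, "default space holds no near-degenerate pair"
    mz1, mz2 = ion_mz(pair[0]), ion_mz(pair[1])
    assert abs(mz2 - mz1) / mz1 * 1e6 < 0.3
    result = assign_peak((mz1 + mz2) / 2, cons)
    assert result.status == "ambiguous"
    assert result.formula is None
    assert result.n_candidates >= 2


@settings(max_examples=30)
@given(st.data())
def test_roundtrip_every_formula_recovers_itself(small_constraints, data):
    """assign at ion_mz(F) always returns a candidate set containing F."""
    b = small_constraints.bounds
    c_total = data.draw(st.integers(1, b.c_max))
    c13 = data.draw(st.integers(0, c_total))
    n = data.draw(st.integers(0, b.n_max))
    h_choices = [h for h in range(b.h_min, min(b.h_max, 2 * c_total + 2 + n) + 1)
                 if (h - n) % 2 == 0]
    h = data.draw(st.sampled_from(h_choices))
    o = data.draw(st.integers(0, min(b.o_max, int(1.2 * c_total))))
    f = MolecularFormula(c12=c_total - c13, c13=c13, h=h, n=n, o=o,
                         p=data.draw(st.integers(0, b.p_max)),
                         s=data.draw(st.integers(0, b.s_max)))
    cands = enumerate_candidates(ion_mz(f), small_constraints)
    match = [c for c in cands if c.formula == f]
    assert len(match) == 1
    assert match[0].error_ppm == pytest.approx(0.0, abs=1e-9)


def test_enumeration_matches_bruteforce_sample(small_constraints):
    """Indexed enumeration equals the exhaustive loop on random m/z values."""
    rng = np.random.default_rng(11)
    for mz in rng.uniform(90, 515, 20):
        for mode in ("c12_only", "mixed"):
            cons = small_constraints.with_mode(mode)
            fast = enumerate_candidates(float(mz), cons)
            slow = enumerate_reference(float(mz), cons)
            assert [c.formula for c in fast] == [c.formula for c in slow]


def test_candidates_sorted_by_absolute_error():
    cons = AssignmentConstraints(isotope_mode="mixed", tolerance_ppm=3.0)
    cands = enumerate_candidates(ion_mz(GLUCOSE) * (1 + 1e-6), cons)
    errors = [abs(c.error_ppm) for c in cands]
    assert errors == sorted(errors)


def test_c12_only_candidates_carry_zero_labeling():
    cons = AssignmentConstraints(isotope_mode="c12_only", tolerance_ppm=2.0)
    for c in enumerate_candidates(252.157, cons):
        assert labeling_percent(c.formula) == 0.0
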