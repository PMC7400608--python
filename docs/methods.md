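# Methods

## Formula model

A molecular formula is an isotopologue: ¹²C and ¹³C counts are tracked
separately over the element set C, H, N, O, P, S, and the exact neutral
mass is the sum of per-isotope monoisotopic masses (CODATA/AME values;
¹³C − ¹²C = 1.0033548 Da; natural ¹³C abundance 1.07 atom%, the baseline
for all atom-percent-excess arithmetic). Only the singly deprotonated
even-electron ion [M−H]⁻ is modeled — negative-mode electrospray of DOM is
overwhelmingly [M−H]⁻ — so ion m/z = neutral mass − 1.0072765 Da, and ppm
errors are computed in ion-m/z space, where instrument accuracy statements
live. Peak masses quoted to three decimals are interpreted as ion m/z.

## Assignment

Candidates for an observed m/z are all formulas within a strict ppm
tolerance (default < 0.3 ppm) satisfying:

* element bounds (defaults C 1–40, H 1–80, N 0–5, O 0–30, P 0–2, S 0–2,
  sized for solid-phase-extracted DOM below m/z ~515);
* DBE = C − H/2 + N/2 + 1 non-negative and integer (P and S treated as
  non-contributing, the usual DOM convention);
* the valence cap H ≤ 2C + 2 + N and O/C ≤ 1.2.

Assignment is two-pass: pass 1 considers ¹²C-only formulas; only peaks
pass 1 could not uniquely explain proceed to pass 2, where c13 ranges over
0..C. A peak is accepted only with exactly one in-tolerance candidate;
ambiguity is decided strictly by candidate count and never broken by
heuristics. Candidates are ordered by |error| with lexicographic atom
counts as the tie-break.

The fast path materializes the ¹²C-only formula space once per constraint
set into mass-sorted arrays; a c13 = k query is the same search shifted by
k · 1.0033548 Da. Because the tolerance (< 0.2 mDa) is far below the
hydrogen mass, the table search is exhaustive by construction, and a fully
independent brute-force enumerator (plain nested loops over every element
tuple) is kept in the package and compared against the fast path in the
test suite.

A note on the 252.157 validation peak: enumerating the full mixed space
within ±2 ppm of m/z 252.157 yields a maximum candidate labeling of 83.3%,
not 100% — under the chemical rules above, every fully-¹³C tuple in that
window violates the valence cap, and the nearest chemically valid fully
labeled formula ([¹³C]₁₁H₁₈N₂O₄) lies 2.8 ppm away. The package reports
the computed value.

## Pipeline order and conservatism

Per replicate run: peaks duplicated by overlapping mass windows are merged
first (records from different windows closer than 0.5 ppm are one ion;
the more intense wins — without this, overlap would double-count intensity
in normalization), then the run is normalized to its summed intensity over
all windows. Consensus follows normalization because averaging is defined
on the normalized scale: a formula is retained when uniquely assigned in
at least 2 of 3 replicates — replicates are linked by identical formula,
not by m/z clustering, which sidesteps peak alignment entirely — at the
mean of its normalized intensities over the runs where it was found.
The 2-of-3 rule is applied after normalization and before averaging; the
ordering of these steps is an interpretation choice and is fixed here.
The labeled table keeps records with labeling ≥ 50% (inclusive) and ion
m/z in [90, 391] (inclusive), and control subtraction runs last: any
formula shared with the unlabeled control's 0 h table is removed and the
removal count logged. With a ≥ 50% labeling filter upstream the
subtraction is expected to remove nothing; it is retained as a safeguard
and its no-op behavior is asserted in the tests.

Every record that survives therefore satisfies, simultaneously: unique
assignment, < 0.3 ppm, ≥ 2/3 replicates, ≥ 50% labeling and the mass
window. A dedicated test re-checks each output record against the raw
rules.

## Time-series metrics

The per-formula time series unions the labeled tables across the four
sampling times (absent = 0 intensity). "Mean labeling" is the unweighted
mean over molecules detected at a time point (an intensity-weighted
variant is provided as an option; the unweighted form treats every
molecule equally, which matches a count-based reading of diversification).
Presence uses strict intensity > 0 with no extra floor beyond the
pipeline's detection model. Heatmap-style ordering of rows is display-only
and fixed as presence group desc, class, then 0 h intensity desc.

## Tracer rates

Excess ¹³CO₂ concentration (µM) is regressed against time by ordinary
least squares, all replicate points entering individually; hour inputs
convert to per-day rates by ×24. The slope divided by the substrate label
fraction (default 0.99) gives the substrate remineralization rate, and
100 · rate / added gives the percent of the addition turned over per day.
CO₂ fixation uses the atom-percent-excess ratio form
(APE_POC / APE_DIC) · [POC] / Δt with the biomass 0 h value as the
incorporation baseline; label dilution over time is not corrected for.
Sub-baseline measurements clamp to zero excess.

## The synthetic incubation

The generator's defaults are the study conditions; sizes are chosen so a
full 20-seed benchmark runs in well under a minute per batch.

* **World.** 1000 ambient ¹²C formulas (static over time, 98% of total
  abundance, lognormal spread σ_ln = 1), 60 fully ¹³C substrate molecules
  in the 91–390 m/z range with class mix CHO/N/P/NP = 0.4/0.3/0.2/0.1,
  and 10 fully labeled precursors at m/z 395–510, together 2% of total
  abundance (precursors 20% of the labeled budget, per-species lognormal
  σ_ln = 0.5). Each precursor has one CHO-only sub-formula fragment inside
  the analysis window — heteroatom groups are cleaved off first, so
  breakdown products are CHO-class, consistent with preferential N/P
  release.
* **Screening.** Every world formula is accepted only if uniquely
  assignable with margin: at 0.9 ppm (3× the assignment tolerance),
  labeled formulas have no ¹²C-only explanation and exactly one mixed
  explanation (themselves); ambient formulas are unique in ¹²C space.
  With 0.05 ppm mass noise (≈ 6σ < 0.3 ppm) this guarantees that recovery
  losses measure pipeline defects rather than constructed degeneracies.
  A near-degenerate pair can be injected on request for ambiguity tests.
* **Kinetics.** First-order decay with k_P : k_N : k_CHO = 4 : 2 : 1 at
  5.545 / 2.773 / 1.386 d⁻¹ (half-lives 3, 6, 12 h; NP uses k_P).
  Fragments follow the production-plus-decay closed form. The fraction of
  decayed carbon leaving as CO₂ is calibrated per world so that 25% of the
  added substrate carbon is remineralized over the first day; the
  calibration uses recombination-free dynamics because exchanged atoms
  leave the labeled pool without being respired.
* **Recombination.** At each sampling-interval boundary, with probability
  q = 0.22 per molecule, a not-yet-recombined species is replaced by a
  variant with s of its ¹³C atoms swapped to ¹²C, s drawn uniformly from
  the admissible set (variant ≥ 50% labeled, inside the window, and
  screened unique). q was set from the closed-form expectation
  drop ≈ (1 − (1−q)³) · E[s/c] · 100 to produce a ≈ 15-point decline in
  mean labeling by 28 h. The expected mean labeling at any time point is
  available in closed form and is what the pipeline estimate is scored
  against. Fragments carry the same recombination clock from 0 h (they
  inherit the processing state of their lineage); precursors, which never
  enter the analysis window, do not recombine.
* **Ledger.** Substrate-derived ¹³C is tracked exactly through four
  buckets — resident in molecules, remineralized, transformed into
  unmodeled organics, exchanged out by recombination — using piecewise
  closed-form exponentials; the buckets sum to the initial ¹³C to
  floating-point precision (tested at 10⁻⁹ relative).
* **Measurement.** Observed m/z = true m/z · (1 + ε·10⁻⁶),
  ε ~ N(0, 0.05²); intensity lognormal (σ_ln = 0.25) around abundance;
  detection threshold 0.002 abundance units (≈ 8% of the mean substrate
  species' initial abundance); whole-replicate dropout probability 0.1;
  peaks routed into all five (overlapping) mass windows that contain them.
  Triplicates; amended samples at 0/4/16/28 h, unlabeled control at 0 h.
  A truth table records, per time point, each labeled species' current
  isotopologue and which replicates actually detected it; "detectable"
  means in-window, ≥ 50% labeled and present in ≥ 2 replicates, and
  recovery is scored against that set.

**Benchmark scenarios.** Recovery and label-dilution benchmarks run the
default scenario. The persistence-ordering benchmark (median presence
group CHO > N ≥ P) runs with recombination disabled: a recombination event
changes a molecule's formula and thereby splits one species across two
table rows, which probes formula identity rather than class kinetics; the
decay-ordering question is cleanly posed with decay alone. Both are
20-seed batches with fixed seeds 0–19.

## What the generator does not emulate

Natural-abundance ¹³C satellites and fine isotope structure (³⁴S, ¹⁵N,
¹⁸O), adducts and multiple charging, m/z-dependent calibration drift,
intensity nonlinearity and ion suppression, a dynamic ambient background,
and any mechanistic microbial model (taxa, growth, enzymes). Recombination
is modeled as isotope exchange on an unchanged heavy-atom skeleton rather
than formation of new adduct formulas: that is the mechanism the
labeling-percentage observable can actually constrain, and it keeps
formula identity testable. Passing recovery benchmarks therefore show the
analysis chain is correct under its stated noise model, not that real
spectra are this clean — in particular, real data carry near-degenerate
assignments that the screened worlds exclude by design, which is why
ambiguous peaks are discarded rather than resolved.

## Numerical notes

* Tolerance comparisons are strict (< 0.3 ppm), matching the acceptance
  wording "mass accuracy of < 0.3 ppm"; the 50% labeling and mass-window
  bounds are inclusive.
* The tolerance window in formula-space search is computed exactly as
  theo ∈ (m/(1+tol·10⁻⁶), m/(1−tol·10⁻⁶)), then re-filtered with the
  signed ppm error, so fast path and brute force agree to the boundary.
* All randomness flows from one integer seed through named child streams
  (world, kinetics, render, tracer); identical configs produce
  byte-identical output files.
* Degenerate inputs fail loudly: all-zero runs cannot be normalized,
  consensus needs ≥ 2 runs, carbon-free or hydrogen-free formulas are
  rejected where they are meaningless, and a world request larger than
  the screened formula space raises.

## Limitations

The element bounds and rule set of vendor assignment tools vary; results
at the edges of the bounded space (high O/C, S-rich formulas) depend on
those choices. The 2-of-3 consensus is formula-level, so systematic
calibration error shared by all replicates is invisible to it. Rate
estimation assumes linear accumulation over the fitted window; the
generator's cumulative ¹³CO₂ curve saturates, so an OLS fit across the
full 28 h underestimates the initial rate — fits over the first day are
the right comparison for a day-one rate.
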