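# isodom

Isotopologue-aware molecular formula assignment and stable-isotope-probing
analytics for ultrahigh-resolution mass spectrometry of marine dissolved
organic matter (DOM).

## The problem

Labile DOM released by phytoplankton is turned over by heterotrophic
microbes within hours, but its transformation is hard to observe: the
labile pool is a trace component riding on a large, chemically similar
ambient background. One way through is to add a fully ¹³C-labeled substrate
and follow it by FT-ICR-MS: a molecule derived from the substrate carries
many ¹³C atoms, so its exact mass separates it from every ambient
(essentially all-¹²C) molecule. `isodom` implements the complete data
analysis for such an experiment, for people who have per-replicate peak
lists (m/z, intensity) and bulk isotope-tracer tables and want defensible
molecular formulas, diversification metrics and turnover rates out the
other end.

## What it computes

**Formula assignment.** For an observed [M−H]⁻ ion at m/z *m*, the engine
enumerates every formula ¹²C_{c−k}¹³C_k H_h N_n O_o P_p S_s within a ppm
tolerance of *m*, subject to element bounds and feasibility rules
(DBE = C − H/2 + N/2 + 1 ≥ 0 and integer, H ≤ 2C + 2 + N, O/C ≤ 1.2).
Assignment runs in two passes — first ¹²C-only, then with the ¹³C dimension
open for the unexplained peaks — and a peak is accepted only when exactly
one candidate matches (|error| < 0.3 ppm); peaks with several candidates
are discarded. Per-molecule labeling is 100 · k/c.

**Pipeline.** Replicate runs are normalized to their summed intensity over
all mass windows; a formula is retained when uniquely assigned in ≥ 2 of 3
replicates, at the mean of its normalized intensities; the labeled table
keeps molecules with ≥ 50% labeling inside the unambiguous 90–391 Da range
and subtracts anything shared with an unlabeled control.

**Analytics and rates.** Time-series metrics (formula counts, summed
intensity, mean labeling, presence-pattern groups, heteroatom-class
composition, H:C / O:C summaries) quantify breakdown and recombination.
Bulk rates use ordinary least squares on excess-tracer concentration and
the standard atom-percent-excess incorporation equation
rate = (APE_POC / APE_DIC) · [POC] / Δt.

**Synthetic incubations.** A ground-truth generator renders complete
synthetic experiments — ambient background, fully labeled substrate,
class-dependent decay (P fastest, then N, then CHO-only), sub-391 Da
breakdown products of larger precursors, ¹³C→¹²C recombination exchange,
triplicate measurement with ppm mass error, lognormal intensity noise and
dropouts — so every stage of the analysis can be scored against known
truth.

## Worked example

```python
from isodom.simulate import (SimConfig, generate_world, simulate_kinetics,
                             render_peaklists, evaluate_recovery)
from isodom.pipeline import run_incubation
from isodom.timeseries import build_timeseries, summary_table

config = SimConfig(seed=1)                      # default study conditions
world = generate_world(config)                  # 1000 ambient + 80 labeled species
traj = simulate_kinetics(world, config)
runs, truth = render_peaklists(traj, config)    # 15 replicate runs, 5 windows
result = run_incubation(runs, config.constraints)
table = build_timeseries(result.samples)
print(summary_table(table).round(3).to_string(index=False))
print(evaluate_recovery(truth, result))
```

prints

```
 timepoint_h  n_formulas  summed_intensity  mean_labeling_percent  mean_hc  mean_oc  weighted_mean_mass
         0.0          59             0.018                100.000    1.938    0.257             185.424
         4.0          69             0.013                 93.477    1.836    0.223             193.703
        16.0          50             0.006                 87.843    1.811    0.207             201.743
        28.0          34             0.003                 84.194    1.463    0.203             201.423
{'n_detectable': 212, 'n_recovered': 212, 'n_false': 0, 'recovery_percent': 100.0}
```

Read: the number of detected labeled formulas rises at 4 h as breakdown
products of large precursors enter the analysis window, then falls as the
substrate is remineralized; summed intensity declines throughout; the mean
labeling percentage drops ~16 points by 28 h because recombination with
ambient ¹²C dilutes per-molecule labeling; and the pipeline recovered every
detectable labeled molecule with zero false formulas.

The same machinery is scriptable from the shell:

```sh
isodom simulate --out sim/ --seed 7          # peak lists + truth + tracer
isodom pipeline --peaks sim/peaks.tsv --out sim/out
isodom rates --tracer sim/tracer.tsv
isodom assign 179.056112 --mode mixed        # candidates for one m/z
```

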