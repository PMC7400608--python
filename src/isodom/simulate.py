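"""Synthetic 13C-DOM incubation worlds with known ground truth.

The generator emulates the structure of a labile-DOM stable-isotope-probing
experiment: an unlabeled ambient DOM background, a small fully 13C-labeled
substrate pool (~2% of total), class-dependent first-order breakdown
(P-containing fastest, then N-containing, then CHO-only), sub-391 Da
breakdown products appearing from larger labeled precursors, recombination
events that swap 13C atoms for ambient 12C and thereby dilute per-molecule
labeling, and a triplicate measurement model with ppm-scale mass error,
lognormal intensity noise, detection dropouts and five overlapping mass
windows.

Every molecular formula placed in a world is screened so that it is
*uniquely assignable* by the engine with margin to spare: labeled species
have no 12C-only explanation and exactly one mixed-isotopologue explanation
within ``screen_ppm``, and ambient species are unique in 12C space.  This
makes end-to-end formula recovery a well-posed benchmark — losses measure
pipeline defects, not constructed mass degeneracies (an explicit
near-degenerate pair can be requested for ambiguity testing).

All randomness derives from the config seed; the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assignment import (
    AssignmentConstraints,
    enumerate_candidates,
    find_near_degenerate_pair,
    _formula_space,
)
from .formulas import (
    DEFAULT_MASSES,
    MolecularFormula,
    heteroatom_class,
    ion_mz,
    labeling_percent,
)
from .pipeline import IncubationResult, Peak, ReplicateRun, write_peak_table

__all__ = [
    "SimConfig",
    "Species",
    "TrueWorld",
    "Trajectory",
    "generate_world",
    "simulate_kinetics",
    "render_peaklists",
    "render_tracer_series",
    "simulate_tracer_linear",
    "expected_consensus_survival",
    "evaluate_recovery",
    "write_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of a synthetic incubation; defaults are the study conditions.

    Decay rates are first order, per day; the 4:2:1 P:N:CHO ratio encodes
    preferential heteroatom breakdown with half-lives of 3, 6 and 12 h.
    ``recombination_prob`` is the per-molecule probability, at each sampling
    interval, of a recombination event replacing part of the molecule's 13C
    with ambient 12C.  ``remineralized_share`` (the fraction of decayed
    carbon leaving as CO2 rather than as transformed organic matter) is
    calibrated per world, when left None, so that one quarter of the added
    substrate carbon is remineralized over the first day.
    """

    seed: int = 0
    # world composition
    n_ambient: int = 1000
    n_substrate: int = 60
    n_precursors: int = 10
    substrate_class_mix: tuple = (("CHO", 0.4), ("N", 0.3), ("P", 0.2), ("NP", 0.1))
    ambient_total: float = 98.0
    substrate_total: float = 2.0
    precursor_fraction: float = 0.2
    substrate_label_fraction: float = 0.99
    abundance_sigma: float = 0.5
    ambient_abundance_sigma: float = 1.0
    # kinetics (per day)
    k_cho: float = 1.386
    k_n: float = 2.773
    k_p: float = 5.545
    fragment_mol_yield: float = 1.0
    recombination_prob: float = 0.22
    remineralized_share: float | None = None
    remineralized_day1_target: float = 0.25
    # measurement model
    sigma_ppm: float = 0.05
    intensity_sigma: float = 0.25
    detection_threshold: float = 0.002
    dropout: float = 0.1
    timepoints: tuple = (0.0, 4.0, 16.0, 28.0)
    control_timepoints: tuple = (0.0,)
    replicates: int = 3
    windows: tuple = (("w1", 90.0, 192.0), ("w2", 188.0, 286.0),
                      ("w3", 282.0, 370.0), ("w4", 366.0, 444.0),
                      ("w5", 440.0, 515.0))
    substrate_mz_range: tuple = (91.0, 390.0)
    precursor_mz_range: tuple = (395.0, 510.0)
    mass_window: tuple = (90.0, 391.0)
    screen_ppm: float = 0.9
    include_ambiguity_pair: bool = False
    # bulk tracer model
    added_um: float = 2.0
    poc_um: float = 6.0
    poc_cn_ratio: float = 8.5
    dic_label_at_percent: float = 11.1
    fixation_rate_um_per_day: float = 0.6
    tracer_noise_um: float = 0.02
    tracer_noise_atpercent: float = 0.02
    constraints: AssignmentConstraints = field(default_factory=AssignmentConstraints)

    def __post_init__(self) -> None:
        for name in ("recombination_prob", "dropout", "precursor_fraction",
                     "substrate_label_fraction", "remineralized_day1_target"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("k_cho", "k_n", "k_p", "sigma_ppm", "intensity_sigma",
                     "detection_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")

    def decay_rate(self, klass: str) -> float:
        return {"CHO": self.k_cho, "N": self.k_n,
                "P": self.k_p, "NP": self.k_p}[klass]


@dataclass
class Species:
    """One molecular species of the world, with its kinetic parameters."""

    formula: MolecularFormula          # original isotopologue (fully 13C if labeled)
    kind: str                          # ambient | substrate | precursor | fragment
    klass: str
    a0: float
    k: float                           # first-order decay rate, per day
    parent: int | None = None          # species index of the precursor (fragments)
    mol_yield: float = 0.0             # fragment moles per mole of decayed precursor
    adm_swaps: tuple = ()              # admissible recombination swap counts

    @property
    def labeled(self) -> bool:
        return self.kind in ("substrate", "precursor", "fragment")


@dataclass
class TrueWorld:
    species: list
    config: SimConfig
    ambiguity_pair: tuple | None = None

    def labeled_carbon(self) -> float:
        """Initial substrate-derived 13C, in abundance x atoms units."""
        return sum(sp.a0 * sp.formula.c13 for sp in self.species if sp.labeled)


def _allocate_classes(n: int, mix) -> dict[str, int]:
    """Largest-remainder allocation of n species across heteroatom classes."""
    mix = dict(mix)
    total = sum(mix.values())
    raw = {k: n * v / total for k, v in mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    leftovers = sorted(mix, key=lambda k: raw[k] - counts[k], reverse=True)
    i = 0
    while sum(counts.values()) < n:
        counts[leftovers[i % len(leftovers)]] += 1
        i += 1
    return counts


def _space_formula(space, i: int, c13: int = 0) -> MolecularFormula:
    return MolecularFormula(
        c12=int(space.c[i]) - c13, c13=c13, h=int(space.h[i]), n=int(space.n[i]),
        o=int(space.o[i]), p=int(space.p[i]), s=int(space.s[i]))


class _Screener:
    """Uniqueness screening of candidate world formulas, with margin.

    A labeled formula is admitted when, at ``screen_ppm`` tolerance, the
    mixed-isotopologue enumeration returns exactly itself and the 12C-only
    enumeration returns nothing; an ambient formula when 12C-only
    enumeration returns exactly itself.  The margin (default 0.9 ppm = 3x
    the assignment tolerance) guarantees that mass noise cannot push an
    observed peak within tolerance of any other explanation.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.mixed = config.constraints.with_mode("mixed").with_tolerance(
            config.screen_ppm)
        self.c12 = config.constraints.with_mode("c12_only").with_tolerance(
            config.screen_ppm)

    def labeled_ok(self, formula: MolecularFormula) -> bool:
        mz = ion_mz(formula)
        if enumerate_candidates(mz, self.c12):
            return False
        cands = enumerate_candidates(mz, self.mixed)
        return len(cands) == 1 and cands[0].formula == formula

    def ambient_ok(self, formula: MolecularFormula) -> bool:
        cands = enumerate_candidates(ion_mz(formula), self.c12)
        return len(cands) == 1 and cands[0].formula == formula


def _admissible_swaps(formula: MolecularFormula, screener: _Screener,
                      mz_range: tuple[float, float]) -> tuple:
    """Recombination swap counts keeping the variant >=50% labeled,
    inside the analysis window and uniquely assignable."""
    c = formula.c_total
    out = []
    for s in range(1, c // 2 + 1):
        variant = dataclasses.replace(formula, c12=formula.c12 + s,
                                      c13=formula.c13 - s)
        mz = ion_mz(variant)
        if not (mz_range[0] <= mz <= mz_range[1]):
            continue
        if screener.labeled_ok(variant):
            out.append(s)
    return tuple(out)


def generate_world(config: SimConfig) -> TrueWorld:
    """Draw a ground-truth world: ambient background, substrate, precursors.

    Deterministic under the config seed.  Raises ``ValueError`` when the
    bounded formula space cannot supply the requested number of screened,
    distinct formulas.
    """
    rng = np.random.default_rng([config.seed, 0])
    space = _formula_space(config.constraints, DEFAULT_MASSES)
    screener = _Screener(config)
    delta = DEFAULT_MASSES.c13_delta
    lo_all = min(w[1] for w in config.windows)
    hi_all = max(w[2] for w in config.windows)
    used: set[MolecularFormula] = set()
    species: list[Species] = []

    def _draw(pool: np.ndarray, n: int, accept, what: str):
        picked = []
        if n == 0:
            return picked
        for i in rng.permutation(pool):
            cand = accept(int(i))
            if cand is None:
                continue
            picked.append(cand)
            if len(picked) == n:
                return picked
        raise ValueError(
            f"formula space exhausted: requested {n} {what} formulas, "
            f"found {len(picked)} after screening")

    # --- ambient background (unlabeled, static) ---
    ambient_pool = np.nonzero((space.ion_mz >= lo_all) & (space.ion_mz <= hi_all))[0]

    def _ambient_accept(i):
        f = _space_formula(space, i)
        if f in used or not screener.ambient_ok(f):
            return None
        used.add(f)
        return f

    ambient = _draw(ambient_pool, config.n_ambient, _ambient_accept, "ambient")
    weights = rng.lognormal(0.0, config.ambient_abundance_sigma, len(ambient))
    weights *= config.ambient_total / weights.sum()
    for f, a0 in zip(ambient, weights):
        species.append(Species(f, "ambient", heteroatom_class(f), float(a0), 0.0))

    # --- fully labeled substrate molecules, class-structured ---
    class_counts = _allocate_classes(config.n_substrate, config.substrate_class_mix)
    substrate: list[Species] = []
    labeled_mz = space.ion_mz + space.c * delta
    for klass in ("CHO", "N", "P", "NP"):
        n_needed = class_counts.get(klass, 0)
        if n_needed == 0:
            continue
        if klass == "CHO":
            mask = (space.n == 0) & (space.p == 0)
        elif klass == "N":
            mask = (space.n > 0) & (space.p == 0)
        elif klass == "P":
            mask = (space.n == 0) & (space.p > 0)
        else:
            mask = (space.n > 0) & (space.p > 0)
        mask &= (labeled_mz >= config.substrate_mz_range[0]) \
            & (labeled_mz <= config.substrate_mz_range[1])
        pool = np.nonzero(mask)[0]

        def _labeled_accept(i):
            f = _space_formula(space, i, c13=int(space.c[i]))
            if f in used or not screener.labeled_ok(f):
                return None
            used.add(f)
            return f

        for f in _draw(pool, n_needed, _labeled_accept, f"substrate {klass}"):
            substrate.append(Species(f, "substrate", klass, 0.0,
                                     config.decay_rate(klass)))
    weights = rng.lognormal(0.0, config.abundance_sigma, len(substrate))
    weights *= config.substrate_total * (1 - config.precursor_fraction) / weights.sum()
    for sp, a0 in zip(substrate, weights):
        sp.a0 = float(a0)

    # --- labeled precursors (> analysis window) and their CHO fragments ---
    precursors: list[tuple[Species, Species]] = []
    pre_mask = (labeled_mz >= config.precursor_mz_range[0]) \
        & (labeled_mz <= config.precursor_mz_range[1])
    pre_pool = np.nonzero(pre_mask)[0]
    frag_base = (space.n == 0) & (space.p == 0) & (space.s == 0) \
        & (labeled_mz >= config.substrate_mz_range[0]) \
        & (labeled_mz <= config.substrate_mz_range[1])

    def _precursor_accept(i):
        pre = _space_formula(space, i, c13=int(space.c[i]))
        if pre in used or not screener.labeled_ok(pre):
            return None
        frag_mask = frag_base & (space.c <= pre.c_total) \
            & (space.h <= pre.h) & (space.o <= pre.o)
        for j in rng.permutation(np.nonzero(frag_mask)[0]):
            frag = _space_formula(space, int(j), c13=int(space.c[int(j)]))
            if frag in used or not screener.labeled_ok(frag):
                continue
            used.add(pre)
            used.add(frag)
            klass = heteroatom_class(pre)
            return (Species(pre, "precursor", klass, 0.0, config.decay_rate(klass)),
                    Species(frag, "fragment", "CHO", 0.0, config.k_cho))
        return None

    precursors = _draw(pre_pool, config.n_precursors, _precursor_accept, "precursor")
    weights = rng.lognormal(0.0, config.abundance_sigma, len(precursors))
    if len(precursors):
        weights *= config.substrate_total * config.precursor_fraction / weights.sum()
    for (pre, frag), a0 in zip(precursors, weights):
        pre.a0 = float(a0)
        pre.mol_yield = min(config.fragment_mol_yield,
                            pre.formula.c_total / frag.formula.c_total)
        idx = len(species)
        species.append(pre)
        frag.parent = idx
        species.append(frag)
    species.extend(substrate)

    # --- recombination admissibility (substrate smalls and fragments) ---
    for sp in species:
        if sp.kind in ("substrate", "fragment"):
            sp.adm_swaps = _admissible_swaps(sp.formula, screener,
                                             config.substrate_mz_range)

    pair = None
    if config.include_ambiguity_pair:
        pair = find_near_degenerate_pair(
            config.constraints.with_mode("mixed"), max_ppm=0.3,
            mz_min=lo_all, mz_max=hi_all)
        if pair is None:
            raise ValueError("no near-degenerate pair exists in this space")
        mean_ambient = config.ambient_total / config.n_ambient
        for f in pair:
            species.append(Species(f, "ambient", heteroatom_class(f),
                                   mean_ambient, 0.0))

    return TrueWorld(species, config, pair)


@dataclass
class Trajectory:
    """Realized kinetics of one world: abundances, recombination, ledger.

    ``abundance[i, j]`` is species i at time point j.  ``event_time`` and
    ``swap`` record the realized recombination event per species (NaN / 0
    when none).  The ledger tracks substrate-derived 13C through four
    buckets — still resident in molecules, remineralized to CO2, transformed
    into unmodeled organic products, and exchanged out by recombination —
    which sum to the initial 13C exactly.
    """

    world: TrueWorld
    times: tuple
    abundance: np.ndarray
    event_time: np.ndarray
    swap: np.ndarray
    remaining13: np.ndarray
    remineralized13: np.ndarray
    transformed13: np.ndarray
    exchanged13: np.ndarray
    remineralized_share: float
    init13: float

    def formula_at(self, i: int, t: float) -> MolecularFormula:
        sp = self.world.species[i]
        if self.swap[i] and not np.isnan(self.event_time[i]) \
                and t >= self.event_time[i]:
            s = int(self.swap[i])
            return dataclasses.replace(sp.formula, c12=sp.formula.c12 + s,
                                       c13=sp.formula.c13 - s)
        return sp.formula

    def u_at(self, i: int, t: float) -> int:
        return self.formula_at(i, t).c13

    def expected_mean_labeling(self, t: float) -> float:
        """Closed-form expected mean labeling % over molecules above the
        detection threshold at time t (expectation over recombination)."""
        config = self.world.config
        q = config.recombination_prob
        m = sum(1 for b in config.timepoints[1:] if b <= t)
        j = self.times.index(t)
        values = []
        for i, sp in enumerate(self.world.species):
            if sp.kind not in ("substrate", "fragment"):
                continue
            if self.abundance[i, j] < config.detection_threshold:
                continue
            if not sp.adm_swaps:
                values.append(100.0)
                continue
            pr = 1 - (1 - q) ** m
            c = sp.formula.c_total
            post = float(np.mean([100.0 * (c - s) / c for s in sp.adm_swaps]))
            values.append((1 - pr) * 100.0 + pr * post)
        return float(np.mean(values)) if values else float("nan")


def _abundance_curves(world: TrueWorld, times) -> np.ndarray:
    """Closed-form abundances: static ambient, exponential decay, and
    production-plus-decay for fragments."""
    t_d = np.asarray(times, dtype=float) / 24.0
    out = np.zeros((len(world.species), len(t_d)))
    for i, sp in enumerate(world.species):
        if sp.kind == "ambient":
            out[i] = sp.a0
        elif sp.kind in ("substrate", "precursor"):
            out[i] = sp.a0 * np.exp(-sp.k * t_d)
        else:  # fragment
            pre = world.species[sp.parent]
            kp, kf = pre.k, sp.k
            if abs(kp - kf) < 1e-12:
                out[i] = pre.mol_yield * pre.a0 * kp * t_d * np.exp(-kp * t_d)
            else:
                out[i] = pre.mol_yield * pre.a0 * kp / (kp - kf) \
                    * (np.exp(-kf * t_d) - np.exp(-kp * t_d))
    return out


def _ledger_products13(world, abundance, u, times) -> np.ndarray:
    """Per-interval substrate-13C flux into decay products (CO2-eligible).

    ``u[i]`` is the per-molecule 13C count during the interval.  Fragment
    production diverts part of the precursor's decayed carbon into the
    fragment species instead of the product pool.
    """
    flux = np.zeros(len(times) - 1)
    for j in range(len(times) - 1):
        total = 0.0
        for i, sp in enumerate(world.species):
            dA = abundance[i, j] - abundance[i, j + 1]
            if sp.kind == "substrate":
                total += dA * u[i]
            elif sp.kind == "precursor":
                total += dA * u[i]  # fragment share subtracted below
            elif sp.kind == "fragment":
                pre_i = sp.parent
                inflow = world.species[pre_i].mol_yield * (
                    abundance[pre_i, j] - abundance[pre_i, j + 1])
                outflow = inflow - (abundance[i, j + 1] - abundance[i, j])
                total += outflow * u[i] - inflow * u[i]
                # inflow carbon stays organic: subtract it from the precursor
                # decay carbon counted above (at the fragment's current
                # isotopologue, which newly produced fragments inherit)
        flux[j] = total
    return flux


def simulate_kinetics(world: TrueWorld, config: SimConfig | None = None
                      ) -> Trajectory:
    """Realize decay, fragment production and recombination on a world.

    Recombination events occur at sampling-interval boundaries with
    probability ``recombination_prob`` per species per interval; a species
    recombines at most once, to a variant drawn uniformly from its
    admissible swap counts.  The 13C mass ledger is exact (closed-form
    exponentials, piecewise-constant isotopologues).
    """
    config = config or world.config
    times = tuple(config.timepoints)
    rng = np.random.default_rng([config.seed, 1])
    n = len(world.species)
    abundance = _abundance_curves(world, times)

    event_time = np.full(n, np.nan)
    swap = np.zeros(n, dtype=int)
    for i, sp in enumerate(world.species):
        if sp.kind not in ("substrate", "fragment") or not sp.adm_swaps:
            continue
        for boundary in times[1:]:
            if rng.random() < config.recombination_prob:
                event_time[i] = boundary
                swap[i] = sp.adm_swaps[rng.integers(len(sp.adm_swaps))]
                break

    init13 = world.labeled_carbon()

    # calibrate the CO2 share on recombination-free day-1 dynamics
    r = config.remineralized_share
    if r is None:
        cal_times = (0.0, 24.0)
        cal_ab = _abundance_curves(world, cal_times)
        u0 = np.array([sp.formula.c13 for sp in world.species], dtype=float)
        products_day1 = _ledger_products13(world, cal_ab, u0, cal_times).sum()
        r = min(1.0, config.remineralized_day1_target * init13
                / products_day1) if products_day1 > 0 else 0.0

    # walk the sampling grid, applying events at interval ends
    u = np.array([sp.formula.c13 for sp in world.species], dtype=float)
    remaining13 = np.zeros(len(times))
    remineralized13 = np.zeros(len(times))
    transformed13 = np.zeros(len(times))
    exchanged13 = np.zeros(len(times))
    remaining13[0] = init13
    for j in range(len(times) - 1):
        flux = _ledger_products13(world, abundance[:, j:j + 2], u,
                                  times[j:j + 2])[0]
        remineralized13[j + 1] = remineralized13[j] + r * flux
        transformed13[j + 1] = transformed13[j] + (1 - r) * flux
        exchanged13[j + 1] = exchanged13[j]
        boundary = times[j + 1]
        for i in range(n):
            if swap[i] and event_time[i] == boundary:
                exchanged13[j + 1] += abundance[i, j + 1] * swap[i]
                u[i] -= swap[i]
        remaining13[j + 1] = sum(
            abundance[i, j + 1] * u[i]
            for i, sp in enumerate(world.species) if sp.labeled)

    return Trajectory(world, times, abundance, event_time, swap,
                      remaining13, remineralized13, transformed13,
                      exchanged13, r, init13)


def render_peaklists(traj: Trajectory, config: SimConfig | None = None
                     ) -> tuple[list[ReplicateRun], pd.DataFrame]:
    """Render the trajectory into replicate peak lists plus a truth table.

    Observed m/z carries Normal(0, sigma_ppm) relative error, intensity is
    lognormal around the true abundance, each species can drop out of a
    whole replicate, and peaks are routed into every mass window whose range
    contains them (overlap duplicates included, as the instrument produces
    them).  The truth table records, per time point and species, the current
    isotopologue and which replicates actually detected it.
    """
    config = config or traj.world.config
    rng = np.random.default_rng([config.seed, 2])
    runs: list[ReplicateRun] = []
    truth_records = []
    plan = [("DO13C", t, True) for t in traj.times] \
        + [("DI13C_control", t, False) for t in config.control_timepoints]

    for treatment, t, with_labeled in plan:
        j = traj.times.index(t)
        sample_id = f"{treatment}_t{t:g}"
        rep_peaks: list[list[Peak]] = [[] for _ in range(config.replicates)]
        for i, sp in enumerate(traj.world.species):
            if sp.labeled and not with_labeled:
                continue
            a = traj.abundance[i, j]
            if a <= 0:
                continue
            formula = traj.formula_at(i, t)
            true_mz = ion_mz(formula)
            detected = []
            for rep in range(config.replicates):
                dropout = rng.random() < config.dropout
                hit = False
                for wname, wlo, whi in config.windows:
                    if not (wlo <= true_mz <= whi):
                        continue
                    eps = rng.normal(0.0, config.sigma_ppm)
                    intensity = a * rng.lognormal(0.0, config.intensity_sigma)
                    if dropout or intensity < config.detection_threshold:
                        continue
                    rep_peaks[rep].append(
                        Peak(true_mz * (1 + eps * 1e-6), intensity, wname))
                    hit = True
                detected.append(hit)
            if sp.labeled:
                truth_records.append({
                    "treatment": treatment, "timepoint_h": t,
                    "species_index": i, "kind": sp.kind,
                    "formula_str": str(formula),
                    "heteroatom_class": sp.klass,
                    "abundance": a,
                    "labeling_percent": labeling_percent(formula),
                    "ion_mz": true_mz,
                    "in_window": bool(config.mass_window[0] <= true_mz
                                      <= config.mass_window[1]),
                    "n_reps_detected": int(sum(detected)),
                })
        for rep in range(config.replicates):
            runs.append(ReplicateRun(
                sample_id, treatment, t, rep + 1,
                tuple(sorted(rep_peaks[rep], key=lambda p: p.mz))))

    truth = pd.DataFrame(truth_records)
    if len(truth):
        truth["detectable"] = truth["in_window"] \
            & (truth["labeling_percent"] >= 50.0) & (truth["n_reps_detected"] >= 2)
    return runs, truth


def render_tracer_series(traj: Trajectory, config: SimConfig | None = None
                         ) -> pd.DataFrame:
    """Bulk tracer table: excess 13CO2 (µM), POC/PON concentration, POC at%.

    The cumulative excess 13CO2 maps the remineralized-13C ledger onto the
    added µM-C scale (99% of the added carbon is 13C); the POC atom-percent
    series is consistent with the configured CO2 fixation rate in a
    DI13C-labeled pool.
    """
    config = config or traj.world.config
    rng = np.random.default_rng([config.seed, 3])
    from .rates import NATURAL_BASELINE_PERCENT
    ape_dic = config.dic_label_at_percent - NATURAL_BASELINE_PERCENT
    rows = []
    for j, t in enumerate(traj.times):
        co2 = traj.remineralized13[j] / traj.init13 * config.added_um \
            * config.substrate_label_fraction
        poc_ape = config.fixation_rate_um_per_day * (t / 24.0) \
            * ape_dic / config.poc_um
        for rep in range(1, config.replicates + 1):
            rows.append((t, "DIC", "excess_13c_um", rep,
                         max(0.0, co2 + rng.normal(0, config.tracer_noise_um))))
            rows.append((t, "POC", "atom_percent_13c", rep,
                         NATURAL_BASELINE_PERCENT + poc_ape
                         + rng.normal(0, config.tracer_noise_atpercent)))
            rows.append((t, "POC", "concentration_um", rep,
                         config.poc_um * (1 + rng.normal(0, 0.02))))
            rows.append((t, "PON", "concentration_um", rep,
                         config.poc_um / config.poc_cn_ratio
                         * (1 + rng.normal(0, 0.02))))
    return pd.DataFrame(rows, columns=["time_h", "analyte", "kind",
                                       "replicate", "value"])


def simulate_tracer_linear(slope_um_per_day: float,
                           times_h=(0.0, 4.0, 16.0, 28.0),
                           replicates: int = 3,
                           noise_um: float = 0.02,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A linearly accumulating excess-tracer series with Gaussian noise."""
    rng = np.random.default_rng([seed, 4])
    t = np.repeat(np.asarray(times_h, dtype=float), replicates)
    y = slope_um_per_day * t / 24.0 + rng.normal(0, noise_um, t.size)
    return t, y


def expected_consensus_survival(dropout: float, n_reps: int = 3,
                                min_reps: int = 2) -> float:
    """Closed-form probability that a molecule survives the 2-of-3 rule
    when each replicate independently misses it with probability ``dropout``."""
    p = 1 - dropout
    return float(sum(math.comb(n_reps, k) * p ** k * (1 - p) ** (n_reps - k)
                     for k in range(min_reps, n_reps + 1)))


def evaluate_recovery(truth: pd.DataFrame, result: IncubationResult) -> dict:
    """Score the pipeline's final labeled tables against the ground truth.

    ``recovered`` counts (time point, formula) pairs present in both the
    truth's detectable set (in-window, >=50% labeled, seen in >=2
    replicates) and the final table; ``false`` counts table formulas that
    match no truly present labeled molecule at that time point.
    """
    n_detectable = n_recovered = n_false = 0
    for t, sample in result.samples.items():
        sub = truth[(truth["treatment"] == "DO13C") & (truth["timepoint_h"] == t)]
        detectable = set(sub.loc[sub["detectable"], "formula_str"])
        present = set(sub["formula_str"])
        found = set(sample.table["formula_str"])
        n_detectable += len(detectable)
        n_recovered += len(detectable & found)
        n_false += len(found - present)
    recovery = 100.0 * n_recovered / n_detectable if n_detectable else float("nan")
    return {"n_detectable": n_detectable, "n_recovered": n_recovered,
            "n_false": n_false, "recovery_percent": recovery}


def write_simulation(outdir, config: SimConfig) -> dict:
    """Run the full generator and write peaks, truth, tracer and config.

    Returns the in-memory artifacts for further use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = generate_world(config)
    traj = simulate_kinetics(world, config)
    runs, truth = render_peaklists(traj, config)
    tracer = render_tracer_series(traj, config)
    write_peak_table(runs, outdir / "peaks.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    tracer.to_csv(outdir / "tracer.tsv", sep="\t", index=False)
    snapshot = dataclasses.asdict(config)
    snapshot["constraints"] = dataclasses.asdict(config.constraints)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=False)
    return {"world": world, "trajectory": traj, "runs": runs,
            "truth": truth, "tracer": tracer}
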