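"""Seeded synthetic data carrying the statistical structure of a sealed
algae-bacteria microcosm study.

Three generators emulate the study conditions end to end, each returning a
truth bundle alongside the observations so every downstream analysis can be
closed against its generative parameters:

* :func:`gen_pressure_experiment` — 54-day diel headspace-pressure traces
  for 12 biotic vials plus one abiotic control, with a three-phase amplitude
  scenario (high activity, collapse/recovery, late decline), shared diel
  temperature, temperature-pressure coupling, drift and sensor noise;
* :func:`gen_dom_peaklists` — per-time-point FT-ICR-MS peak lists drawn from
  class-structured van Krevelen regions, with a compositional drift toward
  lignin/CRAM-like and aliphatic/peptide formulas, declining CHOS counts,
  rising CHNO counts, and a chemodiversity trajectory log-coupled to the
  community generator's diversity decline;
* :func:`gen_asv_tables` — Dirichlet-multinomial ASV tables following a
  genus succession from a *Pseudomonas*-dominated community to
  *Brevundimonas*/*Porphyrobacter* dominance with declining diversity.

The diel pressure waveform is a piecewise-linear sawtooth (linear rise over
the light phase to the day's amplitude, linear fall over the dark phase), so
the oscillation amplitude is an exact generative parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import ASVTable
from .constants import MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, PROTON_MASS
from .dom import (
    AssignmentConfig, ClassBox, ClassScheme, MolecularFormula, Peak,
    default_class_scheme, formula_to_string,
)
from .errors import ScenarioError
from .pressure import PressureTrace
from ._util import rng_from_seed, shannon_nats

__all__ = [
    "PhaseWindow",
    "PressureScenario",
    "PressureTruth",
    "DomTimePoint",
    "DomScenario",
    "DomStudy",
    "CommunityScenario",
    "CommunityTruth",
    "gen_pressure_experiment",
    "gen_dom_peaklists",
    "gen_asv_tables",
    "gen_study_bundle",
    "StudyBundle",
    "default_pressure_scenario",
    "default_dom_scenario",
    "default_community_scenario",
    "simulate_diversity_coupling",
]

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# Pressure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseWindow:
    """Days [start_day, end_day] (1-based, inclusive) with a target diel
    amplitude and a day-to-day amplitude CV (unit-and-day lognormal jitter)."""

    start_day: int
    end_day: int
    amplitude_hpa: float
    day_cv: float = 0.0


@dataclass(frozen=True)
class PressureScenario:
    """Generative conditions for the sealed-vial pressure experiment."""

    n_units: int = 12
    duration_days: int = 54
    dt_s: float = 60.0
    photoperiod_h: float = 12.0
    light_on_offset_h: float = 0.0
    phase_windows: tuple[PhaseWindow, ...] = (
        PhaseWindow(1, 8, 18.68, 0.35),
        PhaseWindow(31, 45, 7.22, 0.10),
        PhaseWindow(46, 54, 4.95, 0.25),
    )
    collapse_window: tuple[int, int] | None = (9, 25)
    collapse_drop_hpa: float = 15.0
    temp_mean_c: float = 30.0
    temp_diel_amplitude_c: float = 0.4
    temp_phase_h: float = 0.0
    temp_coupling_hpa_per_c: float = 0.5
    noise_sd_hpa: float = 0.5
    drift_hpa_per_day: float = 0.0
    baseline_hpa: float = 1013.25
    seed: int = 0

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ScenarioError("dt_s must be positive")
        if not 0 < self.photoperiod_h < 24:
            raise ScenarioError("photoperiod must lie in (0, 24) hours")
        if self.dt_s > self.photoperiod_h * 3600.0 / 2:
            raise ScenarioError(
                "dt_s larger than half the photoperiod cannot resolve the "
                "diel signal")
        spans = [(w.start_day, w.end_day) for w in self.phase_windows]
        if self.collapse_window is not None:
            spans.append(tuple(self.collapse_window))
        for lo, hi in spans:
            if not (1 <= lo <= hi <= self.duration_days):
                raise ScenarioError(f"window {(lo, hi)} outside experiment")
        for (a, b), (c, d) in zip(sorted(spans), sorted(spans)[1:]):
            if c <= b:
                raise ScenarioError(f"windows {(a, b)} and {(c, d)} overlap")
        if any(w.amplitude_hpa < 0 for w in self.phase_windows):
            raise ScenarioError("amplitudes must be >= 0")

    def day_amplitude_targets(self) -> np.ndarray:
        """Per-day amplitude target (index 0 = Day 1): window values,
        zero in the collapse window, linear interpolation across gaps."""
        days = np.arange(1, self.duration_days + 1)
        target = np.full(self.duration_days, np.nan)
        for w in self.phase_windows:
            target[w.start_day - 1:w.end_day] = w.amplitude_hpa
        if self.collapse_window is not None:
            cs, ce = self.collapse_window
            target[cs - 1:ce] = 0.0
        known = np.flatnonzero(~np.isnan(target))
        if known.size == 0:
            raise ScenarioError("no amplitude information in scenario")
        target = np.interp(days, days[known], target[known])
        return target

    def day_cv_targets(self) -> np.ndarray:
        days = np.arange(1, self.duration_days + 1)
        cv = np.full(self.duration_days, np.nan)
        for w in self.phase_windows:
            cv[w.start_day - 1:w.end_day] = w.day_cv
        if self.collapse_window is not None:
            cs, ce = self.collapse_window
            cv[cs - 1:ce] = 0.0
        known = np.flatnonzero(~np.isnan(cv))
        return np.interp(days, days[known], cv[known])


@dataclass
class PressureTruth:
    """Generative truth: realized per-unit-per-day amplitudes and targets."""

    amplitudes: pd.DataFrame  # index Day 1..D, columns unit ids
    day_targets: np.ndarray
    scenario: PressureScenario

    def to_payload(self) -> dict:
        return {
            "day_targets": self.day_targets.tolist(),
            "amplitudes": {u: self.amplitudes[u].tolist()
                           for u in self.amplitudes.columns},
            "scenario": _scenario_payload(self.scenario),
        }


def _scenario_payload(s) -> dict:
    d = asdict(s)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _baseline(scenario: PressureScenario, t_days: np.ndarray) -> np.ndarray:
    base = np.full_like(t_days, scenario.baseline_hpa)
    if scenario.collapse_window is not None and scenario.collapse_drop_hpa:
        cs, ce = scenario.collapse_window
        frac = np.clip((t_days - (cs - 1)) / max(ce - (cs - 1), 1e-9), 0.0, 1.0)
        base = base - scenario.collapse_drop_hpa * frac
    return base


def gen_pressure_experiment(
    scenario: PressureScenario,
) -> tuple[list[PressureTrace], PressureTrace, PressureTruth]:
    """Generate biotic traces, the abiotic control and the truth bundle.

    Biotic pressure = baseline (with the collapse-window monotone decline)
    + drift + sawtooth diel signal + temp_coupling*(T - 30) + noise; the
    control carries only baseline, drift, temperature term and noise. All
    vials share one temperature series (one water bath). Deterministic
    given the scenario seed.
    """
    rng = rng_from_seed(scenario.seed)
    s = scenario
    n_t = int(round(s.duration_days * SECONDS_PER_DAY / s.dt_s))
    t = np.arange(n_t) * s.dt_s
    t_days = t / SECONDS_PER_DAY
    schedule = (s.light_on_offset_h, s.photoperiod_h)

    phase = 2 * np.pi * (t / SECONDS_PER_DAY - s.temp_phase_h / 24.0)
    T = s.temp_mean_c + s.temp_diel_amplitude_c * np.sin(phase)
    temp_term = s.temp_coupling_hpa_per_c * (T - 30.0)
    drift = s.drift_hpa_per_day * t_days
    base = _baseline(s, t_days)

    frac_h = (t - s.light_on_offset_h * 3600.0) % SECONDS_PER_DAY / 3600.0
    light = frac_h < s.photoperiod_h
    shape = np.where(light, frac_h / s.photoperiod_h,
                     (24.0 - frac_h) / (24.0 - s.photoperiod_h))
    day_idx = np.minimum((t // SECONDS_PER_DAY).astype(int), s.duration_days - 1)

    targets = s.day_amplitude_targets()
    cvs = s.day_cv_targets()
    sigma = np.sqrt(np.log1p(cvs ** 2))

    unit_ids = [f"CES{u + 1:02d}" for u in range(s.n_units)]
    amp_truth = np.empty((s.duration_days, s.n_units))
    traces = []
    for u, unit in enumerate(unit_ids):
        jitter = np.exp(rng.normal(-sigma ** 2 / 2, np.where(sigma > 0, sigma, 0)))
        jitter = np.where(sigma > 0, jitter, 1.0)
        amps = targets * jitter
        amp_truth[:, u] = amps
        P = (base + drift + amps[day_idx] * shape + temp_term
             + rng.normal(0.0, s.noise_sd_hpa, n_t))
        traces.append(PressureTrace(unit_id=unit, t=t, P=P, T=T,
                                    schedule=schedule))
    P_ctrl = (s.baseline_hpa + drift + temp_term
              + rng.normal(0.0, s.noise_sd_hpa, n_t))
    control = PressureTrace(unit_id="CTRL", t=t, P=P_ctrl, T=T,
                            schedule=schedule)
    truth = PressureTruth(
        amplitudes=pd.DataFrame(amp_truth,
                                index=np.arange(1, s.duration_days + 1),
                                columns=unit_ids),
        day_targets=targets, scenario=s)
    return traces, control, truth


def default_pressure_scenario(seed: int = 0) -> PressureScenario:
    """The study's biphasic-stability conditions at the package test scale."""
    return PressureScenario(seed=seed)


# ---------------------------------------------------------------------------
# DOM peak lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomTimePoint:
    """One sampling day: formula counts per heteroatom series, the compound
    class mixture of the pool, and the target Shannon chemodiversity."""

    label: str
    n_per_series: tuple[tuple[str, int], ...]
    class_mixture: tuple[tuple[str, float], ...]
    target_chemodiversity: float

    def series_counts(self) -> dict[str, int]:
        return dict(self.n_per_series)

    def mixture(self) -> dict[str, float]:
        return dict(self.class_mixture)


@dataclass(frozen=True)
class DomScenario:
    time_points: tuple[DomTimePoint, ...]
    replicates: int = 2
    ppm_noise_sd: float = 0.2
    replicate_intensity_sigma: float = 0.04
    intensity_scale: float = 1e8
    mass_range: tuple[float, float] = (150.0, 750.0)
    shared_core_fraction: float = 0.5
    assignment_config: AssignmentConfig = field(default_factory=AssignmentConfig)
    seed: int = 0

    def __post_init__(self):
        for tp in self.time_points:
            total = sum(p for _, p in tp.class_mixture)
            if abs(total - 1.0) > 1e-9:
                raise ScenarioError(
                    f"class mixture of {tp.label!r} sums to {total}, not 1")
            if any(p < 0 for _, p in tp.class_mixture):
                raise ScenarioError("class mixture probabilities must be >= 0")
        lo, hi = self.mass_range
        win = self.assignment_config.mz_window
        if not (win[0] <= lo <= hi <= win[1]):
            raise ScenarioError(
                f"mass range {self.mass_range} outside instrument window {win}")
        if not 0 <= self.shared_core_fraction < 1:
            raise ScenarioError("shared_core_fraction must be in [0, 1)")


@dataclass
class DomStudy:
    """Generated peak lists plus the ground truth for every peak."""

    peaklists: dict[str, list[Peak]]
    sample_time_points: dict[str, str]
    truth_records: dict[str, pd.DataFrame]
    pool_info: dict[str, dict]
    scenario: DomScenario

    def truth_payload(self) -> dict:
        return {
            "sample_time_points": self.sample_time_points,
            "pool_info": self.pool_info,
            "samples": {k: v.to_dict(orient="list")
                        for k, v in self.truth_records.items()},
        }


def _box_mask(box: ClassBox, hc: np.ndarray, oc: np.ndarray) -> np.ndarray:
    lo, hi = box.hc
    m = (hc >= lo) & ((hc <= hi) if box.hc_closed_hi else (hc < hi))
    lo, hi = box.oc
    return m & (oc >= lo) & ((oc <= hi) if box.oc_closed_hi else (oc < hi))


_SERIES_HETERO = {"CHO": (0, 0), "CHNO": (1, 0), "CHOS": (0, 1)}


class _FormulaSpace:
    """Enumeration of every valid formula per (class box, series), used to
    sample pools uniformly without replacement. Enumerating the whole space
    once makes exhaustion explicit: asking for more distinct formulas than a
    box holds is a scenario error, not an endless rejection loop."""

    def __init__(self, scheme: ClassScheme, config: AssignmentConfig,
                 mass_range: tuple[float, float]):
        from .dom import _catalog_for

        cat = _catalog_for(config)
        c, h, n, o, s = cat.elements.T.astype(np.int64)
        mass = cat.mz + PROTON_MASS
        hc, oc = h / c, o / c
        series = np.where((n > 0) & (s > 0), "CHNOS",
                          np.where(n > 0, "CHNO",
                                   np.where(s > 0, "CHOS", "CHO")))
        in_mass = (mass >= mass_range[0]) & (mass <= mass_range[1])
        self.elements = cat.elements
        self.index: dict[tuple[str, str], np.ndarray] = {}
        for box in scheme.boxes:
            m = _box_mask(box, hc, oc) & in_mass
            for sr in _SERIES_HETERO:
                self.index[(box.label, sr)] = np.flatnonzero(
                    m & (series == sr))

    def sample(self, rng: np.random.Generator, n: int, series: str,
               label: str, exclude: set) -> list[MolecularFormula]:
        if n == 0:
            return []
        if series not in _SERIES_HETERO:
            raise ScenarioError(f"unknown heteroatom series {series!r}")
        idx = self.index.get((label, series))
        if idx is None:
            raise ScenarioError(f"unknown compound class {label!r}")
        if len(idx) == 0:
            raise ScenarioError(
                f"class box {label!r} holds no valid {series} formulas "
                "within the element bounds")
        got: list[MolecularFormula] = []
        for i in rng.permutation(idx):
            f = MolecularFormula(*map(int, self.elements[i]))
            if f not in exclude:
                got.append(f)
                if len(got) == n:
                    return got
        raise ScenarioError(
            f"class box {label!r} holds only {len(idx)} distinct {series} "
            f"formulas; cannot draw {n} more")


def _zipf_exponent_for_entropy(n: int, target_h: float) -> float:
    """Solve for the rank-power-law exponent giving Shannon entropy
    ``target_h`` over ``n`` ranked weights w_i = i^-gamma."""
    if target_h > math.log(n):
        raise ScenarioError(
            f"target chemodiversity {target_h:.3f} exceeds ln(n) = "
            f"{math.log(n):.3f}")
    ranks = np.arange(1, n + 1, dtype=float)

    def entropy(gamma: float) -> float:
        return shannon_nats(ranks ** -gamma)

    lo, hi = 0.0, 4.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if entropy(mid) > target_h:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def gen_dom_peaklists(scenario: DomScenario) -> DomStudy:
    """Generate per-sample peak lists with full formula-level ground truth.

    A shared core pool persists across time points (so consecutive samples
    share formulas, as repeated sampling of one water body must); the
    remainder of each time point's pool is drawn fresh from a class mixture
    chosen so the whole pool matches the time point's target mixture. Base
    intensities follow a rank power law whose exponent is solved to hit the
    time point's target chemodiversity, ranks interleaved across compound
    classes so intensity-weighted class fractions track count fractions;
    replicates multiply base intensities by lognormal noise. Observed m/z =
    theoretical [M-H]- m/z perturbed by Gaussian ppm noise.
    """
    rng = rng_from_seed(scenario.seed)
    scheme = default_class_scheme()
    config = scenario.assignment_config
    space = _FormulaSpace(scheme, config, scenario.mass_range)
    tps = scenario.time_points
    series_names = sorted({s for tp in tps for s, _ in tp.n_per_series})

    core_n = {
        s: int(scenario.shared_core_fraction
               * min(tp.series_counts().get(s, 0) for tp in tps))
        for s in series_names
    }
    # the persistent core represents the study-wide background pool, so it is
    # drawn from the average class mixture; each time point's fresh draw then
    # tops the pool up to that day's target mixture without clipping
    labels0 = list(dict.fromkeys(k for tp in tps for k in tp.mixture()))
    probs0 = np.array([
        np.mean([tp.mixture().get(k, 0.0) for tp in tps]) for k in labels0])
    probs0 = probs0 / probs0.sum()

    core_set: set[MolecularFormula] = set()
    core_pool: list[tuple[MolecularFormula, str, str]] = []
    for s in series_names:
        counts = rng.multinomial(core_n[s], probs0)
        for label, k in zip(labels0, counts):
            for f in space.sample(rng, int(k), s, label, core_set):
                core_set.add(f)
                core_pool.append((f, s, label))
    core_class_counts = pd.Series(
        [label for _, _, label in core_pool], dtype=object
    ).value_counts() if core_pool else pd.Series(dtype=int)

    peaklists: dict[str, list[Peak]] = {}
    sample_tp: dict[str, str] = {}
    truth_records: dict[str, pd.DataFrame] = {}
    pool_info: dict[str, dict] = {}
    for tp in tps:
        counts_t = tp.series_counts()
        mix_t = tp.mixture()
        labels = list(mix_t)
        total_t = sum(counts_t.values())
        fresh_total = total_t - sum(core_n.get(s, 0) for s in counts_t)
        fresh_target = np.array([
            max(mix_t[k] * total_t - core_class_counts.get(k, 0), 0.0)
            for k in labels])
        if fresh_target.sum() == 0:
            fresh_target = np.ones(len(labels))
        fresh_probs = fresh_target / fresh_target.sum()

        pool = list(core_pool)
        pool_set = set(core_set)
        for s, n_s in counts_t.items():
            n_fresh = n_s - core_n.get(s, 0)
            if n_fresh < 0:
                raise ScenarioError(
                    f"core pool larger than {tp.label!r} count for {s}")
            cls_counts = rng.multinomial(n_fresh, fresh_probs)
            for label, k in zip(labels, cls_counts):
                for f in space.sample(rng, int(k), s, label, pool_set):
                    pool_set.add(f)
                    pool.append((f, s, label))

        # rank power-law base weights solved for the target chemodiversity;
        # ranks are dealt to compound classes by a largest-deficit greedy on
        # cumulative weight, so each class's intensity share tracks its count
        # share (the scenario mixture) instead of riding a top-rank lottery
        n_pool = len(pool)
        gamma = _zipf_exponent_for_entropy(n_pool, tp.target_chemodiversity)
        rank_w = np.arange(1, n_pool + 1, dtype=float) ** -gamma
        by_class: dict[str, list[int]] = {}
        for i, (_, _, label) in enumerate(pool):
            by_class.setdefault(label, []).append(i)
        class_labels = list(by_class)
        for label in class_labels:
            rng.shuffle(by_class[label])
        share = np.array([len(by_class[c]) / n_pool for c in class_labels])
        realized = np.zeros(len(class_labels))
        cum = 0.0
        base_w = np.empty(n_pool)
        for r in range(n_pool):
            cum += rank_w[r]
            deficit = share * cum - realized
            for j in np.argsort(-deficit):
                if by_class[class_labels[j]]:
                    break
            realized[j] += rank_w[r]
            base_w[by_class[class_labels[j]].pop()] = rank_w[r]
        base_w /= base_w.mean()

        theo_mz = np.array([
            f.c * MASS_C + f.h * MASS_H + f.n * MASS_N + f.o * MASS_O
            + f.s * MASS_S - PROTON_MASS for f, _, _ in pool])
        pool_info[tp.label] = {
            "series_counts": counts_t,
            "class_counts": pd.Series([lb for _, _, lb in pool],
                                      dtype=object).value_counts().to_dict(),
            "zipf_gamma": float(gamma),
            "target_chemodiversity": tp.target_chemodiversity,
        }
        for r in range(scenario.replicates):
            sample = f"{tp.label}_r{r + 1}"
            noise = rng.normal(0.0, scenario.ppm_noise_sd, n_pool)
            mz_obs = theo_mz * (1.0 + 1e-6 * noise)
            inten = (scenario.intensity_scale * base_w
                     * np.exp(rng.normal(0.0, scenario.replicate_intensity_sigma,
                                         n_pool)))
            order = np.argsort(mz_obs)
            peaklists[sample] = [Peak(float(mz_obs[i]), float(inten[i]))
                                 for i in order]
            sample_tp[sample] = tp.label
            truth_records[sample] = pd.DataFrame({
                "formula": [formula_to_string(pool[i][0]) for i in order],
                "series": [pool[i][1] for i in order],
                "compound_class": [pool[i][2] for i in order],
                "mz_theoretical": theo_mz[order],
                "mz_observed": mz_obs[order],
                "intensity": inten[order],
            })
    return DomStudy(peaklists=peaklists, sample_time_points=sample_tp,
                    truth_records=truth_records, pool_info=pool_info,
                    scenario=scenario)


def default_dom_scenario(seed: int = 0) -> DomScenario:
    """Study-scale DOM conditions: declining CHOS (682 -> 518 -> 452),
    rising CHNO (3046 -> 3182 -> 3448), class drift toward lignin/CRAM-like
    and aliphatic/peptide composition, and chemodiversity targets that sit
    on a logarithmic curve in the community generator's expected Shannon
    diversity (6.60, 6.26, 5.70 nats)."""
    mk = lambda pairs: tuple(pairs.items())
    return DomScenario(
        time_points=(
            DomTimePoint(
                "day08",
                n_per_series=mk({"CHO": 3500, "CHNO": 3046, "CHOS": 682}),
                class_mixture=mk({
                    "lignin/CRAM-like": 0.585, "aliphatic/peptides": 0.137,
                    "lipids": 0.070, "carbohydrates": 0.060,
                    "unsaturated hydrocarbons": 0.045, "tannins": 0.055,
                    "aromatic structures": 0.048}),
                target_chemodiversity=6.60),
            DomTimePoint(
                "day33",
                n_per_series=mk({"CHO": 3550, "CHNO": 3182, "CHOS": 518}),
                class_mixture=mk({
                    "lignin/CRAM-like": 0.634, "aliphatic/peptides": 0.256,
                    "lipids": 0.030, "carbohydrates": 0.025,
                    "unsaturated hydrocarbons": 0.015, "tannins": 0.023,
                    "aromatic structures": 0.017}),
                target_chemodiversity=6.26),
            DomTimePoint(
                "day54",
                n_per_series=mk({"CHO": 3600, "CHNO": 3448, "CHOS": 452}),
                class_mixture=mk({
                    "lignin/CRAM-like": 0.615, "aliphatic/peptides": 0.303,
                    "lipids": 0.020, "carbohydrates": 0.015,
                    "unsaturated hydrocarbons": 0.010, "tannins": 0.022,
                    "aromatic structures": 0.015}),
                target_chemodiversity=5.70),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ASV tables
# ---------------------------------------------------------------------------

_LINEAGES = {
    "Pseudomonas": "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;"
                   "o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas",
    "Brevundimonas": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                     "o__Caulobacterales;f__Caulobacteraceae;g__Brevundimonas",
    "Ensifer": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
               "o__Hyphomicrobiales;f__Rhizobiaceae;g__Ensifer",
    "Duganella": "d__Bacteria;p__Pseudomonadota;c__Betaproteobacteria;"
                 "o__Burkholderiales;f__Oxalobacteraceae;g__Duganella",
    "Ferrovibrio": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                   "o__Rhodospirillales;f__Rhodospirillaceae;g__Ferrovibrio",
    "Porphyrobacter": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                      "o__Sphingomonadales;f__Erythrobacteraceae;"
                      "g__Porphyrobacter",
    "Terrimonas": "d__Bacteria;p__Bacteroidota;c__Chitinophagia;"
                  "o__Chitinophagales;f__Chitinophagaceae;g__Terrimonas",
    "Sphingopyxis": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                    "o__Sphingomonadales;f__Sphingomonadaceae;g__Sphingopyxis",
    "Blastomonas": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                   "o__Sphingomonadales;f__Sphingomonadaceae;g__Blastomonas",
    "Phreatobacter": "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                     "o__Hyphomicrobiales;f__Phreatobacteraceae;"
                     "g__Phreatobacter",
}


@dataclass(frozen=True)
class CommunityScenario:
    """Genus-trajectory succession sampled as Dirichlet-multinomial counts.

    Within each genus the ASV split is a fixed truncated-geometric profile
    (``within_genus_ratio``), so the expected community Shannon diversity is
    a deterministic function of the trajectories.
    """

    time_points: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    n_samples_per_time_point: int = 2
    total_reads: int = 50000
    dirichlet_concentration: float = 5000.0
    asvs_per_genus: tuple[tuple[str, int], ...] = (
        ("Pseudomonas", 12), ("Brevundimonas", 10))
    default_asvs_per_genus: int = 5
    within_genus_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ScenarioError("total_reads must be positive")
        for label, traj in self.time_points:
            total = sum(p for _, p in traj)
            if abs(total - 1.0) > 1e-9:
                raise ScenarioError(
                    f"trajectory of {label!r} sums to {total}, not 1")
            if any(p < 0 for _, p in traj):
                raise ScenarioError("trajectory probabilities must be >= 0")

    def genus_order(self) -> list[str]:
        seen: list[str] = []
        for _, traj in self.time_points:
            for g, _ in traj:
                if g not in seen:
                    seen.append(g)
        return seen

    def n_asvs(self, genus: str) -> int:
        return dict(self.asvs_per_genus).get(genus, self.default_asvs_per_genus)

    def within_split(self, genus: str) -> np.ndarray:
        k = self.n_asvs(genus)
        w = self.within_genus_ratio ** np.arange(k)
        return w / w.sum()

    def expected_shannon(self, label: str) -> float:
        """Deterministic expected ASV-level Shannon diversity of a time point
        (ignoring sampling noise)."""
        traj = dict(dict(self.time_points)[label])
        p = []
        for g, pg in traj.items():
            p.extend(pg * self.within_split(g))
        return shannon_nats(np.array(p))


@dataclass
class CommunityTruth:
    trajectories: dict[str, dict[str, float]]
    expected_shannon: dict[str, float]
    asv_proportions: dict[str, dict[str, float]]
    scenario: CommunityScenario

    def to_payload(self) -> dict:
        return {
            "trajectories": self.trajectories,
            "expected_shannon": self.expected_shannon,
            "asv_proportions": self.asv_proportions,
        }


def gen_asv_tables(scenario: CommunityScenario) -> tuple[ASVTable, CommunityTruth]:
    """Sample ASV count tables along the genus succession trajectories."""
    rng = rng_from_seed(scenario.seed)
    genera = scenario.genus_order()
    asv_ids, taxonomy, genus_of = [], [], []
    for g in genera:
        lineage = _LINEAGES.get(
            g, f"d__Bacteria;p__unknown;c__unknown;o__unknown;f__unknown;g__{g}")
        for j in range(scenario.n_asvs(g)):
            asv_ids.append(f"ASV_{len(asv_ids) + 1:04d}")
            taxonomy.append(lineage)
            genus_of.append(g)
    genus_of = np.array(genus_of, dtype=object)

    columns: dict[str, np.ndarray] = {}
    metadata_rows = []
    asv_prop: dict[str, dict[str, float]] = {}
    for label, traj_pairs in scenario.time_points:
        traj = dict(traj_pairs)
        p = np.zeros(len(asv_ids))
        for g, pg in traj.items():
            idx = np.flatnonzero(genus_of == g)
            p[idx] = pg * scenario.within_split(g)
        asv_prop[label] = {a: float(v) for a, v in zip(asv_ids, p) if v > 0}
        pos = np.flatnonzero(p > 0)
        for r in range(scenario.n_samples_per_time_point):
            sample = f"{label}_r{r + 1}"
            q = rng.dirichlet(scenario.dirichlet_concentration * p[pos])
            counts = np.zeros(len(asv_ids), dtype=np.int64)
            counts[pos] = rng.multinomial(scenario.total_reads, q)
            columns[sample] = counts
            metadata_rows.append((sample, label, r + 1))
    counts_frame = pd.DataFrame(columns, index=asv_ids)
    meta = pd.DataFrame(metadata_rows,
                        columns=["sample", "time_point", "replicate"]
                        ).set_index("sample")
    table = ASVTable(counts=counts_frame,
                     taxonomy=pd.Series(taxonomy, index=asv_ids),
                     sample_metadata=meta)
    truth = CommunityTruth(
        trajectories={lb: dict(tr) for lb, tr in scenario.time_points},
        expected_shannon={lb: scenario.expected_shannon(lb)
                          for lb, _ in scenario.time_points},
        asv_proportions=asv_prop, scenario=scenario)
    return table, truth


def default_community_scenario(seed: int = 0) -> CommunityScenario:
    """Succession from *Pseudomonas* dominance through *Brevundimonas*
    ascendancy to late *Brevundimonas*/*Porphyrobacter* dominance, with
    expected ASV-level Shannon diversity 2.70 -> 1.98 -> 1.19 nats."""
    mk = lambda pairs: tuple(pairs.items())
    return CommunityScenario(
        time_points=(
            ("day08", mk({
                "Pseudomonas": 0.33, "Brevundimonas": 0.12, "Ensifer": 0.10,
                "Duganella": 0.09, "Ferrovibrio": 0.08, "Porphyrobacter": 0.07,
                "Terrimonas": 0.06, "Sphingopyxis": 0.05, "Blastomonas": 0.05,
                "Phreatobacter": 0.05})),
            ("day33", mk({
                "Brevundimonas": 0.62, "Porphyrobacter": 0.12,
                "Ferrovibrio": 0.06, "Sphingopyxis": 0.05, "Blastomonas": 0.05,
                "Ensifer": 0.04, "Phreatobacter": 0.04, "Terrimonas": 0.02})),
            ("day54", mk({
                "Brevundimonas": 0.84, "Porphyrobacter": 0.12,
                "Phreatobacter": 0.025, "Ferrovibrio": 0.008,
                "Sphingopyxis": 0.007})),
        ),
        seed=seed,
    )


def simulate_diversity_coupling(
    n_runs: int = 100,
    seed: int = 0,
    dom_scenario: DomScenario | None = None,
    community_scenario: CommunityScenario | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Replicated draws of paired (microbial Shannon, DOM chemodiversity).

    Each run generates a fresh ASV table from the community scenario and
    fresh replicate intensities from the DOM generator's rank-power-law
    intensity model (whose entropy is invariant to the class interleaving of
    ranks, so formula identities are not resampled). Returns one (x, y)
    pair of arrays per run, samples ordered time point by replicate —
    the inputs :func:`cesdyn.coupling.diversity_fit` expects.
    """
    ds = dom_scenario or default_dom_scenario()
    cs = community_scenario or default_community_scenario()
    counts = {tp.label: sum(tp.series_counts().values())
              for tp in ds.time_points}
    gammas = {tp.label: _zipf_exponent_for_entropy(
        counts[tp.label], tp.target_chemodiversity) for tp in ds.time_points}
    base = {
        label: (np.arange(1, counts[label] + 1.0) ** -gammas[label])
        for label in counts
    }
    from dataclasses import replace as _replace

    out = []
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for child in children:
        s_comm, s_dom = (int(c.generate_state(1)[0] % (2 ** 31))
                         for c in child.spawn(2))
        table, _ = gen_asv_tables(_replace(cs, seed=s_comm))
        meta = table.sample_metadata
        rng = rng_from_seed(s_dom)
        x, y = [], []
        for tp in ds.time_points:
            comm_samples = meta.index[meta["time_point"] == tp.label]
            for r in range(ds.replicates):
                inten = base[tp.label] * np.exp(
                    rng.normal(0.0, ds.replicate_intensity_sigma,
                               counts[tp.label]))
                y.append(shannon_nats(inten))
                if r < len(comm_samples):
                    col = table.counts[comm_samples[r]]
                    x.append(shannon_nats(col[col > 0]))
                else:
                    x.append(np.nan)
        out.append((np.array(x), np.array(y)))
    return out


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    root: Path
    pressure_csv: Path
    peaklist_csvs: dict[str, Path]
    asv_tsv: Path
    samples_tsv: Path
    truth_jsons: dict[str, Path]


def gen_study_bundle(
    outdir,
    pressure_scenario: PressureScenario | None = None,
    dom_scenario: DomScenario | None = None,
    community_scenario: CommunityScenario | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Generate all three datasets and write them in the interchange formats.

    If ``seed`` is given, per-generator seeds are derived from it; otherwise
    each scenario's own seed is used. Written files round-trip losslessly
    through :mod:`cesdyn.io`.
    """
    from dataclasses import replace as _replace

    from . import io as cio

    if seed is not None:
        child = np.random.SeedSequence(seed).spawn(3)
        seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in child]
    else:
        seeds = [None] * 3
    ps = pressure_scenario or default_pressure_scenario()
    ds = dom_scenario or default_dom_scenario()
    cs = community_scenario or default_community_scenario()
    if seed is not None:
        ps = _replace(ps, seed=seeds[0])
        ds = _replace(ds, seed=seeds[1])
        cs = _replace(cs, seed=seeds[2])

    root = Path(outdir)
    (root / "dom").mkdir(parents=True, exist_ok=True)
    (root / "truth").mkdir(exist_ok=True)

    traces, control, p_truth = gen_pressure_experiment(ps)
    pressure_csv = root / "pressure.csv"
    cio.write_pressure_csv(list(traces) + [control], pressure_csv)

    dom_study = gen_dom_peaklists(ds)
    peak_paths = {}
    for sample, peaks in dom_study.peaklists.items():
        path = root / "dom" / f"{sample}.csv"
        cio.write_peaklist_csv(peaks, path)
        peak_paths[sample] = path

    table, c_truth = gen_asv_tables(cs)
    asv_tsv = root / "asv_table.tsv"
    cio.write_asv_table(table, asv_tsv)
    samples_tsv = root / "samples.tsv"
    table.sample_metadata.reset_index().to_csv(samples_tsv, sep="\t", index=False)

    truth_paths = {
        "pressure": root / "truth" / "pressure.json",
        "dom": root / "truth" / "dom.json",
        "community": root / "truth" / "community.json",
    }
    cio.write_json(p_truth.to_payload(), truth_paths["pressure"])
    cio.write_json(dom_study.truth_payload(), truth_paths["dom"])
    cio.write_json(c_truth.to_payload(), truth_paths["community"])
    return StudyBundle(root=root, pressure_csv=pressure_csv,
                       peaklist_csvs=peak_paths, asv_tsv=asv_tsv,
                       samples_tsv=samples_tsv, truth_jsons=truth_paths)
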