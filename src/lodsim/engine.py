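"""Forward-time diagnosis engine.

Each simulated year, the expected number of new diagnoses I(t) * N_u(t) is
drawn from the currently unaffected pool *without replacement*, with each
individual's inclusion weight proportional to the hazard multiplier implied
by their polygenic score (an individual with hazard ratio 15 is 150 times
more likely to be drawn than one with 0.1).  The weighted draw uses the
exponential-race formulation — take the ``n`` smallest of E_i / w_i with
E_i ~ Exp(1) — which is a one-pass O(N) equivalent of Gumbel top-k sampling
and of the literal cumulative-weight lookup kept in :mod:`lodsim.oracles`.

Two study designs are provided: the individual-values analysis (IVA), a
1-year age-slice contrast of newly diagnosed cases against the unaffected
population with no mortality, and the cohort design, where ``span`` staggered
birth cohorts accumulate cases while yearly mortality thins both pools and
statistics are indexed by mid-cohort age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import GeneticArchitecture, build_architecture
from .epidemiology import IncidenceModel, MortalityModel, make_lod_preset
from .population import DIAGNOSED, UNAFFECTED, DEAD, Population, sample_population

__all__ = [
    "SimulationConfig",
    "YearRecord",
    "CohortRecord",
    "or_to_hr",
    "diagnose_year",
    "run_iva",
    "run_cohort",
    "run_replicates",
    "config_from_preset",
]

#: minimum pool fraction (of the initial population) for cohort reporting
MIN_POOL_FRACTION = 0.0025


@dataclass
class SimulationConfig:
    """Inputs of one simulation run (all replicates)."""

    architecture: GeneticArchitecture
    incidence: IncidenceModel
    mortality: MortalityModel = field(default_factory=MortalityModel)
    n_population: int = 1_000_000
    mode: str = "cohort"
    cohort_span: int = 10
    max_age: int = 100
    seed: int = 0
    replicates: int = 1
    or_to_hr_mode: str = "zhang_yu"
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if self.n_population < 10_000:
            raise ValueError("n_population must be >= 1e4")
        if self.cohort_span < 1:
            raise ValueError("cohort_span must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in {"IVA", "cohort"}:
            raise ValueError("mode must be 'IVA' or 'cohort'")
        if self.or_to_hr_mode not in {"zhang_yu", "identity"}:
            raise ValueError("or_to_hr_mode must be 'zhang_yu' or 'identity'")


def config_from_preset(
    name: str,
    n_population: int = 1_000_000,
    mode: str = "cohort",
    seed: int = 0,
    scenario: str = "A",
    mortality: MortalityModel | None = None,
    **kwargs,
) -> SimulationConfig:
    """Convenience constructor: disease preset -> full simulation config."""
    preset = make_lod_preset(name, mortality=mortality)
    arch = build_architecture(scenario, preset.target_h2)
    return SimulationConfig(
        architecture=arch,
        incidence=preset.incidence,
        mortality=preset.mortality,
        n_population=n_population,
        mode=mode,
        seed=seed,
        preset_name=preset.name,
        **kwargs,
    )


@dataclass
class YearRecord:
    """IVA statistics for one year of age."""

    age: int
    n_new_cases: int
    n_unaffected: int
    case_prs_mean: float | None
    case_prs_sd: float | None
    unaffected_prs_mean: float | None
    unaffected_prs_sd: float | None
    maf_cases: dict[str, float] | None
    maf_unaffected: dict[str, float] | None
    cumulative_incidence: float
    exhausted: bool = False

    @property
    def delta_maf(self) -> dict[str, float] | None:
        if self.maf_cases is None or self.maf_unaffected is None:
            return None
        return {k: self.maf_cases[k] - self.maf_unaffected[k] for k in self.maf_cases}


@dataclass
class CohortRecord:
    """Cohort-design statistics at one mid-cohort age."""

    mid_cohort_age: int
    n_cases: int
    n_controls: int
    case_prs_mean: float | None
    case_prs_sd: float | None
    control_prs_mean: float | None
    control_prs_sd: float | None
    maf_cases: dict[str, float] | None
    maf_controls: dict[str, float] | None
    cumulative_incidence: float
    reportable: bool
    cases_needed_80: dict[str, float] | None = None

    @property
    def delta_maf(self) -> dict[str, float] | None:
        if self.maf_cases is None or self.maf_controls is None:
            return None
        return {k: self.maf_cases[k] - self.maf_controls[k] for k in self.maf_cases}


def or_to_hr(or_value, baseline_rate: float, mode: str = "zhang_yu"):
    """Convert odds ratios to hazard-rate multipliers.

    ``zhang_yu``: RR = OR / (1 - P0 + P0 * OR), with P0 the current-year
    baseline incidence; reduces to the identity as P0 -> 0, the stated
    low-incidence regime where OR ~ HR.  ``identity`` returns OR unchanged.
    """
    orv = np.asarray(or_value, dtype=float)
    if np.any(orv <= 0):
        raise ValueError("odds ratios must be positive")
    if not 0.0 <= baseline_rate < 1.0:
        raise ValueError("baseline_rate must be in [0, 1)")
    if mode == "identity":
        out = orv
    elif mode == "zhang_yu":
        out = orv / (1.0 - baseline_rate + baseline_rate * orv)
    else:
        raise ValueError(f"unknown or_to_hr mode {mode!r}")
    return float(out) if np.isscalar(or_value) else out


def _weighted_draw_without_replacement(
    weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Positions of ``n`` distinct draws, inclusion odds proportional to weight.

    Exponential race: position i finishes at time E_i / w_i; the n earliest
    finishers are exactly a sequential weighted sample without replacement.
    Race keys are kept in the weights' dtype (float32 on the engine hot path).
    """
    m = weights.shape[0]
    if n > m:
        raise ValueError("cannot draw more individuals than the pool holds")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    total = float(weights.sum(dtype=np.float64))
    if not total > 0:
        raise ValueError("total sampling weight must be positive")
    dtype = weights.dtype if weights.dtype == np.float32 else np.float64
    keys = rng.standard_exponential(m, dtype=dtype) / weights
    if n == m:
        return np.arange(m, dtype=np.int64)
    return np.argpartition(keys, n - 1)[:n]


def _hazard_weights(exp_prs_pool: np.ndarray, baseline_rate: float, mode: str):
    """OR -> HR conversion on the hot path, preserving the pool's dtype."""
    if mode == "identity" or baseline_rate == 0.0:
        return exp_prs_pool
    p0 = exp_prs_pool.dtype.type(baseline_rate)
    one = exp_prs_pool.dtype.type(1.0)
    return exp_prs_pool / (one - p0 + p0 * exp_prs_pool)


def diagnose_year(
    population: Population,
    n_new_cases: int,
    age: int,
    rng: np.random.Generator,
    baseline_rate: float = 0.0,
    or_to_hr_mode: str = "zhang_yu",
) -> np.ndarray:
    """Mark ``n_new_cases`` unaffected individuals diagnosed at ``age``.

    Returns the drawn indices.  Weights are the individuals' centered
    polygenic odds exp(PRS) passed through the OR->HR conversion.
    """
    pool = np.flatnonzero(population.status == UNAFFECTED)
    if n_new_cases > pool.size:
        raise ValueError("n_new_cases exceeds the unaffected pool")
    w = _hazard_weights(np.exp(population.prs[pool]), baseline_rate, or_to_hr_mode)
    sel = pool[_weighted_draw_without_replacement(w, n_new_cases, rng)]
    population.status[sel] = DIAGNOSED
    population.event_age[sel] = age
    return sel


def _round_with_carry(x: float, carry: float) -> tuple[int, float]:
    """Round half-to-even with fractional carry to the next year."""
    total = x + carry
    n = int(round(total))  # Python round = banker's rounding
    return n, total - n


class _RunningPool:
    """Incrementally maintained count / PRS moments / allele totals."""

    def __init__(self, population: Population):
        self.pop = population
        self.count = 0
        self.prs_sum = 0.0
        self.prs_sq = 0.0
        self.geno = np.zeros(population.genotypes.shape[0], dtype=np.int64)

    def add(self, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        prs = self.pop.prs[idx]
        self.count += idx.size
        self.prs_sum += float(prs.sum())
        self.prs_sq += float((prs * prs).sum())
        self.geno += self.pop.genotypes[:, idx].sum(axis=1, dtype=np.int64)

    def remove(self, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        prs = self.pop.prs[idx]
        self.count -= idx.size
        self.prs_sum -= float(prs.sum())
        self.prs_sq -= float((prs * prs).sum())
        self.geno -= self.pop.genotypes[:, idx].sum(axis=1, dtype=np.int64)

    def mean_sd(self) -> tuple[float | None, float | None]:
        if self.count == 0:
            return None, None
        mean = self.prs_sum / self.count
        if self.count < 2:
            return mean, 0.0
        var = max(0.0, (self.prs_sq - self.count * mean * mean) / (self.count - 1))
        return mean, math.sqrt(var)

    def maf(self) -> dict[str, float] | None:
        if self.count == 0:
            return None
        freq = self.geno / (2.0 * self.count)
        return dict(zip(self.pop.tracked_ids, freq))


def _rngs(config: SimulationConfig, replicate: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(replicate,))
    pop_ss, dyn_ss = ss.spawn(2)
    return np.random.default_rng(pop_ss), np.random.default_rng(dyn_ss)


def run_iva(config: SimulationConfig, replicate: int = 0) -> list[YearRecord]:
    """Individual-values analysis: 1-year age slices, no mortality."""
    if config.mode != "IVA":
        raise ValueError("config.mode must be 'IVA'")
    pop_rng, dyn_rng = _rngs(config, replicate)
    pop = sample_population(config.n_population, config.architecture, pop_rng)
    exp_prs = np.exp(pop.prs).astype(np.float32)

    unaffected = _RunningPool(pop)
    unaffected.add(np.arange(pop.n_total, dtype=np.int64))
    pool = np.arange(pop.n_total, dtype=np.int64)

    records: list[YearRecord] = []
    carry = 0.0
    n_diagnosed_total = 0
    for age in range(config.max_age + 1):
        if pool.size == 0:
            records.append(
                YearRecord(age, 0, 0, None, None, None, None, None, None,
                           n_diagnosed_total / pop.n_total, exhausted=True)
            )
            break
        rate = float(config.incidence.rate(age))
        n_new, carry = _round_with_carry(rate * pool.size, carry)
        n_new = min(n_new, pool.size)

        w = _hazard_weights(exp_prs[pool], rate, config.or_to_hr_mode)
        sel_pos = _weighted_draw_without_replacement(w, n_new, dyn_rng)
        sel = pool[sel_pos]
        pop.status[sel] = DIAGNOSED
        pop.event_age[sel] = age
        n_diagnosed_total += sel.size

        mask = np.ones(pool.size, dtype=bool)
        mask[sel_pos] = False
        pool = pool[mask]
        unaffected.remove(sel)

        cases = _RunningPool(pop)
        cases.add(sel)
        c_mean, c_sd = cases.mean_sd()
        u_mean, u_sd = unaffected.mean_sd()
        records.append(
            YearRecord(
                age=age,
                n_new_cases=int(sel.size),
                n_unaffected=int(pool.size),
                case_prs_mean=c_mean,
                case_prs_sd=c_sd,
                unaffected_prs_mean=u_mean,
                unaffected_prs_sd=u_sd,
                maf_cases=cases.maf(),
                maf_unaffected=unaffected.maf(),
                cumulative_incidence=n_diagnosed_total / pop.n_total,
            )
        )
    return records


def run_cohort(config: SimulationConfig, replicate: int = 0) -> list[CohortRecord]:
    """Staggered-entry cohort design with mortality.

    ``span`` birth cohorts of equal size enter one calendar year apart; cases
    accumulate (anyone diagnosed at or before their current age), controls
    are the currently unaffected survivors, and records are indexed by
    mid-cohort age.  Reporting of a record requires both pools to hold at
    least 0.25% of the initial population.
    """
    if config.mode != "cohort":
        raise ValueError("config.mode must be 'cohort'")
    span = config.cohort_span
    pop_rng, dyn_rng = _rngs(config, replicate)
    pop = sample_population(config.n_population, config.architecture, pop_rng)
    exp_prs = np.exp(pop.prs).astype(np.float32)
    mort = config.mortality
    equal_mortality = mort.case_multiplier == 1.0

    # presampled baseline death ages (valid until diagnosis; thereafter only
    # when case mortality equals control mortality)
    death_age = mort.sample_death_ages(pop.n_total, pop_rng, max_age=config.max_age + span + 20)
    pop.death_age[:] = death_age

    # contiguous blocks enter at calendar years 0..span-1
    bounds = np.linspace(0, pop.n_total, span + 1).astype(np.int64)
    pools = [np.arange(bounds[j], bounds[j + 1], dtype=np.int64) for j in range(span)]
    carries = [0.0] * span

    controls = _RunningPool(pop)
    for p in pools:
        controls.add(p)
    cases_pool = _RunningPool(pop)
    case_idx = np.empty(0, dtype=np.int64)  # alive diagnosed individuals
    ever_diagnosed = 0

    min_pool = MIN_POOL_FRACTION * pop.n_total
    records: list[CohortRecord] = []

    last_year = config.max_age + span // 2 + span - 1
    for year in range(last_year + 1):
        active = min(year + 1, span)
        for j in range(active):
            age = year - j
            if age > config.max_age + span:
                continue
            pool = pools[j]
            if pool.size:
                # diagnoses for this sub-cohort at its current age
                rate = float(config.incidence.rate(min(age, config.incidence.max_age)))
                n_new, carries[j] = _round_with_carry(rate * pool.size, carries[j])
                n_new = min(n_new, pool.size)
                if n_new or rate:
                    w = _hazard_weights(exp_prs[pool], rate, config.or_to_hr_mode)
                    sel_pos = _weighted_draw_without_replacement(w, n_new, dyn_rng)
                    sel = pool[sel_pos]
                    if sel.size:
                        pop.status[sel] = DIAGNOSED
                        pop.event_age[sel] = age
                        mask = np.ones(pool.size, dtype=bool)
                        mask[sel_pos] = False
                        pool = pool[mask]
                        controls.remove(sel)
                        cases_pool.add(sel)
                        case_idx = np.concatenate([case_idx, sel])
                        ever_diagnosed += sel.size
            # control deaths at this age (presampled death year)
            if pool.size and mort.form != "none":
                dying = pool[pop.death_age[pool] == age]
                if dying.size:
                    pop.status[dying] = DEAD
                    controls.remove(dying)
                    pool = pool[pop.death_age[pool] != age]
            pools[j] = pool

        # case deaths across all sub-cohorts
        if case_idx.size and mort.form != "none" and mort.case_multiplier != 0.0:
            ages = year - (np.searchsorted(bounds[1:], case_idx, side="right"))
            if equal_mortality:
                dying_mask = pop.death_age[case_idx] == ages
            else:
                q = np.clip(mort.case_multiplier * mort.q(ages.astype(float)), 0, 1)
                dying_mask = dyn_rng.random(case_idx.size) < q
            dying = case_idx[dying_mask]
            if dying.size:
                pop.status[dying] = DEAD
                cases_pool.remove(dying)
                case_idx = case_idx[~dying_mask]

        # record once all sub-cohorts are present
        if year >= span - 1:
            mid_age = year - span + 1 + span // 2
            if mid_age > config.max_age:
                break
            c_mean, c_sd = cases_pool.mean_sd()
            u_mean, u_sd = controls.mean_sd()
            reportable = (
                cases_pool.count >= min_pool and controls.count >= min_pool
            )
            records.append(
                CohortRecord(
                    mid_cohort_age=mid_age,
                    n_cases=cases_pool.count,
                    n_controls=controls.count,
                    case_prs_mean=c_mean,
                    case_prs_sd=c_sd,
                    control_prs_mean=u_mean,
                    control_prs_sd=u_sd,
                    maf_cases=cases_pool.maf(),
                    maf_controls=controls.maf(),
                    cumulative_incidence=ever_diagnosed / pop.n_total,
                    reportable=reportable,
                )
            )
    return records


def run_replicates(config: SimulationConfig) -> list[list]:
    """Run ``config.replicates`` independent replicates (seed-spawned)."""
    runner = run_iva if config.mode == "IVA" else run_cohort
    return [runner(config, replicate=i) for i in range(config.replicates)]
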