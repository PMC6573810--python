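"""Population allocation under Hardy-Weinberg equilibrium.

Each individual carries a fixed, zero-centered polygenic risk score (PRS)
computed at birth and an allele-count genotype (0/1/2) at each *tracked*
variant.  Untracked genotypes exist only transiently while their ln(OR)
contributions are accumulated into the PRS, so populations of 1e7+ fit
comfortably in memory.

Variants that share identical (EAF, OR) — the replicated grid sets — are
drawn as a single grouped Binomial(2*m, p) allele count per individual, which
has exactly the same distribution as summing m independent Binomial(2, p)
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .architecture import GeneticArchitecture, mean_prs_offset

__all__ = ["Population", "SubsetSummary", "sample_population", "population_summary"]

#: status codes
UNAFFECTED = 0
DIAGNOSED = 1
DEAD = 2


@dataclass
class Population:
    """Per-individual simulation state.

    ``status`` is one of {0 unaffected, 1 diagnosed, 2 dead}; ``event_age``
    holds the diagnosis age (and ``death_age`` the death age) or -1.
    Transitions are one-way: unaffected -> diagnosed, and either -> dead.
    """

    n_total: int
    prs: np.ndarray  # float64 (n,)
    status: np.ndarray  # int8 (n,)
    event_age: np.ndarray  # int16 (n,), diagnosis age or -1
    death_age: np.ndarray  # int16 (n,), death age or -1
    genotypes: np.ndarray  # uint8 (n_tracked, n)
    tracked_ids: list[str]
    rng_seed: int
    tracked_eaf: np.ndarray = field(default=None)  # initial EAF per tracked variant
    tracked_or: np.ndarray = field(default=None)

    def tracked_index(self, variant_id: str) -> int:
        try:
            return self.tracked_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} is not tracked") from None


def _binomial_inverse_cdf(
    trials: int, p: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomial(trials, p) sample of size n via inverse-CDF table lookup.

    Exact (the cdf table carries the full double-precision pmf); much faster
    than per-element binomial generation when ``trials`` is modest, which is
    the regime here (at most 2 alleles per variant times the set count).
    """
    k = np.arange(trials + 1)
    logpmf = (
        gammaln(trials + 1)
        - gammaln(k + 1)
        - gammaln(trials - k + 1)
        + k * np.log(p)
        + (trials - k) * np.log1p(-p)
    )
    cdf = np.cumsum(np.exp(logpmf))
    cdf[-1] = 1.0
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def sample_population(
    n: int, architecture: GeneticArchitecture, seed: int | np.random.Generator
) -> Population:
    """Draw ``n`` individuals' genotypes and centered PRSs.

    Allele counts at each variant are independent Binomial(2, p) draws
    (Hardy-Weinberg proportions p^2, 2p(1-p), (1-p)^2); the PRS is
    sum_k a_k ln(OR_k) minus the population offset 2 sum_k p_k ln(OR_k).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if architecture.n_variants == 0:
        raise ValueError("architecture must contain at least one variant")
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tracked = architecture.tracked_variants()
    tracked_set = set(architecture.tracked_ids)

    prs = np.zeros(n)
    # untracked variants grouped by identical (eaf, OR)
    groups: dict[tuple[float, float], int] = {}
    for v in architecture.variants:
        if v.variant_id in tracked_set:
            continue
        key = (v.eaf, v.odds_ratio)
        groups[key] = groups.get(key, 0) + 1
    for (p, orv), m in sorted(groups.items()):
        counts = _binomial_inverse_cdf(2 * m, p, n, rng)
        prs += np.log(orv) * counts

    genotypes = np.empty((len(tracked), n), dtype=np.uint8)
    for i, v in enumerate(tracked):
        g = _binomial_inverse_cdf(2, v.eaf, n, rng).astype(np.uint8)
        genotypes[i] = g
        prs += v.log_or * g

    prs -= mean_prs_offset(architecture.variants)

    return Population(
        n_total=n,
        prs=prs,
        status=np.zeros(n, dtype=np.int8),
        event_age=np.full(n, -1, dtype=np.int16),
        death_age=np.full(n, -1, dtype=np.int16),
        genotypes=genotypes,
        tracked_ids=list(architecture.tracked_ids),
        rng_seed=-1 if isinstance(seed, np.random.Generator) else int(seed),
        tracked_eaf=np.array([v.eaf for v in tracked]),
        tracked_or=np.array([v.odds_ratio for v in tracked]),
    )


@dataclass
class SubsetSummary:
    """Moments of a population subset; ``empty`` flags a zero-size mask."""

    count: int
    prs_mean: float | None
    prs_sd: float | None
    allele_freq: np.ndarray | None  # per tracked variant
    empty: bool

    def freq_of(self, population: Population, variant_id: str) -> float | None:
        if self.empty:
            return None
        return float(self.allele_freq[population.tracked_index(variant_id)])


def population_summary(population: Population, mask: np.ndarray) -> SubsetSummary:
    """Count, PRS moments and tracked allele frequencies of a subset.

    ``mask`` is boolean (n,) or an integer index array.  An empty subset is
    flagged rather than propagating NaNs.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        idx = np.flatnonzero(mask)
    else:
        idx = mask
    count = int(idx.size)
    if count == 0:
        return SubsetSummary(0, None, None, None, empty=True)
    prs = population.prs[idx]
    freq = population.genotypes[:, idx].mean(axis=1) / 2.0
    sd = float(prs.std(ddof=1)) if count > 1 else 0.0
    return SubsetSummary(count, float(prs.mean()), sd, freq, empty=False)
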