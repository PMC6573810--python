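"""Model genetic architectures for polygenic late-onset diseases.

A disease's genetic architecture is represented as a grid of independent
causal SNPs.  Minor-allele frequencies (MAFs) and per-allele odds ratios
(ORs) are each discretized into equally spaced values inside scenario-specific
bounds, and the full MAF x OR cross-product forms one variant "set".  Sets are
replicated until the liability-scale heritability

    h2 = var / (var + pi^2 / 3),    var = 2 * sum_k p_k (1 - p_k) ln(OR_k)^2

reaches the disease's target, pi^2/3 being the variance of the standard
logistic distribution.  Individual polygenic risk scores are sums of risk
allele counts times ln(OR), centered by the population mean offset

    beta_mean = 2 * sum_k p_k ln(OR_k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

LOGISTIC_VARIANCE = math.pi**2 / 3.0

__all__ = [
    "VariantSpec",
    "ArchitectureScenario",
    "GeneticArchitecture",
    "SCENARIOS",
    "build_scenario_grid",
    "architecture_variance",
    "heritability_from_variance",
    "variance_for_heritability",
    "sets_for_heritability",
    "mean_prs_offset",
    "build_architecture",
    "write_variant_table",
    "read_variant_table",
]


@dataclass(frozen=True)
class VariantSpec:
    """One causal SNP: effect-allele frequency and per-allele odds ratio.

    The grid allele is always the risk allele (OR >= 1), so the effect-allele
    frequency and the minor-allele frequency coincide by construction.
    """

    variant_id: str
    eaf: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if self.odds_ratio <= 0.0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio)


@dataclass(frozen=True)
class ArchitectureScenario:
    """Bounds of one MAF x OR grid scenario.

    ``decimals`` is the precision to which the equally spaced grid values are
    rounded; the common-low scenario A is defined on 3-decimal MAFs
    (0.073, 0.180, 0.286, 0.393, 0.500) while the rarer scenarios need 4.
    """

    name: str
    maf_low: float
    maf_high: float
    or_low: float
    or_high: float
    grid_points: int = 5
    decimals: int = 4

    def __post_init__(self) -> None:
        if self.maf_low >= self.maf_high:
            raise ValueError("maf_low must be < maf_high")
        if self.or_low >= self.or_high:
            raise ValueError("or_low must be < or_high")
        if not (0.0 < self.maf_low and self.maf_high <= 0.5):
            raise ValueError("MAF bounds must lie in (0, 0.5]")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")

    @property
    def grid_size(self) -> int:
        return self.grid_points**2


#: The five modeled scenarios, common/low effect through rare/high effect.
SCENARIOS: dict[str, ArchitectureScenario] = {
    "A": ArchitectureScenario("A", 0.073, 0.500, 1.05, 1.15, decimals=3),
    "B": ArchitectureScenario("B", 0.0365, 0.2495, 1.05, 1.15),
    "C": ArchitectureScenario("C", 0.0146, 0.0998, 1.05, 1.15),
    "D": ArchitectureScenario("D", 0.0146, 0.0998, 1.28, 2.01),
    "E": ArchitectureScenario("E", 0.0073, 0.0499, 1.63, 4.05),
}


def build_scenario_grid(
    scenario: ArchitectureScenario, set_index: int = 1
) -> list[VariantSpec]:
    """Build one variant set: the full cross-product of the scenario's grid.

    MAFs ascend while the OR axis is listed descending (the orientation is
    immaterial for a full cross-product but fixes variant labels).  Labels are
    ``s{set}_m{maf_index}_o{or_index}`` with 1-based grid indices.
    """
    k = scenario.grid_points
    mafs = np.round(np.linspace(scenario.maf_low, scenario.maf_high, k), scenario.decimals)
    ors = np.round(np.linspace(scenario.or_high, scenario.or_low, k), scenario.decimals)
    variants = []
    for mi, p in enumerate(mafs, start=1):
        for oi, orv in enumerate(ors, start=1):
            variants.append(
                VariantSpec(f"s{set_index}_m{mi}_o{oi}", float(p), float(orv))
            )
    return variants


def architecture_variance(variants: Sequence[VariantSpec]) -> float:
    """Liability variance 2 * sum p(1-p) ln(OR)^2 of independent variants."""
    if len(variants) == 0:
        raise ValueError("variant list must be non-empty")
    p = np.array([v.eaf for v in variants])
    b = np.array([v.log_or for v in variants])
    return float(2.0 * np.sum(p * (1.0 - p) * b**2))


def heritability_from_variance(variance: float) -> float:
    """Liability-scale heritability var / (var + pi^2/3)."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    return variance / (variance + LOGISTIC_VARIANCE)


def variance_for_heritability(target_h2: float) -> float:
    """Invert the heritability relation: required liability variance."""
    if not 0.0 <= target_h2 < 1.0:
        raise ValueError("target_h2 must be in [0, 1)")
    return target_h2 / (1.0 - target_h2) * LOGISTIC_VARIANCE


def sets_for_heritability(
    target_h2: float, scenario: ArchitectureScenario | str = "A"
) -> int:
    """Number of replicated grid sets whose total variance best approximates
    the target heritability (round-to-nearest integer set count)."""
    scenario = _resolve_scenario(scenario)
    v_star = variance_for_heritability(target_h2)
    v_one = architecture_variance(build_scenario_grid(scenario))
    return int(round(v_star / v_one))


def mean_prs_offset(variants: Sequence[VariantSpec]) -> float:
    """Population mean polygenic score 2 * sum p ln(OR), used for centering."""
    if len(variants) == 0:
        raise ValueError("variant list must be non-empty")
    p = np.array([v.eaf for v in variants])
    b = np.array([v.log_or for v in variants])
    return float(2.0 * np.sum(p * b))


def _resolve_scenario(scenario: ArchitectureScenario | str) -> ArchitectureScenario:
    if isinstance(scenario, str):
        try:
            return SCENARIOS[scenario.upper()]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; choose one of {sorted(SCENARIOS)}"
            ) from None
    return scenario


@dataclass
class GeneticArchitecture:
    """A replicated-grid architecture sized to a target heritability."""

    scenario: ArchitectureScenario
    n_sets: int
    target_h2: float
    variants: list[VariantSpec] = field(repr=False)
    tracked_ids: list[str]

    @property
    def variance(self) -> float:
        return architecture_variance(self.variants) if self.variants else 0.0

    @property
    def achieved_h2(self) -> float:
        return heritability_from_variance(self.variance)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def tracked_variants(self) -> list[VariantSpec]:
        by_id = {v.variant_id: v for v in self.variants}
        return [by_id[t] for t in self.tracked_ids]


def _default_tracked_ids(scenario: ArchitectureScenario) -> list[str]:
    """The 3x3 {min, mid, max MAF} x {min, mid, max OR} subgrid of set 1.

    Nine representative variants are tracked per run; which nine is
    configurable.  Note o-index 1 is the *highest* OR (descending OR axis),
    so m{k}_o1 pairs the largest MAF with the largest OR.
    """
    k = scenario.grid_points
    picks = sorted({1, (k + 1) // 2, k})
    return [f"s1_m{mi}_o{oi}" for mi in picks for oi in picks]


def build_architecture(
    scenario: ArchitectureScenario | str,
    target_h2: float,
    n_sets: int | None = None,
    tracked_ids: Sequence[str] | None = None,
) -> GeneticArchitecture:
    """Assemble ``n_sets`` replicated grids (nearest-set sizing by default).

    ``n_sets`` may be forced explicitly, e.g. to reproduce published variant
    counts that differ from nearest rounding.
    """
    scenario = _resolve_scenario(scenario)
    if n_sets is None:
        n_sets = sets_for_heritability(target_h2, scenario)
    if n_sets < 0:
        raise ValueError("n_sets must be >= 0")
    variants: list[VariantSpec] = []
    for s in range(1, n_sets + 1):
        variants.extend(build_scenario_grid(scenario, set_index=s))
    tracked = list(tracked_ids) if tracked_ids is not None else (
        _default_tracked_ids(scenario) if n_sets >= 1 else []
    )
    known = {v.variant_id for v in variants}
    missing = [t for t in tracked if t not in known]
    if missing:
        raise ValueError(f"tracked ids not in architecture: {missing}")
    return GeneticArchitecture(
        scenario=scenario,
        n_sets=n_sets,
        target_h2=target_h2,
        variants=variants,
        tracked_ids=tracked,
    )


def write_variant_table(variants: Iterable[VariantSpec], path: str | Path) -> None:
    """Write the 3-column (SNP, EAF, OR) whitespace-delimited variant table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("SNP\tEAF\tOR\n")
        for v in variants:
            fh.write(f"{v.variant_id}\t{v.eaf:.6g}\t{v.odds_ratio:.6g}\n")


def read_variant_table(path: str | Path) -> list[VariantSpec]:
    """Read a 3-column (SNP, EAF, OR) variant table; extra columns ignored."""
    variants = []
    with Path(path).open() as fh:
        header = fh.readline().split()
        if len(header) < 3:
            raise ValueError("variant table needs at least 3 columns: SNP EAF OR")
        for line in fh:
            if not line.strip():
                continue
            snp, eaf, orv = line.split()[:3]
            variants.append(VariantSpec(snp, float(eaf), float(orv)))
    return variants
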