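"""GWAS discovery power from case/control allele-frequency divergence.

The association test for one variant in a balanced case/control study of
total size N is modeled as a noncentral F(1, N-4) statistic with
non-centrality

    lambda = N * p1 * p2 * (f_cases - f_controls)^2,

p1, p2 being the case and control fractions (0.5 each throughout) and the
frequency difference delta = f_cases - f_controls.  Power at genome-wide
significance 5e-8 is the upper tail of the noncentral F beyond the central
F quantile at PSign = 0.99999995:

    power = 1 - pf(qf(PSign, 1, N-4), 1, N-4, lambda).

``cases_for_power`` inverts this for the N giving 80% power; ratios of
cases-needed between cohort ages cancel the significance constant, which is
why the age multiple is the robust cross-study quantity.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "GENOME_WIDE_PSIGN",
    "ncp",
    "power_at",
    "cases_for_power",
    "power_multiple",
]

#: upper-quantile form of the 5e-8 genome-wide significance level
GENOME_WIDE_PSIGN = 0.99999995


def ncp(n_total: float, p1: float, p2: float, delta: float) -> float:
    """Non-centrality parameter N * p1 * p2 * delta^2."""
    if n_total <= 4:
        raise ValueError("n_total must exceed 4")
    if not (0 < p1 < 1 and 0 < p2 < 1) or abs(p1 + p2 - 1.0) > 1e-9:
        raise ValueError("case/control fractions must be in (0,1) and sum to 1")
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    return n_total * p1 * p2 * delta * delta


def power_at(
    n_total: float, lam: float, significance: float = GENOME_WIDE_PSIGN
) -> float:
    """Statistical power of the 1-df association test at sample size N.

    ``significance`` is the upper quantile PSign (0.99999995 <-> 5e-8).
    At lam = 0 this returns exactly the test size 1 - PSign.
    """
    if n_total <= 4:
        raise ValueError("n_total must exceed 4")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < significance < 1:
        raise ValueError("significance quantile must be in (0,1)")
    dfd = n_total - 4
    crit = stats.f.ppf(significance, 1, dfd)
    if lam == 0:
        return 1.0 - significance
    return float(stats.ncf.sf(crit, 1, dfd, lam))


def cases_for_power(
    delta: float,
    target_power: float = 0.8,
    significance: float = GENOME_WIDE_PSIGN,
    rel_tol: float = 1e-4,
) -> float:
    """Number of cases (N/2, equal controls) for the target discovery power.

    Monotone bisection in log N until the achieved power matches
    ``target_power`` to ``rel_tol`` relative (0.01% by default).
    """
    if delta == 0:
        raise ValueError("delta = 0 has no finite solution")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0,1)")
    delta = abs(delta)

    def gap(log_n: float) -> float:
        n = math.exp(log_n)
        val = power_at(n, ncp(n, 0.5, 0.5, delta), significance)
        if math.isnan(val):  # numeric saturation at extreme N: power -> 1
            val = 1.0
        return val - target_power

    # bracket around the noncentral-chi-square initial guess
    crit = stats.chi2.ppf(significance, 1)
    lam0 = (math.sqrt(crit) + stats.norm.ppf(target_power)) ** 2
    floor = math.log(8.0)
    center = max(floor, math.log(lam0 / (0.25 * delta * delta)))
    lo, hi = max(floor, center - 6.0), center + 6.0
    while gap(lo) > 0 and lo > floor:
        lo = max(floor, lo - 4.0)
    while gap(hi) < 0:
        hi += 4.0
    log_n = brentq(gap, lo, hi, xtol=rel_tol / 4)
    n_total = math.exp(log_n)
    achieved = power_at(n_total, ncp(n_total, 0.5, 0.5, delta), significance)
    assert abs(achieved - target_power) <= 5e-3, "solver failed to converge"
    return n_total / 2.0


def power_multiple(
    deltas: Mapping[float, float] | Sequence,
    variant: str | None = None,
    target_power: float = 0.8,
    significance: float = GENOME_WIDE_PSIGN,
) -> dict[float, float | None]:
    """Cases-needed multiples relative to the youngest cohort.

    ``deltas`` maps mid-cohort age -> case-minus-control frequency difference,
    or is a sequence of cohort records (objects with ``mid_cohort_age`` and a
    ``delta_maf`` mapping keyed by variant id, in which case ``variant``
    selects the allele).  The youngest (smallest) age is the reference; ages
    with zero or missing delta report ``None``.
    """
    if not isinstance(deltas, Mapping):
        if variant is None:
            raise ValueError("variant id required with cohort records")
        deltas = {
            r.mid_cohort_age: r.delta_maf.get(variant)
            for r in deltas
            if r.delta_maf is not None
        }
    if not deltas:
        raise ValueError("no cohorts supplied")
    ages = sorted(deltas)
    ref_delta = deltas[ages[0]]
    if ref_delta is None or ref_delta == 0:
        raise ValueError("youngest cohort has no usable frequency difference")
    ref_cases = cases_for_power(ref_delta, target_power, significance)
    out: dict[float, float | None] = {}
    for age in ages:
        d = deltas[age]
        if d is None or d == 0:
            out[age] = None
        else:
            out[age] = cases_for_power(d, target_power, significance) / ref_cases
    return out
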