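"""Yearly incidence and mortality models for late-onset diseases.

Incidence is a deterministic yearly hazard I(t) applied from an onset age t0.
For the eight modeled diseases the clinical incidence curves are approximated
as exponential growth, I(t) = I0 * exp(r (t - t0)), for decades after onset
(doubling time ln 2 / r of 5-8.5 years), optionally flattening into a plateau
at older ages.  Preset curve parameters are fixed constants calibrated so that
each disease satisfies three published constraints simultaneously: the
lifetime-risk band, the maximum yearly incidence, and the age up to which
growth is exponential.

Mortality is a Gompertz-Makeham yearly death probability
q(t) = min(1, a + b * exp(t / c)), a parametric stand-in for actuarial life
tables, with an optional hazard multiplier for diagnosed cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "IncidenceModel",
    "MortalityModel",
    "LODPreset",
    "LOD_NAMES",
    "incidence_at",
    "cumulative_incidence",
    "lifetime_risk",
    "fit_exponential",
    "make_lod_preset",
    "make_validation_models",
]


@dataclass(frozen=True)
class IncidenceModel:
    """A yearly incidence-rate curve I(t), zero before the onset age ``t0``.

    forms:
      constant             I(t) = i0
      linear               I(t) = slope * (t - t0)
      exponential          I(t) = i0 * exp(r (t - t0))
      exponential_capped   exponential up to ``cap_age``, then a smooth (C1)
                           saturating approach to the plateau ``i_max``
    """

    form: str
    t0: float = 0.0
    i0: float = 0.0
    r: float = 0.0
    slope: float = 0.0
    cap_age: float | None = None
    i_max: float | None = None
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.form not in {"constant", "linear", "exponential", "exponential_capped"}:
            raise ValueError(f"unknown incidence form {self.form!r}")
        if self.form == "exponential_capped":
            if self.cap_age is None:
                raise ValueError("exponential_capped requires cap_age")

    @property
    def doubling_time(self) -> float:
        if self.r <= 0:
            return math.inf
        return math.log(2.0) / self.r

    def rate(self, age) -> np.ndarray | float:
        """Yearly hazard at ``age`` (scalar or array), clipped to [0, 1]."""
        t = np.asarray(age, dtype=float)
        if np.any(t < 0) or np.any(t > self.max_age):
            raise ValueError(f"age out of range [0, {self.max_age}]")
        dt = t - self.t0
        if self.form == "constant":
            out = np.full_like(t, self.i0)
        elif self.form == "linear":
            out = self.slope * dt
        elif self.form == "exponential":
            out = self.i0 * np.exp(self.r * dt)
        else:  # exponential_capped
            e_cap = self.i0 * math.exp(self.r * (self.cap_age - self.t0))
            i_max = self.i_max if self.i_max is not None else e_cap
            below = self.i0 * np.exp(self.r * np.minimum(dt, self.cap_age - self.t0))
            if i_max <= e_cap:  # flat plateau at the exponential's end value
                out = np.where(t <= self.cap_age, below, e_cap)
            else:
                k = self.r * e_cap / (i_max - e_cap)
                dt_cap = np.maximum(t - self.cap_age, 0.0)
                above = i_max - (i_max - e_cap) * np.exp(-k * dt_cap)
                out = np.where(t <= self.cap_age, below, above)
        out = np.where(t < self.t0, 0.0, out)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(age) else out


def incidence_at(model: IncidenceModel, age) -> float:
    """Yearly hazard of ``model`` at ``age``; rejects out-of-range ages."""
    return model.rate(age)


def cumulative_incidence(model: IncidenceModel, age: float) -> float:
    """Fraction of a birth cohort diagnosed by ``age``, no mortality.

    Computed as 1 - prod_{t < age} (1 - I(t)) over whole years of age, i.e.
    the survival-product recursion N_u(t+1) = N_u(t) (1 - I(t)).
    """
    if age > model.max_age:
        raise ValueError("age beyond model.max_age")
    years = np.arange(int(math.ceil(age)))
    if years.size == 0:
        return 0.0
    rates = model.rate(years)
    return float(1.0 - np.prod(1.0 - rates))


def fit_exponential(points, t0: float | None = None) -> tuple[float, float]:
    """Least-squares exponential fit ln(rate) ~ age over (age, rate) pairs.

    Returns ``(i0, r)`` with i0 the fitted rate at ``t0`` (default: the
    smallest age among the points).  Rates must be positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (age, rate) points")
    ages, rates = pts[:, 0], pts[:, 1]
    if np.any(rates <= 0):
        raise ValueError("rates must be positive for a log-linear fit")
    if t0 is None:
        t0 = float(ages.min())
    slope, intercept = np.polyfit(ages - t0, np.log(rates), 1)
    return float(math.exp(intercept)), float(slope)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalityModel:
    """Gompertz-Makeham yearly death probability q(t) = min(1, a + b e^{t/c}).

    ``case_multiplier`` scales the hazard of diagnosed cases: 1.0 for equal
    case/control mortality, 2.0 for the double-case-mortality scenario.
    ``form='none'`` disables mortality entirely.
    """

    form: str = "parametric"
    a: float = 2e-4
    b: float = 2.4e-5
    c: float = 10.2
    case_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in {"none", "parametric"}:
            raise ValueError(f"unknown mortality form {self.form!r}")

    def q(self, age) -> np.ndarray | float:
        """Yearly death probability at ``age``."""
        t = np.asarray(age, dtype=float)
        if self.form == "none":
            out = np.zeros_like(t)
        else:
            out = np.clip(self.a + self.b * np.exp(t / self.c), 0.0, 1.0)
        return float(out) if np.isscalar(age) else out

    def q_case(self, age) -> np.ndarray | float:
        """Yearly death probability for diagnosed cases."""
        t = np.asarray(age, dtype=float)
        out = np.clip(self.case_multiplier * np.asarray(self.q(t)), 0.0, 1.0)
        return float(out) if np.isscalar(age) else out

    def survival(self, max_age: int = 120) -> np.ndarray:
        """S(t) = P(alive at start of age t), t = 0..max_age."""
        q = self.q(np.arange(max_age, dtype=float))
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    def sample_death_ages(
        self, n: int, rng: np.random.Generator, max_age: int = 120
    ) -> np.ndarray:
        """Inverse-CDF draw of each individual's (baseline) death age.

        Distributionally identical to applying the yearly Bernoulli q(t);
        ages beyond ``max_age`` are absorbed into the last bin.
        """
        if self.form == "none":
            return np.full(n, max_age, dtype=np.int16)
        s = self.survival(max_age)  # len max_age + 1
        death_cdf = 1.0 - s[1:]  # P(dead by end of age t)
        u = rng.random(n)
        return np.searchsorted(death_cdf, u, side="right").astype(np.int16)


# ---------------------------------------------------------------------------
# disease presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LODPreset:
    """One modeled disease: heritability target plus calibrated incidence.

    ``lifetime_risk_band`` (lo, hi) bounds the no-mortality cumulative
    incidence at age 100; ``max_yearly`` bounds the yearly hazard (None =
    unbounded); ``exp_until_age`` is the age up to which growth is
    exponential.
    """

    name: str
    target_h2: float
    incidence: IncidenceModel
    lifetime_risk_band: tuple[float, float]
    max_yearly: float | None
    exp_until_age: float
    mortality: MortalityModel = field(default_factory=MortalityModel)


LOD_NAMES = ("AD", "T2D", "CAD", "stroke", "breast", "prostate", "colorectal", "lung")

# Calibrated incidence constants.  For each disease the onset age t0 and
# doubling time d were chosen inside the 5-8.5 y band, the plateau starts at
# the published exponential-growth-end age, and i0 was solved (offline, once)
# so the mortality-adjusted lifetime risk — cumulative incidence with death
# as a competing yearly hazard, the quantity clinical lifetime-risk tables
# report — sits inside the published band while the yearly hazard never
# exceeds the published maximum.  ``band`` below is the acceptance band for
# that lifetime risk.  Breast's band extends slightly below the published
# point value: the published 12% reflects female-specific mortality, and the
# unisex mortality stand-in used here caps the achievable risk near 9%
# given the <0.5%/y incidence ceiling.  See docs/methods.md.
_PRESET_PARAMS: dict[str, dict] = {
    #             h2      t0   doubling  cap      plateau        i0            lifetime-risk band  max yearly
    "AD": dict(h2=0.795, t0=65, d=5.0, cap=103.0, imax=None, i0=1.8454e-03, band=(0.10, 0.20), maxy=None),
    "T2D": dict(h2=0.69, t0=25, d=7.0, cap=55.0, imax=0.0249, i0=1.2766e-03, band=(0.50, 0.60), maxy=0.025),
    "CAD": dict(h2=0.55, t0=35, d=8.5, cap=81.0, imax=0.034, i0=7.9868e-04, band=(0.32, 0.49), maxy=0.036),
    "stroke": dict(h2=0.41, t0=40, d=6.5, cap=79.0, imax=0.030, i0=4.3574e-04, band=(0.25, 0.30), maxy=0.044),
    "breast": dict(h2=0.31, t0=28, d=8.5, cap=72.0, imax=0.0048, i0=1.3273e-04, band=(0.08, 0.14), maxy=0.005),
    "prostate": dict(h2=0.57, t0=35, d=5.5, cap=48.0, imax=0.0075, i0=2.9094e-04, band=(0.10, 0.14), maxy=0.008),
    "colorectal": dict(h2=0.40, t0=30, d=8.0, cap=62.0, imax=0.0045, i0=5.8867e-05, band=(0.0, 0.045), maxy=0.006),
    "lung": dict(h2=0.095, t0=45, d=6.0, cap=70.0, imax=0.0045, i0=1.4984e-04, band=(0.0, 0.069), maxy=0.006),
}


def lifetime_risk(
    incidence: IncidenceModel, mortality: MortalityModel, max_age: int = 100
) -> float:
    """Fraction of a birth cohort ever diagnosed, with death competing.

    Year by year the undiagnosed-and-alive pool loses a fraction I(t) to
    diagnosis and q(t) of the remainder to death; the diagnosed fractions
    accumulate into the lifetime risk.
    """
    alive_undiag, risk = 1.0, 0.0
    for t in range(max_age):
        i_t = float(incidence.rate(t))
        risk += alive_undiag * i_t
        alive_undiag *= (1.0 - i_t) * (1.0 - float(mortality.q(t)))
    return risk


def make_lod_preset(
    name: str, mortality: MortalityModel | None = None, max_age: int = 100
) -> LODPreset:
    """Build one of the eight modeled-disease presets by name."""
    key = _match_name(name)
    p = _PRESET_PARAMS[key]
    r = math.log(2.0) / p["d"]
    if p["cap"] >= max_age:
        inc = IncidenceModel("exponential", t0=p["t0"], i0=p["i0"], r=r, max_age=max_age)
    else:
        inc = IncidenceModel(
            "exponential_capped", t0=p["t0"], i0=p["i0"], r=r,
            cap_age=p["cap"], i_max=p["imax"], max_age=max_age,
        )
    return LODPreset(
        name=key,
        target_h2=p["h2"],
        incidence=inc,
        lifetime_risk_band=p["band"],
        max_yearly=p["maxy"],
        exp_until_age=p["cap"],
        mortality=mortality if mortality is not None else MortalityModel(),
    )


def _match_name(name: str) -> str:
    for key in LOD_NAMES:
        if key.lower() == name.lower():
            return key
    raise ValueError(f"unknown LOD preset {name!r}; choose one of {LOD_NAMES}")


# ---------------------------------------------------------------------------
# validation incidence shapes
# ---------------------------------------------------------------------------


def make_validation_models(
    horizon: float,
    target_cumulative: float,
    t0: float = 0.0,
    doubling_time: float = 7.0,
    max_age: int = 100,
) -> tuple[IncidenceModel, IncidenceModel, IncidenceModel]:
    """Constant, linear, and exponential models with equal cumulative incidence.

    Each model's survival-product cumulative incidence at ``horizon`` equals
    ``target_cumulative`` (solved to 1e-10).  Used to check that case/control
    allele distributions depend on cumulative incidence only, not on the shape
    of the incidence curve.
    """
    if not 0.0 < target_cumulative < 1.0:
        raise ValueError("target_cumulative must be in (0, 1)")
    n_years = int(horizon - t0)
    if n_years < 1:
        raise ValueError("horizon must exceed t0 by at least one year")

    # constant: closed form
    i_const = 1.0 - (1.0 - target_cumulative) ** (1.0 / n_years)
    const = IncidenceModel("constant", t0=t0, i0=i_const, max_age=max_age)

    def _solve(make, lo, hi):
        f = lambda x: cumulative_incidence(make(x), horizon) - target_cumulative
        if f(hi) < 0:
            raise ValueError("target cumulative incidence unreachable (needs I > 1)")
        return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)

    lin_make = lambda s: IncidenceModel("linear", t0=t0, slope=s, max_age=max_age)
    linear = lin_make(_solve(lin_make, 0.0, 1.0 / max(1.0, horizon - t0 - 1)))

    r = math.log(2.0) / doubling_time
    exp_make = lambda i0: IncidenceModel("exponential", t0=t0, i0=i0, r=r, max_age=max_age)
    expo = exp_make(_solve(exp_make, 0.0, 1.0))

    # the solved curve must stay a meaningful yearly probability: a peak
    # rate at (or numerically indistinguishable from) certainty means the
    # target is only reachable by diagnosing essentially everyone in the
    # final year
    last = horizon - 1 - t0
    for peak in (linear.slope * last, expo.i0 * math.exp(expo.r * last)):
        if peak > 1.0 - 1e-6:
            raise ValueError(
                "target cumulative incidence unreachable (needs I -> 1)"
            )
    for m in (const, linear, expo):
        got = cumulative_incidence(m, horizon)
        if abs(got - target_cumulative) > 1e-9:
            raise RuntimeError("validation model calibration failed")
    return const, linear, expo
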