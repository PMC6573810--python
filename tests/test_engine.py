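"""Year-by-year diagnosis engine: weighted sampling, IVA and cohort modes."""

import numpy as np
import pytest

from lodsim.architecture import GeneticArchitecture, SCENARIOS, VariantSpec
from lodsim.engine import (
    SimulationConfig,
    _round_with_carry,
    config_from_preset,
    diagnose_year,
    or_to_hr,
    run_cohort,
    run_iva,
)
from lodsim.epidemiology import IncidenceModel, MortalityModel
from lodsim.oracles import zero_incidence_case_maf
from lodsim.population import DIAGNOSED, sample_population


def _arch_one(eaf=0.5, orv=1.15):
    return GeneticArchitecture(
        scenario=SCENARIOS["A"], n_sets=1, target_h2=0.0,
        variants=[VariantSpec("v1", eaf, orv)], tracked_ids=["v1"],
    )


def _arch_null():
    variants = [VariantSpec(f"n{i}", 0.3, 1.0) for i in range(10)]
    return GeneticArchitecture(
        scenario=SCENARIOS["A"], n_sets=1, target_h2=0.0,
        variants=variants, tracked_ids=["n0"],
    )


class TestOrToHr:
    def test_null_odds_ratio(self):
        assert or_to_hr(1.0, 0.3) == 1.0

    def test_low_incidence_limit(self):
        assert or_to_hr(1.15, 0.0) == pytest.approx(1.15)
        assert or_to_hr(1.15, 1e-9) == pytest.approx(1.15, rel=1e-6)

    def test_hand_value(self):
        assert or_to_hr(1.15, 0.2) == pytest.approx(1.15 / 1.03, rel=1e-9)
        assert or_to_hr(1.15, 0.2) == pytest.approx(1.11650, abs=5e-6)

    def test_identity_mode(self):
        assert or_to_hr(3.0, 0.4, mode="identity") == 3.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            or_to_hr(1.15, 1.0)
        with pytest.raises(ValueError):
            or_to_hr(-1.0, 0.1)


class TestRoundWithCarry:
    def test_mass_is_conserved(self):
        carry, total = 0.0, 0
        for _ in range(1000):
            n, carry = _round_with_carry(0.37, carry)
            total += n
        assert total == pytest.approx(370, abs=1)

    def test_half_to_even(self):
        n, carry = _round_with_carry(2.5, 0.0)
        assert n == 2 and carry == pytest.approx(0.5)


class TestDiagnoseYear:
    def test_uniform_weights_preserve_population_maf(self):
        pop = sample_population(200_000, _arch_null(), seed=4)
        rng = np.random.default_rng(10)
        sel = diagnose_year(pop, 20_000, age=50, rng=rng)
        case_freq = pop.genotypes[0, sel].mean() / 2
        se = np.sqrt(0.3 * 0.7 / (2 * sel.size))
        assert case_freq == pytest.approx(0.3, abs=3 * se)
        assert np.all(pop.status[sel] == DIAGNOSED)
        assert np.all(pop.event_age[sel] == 50)

    @pytest.mark.parametrize("eaf", [0.5, 0.286])
    def test_first_draw_enrichment_matches_closed_form(self, eaf):
        expected = zero_incidence_case_maf(eaf, 1.15)
        freqs = []
        for rep in range(8):
            pop = sample_population(150_000, _arch_one(eaf=eaf), seed=100 + rep)
            rng = np.random.default_rng(200 + rep)
            sel = diagnose_year(pop, 1500, age=40, rng=rng)
            freqs.append(pop.genotypes[0, sel].mean() / 2)
        freqs = np.array(freqs)
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert freqs.mean() == pytest.approx(expected, abs=3 * se + 1e-4)

    def test_overdraw_rejected(self):
        pop = sample_population(10_000, _arch_one(), seed=1)
        with pytest.raises(ValueError):
            diagnose_year(pop, 10_001, 50, np.random.default_rng(0))


def _iva_config(arch, i0=0.01, n=50_000, seed=42, **kw):
    return SimulationConfig(
        architecture=arch,
        incidence=IncidenceModel("constant", i0=i0),
        n_population=n, mode="IVA", seed=seed, **kw,
    )


class TestRunIVA:
    def test_null_architecture_shows_no_signal(self):
        recs = run_iva(_iva_config(_arch_null(), n=100_000))
        for rec in recs[:40:5]:
            n_c, n_u = rec.n_new_cases, rec.n_unaffected
            se = np.sqrt(0.3 * 0.7 / 2 * (1 / n_c + 1 / n_u))
            d = rec.delta_maf["n0"]
            assert abs(d) < 3.5 * se

    def test_case_prs_declines_with_age(self):
        cfg = config_from_preset(
            "stroke", n_population=200_000, mode="IVA", seed=5
        )
        recs = run_iva(cfg)
        by_age = {r.age: r.case_prs_mean for r in recs if r.n_new_cases > 500}
        ages = sorted(by_age)
        early = np.mean([by_age[a] for a in ages[:5]])
        late = np.mean([by_age[a] for a in ages[-5:]])
        assert early > 0
        assert late < early

    def test_unaffected_prs_nonincreasing(self):
        recs = run_iva(_iva_config(_arch_one(), i0=0.02, n=100_000))
        means = [r.unaffected_prs_mean for r in recs]
        assert all(b <= a + 1e-4 for a, b in zip(means, means[1:]))

    def test_conservation_every_year(self):
        recs = run_iva(_iva_config(_arch_one(), n=50_000))
        total_cases = 0
        for rec in recs:
            total_cases += rec.n_new_cases
            assert total_cases + rec.n_unaffected == 50_000

    def test_same_seed_identical_records(self):
        cfg = _iva_config(_arch_one())
        a = run_iva(cfg)
        b = run_iva(cfg)
        assert [r.maf_cases for r in a] == [r.maf_cases for r in b]

    def test_expected_case_counts_follow_incidence(self):
        recs = run_iva(_iva_config(_arch_one(), i0=0.01, n=50_000))
        # year 0: round(0.01 * 50000) = 500 exactly
        assert recs[0].n_new_cases == 500


class TestRunCohort:
    def test_span_one_no_mortality_counts_cumulative_cases(self):
        arch = _arch_one()
        cfg = SimulationConfig(
            architecture=arch,
            incidence=IncidenceModel("constant", i0=0.01),
            mortality=MortalityModel(form="none"),
            n_population=50_000, mode="cohort", cohort_span=1, seed=8,
        )
        recs = run_cohort(cfg)
        for rec in recs[:50]:
            expected = 1 - 0.99 ** (rec.mid_cohort_age + 1)
            assert rec.n_cases / 50_000 == pytest.approx(expected, abs=0.01)
            assert rec.n_cases + rec.n_controls == 50_000

    def test_status_transitions_one_way(self):
        cfg = config_from_preset("T2D", n_population=20_000, seed=3)
        recs = run_cohort(cfg)
        cases = [r.n_cases + 0 for r in recs]
        # with mortality cases can shrink, but cumulative incidence cannot
        cums = [r.cumulative_incidence for r in recs]
        assert all(b >= a for a, b in zip(cums, cums[1:]))

    def test_conservation_with_mortality(self):
        cfg = config_from_preset("stroke", n_population=20_000, seed=3)
        recs = run_cohort(cfg)
        for rec in recs:
            assert 0 <= rec.n_cases and 0 <= rec.n_controls
            assert rec.n_cases + rec.n_controls <= 20_000

    def test_deterministic_given_seed(self):
        cfg = config_from_preset("lung", n_population=20_000, seed=9)
        a = run_cohort(cfg)
        b = run_cohort(cfg)
        assert [r.maf_cases for r in a] == [r.maf_cases for r in b]

    def test_mid_cohort_indexing(self):
        cfg = config_from_preset("lung", n_population=20_000, seed=9)
        recs = run_cohort(cfg)
        assert recs[0].mid_cohort_age == 5  # span 10, first full window 0-9
        assert recs[-1].mid_cohort_age == 100

    def test_invalid_configs_rejected(self):
        arch = _arch_one()
        inc = IncidenceModel("constant", i0=0.01)
        with pytest.raises(ValueError):
            SimulationConfig(architecture=arch, incidence=inc, n_population=100)
        with pytest.raises(ValueError):
            SimulationConfig(
                architecture=arch, incidence=inc,
                n_population=20_000, cohort_span=0,
            )
        with pytest.raises(ValueError):
            SimulationConfig(
                architecture=arch, incidence=inc,
                n_population=20_000, mode="both",
            )
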