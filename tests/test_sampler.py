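"""Virtual-individual sampling: conversions, truncation, allometry, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hkafsim as hk
from hkafsim.sampler import MIN_ACCEPTANCE


class TestLognormalConversion:
    def test_geometric_mean_oracle(self):
        # GM = mean / sqrt(1 + (sd/mean)^2), evaluated by hand for 9 +/- 2
        mu, sigma = hk.lognormal_params_from_arithmetic(9, 2)
        assert np.exp(mu) == pytest.approx(8.7857, rel=1e-4)

    def test_degenerate_limit(self):
        mu, sigma = hk.lognormal_params_from_arithmetic(50, 1e-9)
        assert sigma == pytest.approx(0.0, abs=1e-8)
        assert np.exp(mu) == pytest.approx(50.0)

    @given(
        mean=st.floats(0.5, 500),
        cv=st.floats(0.01, 1.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_moment_matching_closed_form(self, mean, cv):
        sd = cv * mean
        mu, sigma = hk.lognormal_params_from_arithmetic(mean, sd)
        # the lognormal with these log-scale parameters has exactly the
        # requested arithmetic moments
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-9)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(sd, rel=1e-9)

    def test_monte_carlo_mean_recovery(self, rng):
        # pre-truncation draws recover the arithmetic mean (adult body weight)
        mu, sigma = hk.lognormal_params_from_arithmetic(76, 17)
        draws = rng.lognormal(mu, sigma, 400_000)
        assert draws.mean() == pytest.approx(76, rel=5e-3)

    @pytest.mark.parametrize("mean,sd", [(-1, 1), (1, 0), (0, 1)])
    def test_invalid_inputs(self, mean, sd):
        with pytest.raises(ValueError):
            hk.lognormal_params_from_arithmetic(mean, sd)


def _all_distribution_specs(specs):
    out = []
    for spec in specs.values():
        out.append((f"{spec.name}:bw", spec.bw_dist))
        out.append((f"{spec.name}:cyp2e1", spec.cyp2e1_dist))
        out.append((f"{spec.name}:qp_var", spec.qp_var))
        out.append((f"{spec.name}:vl_var", spec.vl_var))
        out.append((f"{spec.name}:ql_var", spec.ql_var))
        if spec.pregnancy_gain_dist is not None:
            out.append((f"{spec.name}:gain", spec.pregnancy_gain_dist))
    return out


class TestTruncatedSampling:
    def test_bounds_never_violated(self, specs, rng):
        for label, dist in _all_distribution_specs(specs):
            draws = hk.sample_truncated(dist, rng, 20_000)
            assert draws.min() >= dist.lower, label
            assert draws.max() <= dist.upper, label

    def test_scalar_draw(self, specs, rng):
        value = hk.sample_truncated(specs["neonates"].cyp2e1_dist, rng)
        assert isinstance(value, float)
        assert 1 <= value <= 56

    def test_geometric_spec_median(self, specs, rng):
        # adult CYP2E1: GM 49, GSD 2, bounds 11-130; the asymmetric upper
        # truncation pulls the median slightly below the GM
        draws = hk.sample_truncated(specs["adults"].cyp2e1_dist, rng, 200_000)
        assert np.median(draws) == pytest.approx(46.3, rel=0.03)

    def test_pinched_truncation(self, rng):
        # interval narrow but still above the feasibility guard
        dist = hk.DistributionSpec("truncated-normal", 1.0, 0.1, 1.0, 1.004)
        assert hk.sample_truncated(dist, rng) == pytest.approx(1.0, abs=5e-3)

    def test_negligible_mass_raises(self, rng):
        dist = hk.DistributionSpec("truncated-normal", 0.0, 1.0, 8.0, 9.0)
        with pytest.raises(ValueError, match="negligible"):
            hk.sample_truncated(dist, rng)
        assert MIN_ACCEPTANCE < 1e-3

    def test_variability_term_bounds(self, specs, rng):
        draws = hk.sample_truncated(specs["adults"].qp_var, rng, 50_000)
        assert draws.min() >= 0.8 and draws.max() <= 1.2


class TestAllometry:
    def test_alveolar_ventilation_point_values(self):
        # hand evaluation of the mean-of-two-power-laws formula, L/min -> L/h
        assert hk.compute_qp(76, 1.0) == pytest.approx(425.9, rel=1e-3)
        assert hk.compute_qp(4, 1.0) == pytest.approx(43.93, rel=1e-3)

    def test_ventilation_variability_ratio(self):
        for bw in (4, 13, 76):
            ratio = hk.compute_qp(bw, 1.2) / hk.compute_qp(bw, 0.8)
            assert ratio == pytest.approx(1.5, rel=1e-12)

    def test_liver_volume_point_values(self):
        assert hk.compute_vl(76, 1.0) == pytest.approx(1.469, rel=1e-3)
        assert hk.compute_vl(4, 1.0) == pytest.approx(0.1479, rel=1e-3)

    def test_liver_blood_flow(self):
        assert hk.compute_ql(1.469, 1.0) == pytest.approx(81.1, rel=2e-3)
        assert hk.compute_ql(0.1479, 1.0) == pytest.approx(8.16, rel=2e-3)
        # linear in liver volume
        assert hk.compute_ql(2.938, 1.0) == pytest.approx(2 * hk.compute_ql(1.469, 1.0))


class TestCohortSampling:
    def test_individual_invariants(self, specs, rng):
        for name, spec in specs.items():
            ind = hk.sample_individual(spec, rng)
            assert ind.subpop == name
            assert min(ind.bw, ind.cyp2e1, ind.qp, ind.vl, ind.ql) > 0
            assert spec.bw_dist.lower <= ind.bw <= spec.bw_dist.upper
            assert spec.cyp2e1_dist.lower <= ind.cyp2e1 <= spec.cyp2e1_dist.upper
            if name == "pregnant_women":
                assert ind.bw <= ind.bw_pregnant <= ind.bw + 14.1
            else:
                assert ind.bw_pregnant == ind.bw

    def test_neonate_weights_in_range(self, specs, rng):
        cohort = hk.sample_cohort(specs["neonates"], 20_000, rng)
        assert cohort.bw.min() >= 2 and cohort.bw.max() <= 7

    def test_adult_median_weight_near_geometric_mean(self, specs, rng):
        cohort = hk.sample_cohort(specs["adults"], 100_000, rng)
        # GM of the 76 +/- 17 lognormal is 74.2 kg; truncation is nearly
        # symmetric so the sampled median sits on it
        assert np.median(cohort.bw) == pytest.approx(74.2, rel=0.02)

    def test_seed_determinism(self, specs):
        a = hk.sample_cohort(specs["adults"], 2_000, np.random.default_rng(7))
        b = hk.sample_cohort(specs["adults"], 2_000, np.random.default_rng(7))
        c = hk.sample_cohort(specs["adults"], 2_000, np.random.default_rng(8))
        assert a.equals(b)
        assert not a.bw.equals(c.bw)

    def test_pregnancy_raises_ventilation(self, specs):
        pw = specs["pregnant_women"]
        cohort = hk.sample_cohort(pw, 50_000, np.random.default_rng(3))
        # ventilation is stochastically above the non-pregnant allometric
        # value for the same women (gain >= 0 and qp_scale > 1)
        assert np.all(cohort.qp >= hk.compute_qp(cohort.bw, 0.8))
        assert np.median(cohort.qp) > np.median(hk.compute_qp(cohort.bw, 1.0))
        # qp is bounded by the variability envelope at the pregnant weight
        assert np.all(cohort.qp <= hk.compute_qp(cohort.bw_pregnant, 1.2) * pw.qp_scale + 1e-9)
        # liver volume and blood flow use the non-pregnant weight
        assert np.all(cohort.vl <= hk.compute_vl(cohort.bw, 1.34) + 1e-9)
        assert np.all(cohort.vl >= hk.compute_vl(cohort.bw, 0.66) - 1e-9)
        assert np.all(cohort.ql <= hk.compute_ql(cohort.vl, 1.33) + 1e-9)
        assert np.all(cohort.ql >= hk.compute_ql(cohort.vl, 0.67) - 1e-9)

    def test_empty_cohort_rejected(self, specs, rng):
        with pytest.raises(ValueError):
            hk.sample_cohort(specs["adults"], 0, rng)
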