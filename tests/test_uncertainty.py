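"""Parameter catalogue, LHS stratification, quantiles, K-S fitting, UF."""

import numpy as np
import pytest
import scipy.stats as st

import respdose as rd
from respdose.uncertainty import (
    DistributionSpec,
    UncertainParameter,
    UncertainParameterSet,
    UncertaintyError,
    quantile,
    required_sample_size,
)


class TestReferenceTable:
    def test_eighteen_parameters_with_expected_names(self):
        params = rd.reference_parameter_table()
        assert len(params) == 18
        assert params.names[0] == "Fn"
        assert params.names[-1] == "K_factor"
        assert "Cae_AI" in params.names and "fd_bbseq" in params.names

    def test_fn_is_right_angled_triangular(self):
        fn = rd.reference_parameter_table().parameters[0]
        assert fn.spec.family == "triangular"
        assert fn.spec.params == (0.4, 1.0, 1.0)

    def test_cae_et1_lognormal(self):
        p = {q.name: q for q in rd.reference_parameter_table().parameters}
        assert p["Cae_ET1"].spec.family == "lognormal"
        assert p["Cae_ET1"].spec.params == (1.00, 1.82)

    def test_kpt_lognormal_median_unity(self):
        p = {q.name: q for q in rd.reference_parameter_table().parameters}
        assert p["K_factor"].spec.params == (1.0, 1.73)
        assert p["K_factor"].spec.median == pytest.approx(1.0)

    def test_bindings_cover_all_model_slots(self):
        kinds = [p.binding[0] for p in rd.reference_parameter_table().parameters]
        assert kinds.count("c_ae") == 5 and kinds.count("c_th") == 5
        assert kinds.count("f_d") == 3 and kinds.count("rate") == 3
        assert kinds.count("fn") == 1 and kinds.count("kpt") == 1

    def test_deposition_multiplier_gsds_match_scaling_constants(self):
        """Table GSDs equal sqrt(c_i) of the bundled scaling constants."""
        constants = rd.deposition.load_deposition_constants()
        p = {q.name: q for q in rd.reference_parameter_table().parameters}
        for region in ("ET1", "ET2", "BB", "bb", "AI"):
            assert p[f"Cae_{region}"].spec.params[1] == pytest.approx(
                constants.multiplier_gsd(region, "ae"), abs=5e-3
            )


def bisection_quantile(spec, u, lo, hi, tol=1e-12):
    def cdf(x):
        if spec.family == "lognormal":
            gm, gsd = spec.params
            return st.norm.cdf((np.log(x) - np.log(gm)) / np.log(gsd))
        a, m, b = spec.params
        if x <= a:
            return 0.0
        if x >= b:
            return 1.0
        if x <= m:
            return (x - a) ** 2 / ((b - a) * (m - a)) if m > a else 0.0
        return 1.0 - (b - x) ** 2 / ((b - a) * (b - m))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < u:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestQuantiles:
    def test_lognormal_median(self):
        spec = DistributionSpec("lognormal", (1.0, 1.82))
        assert quantile(spec, 0.5) == pytest.approx(1.0)

    def test_triangular_endpoints(self):
        spec = DistributionSpec("triangular", (0.4, 1.0, 1.0))
        assert quantile(spec, 0.0) == pytest.approx(0.4)
        assert quantile(spec, 1.0) == pytest.approx(1.0)

    def test_lognormal_upper_tail_matches_bisection(self):
        spec = DistributionSpec("lognormal", (1.0, 1.73))
        ours = float(quantile(spec, 0.975))
        ref = bisection_quantile(spec, 0.975, 1e-6, 1e3)
        assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("family,params,lo,hi", [
        ("lognormal", (0.002, 1.73), 1e-9, 10.0),
        ("lognormal", (1.0, 4.5), 1e-9, 1e6),
        ("triangular", (0.4, 1.0, 1.0), 0.4, 1.0),
        ("triangular", (0.3, 0.6, 1.0), 0.3, 1.0),
    ])
    def test_quantiles_match_bisection_on_random_probabilities(
        self, family, params, lo, hi, rng
    ):
        spec = DistributionSpec(family, params)
        for u in rng.uniform(0.01, 0.99, 20):
            assert float(quantile(spec, u)) == pytest.approx(
                bisection_quantile(spec, u, lo, hi), abs=1e-10
            )

    def test_triangular_cdf_round_trip_against_scipy(self, rng):
        a, m, b = 0.3, 0.6, 1.0
        spec = DistributionSpec("triangular", (a, m, b))
        u = rng.uniform(0, 1, 50)
        ours = quantile(spec, u)
        scipy_q = st.triang.ppf(u, c=(m - a) / (b - a), loc=a, scale=b - a)
        assert np.allclose(ours, scipy_q, atol=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(UncertaintyError):
            DistributionSpec("lognormal", (0.0, 1.5))
        with pytest.raises(UncertaintyError):
            DistributionSpec("triangular", (1.0, 0.5, 0.9))
        with pytest.raises(UncertaintyError):
            quantile(DistributionSpec("lognormal", (1.0, 2.0)), 1.5)


class TestLHS:
    def test_two_strata_straddle_the_median(self):
        params = rd.reference_parameter_table()
        design = rd.lhs_design(params, 2, seed=5)
        for j, p in enumerate(params.parameters):
            med = p.spec.median
            col = np.sort(design.values[:, j])
            assert col[0] <= med <= col[1]

    def test_quartile_occupancy_at_n_4(self):
        params = rd.reference_parameter_table()
        design = rd.lhs_design(params, 4, seed=9)
        for j, p in enumerate(params.parameters):
            edges = quantile(p.spec, np.array([0.25, 0.5, 0.75]))
            counts = np.histogram(
                design.values[:, j],
                bins=[-np.inf, *edges, np.inf],
            )[0]
            assert np.all(counts == 1)

    def test_stratification_exact_for_all_n_up_to_100(self):
        """Mapping samples through the CDF occupies each of the n strata once."""
        spec_ln = DistributionSpec("lognormal", (1.0, 1.73))
        spec_tr = DistributionSpec("triangular", (0.4, 1.0, 1.0))
        params = UncertainParameterSet(
            (
                UncertainParameter("a", spec_ln, ("kpt",)),
                UncertainParameter("b", spec_tr, ("fn",)),
            )
        )
        for n in range(1, 101):
            design = rd.lhs_design(params, n, seed=n)
            u_ln = st.norm.cdf(np.log(design.values[:, 0]) / np.log(1.73))
            u_tr = (design.values[:, 1] - 0.4) ** 2 / (0.6 * 0.6)
            for u in (u_ln, u_tr):
                strata = np.floor(u * n).astype(int)
                assert sorted(strata) == list(range(n))

    def test_large_design_kpt_median_close_to_unity(self):
        params = rd.reference_parameter_table()
        design = rd.lhs_design(params, 10_000, seed=3)
        k = design.values[:, list(params.names).index("K_factor")]
        assert abs(np.median(k) - 1.0) < 0.02
        # log-SD converges to ln(GSD) within stratified-sampling error
        assert np.log(k).std(ddof=1) == pytest.approx(np.log(1.73), rel=0.02)

    def test_seed_determinism_and_n_validation(self):
        params = rd.reference_parameter_table()
        a = rd.lhs_design(params, 16, seed=7)
        b = rd.lhs_design(params, 16, seed=7)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(UncertaintyError):
            rd.lhs_design(params, 0, seed=1)


class TestSampleSize:
    def test_unit_ratio(self):
        assert required_sample_size(sd=1.0, precision=1.0) == 4

    def test_zero_sd_floor(self):
        assert required_sample_size(sd=0.0, precision=1.0) == 1

    def test_invalid_precision(self):
        with pytest.raises(UncertaintyError):
            required_sample_size(sd=1.0, precision=0.0)

    def test_ci_half_width_simulation(self, rng):
        """At the returned n, the empirical 95% CI half-width of the mean is
        within 10% of the requested precision."""
        sd, e = 1.0, 0.2
        n = required_sample_size(sd, e)
        means = rng.normal(0.0, sd, size=(500, n)).mean(axis=1)
        half_width = 1.959964 * means.std(ddof=1)
        assert half_width == pytest.approx(e, rel=0.10)


class TestSummaries:
    def test_constant_vector(self):
        out = rd.summarize(np.full(10, 3.3))
        assert out["mean"] == 3.3 and out["sd"] == 0.0
        assert out["p2.5"] == out["p97.5"] == 3.3

    def test_percentiles_match_sort_interpolate_oracle(self):
        values = np.arange(1.0, 101.0)
        out = rd.summarize(values)

        def oracle(q):
            pos = q / 100 * (len(values) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            srt = np.sort(values)
            return srt[lo] * (1 - frac) + srt[min(lo + 1, len(values) - 1)] * frac

        for key, q in [("p2.5", 2.5), ("p25", 25), ("p50", 50), ("p75", 75), ("p97.5", 97.5)]:
            assert out[key] == pytest.approx(oracle(q), rel=1e-12)
        assert out["sd"] == pytest.approx(np.std(values, ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(UncertaintyError):
            rd.summarize(np.array([]))


def ks_sup_distance_oracle(values, cdf):
    """Explicit sup-distance between the eCDF and a theoretical CDF."""
    x = np.sort(values)
    n = len(x)
    f = cdf(x)
    upper = np.max(np.arange(1, n + 1) / n - f)
    lower = np.max(f - np.arange(0, n) / n)
    return max(upper, lower)


class TestDistributionFitting:
    def test_ks_distance_equals_sup_distance_oracle(self, rng):
        values = rng.lognormal(-18, 0.4, 500)
        fitted = st.lognorm.fit(values)
        ks = st.kstest(values, "lognorm", args=fitted)
        oracle = ks_sup_distance_oracle(
            values, lambda x: st.lognorm.cdf(x, *fitted)
        )
        assert ks.statistic == pytest.approx(oracle, abs=1e-12)

    def test_quantile_matched_sample_attains_minimal_distance(self):
        """A sample placed at CDF quantiles (i - 0.5)/n has D = 1/(2n)."""
        n = 200
        values = st.norm.ppf((np.arange(1, n + 1) - 0.5) / n, loc=2.0, scale=3.0)
        ks = st.kstest(values, "norm", args=(2.0, 3.0))
        assert ks.statistic == pytest.approx(1.0 / (2 * n), abs=1e-12)

    def test_known_generator_recovery(self):
        """5000 seeded normal draws: the normal fit is statistically adequate
        and the winner lies in the normal-nesting family group (MLE-fitted
        three-parameter families may edge out the normal itself by K-S D)."""
        values = np.random.default_rng(7).standard_normal(5000)
        fits = rd.best_fit_distribution(
            values, candidates=("norm", "lognorm", "gamma", "loggamma", "uniform")
        )
        by_name = {f.family: f for f in fits}
        assert by_name["norm"].p_value > 0.05
        assert fits[0].family in {"norm", "lognorm", "gamma", "loggamma"}
        assert fits[-1].family == "uniform"
        assert fits[0].accepted

    def test_rankings_sorted_by_distance(self, rng):
        values = rng.lognormal(-18, 0.3, 400)
        fits = rd.best_fit_distribution(values)
        ds = [f.d_statistic for f in fits]
        assert ds == sorted(ds)
        assert all(0 <= f.d_statistic <= 1 and 0 <= f.p_value <= 1 for f in fits)

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(UncertaintyError):
            rd.best_fit_distribution(np.ones(30))
        with pytest.raises(UncertaintyError, match="constant"):
            rd.best_fit_distribution(np.ones(100))


class TestUncertaintyFactor:
    def test_degenerate_interval(self):
        assert rd.uncertainty_factor(2.0, 2.0, 2.0).uf == 1.0

    def test_scale_invariance(self, rng):
        c, ql, qu = 1.1e-8, 8.45e-9, 1.14e-8
        base = rd.uncertainty_factor(c, ql, qu).uf
        for alpha in rng.lognormal(0, 2, 5):
            assert rd.uncertainty_factor(alpha * c, alpha * ql, alpha * qu).uf == pytest.approx(base)

    def test_nonpositive_rejected(self):
        with pytest.raises(UncertaintyError):
            rd.uncertainty_factor(1.0, 0.0, 2.0)

    def test_inside_interval_implies_uf_at_least_one(self, rng):
        for _ in range(20):
            ql, qu = np.sort(rng.lognormal(0, 1, 2))
            c = rng.uniform(ql, qu)
            assert rd.uncertainty_factor(c, ql, qu).uf >= 1.0


@pytest.fixture(scope="module")
def neutral_params():
    """Point masses at neutral values (reference model)."""
    ref = rd.reference_parameter_table()
    neutral = {"fn": 1.0, "kpt": 1.0, "c_ae": 1.0, "c_th": 1.0, "f_d": 0.002}
    rates = {"l_alv_int": 0.001, "l_alv_bb": 0.002, "l_int_lnth": 0.00003}
    out = []
    for p in ref.parameters:
        kind = p.binding[0]
        value = rates[p.binding[1]] if kind == "rate" else neutral[kind]
        out.append(
            UncertainParameter(p.name, DistributionSpec("fixed", (value,)), p.binding)
        )
    return UncertainParameterSet(tuple(out))


class TestPropagation:
    def test_degenerate_design_reproduces_deterministic(
        self, worker, aerosol_5um, s_pair, neutral_params
    ):
        design = rd.lhs_design(neutral_params, 3, seed=1)
        sample = rd.propagate(
            design, aerosol_5um, worker, s_pair, params=neutral_params, tau_d=365.25
        )
        expected = rd.deterministic_cedc(
            aerosol_5um, worker, s_pair, tau_d=365.25
        ).effective
        assert np.allclose(sample.values, expected, rtol=1e-12)

    def test_small_run_positive_and_bit_reproducible(self, worker, aerosol_5um, s_pair):
        params = rd.reference_parameter_table()
        design = rd.lhs_design(params, 16, seed=21)
        a = rd.propagate(design, aerosol_5um, worker, s_pair, tau_d=365.25)
        b = rd.propagate(design, aerosol_5um, worker, s_pair, tau_d=365.25)
        assert np.array_equal(a.values, b.values)
        assert np.all(a.values > 0) and len(a.values) == 16

    def test_mismatched_design_rejected(self, worker, aerosol_5um, s_pair, neutral_params):
        design = rd.lhs_design(neutral_params, 2, seed=1)
        bad = rd.DesignMatrix(design.values, tuple("c" + n for n in design.names), 1)
        with pytest.raises(UncertaintyError):
            rd.propagate(bad, aerosol_5um, worker, s_pair)
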