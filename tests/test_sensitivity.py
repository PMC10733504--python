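"""One-way DSA, ART-uptake threshold analysis and PSA machinery."""

import numpy as np
import pytest
from scipy import stats

from deafcea.model import ModelVariant, icer_magnitude, run_model
from deafcea.parameters import PROBABILITY_BLOCKS, load_parameters
from deafcea.sensitivity import (
    DistSpec,
    art_uptake_sweep,
    ceac,
    ellipse_contains,
    fit_coverage_ellipse,
    one_way,
    perturb,
    run_psa,
    sample_parameters,
    span_for,
    tornado,
)


class TestOneWay:
    def test_perturbed_blocks_stay_on_simplex(self, params):
        q = perturb(params, "p.med_art", 0.30)
        assert q.get("p.med_art") == 0.30
        for keys in PROBABILITY_BLOCKS.values():
            assert sum(q.get(k) for k in keys) == pytest.approx(1.0, abs=1e-9)
        # non-perturbed members keep their relative proportions
        assert q.get("p.med_amnio") / q.get("p.med_natural") == pytest.approx(
            params.get("p.med_amnio") / params.get("p.med_natural")
        )

    def test_higher_art_uptake_lowers_cost_per_healthy_birth(self, params):
        entry = one_way(params, "p.med_art", ModelVariant.HEALTHY_COUNT)
        assert entry.icer_low > entry.icer_base > entry.icer_high

    def test_cost_span_moves_icer_monotonically(self, params):
        entry = one_way(params, "c.intervention.art_pgt", ModelVariant.DEAF_COUNT)
        assert entry.icer_low < entry.icer_base < entry.icer_high
        assert entry.swing > 0

    def test_reproductive_cost_effect_is_purely_differential_birth_mass(self, params):
        # the delivery cost hits both arms; its ICER effect comes only from
        # the arms' different birth masses (screening has childless paths)
        entry = one_way(params, "c.intervention.reproductive", ModelVariant.DEAF_COUNT)
        for value, observed in ((entry.span.low, entry.icer_low), (entry.span.high, entry.icer_high)):
            q = perturb(params, "c.intervention.reproductive", value)
            mr = run_model(q, ModelVariant.DEAF_COUNT)
            base = run_model(params, ModelVariant.DEAF_COUNT)
            mass_gap = (
                base.screening.outcome_mass["no_birth"]
                - base.status_quo.outcome_mass["no_birth"]
            )
            predicted = base.comparison.delta_cost - (value - 651.00) * mass_gap
            assert mr.comparison.delta_cost == pytest.approx(predicted, rel=1e-9)
            assert observed == pytest.approx(icer_magnitude(mr.comparison), rel=1e-12)

    def test_span_rule_by_provenance(self, params):
        survey = span_for(params, "c.screening.test")  # survey-sourced
        literature = span_for(params, "c.intervention.reproductive")
        assert survey.span_rule == "pm20"
        assert literature.span_rule == "pm10"

    def test_probability_span_clipped_at_one_with_warning(self, params):
        with pytest.warns(UserWarning, match="clipped"):
            span = span_for(params, "p.deaf_given_high_natural", "pm20")
        assert span.high == 1.0

    def test_tornado_sorted_by_swing_with_one_entry_per_parameter(self, params):
        ids = ["p.med_art", "c.intervention.art_pgt", "c.screening.test", "p.high_risk_birth"]
        entries = tornado(params, ids, ModelVariant.HEALTHY_COUNT)
        assert sorted(e.parameter for e in entries) == sorted(ids)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_tornado_over_all_scalar_inputs_completes(self, params):
        ids = [k for k in params.to_config() if k.startswith(("c.", "p."))]
        entries = tornado(params, ids, ModelVariant.DEAF_COUNT)
        assert len(entries) == len(ids)
        assert all(np.isfinite(e.icer_base) for e in entries)


class TestThreshold:
    def test_base_uptake_reproduces_base_model(self, params):
        curve = art_uptake_sweep(params, [0.0, 0.1774, 0.9])
        mr = run_model(params, ModelVariant.HEALTHY_COUNT)
        i = 1
        assert curve.uptake[i] == 0.1774
        assert curve.incr_healthy[i] == pytest.approx(mr.comparison.delta_eff, rel=1e-12)

    def test_break_even_close_to_published_threshold(self, params):
        curve = art_uptake_sweep(params, np.linspace(0, 1, 21))
        assert curve.break_even_uptake == pytest.approx(0.174, abs=0.02)

    def test_proportional_rule_gives_lower_break_even(self, params):
        na = art_uptake_sweep(params, [0.0, 0.5, 1.0], "none_absorbing")
        prop = art_uptake_sweep(params, [0.0, 0.5, 1.0], "proportional")
        assert prop.break_even_uptake < na.break_even_uptake

    def test_full_uptake_forces_art_outcome_for_medium_risk(self, params):
        # at u=1 every medium-risk couple conceives through ART with PGT
        from deafcea.sensitivity import _uptake_parameters

        q = _uptake_parameters(params, 1.0, "none_absorbing")
        assert q.get("p.med_art") == 1.0
        assert q.get("p.med_amnio") == 0.0 and q.get("p.med_none") == 0.0
        sc = run_model(q, ModelVariant.DEAF_COUNT).screening
        # childless mass now only from high-risk couples declining birth
        assert sc.outcome_mass["no_birth"] == pytest.approx(
            3.7e-05 * params.behavior.high_risk_none, rel=1e-6
        )

    def test_decreasing_grid_rejected(self, params):
        with pytest.raises(ValueError):
            art_uptake_sweep(params, [0.5, 0.2])


class TestSampling:
    def test_zero_cv_draws_equal_base(self, params):
        spec = DistSpec(cost_cv=0.0, prob_cv=0.0)
        draws = list(sample_parameters(params, seed=5, n=3, dist_spec=spec))
        for q in draws:
            assert q.to_config() == params.to_config()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            DistSpec(cost_cv=-0.1)

    def test_gamma_cost_mean_recovers_base(self, params):
        draws = sample_parameters(params, seed=9, n=10_000)
        vals = np.array([q.get("c.intervention.art_pgt") for q in draws])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 11940.30) <= 3 * se

    def test_sampled_blocks_stay_on_simplex(self, params):
        for q in sample_parameters(params, seed=2, n=200):
            for keys in PROBABILITY_BLOCKS.values():
                assert sum(q.get(k) for k in keys) == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_is_bit_identical(self, params):
        a = [q.to_config() for q in sample_parameters(params, seed=3, n=5)]
        b = [q.to_config() for q in sample_parameters(params, seed=3, n=5)]
        assert a == b


class TestPsa:
    def test_zero_cv_psa_reproduces_deterministic_comparison(self, params):
        spec = DistSpec(cost_cv=0.0, prob_cv=0.0)
        res = run_psa(params, ModelVariant.DEAF_COUNT, n=10, seed=0, dist_spec=spec)
        mr = run_model(params, ModelVariant.DEAF_COUNT)
        assert np.all(res.delta_cost == mr.comparison.delta_cost)
        assert np.all(res.delta_eff == mr.comparison.delta_eff)

    def test_ceac_at_zero_wtp_counts_cost_saving_draws(self, params):
        res = run_psa(params, ModelVariant.HEALTHY_COUNT, n=500, seed=4)
        expected = float((res.delta_cost <= 0).mean())
        assert res.ceac.probability[0] == pytest.approx(expected)

    def test_ceac_matches_brute_force_indicator_recount(self, params):
        res = run_psa(params, ModelVariant.HEALTHY_COUNT, n=300, seed=8)
        for w, prob in zip(res.ceac.wtp, res.ceac.probability):
            count = sum(
                1
                for dc, de in zip(res.delta_cost, res.delta_eff)
                if w * de - dc >= 0
            )
            assert prob == count / res.n

    def test_degenerate_single_sign_draws(self):
        curve = ceac(np.array([-1.0]), np.array([0.0]), [0.0, 1e6])
        assert np.all(curve.probability == 1.0)
        curve = ceac(np.array([1.0]), np.array([0.0]), [0.0, 1e6])
        assert np.all(curve.probability == 0.0)

    def test_ceac_recovers_normal_cdf_shape(self):
        rng = np.random.default_rng(0)
        dc = rng.normal(0.0, 1.0, 20_000)
        de = np.ones_like(dc)
        curve = ceac(dc, de, [0.0])
        # P(w*1 - dc >= 0) at w=0 is Phi(0) = 0.5
        assert curve.probability[0] == pytest.approx(0.5, abs=0.02)

    def test_psa_seed_determinism(self, params):
        a = run_psa(params, ModelVariant.UTILITY, n=50, seed=21)
        b = run_psa(params, ModelVariant.UTILITY, n=50, seed=21)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_eff, b.delta_eff)

    def test_ellipse_covers_95_percent_of_bivariate_normal(self):
        rng = np.random.default_rng(77)
        n = 10_000
        pts = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.8], [0.8, 1.0]], size=n)
        ell = fit_coverage_ellipse(pts[:, 0], pts[:, 1], level=0.95)
        frac = ellipse_contains(ell, pts[:, 0], pts[:, 1]).mean()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.95) / n
        assert lo <= frac <= hi
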