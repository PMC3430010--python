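"""Decision-theoretic machinery: likelihoods, thresholds, optimal windows."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from twinrt import (
    CSP,
    FAP_VISUAL,
    DecisionContext,
    NoOptimalWindowError,
    TwinConfigError,
    TwinParams,
    cre,
    cre_optimal,
    decision_threshold,
    density_common,
    density_separate,
    likelihood_ratio,
    optimal_window_closed_form,
    optimal_window_numeric,
    posterior_common,
)

LAM = 0.03  # reference matched rate, 1/ms
S = 1000.0  # reference observation-interval length, ms


def ctx_for(paradigm, p, s=S, **payoffs):
    maker = (
        DecisionContext.for_fap if paradigm.is_fap else DecisionContext.for_csp
    )
    return maker(p, s, **payoffs)


class TestContexts:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_common=0.0, t0=0, t1=100),
            dict(p_common=1.5, t0=0, t1=100),
            dict(p_common=0.5, t0=100, t1=100),
            dict(p_common=0.5, t0=0, t1=100, u11=0.0, u10=0.0),  # u11 == u10
            dict(p_common=0.5, t0=0, t1=100, u21=2.0),  # u20 < u21
        ],
    )
    def test_invalid_contexts_rejected(self, kwargs):
        with pytest.raises(TwinConfigError):
            DecisionContext(**kwargs)

    def test_paradigm_interval_conventions(self):
        with pytest.raises(TwinConfigError):
            DecisionContext.for_csp(0.5, S).validate_for(FAP_VISUAL)
        with pytest.raises(TwinConfigError):
            DecisionContext(0.5, -100.0, 100.0).validate_for(CSP)

    def test_dict_round_trip(self):
        ctx = DecisionContext(0.3, -200.0, 300.0, u20=2.0)
        assert DecisionContext.from_dict(ctx.to_dict()) == ctx


class TestDensities:
    def test_uniform_separate_source_density(self):
        ctx = DecisionContext(0.5, 0.0, 1000.0)
        assert density_separate(500.0, ctx) == 0.001
        assert density_separate(-1.0, ctx) == 0.0
        assert density_separate(1001.0, ctx) == 0.0
        assert quad(density_separate, ctx.t0, ctx.t1, args=(ctx,))[0] == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize("lv,la", [(0.03, 0.03), (0.01, 0.05), (0.2, 0.002)])
    def test_common_source_densities_normalize(self, lv, la):
        fap_mass = (
            quad(density_common, -np.inf, 0.0, args=(lv, la, FAP_VISUAL), limit=200)[0]
            + quad(density_common, 0.0, np.inf, args=(lv, la, FAP_VISUAL), limit=200)[0]
        )
        csp_mass = quad(
            density_common, 0.0, np.inf, args=(lv, la, CSP), limit=200
        )[0]
        assert fap_mass == pytest.approx(1.0, abs=1e-8)
        assert csp_mass == pytest.approx(1.0, abs=1e-8)

    def test_matched_peak_heights(self):
        assert density_common(0.0, LAM, LAM, FAP_VISUAL) == pytest.approx(LAM / 2)
        assert density_common(0.0, LAM, LAM, CSP) == pytest.approx(LAM)

    def test_absolute_difference_density_folds_the_signed_one(self):
        for t in np.linspace(0.0, 400.0, 23):
            folded = density_common(t, 0.01, 0.04, FAP_VISUAL) + density_common(
                -t, 0.01, 0.04, FAP_VISUAL
            )
            assert density_common(t, 0.01, 0.04, CSP) == pytest.approx(
                folded, rel=1e-12
            )

    def test_csp_rejects_signed_differences(self):
        with pytest.raises(ValueError):
            density_common(-5.0, 0.01, 0.01, CSP)


class TestLikelihoodAndPosterior:
    def test_reference_likelihood_ratios_at_zero_disparity(self):
        assert likelihood_ratio(
            0.0, LAM, LAM, ctx_for(FAP_VISUAL, 0.5), FAP_VISUAL
        ) == pytest.approx(15.0)
        assert likelihood_ratio(
            1e-12, LAM, LAM, ctx_for(CSP, 0.5), CSP
        ) == pytest.approx(30.0)

    def test_likelihood_peaks_at_simultaneity(self):
        ctx = ctx_for(FAP_VISUAL, 0.5)
        peak = likelihood_ratio(0.0, 0.02, 0.05, ctx, FAP_VISUAL)
        for t in (-300.0, -20.0, 5.0, 150.0):
            assert likelihood_ratio(t, 0.02, 0.05, ctx, FAP_VISUAL) < peak

    def test_rejects_disparities_outside_observation_interval(self):
        with pytest.raises(ValueError):
            likelihood_ratio(600.0, LAM, LAM, ctx_for(FAP_VISUAL, 0.5), FAP_VISUAL)

    def test_posterior_is_bayes_rule(self):
        ctx = ctx_for(CSP, 0.5)
        for t in (1.0, 30.0, 200.0):
            lr = likelihood_ratio(t, LAM, LAM, ctx, CSP)
            assert posterior_common(t, LAM, LAM, ctx, CSP) == pytest.approx(
                lr / (lr + 1.0)
            )
        certain = DecisionContext.for_csp(1.0, S)
        assert posterior_common(123.0, LAM, LAM, certain, CSP) == 1.0

    def test_csp_posterior_decreases_with_disparity(self):
        ctx = ctx_for(CSP, 0.3)
        grid = np.linspace(1.0, 900.0, 40)
        post = [posterior_common(t, 0.01, 0.04, ctx, CSP) for t in grid]
        assert all(a > b for a, b in zip(post, post[1:]))


class TestDecisionThreshold:
    def test_prior_odds_with_unit_utilities(self):
        assert decision_threshold(DecisionContext(0.5, 0, S)) == pytest.approx(1.0)
        assert decision_threshold(DecisionContext(0.2, 0, S)) == pytest.approx(4.0)

    def test_threshold_falls_as_prior_rises(self):
        priors = np.linspace(0.05, 0.95, 19)
        th = [decision_threshold(DecisionContext(p, 0, S)) for p in priors]
        assert all(a > b for a, b in zip(th, th[1:]))

    def test_payoffs_scale_the_threshold(self):
        base = DecisionContext(0.5, 0, S)
        costly = DecisionContext(0.5, 0, S, u21=-1.0)  # u20 − u21 doubled
        assert decision_threshold(costly) == pytest.approx(
            2.0 * decision_threshold(base)
        )


class TestClosedFormWindow:
    def test_reference_widths(self):
        fap = optimal_window_closed_form(LAM, ctx_for(FAP_VISUAL, 0.5), FAP_VISUAL)
        csp = optimal_window_closed_form(LAM, ctx_for(CSP, 0.5), CSP)
        assert fap.width == pytest.approx(180.54, abs=5e-3)
        assert csp.width == pytest.approx(113.37, abs=5e-3)
        assert fap.lower == pytest.approx(-fap.upper)  # symmetric about 0
        assert csp.lower == 0.0

    def test_existence_thresholds(self):
        p_csp = 1.0 / (LAM * S + 1.0)  # ≈ 0.03226
        p_fap = 2.0 / (LAM * S + 2.0)  # = 0.0625
        assert p_csp == pytest.approx(0.03226, abs=5e-6)
        assert p_fap == pytest.approx(0.0625)
        eps = 1e-6
        assert optimal_window_closed_form(LAM, ctx_for(CSP, p_csp + eps), CSP).exists
        assert not optimal_window_closed_form(LAM, ctx_for(CSP, p_csp - eps), CSP).exists
        assert optimal_window_closed_form(
            LAM, ctx_for(FAP_VISUAL, p_fap + eps), FAP_VISUAL
        ).exists
        below = optimal_window_closed_form(
            LAM, ctx_for(FAP_VISUAL, p_fap - eps), FAP_VISUAL
        )
        assert not below.exists and below.width == 0.0

    def test_widths_increase_with_prior_and_interval(self):
        widths_p = [
            optimal_window_closed_form(LAM, ctx_for(CSP, p), CSP).width
            for p in np.linspace(0.1, 0.95, 18)
        ]
        assert all(a < b for a, b in zip(widths_p, widths_p[1:]))
        widths_s = [
            optimal_window_closed_form(LAM, ctx_for(FAP_VISUAL, 0.5, s), FAP_VISUAL).width
            for s in (200.0, 500.0, 1000.0, 4000.0)
        ]
        assert all(a < b for a, b in zip(widths_s, widths_s[1:]))

    def test_paradigm_crossover_prior(self):
        """FAP window is wider above p* = 4/(λs + 4), narrower below it."""
        p_star = 4.0 / (LAM * S + 4.0)
        assert p_star == pytest.approx(0.11765, abs=5e-6)
        for p in (p_star + 0.01, 0.3, 0.8):
            assert (
                optimal_window_closed_form(LAM, ctx_for(FAP_VISUAL, p), FAP_VISUAL).width
                > optimal_window_closed_form(LAM, ctx_for(CSP, p), CSP).width
            )
        for p in (0.07, p_star - 0.01):
            fap = optimal_window_closed_form(LAM, ctx_for(FAP_VISUAL, p), FAP_VISUAL)
            csp = optimal_window_closed_form(LAM, ctx_for(CSP, p), CSP)
            if fap.exists:
                assert fap.width < csp.width

    def test_clipping_at_observation_interval(self):
        # tiny interval: the unclipped bound exceeds t1
        w = optimal_window_closed_form(0.5, DecisionContext.for_csp(0.99, 10.0), CSP)
        assert w.exists and w.clipped and w.upper == 10.0


class TestNumericWindow:
    def test_matches_closed_form_on_grid(self):
        """Numeric bounds equal the matched-rate closed form to 1e−6 ms on
        a 50-point (λ, p, s) grid."""
        lams = (0.005, 0.01, 0.03, 0.08, 0.2)
        priors = (0.05, 0.12, 0.3, 0.5, 0.9)
        ss = (500.0, 2000.0)
        checked = 0
        for lam in lams:
            for p in priors:
                for s in ss:
                    for paradigm in (CSP, FAP_VISUAL):
                        ctx = ctx_for(paradigm, p, s)
                        cf = optimal_window_closed_form(lam, ctx, paradigm)
                        nm = optimal_window_numeric(lam, lam, ctx, paradigm)
                        assert cf.exists == nm.exists
                        if cf.exists:
                            assert nm.lower == pytest.approx(cf.lower, abs=1e-6)
                            assert nm.upper == pytest.approx(cf.upper, abs=1e-6)
                        checked += 1
        assert checked >= 50

    def test_threshold_above_peak_means_no_window(self):
        ctx = DecisionContext.for_fap(0.001, 100.0)
        assert not optimal_window_numeric(0.01, 0.01, ctx, FAP_VISUAL).exists

    def test_payoff_doubling_equals_halved_prior_odds(self):
        # doubling (u20 − u21) at p = 0.5 yields threshold 2, the same as
        # unit payoffs at prior odds 1/2 (p = 1/3)
        doubled = DecisionContext.for_fap(0.5, S, u21=-1.0)
        odds_half = DecisionContext.for_fap(1.0 / 3.0, S)
        w1 = optimal_window_numeric(LAM, LAM, doubled, FAP_VISUAL)
        w2 = optimal_window_numeric(LAM, LAM, odds_half, FAP_VISUAL)
        assert w1.lower == pytest.approx(w2.lower, abs=1e-6)
        assert w1.upper == pytest.approx(w2.upper, abs=1e-6)

    def test_unmatched_rates_give_asymmetric_window(self):
        ctx = DecisionContext.for_fap(0.5, S)
        w = optimal_window_numeric(0.01, 0.05, ctx, FAP_VISUAL)
        assert w.exists and w.lower < 0.0 < w.upper
        assert abs(w.lower) != pytest.approx(w.upper, rel=1e-3)
        # boundary condition: L equals the threshold at both ends
        for t in (w.lower, w.upper):
            assert likelihood_ratio(t, 0.01, 0.05, ctx, FAP_VISUAL) == pytest.approx(
                decision_threshold(ctx), rel=1e-8
            )

    def test_decision_rule_equivalence_on_grid(self):
        """Membership of t in the window ⇔ the posterior of a common source
        exceeds its payoff-implied cutoff (Bayes consistency)."""
        ctx = ctx_for(CSP, 0.4)
        w = optimal_window_numeric(LAM, LAM, ctx, CSP)
        theta = decision_threshold(ctx)
        p = ctx.p_common
        post_cut = p * theta / (p * theta + (1.0 - p))
        for t in np.linspace(1.0, 900.0, 101):
            inside = w.lower < t < w.upper
            post = posterior_common(t, LAM, LAM, ctx, CSP)
            assert inside == (post > post_cut)


class TestOptimalCRE:
    def test_reference_values(self):
        assert cre_optimal(LAM, ctx_for(CSP, 0.5), 20.0, 100.0, CSP) == pytest.approx(
            27.00, abs=5e-3
        )
        assert cre_optimal(
            LAM, ctx_for(FAP_VISUAL, 0.5), 20.0, 100.0, FAP_VISUAL
        ) == pytest.approx(7.47, abs=5e-3)

    @pytest.mark.parametrize("lam", [0.01, 0.03, 0.1])
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.9])
    def test_consistent_with_direct_enhancement_at_optimal_width(self, lam, p):
        """Plugging ω_opt back into the general enhancement formula must
        reproduce the substituted closed form to 1e−10 relative."""
        for paradigm in (CSP, FAP_VISUAL):
            ctx = ctx_for(paradigm, p)
            w = optimal_window_closed_form(lam, ctx, paradigm)
            params = TwinParams(
                lambda_v=lam, lambda_a=lam, omega=w.width, delta=20.0, mu=100.0
            )
            assert cre_optimal(lam, ctx, 20.0, 100.0, paradigm) == pytest.approx(
                cre(params, paradigm), rel=1e-10
            )

    def test_missing_window_raises(self):
        with pytest.raises(NoOptimalWindowError):
            cre_optimal(LAM, ctx_for(CSP, 0.01), 20.0, 100.0, CSP)

    def test_non_unit_utility_ratio_rejected(self):
        ctx = DecisionContext.for_csp(0.5, S, u20=3.0)
        with pytest.raises(TwinConfigError):
            cre_optimal(LAM, ctx, 20.0, 100.0, CSP)

    def test_csp_dominates_fap_across_grid(self):
        for lam in (0.02, 0.05, 0.2, 1.0):
            for p in (0.2, 0.5, 0.8):
                csp = cre_optimal(lam, ctx_for(CSP, p), 20.0, 100.0, CSP)
                fap = cre_optimal(
                    lam, ctx_for(FAP_VISUAL, p), 20.0, 100.0, FAP_VISUAL
                )
                assert csp >= fap

    def test_ratio_approaches_two_at_high_intensity(self):
        ratios = []
        for lam in (1.0, 10.0, 1000.0):
            csp = cre_optimal(lam, ctx_for(CSP, 0.5), 20.0, 100.0, CSP)
            fap = cre_optimal(lam, ctx_for(FAP_VISUAL, 0.5), 20.0, 100.0, FAP_VISUAL)
            ratios.append(csp / fap)
        assert abs(ratios[-1] - 2.0) < 1e-3
        assert abs(ratios[1] - 2.0) < abs(ratios[0] - 2.0)


def test_integration_probability_identity_at_optimal_width():
    """e^{−λω_opt} inside the substituted enhancement equals the survival
    term the integration probability uses, to 1e−12 relative."""
    for p in (0.2, 0.5, 0.9):
        ctx = DecisionContext.for_csp(p, S)
        w = optimal_window_closed_form(LAM, ctx, CSP)
        assert math.exp(-LAM * w.width) == pytest.approx(
            (1.0 - p) / (LAM * p * S), rel=1e-12
        )
        ctx_f = DecisionContext.for_fap(p, S)
        wf = optimal_window_closed_form(LAM, ctx_f, FAP_VISUAL)
        assert math.exp(-LAM * wf.width) == pytest.approx(
            (2.0 * (1.0 - p) / (LAM * p * S)) ** 2, rel=1e-12
        )
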