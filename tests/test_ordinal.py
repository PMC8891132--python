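"""Prior elicitation, cumulative-logit likelihood oracles, and model fits."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from csbayes.cohort import ContingencyTable, MutationGroup, build_contingency, filter_analyzable
from csbayes.mcmc import McmcSettings
from csbayes.ordinal import (
    OrdinalSeverityModel,
    PriorSpec,
    elicit_normal_prior,
    fit_ordinal,
    prior_or_interval,
    sensitivity_suite,
)
from csbayes.synthgen import CohortSimSpec, expand_table, generate_cohort

from conftest import short_settings

Z975 = 1.959964


class TestElicitation:
    @pytest.mark.parametrize(
        "bounds, mu, sigma2",
        [
            ((0.2, 5), 0.000, 0.674),
            ((0.9, 10), 1.099, 0.377),
            ((0.75, 5), 0.661, 0.234),
        ],
    )
    def test_published_priors_recovered_exactly(self, bounds, mu, sigma2):
        prior = elicit_normal_prior(*bounds)
        assert prior.mu == pytest.approx(mu, abs=5e-4)
        assert prior.sigma2 == pytest.approx(sigma2, abs=5e-4)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            elicit_normal_prior(5, 0.2)
        with pytest.raises(ValueError):
            elicit_normal_prior(-1, 2)
        with pytest.raises(ValueError):
            elicit_normal_prior(0.2, 5, coverage=1.2)

    def test_precise_prior_interval_roundtrip(self):
        lo, hi = prior_or_interval(PriorSpec(0.0, 0.674))
        assert round(lo, 1) == 0.2 and round(hi, 1) == 5.0

    def test_vague_prior_interval_upper_bound(self):
        _, hi = prior_or_interval(PriorSpec(0.0, 1000.0))
        assert hi == pytest.approx(math.exp(Z975 * math.sqrt(1000.0)), rel=1e-6)
        assert f"{hi:.1e}" == "8.3e+26"

    def test_elicit_interval_inverse_pair(self):
        prior = elicit_normal_prior(0.35, 4.2)
        lo, hi = prior_or_interval(prior)
        again = elicit_normal_prior(lo, hi)
        assert again.mu == pytest.approx(prior.mu, abs=2e-3)
        assert again.sigma2 == pytest.approx(prior.sigma2, abs=2e-3)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, 0.0)


class TestLogPosteriorOracles:
    def test_intercept_only_likelihood_attains_saturated_multinomial(self, table2):
        # with beta = 0 and cutpoints at the pooled empirical cumulative
        # logits, the likelihood equals the intercept-only multinomial max
        model = OrdinalSeverityModel.from_table(table2)
        totals = model.counts.sum(axis=0)
        n = totals.sum()
        c1, c2 = totals[0] / n, (totals[0] + totals[1]) / n
        t1 = math.log(c1 / (1 - c1))
        t2 = math.log(c2 / (1 - c2))
        got = model.log_likelihood((t1, t2), (0.0, 0.0))
        oracle = sum(tk * math.log(tk / n) for tk in totals)
        assert got == pytest.approx(oracle, rel=1e-12)
        # and no beta-free configuration does better
        res = minimize(
            lambda v: -model.log_likelihood((v[0], v[0] + math.exp(v[1])), (0.0, 0.0)),
            [t1, math.log(t2 - t1)],
        )
        assert -res.fun == pytest.approx(oracle, abs=1e-8)

    def test_likelihood_linear_in_counts(self, table2):
        model = OrdinalSeverityModel.from_table(table2)
        doubled = OrdinalSeverityModel.from_table(ContingencyTable(table2.counts * 2))
        theta, beta = (-1.5, 0.3), (0.2, -0.4)
        assert doubled.log_likelihood(theta, beta) == pytest.approx(
            2 * model.log_likelihood(theta, beta), rel=1e-12
        )

    def test_two_group_two_category_mle_is_log_cumulative_or(self):
        # categories III/I only; closed form: beta-hat = logit(p1|ref) - logit(p1|x)
        counts = np.array([[10, 5, 0], [4, 12, 0]])
        model = OrdinalSeverityModel(
            counts, np.array([[0.0], [1.0]]), ["x"], PriorSpec.vague()
        )
        res = minimize(
            lambda v: -model.log_likelihood((v[0], 50.0), (v[1],)), [0.0, 0.0],
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12},
        )
        beta_hat = res.x[1]
        oracle = math.log((10 / 5) / (4 / 12))
        assert beta_hat == pytest.approx(oracle, abs=1e-5)

    def test_table_and_expanded_records_share_the_posterior(self, table2):
        lp_table = OrdinalSeverityModel.from_table(table2).make_log_posterior()
        records = expand_table(table2)
        lp_records = OrdinalSeverityModel.from_records(records).make_log_posterior()
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(scale=0.8, size=4)
            assert lp_table(v) == pytest.approx(lp_records(v), rel=1e-12)

    def test_prior_enters_the_posterior(self, table2):
        v = np.array([-1.9, 0.0, 0.1, 0.8])
        vague = OrdinalSeverityModel.from_table(table2, priors=PriorSpec.vague())
        tight = OrdinalSeverityModel.from_table(table2, priors=PriorSpec(0.0, 0.01))
        assert tight.make_log_posterior()(v) < vague.make_log_posterior()(v)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            OrdinalSeverityModel(
                np.array([[5, 5, 5], [5, 5, 5]]),
                np.array([[1.0], [1.0]]),  # constant column, collinear with intercept
                ["x"],
            )
        with pytest.raises(ValueError):
            OrdinalSeverityModel(
                np.array([[5, 0, 0], [3, 0, 0]]), np.array([[0.0], [1.0]]), ["x"]
            )


class TestFits:
    def test_parameter_recovery_on_large_synthetic_cohort(self):
        # two-part recovery check at n = 5000: the posterior median must sit
        # on the cohort's own maximum-likelihood estimate (independent
        # statsmodels oracle; vague prior is negligible at this n), and both
        # must lie inside a 3-standard-error envelope of the generating truth
        import pandas as pd
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        spec = CohortSimSpec(
            n_patients=5000, seed=23, ambiguous_label_prob=0.0,
            true_beta=(-0.105, 0.693),
        )
        kept, _ = filter_analyzable(generate_cohort(spec))
        table = build_contingency(kept)
        result = OrdinalSeverityModel.from_table(table).fit(short_settings(seed=24, chains=3))
        med = {
            c: math.log(result.coef_summary(c).point) for c in ("1U1D", "2D")
        }

        rows = []
        ascending = {0: 2, 1: 1, 2: 0}  # table cols II,I,III -> ordinal code
        for gi, g in enumerate(["2U", "1U1D", "2D"]):
            for ci in range(3):
                rows += [(g, ascending[ci])] * int(table.counts[gi, ci])
        frame = pd.DataFrame(rows, columns=["g", "y"])
        design = pd.get_dummies(frame.g)[["1U1D", "2D"]].astype(float)
        mle = OrderedModel(frame.y, design, distr="logit").fit(method="bfgs", disp=0)
        for c, truth in zip(("1U1D", "2D"), spec.true_beta):
            assert med[c] == pytest.approx(mle.params[c], abs=0.05)
            assert abs(med[c] - truth) < 3 * mle.bse[c]

    def test_reference_relabeling_negates_the_coefficient(self, table2):
        fwd = OrdinalSeverityModel.from_table(table2).fit(short_settings(seed=31))
        rev = OrdinalSeverityModel.from_table(
            table2, reference=MutationGroup.TWO_DOWN
        ).fit(short_settings(seed=32))
        prod = fwd.coef_summary("2D").point * rev.coef_summary("2U").point
        assert prod == pytest.approx(1.0, abs=0.1)

    def test_prior_dominance_at_tiny_variance(self, table2):
        prior = PriorSpec(0.5, 1e-6)
        result = OrdinalSeverityModel.from_table(table2, priors=prior).fit(
            short_settings(seed=33)
        )
        assert result.coef_summary("2D").point == pytest.approx(math.exp(0.5), abs=0.01)

    def test_priors_wash_out_with_100x_data(self, table2):
        big = ContingencyTable(table2.counts * 100)
        medians = []
        for i, prior in enumerate(
            [PriorSpec.vague(), PriorSpec.precise(), PriorSpec.optimistic()]
        ):
            result = OrdinalSeverityModel.from_table(big, priors=prior).fit(
                short_settings(seed=40 + i, chains=3)
            )
            medians.append(result.coef_summary("2D").point)
        assert max(medians) - min(medians) < 0.05

    def test_variant_model_drops_unknown_pairs(self):
        spec = CohortSimSpec(n_patients=400, seed=51, ambiguous_label_prob=0.0)
        kept, _ = filter_analyzable(generate_cohort(spec))
        model = OrdinalSeverityModel.from_records(kept, covariates=("variant",))
        assert model.coef_names == ["PTV"]
        assert model.counts.sum() == len(kept)  # generator always sets classes

    def test_multivariate_model_has_both_coefficients(self):
        spec = CohortSimSpec(n_patients=600, seed=52, ambiguous_label_prob=0.0)
        kept, _ = filter_analyzable(generate_cohort(spec))
        model = OrdinalSeverityModel.from_records(
            kept, covariates=("position", "variant")
        )
        assert model.coef_names == ["1U1D", "2D", "PTV"]
        assert model.design.shape[1] == 3

    def test_fit_ordinal_functional_alias(self, table2):
        settings = McmcSettings(n_chains=2, burn_in=300, n_iterations=900, thin=3, seed=1)
        result = fit_ordinal(OrdinalSeverityModel.from_table(table2), settings)
        assert set(result.or_summaries) == {"1U1D", "2D"}


class TestSensitivitySuite:
    def test_identical_priors_reproduce_draw_for_draw(self, table2):
        settings = short_settings(seed=61)
        prior = PriorSpec.precise()
        frame = sensitivity_suite(table2, [prior, prior], settings)
        a = frame[frame.coefficient == "2D"].iloc[0]
        b = frame[frame.coefficient == "2D"].iloc[1]
        assert a.or_median == b.or_median
        assert a.pr_or_gt_1_pct == b.pr_or_gt_1_pct

    def test_upward_prior_shift_raises_pr_or_gt_1(self, table2):
        frame = sensitivity_suite(
            table2, [PriorSpec.vague(), PriorSpec.optimistic()], short_settings(seed=62)
        )
        pr = frame[frame.coefficient == "2D"].pr_or_gt_1_pct.tolist()
        assert pr[1] >= pr[0]

    def test_empty_prior_list_rejected(self, table2):
        with pytest.raises(ValueError):
            sensitivity_suite(table2, [])
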