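"""Prediction core: softmax probabilities, threshold calling, MLE fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irisplex as ip
from irisplex.panel import CATEGORIES


def make_params(panel, reference, alpha, beta):
    nonref = [c for c in CATEGORIES if c != reference]
    return ip.ParameterSet(
        reference_category=reference,
        alpha=dict(zip(nonref, alpha)),
        beta={k: np.asarray(b, dtype=float) for k, b in zip(nonref, beta)},
        panel=panel,
    )


dosage_arrays = st.lists(st.integers(0, 2), min_size=6, max_size=6).map(
    lambda v: np.array(v, dtype=float)
)
coef_arrays = st.lists(
    st.floats(-8, 8, allow_nan=False), min_size=6, max_size=6
).map(np.array)


class TestPredictProbabilities:
    def test_null_model_is_uniform(self, panel):
        ps = make_params(panel, "blue", [0.0, 0.0], [np.zeros(6), np.zeros(6)])
        g = ip.GenotypeRecord("s", [1, 2, 0, 1, 2, 0], panel)
        np.testing.assert_allclose(
            ip.predict_probabilities(g, ps).as_array(), [1 / 3] * 3, atol=1e-12
        )

    def test_single_snp_closed_form(self, panel):
        """Agreement with a direct scalar evaluation of the softmax formula:
        alpha=(1.0,-0.5), beta=(2.0,-1.0) on the first SNP, dosage 2."""
        beta1 = np.zeros(6); beta1[0] = 2.0
        beta2 = np.zeros(6); beta2[0] = -1.0
        ps = make_params(panel, "blue", [1.0, -0.5], [beta1, beta2])
        g = ip.GenotypeRecord("s", [2, 0, 0, 0, 0, 0], panel)
        odds_int = math.exp(1.0 + 2.0 * 2)      # first non-reference: intermediate
        odds_brown = math.exp(-0.5 + (-1.0) * 2)
        denom = 1.0 + odds_int + odds_brown
        expected = [1.0 / denom, odds_int / denom, odds_brown / denom]
        np.testing.assert_allclose(
            ip.predict_probabilities(g, ps).as_array(), expected, atol=1e-12
        )

    def test_numerically_stable_at_huge_linear_predictors(self, panel):
        ps = make_params(panel, "blue", [700.0, -700.0], [np.zeros(6), np.zeros(6)])
        g = ip.GenotypeRecord("s", [0] * 6, panel)
        p = ip.predict_probabilities(g, ps).as_array()
        assert np.all(np.isfinite(p))
        assert p[1] == pytest.approx(1.0)

    def test_missing_dosage_raises_naming_snp(self, panel, demo_params):
        g = ip.GenotypeRecord("s", [0, np.nan, 0, 0, 0, 0], panel)
        with pytest.raises(ip.MissingGenotypeError, match="rs1800407"):
            ip.predict_probabilities(g, demo_params)

    @settings(deadline=None, max_examples=200)
    @given(
        d=dosage_arrays,
        a=st.tuples(st.floats(-8, 8), st.floats(-8, 8)),
        b1=coef_arrays,
        b2=coef_arrays,
        ref=st.sampled_from(CATEGORIES),
    )
    def test_probabilities_sum_to_one_and_reference_invariance(self, panel, d, a, b1, b2, ref):
        ps = make_params(panel, ref, list(a), [b1, b2])
        g = ip.GenotypeRecord("s", d, panel)
        p = ip.predict_probabilities(g, ps).as_array()
        assert abs(p.sum() - 1.0) < 1e-9
        for new_ref in CATEGORIES:
            p2 = ip.predict_probabilities(g, ps.with_reference(new_ref)).as_array()
            np.testing.assert_allclose(p, p2, atol=1e-9)

    def test_monotone_in_positive_beta(self, panel, demo_params):
        """Raising the dosage of a SNP with positive beta toward a category
        never decreases that category's probability."""
        ps = demo_params  # beta['blue'][1] = +1.1 (rs1800407)
        probs = []
        for d in (0, 1, 2):
            g = ip.GenotypeRecord("s", [1, d, 0, 0, 0, 0], panel)
            probs.append(ip.predict_probabilities(g, ps)["blue"])
        assert probs[0] <= probs[1] <= probs[2]


class TestCallEyeColor:
    @pytest.mark.parametrize(
        "triple,threshold,expected",
        [
            ((0.95, 0.03, 0.02), 0.7, "blue"),
            ((0.5, 0.2, 0.3), 0.7, "inconclusive"),
            ((0.7, 0.2, 0.1), 0.7, "blue"),  # boundary is inclusive
            ((0.1, 0.2, 0.7), 0.7, "brown"),
            ((0.2, 0.75, 0.05), 0.7, "intermediate"),
        ],
    )
    def test_examples(self, triple, threshold, expected):
        call = ip.call_eye_color(ip.ProbabilityTriple(*triple), threshold)
        assert call.call == expected

    def test_tie_at_threshold_is_inconclusive(self):
        call = ip.call_eye_color(ip.ProbabilityTriple(0.45, 0.45, 0.10), 0.4)
        assert call.call == "inconclusive"

    @pytest.mark.parametrize("bad", [0.2, 1.0 / 3.0, 0.0, 1.2])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            ip.call_eye_color(ip.ProbabilityTriple(1.0, 0.0, 0.0), bad)

    @settings(deadline=None, max_examples=300)
    @given(
        raw=st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
        threshold=st.floats(0.34, 1.0),
    )
    def test_never_calls_below_threshold(self, raw, threshold):
        p = np.array(raw) / sum(raw)
        call = ip.call_eye_color(ip.ProbabilityTriple(*p), threshold)
        if call.call != "inconclusive":
            assert call.winning_probability >= threshold
            assert call.winning_probability == pytest.approx(p.max())
        else:
            assert p.max() < threshold or (p == p.max()).sum() > 1


class TestMissingPolicy:
    def test_complete_record_unchanged(self, panel):
        g = ip.GenotypeRecord("s", [0, 1, 2, 0, 1, 2], panel)
        assert ip.apply_missing_policy(g, "strict") is g
        assert ip.apply_missing_policy(g, "mean-impute", {}) is g

    def test_strict_raises(self, panel):
        g = ip.GenotypeRecord("s", [np.nan, 1, 2, 0, 1, 2], panel)
        with pytest.raises(ip.MissingGenotypeError, match="rs12913832"):
            ip.apply_missing_policy(g, "strict")

    def test_mean_impute_uses_hardy_weinberg_expectation(self, panel):
        g = ip.GenotypeRecord("s", [0, np.nan, 0, 0, 0, 0], panel)
        out = ip.apply_missing_policy(g, "mean-impute", {"rs1800407": 0.119})
        assert out.imputed
        assert out.dosages[1] == pytest.approx(2 * 0.119)

    def test_mean_impute_without_frequency_errors(self, panel):
        g = ip.GenotypeRecord("s", [0, np.nan, 0, 0, 0, 0], panel)
        with pytest.raises(ValueError):
            ip.apply_missing_policy(g, "mean-impute", None)
        with pytest.raises(ValueError, match="rs1800407"):
            ip.apply_missing_policy(g, "mean-impute", {"rs12913832": 0.3})


def _grid_refine(loglike, centers, widths, rounds=14, points=7):
    """Coordinate-free nested grid search over a small parameter vector."""
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    for _ in range(rounds):
        axes = [np.linspace(c - w, c + w, points) for c, w in zip(centers, widths)]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([loglike(v) for v in flat])
        centers = flat[int(vals.argmax())]
        widths = widths * (2.0 / (points - 1))
    return centers


class TestFitting:
    def test_single_snp_fit_matches_grid_search(self, panel):
        """Degenerate one-informative-SNP fit against a brute-force nested
        grid search of the log-likelihood (agreement to 1e-3)."""
        rng = np.random.default_rng(42)
        n = 400
        x = rng.integers(0, 3, size=n).astype(float)
        true = make_params(
            panel, "blue", [0.4, -0.6],
            [np.array([1.2, 0, 0, 0, 0, 0]), np.array([-0.8, 0, 0, 0, 0, 0])],
        )
        X = np.zeros((n, 6)); X[:, 0] = x
        P = true.predict_proba(X)
        cats = [CATEGORIES[i] for i in (rng.random(n)[:, None] > P.cumsum(1)).sum(1)]
        # fit only the informative column: build a 1-SNP panel
        mini = ip.SnpPanel((panel.snps[0],))
        model = ip.EyeColorModel(X[:, :1], cats, mini, reference="blue")
        res = model.fit()
        w_hat = res._w  # (a_int, b_int, a_brown, b_brown)
        # independent route: nested grid search from a broad box around zero
        w_grid = _grid_refine(model.loglike, [0.0] * 4, [4.0] * 4, rounds=18)
        np.testing.assert_allclose(w_hat, w_grid, atol=1e-3)

    def test_six_snp_fit_matches_statsmodels(self, panel, demo_params):
        """Independent cross-check of the MLE against statsmodels MNLogit."""
        import statsmodels.api as sm

        cohort = ip.generate_training_cohort(
            demo_params, {rs: 0.3 for rs in panel.rs_ids}, n=3000, seed=11
        )
        model = ip.EyeColorModel.from_records(
            cohort.genotypes, cohort.phenotypes, reference="blue"
        )
        res = model.fit()
        X = np.vstack([g.dosages for g in cohort.genotypes])
        y = np.array(
            [CATEGORIES.index(p.category) for p in cohort.phenotypes]
        )  # blue=0 is MNLogit's reference too
        sm_res = sm.MNLogit(y, sm.add_constant(X)).fit(method="newton", disp=False)
        np.testing.assert_allclose(
            model._unpack(res._w), sm_res.params.T, atol=1e-5
        )
        assert res.llf == pytest.approx(sm_res.llf, abs=1e-6)

    def test_parameter_recovery_within_3_se(self, panel, demo_params):
        """Fitting data simulated from known coefficients recovers them
        within three standard errors (n=5000)."""
        freqs = dict(zip(panel.rs_ids, [0.34, 0.12, 0.05, 0.26, 0.45, 0.14]))
        cohort = ip.generate_training_cohort(demo_params, freqs, n=5000, seed=20130804)
        model = ip.EyeColorModel.from_records(
            cohort.genotypes, cohort.phenotypes, reference="brown"
        )
        res = model.fit()
        W = model._unpack(res._w)
        truth = np.vstack(
            [
                np.concatenate([[demo_params.alpha[k]], demo_params.beta[k]])
                for k in model.nonref
            ]
        )
        se = res.bse.reshape(W.shape)
        assert np.all(np.abs(W - truth) <= 3 * se)

    def test_calibration_in_the_large(self, panel, demo_params):
        """Mean fitted probabilities equal empirical category frequencies on
        the training data (a property of the multinomial-logit MLE)."""
        freqs = {rs: 0.3 for rs in panel.rs_ids}
        cohort = ip.generate_training_cohort(demo_params, freqs, n=2000, seed=5)
        model = ip.EyeColorModel.from_records(cohort.genotypes, cohort.phenotypes)
        res = model.fit()
        X = np.vstack([g.dosages for g in cohort.genotypes])
        mean_p = res.predict_proba(X).mean(axis=0)
        emp = np.array(
            [np.mean([p.category == c for p in cohort.phenotypes]) for c in CATEGORIES]
        )
        np.testing.assert_allclose(mean_p, emp, atol=1e-6)

    def test_refit_self_consistency(self, panel, demo_params):
        """Refitting on data generated from a fitted model reproduces the
        fitted coefficients within Monte-Carlo error."""
        freqs = dict(zip(panel.rs_ids, [0.34, 0.12, 0.05, 0.26, 0.45, 0.14]))
        cohort = ip.generate_training_cohort(demo_params, freqs, n=20000, seed=9)
        fitted = ip.fit_parameters(cohort.genotypes, cohort.phenotypes, "brown")
        cohort2 = ip.generate_training_cohort(fitted, freqs, n=20000, seed=10)
        model2 = ip.EyeColorModel.from_records(
            cohort2.genotypes, cohort2.phenotypes, reference="brown"
        )
        res2 = model2.fit()
        se = res2.bse
        w1 = np.concatenate(
            [np.concatenate([[fitted.alpha[k]], fitted.beta[k]]) for k in model2.nonref]
        )
        assert np.all(np.abs(res2._w - w1) <= 4 * se)

    def test_perfect_separation_detected_and_ridge_recovers(self, panel):
        X = np.zeros((30, 6))
        X[:10, 0] = 0; X[10:20, 0] = 1; X[20:, 0] = 2
        cats = ["blue"] * 10 + ["intermediate"] * 10 + ["brown"] * 10
        model = ip.EyeColorModel(X, cats, panel)
        with pytest.raises((ip.PerfectSeparationError, ip.ConvergenceError)):
            model.fit()
        res = model.fit(ridge=1.0)
        assert "ridge" in res.parameter_set.provenance

    def test_requires_all_three_categories(self, panel):
        X = np.zeros((10, 6))
        with pytest.raises(ValueError, match="categor"):
            ip.EyeColorModel(X, ["blue"] * 5 + ["brown"] * 5, panel)

    def test_summary_mentions_fit_dimensions(self, panel, demo_params):
        freqs = {rs: 0.3 for rs in panel.rs_ids}
        cohort = ip.generate_training_cohort(demo_params, freqs, n=500, seed=3)
        res = ip.EyeColorModel.from_records(cohort.genotypes, cohort.phenotypes).fit()
        s = res.summary()
        assert "n = 500" in s and "rs12913832" in s
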