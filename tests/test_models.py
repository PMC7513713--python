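"""Regression engine: 2-SD standardization, GLM/GLMM fits vs independent
oracles, AICc model averaging, and back-transformed probabilities."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from matechoice import (
    ModelSpec,
    fit_glm,
    fitted_probabilities,
    model_average,
    standardize_2sd,
    standardize_within_group,
    two_sd_constants,
)
from matechoice.glmm import fit_glmm
from matechoice.models import aicc


def grid_mle(loglik_fn, n_params, lo=-4.0, hi=4.0, rounds=14, grid=9):
    """Independent coarse-to-fine grid maximizer of a likelihood surface."""
    centers = np.zeros(n_params)
    width = (hi - lo) / 2
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, grid) for c in centers]
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        lls = np.array([loglik_fn(theta) for theta in flat])
        centers = flat[np.argmax(lls)]
        width *= 2.0 / (grid - 1)
    return centers


class TestStandardize:
    def test_symmetric_pattern_and_value(self):
        z = standardize_2sd([2, 2, 4, 4])
        # mean 3, sample SD sqrt(4/3); independent arithmetic: +-1/(2*sqrt(4/3))
        expect = 1.0 / (2.0 * np.sqrt(4.0 / 3.0))
        assert z == pytest.approx([-expect, -expect, expect, expect])

    def test_fixed_point(self):
        x = np.array([-0.5, 0.5, -0.5, 0.5])  # mean 0, sample SD ~0.577...
        v = np.array([-1.0, 1.0])
        # a variable with mean 0 and SD 0.5 restandardizes to itself
        base = np.array([-0.5, 0.5])
        sd = base.std(ddof=1)
        scaled = base * (0.5 / sd)
        assert standardize_2sd(scaled) == pytest.approx(scaled)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_2sd([3.0, 3.0, 3.0], name="age")

    def test_within_group(self):
        df = pd.DataFrame(
            {
                "enclosure_year_id": ["E1"] * 2 + ["E2"] * 3,
                "sex": ["F"] * 5,
                "age": [2.0, 4.0, 3.0, 3.0, 3.0],
            }
        )
        with pytest.warns(UserWarning, match="zero SD"):
            out = standardize_within_group(df, ["age"])
        # two-member group (2,4): mean 3, sample SD sqrt(2) -> +-1/(2*sqrt(2))
        expect = 1.0 / (2.0 * np.sqrt(2.0))
        assert out["z_age"].tolist()[:2] == pytest.approx([-expect, expect])
        assert out["z_age"].tolist()[2:] == [0.0, 0.0, 0.0]  # degenerate group
        # group-wise centring identity
        assert out.groupby("enclosure_year_id")["z_age"].mean().abs().max() < 1e-12


class TestGlmOracle:
    def test_intercept_only_binomial_closed_form(self):
        df = pd.DataFrame({"bred": [1] * 10 + [0] * 10})
        fit = fit_glm(ModelSpec("bred", "binomial", ()), df)
        assert fit.coefficients["(Intercept)"] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_poisson_closed_form(self):
        counts = [1, 2, 3, 2, 1, 3, 2, 2]
        df = pd.DataFrame({"n_offspring": counts})
        fit = fit_glm(ModelSpec("n_offspring", "poisson", ()), df)
        assert fit.coefficients["(Intercept)"] == pytest.approx(np.log(np.mean(counts)), abs=1e-8)

    def test_logistic_matches_grid_oracle(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.5 - 0.8 * x)).astype(float)
        df = pd.DataFrame({"bred": y, "x": x})
        fit = fit_glm(ModelSpec("bred", "binomial", ("x",)), df)

        def ll(theta):
            eta = theta[0] + theta[1] * x
            return float(np.sum(y * eta - np.logaddexp(0, eta)))

        oracle = grid_mle(ll, 2)
        assert fit.coefficients["(Intercept)"] == pytest.approx(oracle[0], abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(oracle[1], abs=1e-4)

    def test_poisson_matches_grid_oracle(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.3 + 0.5 * x)).astype(float)
        df = pd.DataFrame({"n_offspring": y, "x": x})
        fit = fit_glm(ModelSpec("n_offspring", "poisson", ("x",)), df)

        def ll(theta):
            eta = theta[0] + theta[1] * x
            return float(np.sum(y * eta - np.exp(eta)))

        oracle = grid_mle(ll, 2)
        assert fit.coefficients["(Intercept)"] == pytest.approx(oracle[0], abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(oracle[1], abs=1e-4)

    def test_binomial_out_of_4_matches_grid_oracle(self, rng):
        n = 50
        x = rng.normal(size=n)
        y = rng.binomial(4, expit(0.4 - 0.6 * x)).astype(float)
        y = np.clip(y, 1, 4)  # breeders only, as in the offspring models
        df = pd.DataFrame({"n_offspring": y, "x": x})
        fit = fit_glm(ModelSpec("n_offspring", "binomial_out_of_4", ("x",)), df)

        def ll(theta):
            eta = theta[0] + theta[1] * x
            return float(np.sum(y * eta - 4 * np.logaddexp(0, eta)))

        oracle = grid_mle(ll, 2)
        assert fit.coefficients["x"] == pytest.approx(oracle[1], abs=1e-4)

    def test_aicc_formula_on_every_fit(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + x)).astype(float)
        df = pd.DataFrame({"bred": y, "x": x, "w": rng.normal(size=n)})
        for preds in [(), ("x",), ("x", "w")]:
            fit = fit_glm(ModelSpec("bred", "binomial", preds), df)
            k = len(preds) + 1
            assert fit.k == k
            assert fit.aicc == pytest.approx(
                -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            )


class TestGlmm:
    def test_matches_lme4_agq(self, rng, tmp_path):
        """Cross-check the adaptive Gauss-Hermite fit against lme4::glmer."""
        g = np.repeat(np.arange(30), 8)
        u = rng.normal(size=30)
        x = rng.normal(size=240)
        y = (rng.random(240) < expit(0.3 + 0.8 * x + 0.9 * u[g])).astype(float)
        res = fit_glmm(y, np.column_stack([np.ones(240), x]), g, "binomial")
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(csv, index=False)
        script = (
            f'd <- read.csv("{csv}"); suppressMessages(library(lme4));'
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25);"
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        b0, b1, sigma, ll = map(float, proc.stdout.split())
        assert res.beta[0] == pytest.approx(b0, abs=2e-3)
        assert res.beta[1] == pytest.approx(b1, abs=2e-3)
        assert res.sigma == pytest.approx(sigma, abs=5e-3)
        assert res.loglik == pytest.approx(ll, abs=1e-3)

    def test_zero_variance_recovered(self, rng):
        """Group variance 0 in truth: median estimate over replicates is ~0
        (single binary datasets can yield sizable spurious variance MLEs)."""
        ests = []
        for _ in range(7):
            g = np.repeat(np.arange(25), 12)
            x = rng.normal(size=300)
            y = (rng.random(300) < expit(0.1 + 0.5 * x)).astype(float)
            res = fit_glmm(y, np.column_stack([np.ones(300), x]), g, "binomial")
            ests.append(res.sigma**2)
        assert np.median(ests) < 0.1

    def test_unit_variance_recovered(self, rng):
        ests = []
        for _ in range(20):
            g = np.repeat(np.arange(40), 10)
            u = rng.normal(size=40)
            x = rng.normal(size=400)
            y = (rng.random(400) < expit(0.2 + 0.5 * x + u[g])).astype(float)
            res = fit_glmm(y, np.column_stack([np.ones(400), x]), g, "binomial")
            ests.append(res.sigma**2)
        assert abs(np.median(ests) - 1.0) < 0.3


class TestModelAverage:
    def test_strong_and_noise_predictor(self, rng):
        n = 500
        strong = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 * strong)).astype(float)
        df = pd.DataFrame({"bred": y, "strong": strong, "noise": noise})
        avg = model_average(ModelSpec("bred", "binomial", ("strong", "noise")), df)
        assert avg.relative_importance["strong"] == 1.0
        assert avg.relative_importance["noise"] < 1.0
        assert len(avg.all_models) == 4  # all subsets enumerated
        assert sum(f.weight for f in avg.top_models) == pytest.approx(1.0)

    def test_full_average_shrinks_toward_zero(self, rng):
        n = 300
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        y = (rng.random(n) < expit(1.2 * x)).astype(float)
        df = pd.DataFrame({"bred": y, "x": x, "w": w})
        full = model_average(ModelSpec("bred", "binomial", ("x", "w")), df, method="full")
        cond = model_average(ModelSpec("bred", "binomial", ("x", "w")), df, method="conditional")
        if full.relative_importance["w"] < 1.0 and full.relative_importance["w"] > 0:
            assert abs(full.estimates["w"]) < abs(cond.estimates["w"])

    def test_delta_aicc_threshold_respected(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(x)).astype(float)
        df = pd.DataFrame({"bred": y, "x": x})
        avg = model_average(ModelSpec("bred", "binomial", ("x",)), df)
        assert all(f.delta_aicc <= 2.0 for f in avg.top_models)
        assert avg.top_models[0].delta_aicc == 0.0


class TestFittedProbabilities:
    def test_all_zero_coefficients_give_half(self, rng):
        n = 200
        age = rng.integers(2, 6, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({"bred": y, "age": standardize_2sd(age)})
        avg = model_average(ModelSpec("bred", "binomial", ("age",)), df)
        # override to the degenerate case: zero intercept and slope
        avg.estimates = {"(Intercept)": 0.0, "age": 0.0}
        std = {"age": two_sd_constants(age)}
        fp = fitted_probabilities(avg, {"age": 3.0}, std)
        assert fp.probability == 0.5

    def test_negative_age_coefficient_monotone_decreasing(self, rng):
        n = 400
        age = rng.integers(2, 6, n).astype(float)
        z = standardize_2sd(age)
        y = (rng.random(n) < expit(-1.2 * z)).astype(float)
        df = pd.DataFrame({"bred": y, "age": z})
        avg = model_average(ModelSpec("bred", "binomial", ("age",)), df)
        std = {"age": two_sd_constants(age)}
        probs = [fitted_probabilities(avg, {"age": a}, std).probability for a in (2, 3, 4, 5)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_extrapolation_warns_and_ri_flagging(self, rng):
        n = 300
        age = rng.integers(2, 6, n).astype(float)
        noise = rng.normal(size=n)
        z = standardize_2sd(age)
        y = (rng.random(n) < expit(-1.5 * z)).astype(float)
        df = pd.DataFrame({"bred": y, "age": z, "noise": noise})
        avg = model_average(ModelSpec("bred", "binomial", ("age", "noise")), df)
        std = {"age": two_sd_constants(age), "noise": two_sd_constants(noise)}
        with pytest.warns(UserWarning, match="extrapolating"):
            fp = fitted_probabilities(avg, {"age": 9.0, "noise": 0.0}, std)
        if avg.relative_importance["noise"] < 1.0:
            assert "noise" in fp.uncertain_predictors
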