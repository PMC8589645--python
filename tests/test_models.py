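"""Regression battery: closed-form sanity, invariances, planted-parameter
recovery and null calibration for every model family."""

import numpy as np
import pandas as pd
import pytest

from cnvburden.models import (
    ModelSpec,
    bonferroni,
    fit_association,
    per_sd_effect,
)

RNG = np.random.default_rng(20_260_923)


def logistic_table(n, beta=0.0, p_exposed=0.3, rng=RNG):
    x = (rng.random(n) < p_exposed).astype(float)
    c1 = rng.standard_normal(n)
    eta = -0.2 + beta * x + 0.3 * c1
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame({"y": y.astype(int), "x": x, "c1": c1})


def ologit_table(n, beta=0.0, rng=RNG, levels=4):
    x = (rng.random(n) < 0.3).astype(float)
    c1 = rng.standard_normal(n)
    latent = beta * x + 0.3 * c1 + rng.logistic(size=n)
    cuts = np.array([-1.0, 0.2, 1.3])[: levels - 1]
    y = np.searchsorted(cuts, latent) + 1
    return pd.DataFrame({"y": y.astype(float), "x": x, "c1": c1})


def survival_table(n, beta=0.0, rng=RNG):
    x = (rng.random(n) < 0.3).astype(float)
    c1 = rng.standard_normal(n)
    rate = 0.08 * np.exp(beta * x + 0.2 * c1)
    t = rng.exponential(1 / rate)
    cens = rng.uniform(5, 15, n)
    return pd.DataFrame({"t": np.minimum(t, cens), "death": (t <= cens),
                         "x": x, "c1": c1})


def count_table(n, beta=0.0, rng=RNG):
    x = (rng.random(n) < 0.3).astype(float)
    c1 = rng.standard_normal(n)
    y = rng.poisson(np.exp(-0.5 + beta * x + 0.2 * c1))
    return pd.DataFrame({"y": y.astype(float), "x": x, "c1": c1})


class TestClosedFormsAndContracts:
    def test_logistic_null_ci_covers_one(self):
        res = fit_association(
            logistic_table(10_000, beta=0.0, rng=np.random.default_rng(1)),
            ModelSpec("logistic", "y", "x", ("c1",)))
        lo, hi = res.ci95
        assert lo < 1 < hi
        assert res.ratio == pytest.approx(np.exp(res.estimate))

    def test_poisson_intercept_only_equals_mean(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.poisson(1.7, 5000).astype(float),
                           "x": np.r_[np.zeros(2500), np.ones(2500)]})
        res = fit_association(df, ModelSpec("poisson", "y", "x"))
        # with a null exposure the intercept recovers log(mean)
        intercept = res.coef_table.loc["const", "coef"]
        assert np.exp(intercept) == pytest.approx(df["y"].mean(), rel=0.05)

    def test_zero_variance_exposure_is_error(self):
        df = logistic_table(200)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            fit_association(df, ModelSpec("logistic", "y", "x"))

    def test_separation_flagged_not_silent(self):
        df = pd.DataFrame({
            "y": np.r_[np.ones(30), np.zeros(30)],
            "x": np.r_[np.ones(30), np.zeros(30)],
        })
        res = fit_association(df, ModelSpec("logistic", "y", "x"))
        assert not res.converged
        assert res.note

    def test_missing_column_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            fit_association(logistic_table(100),
                            ModelSpec("logistic", "y", "x", ("nope",)))


class TestInvariances:
    def test_cox_invariant_to_monotone_time_rescaling(self):
        df = survival_table(3000, beta=0.4, rng=np.random.default_rng(3))
        spec = ModelSpec("cox", "t", "x", ("c1",), event_col="death")
        base = fit_association(df, spec)
        rescaled = fit_association(df.assign(t=df["t"] ** 1.3 * 7.0), spec)
        assert rescaled.estimate == pytest.approx(base.estimate, abs=1e-6)

    def test_ologit_invariant_to_order_preserving_relabeling(self):
        df = ologit_table(3000, beta=-0.3, rng=np.random.default_rng(4))
        spec = ModelSpec("ordered_logit", "y", "x", ("c1",))
        base = fit_association(df, spec)
        relabeled = fit_association(
            df.assign(y=df["y"].map({1: 10, 2: 20, 3: 35, 4: 99})), spec)
        assert relabeled.estimate == pytest.approx(base.estimate, abs=1e-6)

    def test_per_sd_estimate_invariant_to_raw_scale(self):
        rng = np.random.default_rng(5)
        n = 5000
        s = rng.standard_normal(n)
        df = pd.DataFrame({"y": 10 + 0.84 * s + rng.normal(0, 2, n),
                           "s": s, "c1": rng.standard_normal(n)})
        spec = ModelSpec("linear", "y", "s", ("c1",))
        a = per_sd_effect(df, spec)
        b = per_sd_effect(df.assign(s=2.0 * df["s"]), spec)
        assert b.estimate == pytest.approx(a.estimate, rel=1e-10)
        assert a.estimate == pytest.approx(0.84, abs=0.1)

    def test_per_sd_null_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"y": rng.normal(size=4000),
                           "s": rng.standard_normal(4000)})
        res = per_sd_effect(df, ModelSpec("linear", "y", "s"))
        lo, hi = res.ci95
        assert lo < 0 < hi


class TestRecoveryAndConsistency:
    def test_ologit_recovers_planted_effect(self):
        beta = np.log(0.77)
        ests = [
            fit_association(
                ologit_table(20_000, beta, rng=np.random.default_rng(100 + i)),
                ModelSpec("ordered_logit", "y", "x", ("c1",))).estimate
            for i in range(8)
        ]
        assert np.mean(ests) == pytest.approx(beta, abs=0.03)

    def test_estimates_tighten_with_sample_size(self):
        beta = 0.5
        def bias(n, reps, offset):
            ests = [fit_association(
                logistic_table(n, beta, rng=np.random.default_rng(offset + i)),
                ModelSpec("logistic", "y", "x", ("c1",))).estimate
                for i in range(reps)]
            return abs(np.mean(ests) - beta)
        assert bias(20_000, 10, 200) < bias(2_000, 10, 300) + 0.02
        assert bias(20_000, 10, 200) < 0.04

    def test_cox_recovers_planted_hazard_ratio(self):
        beta = np.log(1.55)
        ests = [fit_association(
            survival_table(8000, beta, rng=np.random.default_rng(400 + i)),
            ModelSpec("cox", "t", "x", ("c1",), event_col="death")).estimate
            for i in range(8)]
        assert np.mean(ests) == pytest.approx(beta, abs=0.05)


class TestNullCalibration:
    """Type-I error at alpha = 0.05 under the null, per family."""

    @pytest.mark.parametrize(
        "maker, spec",
        [
            (logistic_table, ModelSpec("logistic", "y", "x", ("c1",))),
            (ologit_table, ModelSpec("ordered_logit", "y", "x", ("c1",))),
            (count_table, ModelSpec("poisson", "y", "x", ("c1",))),
            (survival_table,
             ModelSpec("cox", "t", "x", ("c1",), event_col="death")),
        ],
        ids=["logistic", "ordered_logit", "poisson", "cox"],
    )
    def test_type_one_error_near_nominal(self, maker, spec):
        n_reps, n = 500, 400
        rejections = 0
        for i in range(n_reps):
            df = maker(n, 0.0, rng=np.random.default_rng(10_000 + i))
            res = fit_association(df, spec)
            rejections += res.p < 0.05
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.08  # 0.05 +/- 3 binomial SD

    def test_linear_type_one_error(self):
        rejections = 0
        for i in range(500):
            rng = np.random.default_rng(20_000 + i)
            df = pd.DataFrame({"y": rng.normal(size=400),
                               "x": (rng.random(400) < 0.3).astype(float)})
            rejections += fit_association(
                df, ModelSpec("linear", "y", "x")).p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08


class TestMultinomial:
    def test_two_contrasts_against_reference(self):
        rng = np.random.default_rng(7)
        n = 4000
        x = (rng.random(n) < 0.3).astype(float)
        # true multinomial logit, group 2 baseline: planted 1-vs-2 log-OR 0.8
        eta = np.column_stack([-0.8 + 0.8 * x, np.zeros(n),
                               np.full(n, -0.5)])
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        y = 1 + (u > p[:, 0]).astype(int) + (u > p[:, 0] + p[:, 1]).astype(int)
        df = pd.DataFrame({"g": y, "x": x})
        res = fit_association(df, ModelSpec("multinomial", "g", "x",
                                            reference=2))
        assert [r.contrast for r in res] == ["1_vs_2", "3_vs_2"]
        r1 = {r.contrast: r for r in res}["1_vs_2"]
        assert r1.estimate == pytest.approx(0.8, abs=0.25)


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.05)
        assert bonferroni(0.5, 5) == 1.0
        assert np.allclose(bonferroni([0.001, 0.02], 40), [0.04, 0.8])

    def test_monotone_and_bounded(self):
        p = np.linspace(0.001, 0.9, 50)
        adj = bonferroni(p, 50)
        assert (np.diff(adj) >= 0).all()
        assert (adj <= 1).all() and (adj >= p).all()

    def test_family_size_must_cover_tests(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)
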