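"""The NB-GAM engine: likelihood, bases, fitting, prediction contracts."""

import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from petreldsm.nbgam import (Factor, Linear, ModelError, Smooth1D, Smooth2D,
                             build_design, fit_nbgam, nb_deviance, nb_loglik)


def sim_nb(rng, eta, theta, area=1.0):
    mu = np.exp(eta) * area
    return rng.negative_binomial(theta, theta / (theta + mu))


class TestLikelihood:
    def test_poisson_limit_at_zero(self):
        """y=0, mu=1, theta -> inf: log-lik -> log Poisson(1) at 0 = -1."""
        assert nb_loglik(np.array([0]), np.array([1.0]), 1e12) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        """y=2, mu=2, theta=1 against the closed form evaluated with
        math.lgamma (independent of the vectorised implementation)."""
        y, mu, th = 2, 2.0, 1.0
        want = (th * math.log(th) + y * math.log(mu)
                + math.lgamma(y + th) - math.lgamma(th) - math.lgamma(y + 1)
                - (y + th) * math.log(mu + th))
        got = nb_loglik(np.array([y]), np.array([mu]), th)
        assert got == pytest.approx(want, abs=1e-12)

    def test_maximised_at_mu_equals_y(self):
        mus = np.linspace(1.0, 12.0, 200)
        ll = [nb_loglik(np.array([5]), np.array([m]), 2.0) for m in mus]
        assert mus[int(np.argmax(ll))] == pytest.approx(5.0, abs=0.1)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            nb_loglik(np.array([1]), np.array([-1.0]), 2.0)
        with pytest.raises(ValueError):
            nb_loglik(np.array([1.5]), np.array([1.0]), 2.0)

    def test_deviance_zero_at_saturation(self):
        y = np.array([0.0, 1, 3, 7])
        mu = np.maximum(y, 1e-8)
        assert nb_deviance(y, mu, 2.0) == pytest.approx(0.0, abs=1e-6)


class TestBasis:
    def test_k5_gives_four_columns(self):
        """The sum-to-zero constraint removes one degree of freedom."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.random(100)})
        X, built, pens = build_design([Smooth1D("x", k=5)], df)
        assert X.shape[1] == 1 + 4  # intercept + (k - 1)
        assert abs(X[:, 1:].sum(axis=0)).max() < 1e-9  # centred columns

    def test_too_few_distinct_values_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0] * 10})
        with pytest.raises(ModelError, match="reduce k"):
            build_design([Smooth1D("x", k=5)], df)

    def test_predict_fit_self_consistency(self):
        """Evaluating the basis at the training x reproduces the in-sample
        smooth to 1e-10."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.random(300)})
        X, built, _ = build_design([Smooth1D("x", k=8)], df)
        again = built[0].columns(df)
        assert np.allclose(X[:, built[0].sl], again, atol=1e-10)

    def test_infinite_penalty_kills_term(self):
        """With both smoothing parameters huge, the fitted term is ~0."""
        rng = np.random.default_rng(2)
        n = 400
        x = rng.random(n)
        y = rng.poisson(np.exp(0.5 + np.sin(2 * np.pi * x)))
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_nbgam(df, [Smooth1D("x")], y="y", theta=1e6,
                        rho_init=np.array([30.0, 30.0]), fix_smoothing=True,
                        max_outer=1)
        assert np.max(np.abs(fit.term_effect("s(x)", df))) < 1e-6
        assert fit.edf["s(x)"] < 1e-3

    def test_penalty_ranks_cover_term(self):
        """Wiggliness + null-space penalty jointly span each shrinkage
        smooth, so every direction can be shrunk."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.random(100), "y2": rng.random(100)})
        _, built, pens = build_design([Smooth1D("x", k=6),
                                       Smooth2D("x", "y2", k=10)], df)
        for bt in built:
            q = bt.sl.stop - bt.sl.start
            assert sum(p.rank for p in pens if p.sl.start >= bt.sl.start
                       and p.sl.stop <= bt.sl.stop) == q


class TestFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(4)
        a = np.full(300, 2.5)
        y = rng.poisson(0.8 * a)
        fit = fit_nbgam(pd.DataFrame({"y": y}), [], y="y", offset=np.log(a),
                        theta=1e8)
        assert fit.beta[0] == pytest.approx(np.log(y.mean() / 2.5), abs=1e-10)

    def test_poisson_limit_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 500
        x, z = rng.random(n), rng.random(n)
        a = np.exp(rng.normal(0, 0.3, n))
        y = rng.poisson(np.exp(0.3 + 0.8 * x - 0.5 * z) * a)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        ours = fit_nbgam(df, [Linear("x"), Linear("z")], y="y",
                         offset=np.log(a), theta=1e8)
        ref = sm.GLM(y, sm.add_constant(np.column_stack([x, z])),
                     family=sm.families.Poisson(), offset=np.log(a)).fit()
        assert np.max(np.abs(ours.beta - ref.params)) < 1e-4

    def test_offset_scaling_shifts_only_intercept(self):
        """Scaling all efforts by c moves the intercept by -log c and
        nothing else (smoothing and theta held)."""
        rng = np.random.default_rng(6)
        n = 500
        x = rng.random(n)
        a = np.full(n, 1.6)
        y = sim_nb(rng, 0.2 + np.sin(2 * np.pi * x), 2.0, a)
        df = pd.DataFrame({"y": y, "x": x})
        base = fit_nbgam(df, [Smooth1D("x")], y="y", offset=np.log(a), theta=2.0)
        kw = dict(theta=2.0, rho_init=base.rho, fix_smoothing=True, max_outer=1)
        f1 = fit_nbgam(df, [Smooth1D("x")], y="y", offset=np.log(a), **kw)
        f2 = fit_nbgam(df, [Smooth1D("x")], y="y", offset=np.log(5.0 * a), **kw)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(5.0), abs=1e-6)
        assert np.max(np.abs(f2.beta[1:] - f1.beta[1:])) < 1e-6

    def test_sine_recovery_and_decoy_shrinkage(self):
        rng = np.random.default_rng(7)
        n = 2000
        x1, x2 = rng.random(n), rng.random(n)
        a = np.full(n, 1.6)
        y = sim_nb(rng, np.log(0.4) + np.sin(2 * np.pi * x1), 2.0, a)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = fit_nbgam(df, [Smooth1D("x1"), Smooth1D("x2")], y="y",
                        offset=np.log(a))
        g = fit.term_effect("s(x1)", df)
        truth = np.sin(2 * np.pi * x1)
        assert np.corrcoef(g, truth - truth.mean())[0, 1] > 0.95
        assert fit.edf["s(x2)"] < 0.5
        assert 1.0 < fit.theta < 4.0

    def test_null_model_zero_deviance_explained(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(1.0, 300)
        fit = fit_nbgam(pd.DataFrame({"y": y}), [], y="y", theta=1e8)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-10)

    def test_adding_terms_never_increases_deviance(self):
        rng = np.random.default_rng(9)
        n = 600
        x = rng.random(n)
        y = sim_nb(rng, 0.3 + 0.7 * np.sin(2 * np.pi * x), 2.0)
        df = pd.DataFrame({"y": y, "x": x})
        f0 = fit_nbgam(df, [], y="y", theta=2.0)
        f1 = fit_nbgam(df, [Smooth1D("x")], y="y", theta=2.0,
                       rho_init=np.array([-8.0, -8.0]), fix_smoothing=True)
        assert f1.deviance <= f0.deviance + 1e-8
        assert f1.deviance_explained > 0.0

    def test_edf_within_bounds(self):
        rng = np.random.default_rng(10)
        n = 800
        x1, x2 = rng.random(n), rng.random(n)
        y = sim_nb(rng, 0.2 + np.sin(2 * np.pi * x1), 2.0)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = fit_nbgam(df, [Smooth1D("x1", k=5), Smooth1D("x2", k=5)], y="y")
        for lab, e in fit.edf.items():
            assert -1e-8 <= e <= 4.0 + 1e-8 if lab != "(intercept)" else e <= 1.0 + 1e-8

    def test_negative_counts_rejected(self):
        with pytest.raises(ModelError):
            fit_nbgam(pd.DataFrame({"y": [-1, 2]}), [], y="y", theta=1.0)

    def test_zero_effort_offset_rejected(self):
        with np.errstate(divide="ignore"), pytest.raises(ModelError):
            fit_nbgam(pd.DataFrame({"y": [1, 2]}), [], y="y",
                      offset=np.log(np.array([0.0, 1.0])), theta=1.0)


class TestPredict:
    def fixture_fit(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.random(n)
        alt = np.where(rng.random(n) < 0.5, "high", "low")
        y = sim_nb(rng, 0.2 + 0.5 * np.sin(2 * np.pi * x) - 0.4 * (alt == "high"), 2.0)
        df = pd.DataFrame({"y": y, "x": x, "altitude": alt})
        fit = fit_nbgam(df, [Smooth1D("x"), Factor("altitude", ref="low")],
                        y="y", theta=2.0)
        return fit, df

    def test_training_rows_reproduced(self):
        fit, df = self.fixture_fit()
        mu = fit.predict(df, offset=0.0)
        assert np.allclose(mu, fit.fitted, atol=1e-10)

    def test_offset_doubles_mu_exactly(self):
        fit, df = self.fixture_fit()
        m1 = fit.predict(df, offset=np.log(2.0))
        m0 = fit.predict(df, offset=0.0)
        assert np.allclose(m1, 2.0 * m0, rtol=1e-12)

    def test_unknown_factor_level_rejected(self):
        fit, df = self.fixture_fit()
        bad = df.head(3).copy()
        bad["altitude"] = "medium"
        with pytest.raises(ModelError, match="unknown factor level"):
            fit.predict(bad, offset=0.0)

    def test_extrapolation_guard(self):
        fit, df = self.fixture_fit()
        out = df.head(3).copy()
        out["x"] = 2.5
        with pytest.raises(ModelError, match="training"):
            fit.predict(out, offset=0.0)
        mu = fit.predict(out, offset=0.0, allow_extrapolation=True)
        assert np.all(np.isfinite(mu))

    def test_se_positive_and_finite(self):
        fit, df = self.fixture_fit()
        mu, se = fit.predict(df, offset=0.0, se=True)
        assert np.all(se >= 0) and np.all(np.isfinite(se))


class TestAgainstMgcv:
    def test_smooth_fit_matches_mgcv_reference(self, tmp_path):
        """Independent cross-check: the same NB data fitted with mgcv's
        shrinkage thin-plate smooth gives near-identical fitted curves."""
        rng = np.random.default_rng(12)
        n = 500
        x = rng.random(n)
        mu = np.exp(0.3 + np.sin(2 * np.pi * x)) * 1.5
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        df = pd.DataFrame({"y": y, "x": x, "off": np.log(1.5)})
        fit = fit_nbgam(df, [Smooth1D("x", k=8)], y="y", offset="off",
                        theta=2.0, gamma=1.0)
        csv = tmp_path / "d.csv"
        out = tmp_path / "mu.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f'd <- read.csv("{csv}")\n'
            'library(mgcv)\n'
            'm <- gam(y ~ s(x, k=8, bs="ts") + offset(off), data=d,\n'
            '         family=negbin(2), method="REML")\n'
            f'write.csv(data.frame(mu=fitted(m)), "{out}", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(out)["mu"].to_numpy()
        r = np.corrcoef(fit.fitted, ref)[0, 1]
        assert r > 0.98
        assert np.mean(np.abs(fit.fitted - ref)) / ref.mean() < 0.1
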