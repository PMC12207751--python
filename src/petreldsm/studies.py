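"""Seeded simulation studies over the pipeline.

Each study generates synthetic survey data with known truth, runs the
relevant stage of the pipeline, and reports recovery/calibration
quantities: smooth-recovery and shrinkage rates for the spline engine,
power and type-I error of the survey-altitude detectability test, total
abundance recovery over replicate worlds, winsorised-bootstrap CI
coverage, and the 80/20 validation harness.  The analysis drivers, the
test suite and the acceptance script all call these functions, so every
reported number is recomputed from scratch for a given seed.

Problem sizes default to desk scale (hundreds to a couple of thousand
surveyed cells per replicate) so a full set of studies runs in minutes on
one core; the statistical structure — sparse NB counts against smooth
habitat effects with altitude/sea-state thinning — mirrors the full
study-scale world.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import abundance as ab
from . import covariates as cov
from . import selection as sel
from . import synthetic as syn
from .nbgam import Factor, FactorSmooth, ModelError, Smooth1D, Smooth2D, fit_nbgam


# ---------------------------------------------------------------------------
# fast cell-level survey simulation (no strip geometry)
# ---------------------------------------------------------------------------


def simulate_cell_survey(n_cells: int = 800, effort: float = 1.6,
                         theta: float = 2.0, delta_alt: float = np.log(0.5),
                         beta_ss: tuple[float, float] = (-0.20, -0.10),
                         seed: int = 0, intercept: float = np.log(0.33),
                         passes: tuple[str, ...] = ("high", "low"),
                         spatial: bool = True) -> pd.DataFrame:
    """Survey records drawn directly at the cell level.

    Latent NB counts (mean density x effort area, size theta) are thinned
    binomially with the altitude/sea-state detection probability; every
    cell is surveyed once per altitude class in ``passes``.  This is the
    cheap counterpart of the full strip-geometry generator, with identical
    expected counts, used by the replicate studies.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 160, n_cells)
    y = rng.uniform(0, 200, n_cells)
    c1 = rng.random(n_cells)
    rows = []
    for alt_i, alt in enumerate(passes):
        ss = rng.choice(5, size=n_cells, p=[0.3, 0.3, 0.25, 0.12, 0.03])
        eta = intercept + 0.8 * np.sin(2 * np.pi * c1)
        if spatial:
            eta = eta + 0.3 * np.cos(x / 40.0)
        lam = np.exp(eta)
        bss = beta_ss[0] if alt == "high" else beta_ss[1]
        p = np.minimum(np.exp(delta_alt * (alt == "high") + bss * ss), 1.0)
        latent = syn.nb_counts(rng, lam * effort, theta)
        count = rng.binomial(latent, p)
        rows.append(pd.DataFrame({
            "ix": np.arange(n_cells), "iy": 0, "x": x, "y": y,
            "pass_id": alt_i * n_cells + np.arange(n_cells),
            "altitude": alt, "sea_state": ss.astype(float),
            "julian_day": rng.integers(140, 261, n_cells),
            "year": rng.choice([2015, 2016, 2021, 2022], n_cells),
            "effort_area": effort, "count": count, "c1": c1,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# spline engine: smooth recovery and shrinkage selection
# ---------------------------------------------------------------------------


def smooth_recovery(seed: int = 7, n: int = 2000, theta: float = 2.0) -> float:
    """Correlation between the fitted partial effect and the generating
    sine curve at one fixed seed."""
    rng = np.random.default_rng(seed)
    x1, x2 = rng.random(n), rng.random(n)
    a = np.full(n, 1.6)
    mu = np.exp(np.log(0.4) + np.sin(2 * np.pi * x1)) * a
    y = rng.negative_binomial(theta, theta / (theta + mu))
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    fit = fit_nbgam(df, [Smooth1D("x1"), Smooth1D("x2")], y="y", offset=np.log(a))
    g = fit.term_effect("s(x1)", df)
    truth = np.sin(2 * np.pi * x1)
    return float(np.corrcoef(g, truth - truth.mean())[0, 1])


def decoy_shrinkage_rate(n_reps: int = 50, seed: int = 0, n: int = 2000,
                         theta: float = 2.0) -> float:
    """Share of replicates in which a pure-noise covariate's shrinkage
    smooth ends below 0.5 effective degrees of freedom."""
    shrunk = 0
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        x1, x2 = rng.random(n), rng.random(n)
        a = np.full(n, 1.6)
        mu = np.exp(np.log(0.4) + np.sin(2 * np.pi * x1)) * a
        y = rng.negative_binomial(theta, theta / (theta + mu))
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = fit_nbgam(df, [Smooth1D("x1"), Smooth1D("x2")], y="y",
                        offset=np.log(a))
        shrunk += fit.edf["s(x2)"] < 0.5
    return shrunk / n_reps


# ---------------------------------------------------------------------------
# detectability: power and type-I error of the altitude term
# ---------------------------------------------------------------------------


def altitude_test_once(seed: int, delta_alt: float,
                       beta_ss: tuple[float, float], n_cells: int = 800,
                       theta: float = 2.0) -> tuple[float, float]:
    """(coefficient, p-value) of the parametric altitude term for one
    simulated dual-altitude survey, using the detectability model
    structure (spatial smooth, sea-state factor smooth, altitude factor,
    year factor, habitat smooth, log-effort offset)."""
    recs = simulate_cell_survey(n_cells=n_cells, theta=theta,
                                delta_alt=delta_alt, beta_ss=beta_ss, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit, _ = sel.altitude_model(recs, covariate_names=("c1",), xy_k=10)
    bt = next(b for b in fit.terms if b.label == "factor(altitude)")
    coef = float(fit.beta[bt.sl][0])
    p = float(fit.term_table.set_index("term").loc["factor(altitude)", "p_value"])
    return coef, p


def detectability_power_study(n_reps: int = 25, seed: int = 100,
                              delta_alt: float = np.log(0.5),
                              beta_ss: tuple[float, float] = (-0.20, -0.10),
                              n_cells: int = 800) -> pd.DataFrame:
    rows = []
    for r in range(n_reps):
        coef, p = altitude_test_once(seed + r, delta_alt, beta_ss, n_cells)
        rows.append({"rep": r, "coef": coef, "p_value": p,
                     "significant": p < 0.05})
    return pd.DataFrame(rows)


def detectability_null_study(n_reps: int = 50, seed: int = 500,
                             n_cells: int = 800) -> pd.DataFrame:
    return detectability_power_study(n_reps=n_reps, seed=seed, delta_alt=0.0,
                                     beta_ss=(0.0, 0.0), n_cells=n_cells)


# ---------------------------------------------------------------------------
# abundance recovery over replicate worlds
# ---------------------------------------------------------------------------


def _world_survey(seed: int, n_surveyed: int = 2000, theta: float = 2.0,
                  detect: syn.DetectParams | None = None):
    """One synthetic world with engineered covariates and a random
    cell-level survey of ``n_surveyed`` sea cells at both altitudes."""
    rng = np.random.default_rng(seed)
    config = syn.WorldConfig(
        extent=(0.0, 240.0, 0.0, 240.0), cell_km=4.0,
        land=syn.LandSpec(cx=215.0, cy=120.0, rx=22.0, ry=70.0,
                          islets=((180.0, 40.0, 6.0),)),
        seed=seed)
    env = syn.gen_environment(config)
    truth = syn.gen_truth(env, target_total=40_000.0, theta=theta,
                          detect=detect)
    ct = cov.covariate_table(env.grid, env.land_mask, env.fields)
    n_surveyed = min(n_surveyed, len(ct))
    pick = rng.choice(len(ct), size=n_surveyed, replace=False)
    surveyed = ct.iloc[pick].reset_index(drop=True)
    lam = truth.density[surveyed["iy"], surveyed["ix"]]
    rows = []
    for alt, frac, effort in (("high", 0.6, 1.6), ("low", 0.4, 1.6)):
        m = int(frac * n_surveyed)
        sub = surveyed.iloc[:m] if alt == "high" else surveyed.iloc[m:]
        lam_s = lam[:m] if alt == "high" else lam[m:]
        ss = rng.choice(5, size=len(sub), p=[0.3, 0.3, 0.25, 0.12, 0.03])
        p = syn.detection_prob(truth.detect, alt, ss)
        latent = syn.nb_counts(rng, lam_s * effort, theta)
        count = rng.binomial(latent, p)
        r = sub.copy()
        r["altitude"] = alt
        r["sea_state"] = ss.astype(float)
        r["effort_area"] = effort
        r["count"] = count
        rows.append(r)
    records = pd.concat(rows, ignore_index=True)
    return env, truth, ct, records


ABUNDANCE_TERMS = [Smooth2D("x", "y", k=12), Smooth1D("dist_coast"),
                   Smooth1D("depth"), Smooth1D("sst"),
                   FactorSmooth("sea_state", by="altitude", k=4),
                   Factor("altitude", ref="low")]


def abundance_recovery_once(seed: int, n_surveyed: int = 2000,
                            theta: float = 2.0) -> dict:
    """Fit the habitat model to one world's survey and predict the total
    under standardised conditions (sea state 0, low altitude, full-cell
    offset); report the estimate against the known total."""
    env, truth, ct, records = _world_survey(seed, n_surveyed, theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_nbgam(records, ABUNDANCE_TERMS, y="count",
                        offset=np.log(records["effort_area"].to_numpy()))
        pred = ab.build_prediction_grid(ct, {}, julian_day=195)
        est = ab.estimate_total(fit, pred, cell_area=env.grid.cell_area)
    return {"seed": seed, "total_est": est.total, "total_true": truth.total,
            "ratio": est.total / truth.total, "theta_hat": fit.theta,
            "deviance_explained": fit.deviance_explained}


def abundance_recovery_study(n_worlds: int = 25, seed: int = 1000,
                             n_surveyed: int = 2000) -> pd.DataFrame:
    return pd.DataFrame([abundance_recovery_once(seed + w, n_surveyed)
                         for w in range(n_worlds)])


# ---------------------------------------------------------------------------
# bootstrap coverage
# ---------------------------------------------------------------------------


def bootstrap_coverage_once(seed: int, n_cells: int = 600, B: int = 200,
                            theta: float = 2.0, cell_area: float = 16.0) -> dict:
    """One world: winsorised percentile-bootstrap CI for the total versus
    the known truth (well-specified two-smooth habitat model)."""
    rng = np.random.default_rng(seed)
    x1, x2 = rng.random(n_cells), rng.random(n_cells)
    effort = 1.6
    lam = np.exp(np.log(0.33) + np.sin(2 * np.pi * x1) + 0.5 * (x2 - 0.5))
    total_true = float(lam.sum() * cell_area)
    mu = lam * effort
    y = rng.negative_binomial(theta, theta / (theta + mu))
    recs = pd.DataFrame({"x1": x1, "x2": x2, "count": y, "effort_area": effort})
    terms = [Smooth1D("x1"), Smooth1D("x2")]
    pred = recs[["x1", "x2"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_nbgam(recs, terms, y="count", offset=np.log(effort))
        est = ab.estimate_total(fit, pred, cell_area=cell_area)
        lo, hi = ab.bootstrap_ci(recs, terms, pred, B=B, seed=seed,
                                 cell_area=cell_area, base_fit=fit)
    return {"seed": seed, "total_true": total_true, "total_est": est.total,
            "lo": lo, "hi": hi, "covered": bool(lo <= total_true <= hi)}


def bootstrap_coverage_study(n_worlds: int = 100, seed: int = 2000,
                             B: int = 200) -> pd.DataFrame:
    return pd.DataFrame([bootstrap_coverage_once(seed + w, B=B)
                         for w in range(n_worlds)])


# ---------------------------------------------------------------------------
# validation harness on well-specified data
# ---------------------------------------------------------------------------


def validation_study(seed: int = 3000, n: int = 2000, n_iter: int = 100,
                     theta: float = 2.0) -> ab.ValidationReport:
    rng = np.random.default_rng(seed)
    x1, x2 = rng.random(n), rng.random(n)
    effort = 1.6
    mu = np.exp(np.log(0.4) + np.sin(2 * np.pi * x1) + 0.5 * (x2 - 0.5)) * effort
    y = rng.negative_binomial(theta, theta / (theta + mu))
    recs = pd.DataFrame({"x1": x1, "x2": x2, "count": y, "effort_area": effort})
    return ab.validate_split(recs, [Smooth1D("x1"), Smooth1D("x2")],
                             n_iter=n_iter, seed=seed, theta=theta)
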