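"""Abundance prediction, uncertainty and validation.

The fitted distribution model is pushed over the full prediction grid
under standardised conditions (median surveyed Julian day, Beaufort sea
state 0, low survey altitude — the regime where detection is best), with
a full-cell offset of log(16 km^2) so predictions are densities times
cell area.  Total abundance is the rounded sum of per-cell predictions;
per-cell uncertainty is the delta-method coefficient of variation (which
on the log link equals the link-scale standard error).  The 95% CI comes
from a winsorised percentile bootstrap: counts capped at their 97.5th
percentile, surveyed rows resampled with replacement, the final model
structure refitted per replicate (smoothing re-estimated from a warm
start), and the 2.5th/97.5th percentiles of the replicate totals taken.
An 80/20 x 100 train/test harness quantifies predictive calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nbgam import (FittedDSM, ModelError, TermSpec, design_matrix,
                    fit_nbgam, refit_nbgam)

CELL_AREA_KM2 = 16.0


# ---------------------------------------------------------------------------
# prediction grid
# ---------------------------------------------------------------------------


def build_prediction_grid(cov_table: pd.DataFrame, transforms: dict,
                          julian_day: int, yearly_dynamic: dict[str, list[np.ndarray]] | None = None,
                          sea_state: float = 0.0, altitude: str = "low") -> pd.DataFrame:
    """Per-sea-cell covariate table under the standardised conditions.

    ``cov_table`` holds the raw (untransformed) static covariates per sea
    cell; ``yearly_dynamic`` optionally maps a dynamic variable to its
    per-year values at the chosen Julian-day window, which are averaged
    across years (years with a missing layer are omitted with a warning).
    Box-Cox transforms are re-applied with the *stored* lambda and shift —
    never re-estimated.
    """
    out = cov_table.copy()
    if yearly_dynamic:
        for name, layers in yearly_dynamic.items():
            ok = [l for l in layers if l is not None]
            if len(ok) < len(layers):
                warnings.warn(f"{len(layers) - len(ok)} yearly layer(s) of "
                              f"{name!r} missing; omitted from the mean",
                              RuntimeWarning)
            if not ok:
                raise ValueError(f"no yearly layers available for {name!r}")
            out[name] = np.mean(ok, axis=0)
    for name, tr in transforms.items():
        if name in out.columns:
            out[name] = tr.transform(out[name].to_numpy(dtype=float))
    out["sea_state"] = sea_state
    out["altitude"] = altitude
    out["julian_day"] = julian_day
    return out


# ---------------------------------------------------------------------------
# totals and winsorisation
# ---------------------------------------------------------------------------


@dataclass
class AbundanceEstimate:
    predicted: np.ndarray          # per-cell expected count (density x area)
    cv: np.ndarray                 # per-cell coefficient of variation
    total: int                     # rounded total abundance
    total_raw: float               # the unrounded sum
    ci95: tuple[float, float] | None
    conditions: dict


def estimate_total(fit: FittedDSM, prediction_table: pd.DataFrame,
                   cell_area: float = CELL_AREA_KM2) -> AbundanceEstimate:
    """Point prediction of total abundance with per-cell CV."""
    mu, se_link = fit.predict(prediction_table, offset=np.log(cell_area),
                              se=True, allow_extrapolation=True)
    if not np.all(np.isfinite(mu)):
        bad = int(np.flatnonzero(~np.isfinite(mu))[0])
        raise ModelError(f"non-finite prediction at cell row {bad}")
    total_raw = float(mu.sum())
    conditions = {c: prediction_table[c].iloc[0]
                  for c in ("julian_day", "sea_state", "altitude")
                  if c in prediction_table.columns}
    return AbundanceEstimate(predicted=mu, cv=se_link, total=int(round(total_raw)),
                             total_raw=total_raw, ci95=None, conditions=conditions)


def winsorise(counts, upper_percentile: float = 97.5) -> np.ndarray:
    """Cap values above the interpolated upper percentile at that value."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty input")
    cap = np.percentile(counts, upper_percentile)  # linear interpolation
    return np.minimum(counts, cap)


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------


def bootstrap_ci(records: pd.DataFrame, terms: list[TermSpec],
                 prediction_table: pd.DataFrame, B: int = 1000, seed: int = 0,
                 cell_area: float = CELL_AREA_KM2, upper_percentile: float = 97.5,
                 percentiles: tuple[float, float] = (2.5, 97.5),
                 mode: str = "refit", base_fit: FittedDSM | None = None,
                 point_total: float | None = None,
                 **fit_kwargs) -> tuple[float, float]:
    """Winsorised percentile-bootstrap CI for total abundance.

    ``mode="refit"`` (default) resamples surveyed rows with replacement
    and refits the final model structure per replicate (smoothing
    re-estimated from a warm start; theta held at the base fit's value
    when one is supplied).  ``mode="parametric"`` draws coefficients from
    the base fit's posterior instead — a cheap alternative.  Replicates
    that fail to converge are dropped and counted; more than 20% failures
    is an error.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    records = records[records["effort_area"] > 0].reset_index(drop=True)
    records = records.copy()
    counts = records["count"].to_numpy(dtype=float)
    pos = counts[counts > 0]
    if pos.size:
        # cap the highest counts at the upper percentile of the observed
        # (positive) counts: with mostly-zero survey cells, a zero-inclusive
        # quantile would truncate ordinary sightings, not outliers, and
        # bias every bootstrap total downward
        cap = np.percentile(pos, upper_percentile)
        records["count"] = np.minimum(counts, cap).round().astype(int)

    if mode == "parametric":
        if base_fit is None:
            raise ValueError("parametric mode needs base_fit")
        X = design_matrix(base_fit.terms, prediction_table)
        betas = rng.multivariate_normal(base_fit.beta, base_fit.Vb, size=B,
                                        method="cholesky")
        totals = np.exp(np.clip(X @ betas.T + np.log(cell_area), -30, 30)).sum(axis=0)
    else:
        n = len(records)
        totals_l = []
        failures = 0
        Xpred = None
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            boot = records.iloc[idx].reset_index(drop=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if base_fit is not None:
                        # reuse the fitted structure: bases and centring are
                        # part of the model; smoothing re-estimated per
                        # replicate from a warm start, theta held
                        f = refit_nbgam(base_fit, boot, y="count",
                                        offset=np.log(boot["effort_area"].to_numpy()))
                        if Xpred is None:
                            Xpred = design_matrix(f.terms, prediction_table)
                        eta = Xpred @ f.beta + np.log(cell_area)
                        mu = np.exp(np.clip(eta, -30, 30))
                    else:
                        f = fit_nbgam(boot, terms, y="count",
                                      offset=np.log(boot["effort_area"].to_numpy()),
                                      **fit_kwargs)
                        mu = f.predict(prediction_table, offset=np.log(cell_area),
                                       allow_extrapolation=True)
                totals_l.append(float(mu.sum()))
            except (ModelError, np.linalg.LinAlgError):
                failures += 1
        if failures > 0.2 * B:
            raise ModelError(f"{failures}/{B} bootstrap replicates failed")
        totals = np.asarray(totals_l)

    lo, hi = np.percentile(totals, percentiles)
    if point_total is not None and not (lo <= point_total <= hi):
        warnings.warn("point estimate outside the bootstrap interval "
                      f"({lo:.0f}, {hi:.0f}); reported as computed", RuntimeWarning)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# 80/20 validation harness
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    n_iterations: int
    train_fraction: float
    results: pd.DataFrame          # predicted_total, observed_total, rel_error
    share_within_5pct: float
    share_within_10pct: float
    median_abs_rel_error: float
    mean_rel_error: float          # signed; negative = underestimation
    n_failed: int


def train_test_splits(n: int, frac: float = 0.8, n_iter: int = 100,
                      seed: int = 0):
    """Yield ``n_iter`` random (train, test) index partitions of range(n).

    Each partition is disjoint and exhaustive with ``round(frac * n)``
    training rows.
    """
    rng = np.random.default_rng(seed)
    n_train = int(round(frac * n))
    for _ in range(n_iter):
        perm = rng.permutation(n)
        yield perm[:n_train], perm[n_train:]


def validate_split(records: pd.DataFrame, terms: list[TermSpec],
                   n_iter: int = 100, frac: float = 0.8, seed: int = 0,
                   **fit_kwargs) -> ValidationReport:
    """Random 80/20 train/test splits comparing predicted vs observed totals."""
    records = records[records["effort_area"] > 0].reset_index(drop=True)
    n = len(records)
    if n < 50:
        raise ValueError("validation needs at least 50 surveyed rows")
    rows = []
    failed = 0
    for it, (tr, te) in enumerate(train_test_splits(n, frac, n_iter, seed)):
        train = records.iloc[tr].reset_index(drop=True)
        test = records.iloc[te].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = fit_nbgam(train, terms, y="count",
                              offset=np.log(train["effort_area"].to_numpy()),
                              **fit_kwargs)
                mu = f.predict(test, offset=np.log(test["effort_area"].to_numpy()),
                               allow_extrapolation=True)
        except (ModelError, np.linalg.LinAlgError):
            failed += 1
            continue
        pred, obs = float(mu.sum()), float(test["count"].sum())
        rows.append({"iteration": it, "predicted_total": pred,
                     "observed_total": obs,
                     "rel_error": (pred - obs) / obs if obs > 0 else np.nan})
    res = pd.DataFrame(rows)
    rel = res["rel_error"].dropna()
    return ValidationReport(
        n_iterations=n_iter, train_fraction=frac, results=res,
        share_within_5pct=float((rel.abs() <= 0.05).mean()),
        share_within_10pct=float((rel.abs() <= 0.10).mean()),
        median_abs_rel_error=float(rel.abs().median()),
        mean_rel_error=float(rel.mean()), n_failed=failed)
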