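"""Model selection and the two modelling studies.

Two fitted studies are reproduced here on top of the NB-GAM engine:

* the *altitude/detectability model*, fitted only to grid cells surveyed
  at both altitudes so the survey-altitude effect is not masked by the
  spatial covariates, and
* the *distribution model*, fitted to every surveyed cell-pass, with year
  as a random effect that is dropped (and the model refitted) when
  non-significant.

Both share the selection machinery: a concurvity screen (worst-case
measure, the squared largest canonical correlation between one term's
basis columns and the span of all the others), transitive grouping of
pairs exceeding 0.8, and an exhaustive AIC comparison over all subsets of
each correlated covariate group.  Structural terms (the spatial smooth,
the sea-state factor smooth, the parametric altitude term and the year
term) are always retained; shrinkage penalties may still reduce any smooth
to ~0 effective degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nbgam import (Factor, FactorSmooth, FittedDSM, Linear, ModelError,
                    RandomEffect, Smooth1D, Smooth2D, TermSpec, build_design,
                    fit_nbgam)

log = logging.getLogger(__name__)

CONCURVITY_THRESHOLD = 0.8


# ---------------------------------------------------------------------------
# concurvity
# ---------------------------------------------------------------------------


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column span (rank-truncated SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    return U[:, keep]


def concurvity_matrix(data: pd.DataFrame, terms: list[TermSpec]) -> pd.DataFrame:
    """Pairwise worst-case concurvity plus a 'worst_vs_rest' column.

    Entry (i, j) is the squared largest canonical correlation between the
    centred basis columns of term i and term j; 'worst_vs_rest' measures
    each term against the joint span of all the other terms.
    """
    X, built, _ = build_design(terms, data)
    bases = {bt.label: _orth(X[:, bt.sl]) for bt in built}
    labels = list(bases)
    M = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        if bases[a].shape[1] == 0 or bases[b].shape[1] == 0:
            v = 0.0
        else:
            s = np.linalg.svd(bases[a].T @ bases[b], compute_uv=False)
            v = float(np.clip(s[0] ** 2, 0.0, 1.0))
        M.loc[a, b] = M.loc[b, a] = v
    worst = {}
    for lab in labels:
        others = [bases[o] for o in labels if o != lab and bases[o].shape[1]]
        if not others or bases[lab].shape[1] == 0:
            worst[lab] = 0.0
            continue
        Q = _orth(np.hstack(others))
        s = np.linalg.svd(bases[lab].T @ Q, compute_uv=False)
        worst[lab] = float(np.clip(s[0] ** 2, 0.0, 1.0))
    M["worst_vs_rest"] = pd.Series(worst)
    return M


def correlated_groups(conc: pd.DataFrame, threshold: float = CONCURVITY_THRESHOLD) -> list[list[str]]:
    """Connected components of the pairwise concurvity graph above threshold."""
    labels = [l for l in conc.columns if l != "worst_vs_rest"]
    parent = {l: l for l in labels}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(labels, 2):
        if conc.loc[a, b] > threshold:
            parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for l in labels:
        comps.setdefault(find(l), []).append(l)
    return [sorted(c) for c in comps.values() if len(c) > 1]


# ---------------------------------------------------------------------------
# combinatorial AIC selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    concurvity: pd.DataFrame
    groups: list[list[str]]
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    chosen_terms: list[str] = field(default_factory=list)
    dropped_terms: list[str] = field(default_factory=list)
    shrunk_terms: list[str] = field(default_factory=list)
    term_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def combinatorial_aic_selection(data: pd.DataFrame, base_terms: list[TermSpec],
                                group: list[str], y: str, offset,
                                **fit_kwargs) -> tuple[FittedDSM, pd.DataFrame]:
    """Fit every subset of the correlated covariate group; keep lowest AIC.

    Terms outside the group are always included.  AIC ties (< 1e-6) break
    toward fewer total effective degrees of freedom; candidates that fail
    to converge are excluded with a log message.
    """
    if len(group) > 12:
        raise ModelError("correlated group too large for exhaustive selection")
    group = [g for g in group if any(t.label == g for t in base_terms)]

    # fit the full model once; warm-start every subset from its smoothing
    # parameters and dispersion (matched per penalty label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full = fit_nbgam(data, base_terms, y=y, offset=offset, **fit_kwargs)
    rho_by_label: dict[str, list[float]] = {}
    for pen, r in zip(full.penalties, full.rho):
        rho_by_label.setdefault(pen.term, []).append(float(r))
    warm = dict(fit_kwargs)
    warm.setdefault("max_outer", 3)
    warm.setdefault("optimizer_maxiter", 40)
    if "theta" not in warm:
        warm.setdefault("theta_init", full.theta)

    records = []
    fits = {}
    for r in range(len(group) + 1):
        for subset in itertools.combinations(group, r):
            terms = [t for t in base_terms
                     if t.label not in group or t.label in subset]
            key = frozenset(subset)
            # every candidate (the full set included) is fitted under the
            # same warm-start protocol so AIC comparisons are symmetric
            kept = {t.label for t in terms}
            try:
                parts = [rho_by_label[lab] for lab in rho_by_label
                         if lab.split("[")[0] in kept]
                rho0 = np.concatenate(parts) if parts else None
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = fit_nbgam(data, terms, y=y, offset=offset,
                                    rho_init=rho0, **warm)
            except (ModelError, np.linalg.LinAlgError) as exc:
                log.info("candidate %s excluded: %s", sorted(subset), exc)
                continue
            fits[key] = fit
            records.append({"subset": "+".join(sorted(subset)) or "(none)",
                            "n_terms": len(terms), "aic": fit.aic,
                            "edf_total": fit.edf_total})
    if not fits:
        raise ModelError("no candidate model converged")
    cand = pd.DataFrame(records).sort_values(["aic", "edf_total"]).reset_index(drop=True)
    best_aic = cand["aic"].min()
    near = cand[cand["aic"] <= best_aic + 1e-6]
    chosen_row = near.sort_values("edf_total").iloc[0]
    chosen_key = frozenset(s for s in chosen_row["subset"].split("+") if s != "(none)")
    return fits[chosen_key], cand


# ---------------------------------------------------------------------------
# the two studies
# ---------------------------------------------------------------------------

DEFAULT_ENV_COVARIATES = ("dist_coast", "dist_shelf", "depth", "slope",
                          "chl_a", "sst", "sss", "grad_chl", "grad_sst",
                          "grad_sss", "colony_score", "julian_day")


def _structural_terms(records: pd.DataFrame, xy_k: int, seastate_k: int,
                      year_term: str) -> list[TermSpec]:
    terms: list[TermSpec] = [Smooth2D("x", "y", k=xy_k)]
    if records["year"].nunique() >= 2:
        terms.append(RandomEffect("year") if year_term == "random" else Factor("year"))
    n_ss = records["sea_state"].nunique()
    if n_ss >= 4:
        terms.append(FactorSmooth("sea_state", by="altitude", k=seastate_k))
    elif n_ss >= 2:
        terms.append(Linear("sea_state"))
    terms.append(Factor("altitude", ref="low"))  # low altitude = best detection
    return terms


def _run_study(records: pd.DataFrame, covariate_names, xy_k, seastate_k, k,
               year_term, y, fit_kwargs) -> tuple[FittedDSM, SelectionReport]:
    records = records[records["effort_area"] > 0].reset_index(drop=True)
    structural = _structural_terms(records, xy_k, seastate_k, year_term)
    structural_labels = {t.label for t in structural}
    covs = [c for c in covariate_names if c in records.columns
            and records[c].nunique() > k]
    terms = structural + [Smooth1D(c, k=k) for c in covs]
    offset = np.log(records["effort_area"].to_numpy())

    conc = concurvity_matrix(records, terms)
    groups = correlated_groups(conc)
    report = SelectionReport(concurvity=conc, groups=groups)

    fit = None
    base = list(terms)
    cands = []
    for grp in sorted(groups, key=len, reverse=True):
        selectable = [g for g in grp if g not in structural_labels]
        if not selectable:
            continue
        fit, cand = combinatorial_aic_selection(records, base, selectable,
                                                y=y, offset=offset, **fit_kwargs)
        cands.append(cand)
        kept = {bt.label for bt in fit.terms}
        base = [t for t in base if t.label in kept]
    if fit is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_nbgam(records, base, y=y, offset=offset, **fit_kwargs)
    if cands:
        report.candidates = pd.concat(cands, ignore_index=True)

    report.chosen_terms = [bt.label for bt in fit.terms]
    report.dropped_terms = sorted({t.label for t in terms} - set(report.chosen_terms))
    report.shrunk_terms = [l for l, e in fit.edf.items()
                           if l != "(intercept)" and e < 0.5]
    report.term_table = fit.term_table
    near_sig = fit.term_table[(fit.term_table["p_value"] >= 0.05)
                              & (fit.term_table["p_value"] < 0.10)]
    for t in near_sig["term"]:
        log.info("term %s approaching significance (no action taken)", t)
    return fit, report


def altitude_model(records: pd.DataFrame,
                   covariate_names=DEFAULT_ENV_COVARIATES,
                   xy_k: int = 20, seastate_k: int = 5, k: int = 5,
                   **fit_kwargs) -> tuple[FittedDSM, SelectionReport]:
    """Detectability study on the dual-altitude subset.

    counts ~ s(x,y) + year(factor) + s(sea_state, by altitude) + altitude
    + shrinkage smooths of the environmental covariates, offset log effort.
    """
    if records[records["effort_area"] > 0]["altitude"].nunique() < 2:
        raise ModelError("altitude model needs both altitude classes")
    return _run_study(records, covariate_names, xy_k, seastate_k, k,
                      year_term="factor", y="count", fit_kwargs=fit_kwargs)


def distribution_model(records: pd.DataFrame,
                       covariate_names=DEFAULT_ENV_COVARIATES,
                       xy_k: int = 30, seastate_k: int = 5, k: int = 5,
                       **fit_kwargs) -> tuple[FittedDSM, SelectionReport]:
    """Distribution/abundance study on all surveyed cell-passes.

    Same structure as the altitude model but with year as a random effect;
    a non-significant year effect (p >= 0.05) is removed and the model
    refitted.
    """
    fit, report = _run_study(records, covariate_names, xy_k, seastate_k, k,
                             year_term="random", y="count", fit_kwargs=fit_kwargs)
    tt = fit.term_table
    yr = tt[tt["term"] == "re(year)"]
    if not yr.empty and float(yr["p_value"].iloc[0]) >= 0.05:
        keep = [bt.spec for bt in fit.terms if bt.label != "re(year)"]
        records_f = records[records["effort_area"] > 0].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_nbgam(records_f, keep, y="count",
                            offset=np.log(records_f["effort_area"].to_numpy()),
                            **fit_kwargs)
        report.dropped_terms = sorted(set(report.dropped_terms) | {"re(year)"})
        report.chosen_terms = [bt.label for bt in fit.terms]
        report.term_table = fit.term_table
    return fit, report
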