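"""Inferential models relating RTACC to cognitive outcome.

Four model families, all operating on a rectangular analysis table that
joins per-participant RTACC values with the participant profiles:

* an adjusted linear regression of the week-24 RBANS score on RTACC and
  clinical covariates (age, sex, education, APOE e4, baseline RBANS) —
  because baseline is a covariate, the fit is equivalently a model of the
  RBANS *change*;
* a Huber robust variant of the same regression (M-estimation by IRLS with
  MAD-rescaled residuals), used as an outlier-insensitivity check;
* a recursive path system in observed variables: RTACC -> each blood
  biomarker change, and RTACC + biomarker changes -> outcome, estimated
  equation by equation (equivalent to ML for a recursive system with
  uncorrelated errors), with backward pruning of non-significant marker
  paths;
* responder classification: logistic models of "good responder" (RBANS
  increased at week 24) from clinical covariates (model 1), RTACC alone
  (model 2), or both (model 3), scored by the rank-based ROC AUC with a
  stratified bootstrap CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_TERMS = ["age", "sex", "education_years", "apoe_e4"]
LINEAR_TERMS = ["intercept"] + COVARIATE_TERMS + ["rbans_baseline", "rtacc"]
DEFAULT_MARKERS = ("bdnf", "ptau", "nfl", "gfap")

OUTCOME = "rbans"  # node name of the cognitive outcome in the path system


@dataclass
class ModelFit:
    """Coefficient table of one fitted equation."""

    model_kind: str  # ols | rlm | logistic | path_equation
    response: str
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_or_z: np.ndarray
    p_values: np.ndarray
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    deviance: float | None = None  # -2 loglik, logistic fits only

    def __post_init__(self) -> None:
        k = len(self.terms)
        for v in (self.coefficients, self.standard_errors, self.t_or_z, self.p_values):
            if len(v) != k:
                raise ValueError("per-term vectors must align with terms")

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Classical Wald interval (t for ols/rlm, z for logistic)."""
        i = self.terms.index(term)
        if self.model_kind == "logistic":
            q = stats.norm.ppf(0.5 + level / 2)
        else:
            q = stats.t.ppf(0.5 + level / 2, df=self.n_obs - len(self.terms))
        half = q * self.standard_errors[i]
        return float(self.coefficients[i] - half), float(self.coefficients[i] + half)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coefficient": self.coefficients,
            "std_error": self.standard_errors,
            "t_or_z": self.t_or_z,
            "p_value": self.p_values,
        })


def build_analysis_table(profiles: pd.DataFrame, rtacc_values: pd.DataFrame,
                         window_weeks: int = 24,
                         excluded_game: str | None = None) -> pd.DataFrame:
    """Join profiles with one defined RTACC per participant.

    Selects the rows of ``rtacc_values`` matching the requested window and
    exclusion, drops participants whose RTACC is undefined (count logged
    and stored in ``table.attrs['n_dropped']``), and returns a complete-case
    table whose columns are exactly the regression terms plus the outcome
    and optional biomarker columns.
    """
    win_mask = rtacc_values["window_weeks"] == window_weeks
    if excluded_game is None:
        excl_mask = rtacc_values["excluded_game"].isna()
    else:
        excl_mask = rtacc_values["excluded_game"] == excluded_game
    sel = rtacc_values[win_mask & excl_mask]
    if sel.empty:
        raise ValueError(
            f"no RTACC values computed for window={window_weeks}, "
            f"excluded_game={excluded_game!r}")

    defined = sel[sel["defined"].astype(bool)]
    n_dropped = len(sel) - len(defined)
    if n_dropped:
        logger.info("dropping %d participant(s) with undefined RTACC", n_dropped)

    merged = profiles.merge(
        defined[["participant_id", "value"]].rename(columns={"value": "rtacc"}),
        on="participant_id", how="inner")
    core = COVARIATE_TERMS + ["rbans_baseline", "rbans_week24", "rtacc"]
    before = len(merged)
    merged = merged.dropna(subset=core).reset_index(drop=True)
    n_dropped += before - len(merged)
    if merged.empty:
        raise ValueError("no usable rows after joining profiles with RTACC values")
    merged["rbans_change"] = merged["rbans_week24"] - merged["rbans_baseline"]
    merged.attrs["n_dropped"] = n_dropped
    return merged


def _design(table: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(table)) if t == "intercept" else table[t].to_numpy(float)
            for t in terms]
    return np.column_stack(cols)


def _check_full_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name a term whose removal restores full column rank
    for j, t in enumerate(terms):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(f"design matrix is rank-deficient: term {t!r} is collinear")
    raise ValueError("design matrix is rank-deficient")


def _ols_fit(table: pd.DataFrame, response: str, terms: Sequence[str],
             model_kind: str = "ols") -> ModelFit:
    y = table[response].to_numpy(float)
    X = _design(table, terms)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more terms than observations")
    _check_full_rank(X, terms)
    res = sm.OLS(y, X).fit()
    return ModelFit(model_kind, response, list(terms),
                    np.asarray(res.params), np.asarray(res.bse),
                    np.asarray(res.tvalues), np.asarray(res.pvalues),
                    n_obs=int(res.nobs))


def fit_linear_rbans(table: pd.DataFrame) -> ModelFit:
    """Adjusted linear regression of the week-24 RBANS score.

    rbans_week24 = b0 + b1 age + b2 sex + b3 education + b4 APOEe4
                   + b5 rbans_baseline + b6 rtacc + eps

    Classical (homoskedastic) standard errors and two-sided t p-values.
    """
    return _ols_fit(table, "rbans_week24", LINEAR_TERMS)


def fit_robust_rbans(table: pd.DataFrame, tuning: float = 1.345,
                     tol: float = 1e-8, max_iter: int = 50) -> ModelFit:
    """Huber robust variant of :func:`fit_linear_rbans`.

    M-estimation by iteratively reweighted least squares with the Huber psi
    (default tuning constant 1.345 for 95% Gaussian efficiency); the scale
    is the MAD of the residuals, re-estimated each iteration.  A fit that
    exhausts ``max_iter`` is returned with ``converged = False`` and a
    warning rather than raising.
    """
    y = table["rbans_week24"].to_numpy(float)
    X = _design(table, LINEAR_TERMS)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more terms than observations")
    _check_full_rank(X, LINEAR_TERMS)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(maxiter=max_iter, tol=tol, conv="coefs", scale_est="mad")
    n_iter = len(res.fit_history.get("params", [])) or max_iter
    converged = bool(res.fit_history.get("converged", n_iter < max_iter))
    if not converged:
        warnings.warn("robust regression did not converge within "
                      f"{max_iter} iterations", UserWarning, stacklevel=2)
    z = np.asarray(res.params) / np.asarray(res.bse)
    return ModelFit("rlm", "rbans_week24", list(LINEAR_TERMS),
                    np.asarray(res.params), np.asarray(res.bse),
                    z, np.asarray(res.pvalues),
                    n_obs=int(res.nobs), converged=converged, n_iter=n_iter)


# --------------------------------------------------------------------------
# recursive path system
# --------------------------------------------------------------------------

Path = tuple[str, str]  # (source, target) in {"rtacc", marker, OUTCOME}


@dataclass
class PathModelResult:
    """A fitted recursive path system and its effect decomposition."""

    markers: list[str]
    adjust_covariates: bool
    retained_paths: list[Path]
    equations: dict[str, ModelFit]  # keyed by endogenous variable
    direct_effect: float
    direct_se: float
    direct_p: float
    indirect_effects: dict[str, float]  # product of the two path estimates
    pruning_trace: list[tuple[Path, float]] = field(default_factory=list)
    _table: pd.DataFrame | None = field(default=None, repr=False)

    def path_coef(self, path: Path) -> float:
        src, dst = path
        eq = self.equations[dst]
        term = "rtacc" if src == "rtacc" else f"{src}_change"
        return eq.coef(term)

    def path_p(self, path: Path) -> float:
        src, dst = path
        eq = self.equations[dst]
        term = "rtacc" if src == "rtacc" else f"{src}_change"
        return eq.pvalue(term)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for src, dst in self.retained_paths:
            eq = self.equations[dst]
            term = "rtacc" if src == "rtacc" else f"{src}_change"
            rows.append({
                "source": src, "target": dst,
                "coefficient": eq.coef(term), "std_error": eq.se(term),
                "p_value": eq.pvalue(term),
            })
        return pd.DataFrame(rows)


def _fit_path_system(table: pd.DataFrame, markers: Sequence[str],
                     retained: Iterable[Path],
                     adjust_covariates: bool) -> PathModelResult:
    retained = list(retained)
    equations: dict[str, ModelFit] = {}

    for m in markers:
        if ("rtacc", m) not in retained:
            continue
        terms = ["intercept", "rtacc"]
        if adjust_covariates:
            terms += COVARIATE_TERMS
        equations[m] = _ols_fit(table, f"{m}_change", terms, model_kind="path_equation")

    out_terms = ["intercept", "rtacc"]
    out_terms += [f"{m}_change" for m in markers if (m, OUTCOME) in retained]
    if adjust_covariates:
        out_terms += COVARIATE_TERMS + ["rbans_baseline"]
        response = "rbans_week24"
    else:
        response = "rbans_change"
    equations[OUTCOME] = _ols_fit(table, response, out_terms,
                                  model_kind="path_equation")

    out_eq = equations[OUTCOME]
    indirect = {
        m: equations[m].coef("rtacc") * out_eq.coef(f"{m}_change")
        for m in markers
        if ("rtacc", m) in retained and (m, OUTCOME) in retained
    }
    return PathModelResult(
        markers=list(markers), adjust_covariates=adjust_covariates,
        retained_paths=retained, equations=equations,
        direct_effect=out_eq.coef("rtacc"), direct_se=out_eq.se("rtacc"),
        direct_p=out_eq.pvalue("rtacc"), indirect_effects=indirect,
        _table=table)


def fit_path_model(table: pd.DataFrame,
                   markers: Sequence[str] = DEFAULT_MARKERS,
                   adjust_covariates: bool = True) -> PathModelResult:
    """Fit the full recursive path system.

    Equations (each by least squares on the complete-case table):
    each ``<marker>_change`` on RTACC (plus covariates when adjusting), and
    the RBANS outcome on RTACC plus all marker changes (plus covariates and
    baseline when adjusting).  The per-marker indirect effect is the product
    of its two path estimates.
    """
    missing = [m for m in markers if f"{m}_change" not in table.columns]
    if missing:
        raise ValueError(f"missing biomarker column(s): "
                         f"{[f'{m}_change' for m in missing]}")
    cc = table.dropna(subset=[f"{m}_change" for m in markers]).reset_index(drop=True)
    if cc.empty:
        raise ValueError("no complete cases across the requested biomarkers")
    paths: list[Path] = [("rtacc", m) for m in markers]
    paths += [(m, OUTCOME) for m in markers]
    paths.append(("rtacc", OUTCOME))
    return _fit_path_system(cc, markers, paths, adjust_covariates)


def prune_path_model(result: PathModelResult, alpha: float = 0.05) -> PathModelResult:
    """Backward elimination of non-significant marker paths.

    Repeatedly drops the single largest-p marker path with p >= alpha and
    refits, stopping when every remaining marker path is significant or
    only the direct RTACC -> outcome path remains; the direct path is never
    dropped.  The full ordered trace of removals is recorded.
    """
    if result._table is None:
        raise ValueError("result does not carry its analysis table; refit first")
    current = result
    trace: list[tuple[Path, float]] = []
    while True:
        candidates = [p for p in current.retained_paths if p != ("rtacc", OUTCOME)]
        if not candidates:
            break
        pvals = {p: current.path_p(p) for p in candidates}
        worst = max(pvals, key=lambda p: pvals[p])
        if pvals[worst] < alpha:
            break
        trace.append((worst, pvals[worst]))
        retained = [p for p in current.retained_paths if p != worst]
        current = _fit_path_system(result._table, result.markers, retained,
                                   result.adjust_covariates)
    current.pruning_trace = trace
    return current


# --------------------------------------------------------------------------
# responder classification
# --------------------------------------------------------------------------

@dataclass
class ResponderModelResult:
    """One of the three good-responder logistic models with its ROC AUC."""

    model_id: int
    fit: ModelFit
    auc: float
    auc_ci: tuple[float, float]
    n_good: int
    n_poor: int
    separation: bool = False
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    The probability that a random positive's score exceeds a random
    negative's, counting ties as 1/2 — identical to trapezoidal integration
    of the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc_ci(scores, labels, reps: int = 2000, level: float = 0.95,
                     rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the ROC AUC.

    Resamples within the positive and negative classes separately so every
    replicate has both classes, then takes percentile bounds of the
    replicate AUCs.
    """
    rng = rng if rng is not None else np.random.default_rng()
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = s[y]
    neg = s[~y]
    aucs = np.empty(reps)
    labs = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    for b in range(reps):
        sp = pos[rng.integers(0, pos.size, pos.size)]
        sn = neg[rng.integers(0, neg.size, neg.size)]
        aucs[b] = roc_auc(np.concatenate([sp, sn]), labs)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def _logistic_fit(table: pd.DataFrame, y: np.ndarray,
                  terms: Sequence[str]) -> tuple[ModelFit, np.ndarray, bool]:
    X = _design(table, terms)
    _check_full_rank(X, terms)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation aborts plain MLE
            separation = True
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0, maxiter=500)
    for w in caught:
        if "separation" in str(w.message).lower():
            separation = True
    if separation:
        warnings.warn("possible complete separation in logistic fit; "
                      "coefficients may be unstable", UserWarning, stacklevel=2)
    params = np.asarray(res.params)
    try:
        bse = np.asarray(res.bse)
    except Exception:
        bse = np.full_like(params, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
        p = 2 * stats.norm.sf(np.abs(z))
    eta = X @ params
    probs = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    fit = ModelFit("logistic", "good_responder", list(terms), params, bse, z, p,
                   n_obs=len(y), converged=not separation, deviance=-2 * ll)
    return fit, probs, separation


def fit_responder_models(table: pd.DataFrame, labels: pd.DataFrame,
                         bootstrap_reps: int = 2000,
                         rng: np.random.Generator | None = None
                         ) -> list[ResponderModelResult]:
    """Fit the three good-responder logistic models and score them by AUC.

    Model 1: clinical covariates only (age, sex, education, APOE e4);
    model 2: RTACC only; model 3: covariates + RTACC.  Ties (zero RBANS
    change) are excluded.  In-sample predicted probabilities are scored by
    the rank AUC with a seeded stratified-bootstrap 95% CI.
    """
    rng = rng if rng is not None else np.random.default_rng()
    merged = table.merge(labels, on="participant_id", how="inner")
    merged = merged[merged["label"] != "tie"].reset_index(drop=True)
    classes = set(merged["label"])
    if classes != {"good", "poor"}:
        raise ValueError("need at least one good and one poor responder "
                         f"after tie exclusion (got {sorted(classes)})")
    y = (merged["label"] == "good").to_numpy(int)
    n_good, n_poor = int(y.sum()), int((1 - y).sum())
    if n_good < 2 or n_poor < 2:
        raise ValueError("need >= 2 responders in each class")

    specs = {
        1: ["intercept"] + COVARIATE_TERMS,
        2: ["intercept", "rtacc"],
        3: ["intercept"] + COVARIATE_TERMS + ["rtacc"],
    }
    results = []
    for model_id, terms in specs.items():
        fit, probs, sep = _logistic_fit(merged, y, terms)
        auc = roc_auc(probs, y)
        ci = bootstrap_auc_ci(probs, y, reps=bootstrap_reps, rng=rng)
        results.append(ResponderModelResult(model_id, fit, auc, ci,
                                            n_good, n_poor, sep, probs,
                                            y.astype(bool)))
    return results
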