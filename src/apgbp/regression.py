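"""Blood-pressure regression: the multiple-regression estimator with
stepwise feature selection, the conventional PTT simple-regression
baseline, and the evaluation protocols (error metrics, leave-one-out
cross-validation, static-feature ablation).

The estimated pressure is the linear form

    y = u0 + u1*x1 + u2*x2 + ... + up*xp     [mmHg]

with the explanatory variables chosen from the 20-feature candidate set
by bidirectional stepwise selection: a feature enters while its partial
t-test p-value is below ``alpha_in`` and leaves when it rises above
``alpha_out`` (classical 0.05 / 0.10 defaults).  An information-
criterion mode (BIC) is provided as an alternative selection rule.

Error convention: ``error = estimated - measured`` throughout; the
summary triplet is the Pearson correlation r between measured and
estimated pressure, the mean error, and the sample standard deviation
(n-1 denominator) of the errors.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and
compose with sklearn model selection.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import (DegenerateBaselineError, FoldFitError, InputError,
                     MissingFeatureError, SingularFitError)
from .features import FEATURE_NAMES, STATIC_FEATURES

__all__ = [
    "RegressionModel",
    "EvalReport",
    "PTTBaseline",
    "StepwiseLinearRegression",
    "PTTBaselineRegression",
    "fit_ols",
    "stepwise_select",
    "predict",
    "fit_ptt_baseline",
    "error_metrics",
    "loocv",
    "ablation_static_features",
]


# ---------------------------------------------------------------------------
# Core OLS with inference.  numpy/scipy only: these solves run thousands of
# times inside stepwise LOOCV, and the closed-form normal-equations oracle in
# the test suite (plus a statsmodels cross-check) guards their correctness.

def _ols_fit(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns coefficient stats and BIC."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < p + 1:
        raise SingularFitError(_collinear_columns(Xd))
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    dof = n - p - 1
    tss = float(np.sum((y - y.mean()) ** 2))
    if dof > 0:
        sigma2 = rss / dof
        XtX_inv = np.linalg.inv(Xd.T @ Xd)
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        pvals = np.where(np.isfinite(tvals), pvals, 0.0)
    else:
        se = np.full(p + 1, np.nan)
        pvals = np.full(p + 1, np.nan)
    # Gaussian log-likelihood BIC (MLE variance)
    if rss <= 0 or n == 0:
        bic = -np.inf
    else:
        ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        bic = (p + 2) * np.log(n) - 2.0 * ll
    return beta, pvals, rss, tss, bic


def _collinear_columns(Xd: np.ndarray):
    """Name columns involved in rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    # also columns beyond the numerical rank
    rank = int(np.sum(diag >= tol))
    bad = sorted(set(bad.tolist()) | set(piv[rank:].tolist()))
    return [f"x{j - 1}" if j > 0 else "intercept" for j in bad]


def _near_perfect(rss: float, tss: float) -> bool:
    return tss <= 0 or rss <= 1e-12 * max(tss, 1.0)


@dataclass
class RegressionModel:
    """Serialized regression: intercept u0, coefficients u_i by feature name."""

    intercept: float
    coefficients: dict
    selected_features: list
    target: str = "SBP"
    feature_stats: dict = field(default_factory=dict)  # name -> (mean, sd)

    def predict(self, fv) -> float:
        return predict(self, fv)

    def to_json(self, path) -> None:
        doc = {
            "target": self.target,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "selected_features": self.selected_features,
            "feature_stats": self.feature_stats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(intercept=doc["intercept"], coefficients=doc["coefficients"],
                   selected_features=doc["selected_features"], target=doc["target"],
                   feature_stats=doc.get("feature_stats", {}))


@dataclass
class EvalReport:
    """The metric triplet plus a per-subject breakdown."""

    r: float
    mean_error: float
    sd_error: float
    n: int
    r_defined: bool = True
    per_subject: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"r": float(self.r), "mean_error": float(self.mean_error),
                "sd_error": float(self.sd_error), "n": int(self.n),
                "r_defined": bool(self.r_defined)}


@dataclass
class PTTBaseline:
    """Simple regression of BP deviation on PTT deviation."""

    slope: float        # mmHg per ms
    intercept: float    # mmHg
    reference_bp: float
    reference_ptt: float

    def predict_bp(self, ptt) -> np.ndarray:
        ptt = np.asarray(ptt, dtype=float)
        return self.reference_bp + self.intercept + self.slope * (ptt - self.reference_ptt)


class StepwiseLinearRegression(RegressorMixin, BaseEstimator):
    """Linear BP regression with bidirectional stepwise selection.

    Parameters
    ----------
    alpha_in, alpha_out : float
        Entry / exit p-value thresholds for the partial t-tests
        (``alpha_in <= alpha_out`` avoids cycling).
    criterion : {"pvalue", "bic", "none"}
        "pvalue" is the classical stepwise rule; "bic" adds/removes
        whichever single change most improves the BIC; "none" skips
        selection (plain least squares on all candidates).
    feature_names : sequence of str, optional
        Names for the columns of X; defaults to x0..x{p-1}.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,), zeros at unselected features
    support_ : boolean mask of selected columns
    selected_features_ : list of selected names, in selection order
    """

    def __init__(self, alpha_in: float = 0.05, alpha_out: float = 0.10,
                 criterion: str = "pvalue", max_iter: int = 200,
                 feature_names=None):
        self.alpha_in = alpha_in
        self.alpha_out = alpha_out
        self.criterion = criterion
        self.max_iter = max_iter
        self.feature_names = feature_names

    # -- selection rules ---------------------------------------------------
    def _step_pvalue(self, X, y, selected):
        p = X.shape[1]
        changed = False
        remaining = [j for j in range(p) if j not in selected]
        _, _, rss_cur, tss, _ = _ols_fit(X[:, selected], y) if selected else _ols_fit(
            np.empty((len(y), 0)), y)
        if remaining and not _near_perfect(rss_cur, tss):
            best_j, best_p = None, np.inf
            for j in remaining:
                try:
                    _, pv, _, _, _ = _ols_fit(X[:, selected + [j]], y)
                except SingularFitError:
                    continue
                if pv[-1] < best_p:
                    best_j, best_p = j, pv[-1]
            if best_j is not None and best_p < self.alpha_in:
                selected.append(best_j)
                changed = True
        if selected:
            _, pv, _, _, _ = _ols_fit(X[:, selected], y)
            worst = int(np.argmax(pv[1:]))
            if pv[1 + worst] > self.alpha_out:
                del selected[worst]
                changed = True
        return changed

    def _step_bic(self, X, y, selected):
        p = X.shape[1]
        _, _, _, _, bic_cur = _ols_fit(X[:, selected], y)
        best = (None, bic_cur)
        for j in range(p):
            if j in selected:
                cand = [k for k in selected if k != j]
            else:
                cand = selected + [j]
            try:
                _, _, _, _, bic = _ols_fit(X[:, cand], y)
            except SingularFitError:
                continue
            if bic < best[1] - 1e-10:
                best = (cand, bic)
        if best[0] is None:
            return False
        selected[:] = best[0]
        return True

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        names = list(self.feature_names) if self.feature_names is not None else [
            f"x{j}" for j in range(p)]
        if len(names) != p:
            raise InputError(f"{len(names)} feature names for {p} columns")
        if self.criterion == "none":
            selected = list(range(p))
        else:
            selected = []
            seen = set()
            for _ in range(self.max_iter):
                if self.criterion == "pvalue":
                    changed = self._step_pvalue(X, y, selected)
                elif self.criterion == "bic":
                    changed = self._step_bic(X, y, selected)
                else:
                    raise InputError(f"unknown criterion {self.criterion!r}")
                key = tuple(sorted(selected))
                if not changed or key in seen:
                    break
                seen.add(key)
        beta, pvals, rss, tss, bic = _ols_fit(X[:, selected], y)
        self.n_features_in_ = p
        self.feature_names_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = np.zeros(p)
        for bj, j in zip(beta[1:], selected):
            self.coef_[j] = bj
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.selected_idx_ = list(selected)
        self.selected_features_ = [names[j] for j in selected]
        self.pvalues_ = pvals
        self.bic_ = bic
        self.feature_means_ = X.mean(axis=0)
        self.feature_sds_ = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    def to_model(self, target: str = "SBP") -> RegressionModel:
        check_is_fitted(self, "coef_")
        coeffs = {self.feature_names_[j]: float(self.coef_[j]) for j in self.selected_idx_}
        stats_ = {self.feature_names_[j]: (float(self.feature_means_[j]),
                                           float(self.feature_sds_[j]))
                  for j in range(self.n_features_in_)}
        return RegressionModel(intercept=self.intercept_, coefficients=coeffs,
                               selected_features=list(self.selected_features_),
                               target=target, feature_stats=stats_)


class PTTBaselineRegression(RegressorMixin, BaseEstimator):
    """Conventional pulse-transit-time baseline.

    BP variation (deviation from a reference reading) is regressed on
    PTT variation by simple least squares; absolute pressure is
    recovered by adding back the reference.  The reference is the first
    paired (PTT, BP) sample unless given explicitly.
    """

    def __init__(self, reference: tuple | None = None):
        self.reference = reference

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] != 1:
            raise InputError("PTT baseline expects a single PTT column")
        ptt = X[:, 0]
        if len(ptt) < 3:
            raise InputError("need at least 3 paired points")
        if self.reference is None:
            ref_ptt, ref_bp = float(ptt[0]), float(y[0])
        else:
            ref_ptt, ref_bp = map(float, self.reference)
        pttv = ptt - ref_ptt
        bpv = y - ref_bp
        if np.ptp(pttv) == 0:
            raise DegenerateBaselineError("PTT deviations have zero variance")
        res = stats.linregress(pttv, bpv)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.reference_ptt_ = ref_ptt
        self.reference_bp_ = ref_bp
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = check_array(X)
        return (self.reference_bp_ + self.intercept_
                + self.slope_ * (X[:, 0] - self.reference_ptt_))

    def to_baseline(self) -> PTTBaseline:
        check_is_fitted(self, "slope_")
        return PTTBaseline(self.slope_, self.intercept_,
                           self.reference_bp_, self.reference_ptt_)


# ---------------------------------------------------------------------------
# Functional facade

def _frame_to_xy(feature_table, target, feature_names):
    if isinstance(feature_table, pd.DataFrame):
        X = feature_table.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(feature_table, dtype=float)
    y = np.asarray(target, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("missing values in the selected columns")
    return X, y


def fit_ols(feature_table, target, feature_names) -> RegressionModel:
    """Plain least squares on the named columns (no selection)."""
    X, y = _frame_to_xy(feature_table, target, feature_names)
    est = StepwiseLinearRegression(criterion="none",
                                   feature_names=list(feature_names)).fit(X, y)
    return est.to_model()


def stepwise_select(feature_table, target, candidate_features,
                    criteria: dict | None = None) -> RegressionModel:
    """Bidirectional stepwise selection over the candidate features.

    ``criteria`` may override ``alpha_in``, ``alpha_out`` or
    ``criterion`` ("pvalue" or "bic").  An empty candidate list or no
    feature passing entry yields the intercept-only model.
    """
    criteria = dict(criteria or {})
    candidates = list(candidate_features)
    if not candidates:
        y = np.asarray(target, dtype=float)
        return RegressionModel(intercept=float(np.mean(y)), coefficients={},
                               selected_features=[])
    X, y = _frame_to_xy(feature_table, target, candidates)
    est = StepwiseLinearRegression(
        alpha_in=criteria.get("alpha_in", 0.05),
        alpha_out=criteria.get("alpha_out", 0.10),
        criterion=criteria.get("criterion", "pvalue"),
        feature_names=candidates,
    ).fit(X, y)
    return est.to_model()


def predict(model: RegressionModel, fv) -> float:
    """Apply the regression: u0 + sum(u_i * x_i), exact arithmetic."""
    if isinstance(fv, (dict, pd.Series)):
        values = fv
    elif hasattr(fv, "values") and isinstance(fv.values, dict):
        values = fv.values  # FeatureVector
    else:
        values = fv
    y = model.intercept
    for name, coef in model.coefficients.items():
        try:
            x = values[name]
        except (KeyError, IndexError):
            raise MissingFeatureError(name) from None
        y += coef * float(x)
    return float(y)


def fit_ptt_baseline(pttv, bpv) -> PTTBaseline:
    """Simple regression of BP deviations on PTT deviations.

    Deviations are taken from the first paired sample (the reference
    reading), whose PTTV and BPV are therefore zero by construction.
    """
    pttv = np.asarray(pttv, dtype=float)
    bpv = np.asarray(bpv, dtype=float)
    if pttv.size != bpv.size or pttv.size < 3:
        raise InputError("need at least 3 paired deviation points")
    if np.ptp(pttv) == 0:
        raise DegenerateBaselineError("PTT deviations have zero variance")
    res = stats.linregress(pttv, bpv)
    return PTTBaseline(float(res.slope), float(res.intercept), 0.0, 0.0)


def error_metrics(measured, estimated, subject_ids=None) -> EvalReport:
    """r, mean error and SD of errors (estimated - measured)."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise InputError("measured and estimated lengths differ")
    n = measured.size
    if n < 2:
        raise InputError("need at least 2 paired values")
    err = estimated - measured
    mean_error = float(err.mean())
    sd_error = float(err.std(ddof=1))
    r_defined = np.ptp(measured) > 0 and np.ptp(estimated) > 0
    r = float(stats.pearsonr(measured, estimated).statistic) if r_defined else float("nan")
    per_subject = None
    if subject_ids is not None:
        per = pd.DataFrame({"subject_id": subject_ids, "error": err})
        per_subject = per.groupby("subject_id")["error"].agg(
            mean_error="mean", sd_error=lambda e: e.std(ddof=1), n="count").reset_index()
    return EvalReport(r=r, mean_error=mean_error, sd_error=sd_error, n=n,
                      r_defined=r_defined, per_subject=per_subject)


_FITTERS = ("stepwise", "ols", "ptt", "bic")


def _make_estimator(fitter: str, feature_names):
    if fitter == "stepwise":
        return StepwiseLinearRegression(feature_names=list(feature_names))
    if fitter == "bic":
        return StepwiseLinearRegression(criterion="bic", feature_names=list(feature_names))
    if fitter == "ols":
        return StepwiseLinearRegression(criterion="none", feature_names=list(feature_names))
    raise InputError(f"unknown fitter {fitter!r}; expected one of {_FITTERS}")


def loocv(dataset: pd.DataFrame, fitter: str = "stepwise",
          target_col: str = "sbp", candidates=None,
          subject_col: str | None = None) -> EvalReport:
    """Leave-one-out cross-validation of a fitter over the dataset.

    Each sample is predicted by a model fit on the other n-1 samples
    and the pooled predictions are summarized by :func:`error_metrics`.
    ``fitter`` is "stepwise", "bic", "ols" or "ptt"; for "ptt" the
    dataset needs a ``ptt`` column and deviations are taken from the
    first row (the reference reading), which is then excluded from its
    own fold's training deviations but still predicted.
    """
    n = len(dataset)
    if n < 3:
        raise InputError("LOOCV needs at least 3 samples")
    y = dataset[target_col].to_numpy(dtype=float)
    preds = np.empty(n)
    if fitter == "ptt":
        ptt = dataset["ptt"].to_numpy(dtype=float)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                est = PTTBaselineRegression(
                    reference=(ptt[0], y[0])).fit(ptt[mask, None], y[mask])
            except Exception as exc:  # noqa: BLE001 - report names the fold
                raise FoldFitError(i, exc) from exc
            preds[i] = est.predict(ptt[i:i + 1, None])[0]
    else:
        if candidates is None:
            candidates = [c for c in FEATURE_NAMES if c in dataset.columns]
        X = dataset.loc[:, list(candidates)].to_numpy(dtype=float)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                est = _make_estimator(fitter, candidates).fit(X[mask], y[mask])
            except Exception as exc:  # noqa: BLE001
                raise FoldFitError(i, exc) from exc
            preds[i] = est.predict(X[i:i + 1])[0]
    ids = dataset[subject_col].to_numpy() if subject_col else None
    return error_metrics(y, preds, subject_ids=ids)


def ablation_static_features(dataset: pd.DataFrame, fitter: str = "stepwise",
                             target_col: str = "sbp", candidates=None,
                             subject_col: str | None = None):
    """LOOCV with the full candidate set vs. without the questionnaire
    covariates (height, weight, age, sex); returns (full, ablated)."""
    if candidates is None:
        candidates = [c for c in FEATURE_NAMES if c in dataset.columns]
    ablated = [c for c in candidates if c not in STATIC_FEATURES]
    full_report = loocv(dataset, fitter, target_col, candidates, subject_col)
    ablated_report = loocv(dataset, fitter, target_col, ablated, subject_col)
    return full_report, ablated_report
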