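"""Prediction-equivalence experiments: does rescoring lose information?

Cross-validated logistic and random-forest models predict 30-day all-cause
mortality from the original versus rescored GCS sub-scores (entered as
categorical indicators, plus the numeric total; experiment 2 adds age, sex,
ISS and body region as additive effects).  Models are compared on the Brier
score (with an empirical standard error), the logloss, and a Wilcoxon
signed-rank test of per-case squared-error differences, followed by an
individual-level risk-difference analysis at 2.5 / 5 / 10 percentage-point
thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
import statsmodels.api as sm

from .registry import REGIONS, RecordSet
from .rescoring import CollapseMap

__all__ = [
    "PredictionResult",
    "ScoreSummary",
    "make_cv_folds",
    "build_features",
    "fit_logistic",
    "fit_predict_logistic",
    "fit_predict_forest",
    "brier",
    "wilcoxon_signed_rank",
    "risk_difference_analysis",
]

logger = logging.getLogger(__name__)

#: ridge penalty used when plain maximum likelihood is unavailable
#: (separation or a rank-deficient design)
RIDGE_PENALTY = 1e-6


@dataclass(frozen=True)
class PredictionResult:
    """Out-of-fold predicted probabilities: one row per case."""

    frame: pd.DataFrame  # columns: id, fold, p_hat, y
    model: str
    features: str

    def __post_init__(self):
        f = self.frame
        required = {"id", "fold", "p_hat", "y"}
        if not required.issubset(f.columns):
            raise ValueError(f"prediction frame needs columns {sorted(required)}")
        if f["id"].duplicated().any():
            raise ValueError("each case must be predicted exactly once")
        if ((f["p_hat"] < 0) | (f["p_hat"] > 1)).any():
            raise ValueError("predicted probabilities outside [0, 1]")


@dataclass(frozen=True)
class ScoreSummary:
    brier: float
    brier_se: float
    logloss: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def make_cv_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold assignment 0..k-1 with sizes differing by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    return base[rng.permutation(n)]


def build_features(
    rs: RecordSet,
    collapse: CollapseMap | None = None,
    ancillary: bool = False,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix, outcome vector and case ids for the experiments.

    Sub-scores enter as 0/1 category indicators (reference = lowest
    category) plus the numeric total; with ``ancillary`` the model adds age,
    male sex, ISS and region indicators.  Outcomes must be observed
    (apply :func:`~gcsrasch.registry.drop_missing_outcome` upstream).
    """
    from .registry import to_response_matrix

    if (rs.df["outcome"] == "missing").any():
        raise ValueError("missing outcomes present; case-wise delete them first")
    matrix = to_response_matrix(rs, scoring=collapse)
    cols = {}
    names = ("eye", "verbal", "motor")
    for i, name in enumerate(names):
        for cat in range(1, matrix.maxima[i] + 1):
            cols[f"{name}_{cat}"] = (matrix.responses[:, i] == cat).astype(float)
    cols["total"] = matrix.totals.astype(float)
    if ancillary:
        cols["age"] = rs.df["age"].to_numpy(dtype=float)
        cols["male"] = (rs.df["sex"] == "male").to_numpy(dtype=float)
        cols["iss"] = rs.df["iss"].to_numpy(dtype=float)
        for r in REGIONS[1:]:  # first region is the reference level
            cols[f"region_{r}"] = (rs.df["region"] == r).to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    y = (rs.df["outcome"] == "dead").to_numpy(dtype=np.int64)
    ids = rs.df["id"].to_numpy()
    return X, y, ids


def fit_logistic(X, y) -> tuple[np.ndarray, float, bool]:
    """Logistic fit: plain MLE when possible, tiny-ridge fallback otherwise.

    Returns (coefficients, intercept, used_fallback).  The fallback (L2
    penalty ``RIDGE_PENALTY``) covers separation, constant outcomes and
    rank-deficient designs, where the MLE is unbounded or non-unique; the
    fitted probabilities are essentially unaffected.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    design = np.column_stack([np.ones(len(Xa)), Xa])
    full_rank = np.linalg.matrix_rank(design) == design.shape[1]
    if full_rank and 0 < y.mean() < 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False):
                return res.params[1:], float(res.params[0]), False
        except Exception:
            pass
    logger.warning("logistic MLE unavailable (separation or collinearity); "
                   "using ridge fallback with penalty %g", RIDGE_PENALTY)
    model = LogisticRegression(C=1.0 / RIDGE_PENALTY, solver="lbfgs", max_iter=2000)
    if y.mean() in (0.0, 1.0):
        # degenerate training outcome: intercept-only ridge solution
        p = max(min((y.sum() + RIDGE_PENALTY) / (len(y) + 2 * RIDGE_PENALTY), 1 - 1e-9), 1e-9)
        return np.zeros(Xa.shape[1]), float(np.log(p / (1 - p))), True
    model.fit(Xa, y)
    return model.coef_[0], float(model.intercept_[0]), True


def _predict_logistic(coefs, intercept, X) -> np.ndarray:
    lp = np.asarray(X, dtype=float) @ coefs + intercept
    return 1.0 / (1.0 + np.exp(-lp))


def fit_predict_logistic(
    features, y, folds=None, ids=None, *, model_tag="logistic", feature_tag=""
) -> PredictionResult:
    """Per-fold maximum-likelihood logistic fits with out-of-fold predictions.

    With ``folds=None`` a single fit on all cases predicts all cases
    (in-sample; used for closed-form checks rather than experiments).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    p_hat = np.empty(n, dtype=float)
    fold_col = np.zeros(n, dtype=np.int64)
    if folds is None:
        coefs, intercept, _ = fit_logistic(X, y)
        p_hat[:] = _predict_logistic(coefs, intercept, X)
    else:
        folds = np.asarray(folds)
        for f in np.unique(folds):
            train, test = folds != f, folds == f
            coefs, intercept, _ = fit_logistic(X[train], y[train])
            p_hat[test] = _predict_logistic(coefs, intercept, X[test])
            fold_col[test] = f
    frame = pd.DataFrame({"id": ids, "fold": fold_col, "p_hat": p_hat, "y": y})
    return PredictionResult(frame=frame, model=model_tag, features=feature_tag)


def fit_predict_forest(
    features,
    y,
    folds,
    tree_grid=(100, 250, 500, 1000, 2000),
    seed: int = 0,
    *,
    feature_tag="",
) -> PredictionResult:
    """Random-forest out-of-fold predictions with nested tree-count tuning.

    Per outer fold, an inner 3-fold grid search picks the number of trees by
    Brier score; a grid of size one skips the inner search.  Deterministic
    given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    folds = np.asarray(folds)
    tree_grid = tuple(tree_grid)
    p_hat = np.empty(len(y), dtype=float)
    rng = np.random.default_rng(seed)
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        Xtr, ytr = X[train], y[train]
        if len(tree_grid) == 1:
            best = tree_grid[0]
        else:
            inner = make_cv_folds(len(ytr), 3, int(rng.integers(2**31)))
            scores = []
            for n_trees in tree_grid:
                sq = np.empty(len(ytr))
                for g in range(3):
                    itr, ite = inner != g, inner == g
                    rf = RandomForestClassifier(
                        n_estimators=n_trees, random_state=int(rng.integers(2**31))
                    )
                    rf.fit(Xtr[itr], ytr[itr])
                    sq[ite] = (rf.predict_proba(Xtr[ite])[:, -1] - ytr[ite]) ** 2
                scores.append(sq.mean())
            best = tree_grid[int(np.argmin(scores))]
        rf = RandomForestClassifier(
            n_estimators=best, random_state=int(rng.integers(2**31))
        )
        rf.fit(Xtr, ytr)
        proba = rf.predict_proba(X[test])
        p_hat[test] = proba[:, -1] if proba.shape[1] == 2 else float(ytr.mean())
    frame = pd.DataFrame(
        {"id": np.arange(len(y)), "fold": folds, "p_hat": p_hat, "y": y}
    )
    return PredictionResult(frame=frame, model="random_forest", features=feature_tag)


def brier(pred: PredictionResult) -> ScoreSummary:
    """Brier score, its empirical standard error, and logloss.

    The SE is the sample standard deviation of the per-case squared errors
    over sqrt(n); logloss clips probabilities away from {0, 1}.
    """
    p = pred.frame["p_hat"].to_numpy()
    y = pred.frame["y"].to_numpy()
    if p.size == 0:
        raise ValueError("empty prediction result")
    sq = (p - y) ** 2
    se = float(np.std(sq, ddof=1) / np.sqrt(sq.size)) if sq.size > 1 else 0.0
    pc = np.clip(p, 1e-15, 1 - 1e-15)
    ll = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    return ScoreSummary(brier=float(sq.mean()), brier_se=se, logloss=ll)


def wilcoxon_signed_rank(per_case_diffs) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are dropped (Wilcoxon convention) and ties mid-ranked; the exact
    null distribution is used up to n = 25 when the absolute differences are
    tie-free, otherwise the normal approximation with continuity and tie
    corrections.
    """
    d = np.asarray(per_case_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if d.size < 5:
        warnings.warn("fewer than 5 non-zero differences; exact p is coarse")
    tie_free = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and tie_free) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue)


def risk_difference_analysis(
    pred_original: PredictionResult,
    pred_rescored: PredictionResult,
    thresholds=(0.025, 0.05, 0.10),
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Individual-level differences in predicted risk, rescored - original.

    Returns threshold exceedance counts/percentages on |delta|, and (when
    ``covariates`` with id/iss/age/region columns are supplied) long-format
    summaries of the signed differences for the cases beyond the smallest
    threshold, stratified by ISS, 5-year age bin and region.
    """
    a = pred_original.frame.set_index("id")
    b = pred_rescored.frame.set_index("id")
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("prediction results cover different case sets")
    b = b.reindex(a.index)
    delta = (b["p_hat"] - a["p_hat"]).to_numpy()
    n = delta.size
    exceed = {
        t: {
            "count": int((np.abs(delta) > t).sum()),
            "percent": float((np.abs(delta) > t).mean() * 100.0),
        }
        for t in thresholds
    }
    out = {
        "n": n,
        "mean_delta": float(delta.mean()),
        "median_delta": float(np.median(delta)),
        "thresholds": exceed,
    }
    if covariates is not None:
        t0 = min(thresholds)
        cov = covariates.set_index("id").reindex(a.index)
        sub = pd.DataFrame({"delta": delta}, index=a.index)[np.abs(delta) > t0]
        cov = cov.loc[sub.index]
        strata = []
        age_bin = (cov["age"] // 5 * 5).astype(int).astype(str) + "-"
        for var, values in (
            ("iss", cov["iss"].astype(str)),
            ("age_bin", age_bin),
            ("region", cov["region"]),
        ):
            g = sub.groupby(values.rename("stratum"))["delta"]
            s = g.agg(n="size", mean="mean", median="median",
                      q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
            s = s.reset_index()
            s.insert(0, "variable", var)
            strata.append(s)
        out["strata"] = pd.concat(strata, ignore_index=True)
    return out
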