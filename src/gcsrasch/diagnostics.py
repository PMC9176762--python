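"""Rasch fit and reliability diagnostics.

Covers the RUMM-style battery: standardized response residuals, item and
person fit residuals (a Wilson-Hilferty cube-root standardization of the sum
of squared residuals), the item-trait interaction chi-square over
equal-count class intervals, the person separation index (PSI), Cronbach's
alpha, threshold ordering, category probability curves, and the four-sample
analysis design (full non-extreme sample, n=500 subsample, 10% sample with
extremes, and approx. 500 valid cases from the latter).

With only three items the fit statistics are approximate in a structural
way: person locations are estimated from the raw total, so the three item
residuals of a person sum to exactly zero and residual variances are
conditional-on-total rather than conditional-on-theta.  See the methods note
for what this does to the nominal (0, 1) targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import (
    PcmItemParams,
    PersonEstimate,
    ResponseMatrix,
    estimate_persons,
    fit_items_cml,
    pcm_probs_grid,
    score_table,
)

__all__ = [
    "FitReport",
    "ThresholdOrderReport",
    "standardized_residuals",
    "item_fit_residual",
    "person_fit_residual",
    "item_trait_chi_square",
    "psi",
    "cronbach_alpha",
    "threshold_order_report",
    "category_probability_curves",
    "compute_fit_report",
    "run_sample_design",
]


@dataclass(frozen=True)
class FitReport:
    """One row of the summary fit table for a single analysed sample."""

    label: str
    n_valid: int
    n_extreme: int
    item_fit_mean: float
    item_fit_sd: float
    person_fit_mean: float
    person_fit_sd: float
    chi_square: float
    df: int
    p_value: float
    psi_with_extremes: float
    psi_no_extremes: float
    alpha_with_extremes: float
    alpha_no_extremes: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def to_row(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ThresholdOrderReport:
    """Adjacent-pair disorder flags per item: flag k is True iff
    ``delta_k >= delta_{k+1}``."""

    thresholds: tuple[np.ndarray, ...]
    disordered: tuple[tuple[bool, ...], ...]

    @property
    def any_disordered(self) -> bool:
        return any(any(f) for f in self.disordered)


def _theta_se_arrays(persons) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.array([p.theta for p in persons])
    se = np.array([p.se for p in persons])
    extreme = np.array([p.extreme for p in persons], dtype=bool)
    return theta, se, extreme


def standardized_residuals(
    matrix: ResponseMatrix, params: PcmItemParams, persons
) -> np.ndarray:
    """Standardized residuals z = (x - E[X|theta]) / sqrt(Var(X|theta)).

    Only non-extreme persons contribute; extreme rows (if present) are
    filtered out, keeping alignment between matrix rows and person estimates.
    """
    theta, _, extreme = _theta_se_arrays(persons)
    if len(persons) != matrix.n_persons:
        raise ValueError("persons do not align with matrix rows")
    keep = ~extreme
    resp = matrix.responses[keep]
    theta = theta[keep]
    z = np.empty(resp.shape, dtype=float)
    for i, delta in enumerate(params.thresholds):
        p = pcm_probs_grid(theta, delta)
        x = np.arange(p.shape[1])
        mu = p @ x
        var = p @ (x**2) - mu**2
        z[:, i] = (resp[:, i] - mu) / np.sqrt(var)
    return z


def _wilson_hilferty(y: float, nu: int) -> float:
    """Cube-root standardization of a chi-square-like sum against nu d.f."""
    if nu < 2:
        raise ValueError("need at least 2 contributing observations")
    c = 2.0 / (9.0 * nu)
    return ((y / nu) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c)


def item_fit_residual(z_column, nu: int | None = None) -> float:
    """Item fit residual: Wilson-Hilferty transform of the column's sum of
    squared standardized residuals.  Negative values mean less misfit than
    the model expects."""
    z = np.asarray(z_column, dtype=float)
    nu = z.size if nu is None else nu
    return float(_wilson_hilferty(float(np.sum(z**2)), nu))


def person_fit_residual(z_row, nu: int | None = None) -> float:
    """Person fit residual: the same transform across one person's items."""
    return item_fit_residual(z_row, nu)


def item_trait_chi_square(
    matrix: ResponseMatrix,
    persons,
    params: PcmItemParams,
    n_class_intervals: int = 6,
) -> tuple[float, int, float]:
    """Item-trait interaction chi-square over equal-count class intervals.

    Non-extreme persons are ranked by estimated location (ties broken by
    person index, so the cut is deterministic) and split into G equal-count
    intervals.  Each item-by-interval cell contributes
    ``(sum(observed) - sum(expected))^2 / sum(variance)``;
    df = n_items * (G - 1).
    """
    if n_class_intervals < 2:
        raise ValueError("need at least 2 class intervals")
    theta, _, extreme = _theta_se_arrays(persons)
    keep = ~extreme
    resp = matrix.responses[keep]
    theta = theta[keep]
    n = resp.shape[0]
    if n < n_class_intervals:
        raise ValueError("empty class interval: more intervals than persons")
    order = np.argsort(theta, kind="stable")
    groups = np.array_split(order, n_class_intervals)
    chi2 = 0.0
    for i, delta in enumerate(params.thresholds):
        p = pcm_probs_grid(theta, delta)
        x = np.arange(p.shape[1])
        mu = p @ x
        var = p @ (x**2) - mu**2
        obs = resp[:, i].astype(float)
        for g in groups:
            if g.size == 0:
                raise ValueError("empty class interval")
            num = (obs[g].sum() - mu[g].sum()) ** 2
            chi2 += num / var[g].sum()
    df = matrix.n_items * (n_class_intervals - 1)
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p_value


def psi(persons, include_extremes: bool = False) -> float:
    """Person separation index: (Var(theta_hat) - mean(SE^2)) / Var(theta_hat).

    With extremes included, the extrapolated estimates (and their large
    standard errors) enter the computation; the index can be negative when
    the error variance exceeds the observed spread.
    """
    theta, se, extreme = _theta_se_arrays(persons)
    if not include_extremes:
        theta, se = theta[~extreme], se[~extreme]
    if theta.size < 2:
        raise ValueError("need at least 2 persons")
    var = float(np.var(theta, ddof=1))
    if var == 0:
        raise ValueError("zero variance of person estimates")
    return (var - float(np.mean(se**2))) / var


def cronbach_alpha(matrix: ResponseMatrix, include_extremes: bool = True) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    m = matrix if include_extremes else matrix.drop_extremes()
    k = m.n_items
    if k < 2:
        raise ValueError("need at least 2 items")
    item_var = np.var(m.responses, axis=0, ddof=1)
    total_var = np.var(m.totals, ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def threshold_order_report(params: PcmItemParams) -> ThresholdOrderReport:
    flags = tuple(
        tuple(bool(d[k] >= d[k + 1]) for k in range(d.size - 1))
        for d in params.thresholds
    )
    return ThresholdOrderReport(thresholds=params.thresholds, disordered=flags)


def category_probability_curves(
    params: PcmItemParams, theta_grid, item_names=None
) -> pd.DataFrame:
    """Plot-ready long table of category probability curves.

    Columns: item, category, theta, probability, modal (True where the
    category is the most probable response at that grid point).  A category
    that is never modal anywhere on the grid signals disordered thresholds.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("theta grid must be finite")
    names = item_names or [f"item{i}" for i in range(params.n_items)]
    frames = []
    for name, delta in zip(names, params.thresholds):
        p = pcm_probs_grid(grid, delta)
        modal = np.zeros_like(p, dtype=bool)
        modal[np.arange(grid.size), p.argmax(axis=1)] = True
        for x in range(p.shape[1]):
            frames.append(
                pd.DataFrame(
                    {
                        "item": name,
                        "category": x,
                        "theta": grid,
                        "probability": p[:, x],
                        "modal": modal[:, x],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def never_modal_categories(params: PcmItemParams, theta_grid) -> list[list[int]]:
    """Per item, the categories that are not the argmax at any grid point."""
    out = []
    for delta in params.thresholds:
        p = pcm_probs_grid(np.asarray(theta_grid, dtype=float), delta)
        modal = set(np.unique(p.argmax(axis=1)))
        out.append([x for x in range(p.shape[1]) if x not in modal])
    return out


def compute_fit_report(
    matrix: ResponseMatrix,
    G: int = 6,
    label: str = "",
    params: PcmItemParams | None = None,
    eps: float = 0.3,
) -> FitReport:
    """Fit (if needed) and summarise one sample: the full Table-row battery.

    The matrix may contain extreme rows; the fit and the residual statistics
    use non-extreme persons only, while the with-extremes PSI and alpha use
    the extrapolated person estimates and the complete matrix respectively.
    """
    extreme = matrix.extreme_mask
    valid = matrix.subset(~extreme)
    if params is None:
        params = fit_items_cml(valid)
    persons_all = estimate_persons(matrix, params, eps=eps)
    persons_valid = [p for p in persons_all if not p.extreme]

    z = standardized_residuals(valid, params, persons_valid)
    n_valid = valid.n_persons
    item_res = np.array([item_fit_residual(z[:, i], n_valid) for i in range(z.shape[1])])
    person_res = np.array([person_fit_residual(z[v], z.shape[1]) for v in range(n_valid)])
    chi2, df, p = item_trait_chi_square(valid, persons_valid, params, G)

    has_extremes = bool(extreme.any())
    psi_no = psi(persons_valid, include_extremes=False)
    psi_with = psi(persons_all, include_extremes=True) if has_extremes else psi_no
    alpha_no = cronbach_alpha(valid)
    alpha_with = cronbach_alpha(matrix) if has_extremes else alpha_no

    return FitReport(
        label=label,
        n_valid=n_valid,
        n_extreme=int(extreme.sum()),
        item_fit_mean=float(item_res.mean()),
        item_fit_sd=float(item_res.std(ddof=1)),
        person_fit_mean=float(person_res.mean()),
        person_fit_sd=float(person_res.std(ddof=1)),
        chi_square=chi2,
        df=df,
        p_value=p,
        psi_with_extremes=psi_with,
        psi_no_extremes=psi_no,
        alpha_with_extremes=alpha_with,
        alpha_no_extremes=alpha_no,
    )


def run_sample_design(
    matrix: ResponseMatrix, seed: int, G: int = 6
) -> dict[str, FitReport]:
    """The four-sample analysis design on a complete response matrix.

    1. the complete non-extreme sample;
    2. a random n=500 draw from sample 1;
    3. a random 10% sample (floor rule) of the complete matrix, extremes and
       all;
    4. the valid (non-extreme) cases of a random 500-person draw from
       sample 3.

    Deterministic given ``seed``; each sample gets its own fit and report.
    """
    rng = np.random.default_rng(seed)
    extreme = matrix.extreme_mask
    sample1 = matrix.subset(~extreme)
    idx2 = rng.choice(sample1.n_persons, size=min(500, sample1.n_persons), replace=False)
    sample2 = sample1.subset(np.sort(idx2))
    n3 = matrix.n_persons // 10  # exact 10% floor rule
    idx3 = rng.choice(matrix.n_persons, size=n3, replace=False)
    sample3 = matrix.subset(np.sort(idx3))
    # sample 4 targets approx. 500 *valid* cases: the draw from sample 3 is
    # sized by the inverse of sample 3's valid fraction, and its extremes
    # stay in for the with-extremes reliability columns
    valid_frac = float((~sample3.extreme_mask).mean())
    n4 = min(sample3.n_persons, int(round(500 / max(valid_frac, 1e-9))))
    idx4 = rng.choice(sample3.n_persons, size=n4, replace=False)
    sample4_draw = sample3.subset(np.sort(idx4))
    return {
        "sample1": compute_fit_report(sample1, G=G, label="complete non-extreme sample"),
        "sample2": compute_fit_report(sample2, G=G, label="random n=500 from sample 1"),
        "sample3": compute_fit_report(sample3, G=G, label="random 10% of full sample"),
        "sample4": compute_fit_report(
            sample4_draw, G=G, label="approx. n=500 valid cases from sample 3"
        ),
    }
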