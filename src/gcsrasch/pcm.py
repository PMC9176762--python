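"""Partial credit model (PCM) engine.

The PCM is the unrestricted polytomous Rasch model: the probability that a
person with latent location ``theta`` responds in category ``x`` of an item
with thresholds ``delta_1 .. delta_m`` is

    P(X = x | theta) = exp(sum_{k<=x} (theta - delta_k)) / normaliser,

with the empty sum for ``x = 0`` equal to zero.  Item parameters are
estimated by conditional maximum likelihood (CML): conditioning on each
person's raw total score removes the person parameters from the likelihood,
which is then maximised by Newton iteration using elementary symmetric
functions.  Person locations are estimated afterwards by maximum likelihood
given the fitted thresholds; minimum/maximum raw scores carry no information
about the item parameters and receive extrapolated locations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ResponseMatrix",
    "PcmItemParams",
    "PersonEstimate",
    "NullCategoryError",
    "ConvergenceError",
    "pcm_category_probs",
    "pcm_probs_grid",
    "expected_score",
    "score_variance",
    "elementary_symmetric",
    "item_weights",
    "fit_items_cml",
    "estimate_persons",
    "score_table",
]


class NullCategoryError(ValueError):
    """An item category was never observed, so its threshold is inestimable."""

    def __init__(self, item: int, category: int):
        self.item = item
        self.category = category
        super().__init__(
            f"item {item} has no observations in category {category}; "
            "collapse categories before fitting"
        )


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items integer responses, rebased to ``0..m_i`` per item."""

    responses: np.ndarray
    maxima: tuple[int, ...]

    def __post_init__(self):
        resp = np.asarray(self.responses, dtype=np.int64)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "maxima", tuple(int(m) for m in self.maxima))
        if resp.ndim != 2 or resp.shape[1] != len(self.maxima):
            raise ValueError(
                f"responses shape {resp.shape} does not match {len(self.maxima)} items"
            )
        for i, m in enumerate(self.maxima):
            col = resp[:, i]
            if col.size and (col.min() < 0 or col.max() > m):
                raise ValueError(f"item {i} responses outside 0..{m}")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def max_total(self) -> int:
        return sum(self.maxima)

    @property
    def totals(self) -> np.ndarray:
        return self.responses.sum(axis=1)

    @property
    def extreme_mask(self) -> np.ndarray:
        """True for rows at the floor (0) or ceiling (sum of maxima)."""
        t = self.totals
        return (t == 0) | (t == self.max_total)

    def subset(self, rows) -> "ResponseMatrix":
        return ResponseMatrix(self.responses[rows], self.maxima)

    def drop_extremes(self) -> "ResponseMatrix":
        return self.subset(~self.extreme_mask)


@dataclass(frozen=True)
class PcmItemParams:
    """Fitted Andrich thresholds per item, identified by mean item location 0."""

    thresholds: tuple[np.ndarray, ...]
    converged: bool = True
    n_iter: int = 0
    max_grad: float = 0.0

    def __post_init__(self):
        ths = tuple(np.asarray(t, dtype=float) for t in self.thresholds)
        object.__setattr__(self, "thresholds", ths)
        for t in ths:
            if t.size < 1 or not np.all(np.isfinite(t)):
                raise ValueError("each item needs >= 1 finite threshold")

    @property
    def n_items(self) -> int:
        return len(self.thresholds)

    @property
    def maxima(self) -> tuple[int, ...]:
        return tuple(t.size for t in self.thresholds)

    @property
    def locations(self) -> np.ndarray:
        """Item locations: the mean of each item's thresholds."""
        return np.array([t.mean() for t in self.thresholds])

    def to_json(self) -> str:
        return json.dumps(
            {
                "thresholds": [t.tolist() for t in self.thresholds],
                "converged": self.converged,
                "n_iter": self.n_iter,
                "max_grad": self.max_grad,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PcmItemParams":
        d = json.loads(text)
        return cls(
            thresholds=tuple(np.asarray(t, dtype=float) for t in d["thresholds"]),
            converged=d.get("converged", True),
            n_iter=d.get("n_iter", 0),
            max_grad=d.get("max_grad", 0.0),
        )


@dataclass(frozen=True)
class PersonEstimate:
    """ML person location for one raw total score."""

    theta: float
    se: float
    raw_score: int
    extreme: bool


def pcm_category_probs(theta: float, thresholds) -> np.ndarray:
    """Category probabilities (length m+1) of the PCM at a single location."""
    delta = np.asarray(thresholds, dtype=float)
    m = delta.size
    # log unnormalised weight of category x: x*theta - sum_{k<=x} delta_k
    logw = np.concatenate(([0.0], np.arange(1, m + 1) * theta - np.cumsum(delta)))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def pcm_probs_grid(thetas, thresholds) -> np.ndarray:
    """Vectorised ``pcm_category_probs``: rows = locations, cols = categories."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    delta = np.asarray(thresholds, dtype=float)
    m = delta.size
    x = np.arange(m + 1)
    csum = np.concatenate(([0.0], np.cumsum(delta)))
    logw = thetas[:, None] * x[None, :] - csum[None, :]
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def expected_score(theta, thresholds) -> np.ndarray:
    p = pcm_probs_grid(theta, thresholds)
    return p @ np.arange(p.shape[1])


def score_variance(theta, thresholds) -> np.ndarray:
    p = pcm_probs_grid(theta, thresholds)
    x = np.arange(p.shape[1])
    mu = p @ x
    return p @ (x**2) - mu**2


def item_weights(thresholds) -> np.ndarray:
    """Category weights ``w[x] = exp(-sum_{k<=x} delta_k)`` with ``w[0] = 1``."""
    delta = np.asarray(thresholds, dtype=float)
    return np.exp(np.concatenate(([0.0], -np.cumsum(delta))))


def _gamma_all(weights: list[np.ndarray]) -> np.ndarray:
    """Elementary symmetric functions over all items by recursive convolution."""
    g = np.array([1.0])
    for w in weights:
        g = np.convolve(g, np.asarray(w, dtype=float))
    return g


def elementary_symmetric(item_category_weights, r: int | None = None):
    """Elementary symmetric function gamma_r of per-item category weights.

    ``gamma_r`` sums, over all response patterns with total score ``r``, the
    product of the pattern's category weights.  With ``r=None`` the full
    vector ``gamma_0 .. gamma_{sum m_i}`` is returned.
    """
    weights = [np.asarray(w, dtype=float) for w in item_category_weights]
    g = _gamma_all(weights)
    if r is None:
        return g
    if not 0 <= r < g.size:
        raise ValueError(f"total score {r} outside 0..{g.size - 1}")
    return float(g[r])


def _conditional_tables(delta: list[np.ndarray], totals: np.ndarray):
    """Per total score r: item score distributions and pairwise joints given r.

    Returns (probs, joints): probs[r][i] is the vector P(X_i = x | r);
    joints[r][(i, j)] the matrix P(X_i = x, X_j = y | r) for i < j.
    Conditional distributions follow from the elementary symmetric functions
    with one (resp. two) items left out.
    """
    weights = [item_weights(d) for d in delta]
    n_items = len(weights)
    g_all = _gamma_all(weights)
    g_minus = {}
    for i in range(n_items):
        g_minus[i] = _gamma_all([w for j, w in enumerate(weights) if j != i])
    g_minus2 = {}
    for i in range(n_items):
        for j in range(i + 1, n_items):
            g_minus2[(i, j)] = _gamma_all(
                [w for k, w in enumerate(weights) if k not in (i, j)]
            )
    probs, joints = {}, {}
    for r in np.unique(totals):
        r = int(r)
        gr = g_all[r]
        pr = []
        for i, w in enumerate(weights):
            x = np.arange(w.size)
            lo = r - x
            p = np.zeros(w.size)
            ok = (lo >= 0) & (lo < g_minus[i].size)
            p[ok] = w[ok] * g_minus[i][lo[ok]] / gr
            pr.append(p)
        probs[r] = pr
        jr = {}
        for (i, j), g2 in g_minus2.items():
            wi, wj = weights[i], weights[j]
            J = np.zeros((wi.size, wj.size))
            for x in range(wi.size):
                rem = r - x - np.arange(wj.size)
                ok = (rem >= 0) & (rem < g2.size)
                J[x, ok] = wi[x] * wj[ok] * g2[rem[ok]] / gr
            jr[(i, j)] = J
        joints[r] = jr
    return probs, joints


def fit_items_cml(
    matrix: ResponseMatrix,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PcmItemParams:
    """Conditional maximum-likelihood estimation of PCM thresholds.

    Persons with extreme totals are ignored (they contribute nothing to the
    conditional likelihood).  Thresholds are centred so that the mean item
    location is zero, the conventional identification for the PCM.

    Raises
    ------
    NullCategoryError
        if any category of any item is unobserved among non-extreme persons.
    ConvergenceError
        if the Newton iteration does not reach ``tol`` in ``max_iter`` steps.
    """
    valid = matrix.drop_extremes()
    if valid.n_persons == 0:
        raise ValueError("no non-extreme persons to fit")
    n_items = valid.n_items
    maxima = valid.maxima
    for i, m in enumerate(maxima):
        counts = np.bincount(valid.responses[:, i], minlength=m + 1)
        if (counts == 0).any():
            raise NullCategoryError(i, int(np.flatnonzero(counts == 0)[0]))

    totals = valid.totals
    uniq, n_per = np.unique(totals, return_counts=True)
    score_counts = dict(zip(uniq.astype(int), n_per.astype(int)))
    # observed cumulative step counts O[i][k-1] = #{v: x_vi >= k}
    observed = [
        np.array(
            [(valid.responses[:, i] >= k).sum() for k in range(1, maxima[i] + 1)],
            dtype=float,
        )
        for i in range(n_items)
    ]

    delta = [np.zeros(m) for m in maxima]
    sizes = list(maxima)
    offs = np.concatenate(([0], np.cumsum(sizes)))
    n_par = offs[-1]

    def centre(d):
        shift = np.mean([di.mean() for di in d])
        return [di - shift for di in d]

    def nll(d):
        g = _gamma_all([item_weights(di) for di in d])
        val = sum(float(observed[i] @ d[i]) for i in range(n_items))
        val += sum(n * np.log(g[r]) for r, n in score_counts.items())
        return val

    current = nll(delta)
    grad = np.empty(n_par)
    it = 0
    for it in range(1, max_iter + 1):
        probs, joints = _conditional_tables(delta, totals)
        # gradient: observed minus expected cumulative step counts
        grad[:] = 0.0
        H = np.zeros((n_par, n_par))
        exp_steps = [np.zeros(m) for m in maxima]
        for r, n in score_counts.items():
            for i in range(n_items):
                p = probs[r][i]
                # P(X_i >= k | r) for k = 1..m_i
                tail = np.cumsum(p[::-1])[::-1][1:]
                exp_steps[i] += n * tail
                # within-item covariance of step indicators:
                # E[S_k S_l] = P(X >= max(k, l))
                tail_full = np.cumsum(p[::-1])[::-1]
                kk = np.arange(1, maxima[i] + 1)
                joint_ii = tail_full[np.maximum.outer(kk, kk)]
                cov = joint_ii - np.outer(tail, tail)
                sl = slice(offs[i], offs[i + 1])
                H[sl, sl] += n * cov
            for i in range(n_items):
                for j in range(i + 1, n_items):
                    J = joints[r][(i, j)]
                    # P(X_i >= k, X_j >= l | r): reverse 2-D cumulative sum
                    T = np.cumsum(np.cumsum(J[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
                    T = T[1:, 1:]
                    ti = np.cumsum(probs[r][i][::-1])[::-1][1:]
                    tj = np.cumsum(probs[r][j][::-1])[::-1][1:]
                    cov = T - np.outer(ti, tj)
                    H[offs[i] : offs[i + 1], offs[j] : offs[j + 1]] += n * cov
                    H[offs[j] : offs[j + 1], offs[i] : offs[i + 1]] += n * cov.T
        for i in range(n_items):
            grad[offs[i] : offs[i + 1]] = observed[i] - exp_steps[i]

        if np.max(np.abs(grad)) < tol:
            break
        # H is singular along the all-ones direction (overall location);
        # the pseudo-inverse step stays orthogonal to it.
        step = np.linalg.pinv(H, rcond=1e-12) @ grad
        scale = 1.0
        stalled = False
        for _ in range(40):
            trial = [
                delta[i] - scale * step[offs[i] : offs[i + 1]] for i in range(n_items)
            ]
            trial = centre(trial)
            t_nll = nll(trial)
            if t_nll <= current + 1e-10 * max(1.0, abs(current)):
                delta, current = trial, t_nll
                break
            scale /= 2.0
        else:
            stalled = True
        if stalled:
            # objective improvement below float precision: accept if the
            # gradient is already negligible for practical purposes
            if np.max(np.abs(grad)) < 1e-5:
                break
            raise ConvergenceError(f"line search failed; |grad|={np.abs(grad).max()}")
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; max |grad| = {np.abs(grad).max():.3g}"
        )

    delta = centre(delta)
    return PcmItemParams(
        thresholds=tuple(delta),
        converged=True,
        n_iter=it,
        max_grad=float(np.abs(grad).max()),
    )


def _solve_theta(params: PcmItemParams, target: float) -> float:
    def f(th):
        return sum(float(expected_score(th, d)[0]) for d in params.thresholds) - target

    return brentq(f, -50.0, 50.0, xtol=1e-10)


def score_table(params: PcmItemParams, eps: float = 0.3) -> dict[int, PersonEstimate]:
    """ML person estimate for every possible raw total score.

    Extreme scores (0 and the maximum) have no finite ML estimate; they are
    extrapolated by solving for an effective score ``eps`` inside the range
    (``r=0 -> eps``, ``r=max -> max-eps``) and flagged.
    """
    max_total = sum(params.maxima)
    table = {}
    for r in range(max_total + 1):
        extreme = r in (0, max_total)
        target = float(np.clip(r, eps, max_total - eps))
        theta = _solve_theta(params, target)
        info = sum(float(score_variance(theta, d)[0]) for d in params.thresholds)
        table[r] = PersonEstimate(
            theta=theta, se=1.0 / np.sqrt(info), raw_score=r, extreme=extreme
        )
    return table


def estimate_persons(
    matrix: ResponseMatrix, params: PcmItemParams, eps: float = 0.3
) -> list[PersonEstimate]:
    """Per-person ML location estimates (extremes extrapolated, see score_table)."""
    table = score_table(params, eps=eps)
    return [table[int(r)] for r in matrix.totals]
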