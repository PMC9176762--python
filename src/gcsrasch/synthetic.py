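"""Synthetic trauma-registry generator and model-based PCM simulator.

The registry-mimic fixture reproduces the printed cohort constants of the
emulated national trauma registry exactly where they are counts (exclusion
arithmetic, GCS sub-score marginals, extreme-pattern allocations) and in
expectation where they are rates (sex split, mortality, ISS quartiles).  The
joint Eye x Verbal x Motor table is constructed, not sampled: the two
extreme cells are fixed, the non-extreme mass is filled by iterative
proportional fitting (IPF) on the residual marginals with the extreme cells
as structural zeros, and the continuous fit is integer-rounded by a
largest-remainder scheme that preserves all three marginals exactly.

The PCM simulator draws responses from the partial credit model at sampled
person locations; it backs the parameter-recovery and null-calibration
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pcm import ResponseMatrix, pcm_probs_grid
from .registry import REGIONS, RecordSet
from .rescoring import published_rescore_map

__all__ = [
    "JointGcsTable",
    "GeneratorConfig",
    "PcmSimConfig",
    "InfeasibleTableError",
    "build_joint_gcs_table",
    "generate_registry",
    "calibrate_mortality_intercept",
    "simulate_pcm",
]

#: complete-sample GCS sub-score marginals (categories 1..m per item)
DEFAULT_MARGINALS = {
    "eye": (16347, 2844, 12122, 289890),
    "verbal": (15622, 6359, 3813, 26261, 269148),
    "motor": (11072, 1579, 1626, 3332, 10950, 292644),
}


class InfeasibleTableError(ValueError):
    """The requested extreme allocations are incompatible with the marginals."""


@dataclass(frozen=True)
class JointGcsTable:
    """4x5x6 joint count table over (Eye, Verbal, Motor) categories."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (4, 5, 6) or (c < 0).any():
            raise ValueError("counts must be a non-negative 4x5x6 array")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def marginals(self) -> dict[str, np.ndarray]:
        return {
            "eye": self.counts.sum(axis=(1, 2)),
            "verbal": self.counts.sum(axis=(0, 2)),
            "motor": self.counts.sum(axis=(0, 1)),
        }

    @property
    def n_extreme(self) -> int:
        return int(self.counts[0, 0, 0] + self.counts[3, 4, 5])

    @property
    def n_non_extreme(self) -> int:
        return self.total - self.n_extreme


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition constants of the registry-mimic fixture.

    Count fields are exact targets; rate fields are expectations.  The
    mortality model is logistic in the rescored GCS total with additive
    region offsets; its intercept is calibrated at generation time so the
    expected mortality over the complete adult sample hits
    ``target_mortality``.
    """

    n_total: int = 364_355
    n_paediatric: int = 22_051
    n_incomplete: int = 21_101
    gcs_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    extreme3_count: int = 8_000
    extreme15_count: int = 264_786
    sex_male_prob: float = 0.559
    age_quantile_knots: tuple = (
        (0.0, 18.0),
        (0.25, 44.2),
        (0.5, 62.7),
        (0.75, 80.8),
        (1.0, 100.0),
    )
    iss_distribution: dict = field(
        default_factory=lambda: {
            4: 0.15, 9: 0.40, 13: 0.10, 17: 0.15,
            22: 0.10, 25: 0.05, 29: 0.03, 34: 0.02,
        }
    )
    region_probabilities: dict = field(
        default_factory=lambda: {
            "Head": 0.25, "Limbs": 0.30, "Chest": 0.18, "Spine": 0.08,
            "Abdomen": 0.05, "Multiple": 0.08, "Other": 0.04, "Face": 0.02,
        }
    )
    mortality_slope: float = -0.45
    region_offsets: dict = field(default_factory=lambda: {"Head": 0.5})
    target_mortality: float = 0.066
    missing_outcome_rate: float = 0.0465
    seed: int = 0

    @property
    def n_complete_adult(self) -> int:
        return self.n_total - self.n_paediatric - self.n_incomplete

    def validate(self) -> None:
        marg = {k: np.asarray(v, dtype=np.int64) for k, v in self.gcs_marginals.items()}
        sums = {k: int(v.sum()) for k, v in marg.items()}
        if len(set(sums.values())) != 1:
            raise InfeasibleTableError(f"marginal sums differ across items: {sums}")
        if sums["eye"] != self.n_complete_adult:
            raise InfeasibleTableError(
                f"marginal total {sums['eye']} != complete adults {self.n_complete_adult}"
            )
        if not np.isclose(sum(self.iss_distribution.values()), 1.0):
            raise ValueError("ISS probabilities must sum to 1")
        if not np.isclose(sum(self.region_probabilities.values()), 1.0):
            raise ValueError("region probabilities must sum to 1")
        _check_extreme_feasibility(marg, self.extreme3_count, self.extreme15_count)

    def scaled(self, fraction: float, seed: int | None = None) -> "GeneratorConfig":
        """A consistent down-scaled fixture for fast experiments.

        Counts are scaled by ``fraction`` with largest-remainder rounding so
        every marginal still sums to the scaled complete-adult count and the
        extreme allocations remain feasible; rates are untouched.
        """
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n_pa = round(self.n_paediatric * fraction)
        n_inc = round(self.n_incomplete * fraction)
        n_complete = round(self.n_complete_adult * fraction)
        marg = {
            k: tuple(_scale_counts(np.asarray(v), n_complete))
            for k, v in self.gcs_marginals.items()
        }
        a = round(self.extreme3_count * fraction)
        ne = round(
            (self.n_complete_adult - self.extreme3_count - self.extreme15_count)
            * fraction
        )
        b = n_complete - a - ne
        cfg = replace(
            self,
            n_total=n_pa + n_inc + n_complete,
            n_paediatric=n_pa,
            n_incomplete=n_inc,
            gcs_marginals=marg,
            extreme3_count=a,
            extreme15_count=b,
            seed=self.seed if seed is None else seed,
        )
        cfg.validate()
        return cfg


def _scale_counts(counts: np.ndarray, target_total: int) -> np.ndarray:
    """Scale an integer vector to a new total by largest remainder."""
    raw = counts * (target_total / counts.sum())
    out = np.floor(raw).astype(np.int64)
    short = target_total - out.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    out[order[:short]] += 1
    return out


def _check_extreme_feasibility(marg, a: int, b: int) -> None:
    mins = {k: int(v[0]) for k, v in marg.items()}
    maxs = {k: int(v[-1]) for k, v in marg.items()}
    for k, v in mins.items():
        if a > v:
            raise InfeasibleTableError(
                f"extreme-3 count {a} exceeds the {k} category-1 marginal {v}"
            )
    for k, v in maxs.items():
        if b > v:
            raise InfeasibleTableError(
                f"extreme-15 count {b} exceeds the {k} top-category marginal {v}"
            )
    if a < 0 or b < 0:
        raise InfeasibleTableError("extreme counts must be non-negative")


def _ipf(seed_table: np.ndarray, targets: list[np.ndarray], tol=1e-9, max_iter=2000):
    X = seed_table.copy()
    axes = [(1, 2), (0, 2), (0, 1)]
    for _ in range(max_iter):
        for ax, t in zip(axes, targets):
            s = X.sum(axis=ax)
            ratio = np.divide(t, s, out=np.ones_like(t, dtype=float), where=s > 0)
            X *= ratio.reshape([-1 if i not in ax else 1 for i in range(3)])
        dev = max(
            np.abs(X.sum(axis=ax) - t).max() for ax, t in zip(axes, targets)
        )
        if dev < tol:
            break
    return X


def _round_preserving_marginals(X, targets, forbidden):
    """Largest-remainder integer rounding that keeps all three axial
    marginals exact.

    Floors every cell, then places the remaining units one at a time into the
    feasible cell (positive deficit on all three axes, not a structural zero)
    with the largest fractional remainder.  If the only remaining signature
    is a forbidden cell, a three-cell exchange reroutes the unit without
    disturbing any exact marginal.
    """
    F = np.floor(X).astype(np.int64)
    R = X - F
    T = F.copy()
    axes = [(1, 2), (0, 2), (0, 1)]
    deficits = [t - T.sum(axis=ax) for ax, t in zip(axes, targets)]
    n_units = int(deficits[0].sum())
    assert all(int(d.sum()) == n_units for d in deficits)
    shape = X.shape
    flat_order = np.argsort(-R.ravel(), kind="stable")
    for _ in range(n_units):
        placed = False
        for f in flat_order:
            i, j, k = np.unravel_index(f, shape)
            if (i, j, k) in forbidden:
                continue
            if deficits[0][i] > 0 and deficits[1][j] > 0 and deficits[2][k] > 0:
                T[i, j, k] += 1
                deficits[0][i] -= 1
                deficits[1][j] -= 1
                deficits[2][k] -= 1
                placed = True
                break
        if not placed:
            # forced signature is a forbidden cell: 3-cell exchange
            i = int(np.argmax(deficits[0]))
            j = int(np.argmax(deficits[1]))
            k = int(np.argmax(deficits[2]))
            done = False
            for i2 in range(shape[0]):
                for j2 in range(shape[1]):
                    for k2 in range(shape[2]):
                        if k2 == k or T[i2, j2, k2] < 1:
                            continue
                        if (i, j, k2) in forbidden or (i2, j2, k) in forbidden:
                            continue
                        T[i, j, k2] += 1
                        T[i2, j2, k] += 1
                        T[i2, j2, k2] -= 1
                        deficits[0][i] -= 1
                        deficits[1][j] -= 1
                        deficits[2][k] -= 1
                        done = True
                        break
                    if done:
                        break
                if done:
                    break
            if not done:  # pragma: no cover - no donor cell available
                raise InfeasibleTableError("integer rounding could not be repaired")
    return T


def build_joint_gcs_table(marginals, a: int, b: int) -> JointGcsTable:
    """Construct the joint (Eye, Verbal, Motor) table from its marginals.

    ``a`` is the count of the all-minimum pattern (GCS 3) fixed at cell
    (1,1,1); ``b`` the all-maximum pattern (GCS 15) at (4,5,6).  The
    remaining mass is IPF-fitted to the residual marginals with those two
    cells as structural zeros, then integer-rounded preserving every
    marginal exactly.
    """
    marg = {k: np.asarray(marginals[k], dtype=np.int64) for k in ("eye", "verbal", "motor")}
    if len({int(v.sum()) for v in marg.values()}) != 1:
        raise InfeasibleTableError("marginal sums differ across items")
    _check_extreme_feasibility(marg, a, b)
    residual = {k: v.astype(float).copy() for k, v in marg.items()}
    for k in residual:
        residual[k][0] -= a
        residual[k][-1] -= b
        if (residual[k] < 0).any():
            raise InfeasibleTableError(
                f"extreme allocations exceed the {k} marginal at an end category"
            )
    ne = residual["eye"].sum()
    targets = [residual["eye"], residual["verbal"], residual["motor"]]
    forbidden = {(0, 0, 0), (3, 4, 5)}
    if ne > 0:
        seed = np.einsum("i,j,k->ijk", *targets) / ne**2
        for cell in forbidden:
            seed[cell] = 0.0
        X = _ipf(seed, targets)
        T = _round_preserving_marginals(X, [t.astype(np.int64) for t in targets], forbidden)
    else:
        T = np.zeros((4, 5, 6), dtype=np.int64)
    T[0, 0, 0] = a
    T[3, 4, 5] = b
    table = JointGcsTable(T)
    got = table.marginals
    for k in marg:
        if not np.array_equal(got[k], marg[k]):  # pragma: no cover - invariant
            raise InfeasibleTableError(f"rounded table violates the {k} marginal")
    return table


def calibrate_mortality_intercept(
    cfg: GeneratorConfig,
    linear_predictor: np.ndarray,
    tol: float = 1e-6,
) -> float:
    """Intercept b0 such that mean(logistic(b0 + lp)) = target_mortality.

    Bisection on [-20, 20]; the expected-mortality curve is strictly
    increasing in b0, so the root is unique when reachable.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    target = cfg.target_mortality

    def mean_p(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lp)))))

    lo, hi = -20.0, 20.0
    if not mean_p(lo) <= target <= mean_p(hi):
        raise ValueError(f"target mortality {target} unreachable in [-20, 20]")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    if abs(mean_p(b0) - target) > tol:  # pragma: no cover - bisection guard
        raise ValueError("calibration failed to reach the target rate")
    return b0


def _sample_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(probs.size, size=n, p=probs / probs.sum())


def _piecewise_quantile(u: np.ndarray, knots) -> np.ndarray:
    ps = np.array([p for p, _ in knots])
    qs = np.array([q for _, q in knots])
    return np.interp(u, ps, qs)


def generate_registry(cfg: GeneratorConfig) -> RecordSet:
    """Generate the registry-mimic fixture.

    Complete adults realise the joint GCS table cell counts exactly (the
    rows are allocated, not sampled); paediatric and incomplete-GCS records
    are added so the exclusion arithmetic matches the configured counts.
    Mortality follows a logistic model in the rescored GCS total with region
    offsets, with the intercept calibrated to the target rate over the
    complete adult sample.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    table = build_joint_gcs_table(cfg.gcs_marginals, cfg.extreme3_count, cfg.extreme15_count)

    # --- complete adult GCS rows: exact allocation, then shuffled
    cells = np.repeat(np.arange(table.counts.size), table.counts.ravel())
    e_idx, v_idx, m_idx = np.unravel_index(cells, table.counts.shape)
    perm = rng.permutation(cells.size)
    gcs_complete = np.column_stack([e_idx, v_idx, m_idx])[perm] + 1

    # --- paediatric and incomplete-adult GCS: independent draws from marginals
    marg = {k: np.asarray(v, dtype=float) for k, v in cfg.gcs_marginals.items()}

    def draw_gcs(n):
        return np.column_stack(
            [
                _sample_categorical(rng, marg["eye"], n) + 1,
                _sample_categorical(rng, marg["verbal"], n) + 1,
                _sample_categorical(rng, marg["motor"], n) + 1,
            ]
        )

    gcs_paed = draw_gcs(cfg.n_paediatric)
    gcs_inc = draw_gcs(cfg.n_incomplete)
    # blank a uniformly chosen non-empty subset of the three sub-scores
    blank_patterns = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
    )
    blank = blank_patterns[rng.integers(0, 7, size=cfg.n_incomplete)]

    n = cfg.n_total
    n_adult = n - cfg.n_paediatric
    gcs_underlying = np.vstack([gcs_paed, gcs_inc, gcs_complete])

    # --- ages: paediatric uniform on [0, 18); adults from the quantile knots
    age = np.empty(n)
    age[: cfg.n_paediatric] = rng.uniform(0.0, 17.95, size=cfg.n_paediatric)
    age[cfg.n_paediatric :] = _piecewise_quantile(
        rng.uniform(size=n_adult), cfg.age_quantile_knots
    )
    age = np.round(age, 1)

    sex = np.where(rng.uniform(size=n) < cfg.sex_male_prob, "male", "female")
    iss_vals = np.array(sorted(cfg.iss_distribution))
    iss_probs = np.array([cfg.iss_distribution[v] for v in iss_vals])
    iss = iss_vals[_sample_categorical(rng, iss_probs, n)]
    region_names = [r for r in REGIONS if r in cfg.region_probabilities]
    region_probs = np.array([cfg.region_probabilities[r] for r in region_names])
    region = np.array(region_names)[_sample_categorical(rng, region_probs, n)]

    # --- mortality: logistic in the rescored total, intercept calibrated on
    # the complete adult covariates
    cmap = published_rescore_map()
    rescored = sum(
        cmap.maps[i][gcs_underlying[:, i] - 1] for i in range(3)
    )
    offsets = np.array([cfg.region_offsets.get(r, 0.0) for r in region])
    lp = cfg.mortality_slope * rescored + offsets
    beta0 = calibrate_mortality_intercept(cfg, lp[cfg.n_paediatric + cfg.n_incomplete :])
    p_dead = 1.0 / (1.0 + np.exp(-(beta0 + lp)))
    dead = rng.uniform(size=n) < p_dead
    missing = rng.uniform(size=n) < cfg.missing_outcome_rate
    outcome = np.where(missing, "missing", np.where(dead, "dead", "alive"))

    eye = gcs_underlying[:, 0].astype(float)
    verbal = gcs_underlying[:, 1].astype(float)
    motor = gcs_underlying[:, 2].astype(float)
    inc_sl = slice(cfg.n_paediatric, cfg.n_paediatric + cfg.n_incomplete)
    eye[inc_sl] = np.where(blank[:, 0] == 1, np.nan, eye[inc_sl])
    verbal[inc_sl] = np.where(blank[:, 1] == 1, np.nan, verbal[inc_sl])
    motor[inc_sl] = np.where(blank[:, 2] == 1, np.nan, motor[inc_sl])

    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "id": [f"R{i:07d}" for i in range(n)],
            "age": age[order],
            "sex": sex[order],
            "iss": iss[order].astype("int64"),
            "region": region[order],
            "eye": pd.Series(eye[order]).astype("Int64"),
            "verbal": pd.Series(verbal[order]).astype("Int64"),
            "motor": pd.Series(motor[order]).astype("Int64"),
            "outcome": outcome[order],
        }
    )
    return RecordSet(df, provenance=f"gcsrasch synthetic registry (seed={cfg.seed})")


@dataclass(frozen=True)
class PcmSimConfig:
    """Model-based simulation settings: PCM thresholds and a normal person
    distribution."""

    item_thresholds: tuple
    person_mean: float = 0.0
    person_sd: float = 1.0
    n_persons: int = 500
    seed: int = 0

    def __post_init__(self):
        ths = tuple(np.asarray(t, dtype=float) for t in self.item_thresholds)
        object.__setattr__(self, "item_thresholds", ths)
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for t in ths:
            if t.size < 1:
                raise ValueError("each item needs >= 1 threshold")


def simulate_pcm(cfg: PcmSimConfig) -> ResponseMatrix:
    """Draw PCM responses at person locations sampled from N(mean, sd^2)."""
    rng = np.random.default_rng(cfg.seed)
    theta = rng.normal(cfg.person_mean, cfg.person_sd, size=cfg.n_persons)
    cols = []
    for delta in cfg.item_thresholds:
        p = pcm_probs_grid(theta, delta)
        u = rng.uniform(size=cfg.n_persons)
        cols.append((p.cumsum(axis=1) < u[:, None]).sum(axis=1))
    responses = np.column_stack(cols)
    return ResponseMatrix(responses, tuple(t.size for t in cfg.item_thresholds))
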