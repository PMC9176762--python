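"""Category-collapse engine for repairing disordered thresholds.

When a response category is never the most probable response at any level of
the latent trait, its Andrich thresholds are disordered and adjacent
categories can be collapsed into one.  This module holds the published GCS
rescore map (reconstructed from the rescored threshold wording: merged eye
2+3 "opening eyes to stimulus", merged verbal 3+4 "confused or inappropriate
words", merged motor 2-4 "any movement other than localizing"), a candidate
enumerator for the sensitivity analysis, and a before/after comparison that
refits and ranks each candidate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .pcm import NullCategoryError, ResponseMatrix, fit_items_cml, estimate_persons

__all__ = [
    "CollapseMap",
    "identity_map",
    "published_rescore_map",
    "apply_collapse",
    "enumerate_collapse_candidates",
    "candidate_collapse_maps",
    "compare_rescorings",
    "RescoreComparison",
]

_ITEM_NAMES = ("eye", "verbal", "motor")


@dataclass(frozen=True)
class CollapseMap:
    """Per-item surjective, order-preserving recode of 0-based categories.

    ``maps[i][x]`` is the new category of original (rebased) category ``x``.
    """

    maps: tuple[np.ndarray, ...]
    item_names: tuple[str, ...] = _ITEM_NAMES

    def __post_init__(self):
        arrs = tuple(np.asarray(m, dtype=np.int64) for m in self.maps)
        object.__setattr__(self, "maps", arrs)
        if len(arrs) != len(self.item_names):
            raise ValueError("one map per item required")
        for name, arr in zip(self.item_names, arrs):
            if arr[0] != 0:
                raise ValueError(f"{name}: map must start at 0")
            d = np.diff(arr)
            if ((d < 0) | (d > 1)).any():
                raise ValueError(f"{name}: map must be non-decreasing in unit steps")

    @property
    def new_maxima(self) -> tuple[int, ...]:
        return tuple(int(m[-1]) for m in self.maps)

    @property
    def n_merges(self) -> int:
        """Number of adjacent-category merges across all items."""
        return sum(len(m) - 1 - int(m[-1]) for m in self.maps)

    def to_json(self) -> str:
        return json.dumps({n: m.tolist() for n, m in zip(self.item_names, self.maps)})

    @classmethod
    def from_json(cls, text: str) -> "CollapseMap":
        d = json.loads(text)
        names = tuple(d.keys())
        return cls(maps=tuple(np.asarray(d[n]) for n in names), item_names=names)


def identity_map(maxima, item_names=None) -> CollapseMap:
    maxima = tuple(maxima)
    if item_names is None:
        item_names = _ITEM_NAMES if len(maxima) == 3 else tuple(
            f"item{i}" for i in range(len(maxima))
        )
    return CollapseMap(
        maps=tuple(np.arange(m + 1) for m in maxima), item_names=tuple(item_names)
    )


def published_rescore_map() -> CollapseMap:
    """The published GCS collapse: Eye 4->3, Verbal 5->4, Motor 6->4 categories.

    In original 1-based categories: Eye {2,3} merge; Verbal {3,4} merge
    ("confused or inappropriate words"); Motor {2,3,4} merge ("any movement
    other than localizing").  Rescored totals range 0-8.
    """
    return CollapseMap(
        maps=(
            np.array([0, 1, 1, 2]),
            np.array([0, 1, 2, 2, 3]),
            np.array([0, 1, 1, 1, 2, 3]),
        )
    )


def apply_collapse(matrix: ResponseMatrix, cmap: CollapseMap) -> ResponseMatrix:
    """Element-wise recode of a response matrix; new maxima from the map."""
    if len(cmap.maps) != matrix.n_items:
        raise ValueError("map does not cover the matrix items")
    cols = []
    for i, m in enumerate(cmap.maps):
        if matrix.maxima[i] > len(m) - 1:
            raise ValueError(
                f"item {i}: categories up to {matrix.maxima[i]} outside map domain"
            )
        cols.append(m[matrix.responses[:, i]])
    return ResponseMatrix(np.column_stack(cols), cmap.new_maxima)


def _map_from_merged(m: int, merged: frozenset[int]) -> np.ndarray:
    """Build a recode for categories 0..m removing the boundaries in ``merged``.

    Boundary ``k`` (1..m) separates categories k-1 and k; removing it merges
    them.
    """
    out = np.zeros(m + 1, dtype=np.int64)
    for k in range(1, m + 1):
        out[k] = out[k - 1] + (0 if k in merged else 1)
    return out


def enumerate_collapse_candidates(
    item_max: int, disorder_flags, max_collapses: int
) -> list[np.ndarray]:
    """All adjacent-merge recodes for one item that touch a disordered pair.

    ``disorder_flags[k-1]`` refers to the adjacent threshold pair
    ``(delta_k, delta_{k+1})``; a candidate must remove at least one of the
    two boundaries forming a disordered pair, and at most ``max_collapses``
    boundaries overall.  Deterministic order: fewer merges first, then
    lexicographic by merged boundary set.
    """
    flags = list(disorder_flags)
    if len(flags) != item_max - 1:
        raise ValueError("need one flag per adjacent threshold pair")
    touched = set()
    for k, bad in enumerate(flags, start=1):
        if bad:
            touched.update((k, k + 1))
    if not touched:
        return []
    out = []
    boundaries = range(1, item_max + 1)
    for size in range(1, min(max_collapses, item_max - 1) + 1):
        for combo in itertools.combinations(boundaries, size):
            if touched.intersection(combo):
                out.append(_map_from_merged(item_max, frozenset(combo)))
    return out


def candidate_collapse_maps(
    maxima, order_report, max_collapses: int, limit: int | None = 200
) -> list[CollapseMap]:
    """Cross-product of per-item candidates (identity allowed for clean items).

    Items with no disordered pair keep their identity recode; at least one
    item must be collapsed.  ``limit`` caps the deterministic enumeration.
    """
    per_item = []
    for i, m in enumerate(maxima):
        flags = order_report.disordered[i]
        cands = [np.arange(m + 1)]
        cands += enumerate_collapse_candidates(m, flags, max_collapses)
        per_item.append(cands)
    maps = []
    for combo in itertools.product(*per_item):
        cm = CollapseMap(maps=tuple(combo))
        if cm.n_merges == 0:
            continue
        maps.append(cm)
        if limit is not None and len(maps) >= limit:
            break
    return maps


@dataclass(frozen=True)
class RescoreComparison:
    """One candidate's refit diagnostics within a comparison run."""

    cmap: CollapseMap
    report: object  # FitReport, or None when the candidate is inestimable
    disorder_free: bool
    error: str | None = None


def compare_rescorings(
    matrix: ResponseMatrix, maps, G: int = 6, seed: int = 0
) -> list[RescoreComparison]:
    """Refit and rank candidate collapse maps.

    Ranking: disorder-free candidates first, then smaller item-trait
    chi-square, then larger PSI (extremes excluded); ties broken by fewer
    merges.  Candidates that still leave a null category are ranked last with
    the error recorded — collapsing is the remedy, so such inputs are legal.
    """
    from .diagnostics import compute_fit_report, threshold_order_report

    results = []
    for cmap in maps:
        collapsed = apply_collapse(matrix, cmap)
        try:
            params = fit_items_cml(collapsed)
            order = threshold_order_report(params)
            report = compute_fit_report(collapsed, G=G, params=params)
            results.append(
                RescoreComparison(
                    cmap=cmap,
                    report=report,
                    disorder_free=not order.any_disordered,
                )
            )
        except (NullCategoryError, ValueError) as err:
            results.append(
                RescoreComparison(cmap=cmap, report=None, disorder_free=False, error=str(err))
            )

    def key(rc: RescoreComparison):
        if rc.report is None:
            return (2, np.inf, np.inf, rc.cmap.n_merges)
        return (
            0 if rc.disorder_free else 1,
            rc.report.chi_square,
            -rc.report.psi_no_extremes,
            rc.cmap.n_merges,
        )

    return sorted(results, key=key)
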