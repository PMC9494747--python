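"""Priority vectors and consistency screening for pairwise comparison matrices.

A judge's reciprocal ratio matrix A (a_ij = importance of item i relative to
item j) is condensed into a priority vector w — here the normalized principal
right eigenvector, computed by power iteration.  Internal contradiction in
the judgments is measured by Saaty's consistency index CI = (λmax − n)/(n − 1)
and consistency ratio CR = CI / RI(n), with RI the mean CI of random matrices
of the same order.  The survey screening rule applied by the pipeline is:
CR ≤ 10% acceptable, 10% < CR ≤ 30% flagged for review, CR > 30% excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .protocol import PairwiseComparisonMatrix, SurveyBundle

__all__ = [
    "RANDOM_INDEX",
    "CR_REVIEW_THRESHOLD",
    "CR_EXCLUDE_THRESHOLD",
    "PriorityVector",
    "ConsistencyReport",
    "NonConvergenceError",
    "UnsupportedOrderError",
    "priority_vector",
    "row_geometric_mean",
    "consistency",
    "classify_cr",
    "aggregate_pcms",
    "aggregate_priorities",
    "screen_modelers",
]

#: Saaty's random consistency index for matrix orders 1..15.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

CR_REVIEW_THRESHOLD = 0.10
CR_EXCLUDE_THRESHOLD = 0.30


class NonConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration cap."""


class UnsupportedOrderError(ValueError):
    """Matrix order outside the tabulated random-index range."""


@dataclass(frozen=True)
class PriorityVector:
    """Normalized priority weights of one comparison matrix."""

    items: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        w = np.asarray(self.weights, dtype=float).copy()
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.items), name="weight")


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics of one comparison matrix."""

    ci: float
    cr: float
    flag: str  # "ok" | "review" | "exclude"
    lambda_max: float
    n: int


def priority_vector(
    pcm: PairwiseComparisonMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PriorityVector:
    """Principal-eigenvector priorities of a reciprocal comparison matrix.

    Power iteration from the uniform vector; by Perron-Frobenius the limit is
    the unique positive eigenvector (all entries of A are positive), so the
    result is deterministic for a fixed matrix.
    """
    a = pcm.values
    n = pcm.n
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        v = a @ w
        lam_new = float(v.sum())  # Rayleigh quotient with 1-normalized w
        v /= lam_new
        if np.max(np.abs(v - w)) < tol and abs(lam_new - lam) < tol * max(1.0, lam):
            return PriorityVector(items=pcm.items, weights=v, lambda_max=lam_new)
        w, lam = v, lam_new
    raise NonConvergenceError(
        f"power iteration did not converge in {max_iter} iterations (order {n})"
    )


def row_geometric_mean(pcm: PairwiseComparisonMatrix) -> PriorityVector:
    """Row-geometric-mean priorities (the logarithmic least squares solution).

    Agrees with the eigenvector to high accuracy for near-consistent matrices;
    provided as an alternative derivation, not the default.
    """
    g = np.exp(np.mean(np.log(pcm.values), axis=1))
    w = g / g.sum()
    lam = float((pcm.values @ w).sum())
    return PriorityVector(items=pcm.items, weights=w, lambda_max=lam)


def classify_cr(cr: float) -> str:
    """Screening class for a consistency ratio (10% review / 30% exclude)."""
    if cr > CR_EXCLUDE_THRESHOLD:
        return "exclude"
    if cr > CR_REVIEW_THRESHOLD:
        return "review"
    return "ok"


def consistency(pcm: PairwiseComparisonMatrix) -> ConsistencyReport:
    """Consistency index, ratio and screening flag for one matrix.

    Matrices of order 2 are reciprocally determined and always consistent;
    CR is defined as 0 for them.  Orders beyond the tabulated random index
    (15) raise :class:`UnsupportedOrderError`.
    """
    n = pcm.n
    if n not in RANDOM_INDEX:
        raise UnsupportedOrderError(
            f"no random index tabulated for order {n} (supported: 2..{max(RANDOM_INDEX)})"
        )
    pv = priority_vector(pcm)
    if n <= 2:
        return ConsistencyReport(ci=0.0, cr=0.0, flag="ok", lambda_max=pv.lambda_max, n=n)
    ci = (pv.lambda_max - n) / (n - 1)
    ci = max(ci, 0.0)  # clip fp noise below the λmax >= n bound
    cr = ci / RANDOM_INDEX[n]
    return ConsistencyReport(ci=ci, cr=cr, flag=classify_cr(cr), lambda_max=pv.lambda_max, n=n)


def aggregate_pcms(pcms: Sequence[PairwiseComparisonMatrix]) -> PairwiseComparisonMatrix:
    """Aggregate individual judgments by the element-wise geometric mean.

    The geometric mean is the only aggregation rule that preserves
    reciprocity; reciprocity of the result is enforced exactly by rebuilding
    the lower triangle from the upper.
    """
    if not pcms:
        raise ValueError("cannot aggregate an empty list of matrices")
    items = pcms[0].items
    for p in pcms[1:]:
        if p.items != items:
            raise ValueError(f"mismatched item lists: {p.items} != {items}")
    g = np.exp(np.mean(np.log([p.values for p in pcms]), axis=0))
    iu = np.triu_indices(len(items), k=1)
    a = np.eye(len(items))
    a[iu] = g[iu]
    a.T[iu] = 1.0 / g[iu]
    return PairwiseComparisonMatrix(items=items, values=a)


def aggregate_priorities(priorities: Sequence[PriorityVector]) -> PriorityVector:
    """Aggregate individual priorities by the arithmetic mean of the weights."""
    if not priorities:
        raise ValueError("cannot aggregate an empty list of priority vectors")
    items = priorities[0].items
    for p in priorities[1:]:
        if p.items != items:
            raise ValueError("mismatched item lists")
    w = np.mean([p.weights for p in priorities], axis=0)
    w = w / w.sum()
    return PriorityVector(items=items, weights=w, lambda_max=float(len(items)))


def screen_modelers(
    bundle: SurveyBundle,
    include_category_matrix: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Consistency screening of every matrix of every modeler.

    Returns a table with one row per (modeler, matrix) holding CI, CR and the
    screening flag, and the list of retained modeler ids.  A modeler is
    excluded if *any* of their matrices exceeds the 30% consistency-ratio
    cut-off; review flags (10% < CR ≤ 30%) are reported but do not exclude.
    """
    rows = []
    excluded: set[str] = set()
    for mid in bundle.modeler_ids:
        matrices: list[tuple[str, PairwiseComparisonMatrix]] = [
            (code, bundle.pcms[(mid, code)]) for code in bundle.protocol.category_codes
        ]
        if include_category_matrix:
            matrices.append(("CATEGORIES", bundle.category_pcm[mid]))
        for label, pcm in matrices:
            rep = consistency(pcm)
            rows.append(
                {
                    "modeler_id": mid,
                    "matrix": label,
                    "n": rep.n,
                    "ci": rep.ci,
                    "cr": rep.cr,
                    "flag": rep.flag,
                }
            )
            if rep.flag == "exclude":
                excluded.add(mid)
    table = pd.DataFrame(rows, columns=["modeler_id", "matrix", "n", "ci", "cr", "flag"])
    retained = [mid for mid in bundle.modeler_ids if mid not in excluded]
    return table, retained
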