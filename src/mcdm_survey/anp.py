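"""ANP supermatrix integration of category influence and local priorities.

The hybrid follows the common DEMATEL→ANP coupling: the total relation
matrix T over the categories is column-normalized into a cluster weighting
matrix (the influence-derived weight of each source category on each target
category), local variable priorities come from each judge's per-category
comparison matrices, and both are assembled into a column-stochastic
supermatrix over all variables.  Its limit (power) vector gives the global
importance of every variable; summed per protocol stage these yield the
cumulative stage importances ΣP_s.

Inner dependence among variables within a category is not modeled (the
survey collects variable-level comparisons per category and influence only
between categories), so the supermatrix block for (target category t,
source category s) is the target's local priority column scaled by the
cluster weight w[t, s].  Under this structure the limit factorizes: a
variable's global importance is its within-category priority times its
category's stationary weight — exactly the "variable ranking normalized over
its category score" construction used for the published stage table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dematel import TotalRelationMatrix, dematel
from .pcm import PriorityVector, priority_vector, screen_modelers
from .protocol import ProtocolConfig, SurveyBundle

__all__ = [
    "Supermatrix",
    "ImportanceTable",
    "AnpError",
    "cluster_weights",
    "build_supermatrix",
    "limit_supermatrix",
    "global_priorities",
    "importance_table",
    "stage_totals",
]

COLUMN_TOL = 1e-9


class AnpError(ValueError):
    """Supermatrix construction or limiting failed."""


@dataclass(frozen=True)
class Supermatrix:
    """Column-stochastic supermatrix over all protocol variables.

    Items are (category, variable) pairs in protocol order.
    """

    items: tuple[tuple[str, str], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        a = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if a.shape != (n, n):
            raise AnpError(f"supermatrix must be {n}x{n}, got {a.shape}")
        if np.any(a < -1e-12):
            raise AnpError("supermatrix entries must be non-negative")
        col = a.sum(axis=0)
        if np.any(np.abs(col - 1.0) > COLUMN_TOL):
            j = int(np.argmax(np.abs(col - 1.0)))
            raise AnpError(f"column {j} sums to {col[j]}, not 1")
        a = np.clip(a, 0.0, None).copy()
        a.flags.writeable = False
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ImportanceTable:
    """Global and per-stage variable importances pooled across modelers.

    ``per_variable`` has columns (variable, category, stage, mean, sd) where
    ``mean`` is the global importance averaged over modelers (each modeler's
    importances sum to 1, so the means do too).  ``per_category`` sums the
    means within each category; ``stage_totals`` sums them within each stage
    (the cumulative stage importances ΣP_s, jointly summing to 1).
    """

    per_variable: pd.DataFrame
    per_category: pd.Series
    stage_totals: pd.Series
    n_modelers: int


def cluster_weights(t: TotalRelationMatrix) -> np.ndarray:
    """Column-normalized total relation matrix.

    Entry [i, j] is the influence-derived weight of source category i on
    target category j.  A zero column (a category receiving no influence)
    falls back to uniform weights.
    """
    a = t.values
    col = a.sum(axis=0)
    w = np.empty_like(a)
    for j in range(t.n):
        if col[j] > 0:
            w[:, j] = a[:, j] / col[j]
        else:
            w[:, j] = 1.0 / t.n
    return w


def build_supermatrix(
    local: Mapping[str, PriorityVector],
    weights: np.ndarray,
    protocol: ProtocolConfig,
) -> Supermatrix:
    """Assemble the weighted supermatrix from local priorities and cluster
    weights.

    Block (target category t, source category s) is the outer product of the
    target's local priority column with a row of ones, scaled by the cluster
    weight w[t, s]; every column then sums to Σ_t w[t, s] = 1.
    """
    codes = protocol.category_codes
    k = len(codes)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (k, k):
        raise AnpError(f"cluster weight matrix must be {k}x{k}, got {weights.shape}")
    missing = [c for c in codes if c not in local]
    if missing:
        raise AnpError(f"missing local priorities for categories: {missing}")
    sizes = [protocol.category(c).n_variables for c in codes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    sm = np.zeros((n, n))
    for ti, tcode in enumerate(codes):
        pv = local[tcode]
        expected = protocol.category(tcode).variable_names
        if pv.items != expected:
            raise AnpError(f"local priorities for {tcode!r} not in protocol order")
        rows = slice(offsets[ti], offsets[ti + 1])
        for si in range(k):
            cols = slice(offsets[si], offsets[si + 1])
            sm[rows, cols] = np.outer(pv.weights, np.ones(sizes[si])) * weights[ti, si]
    items = tuple((c, v) for c in codes for v in protocol.category(c).variable_names)
    return Supermatrix(items=items, values=sm)


def _column_spread(a: np.ndarray) -> float:
    return float(np.max(a.max(axis=1) - a.min(axis=1)))


def limit_supermatrix(
    w: Supermatrix,
    tol: float = 1e-9,
    max_squarings: int = 64,
    max_period: int = 64,
) -> PriorityVector:
    """Limit priorities of a column-stochastic supermatrix.

    Repeated squaring until every row is constant across columns (spread
    below ``tol``); for periodic chains, where powers cycle instead of
    converging, the Cesàro average over one detected period is returned.
    The result is normalized to sum 1.
    """
    a = w.values
    m = a.copy()
    for _ in range(max_squarings):
        if _column_spread(m) < tol:
            v = m.mean(axis=1)
            v = v / v.sum()
            return PriorityVector(items=tuple(f"{c}:{n}" for c, n in w.items), weights=v, lambda_max=1.0)
        m = m @ m
        m /= m.sum(axis=0, keepdims=True)  # kill fp drift in column sums
    # Periodic chain: powers cycle with some period p; the Cesàro limit is the
    # average over one full cycle.
    powers = [a]
    for _ in range(max_period):
        powers.append(powers[-1] @ a)
        for p in range(1, len(powers)):
            if np.max(np.abs(powers[-1] - powers[-1 - p])) < 1e-12:
                cycle = np.mean(powers[-1 - p : -1], axis=0)
                if _column_spread(cycle) >= tol:
                    raise AnpError(
                        "supermatrix limit depends on the starting column "
                        f"(spread {_column_spread(cycle):.2e}); the network is reducible"
                    )
                v = cycle.mean(axis=1)
                v = v / v.sum()
                return PriorityVector(
                    items=tuple(f"{c}:{n}" for c, n in w.items), weights=v, lambda_max=1.0
                )
    raise AnpError(
        f"supermatrix powers neither converged nor cycled within the cap "
        f"(spread {_column_spread(m):.2e})"
    )


def global_priorities(
    local: Mapping[str, PriorityVector],
    t: TotalRelationMatrix,
    protocol: ProtocolConfig,
) -> pd.Series:
    """Global variable importances for one judge: supermatrix limit of their
    local priorities weighted by their influence-derived cluster weights."""
    if t.items != protocol.category_codes:
        raise AnpError("total relation matrix categories do not match the protocol")
    sm = build_supermatrix(local, cluster_weights(t), protocol)
    pv = limit_supermatrix(sm)
    index = pd.MultiIndex.from_tuples(
        [(c, v) for c, v in sm.items], names=["category", "variable"]
    )
    return pd.Series(pv.weights, index=index, name="importance")


def importance_table(
    bundle: SurveyBundle,
    retained: Sequence[str] | None = None,
) -> ImportanceTable:
    """Per-variable global importances (mean ± sd across modelers), category
    importances, and cumulative stage importances ΣP_s.

    Each retained modeler's full pipeline is run separately (local priorities
    from their comparison matrices, cluster weights from their influence
    ratings, supermatrix limit), then pooled.  If ``retained`` is omitted the
    consistency screening is applied first.
    """
    if retained is None:
        _, retained = screen_modelers(bundle)
    ids = list(retained)
    if not ids:
        raise AnpError("no retained modelers")
    protocol = bundle.protocol
    per_judge = []
    for mid in ids:
        local = {
            code: priority_vector(bundle.pcms[(mid, code)]) for code in protocol.category_codes
        }
        t = dematel(bundle.influence[mid])
        per_judge.append(global_priorities(local, t, protocol))
    stacked = pd.concat(per_judge, axis=1)
    mean = stacked.mean(axis=1)
    sd = stacked.std(axis=1, ddof=1).fillna(0.0) if len(ids) > 1 else pd.Series(0.0, index=mean.index)
    stage_of = {(v.category, v.name): v.stage for v in protocol.variables}
    per_variable = pd.DataFrame(
        {
            "category": [c for c, _ in mean.index],
            "variable": [v for _, v in mean.index],
            "stage": [stage_of[key] for key in mean.index],
            "mean": mean.to_numpy(),
            "sd": sd.to_numpy(),
        }
    )
    per_category = per_variable.groupby("category", sort=False)["mean"].sum()
    totals = stage_totals(per_variable, n_stages=protocol.n_stages)
    return ImportanceTable(
        per_variable=per_variable,
        per_category=per_category,
        stage_totals=totals,
        n_modelers=len(ids),
    )


def stage_totals(per_variable: pd.DataFrame, n_stages: int | None = None) -> pd.Series:
    """Sum per-variable importances within each protocol stage.

    Works on any table with ``stage`` and ``mean`` columns — an
    :class:`ImportanceTable`'s frame or the packaged published table.
    """
    totals = per_variable.groupby("stage")["mean"].sum()
    if n_stages is not None:
        totals = totals.reindex(range(1, n_stages + 1), fill_value=0.0)
    totals.name = "sigma_p"
    return totals
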