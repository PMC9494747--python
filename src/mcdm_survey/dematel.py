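"""DEMATEL total-relation analysis over the variable categories.

Each judge rates the direct influence every category exerts on every other
(a non-negative matrix D with zero diagonal).  D is normalized by
s = max(max row sum, max column sum) so that the spectral radius of
N = D / s is below 1, and the total relation matrix

    T = N (I − N)^{-1} = N + N² + N³ + ...

accumulates direct and all indirect influence paths.  Row sums G are the
influence a category gives, column sums R the influence it receives; G − R
classifies categories as net influencers (positive) or net receivers
(negative), and G + R measures overall dominance.  Per-judge T's are pooled
as mean ± sd, since the survey reports influence levels per judge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import DirectInfluenceMatrix, SurveyBundle

__all__ = [
    "TotalRelationMatrix",
    "InfluenceProfile",
    "DematelError",
    "normalize_direct",
    "total_relation",
    "dematel",
    "influence_profiles",
    "profiles_frame",
    "pool_influence",
    "edge_list",
]

NEUTRAL_TOL = 1e-9


class DematelError(ValueError):
    """The direct-influence matrix cannot be analyzed."""


@dataclass(frozen=True)
class TotalRelationMatrix:
    """Total (direct + indirect) relation matrix T over the categories."""

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        a = np.asarray(self.values, dtype=float)
        if a.shape != (len(self.items), len(self.items)):
            raise DematelError(f"T must be {len(self.items)}x{len(self.items)}")
        if not np.all(np.isfinite(a)) or np.any(a < -1e-12):
            raise DematelError("T must be finite and non-negative")
        a = np.clip(a, 0.0, None).copy()
        a.flags.writeable = False
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class InfluenceProfile:
    """Influence summary of one category: given G, received R, and derived
    net (G − R), dominance (G + R), outgoing share G/(G+R), and class."""

    category: str
    given: float
    received: float
    net: float
    dominance: float
    outgoing_share: float
    klass: str  # "influencer" | "receiver" | "neutral"


def normalize_direct(d: DirectInfluenceMatrix) -> np.ndarray:
    """Scale D by max(max row sum, max column sum).

    The scaling bounds both the row and column sums of N by 1, which forces
    the spectral radius below 1 for any matrix with a strictly dominant
    scaling; this is verified numerically and violations raise.
    """
    a = d.values
    s = max(a.sum(axis=1).max(), a.sum(axis=0).max())
    if s <= 0:
        raise DematelError("all-zero direct influence matrix: no relations to analyze")
    n = a / s
    rho = float(np.max(np.abs(np.linalg.eigvals(n))))
    if rho >= 1.0 - 1e-12:
        raise DematelError(f"normalized matrix has spectral radius {rho:.6f} >= 1")
    return n


def total_relation(n: np.ndarray, items: Sequence[str]) -> TotalRelationMatrix:
    """T = N (I − N)^{-1}, the sum of direct and all indirect influence."""
    n = np.asarray(n, dtype=float)
    eye = np.eye(n.shape[0])
    rho = float(np.max(np.abs(np.linalg.eigvals(n)))) if n.size else 0.0
    if rho >= 1.0 - 1e-12:
        raise DematelError(
            f"(I - N) is singular: spectral radius {rho:.6f} >= 1, the influence series diverges"
        )
    t = n @ np.linalg.inv(eye - n)
    return TotalRelationMatrix(items=tuple(items), values=t)


def dematel(d: DirectInfluenceMatrix) -> TotalRelationMatrix:
    """Normalize a direct-influence matrix and compute its total relation."""
    return total_relation(normalize_direct(d), d.items)


def influence_profiles(t: TotalRelationMatrix) -> list[InfluenceProfile]:
    """Per-category G, R, G−R, G+R, outgoing share, and influence class.

    ``net = 0`` (within 1e-9) is reported as "neutral" — degenerate inputs
    (e.g. perfectly symmetric T) have no influence direction.
    """
    g = t.values.sum(axis=1)
    r = t.values.sum(axis=0)
    out = []
    for k, cat in enumerate(t.items):
        net = float(g[k] - r[k])
        dom = float(g[k] + r[k])
        share = float(g[k] / dom) if dom > 0 else 0.5
        if net > NEUTRAL_TOL:
            klass = "influencer"
        elif net < -NEUTRAL_TOL:
            klass = "receiver"
        else:
            klass = "neutral"
        out.append(
            InfluenceProfile(
                category=cat,
                given=float(g[k]),
                received=float(r[k]),
                net=net,
                dominance=dom,
                outgoing_share=share,
                klass=klass,
            )
        )
    return out


def profiles_frame(profiles: Sequence[InfluenceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": p.category,
                "G": p.given,
                "R": p.received,
                "net": p.net,
                "dominance": p.dominance,
                "outgoing_share": p.outgoing_share,
                "class": p.klass,
            }
            for p in profiles
        ]
    )


def pool_influence(
    bundle: SurveyBundle,
    retained: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean ± sd influence profile per category across modelers.

    Each retained modeler's total relation matrix is computed first and its
    profile summarized; the pooling then averages profiles across modelers
    (sd with denominator n − 1; 0 for a single modeler).
    """
    ids = list(retained) if retained is not None else list(bundle.modeler_ids)
    if not ids:
        raise DematelError("no retained modelers with influence matrices")
    per_modeler = []
    for mid in ids:
        t = dematel(bundle.influence[mid])
        df = profiles_frame(influence_profiles(t))
        df["modeler_id"] = mid
        per_modeler.append(df)
    stacked = pd.concat(per_modeler, ignore_index=True)
    num_cols = ["G", "R", "net", "dominance", "outgoing_share"]
    agg = stacked.groupby("category", sort=False)[num_cols].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    agg = agg.fillna(0.0)  # single-modeler sd
    order = [c for c in bundle.protocol.category_codes if c in agg.index]
    agg = agg.loc[order]
    klass = np.where(
        agg["net_mean"] > NEUTRAL_TOL,
        "influencer",
        np.where(agg["net_mean"] < -NEUTRAL_TOL, "receiver", "neutral"),
    )
    agg["class"] = klass
    agg["n_modelers"] = len(ids)
    return agg.reset_index()


def edge_list(t: TotalRelationMatrix, cutoff: float = 0.0) -> pd.DataFrame:
    """Directed edges (from, to, weight) of T with weight > ``cutoff``,
    for causal-diagram plotting."""
    rows = [
        {"from": t.items[i], "to": t.items[j], "weight": float(t.values[i, j])}
        for i in range(t.n)
        for j in range(t.n)
        if i != j and t.values[i, j] > cutoff
    ]
    return pd.DataFrame(rows, columns=["from", "to", "weight"])
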