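"""Kendall's coefficient of concordance (tie-corrected) and Wilks' lambda.

Concordance between the m judges ranking the n items of a category is

    W = 12·SS / (m²(n³ − n) − m·F),

where SS is the sum of squared deviations of the per-item rank sums from
their mean, and F = Σ_judges Σ_tie-groups (t³ − t) corrects for tied ranks
(mid-ranks share the average position).  W = 1 means identical rankings,
W = 0 means no agreement (all rank sums equal).  Significance uses the
chi-square approximation χ² = m(n − 1)·W on n − 1 degrees of freedom; an
exact permutation test is available for small tables.

Group differences in the judges' ratings are tested with a one-way MANOVA:
Wilks' Λ = det(W_within) / det(W_within + B_between), with Rao's F
approximation for the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import priority_vector, screen_modelers, PriorityVector
from .protocol import SurveyBundle

__all__ = [
    "RankScoreTable",
    "ConcordanceResult",
    "ManovaResult",
    "AgreementError",
    "rank_scores",
    "kendall_w",
    "concordance_by_category",
    "wilks_manova",
    "univariate_group_tests",
    "holm_adjust",
]

ALPHA = 0.05


class AgreementError(ValueError):
    """Agreement statistic cannot be computed on this input."""


@dataclass(frozen=True)
class RankScoreTable:
    """m × n mid-rank scores: one row per judge, one column per item.

    Ranks ascend with importance (the most important item gets rank n);
    tied values share their average rank, so every row sums to n(n+1)/2.
    """

    items: tuple[str, ...]
    judges: tuple[str, ...]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "judges", tuple(self.judges))
        a = np.asarray(self.ranks, dtype=float)
        m, n = len(self.judges), len(self.items)
        if a.shape != (m, n):
            raise AgreementError(f"rank table must be {m}x{n}, got {a.shape}")
        expected = n * (n + 1) / 2
        if np.any(np.abs(a.sum(axis=1) - expected) > 1e-6):
            j = int(np.argmax(np.abs(a.sum(axis=1) - expected)))
            raise AgreementError(
                f"judge {self.judges[j]!r}: ranks sum to {a.sum(axis=1)[j]}, "
                f"not a mid-rank assignment of 1..{n}"
            )
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "ranks", a)

    @property
    def m(self) -> int:
        return len(self.judges)

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its tie correction and chi-square test."""

    w: float
    ss: float
    f_correction: float
    chi2: float
    df: int
    p_value: float
    significant: bool
    m: int
    n: int


@dataclass(frozen=True)
class ManovaResult:
    """One-way MANOVA summary via Wilks' lambda and Rao's F approximation."""

    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    significant: bool
    group_factor: str = ""


def rank_scores(priorities: Mapping[str, PriorityVector]) -> RankScoreTable:
    """Mid-rank scores of each judge's priority weights (ascending in
    importance: the heaviest item receives rank n)."""
    if len(priorities) < 2:
        raise AgreementError("need at least 2 judges")
    judges = tuple(priorities)
    items = priorities[judges[0]].items
    rows = []
    for j in judges:
        pv = priorities[j]
        if pv.items != items:
            raise AgreementError(f"judge {j!r} has mismatched items")
        rows.append(stats.rankdata(pv.weights, method="average"))
    return RankScoreTable(items=items, judges=judges, ranks=np.asarray(rows))


def _tie_correction(row: np.ndarray) -> float:
    """Σ (t³ − t) over groups of tied ranks in one judge's row."""
    _, counts = np.unique(row, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendall_w(
    table: RankScoreTable,
    method: str = "chi2",
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> ConcordanceResult:
    """Tie-corrected Kendall coefficient of concordance with significance.

    ``method`` selects the significance computation: ``"chi2"`` (the
    χ² = m(n−1)W approximation, default) or ``"permutation"`` (judge-wise
    random relabeling of ranks, exact in the limit, for small tables).
    """
    m, n = table.m, table.n
    if m < 2 or n < 2:
        raise AgreementError("need at least 2 judges and 2 items")
    f = sum(_tie_correction(row) for row in table.ranks)
    denom = m * m * (n**3 - n) - m * f
    if denom <= 0:
        raise AgreementError(
            "degenerate rank table: every judge ties all items, W is undefined"
        )
    rank_sums = table.ranks.sum(axis=0)
    ss = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    w = 12.0 * ss / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df))
    elif method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = np.array([gen.permutation(row) for row in table.ranks])
            sums = perm.sum(axis=0)
            ss_p = float(np.sum((sums - sums.mean()) ** 2))
            if 12.0 * ss_p / denom >= w - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ConcordanceResult(
        w=w,
        ss=ss,
        f_correction=f,
        chi2=chi2,
        df=df,
        p_value=p,
        significant=bool(p < ALPHA),
        m=m,
        n=n,
    )


def concordance_by_category(
    bundle: SurveyBundle,
    retained: Sequence[str] | None = None,
) -> dict[str, ConcordanceResult]:
    """Kendall's W per variable category, plus one result over the categories
    themselves (key ``"CATEGORIES"``), from the retained judges' priorities."""
    if retained is None:
        _, retained = screen_modelers(bundle)
    ids = list(retained)
    if len(ids) < 2:
        raise AgreementError("need at least 2 retained judges")
    out: dict[str, ConcordanceResult] = {}
    for code in bundle.protocol.category_codes:
        priorities = {mid: priority_vector(bundle.pcms[(mid, code)]) for mid in ids}
        out[code] = kendall_w(rank_scores(priorities))
    cat_priorities = {mid: priority_vector(bundle.category_pcm[mid]) for mid in ids}
    out["CATEGORIES"] = kendall_w(rank_scores(cat_priorities))
    return out


def wilks_manova(
    features: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    group_factor: str = "",
) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda.

    ``features`` is the judges × variables rating matrix, ``groups`` the
    group label of each judge.  Λ = det(W)/det(W + B) with W and B the
    within- and between-group cross-product matrices; the p-value uses Rao's
    F approximation.  Requires at least 2 groups with at least 2 judges each,
    and more judges than feature columns (otherwise W is singular — reduce
    the feature set, e.g. one category at a time).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise AgreementError("features must be a 2-d judges x variables matrix")
    groups = np.asarray([str(g) for g in groups])
    if groups.shape[0] != x.shape[0]:
        raise AgreementError("one group label per judge required")
    n_total, p = x.shape
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise AgreementError("need at least 2 groups")
    sizes = np.bincount(inverse)
    if np.any(sizes < 2):
        small = labels[sizes < 2].tolist()
        raise AgreementError(f"group(s) with fewer than 2 judges: {small}")
    if n_total <= p:
        raise AgreementError(
            f"{n_total} judges for {p} features: within-group matrix is singular, "
            "reduce the feature set (e.g. test one category at a time)"
        )
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for k in range(g):
        xk = x[inverse == k]
        mk = xk.mean(axis=0)
        centered = xk - mk
        w += centered.T @ centered
        d = (mk - grand)[:, None]
        b += sizes[k] * (d @ d.T)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise AgreementError(
            "singular within-group cross-product matrix; reduce the feature set"
        )
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)
    # Rao's F approximation
    df_h = g - 1
    t = np.sqrt((p**2 * df_h**2 - 4) / (p**2 + df_h**2 - 5)) if (p**2 + df_h**2 - 5) > 0 else 1.0
    df1 = p * df_h
    ww = n_total - 1 - (p + g) / 2.0
    df2 = ww * t - (p * df_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if df2 <= 0:
        raise AgreementError("too few residual degrees of freedom for Rao's approximation")
    f_stat = ((1.0 - lam_t) / lam_t) * (df2 / df1)
    p_value = float(stats.f.sf(f_stat, df1, df2)) if lam < 1.0 else 1.0
    return ManovaResult(
        wilks_lambda=lam,
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        significant=bool(p_value < ALPHA),
        group_factor=group_factor,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    k = p.size
    order = np.argsort(p)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def univariate_group_tests(
    features: pd.DataFrame,
    groups: Sequence[str],
    holm: bool = False,
) -> pd.DataFrame:
    """Per-variable one-way ANOVA follow-ups to a MANOVA.

    Unadjusted p < 0.05 by default; set ``holm=True`` for a Holm-adjusted
    family of tests.
    """
    groups = np.asarray([str(g) for g in groups])
    labels = np.unique(groups)
    rows = []
    for col in features.columns:
        samples = [features.loc[groups == lab, col].to_numpy(dtype=float) for lab in labels]
        f, p = stats.f_oneway(*samples)
        rows.append({"variable": col, "f_stat": float(f), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if holm:
        out["p_adjusted"] = holm_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < ALPHA
    else:
        out["significant"] = out["p_value"] < ALPHA
    return out
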