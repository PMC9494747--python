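"""Domain containers for the staged model-intercomparison survey.

The survey instrument asks each modeler in a multi-model ensemble study to
judge, category by category, the relative importance of the input variables
released over successive calibration stages, and to rate the direct influence
each variable *category* exerts on every other.  This module defines the
validated containers every analysis step consumes:

* :class:`ProtocolConfig` — the category/variable/stage tree (the packaged
  default has 7 categories, 55 variables, 5 stages);
* :class:`PairwiseComparisonMatrix` — one judge's reciprocal ratio judgments
  over the items of one category (Saaty-style);
* :class:`DirectInfluenceMatrix` — one judge's category-level influence
  ratings (zero diagonal, non-negative);
* :class:`SurveyBundle` — all responses of a survey plus modeler attributes;
* :class:`RRMSESeries` — per-stage ensemble prediction error for one output.

Validation is strict and eager: a container that constructs is a container
every downstream operation may assume well-formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ProtocolError",
    "SurveyFormatError",
    "InputVariable",
    "VariableCategory",
    "ProtocolConfig",
    "ModelerProfile",
    "PairwiseComparisonMatrix",
    "DirectInfluenceMatrix",
    "SurveyBundle",
    "RRMSESeries",
    "SAATY_SCALE",
]

#: Admissible judgment values of the fundamental 1-9 ratio scale (opt-in check).
SAATY_SCALE = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(float(k) for k in range(1, 10))

RECIPROCITY_TOL = 1e-9


class ProtocolError(ValueError):
    """A protocol configuration violates a structural invariant."""


class SurveyFormatError(ValueError):
    """A survey response file or bundle is malformed."""


@dataclass(frozen=True)
class InputVariable:
    """One input variable of the modeling protocol.

    ``stage`` is the calibration stage (1-based) at which the variable is
    first released to the modelers.
    """

    name: str
    category: str
    stage: int


@dataclass(frozen=True)
class VariableCategory:
    """A named cluster of input variables (e.g. soil information)."""

    code: str
    label: str
    variables: tuple[InputVariable, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) < 2:
            raise ProtocolError(
                f"category {self.code!r} has {len(self.variables)} variable(s); "
                "a pairwise comparison matrix needs at least 2"
            )
        for v in self.variables:
            if v.category != self.code:
                raise ProtocolError(
                    f"variable {v.name!r} is tagged {v.category!r} but listed under {self.code!r}"
                )

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)


@dataclass(frozen=True)
class ProtocolConfig:
    """The full category/variable/stage structure of a staged protocol.

    Variable order is the protocol order: categories in listed order, then
    variables in listed order within each category.  Every matrix and table
    downstream is indexed in this order, which makes all results deterministic.
    """

    categories: tuple[VariableCategory, ...]
    n_stages: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        codes = [c.code for c in self.categories]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ProtocolError(f"duplicate category code(s): {dup}")
        if self.n_stages < 1:
            raise ProtocolError("n_stages must be >= 1")
        seen: set[tuple[str, str]] = set()
        stages_used: set[int] = set()
        for cat in self.categories:
            for v in cat.variables:
                key = (v.name, v.category)
                if key in seen:
                    raise ProtocolError(f"duplicate variable {v.name!r} in category {v.category!r}")
                seen.add(key)
                if not 1 <= v.stage <= self.n_stages:
                    raise ProtocolError(
                        f"variable {v.name!r} has stage {v.stage}, outside 1..{self.n_stages}"
                    )
                stages_used.add(v.stage)
        missing = set(range(1, self.n_stages + 1)) - stages_used
        if missing:
            raise ProtocolError(f"stage(s) with no variables: {sorted(missing)}")

    @property
    def category_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.categories)

    @property
    def variables(self) -> tuple[InputVariable, ...]:
        return tuple(v for c in self.categories for v in c.variables)

    @property
    def n_variables(self) -> int:
        return sum(c.n_variables for c in self.categories)

    def category(self, code: str) -> VariableCategory:
        for c in self.categories:
            if c.code == code:
                return c
        raise KeyError(code)

    def variables_in_stage(self, stage: int) -> tuple[InputVariable, ...]:
        return tuple(v for v in self.variables if v.stage == stage)

    def stage_counts(self) -> dict[int, int]:
        counts = {s: 0 for s in range(1, self.n_stages + 1)}
        for v in self.variables:
            counts[v.stage] += 1
        return counts


@dataclass(frozen=True)
class ModelerProfile:
    """Attributes of one survey respondent."""

    modeler_id: str
    model_type: str
    experience_class: str


def _as_square(values: np.ndarray | Sequence, items: Sequence[str], what: str) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    n = len(items)
    if a.ndim != 2 or a.shape != (n, n):
        raise SurveyFormatError(f"{what}: expected a {n}x{n} matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise SurveyFormatError(f"{what}: non-finite entries")
    return a


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A reciprocal matrix of ratio judgments a_ij = importance of i over j.

    Construction validates positivity, a unit diagonal and reciprocity
    (a_ij * a_ji = 1) to within ``1e-9``; violations are reported with the
    offending cell indices.  Restriction of entries to the discrete 1-9 scale
    is *not* enforced by default — call :meth:`validate_scale` for that.
    """

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        a = _as_square(self.values, self.items, "pairwise comparison matrix")
        if len(self.items) < 2:
            raise SurveyFormatError("pairwise comparison matrix needs at least 2 items")
        if np.any(a <= 0):
            i, j = np.argwhere(a <= 0)[0]
            raise SurveyFormatError(
                f"non-positive entry a[{i},{j}]={a[i, j]} ({self.items[i]!r} vs {self.items[j]!r})"
            )
        if np.any(np.abs(np.diag(a) - 1.0) > RECIPROCITY_TOL):
            i = int(np.argmax(np.abs(np.diag(a) - 1.0)))
            raise SurveyFormatError(f"diagonal entry a[{i},{i}]={a[i, i]} differs from 1")
        prod = a * a.T
        bad = np.abs(prod - 1.0) > RECIPROCITY_TOL
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise SurveyFormatError(
                f"reciprocity violated at ({i}, {j}): a_ij={a[i, j]}, a_ji={a[j, i]} "
                f"({self.items[i]!r} vs {self.items[j]!r})"
            )
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return len(self.items)

    def validate_scale(self, tol: float = 1e-9) -> None:
        """Opt-in check that every entry sits on the discrete 1-9 ratio scale."""
        scale = np.asarray(SAATY_SCALE)
        dev = np.min(np.abs(self.values[..., None] - scale), axis=-1)
        if np.any(dev > tol):
            i, j = np.argwhere(dev > tol)[0]
            raise SurveyFormatError(
                f"entry a[{i},{j}]={self.values[i, j]} is not on the 1-9 judgment scale"
            )


@dataclass(frozen=True)
class DirectInfluenceMatrix:
    """Category-level direct influence ratings: d_ij = influence of i on j."""

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        a = _as_square(self.values, self.items, "direct influence matrix")
        if np.any(a < 0):
            i, j = np.argwhere(a < 0)[0]
            raise SurveyFormatError(f"negative influence entry d[{i},{j}]={a[i, j]}")
        if np.any(np.diag(a) != 0):
            i = int(np.argmax(np.diag(a) != 0))
            raise SurveyFormatError(f"diagonal entry d[{i},{i}]={a[i, i]} must be 0")
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class RRMSESeries:
    """Per-stage ensemble prediction error for one output variable.

    RRMSE is the root mean square error normalized by the mean of the
    observations; ``unit`` records whether values are fractions or percent
    and is carried through, never silently converted.
    """

    output_name: str
    values: np.ndarray
    unit: str = "fraction"

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 1 or a.size == 0:
            raise SurveyFormatError(f"RRMSE series {self.output_name!r}: expected a 1-d series")
        if not np.all(np.isfinite(a)):
            raise SurveyFormatError(f"RRMSE series {self.output_name!r}: non-finite values")
        if np.any(a < 0):
            s = int(np.argmax(a < 0))
            raise SurveyFormatError(
                f"RRMSE series {self.output_name!r}: negative value {a[s]} at stage {s + 1}"
            )
        if self.unit not in ("fraction", "percent"):
            raise SurveyFormatError(f"unknown RRMSE unit {self.unit!r}")
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "values", a)

    @property
    def n_stages(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SurveyBundle:
    """All responses of one survey, validated against a protocol.

    ``pcms`` maps ``(modeler_id, category_code)`` to that modeler's
    variable-level comparison matrix; ``category_pcm`` holds each modeler's
    comparison of the categories themselves; ``influence`` their category
    direct-influence ratings.
    """

    protocol: ProtocolConfig
    profiles: tuple[ModelerProfile, ...]
    pcms: Mapping[tuple[str, str], PairwiseComparisonMatrix]
    category_pcm: Mapping[str, PairwiseComparisonMatrix]
    influence: Mapping[str, DirectInfluenceMatrix]

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "pcms", dict(self.pcms))
        object.__setattr__(self, "category_pcm", dict(self.category_pcm))
        object.__setattr__(self, "influence", dict(self.influence))
        ids = [p.modeler_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise SurveyFormatError("duplicate modeler_id in profiles")
        known = set(ids)
        codes = self.protocol.category_codes
        for (mid, code), pcm in self.pcms.items():
            if mid not in known:
                raise SurveyFormatError(f"PCM for unknown modeler {mid!r}")
            if code not in codes:
                raise SurveyFormatError(f"PCM for unknown category {code!r} (modeler {mid!r})")
            expected = self.protocol.category(code).variable_names
            if pcm.items != expected:
                raise SurveyFormatError(
                    f"PCM items for modeler {mid!r}, category {code!r} do not match the "
                    f"protocol order: {pcm.items} != {expected}"
                )
        for mid, pcm in self.category_pcm.items():
            if mid not in known:
                raise SurveyFormatError(f"category PCM for unknown modeler {mid!r}")
            if pcm.items != codes:
                raise SurveyFormatError(
                    f"category PCM items for modeler {mid!r} do not match protocol categories"
                )
        for mid, dim in self.influence.items():
            if mid not in known:
                raise SurveyFormatError(f"influence matrix for unknown modeler {mid!r}")
            if dim.items != codes:
                raise SurveyFormatError(
                    f"influence items for modeler {mid!r} do not match protocol categories"
                )
        for mid in ids:
            for code in codes:
                if (mid, code) not in self.pcms:
                    raise SurveyFormatError(f"missing PCM for modeler {mid!r}, category {code!r}")
            if mid not in self.category_pcm:
                raise SurveyFormatError(f"missing category PCM for modeler {mid!r}")
            if mid not in self.influence:
                raise SurveyFormatError(f"missing influence matrix for modeler {mid!r}")

    @property
    def modeler_ids(self) -> tuple[str, ...]:
        return tuple(p.modeler_id for p in self.profiles)

    def profile(self, modeler_id: str) -> ModelerProfile:
        for p in self.profiles:
            if p.modeler_id == modeler_id:
                return p
        raise KeyError(modeler_id)
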