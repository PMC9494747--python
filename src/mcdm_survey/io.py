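"""Reading and writing protocol, survey, and error-series files.

Formats are deliberately plain text:

* protocol — a JSON tree ``{"n_stages": ..., "categories": [{"code", "label",
  "variables": [{"name", "stage"}, ...]}, ...]}``;
* survey responses — either a single long-format CSV with columns
  ``modeler_id, matrix, row_item, col_item, value`` (``matrix`` is a category
  code, or ``CATEGORIES`` for the category-level comparison, or ``INFLUENCE``
  for the direct-influence ratings), or a directory of per-matrix CSVs named
  ``<modeler>__<matrix>.csv``; modeler attributes live in ``profiles.csv``;
* RRMSE — a CSV with one output per row, one ``stage_<k>`` column per stage
  and an optional ``unit`` column.

Matrix entries are written with ``repr`` so a write/read round-trip is
bit-identical.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .protocol import (
    DirectInfluenceMatrix,
    InputVariable,
    ModelerProfile,
    PairwiseComparisonMatrix,
    ProtocolConfig,
    ProtocolError,
    RRMSESeries,
    SurveyBundle,
    SurveyFormatError,
    VariableCategory,
)

__all__ = [
    "load_protocol",
    "protocol_from_dict",
    "default_protocol",
    "load_survey",
    "save_survey",
    "load_rrmse",
    "save_rrmse",
    "published_stage_importance",
]

CATEGORY_MATRIX = "CATEGORIES"
INFLUENCE_MATRIX = "INFLUENCE"


def protocol_from_dict(data: dict) -> ProtocolConfig:
    """Build and validate a :class:`ProtocolConfig` from a parsed JSON tree."""
    try:
        cats = []
        for cat in data["categories"]:
            variables = tuple(
                InputVariable(name=v["name"], category=cat["code"], stage=int(v["stage"]))
                for v in cat["variables"]
            )
            cats.append(
                VariableCategory(code=cat["code"], label=cat.get("label", cat["code"]), variables=variables)
            )
        return ProtocolConfig(categories=tuple(cats), n_stages=int(data.get("n_stages", 5)))
    except (KeyError, TypeError) as exc:
        raise ProtocolError(f"malformed protocol config: {exc}") from exc


def load_protocol(path: str | Path) -> ProtocolConfig:
    """Load and validate a protocol configuration from a JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ProtocolError(f"cannot parse {path}: {exc}") from exc
    return protocol_from_dict(data)


@lru_cache(maxsize=1)
def default_protocol() -> ProtocolConfig:
    """The packaged default protocol: 7 categories, 55 variables, 5 stages."""
    data = json.loads(resources.files("mcdm_survey.data").joinpath("default_protocol.json").read_text())
    return protocol_from_dict(data)


@lru_cache(maxsize=1)
def published_stage_importance() -> pd.DataFrame:
    """The published per-variable stage importances (mean, sd) of the default
    protocol, as printed in the source study's cumulative-importance table.

    Entries printed below display precision ("<0.01") are stored as 0.0 with
    ``mean_below_precision`` / ``sd_below_precision`` set.
    """
    with resources.files("mcdm_survey.data").joinpath("stage_importance_published.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"category": str, "variable": str})
    for col in ("mean_below_precision", "sd_below_precision"):
        df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    df["stage"] = df["stage"].astype(int)
    return df


# ---------------------------------------------------------------------------
# survey responses


def _matrix_items(matrix: str, protocol: ProtocolConfig) -> tuple[str, ...]:
    if matrix in (CATEGORY_MATRIX, INFLUENCE_MATRIX):
        return protocol.category_codes
    if matrix in protocol.category_codes:
        return protocol.category(matrix).variable_names
    raise SurveyFormatError(f"unknown matrix label {matrix!r}")


def _build_matrix(sub: pd.DataFrame, matrix: str, items: tuple[str, ...], mid: str) -> np.ndarray:
    idx = {name: i for i, name in enumerate(items)}
    n = len(items)
    a = np.full((n, n), np.nan)
    for row in sub.itertuples(index=False):
        try:
            i, j = idx[row.row_item], idx[row.col_item]
        except KeyError as exc:
            raise SurveyFormatError(
                f"modeler {mid!r}, matrix {matrix!r}: unknown item {exc.args[0]!r}"
            ) from exc
        a[i, j] = float(row.value)
    if matrix != INFLUENCE_MATRIX:
        np.fill_diagonal(a, np.where(np.isnan(np.diag(a)), 1.0, np.diag(a)))
    else:
        np.fill_diagonal(a, np.where(np.isnan(np.diag(a)), 0.0, np.diag(a)))
    if np.any(np.isnan(a)):
        i, j = np.argwhere(np.isnan(a))[0]
        raise SurveyFormatError(
            f"modeler {mid!r}, matrix {matrix!r}: missing entry for "
            f"({items[i]!r}, {items[j]!r})"
        )
    return a


def _bundle_from_long(long: pd.DataFrame, profiles: list[ModelerProfile], protocol: ProtocolConfig) -> SurveyBundle:
    required = {"modeler_id", "matrix", "row_item", "col_item", "value"}
    missing = required - set(long.columns)
    if missing:
        raise SurveyFormatError(f"survey file missing column(s): {sorted(missing)}")
    pcms: dict[tuple[str, str], PairwiseComparisonMatrix] = {}
    category_pcm: dict[str, PairwiseComparisonMatrix] = {}
    influence: dict[str, DirectInfluenceMatrix] = {}
    for (mid, matrix), sub in long.groupby(["modeler_id", "matrix"], sort=False):
        mid, matrix = str(mid), str(matrix)
        items = _matrix_items(matrix, protocol)
        a = _build_matrix(sub, matrix, items, mid)
        try:
            if matrix == INFLUENCE_MATRIX:
                influence[mid] = DirectInfluenceMatrix(items=items, values=a)
            elif matrix == CATEGORY_MATRIX:
                category_pcm[mid] = PairwiseComparisonMatrix(items=items, values=a)
            else:
                pcms[(mid, matrix)] = PairwiseComparisonMatrix(items=items, values=a)
        except SurveyFormatError as exc:
            raise SurveyFormatError(f"modeler {mid!r}, matrix {matrix!r}: {exc}") from exc
    return SurveyBundle(
        protocol=protocol,
        profiles=tuple(profiles),
        pcms=pcms,
        category_pcm=category_pcm,
        influence=influence,
    )


def _read_profiles(path: Path) -> list[ModelerProfile]:
    df = pd.read_csv(path, dtype=str)
    required = {"modeler_id", "model_type", "experience_class"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyFormatError(f"{path}: missing profile column(s): {sorted(missing)}")
    return [
        ModelerProfile(
            modeler_id=r.modeler_id, model_type=r.model_type, experience_class=r.experience_class
        )
        for r in df.itertuples(index=False)
    ]


def load_survey(
    path: str | Path,
    protocol: ProtocolConfig,
    profiles_path: str | Path | None = None,
) -> SurveyBundle:
    """Load a survey bundle from a long-format CSV or a response directory.

    ``path`` may be a long-format responses CSV (profiles are then read from
    ``profiles_path`` or a sibling ``profiles.csv``) or a directory holding
    ``profiles.csv`` plus either ``responses.csv`` or per-matrix files
    ``<modeler>__<matrix>.csv``.
    """
    path = Path(path)
    if path.is_dir():
        profiles = _read_profiles(path / "profiles.csv")
        long_file = path / "responses.csv"
        if long_file.exists():
            long = pd.read_csv(long_file, dtype={"modeler_id": str, "matrix": str}, float_precision="round_trip")
        else:
            frames = []
            for f in sorted(path.glob("*__*.csv")):
                mid, matrix = f.stem.split("__", 1)
                items = _matrix_items(matrix, protocol)
                a = pd.read_csv(f, header=None).to_numpy(dtype=float)
                if a.shape != (len(items), len(items)):
                    raise SurveyFormatError(f"{f}: expected a {len(items)}x{len(items)} matrix")
                frames.append(
                    pd.DataFrame(
                        {
                            "modeler_id": mid,
                            "matrix": matrix,
                            "row_item": np.repeat(items, len(items)),
                            "col_item": np.tile(items, len(items)),
                            "value": a.ravel(),
                        }
                    )
                )
            if not frames:
                raise SurveyFormatError(f"{path}: no responses.csv and no per-matrix CSV files")
            long = pd.concat(frames, ignore_index=True)
    else:
        if profiles_path is None:
            profiles_path = path.parent / "profiles.csv"
        profiles = _read_profiles(Path(profiles_path))
        long = pd.read_csv(path, dtype={"modeler_id": str, "matrix": str}, float_precision="round_trip")
    return _bundle_from_long(long, profiles, protocol)


def save_survey(bundle: SurveyBundle, directory: str | Path) -> Path:
    """Write a bundle as ``profiles.csv`` + long-format ``responses.csv``.

    Values are written with full ``repr`` precision, so entries survive a
    write/read round-trip bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "modeler_id": p.modeler_id,
                "model_type": p.model_type,
                "experience_class": p.experience_class,
            }
            for p in bundle.profiles
        ]
    ).to_csv(directory / "profiles.csv", index=False)

    rows: list[dict] = []

    def emit(mid: str, matrix: str, items: tuple[str, ...], a: np.ndarray) -> None:
        for i, ri in enumerate(items):
            for j, cj in enumerate(items):
                rows.append(
                    {
                        "modeler_id": mid,
                        "matrix": matrix,
                        "row_item": ri,
                        "col_item": cj,
                        "value": repr(float(a[i, j])),
                    }
                )

    for mid in bundle.modeler_ids:
        for code in bundle.protocol.category_codes:
            pcm = bundle.pcms[(mid, code)]
            emit(mid, code, pcm.items, pcm.values)
        cat = bundle.category_pcm[mid]
        emit(mid, CATEGORY_MATRIX, cat.items, cat.values)
        dim = bundle.influence[mid]
        emit(mid, INFLUENCE_MATRIX, dim.items, dim.values)

    out = directory / "responses.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


# ---------------------------------------------------------------------------
# RRMSE series


def load_rrmse(path: str | Path, n_stages: int | None = None) -> list[RRMSESeries]:
    """Load per-stage RRMSE series: one output per row, ``stage_<k>`` columns.

    Stage columns may also be bare integers (``1``, ``2``, ...).  Missing
    stages and negative values are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "output" not in df.columns:
        raise SurveyFormatError(f"{path}: missing 'output' column")
    stage_cols: dict[int, str] = {}
    for col in df.columns:
        name = str(col)
        if name.startswith("stage_"):
            stage_cols[int(name[6:])] = col
        elif name.isdigit():
            stage_cols[int(name)] = col
    if not stage_cols:
        raise SurveyFormatError(f"{path}: no stage columns found")
    n = n_stages if n_stages is not None else max(stage_cols)
    missing = set(range(1, n + 1)) - set(stage_cols)
    if missing:
        raise SurveyFormatError(f"{path}: missing stage column(s): {sorted(missing)}")
    ordered = [stage_cols[s] for s in range(1, n + 1)]
    out = []
    for i in range(len(df)):
        row = df.iloc[i]
        unit = str(row["unit"]) if "unit" in df.columns else "fraction"
        out.append(
            RRMSESeries(
                output_name=str(row["output"]),
                values=row[ordered].to_numpy(dtype=float),
                unit=unit,
            )
        )
    return out


def save_rrmse(series: Iterable[RRMSESeries], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in series:
        row = {"output": s.output_name, "unit": s.unit}
        row.update({f"stage_{k + 1}": repr(float(v)) for k, v in enumerate(s.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
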