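"""CSV input/output for participant tables and edge lists.

The survey defines variables, not a file layout, so column naming is
configuration: a column map translates whatever headers the CSV uses onto the
canonical field names. Category levels are matched case-insensitively on read
(with a few common synonyms such as en-dash age ranges) and written in
canonical form.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .exceptions import CategoryError, SchemaError
from .records import (
    BOOLEAN_FIELDS,
    CATEGORY_LEVELS,
    PARTICIPANT_COLUMNS,
    StudyDataset,
    build_dataset,
)

_REQUIRED = [c for c in PARTICIPANT_COLUMNS if c not in ("recruiter_id", "reason_for_use")]

_TRUE = {"true", "yes", "y", "1", "t", "sim", "si", "sí"}
_FALSE = {"false", "no", "n", "0", "f", "nao", "não"}

# synonyms -> canonical level, applied after lowercasing/stripping
_SYNONYMS: dict[str, dict[str, str]] = {
    "city": {"boa vista": "BoaVista", "boa_vista": "BoaVista", "boavista": "BoaVista",
             "manaus": "Manaus"},
    "age_group": {"15–24": "15-24", "25–34": "25-34", "35–49": "35-49",
                  "35+": "35-49", "35-49": "35-49"},
    "education": {"high school": "high_school", "highschool": "high_school",
                  "college education": "college", "elementary school": "elementary"},
    "migratory_status": {"asylum seeker": "asylum_seeker"},
    "reason_for_use": {
        "illness or treatment": "illness_or_treatment",
        "prenatal care": "prenatal",
        "prevention, check-up or childcare": "prevention_checkup_childcare",
        "diagnostic exams": "diagnostic_exams",
    },
}


def _norm_token(value: str) -> str:
    return re.sub(r"\s+", " ", str(value).strip().lower())


def _match_level(field: str, value, row_index: int) -> Optional[str]:
    if value is None or (not isinstance(value, str) and pd.isna(value)) or value == "":
        return None
    token = _norm_token(value)
    levels = CATEGORY_LEVELS[field]
    for level in levels:
        if token == level.lower():
            return level
    mapped = _SYNONYMS.get(field, {}).get(token)
    if mapped is not None:
        return mapped
    raise CategoryError(
        f"row {row_index}: unknown {field} level {value!r} "
        f"(expected one of {list(levels)})"
    )


def _parse_bool(field: str, value, row_index: int) -> Optional[bool]:
    if value is None or (not isinstance(value, str) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    token = _norm_token(value)
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise CategoryError(f"row {row_index}: cannot parse {field} value {value!r} as boolean")


def read_dataset(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    edge_list: Optional[str | Path] = None,
    coupon_limit: int = 3,
    **read_csv_kwargs,
) -> StudyDataset:
    """Read a participant CSV into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path:
        Participant table, one row per completed interview.
    column_map:
        Canonical field -> CSV header. Unmapped fields fall back to their
        canonical name. Missing required columns raise :class:`SchemaError`.
    edge_list:
        Optional two-column CSV (recruiter_id, recruit_id) overriding the
        inline recruiter column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, **read_csv_kwargs)
    raw.replace("", pd.NA, inplace=True)
    cmap = dict(column_map or {})
    rename = {}
    for canonical in PARTICIPANT_COLUMNS:
        src = cmap.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in _REQUIRED:
            raise SchemaError(f"required column {src!r} (field {canonical!r}) not found")
    df = raw.rename(columns=rename)
    for optional in ("recruiter_id", "reason_for_use"):
        if optional not in df.columns:
            df[optional] = pd.NA
    df = df[list(PARTICIPANT_COLUMNS)]

    out = {}
    out["participant_id"] = df["participant_id"].astype(str)
    out["recruiter_id"] = df["recruiter_id"]
    out["is_seed"] = [
        _parse_bool("is_seed", v, i) for i, v in enumerate(df["is_seed"])
    ]
    for field in ("city", "age_group", "education", "migratory_status",
                  "self_rated_health", "reason_for_use"):
        out[field] = [_match_level(field, v, i) for i, v in enumerate(df[field])]
    for field in ("pregnant", "used_health_service_15d", "chronic_disease"):
        out[field] = [_parse_bool(field, v, i) for i, v in enumerate(df[field])]
    for field in ("degree_reported", "months_in_brazil"):
        out[field] = pd.to_numeric(df[field], errors="raise").astype(int)

    clean = pd.DataFrame(out)[list(PARTICIPANT_COLUMNS)]
    edges = None
    if edge_list is not None:
        el = pd.read_csv(edge_list, dtype=str)
        if el.shape[1] < 2:
            raise SchemaError("edge list must have two columns (recruiter_id, recruit_id)")
        edges = list(zip(el.iloc[:, 0].astype(str), el.iloc[:, 1].astype(str)))
    return build_dataset(clean, coupon_limit=coupon_limit, edges=edges)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the participant table with the canonical column set (UTF-8 CSV)."""
    df = dataset.participants.copy()
    for col in BOOLEAN_FIELDS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else ("yes" if v else "no"))
    df.to_csv(path, index=False)


def write_edge_list(dataset: StudyDataset, path: str | Path) -> None:
    """Two-column recruiter -> recruit CSV for network-visualization tools."""
    edges = dataset.forest.edges()
    pd.DataFrame(edges, columns=["recruiter_id", "recruit_id"]).to_csv(path, index=False)
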