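"""CSV and JSON plumbing for the pipeline.

All files are UTF-8 comma-separated with a header row; missing values are
empty fields.  The literal ``never`` is allowed only in the milestone age
column (a milestone reported as never observed, encoded in memory as +inf).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cascade import ChildRecord
from .hd import CentileTable, centile_label
from .items import AssessmentRecord, DomainScore

#: printf format preserving float64 exactly across a CSV round-trip
FLOAT_FMT = "%.17g"


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a pipeline CSV losslessly (UTF-8, header row, empty = missing)."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


COHORT_COLUMNS = [
    "child_id",
    "site",
    "sex",
    "ga_weeks",
    "neuro_morbidity",
    "maternal_mh",
    "cbcl_attention_centile",
    "cbcl_emotional_centile",
    "age_months",
    "assessment_complete",
]


def write_cohort_csv(children: Sequence[ChildRecord], path) -> None:
    rows = [
        {
            "child_id": c.child_id,
            "site": c.site,
            "sex": c.sex,
            "ga_weeks": c.gestational_age_at_birth,
            "neuro_morbidity": int(c.postnatal_neuro_morbidity),
            "maternal_mh": int(c.maternal_mental_health_dx),
            "cbcl_attention_centile": c.cbcl_attention_centile,
            "cbcl_emotional_centile": c.cbcl_emotional_centile,
            "age_months": c.age_at_assessment,
            "assessment_complete": int(c.assessment_complete),
        }
        for c in children
    ]
    write_csv(pd.DataFrame(rows, columns=COHORT_COLUMNS), path)


def read_cohort_csv(path) -> list[ChildRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                ChildRecord(
                    child_id=str(row["child_id"]),
                    site=str(row["site"]),
                    sex=str(row["sex"]),
                    gestational_age_at_birth=float(row["ga_weeks"]),
                    postnatal_neuro_morbidity=bool(int(row["neuro_morbidity"])),
                    maternal_mental_health_dx=bool(int(row["maternal_mh"])),
                    cbcl_attention_centile=_opt_float(row["cbcl_attention_centile"]),
                    cbcl_emotional_centile=_opt_float(row["cbcl_emotional_centile"]),
                    age_at_assessment=float(row["age_months"]),
                    assessment_complete=bool(int(row["assessment_complete"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"cohort CSV row {idx + 2}: {exc}") from exc
    return out


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def write_items_csv(assessments: Sequence[AssessmentRecord], path) -> None:
    rows = [
        {"child_id": a.child_id, "age_months": a.age_at_assessment,
         "item_id": item_id, "score": score}
        for a in assessments
        for item_id, score in a.responses.items()
    ]
    write_csv(pd.DataFrame(rows, columns=["child_id", "age_months", "item_id", "score"]), path)


def read_items_csv(path) -> list[AssessmentRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    for col in ("child_id", "item_id", "score"):
        if col not in df.columns:
            raise ValueError(f"item CSV missing column {col!r}")
    has_age = "age_months" in df.columns
    out = []
    for child_id, grp in df.groupby("child_id", sort=False):
        age = float(grp["age_months"].iloc[0]) if has_age else 0.0
        responses = {
            str(r["item_id"]): int(r["score"]) for _, r in grp.iterrows()
        }
        out.append(
            AssessmentRecord(
                child_id=str(child_id), age_at_assessment=age, responses=responses
            )
        )
    return out


def write_scores_csv(
    scores_by_child: dict[str, Iterable[DomainScore]], path
) -> None:
    rows = []
    for child_id, scores in scores_by_child.items():
        for s in scores:
            rows.append(
                {
                    "child_id": child_id,
                    "domain": s.domain,
                    "raw_mean": s.raw_mean,
                    "scaled": s.scaled,
                    "n_items_answered": s.n_items_answered,
                    "completeness": s.completeness,
                }
            )
    write_csv(
        pd.DataFrame(
            rows,
            columns=["child_id", "domain", "raw_mean", "scaled",
                     "n_items_answered", "completeness"],
        ),
        path,
    )


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"child_id", "domain", "scaled"}
    if not df.empty and (missing := needed - set(df.columns)):
        raise ValueError(f"scores CSV missing column(s): {sorted(missing)}")
    return df


def write_milestones_csv(milestones: pd.DataFrame, path) -> None:
    df = milestones.copy()
    df["age_months"] = df["age_months"].map(
        lambda v: "never" if v == np.inf else ("" if pd.isna(v) else FLOAT_FMT % v)
    )
    df.to_csv(path, index=False)


def read_milestones_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"age_months": str}, keep_default_na=False)
    def parse(v: str) -> float:
        if v == "never":
            return np.inf
        if v == "":
            return np.nan
        return float(v)
    df["age_months"] = df["age_months"].map(parse)
    return df


def write_centile_table(table: CentileTable, json_path=None, csv_path=None) -> None:
    """Serialise a centile table as JSON and/or a CSV in the standards layout
    (rows = domains, columns = centile labels)."""
    if json_path is not None:
        payload = {
            "source": table.source,
            "centiles": list(table.centiles),
            "n": table.n,
            "low_confidence": table.low_confidence,
            "values": table.values,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
    if csv_path is not None:
        table.to_frame().rename_axis("domain").to_csv(csv_path)


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    stage: str
    config_hash: str
    seed: int | None = None
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    record_counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
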