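"""Cohort readers/writers, report serialization and configuration.

Native cohort format: a UTF-8 CSV with header columns

    id, age, sex, side, deformity,
    ext_medial_mm, ext_lateral_mm, flex_medial_mm, flex_lateral_mm
    [, final_ext_medial_mm, final_ext_lateral_mm,
       final_flex_medial_mm, final_flex_lateral_mm]

Laxities are millimetres with a decimal point; ids must be unique;
demographics are optional (empty cells allowed). Values are rounded
half-up to 0.1 mm on ingestion.

SPSS ``.sav`` ingestion (the deposited study file) goes through a column
map — source variable name → schema column — supplied in the configuration,
so uncertainty about the deposited file's variable naming is isolated in
config, not code. Reading .sav requires the optional ``pyreadstat``
dependency.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    BalancedAreaPolicy,
    KneeLaxityProfile,
    LaxityPair,
    LaxityValidationError,
    PHENOTYPE_LABELS,
    ThresholdScheme,
    round_half_up,
)
from .pipeline import (
    KneeRecord,
    Phase1Report,
    Phase2Report,
    PhenotypeDistribution,
    TransitionTable,
)

__all__ = [
    "LAXITY_COLUMNS",
    "FINAL_LAXITY_COLUMNS",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "write_report",
    "read_report_json",
    "scheme_to_dict",
    "scheme_from_dict",
    "policy_from_dict",
    "load_config",
]

LAXITY_COLUMNS = ("ext_medial_mm", "ext_lateral_mm", "flex_medial_mm", "flex_lateral_mm")
FINAL_LAXITY_COLUMNS = tuple(f"final_{c}" for c in LAXITY_COLUMNS)
_DEMOGRAPHIC_COLUMNS = ("age", "sex", "side", "deformity")
_SEX = {"F", "M"}
_SIDE = {"L", "R"}
_DEFORMITY = {"varus", "valgus"}


class CohortSchemaError(LaxityValidationError):
    """A cohort file violates the schema; message names row and column."""


def _parse_laxity(raw: Any, row: int, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise CohortSchemaError(f"row {row}, column {column!r}: not a number: {raw!r}")
    try:
        return round_half_up(value, 0.1)
    except Exception:
        raise CohortSchemaError(f"row {row}, column {column!r}: invalid laxity {value!r}")


def _build_profile(values: Mapping[str, float], prefix: str, row: int) -> KneeLaxityProfile:
    def pair(pos: str) -> LaxityPair:
        med = values[f"{prefix}{pos}_medial_mm"]
        lat = values[f"{prefix}{pos}_lateral_mm"]
        try:
            return LaxityPair(med, lat)
        except LaxityValidationError as exc:
            raise CohortSchemaError(f"row {row}: {exc}") from exc

    return KneeLaxityProfile(extension=pair("ext"), flexion=pair("flex"))


def _frame_to_cohort(df: pd.DataFrame, source: str) -> list[KneeRecord]:
    missing = [c for c in ("id", *LAXITY_COLUMNS) if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{source}: missing required columns {missing}")
    has_final = all(c in df.columns for c in FINAL_LAXITY_COLUMNS)
    ids_seen: set[str] = set()
    records: list[KneeRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rid = str(row["id"]).strip()
        if not rid or rid.lower() == "nan":
            raise CohortSchemaError(f"row {i}: empty id")
        if rid in ids_seen:
            raise CohortSchemaError(f"row {i}: duplicate id {rid!r}")
        ids_seen.add(rid)

        laxities = {c: _parse_laxity(row[c], i, c) for c in LAXITY_COLUMNS}
        initial = _build_profile(laxities, "", i)
        final = None
        if has_final and not any(pd.isna(row[c]) for c in FINAL_LAXITY_COLUMNS):
            finals = {c: _parse_laxity(row[c], i, c) for c in FINAL_LAXITY_COLUMNS}
            final = _build_profile(finals, "final_", i)

        demo: dict[str, Any] = {}
        for col in _DEMOGRAPHIC_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                demo[col] = row[col]
        age = float(demo["age"]) if "age" in demo else None
        sex = str(demo.get("sex", "")).strip() or None
        side = str(demo.get("side", "")).strip() or None
        deformity = str(demo.get("deformity", "")).strip() or None
        if sex is not None and sex not in _SEX:
            raise CohortSchemaError(f"row {i}, column 'sex': expected F/M, got {sex!r}")
        if side is not None and side not in _SIDE:
            raise CohortSchemaError(f"row {i}, column 'side': expected L/R, got {side!r}")
        if deformity is not None and deformity not in _DEFORMITY:
            raise CohortSchemaError(
                f"row {i}, column 'deformity': expected varus/valgus, got {deformity!r}"
            )
        records.append(
            KneeRecord(
                id=rid, initial=initial, final=final,
                age=age, sex=sex, side=side, deformity=deformity,
            )
        )
    if not records:
        raise CohortSchemaError(f"{source}: no records")
    return records


def read_cohort(
    path: str | Path,
    fmt: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> list[KneeRecord]:
    """Read a cohort from CSV (native schema) or SPSS .sav (via a column map).

    ``column_map`` maps source variable names to schema columns and is
    required for .sav input. Every laxity is validated (finite, >= 0,
    sanity-bounded) and rounded half-up to 0.1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "sav":
        if column_map is None:
            raise CohortSchemaError(".sav ingestion requires a column_map in the configuration")
        try:
            import pyreadstat  # type: ignore[import-not-found]
        except ImportError as exc:
            raise RuntimeError(
                "reading SPSS .sav files requires the optional dependency "
                "'pyreadstat' (pip install real-laxity[sav])"
            ) from exc
        df, _ = pyreadstat.read_sav(str(path))
    else:
        raise CohortSchemaError(f"unknown cohort format {fmt!r}")

    if column_map:
        unknown_targets = set(column_map.values()) - {
            "id", *LAXITY_COLUMNS, *FINAL_LAXITY_COLUMNS, *_DEMOGRAPHIC_COLUMNS
        }
        if unknown_targets:
            raise CohortSchemaError(
                f"column_map targets unknown schema columns: {sorted(unknown_targets)}"
            )
        targets = list(column_map.values())
        dup = {t for t in targets if targets.count(t) > 1}
        if dup:
            raise CohortSchemaError(f"column_map maps these targets twice: {sorted(dup)}")
        missing_src = [s for s in column_map if s not in df.columns]
        if missing_src:
            raise CohortSchemaError(
                f"{path.name}: source variables not found: {missing_src}"
            )
        df = df.rename(columns=dict(column_map))
    return _frame_to_cohort(df, path.name)


def write_cohort(cohort: Sequence[KneeRecord], path: str | Path) -> Path:
    """Write a cohort to the native CSV schema (laxities at 0.1 mm)."""
    path = Path(path)
    has_final = any(r.final is not None for r in cohort)
    columns = ["id", *_DEMOGRAPHIC_COLUMNS, *LAXITY_COLUMNS]
    if has_final:
        columns += list(FINAL_LAXITY_COLUMNS)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in cohort:
            row: list[Any] = [
                r.id,
                "" if r.age is None else r.age,
                r.sex or "", r.side or "", r.deformity or "",
            ]
            for profile in (r.initial, r.final) if has_final else (r.initial,):
                if profile is None:
                    row += ["", "", "", ""]
                else:
                    row += [
                        f"{profile.extension.medial_mm:.1f}",
                        f"{profile.extension.lateral_mm:.1f}",
                        f"{profile.flexion.medial_mm:.1f}",
                        f"{profile.flexion.lateral_mm:.1f}",
                    ]
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# report serialization

def _distribution_payload(dist: PhenotypeDistribution) -> dict[str, Any]:
    return {
        "n": dist.n,
        "counts": dict(dist.counts),
        "percentages": dist.percentages,
    }


def scheme_to_dict(scheme: ThresholdScheme) -> dict[str, float]:
    return {"limit1_mm": scheme.limit1_mm, "limit2_mm": scheme.limit2_mm}


def scheme_from_dict(data: Mapping[str, Any]) -> ThresholdScheme:
    return ThresholdScheme(
        limit1_mm=float(data["limit1_mm"]),
        limit2_mm=float(data["limit2_mm"]) if data.get("limit2_mm") is not None else None,
    )


def policy_from_dict(data: Mapping[str, Any]) -> BalancedAreaPolicy:
    return BalancedAreaPolicy(
        balanced_labels=frozenset(data.get("balanced", ["1A"])),
        almost_balanced_labels=frozenset(data.get("almost_balanced", ["1B", "2A"])),
    )


def report_to_dict(report: Phase1Report | Phase2Report) -> dict[str, Any]:
    if isinstance(report, Phase1Report):
        return {
            "kind": "phase1",
            "summaries": {k: dataclasses.asdict(v) for k, v in report.summaries.items()},
            "normality": {k: dataclasses.asdict(v) for k, v in report.normality.items()},
            "scheme": scheme_to_dict(report.scheme),
            "derived_from": list(report.derived_from),
            "distribution": _distribution_payload(report.distribution),
        }
    return {
        "kind": "phase2",
        "scheme": scheme_to_dict(report.scheme),
        "policy": {
            "balanced": sorted(report.policy.balanced_labels),
            "almost_balanced": sorted(report.policy.almost_balanced_labels),
        },
        "initial_distribution": _distribution_payload(report.initial_distribution),
        "final_distribution": _distribution_payload(report.final_distribution),
        "transitions": {
            ini: dict(row) for ini, row in report.transitions.counts.items()
        },
        "balanced_percentage": report.balanced_percentage,
    }


def _distribution_csv_rows(dist: PhenotypeDistribution) -> list[list[str]]:
    rows = [["class", "count", "percentage"]]
    pct = dist.percentages
    for label in PHENOTYPE_LABELS:
        c = dist.counts[label]
        # published tables print "-" for empty cells
        rows.append([label, str(c) if c else "-", f"{pct[label]:.1f}" if c else "-"])
    return rows


def write_report(
    report: Phase1Report | Phase2Report, path: str | Path, fmt: str = "json"
) -> Path:
    """Serialize a phase report to JSON (full fidelity) or CSV (tables)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n", encoding="utf-8")
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            if isinstance(report, Phase1Report):
                writer.writerow(["table", "initial distribution"])
                writer.writerows(_distribution_csv_rows(report.distribution))
            else:
                writer.writerow(["table", "initial distribution"])
                writer.writerows(_distribution_csv_rows(report.initial_distribution))
                writer.writerow([])
                writer.writerow(["table", "final distribution"])
                writer.writerows(_distribution_csv_rows(report.final_distribution))
                writer.writerow([])
                writer.writerow(["balanced_percentage", f"{report.balanced_percentage:.1f}"])
    else:
        raise LaxityValidationError(f"unknown report format {fmt!r}")
    return path


def read_report_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load the YAML configuration (generator params, column maps, scheme
    and policy overrides)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise LaxityValidationError("configuration root must be a mapping")
    return data
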