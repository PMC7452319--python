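"""File round-tripping: bioassay CSV, compatibility CSV, configs and reports.

The bioassay CSV schema is::

    treatment_id,dose,unit,n_exposed,n_dead,replicate,is_control

UTF-8, header required, "." decimal point.  Reports mirror the classic
mixture-virulence table: one row per ratio with the regression equation,
r^2, LC50 and CTC (all to two decimals) plus the interaction label.
Numbers are rounded only at serialization; the report layer never
recomputes anything.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bioassay import BioassayRecord
from .cotoxicity import CoToxicityResult
from .dose_response import DoseResponseFit
from .exceptions import InputDataError, UnitMismatchError

__all__ = [
    "BIOASSAY_COLUMNS",
    "read_bioassay_table",
    "write_bioassay_table",
    "read_compatibility_table",
    "write_ctc_report",
    "RunConfig",
]

BIOASSAY_COLUMNS = ["treatment_id", "dose", "unit", "n_exposed", "n_dead", "replicate", "is_control"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(s: str, line: int) -> bool:
    v = s.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise InputDataError(f"line {line}: is_control must be true/false, got {s!r}")


def read_bioassay_table(path: str | Path) -> list[BioassayRecord]:
    """Read a bioassay CSV into typed records.

    Malformed rows are reported with their 1-based line number; unit
    consistency is enforced per treatment.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputDataError(f"{path}: empty file")
        missing = set(BIOASSAY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise InputDataError(f"{path}: missing required column(s): {sorted(missing)}")
        records: list[BioassayRecord] = []
        errors: list[str] = []
        units: dict[str, str] = {}
        for line, row in enumerate(reader, start=2):
            try:
                rec = BioassayRecord(
                    treatment_id=row["treatment_id"].strip(),
                    dose=float(row["dose"]),
                    unit=row["unit"].strip(),
                    n_exposed=int(row["n_exposed"]),
                    n_dead=int(row["n_dead"]),
                    replicate=int(row["replicate"]),
                    is_control=_parse_bool(row["is_control"], line),
                )
            except (ValueError, InputDataError) as exc:
                errors.append(f"line {line}: {exc}")
                continue
            prior = units.setdefault(rec.treatment_id, rec.unit)
            if prior != rec.unit:
                raise UnitMismatchError(
                    f"line {line}: treatment {rec.treatment_id!r} mixes units "
                    f"{prior!r} and {rec.unit!r}"
                )
            records.append(rec)
    if errors:
        raise InputDataError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    if not records:
        raise InputDataError(f"{path}: no data rows")
    return records


def write_bioassay_table(records: list[BioassayRecord], path: str | Path) -> None:
    """Write records to the standard bioassay CSV (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BIOASSAY_COLUMNS)
        for r in records:
            writer.writerow(
                [r.treatment_id, repr(r.dose), r.unit, r.n_exposed, r.n_dead, r.replicate,
                 str(r.is_control).lower()]
            )


def read_compatibility_table(path: str | Path) -> pd.DataFrame:
    """Read the compatibility CSV (concentration, unit, replicate,
    colony_diameter_cm, germinated, observed)."""
    df = pd.read_csv(path)
    required = {"concentration", "unit", "replicate", "colony_diameter_cm", "germinated", "observed"}
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: missing required column(s): {sorted(missing)}")
    return df


def _report_rows(results: list[tuple[str, DoseResponseFit, CoToxicityResult]]) -> list[dict]:
    rows = []
    for ratio_label, fit, res in results:
        rows.append(
            {
                "ratio": ratio_label,
                "regression_equation": fit.equation_text(),
                "r_squared": round(fit.r_squared, 2),
                "lc50": round(res.lc50_m, 2),
                "ctc": round(res.ctc, 2),
                "classification": res.label,
            }
        )
    return rows


def write_ctc_report(
    results: list[tuple[str, DoseResponseFit, CoToxicityResult]],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Serialize the mixture-virulence report in csv, json or text form.

    One row per mixture ratio: regression equation of the mixture fit,
    r^2, mixture LC50, CTC and the interaction classification.
    """
    if not results:
        raise InputDataError("no results to report")
    rows = _report_rows(results)
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
    elif format == "text":
        widths = {k: max(len(k), *(len(str(r[k])) for r in rows)) for k in rows[0]}
        lines = ["  ".join(k.ljust(widths[k]) for k in rows[0])]
        lines.append("  ".join("-" * widths[k] for k in rows[0]))
        for r in rows:
            lines.append("  ".join(str(r[k]).ljust(widths[k]) for k in r))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise InputDataError(f"unknown report format {format!r} (use csv, json or text)")


@dataclass
class RunConfig:
    """A CTC analysis run: which treatment plays which role.

    JSON schema::

        {
          "input": "assays.csv",
          "agent_a": "azadirachtin",
          "agent_b": "beauveria",
          "mixtures": [{"id": "mix_1to4", "ratio": [1, 4]}, ...],
          "model": "linear",
          "n_boot": 1000, "level": 0.95, "seed": 0,
          "output": "report.csv", "format": "csv"
        }
    """

    input: str
    agent_a: str
    agent_b: str
    mixtures: list[dict]
    model: str = "linear"
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    output: str = "report.csv"
    format: str = "csv"

    def __post_init__(self) -> None:
        ids = [m["id"] for m in self.mixtures]
        if len(ids) != len(set(ids)):
            raise InputDataError("each mixture id may map to only one ratio")
        for m in self.mixtures:
            if "id" not in m or "ratio" not in m:
                raise InputDataError("every mixture entry needs 'id' and 'ratio'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def check_ids(self, records: list[BioassayRecord]) -> None:
        present = {r.treatment_id for r in records}
        wanted = {self.agent_a, self.agent_b, *(m["id"] for m in self.mixtures)}
        missing = wanted - present
        if missing:
            raise InputDataError(f"treatment id(s) not found in input: {sorted(missing)}")
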