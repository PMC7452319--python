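"""Chemical-fungus compatibility: mycelial growth inhibition and spore germination.

Before mixing a chemical pesticide with an entomopathogenic fungus, one
checks that the chemical does not suppress the fungus itself.  Two classic
plate metrics are used:

* colony growth inhibition on amended medium,
  ``(control diameter - test diameter) / control diameter x 100``;
* spore (conidial) germination percentage under the haemocytometer,
  ``germinated / observed x 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputDataError

__all__ = [
    "CompatibilityResult",
    "inhibition_rate",
    "germination_rate",
    "summarize_compatibility",
]


@dataclass(frozen=True)
class CompatibilityResult:
    """Per-concentration compatibility summary (means over replicate plates)."""

    concentration: float
    unit: str
    mean_control_diameter: float
    mean_test_diameter: float
    inhibition_pct: float
    inhibition_sd: float | None
    germinated: int
    observed: int
    germination_pct: float

    def to_dict(self) -> dict:
        return {
            "concentration": self.concentration,
            "unit": self.unit,
            "mean_control_diameter_cm": self.mean_control_diameter,
            "mean_test_diameter_cm": self.mean_test_diameter,
            "inhibition_pct": self.inhibition_pct,
            "inhibition_sd": self.inhibition_sd,
            "germinated": self.germinated,
            "observed": self.observed,
            "germination_pct": self.germination_pct,
        }


def inhibition_rate(control_diameter: float, test_diameter: float) -> float:
    """Colony growth inhibition in percent.

    Negative values (test colony larger than control, i.e. growth
    stimulation) are returned as-is with a warning.
    """
    if control_diameter <= 0:
        raise DomainError(f"control diameter must be positive, got {control_diameter}")
    if test_diameter < 0:
        raise DomainError(f"test diameter must be non-negative, got {test_diameter}")
    rate = (control_diameter - test_diameter) / control_diameter * 100.0
    if rate < 0:
        warnings.warn(
            f"negative inhibition ({rate:.1f}%): test colony outgrew the control "
            "(growth stimulation)",
            stacklevel=2,
        )
    return rate


def germination_rate(germinated: int, observed: int) -> float:
    """Spore germination in percent of observed spores."""
    if observed <= 0:
        raise DomainError(f"observed spore count must be positive, got {observed}")
    if germinated < 0 or germinated > observed:
        raise InputDataError(
            f"germinated count must satisfy 0 <= germinated <= observed, got {germinated}/{observed}"
        )
    return germinated / observed * 100.0


def summarize_compatibility(
    df: pd.DataFrame,
    subtract_plug: bool = False,
    plug_diameter_cm: float = 0.5,
) -> list[CompatibilityResult]:
    """Summarise a replicate-level compatibility table per concentration.

    ``df`` needs columns ``concentration, unit, replicate,
    colony_diameter_cm, germinated, observed``; rows with concentration 0
    are the unamended control plates.  Diameters are averaged per
    concentration before the inhibition formula; the per-replicate spread
    is reported as a standard deviation.  With ``subtract_plug=True`` the
    inoculation-plug diameter is removed from every measurement first, so
    inhibition refers to radial growth beyond the plug.
    """
    required = {"concentration", "unit", "replicate", "colony_diameter_cm", "germinated", "observed"}
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"compatibility table missing columns: {sorted(missing)}")
    df = df.copy()
    if subtract_plug:
        df["colony_diameter_cm"] = df["colony_diameter_cm"] - plug_diameter_cm
        if (df["colony_diameter_cm"] < 0).any():
            raise InputDataError("colony diameter below plug diameter after subtraction")

    controls = df[df["concentration"] == 0]
    if controls.empty:
        raise InputDataError("no control plates (concentration 0) in the table")
    control_mean = float(controls["colony_diameter_cm"].mean())

    results = []
    for conc, grp in df[df["concentration"] > 0].groupby("concentration"):
        units = set(grp["unit"])
        if len(units) > 1:
            raise InputDataError(f"mixed units at concentration {conc}: {sorted(units)}")
        test_mean = float(grp["colony_diameter_cm"].mean())
        per_rep = [
            inhibition_rate(control_mean, d) for d in grp["colony_diameter_cm"]
        ]
        germinated = int(grp["germinated"].sum())
        observed = int(grp["observed"].sum())
        results.append(
            CompatibilityResult(
                concentration=float(conc),
                unit=units.pop(),
                mean_control_diameter=control_mean,
                mean_test_diameter=test_mean,
                inhibition_pct=inhibition_rate(control_mean, test_mean),
                inhibition_sd=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else None,
                germinated=germinated,
                observed=observed,
                germination_pct=germination_rate(germinated, observed),
            )
        )
    return results
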