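"""Core bioassay data model, Abbott control correction and assay validation.

A bioassay exposes batches of insects to a dose gradient of an agent and
records the number dead at a fixed endpoint (here, day 7).  Replicates at
the same dose are pooled before model fitting, and observed mortality is
corrected for background (control) mortality with Abbott's formula

    p_corrected = (p_treatment - p_control) / (1 - p_control).

Mortality is handled internally as a fraction in [0, 1]; percentages only
appear at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InputDataError

__all__ = [
    "BioassayRecord",
    "MortalityTable",
    "Finding",
    "abbott_correct",
    "aggregate_mortality",
    "validate_assay",
]


@dataclass(frozen=True)
class BioassayRecord:
    """One dose x replicate observation.

    Parameters
    ----------
    treatment_id
        Label of the agent or mixture (e.g. ``"azadirachtin"`` or ``"mix_1:4"``).
    dose
        Concentration in ``unit``; 0 for control batches.
    unit
        Declared dose unit, e.g. ``"mg/L"`` or ``"conidia/mL"``.
    n_exposed, n_dead
        Insects exposed / dead at the endpoint.
    replicate
        Replicate index within the treatment.
    is_control
        True iff this is an untreated (dose 0) batch.
    """

    treatment_id: str
    dose: float
    unit: str
    n_exposed: int
    n_dead: int
    replicate: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.n_exposed <= 0:
            raise InputDataError(f"n_exposed must be positive, got {self.n_exposed}")
        if self.n_dead < 0 or self.n_dead > self.n_exposed:
            raise InputDataError(
                f"n_dead must satisfy 0 <= n_dead <= n_exposed, got "
                f"{self.n_dead}/{self.n_exposed}"
            )
        if self.dose < 0:
            raise InputDataError(f"dose must be non-negative, got {self.dose}")
        # control flag and zero dose must agree
        if self.is_control != (self.dose == 0):
            raise InputDataError(
                f"is_control={self.is_control} inconsistent with dose={self.dose}: "
                "control records must have dose 0 and vice versa"
            )


@dataclass
class MortalityTable:
    """Per-dose pooled mortality for one treatment, Abbott-corrected.

    ``doses`` are strictly increasing and positive; control batches are
    summarised by ``control_mortality`` (0 when no controls were run).
    """

    treatment_id: str
    unit: str
    doses: np.ndarray  # strictly increasing, > 0
    n_exposed: np.ndarray  # pooled per dose
    n_dead: np.ndarray  # pooled per dose
    raw_mortality: np.ndarray  # fractions
    corrected_mortality: np.ndarray  # fractions
    control_mortality: float = 0.0
    control_n: int = 0

    def __post_init__(self) -> None:
        for name in ("doses", "n_exposed", "n_dead", "raw_mortality", "corrected_mortality"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise InputDataError("doses must be strictly increasing and positive")
        for m in (self.raw_mortality, self.corrected_mortality):
            if np.any((m < 0) | (m > 1)):
                raise InputDataError("mortality fractions must lie in [0, 1]")

    @property
    def n_doses(self) -> int:
        return len(self.doses)


def abbott_correct(treatment_mortality: float, control_mortality: float) -> float:
    """Correct treatment mortality for background control mortality.

    Returns ``(p_t - p_c) / (1 - p_c)`` clamped to [0, 1].  Clamping only
    triggers when treatment mortality falls below control mortality, which
    is sampling noise under the model; a warning is emitted in that case.
    """
    p_t, p_c = float(treatment_mortality), float(control_mortality)
    if not (0.0 <= p_t <= 1.0 and 0.0 <= p_c <= 1.0):
        raise DomainError(f"mortality fractions must lie in [0, 1], got ({p_t}, {p_c})")
    if p_c >= 1.0:
        raise DomainError("control mortality of 1 leaves the correction undefined")
    corrected = (p_t - p_c) / (1.0 - p_c)
    if corrected < 0.0:
        warnings.warn(
            f"treatment mortality {p_t:.3f} below control {p_c:.3f}; "
            "corrected mortality clamped to 0",
            stacklevel=2,
        )
        corrected = 0.0
    return min(corrected, 1.0)


def aggregate_mortality(records: list[BioassayRecord]) -> MortalityTable:
    """Pool replicates per dose and apply Abbott's correction.

    All records must share one ``treatment_id`` and one unit.  Control
    records (dose 0) are pooled into a single control mortality; without
    controls the correction is the identity.
    """
    if not records:
        raise InputDataError("no records supplied")
    ids = {r.treatment_id for r in records}
    if len(ids) > 1:
        raise InputDataError(f"records mix treatment_ids: {sorted(ids)}")
    units = {r.unit for r in records}
    if len(units) > 1:
        raise InputDataError(f"records mix dose units: {sorted(units)}")

    seen: set[tuple[float, int]] = set()
    for r in records:
        key = (r.dose, r.replicate)
        if key in seen:
            raise InputDataError(f"duplicate (dose, replicate) observation: {key}")
        seen.add(key)

    controls = [r for r in records if r.is_control]
    treated = [r for r in records if not r.is_control]
    if not treated:
        raise InputDataError("no non-control dose records supplied")

    control_n = sum(r.n_exposed for r in controls)
    control_dead = sum(r.n_dead for r in controls)
    control_mortality = control_dead / control_n if control_n else 0.0

    by_dose: dict[float, list[BioassayRecord]] = {}
    for r in treated:
        by_dose.setdefault(r.dose, []).append(r)

    doses = np.array(sorted(by_dose), dtype=float)
    n_exposed = np.array([sum(r.n_exposed for r in by_dose[d]) for d in doses], dtype=float)
    n_dead = np.array([sum(r.n_dead for r in by_dose[d]) for d in doses], dtype=float)
    raw = n_dead / n_exposed
    corrected = np.array([abbott_correct(p, control_mortality) for p in raw])

    return MortalityTable(
        treatment_id=records[0].treatment_id,
        unit=records[0].unit,
        doses=doses,
        n_exposed=n_exposed,
        n_dead=n_dead,
        raw_mortality=raw,
        corrected_mortality=corrected,
        control_mortality=control_mortality,
        control_n=control_n,
    )


@dataclass(frozen=True)
class Finding:
    """One validation finding: ``level`` is 'pass', 'warning' or 'fail'."""

    level: str
    code: str
    message: str


def validate_assay(table: MortalityTable, max_control_mortality: float = 0.20) -> list[Finding]:
    """Check an assay against common quality rules.

    Flags excessive control mortality (assay rejection threshold, default
    20%), designs with fewer than 3 doses, and non-monotone corrected
    mortality (a warning: expected occasionally from binomial noise).
    Never mutates the table.
    """
    findings: list[Finding] = []

    if table.control_mortality > max_control_mortality:
        findings.append(
            Finding(
                "fail",
                "control_mortality",
                f"control mortality {table.control_mortality:.2%} exceeds "
                f"threshold {max_control_mortality:.2%}",
            )
        )
    else:
        findings.append(
            Finding("pass", "control_mortality", f"control mortality {table.control_mortality:.2%} acceptable")
        )

    if table.n_doses < 3:
        findings.append(Finding("fail", "n_doses", f"only {table.n_doses} dose level(s); at least 3 required"))
    else:
        findings.append(Finding("pass", "n_doses", f"{table.n_doses} dose levels"))

    if np.any(np.diff(table.corrected_mortality) < 0):
        findings.append(
            Finding("warning", "monotonicity", "corrected mortality is not monotone non-decreasing in dose")
        )
    else:
        findings.append(Finding("pass", "monotonicity", "corrected mortality monotone in dose"))

    return findings
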