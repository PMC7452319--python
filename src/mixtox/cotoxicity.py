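"""Co-toxicity coefficient (CTC) of a binary pesticide mixture.

The CTC compares the observed potency of a mixture M of agents A and B
against the potency expected under dose additivity.  With A as the
reference (toxicity index 100):

    TI(B)            = LC50_A / LC50_B x 100
    actual TI(M)     = LC50_A / LC50_M x 100
    theoretical TI(M)= TI(A) * w_A + TI(B) * w_B
    CTC              = actual TI(M) / theoretical TI(M) x 100

where w_A, w_B are the weight fractions of the agents in the mixture.
Algebraically the chain collapses to

    CTC = 100 * LC50_additive / LC50_M,
    LC50_additive = 1 / (w_A / LC50_A + w_B / LC50_B),

i.e. the mixture LC50 is compared with the weighted harmonic mean of the
component LC50s (the Loewe-additive reference).  CTC > 120 is scored as
synergism, CTC in [80, 120] as cumulative (additive) action, CTC < 80 as
antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .bioassay import BioassayRecord, aggregate_mortality
from .dose_response import estimate_lc, fit_linear_logdose, lc50_bootstrap_samples
from .exceptions import CIError, DomainError, InputDataError, UnitMismatchError

__all__ = [
    "MixtureRatio",
    "CoToxicityResult",
    "compute_ctc",
    "classify_interaction",
    "additive_lc50",
    "ctc_bootstrap",
]

InteractionLabel = Literal["synergism", "cumulative", "antagonism"]

SYNERGISM_THRESHOLD = 120.0
ANTAGONISM_THRESHOLD = 80.0


@dataclass(frozen=True)
class MixtureRatio:
    """Normalized weight fractions of agents A and B in a mixture."""

    w_a: float
    w_b: float

    def __post_init__(self) -> None:
        if self.w_a < 0 or self.w_b < 0:
            raise InputDataError(f"weight fractions must be non-negative: ({self.w_a}, {self.w_b})")
        if abs(self.w_a + self.w_b - 1.0) > 1e-9:
            raise InputDataError(f"weight fractions must sum to 1: ({self.w_a}, {self.w_b})")

    @classmethod
    def from_parts(cls, part_a: float, part_b: float) -> "MixtureRatio":
        """Build from integer parts, e.g. ``from_parts(9, 1)`` for a 9:1 mix."""
        total = part_a + part_b
        if total <= 0 or part_a < 0 or part_b < 0:
            raise InputDataError(f"ratio parts must be non-negative with positive sum: {part_a}:{part_b}")
        return cls(part_a / total, part_b / total)

    @property
    def label(self) -> str:
        return f"{self.w_a:g}:{self.w_b:g}"

    def swapped(self) -> "MixtureRatio":
        return MixtureRatio(self.w_b, self.w_a)


@dataclass(frozen=True)
class CoToxicityResult:
    """The full TI chain for one mixture, with interaction classification."""

    ti_a: float
    ti_b: float
    actual_ti: float
    theoretical_ti: float
    ctc: float
    label: InteractionLabel
    lc50_a: float
    lc50_b: float
    lc50_m: float
    unit: str
    ratio: MixtureRatio
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None

    def __post_init__(self) -> None:
        if abs(self.ctc - self.actual_ti / self.theoretical_ti * 100.0) > 1e-9 * self.ctc:
            raise DomainError("inconsistent CTC: must equal actual/theoretical TI x 100")
        if self.ti_a != 100.0:
            raise DomainError("the reference agent's toxicity index is 100 by definition")

    def to_dict(self) -> dict:
        d = {
            "ratio": self.ratio.label,
            "ti_a": self.ti_a,
            "ti_b": self.ti_b,
            "actual_ti": self.actual_ti,
            "theoretical_ti": self.theoretical_ti,
            "ctc": self.ctc,
            "label": self.label,
            "lc50_a": self.lc50_a,
            "lc50_b": self.lc50_b,
            "lc50_m": self.lc50_m,
            "unit": self.unit,
        }
        if self.ci_low is not None:
            d |= {"ci_low": self.ci_low, "ci_high": self.ci_high, "ci_level": self.ci_level}
        return d


def classify_interaction(ctc: float) -> InteractionLabel:
    """Score a CTC value: > 120 synergism, [80, 120] cumulative, < 80 antagonism.

    The boundaries are inclusive on the cumulative side ("between 80 and
    120"); synergism requires strictly more than 120 and antagonism
    strictly less than 80.
    """
    if not (ctc > 0 and np.isfinite(ctc)):
        raise DomainError(f"CTC must be positive and finite, got {ctc}")
    if ctc > SYNERGISM_THRESHOLD:
        return "synergism"
    if ctc < ANTAGONISM_THRESHOLD:
        return "antagonism"
    return "cumulative"


def _check_units(*units: str) -> str:
    distinct = set(units)
    if len(distinct) > 1:
        raise UnitMismatchError(
            f"LC50s carry different units {sorted(distinct)}; convert to a common "
            "potency unit before computing a CTC"
        )
    return units[0]


def additive_lc50(
    lc50_a: float,
    lc50_b: float,
    ratio: MixtureRatio,
    unit_a: str = "mg/L",
    unit_b: str = "mg/L",
) -> float:
    """LC50 the mixture would have under dose additivity (CTC = 100).

    This is the weighted harmonic mean ``1 / (w_a/LC50_a + w_b/LC50_b)``.
    """
    _check_units(unit_a, unit_b)
    if lc50_a <= 0 or lc50_b <= 0:
        raise DomainError(f"LC50s must be positive, got ({lc50_a}, {lc50_b})")
    return 1.0 / (ratio.w_a / lc50_a + ratio.w_b / lc50_b)


def compute_ctc(
    lc50_a: float,
    lc50_b: float,
    lc50_m: float,
    ratio: MixtureRatio,
    unit_a: str = "mg/L",
    unit_b: str = "mg/L",
    unit_m: str = "mg/L",
) -> CoToxicityResult:
    """Run the toxicity-index chain and classify the interaction.

    All three LC50s must be positive and share one declared unit; agent A
    is the index-100 reference.
    """
    unit = _check_units(unit_a, unit_b, unit_m)
    for name, v in (("lc50_a", lc50_a), ("lc50_b", lc50_b), ("lc50_m", lc50_m)):
        if not (v > 0 and np.isfinite(v)):
            raise DomainError(f"{name} must be positive and finite, got {v}")
    ti_b = lc50_a / lc50_b * 100.0
    actual_ti = lc50_a / lc50_m * 100.0
    theoretical_ti = 100.0 * ratio.w_a + ti_b * ratio.w_b
    ctc = actual_ti / theoretical_ti * 100.0
    return CoToxicityResult(
        ti_a=100.0,
        ti_b=ti_b,
        actual_ti=actual_ti,
        theoretical_ti=theoretical_ti,
        ctc=ctc,
        label=classify_interaction(ctc),
        lc50_a=lc50_a,
        lc50_b=lc50_b,
        lc50_m=lc50_m,
        unit=unit,
        ratio=ratio,
    )


def ctc_bootstrap(
    records_a: list[BioassayRecord],
    records_b: list[BioassayRecord],
    records_m: list[BioassayRecord],
    ratio: MixtureRatio,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    resample: str = "insect",
) -> CoToxicityResult:
    """Joint bootstrap CI for the CTC, deterministic per seed.

    Each of the three assays is resampled independently (stratified by
    dose), the three LC50s are refitted per replicate and pushed through
    the CTC formula; the CI is the percentile interval of the resulting
    CTC samples.  More than 50% failed replicates raises :class:`CIError`.
    """
    fits = [
        estimate_lc(fit_linear_logdose(aggregate_mortality(recs)), 0.5)
        for recs in (records_a, records_b, records_m)
    ]
    unit = _check_units(*(f.unit for f in fits))
    point = compute_ctc(fits[0].value, fits[1].value, fits[2].value, ratio, unit, unit, unit)

    ss = np.random.SeedSequence(seed)
    samples = []
    for recs, child in zip((records_a, records_b, records_m), ss.spawn(3)):
        rng = np.random.default_rng(child)
        samples.append(
            lc50_bootstrap_samples(recs, p=0.5, n_boot=n_boot, rng=rng, resample=resample)
        )
    lc_a, lc_b, lc_m = samples
    with np.errstate(divide="ignore", invalid="ignore"):
        add = 1.0 / (ratio.w_a / lc_a + ratio.w_b / lc_b)
        ctc_samples = 100.0 * add / lc_m
    valid = ctc_samples[np.isfinite(ctc_samples) & (ctc_samples > 0)]
    if len(valid) < 0.5 * n_boot:
        raise CIError(
            f"{n_boot - len(valid)}/{n_boot} bootstrap replicates failed to yield a "
            "CTC; check that each assay supports a positive-slope fit"
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
    lo, hi = min(float(lo), point.ctc), max(float(hi), point.ctc)
    return CoToxicityResult(
        ti_a=point.ti_a,
        ti_b=point.ti_b,
        actual_ti=point.actual_ti,
        theoretical_ti=point.theoretical_ti,
        ctc=point.ctc,
        label=point.label,
        lc50_a=point.lc50_a,
        lc50_b=point.lc50_b,
        lc50_m=point.lc50_m,
        unit=unit,
        ratio=ratio,
        ci_low=lo,
        ci_high=hi,
        ci_level=level,
    )
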