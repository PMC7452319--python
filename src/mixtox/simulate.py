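"""Synthetic bioassay generator with known ground truth.

No public dataset accompanies the mixture-bioassay workflow, so validation
rests on simulation: mortality is generated from a probit dose-response

    p(d) = c + (1 - c) * Phi(slope * (log10 d - log10 LC50)),

with ``c`` the background (control) mortality, and dead counts drawn
Binomial(n_exposed, p) per replicate.  The generative truth model is a
probit sigmoid even though the analysis pipeline offers a simpler linear
log-dose fit — that mirrors real assays, where the linear "virulence
equation" is an approximation to sigmoid mortality, and lets the recovery
tests measure how well the simple estimator does on realistically curved
data.

Default design constants follow the standard whitefly nymph assay: 5 dose
levels spaced 10-fold, 3 replicates of 30 insects per dose, mortality read
at a fixed endpoint.  The true mixture LC50 is derived from a target CTC
through the additivity closed form ``LC50_M = LC50_additive * 100 / CTC``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .bioassay import BioassayRecord, MortalityTable, aggregate_mortality
from .cotoxicity import MixtureRatio, additive_lc50, compute_ctc
from .design import DilutionSeries, serial_dilution
from .dose_response import estimate_lc, fit_linear_logdose, fit_probit
from .exceptions import DomainError, FitError, InputDataError

__all__ = [
    "SimConfig",
    "simulate_bioassay",
    "simulate_mixture_experiment",
    "recovery_summary",
    "expected_mortality_table",
    "centered_series",
]


def centered_series(lc50: float, fold: float = 10.0, levels: int = 5, unit: str = "mg/L") -> DilutionSeries:
    """Dilution series whose geometric midpoint is ``lc50``.

    Emulates how an experimenter brackets the expected potency: the stock
    is chosen so the middle dilution lands on the anticipated LC50.
    """
    stock = lc50 * fold ** ((levels - 1) / 2)
    return serial_dilution(stock, fold=fold, levels=levels, unit=unit)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated binary-mixture experiment.

    ``true_ctc`` fixes the mixture's latent LC50 via the additivity closed
    form; slopes are probit slopes per log10-dose unit (1-3 is typical of
    insecticide assays).  Dose series default to 5-level 10-fold gradients
    centered on each treatment's true LC50.
    """

    true_lc50_a: float = 5.0
    true_lc50_b: float = 20.0
    unit: str = "mg/L"
    slope_a: float = 1.5
    slope_b: float = 1.5
    slope_m: float = 1.5
    true_ctc: float = 100.0
    ratio: MixtureRatio = field(default_factory=lambda: MixtureRatio.from_parts(1, 4))
    fold: float = 10.0
    levels: int = 5
    n_exposed: int = 30
    n_replicates: int = 3
    control_mortality: float = 0.0
    seed: int = 0
    series_a: DilutionSeries | None = None
    series_b: DilutionSeries | None = None
    series_m: DilutionSeries | None = None

    def __post_init__(self) -> None:
        for name in ("true_lc50_a", "true_lc50_b", "true_ctc", "slope_a", "slope_b", "slope_m"):
            if getattr(self, name) <= 0:
                raise InputDataError(f"{name} must be positive")
        if not 0 <= self.control_mortality < 1:
            raise InputDataError("control mortality must lie in [0, 1)")

    @property
    def true_lc50_m(self) -> float:
        """Latent mixture LC50 implied by the target CTC (closed form)."""
        return additive_lc50(self.true_lc50_a, self.true_lc50_b, self.ratio, self.unit, self.unit) * 100.0 / self.true_ctc

    def resolved_series(self) -> tuple[DilutionSeries, DilutionSeries, DilutionSeries]:
        mk = lambda lc: centered_series(lc, self.fold, self.levels, self.unit)
        return (
            self.series_a or mk(self.true_lc50_a),
            self.series_b or mk(self.true_lc50_b),
            self.series_m or mk(self.true_lc50_m),
        )

    def to_dict(self) -> dict:
        return {
            "true_lc50_a": self.true_lc50_a,
            "true_lc50_b": self.true_lc50_b,
            "unit": self.unit,
            "slope_a": self.slope_a,
            "slope_b": self.slope_b,
            "slope_m": self.slope_m,
            "true_ctc": self.true_ctc,
            "ratio": [self.ratio.w_a, self.ratio.w_b],
            "fold": self.fold,
            "levels": self.levels,
            "n_exposed": self.n_exposed,
            "n_replicates": self.n_replicates,
            "control_mortality": self.control_mortality,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "ratio" in d:
            w_a, w_b = d["ratio"]
            d["ratio"] = MixtureRatio(w_a, w_b)
        return cls(**d)


def _probit_mortality(dose: np.ndarray, lc50: float, slope: float, c: float) -> np.ndarray:
    p = ndtr(slope * (np.log10(dose) - np.log10(lc50)))
    return c + (1.0 - c) * p


def simulate_bioassay(
    lc50: float,
    slope: float,
    series: DilutionSeries,
    n_exposed: int = 30,
    n_replicates: int = 3,
    control_mortality: float = 0.0,
    seed: int | np.random.Generator = 0,
    treatment_id: str = "treatment",
) -> list[BioassayRecord]:
    """Draw one synthetic assay: binomial deaths at each dose x replicate.

    Control batches (dose 0, one per replicate) are always generated, with
    deaths drawn at the background mortality.  Byte-reproducible per seed.
    """
    if lc50 <= 0 or slope <= 0 or n_exposed <= 0 or n_replicates <= 0:
        raise InputDataError("lc50, slope and counts must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    doses = np.asarray(series.concentrations)
    probs = _probit_mortality(doses, lc50, slope, control_mortality)
    records: list[BioassayRecord] = []
    for rep in range(n_replicates):
        dead = rng.binomial(n_exposed, control_mortality)
        records.append(
            BioassayRecord(treatment_id, 0.0, series.unit, n_exposed, int(dead), rep, is_control=True)
        )
    for dose, p in zip(doses, probs):
        for rep in range(n_replicates):
            dead = int(rng.binomial(n_exposed, p))
            records.append(BioassayRecord(treatment_id, float(dose), series.unit, n_exposed, dead, rep))
    return records


def expected_mortality_table(lc50: float, slope: float, series: DilutionSeries, n_exposed_per_dose: float = 90.0) -> MortalityTable:
    """Noise-free assay: expected (non-integer) dead counts at each dose.

    Used to isolate the discretization error of a finite dose design from
    binomial sampling noise.
    """
    doses = np.asarray(series.concentrations)[::-1]
    p = _probit_mortality(doses, lc50, slope, 0.0)
    n = np.full_like(doses, n_exposed_per_dose)
    return MortalityTable(
        treatment_id="expected",
        unit=series.unit,
        doses=doses,
        n_exposed=n,
        n_dead=n * p,
        raw_mortality=p,
        corrected_mortality=p,
    )


def simulate_mixture_experiment(config: SimConfig) -> tuple[list[BioassayRecord], list[BioassayRecord], list[BioassayRecord], dict]:
    """Simulate agent A, agent B and mixture M assays plus a truth summary.

    The mixture's latent LC50 is ``additive_lc50 * 100 / true_ctc``.  A
    warning is emitted when that LC50 falls outside its dose series, since
    estimation must then extrapolate.
    """
    series_a, series_b, series_m = config.resolved_series()
    lc50_m = config.true_lc50_m
    if not (min(series_m.concentrations) <= lc50_m <= max(series_m.concentrations)):
        warnings.warn(
            f"true mixture LC50 {lc50_m:g} lies outside its dose series "
            f"[{min(series_m.concentrations):g}, {max(series_m.concentrations):g}]; "
            "estimates will extrapolate",
            stacklevel=2,
        )
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    common = dict(
        n_exposed=config.n_exposed,
        n_replicates=config.n_replicates,
        control_mortality=config.control_mortality,
    )
    rec_a = simulate_bioassay(config.true_lc50_a, config.slope_a, series_a,
                              seed=np.random.default_rng(kids[0]), treatment_id="agent_a", **common)
    rec_b = simulate_bioassay(config.true_lc50_b, config.slope_b, series_b,
                              seed=np.random.default_rng(kids[1]), treatment_id="agent_b", **common)
    rec_m = simulate_bioassay(lc50_m, config.slope_m, series_m,
                              seed=np.random.default_rng(kids[2]), treatment_id="mixture", **common)
    truth = {
        "lc50_a": config.true_lc50_a,
        "lc50_b": config.true_lc50_b,
        "lc50_m": lc50_m,
        "additive_lc50": additive_lc50(config.true_lc50_a, config.true_lc50_b, config.ratio, config.unit, config.unit),
        "ctc": config.true_ctc,
        "ratio": (config.ratio.w_a, config.ratio.w_b),
        "unit": config.unit,
    }
    return rec_a, rec_b, rec_m, truth


def estimate_ctc_from_records(
    records_a: list[BioassayRecord],
    records_b: list[BioassayRecord],
    records_m: list[BioassayRecord],
    ratio: MixtureRatio,
    model: str = "linear",
) -> dict:
    """Fit all three assays and push the LC50s through the CTC chain."""
    lcs = []
    for recs in (records_a, records_b, records_m):
        if model == "linear":
            fit = fit_linear_logdose(aggregate_mortality(recs))
        elif model == "probit":
            fit = fit_probit(recs)
        else:
            raise InputDataError(f"unknown model {model!r}")
        lcs.append(estimate_lc(fit, 0.5))
    res = compute_ctc(lcs[0].value, lcs[1].value, lcs[2].value, ratio,
                      lcs[0].unit, lcs[1].unit, lcs[2].unit)
    return {"lc50_a": lcs[0].value, "lc50_b": lcs[1].value, "lc50_m": lcs[2].value,
            "ctc": res.ctc, "label": res.label}


def experiment_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Per-experiment seed: SeedSequence keyed on (master_seed, index)."""
    return np.random.SeedSequence([int(master_seed), int(index)])


def recovery_summary(n_experiments: int, config: SimConfig, model: str = "linear") -> pd.DataFrame:
    """Repeated simulate -> fit -> CTC cycles; bias and RMSE per parameter.

    Per-experiment seeds derive from ``config.seed`` via a counter scheme
    (SeedSequence on the pair), so experiments are mutually independent but
    the whole table is a pure function of the master seed.  Fit failures
    are excluded and counted in the ``n_failed`` attribute column.
    """
    if n_experiments < 2:
        raise InputDataError("need at least 2 experiments for a recovery summary")
    rows = []
    n_failed = 0
    for i in range(n_experiments):
        seed_i = experiment_seed(config.seed, i)
        cfg_i = replace(config, seed=int(seed_i.generate_state(1)[0] % (2**31)))
        rec_a, rec_b, rec_m, truth = simulate_mixture_experiment(cfg_i)
        try:
            est = estimate_ctc_from_records(rec_a, rec_b, rec_m, config.ratio, model=model)
        except (FitError, DomainError):
            n_failed += 1
            continue
        rows.append(est | {"truth_" + k: v for k, v in truth.items() if isinstance(v, float)})
    if not rows:
        raise FitError("every simulated experiment failed to fit")
    df = pd.DataFrame(rows)
    out = []
    for param in ("lc50_a", "lc50_b", "lc50_m", "ctc"):
        est = df[param].to_numpy()
        truth_val = df["truth_" + param].iloc[0]
        out.append({
            "parameter": param,
            "truth": truth_val,
            "median_estimate": float(np.median(est)),
            "bias": float(np.mean(est) - truth_val),
            "rmse": float(np.sqrt(np.mean((est - truth_val) ** 2))),
            "n_experiments": len(est),
            "n_failed": n_failed,
        })
    return pd.DataFrame(out)
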