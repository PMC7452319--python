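"""Mortality-vs-log-dose model fitting and LC estimation.

Two models for the same estimand (the median lethal concentration):

* ``linear_logdose`` — ordinary least squares of Abbott-corrected mortality
  (on the percentage scale) against log10(concentration).  This is the
  simple "virulence equation" commonly used in mixture-toxicity work.
* ``probit`` — binomial maximum-likelihood regression of dead counts on
  log10(concentration) through the probit link, the field-standard model.

Both regress on log10 of the concentration in its declared unit; the
convention is recorded in every fit so LC values are reproducible from the
serialized summary alone.  Uncertainty comes from a nonparametric bootstrap
stratified by dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import ndtr, ndtri

from .bioassay import BioassayRecord, MortalityTable, aggregate_mortality
from .exceptions import CIError, DomainError, FitError

__all__ = [
    "DoseResponseFit",
    "LcEstimate",
    "fit_linear_logdose",
    "fit_probit",
    "estimate_lc",
    "bootstrap_lc_ci",
]

ResampleScheme = Literal["replicate", "insect"]


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted mortality-vs-log10(dose) model.

    ``slope`` and ``intercept`` are per log10-dose unit.  For
    ``linear_logdose`` the response is corrected mortality in percent; for
    ``probit`` it is the probit (standard-normal quantile) of corrected
    mortality.
    """

    model_kind: Literal["linear_logdose", "probit"]
    slope: float
    intercept: float
    r_squared: float
    chi_squared_gof: float
    dose_unit: str
    n_doses: int
    log_base: int = 10

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise FitError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict_mortality(self, dose: float | np.ndarray) -> np.ndarray:
        """Predicted corrected mortality fraction at ``dose`` (clamped to [0, 1])."""
        x = np.log10(np.asarray(dose, dtype=float))
        eta = self.intercept + self.slope * x
        if self.model_kind == "linear_logdose":
            return np.clip(eta / 100.0, 0.0, 1.0)
        return ndtr(eta)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "chi_squared_gof": self.chi_squared_gof,
            "unit": self.dose_unit,
            "n_doses": self.n_doses,
            "convention": "log10_concentration",
        }

    def equation_text(self) -> str:
        """Human-readable regression equation, e.g. ``y = 29.54x + 50.00``."""
        sign = "+" if self.intercept >= 0 else "-"
        return f"y = {self.slope:.2f}x {sign} {abs(self.intercept):.2f}"


@dataclass(frozen=True)
class LcEstimate:
    """An LC_p estimate (dose killing a fraction ``p``), optionally with CI."""

    p: float
    value: float
    unit: str
    method: str
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None

    def __post_init__(self) -> None:
        if not (self.value > 0 and np.isfinite(self.value)):
            raise DomainError(f"LC estimate must be positive and finite, got {self.value}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise DomainError("ci_low and ci_high must be given together")
        if self.ci_low is not None and not (self.ci_low <= self.value <= self.ci_high):
            raise DomainError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket estimate {self.value}"
            )

    def to_dict(self) -> dict:
        d = {"p": self.p, "value": self.value, "unit": self.unit, "method": self.method}
        if self.ci_low is not None:
            d |= {"ci_low": self.ci_low, "ci_high": self.ci_high, "ci_level": self.ci_level}
        return d


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS; returns (slope, intercept, r_squared)."""
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_tot = np.sum((y - ybar) ** 2)
    ss_res = np.sum((y - intercept - slope * x) ** 2)
    if ss_tot == 0:
        # constant response: the zero-slope fit reproduces the data exactly
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), float(min(r2, 1.0))


def _pearson_chi2(n: np.ndarray, dead: np.ndarray, p_hat: np.ndarray) -> float:
    """Binomial Pearson chi-square of observed vs expected dead counts.

    Doses whose expected dead (or expected alive) count is below 1 are
    merged with the next dose so the statistic is not dominated by
    near-empty cells.
    """
    p_hat = np.clip(p_hat, 1e-9, 1 - 1e-9)
    exp_dead = n * p_hat
    exp_alive = n * (1 - p_hat)

    # greedy left-to-right merge of deficient cells
    groups: list[tuple[float, float, float]] = []  # (n, dead, exp_dead)
    acc = np.zeros(3)
    for i in range(len(n)):
        acc += (n[i], dead[i], exp_dead[i])
        if acc[2] >= 1.0 and (acc[0] - acc[2]) >= 1.0:
            groups.append(tuple(acc))
            acc = np.zeros(3)
    if acc[0] > 0:
        if groups:
            last = groups.pop()
            acc += last
        groups.append(tuple(acc))

    chi2 = 0.0
    for gn, gdead, gexp in groups:
        var = gexp * (1 - gexp / gn)
        if var <= 0:
            continue
        chi2 += (gdead - gexp) ** 2 / var
    return float(chi2)


def fit_linear_logdose(table: MortalityTable) -> DoseResponseFit:
    """OLS fit of corrected mortality (%) on log10(dose).

    Requires at least two distinct positive doses.  A constant response
    yields a zero-slope fit with a warning (its LC50 is then undefined).
    """
    if table.n_doses < 2:
        raise FitError(f"need >= 2 distinct doses, got {table.n_doses}")
    x = np.log10(table.doses)
    y = table.corrected_mortality * 100.0
    slope, intercept, r2 = _ols(x, y)
    if slope == 0.0:
        warnings.warn("all corrected mortalities identical: zero-slope fit", stacklevel=2)
    p_hat = np.clip((intercept + slope * x) / 100.0, 0.0, 1.0)
    chi2 = _pearson_chi2(table.n_exposed, table.n_dead, p_hat)
    return DoseResponseFit(
        model_kind="linear_logdose",
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        chi_squared_gof=chi2,
        dose_unit=table.unit,
        n_doses=table.n_doses,
    )


def fit_probit(records: list[BioassayRecord]) -> DoseResponseFit:
    """Binomial ML probit regression of mortality on log10(dose).

    Control mortality is handled by Abbott pre-correction of the observed
    per-dose proportions; the corrected proportions are weighted by the
    pooled number exposed.  Complete separation (no dose with mortality
    strictly between 0 and 1) aborts with a :class:`FitError`.
    """
    import statsmodels.api as sm

    table = aggregate_mortality(records)
    if table.n_doses < 2:
        raise FitError(f"need >= 2 distinct doses, got {table.n_doses}")
    y = table.corrected_mortality
    if np.all(y == 0) or np.all(y == 1):
        raise FitError(
            "all corrected mortalities are 0 (or all 1); the probit likelihood is "
            "unbounded — widen the dose range so intermediate mortalities are observed"
        )
    if not np.any((y > 0) & (y < 1)):
        raise FitError(
            "complete separation: every dose shows 0% or 100% corrected mortality; "
            "the probit slope is unidentified — add doses between the extremes"
        )
    x = np.log10(table.doses)
    exog = np.column_stack([np.ones_like(x), x])
    model = sm.GLM(
        y,
        exog,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
        var_weights=table.n_exposed,
    )
    try:
        res = model.fit()
    except Exception as exc:  # statsmodels raises various errors on separation
        raise FitError(f"probit fit failed: {exc}") from exc
    intercept, slope = (float(v) for v in res.params)
    fitted = ndtr(intercept + slope * x)
    if np.std(y) == 0 or np.std(fitted) == 0:
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    chi2 = _pearson_chi2(table.n_exposed, table.n_dead, fitted)
    if table.n_doses == 2:
        chi2 = 0.0 if chi2 < 1e-6 else chi2  # saturated two-parameter fit
    return DoseResponseFit(
        model_kind="probit",
        slope=slope,
        intercept=intercept,
        r_squared=min(r2, 1.0),
        chi_squared_gof=chi2,
        dose_unit=table.unit,
        n_doses=table.n_doses,
    )


def estimate_lc(fit: DoseResponseFit, p: float = 0.5) -> LcEstimate:
    """Inverse prediction of the dose producing mortality fraction ``p``."""
    if not 0 < p < 1:
        raise DomainError(f"target mortality p must be in (0, 1), got {p}")
    if fit.slope == 0:
        raise DomainError("zero slope: LC is undefined for a flat dose-response")
    if fit.model_kind == "linear_logdose":
        log_lc = (100.0 * p - fit.intercept) / fit.slope
    else:
        log_lc = (ndtri(p) - fit.intercept) / fit.slope
    value = float(10.0**log_lc)
    if not np.isfinite(value) or value <= 0:
        raise DomainError(f"non-finite LC estimate (log10 dose = {log_lc})")
    return LcEstimate(p=p, value=value, unit=fit.dose_unit, method=fit.model_kind)


# ---------------------------------------------------------------------------
# bootstrap machinery (shared with the co-toxicity bootstrap)


def _split_records(records: list[BioassayRecord]):
    """Group records into per-dose replicate arrays plus the control pool."""
    controls = [(r.n_exposed, r.n_dead) for r in records if r.is_control]
    by_dose: dict[float, list[tuple[int, int]]] = {}
    for r in records:
        if not r.is_control:
            by_dose.setdefault(r.dose, []).append((r.n_exposed, r.n_dead))
    doses = np.array(sorted(by_dose), dtype=float)
    per_dose = [np.array(by_dose[d], dtype=float) for d in doses]  # (R_d, 2)
    ctrl = np.array(controls, dtype=float) if controls else np.zeros((0, 2))
    return doses, per_dose, ctrl


def lc50_bootstrap_samples(
    records: list[BioassayRecord],
    *,
    p: float = 0.5,
    n_boot: int = 1000,
    rng: np.random.Generator,
    resample: ResampleScheme = "insect",
) -> np.ndarray:
    """Bootstrap LC_p samples from the linear log-dose fit, vectorized.

    Resampling is stratified by dose.  ``resample='insect'`` (default)
    resamples individual insects within the pooled dose group, equivalent
    to a binomial draw at the pooled observed proportion; with ~90 insects
    per dose its variance estimate is close to unbiased.
    ``resample='replicate'`` draws whole replicates with replacement
    within each dose; with only 3 replicates per dose it understates the
    sampling variance by about (R-1)/R and yields anti-conservative CIs.
    Failed fits (non-positive slope or non-finite LC) are returned as NaN.
    """
    doses, per_dose, ctrl = _split_records(records)
    D = len(doses)
    n_pool = np.empty((n_boot, D))
    dead_pool = np.empty((n_boot, D))
    for j, arr in enumerate(per_dose):
        R = arr.shape[0]
        if resample == "replicate":
            idx = rng.integers(0, R, size=(n_boot, R))
            n_pool[:, j] = arr[idx, 0].sum(axis=1)
            dead_pool[:, j] = arr[idx, 1].sum(axis=1)
        elif resample == "insect":
            n_tot = arr[:, 0].sum()
            p_obs = arr[:, 1].sum() / n_tot
            n_pool[:, j] = n_tot
            dead_pool[:, j] = rng.binomial(int(n_tot), p_obs, size=n_boot)
        else:
            raise ValueError(f"unknown resample scheme {resample!r}")

    if ctrl.shape[0] > 0:
        R = ctrl.shape[0]
        if resample == "replicate":
            idx = rng.integers(0, R, size=(n_boot, R))
            c_n = ctrl[idx, 0].sum(axis=1)
            c_dead = ctrl[idx, 1].sum(axis=1)
        else:
            n_tot = ctrl[:, 0].sum()
            c_n = np.full(n_boot, n_tot)
            c_dead = rng.binomial(int(n_tot), ctrl[:, 1].sum() / n_tot, size=n_boot)
        p_c = c_dead / c_n
    else:
        p_c = np.zeros(n_boot)

    raw = dead_pool / n_pool
    corrected = np.clip((raw - p_c[:, None]) / (1.0 - p_c[:, None]), 0.0, 1.0)
    y = corrected * 100.0
    x = np.log10(doses)

    xc = x - x.mean()
    sxx = np.sum(xc**2)
    slope = (y * xc).sum(axis=1) / sxx
    intercept = y.mean(axis=1) - slope * x.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lc = (100.0 * p - intercept) / slope
        lc = 10.0**log_lc
    lc[(slope <= 0) | ~np.isfinite(lc)] = np.nan
    return lc


def bootstrap_lc_ci(
    records: list[BioassayRecord],
    p: float = 0.5,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    resample: ResampleScheme = "insect",
) -> LcEstimate:
    """Percentile bootstrap CI for the linear-fit LC_p, deterministic per seed.

    Raises :class:`CIError` when more than half the bootstrap fits fail
    (non-positive slope), which indicates the data cannot support an LC
    estimate at all.
    """
    table = aggregate_mortality(records)
    fit = fit_linear_logdose(table)
    point = estimate_lc(fit, p)

    rng = np.random.default_rng(seed)
    lc = lc50_bootstrap_samples(records, p=p, n_boot=n_boot, rng=rng, resample=resample)
    valid = lc[np.isfinite(lc)]
    if len(valid) < 0.5 * n_boot:
        raise CIError(
            f"{n_boot - len(valid)}/{n_boot} bootstrap fits failed (non-positive "
            "slope); the dose design does not support a stable LC estimate"
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
    # percentile CI may sit just off the point estimate on skewed resamples
    lo, hi = min(float(lo), point.value), max(float(hi), point.value)
    return LcEstimate(
        p=p,
        value=point.value,
        unit=point.unit,
        method=f"{fit.model_kind}+bootstrap[{resample}]",
        ci_low=lo,
        ci_high=hi,
        ci_level=level,
    )
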