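"""Engraftment inference: measured trajectories versus the washout null.

A dosed organism that merely survives transit should track the no-growth
washout prediction; one that replicates rises above it and one that dies (or
is retained upstream) falls below.  This module quantifies that comparison:

* fold change of the endpoint concentration over the endogenous baseline,
* a log-ratio classification of each compartment series against the
  prediction (ABOVE_EXPECTED / TRACKING / BELOW_EXPECTED),
* a least-squares fit of the per-cycle net growth multiplier g, with a
  residual-bootstrap confidence interval, fitted compartment by compartment
  in chain order because downstream inflow depends on upstream state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import minimize_scalar

from .model import (
    DoseEvent,
    FeedingSchedule,
    GrowthParams,
    ReactorChain,
    simulate_with_growth,
)
from .qpcr import QpcrSeries

__all__ = [
    "FoldChange",
    "Classification",
    "ComparisonSeries",
    "GrowthFit",
    "EngraftmentReport",
    "fold_change",
    "classify_engraftment",
    "fit_growth_multiplier",
    "fit_growth_chain",
    "build_report",
]

DEFAULT_BOOTSTRAP_SEED = 20221026


@dataclass(frozen=True)
class FoldChange:
    """Ratio of a final to a baseline concentration.

    When the baseline is zero the ratio is undefined; the result is flagged
    ``from_zero`` and ``value`` carries the final concentration itself
    (an increase "from zero to" that level).
    """

    value: float
    from_zero: bool = False

    def __float__(self) -> float:
        return self.value


def fold_change(final: float, baseline: float) -> FoldChange:
    if final < 0 or baseline < 0:
        raise ValueError("concentrations must be >= 0")
    if baseline == 0:
        return FoldChange(value=final, from_zero=True)
    return FoldChange(value=final / baseline)


class Classification(str, Enum):
    ABOVE_EXPECTED = "ABOVE_EXPECTED"
    TRACKING = "TRACKING"
    BELOW_EXPECTED = "BELOW_EXPECTED"


@dataclass
class ComparisonSeries:
    """Measured and predicted concentrations on a shared cycle axis."""

    cycles: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    compartment: str = ""
    phase: str = "lumen"

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.measured = np.asarray(self.measured, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if not (len(self.cycles) == len(self.measured) == len(self.predicted)):
            raise ValueError("cycles, measured and predicted must align")


def _pseudo_floor(values: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest positive value (for log ratios)."""
    positive = values[values > 0]
    if positive.size == 0:
        return values
    floor = positive.min() / 2.0
    return np.where(values > 0, values, floor)


def classify_engraftment(
    series: ComparisonSeries,
    window: int = 6,
    factor: float = 2.0,
    min_predicted: float = 0.0,
) -> Classification:
    """Classify a series by its geometric-mean deviation from the prediction.

    Over the final ``window`` eligible cycles, compute the geometric mean R
    of measured/predicted (zeros in the measured series replaced by half the
    smallest positive measurement).  R > ``factor`` means the organism sits
    above the washout expectation (net growth or retention); R < 1/``factor``
    below it (net death or accelerated loss); otherwise it is tracking the
    null.  ``factor`` = 2 corresponds to ~0.3 on the log10 scale.

    Cycles where the prediction has fallen below ``min_predicted`` (e.g. the
    endogenous baseline) are excluded: below that level the baseline-adjusted
    measurement is dominated by subtraction noise and carries no information
    about the dosed cells.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    eligible = series.predicted > max(min_predicted, 0.0)
    if not eligible.any():
        raise ValueError("all predicted values are below the floor; ratio undefined")
    idx = np.flatnonzero(eligible)[-window:]
    measured = _pseudo_floor(series.measured)[idx]
    predicted = series.predicted[idx]
    if np.all(measured == 0):
        raise ValueError("no positive measured values in window; ratio undefined")
    log_ratio = np.log(measured) - np.log(predicted)
    r = float(np.exp(np.mean(log_ratio)))
    if r > factor:
        return Classification.ABOVE_EXPECTED
    if r < 1.0 / factor:
        return Classification.BELOW_EXPECTED
    return Classification.TRACKING


@dataclass(frozen=True)
class GrowthFit:
    """Fitted per-cycle net growth multiplier with a bootstrap interval."""

    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_points: int = 0
    compartment: str = ""


def _model_series(
    g_by_compartment: dict[str, float],
    chain: ReactorChain,
    schedule: FeedingSchedule,
    dose: DoseEvent,
    compartment: str,
    cycles: np.ndarray,
) -> np.ndarray:
    growth = GrowthParams.from_mapping(chain, g_by_compartment)
    traj = simulate_with_growth(chain, schedule, dose, growth, int(cycles.max()))
    return traj.series(compartment)[cycles]


def fit_growth_multiplier(
    measured: QpcrSeries,
    chain: ReactorChain,
    schedule: FeedingSchedule,
    dose: DoseEvent,
    upstream: dict[str, float] | None = None,
    bounds: tuple[float, float] = (1e-3, 5.0),
    min_level: float = 0.0,
    n_bootstrap: int = 0,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> GrowthFit:
    """Least-squares fit of a compartment's net per-cycle growth multiplier.

    Minimises the sum of squared log-residuals between the measured
    (baseline-adjusted) concentrations and the chain simulation as a
    one-dimensional profile in this compartment's multiplier, with upstream
    compartments held at their already-fitted values (and downstream at 1,
    which cannot influence this compartment).  Only post-dose cycles with a
    positive measurement above ``min_level`` enter the fit.

    With ``n_bootstrap`` > 0, a residual bootstrap (resampling log-residuals
    with replacement, refitting each replicate) yields a percentile interval.
    """
    upstream = dict(upstream or {})
    comp = measured.compartment
    post = measured.cycles >= dose.cycle
    usable = post & (measured.cells_per_ml > max(min_level, 0.0))
    cycles = measured.cycles[usable]
    values = measured.cells_per_ml[usable]
    if cycles.size:
        # drop cycles where the model is structurally zero (no mass can have
        # arrived yet); whether a cycle is zero does not depend on g > 0
        reference = _model_series(
            {**upstream, comp: 1.0}, chain, schedule, dose, comp, cycles
        )
        cycles, values = cycles[reference > 0], values[reference > 0]
    if values.size < 4:
        raise ValueError(
            f"need >= 4 positive post-dose measurements to fit {comp}; got {values.size}"
        )
    log_values = np.log(values)

    def predict(g: float) -> np.ndarray:
        return _model_series({**upstream, comp: g}, chain, schedule, dose, comp, cycles)

    def objective(g: float, target: np.ndarray) -> float:
        pred = predict(g)
        if np.any(pred <= 0):
            return np.inf
        return float(np.sum((target - np.log(pred)) ** 2))

    def solve(target: np.ndarray) -> float:
        res = minimize_scalar(
            objective,
            args=(target,),
            bounds=bounds,
            method="bounded",
            options={"xatol": 1e-9},
        )
        return float(res.x)

    estimate = solve(log_values)
    ci_low = ci_high = None
    if n_bootstrap > 0:
        fitted_log = np.log(predict(estimate))
        residuals = log_values - fitted_log
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            resampled = rng.choice(residuals, size=residuals.size, replace=True)
            boots[b] = solve(fitted_log + resampled)
        ci_low, ci_high = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return GrowthFit(estimate, ci_low, ci_high, n_points=values.size, compartment=comp)


def fit_growth_chain(
    series_by_compartment: dict[str, QpcrSeries],
    chain: ReactorChain,
    schedule: FeedingSchedule,
    dose: DoseEvent,
    min_level: float | dict[str, float] = 0.0,
    n_bootstrap: int = 0,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> dict[str, GrowthFit]:
    """Fit multipliers compartment by compartment in chain order (upstream first)."""
    fits: dict[str, GrowthFit] = {}
    fitted: dict[str, float] = {}
    for name in chain.names:
        if name not in series_by_compartment:
            continue
        level = min_level.get(name, 0.0) if isinstance(min_level, dict) else min_level
        fit = fit_growth_multiplier(
            series_by_compartment[name],
            chain,
            schedule,
            dose,
            upstream=fitted,
            min_level=level,
            n_bootstrap=n_bootstrap,
            seed=seed,
        )
        fits[name] = fit
        fitted[name] = fit.estimate
    return fits


@dataclass
class SeriesReport:
    compartment: str
    phase: str
    baseline: float
    fold_change_end_vs_baseline: FoldChange
    log10_reduction_over_period: float
    classification: Classification | None
    growth_fit: GrowthFit | None
    deviation: ComparisonSeries | None

    def to_dict(self) -> dict:
        d = {
            "compartment": self.compartment,
            "phase": self.phase,
            "baseline_cells_per_ml": self.baseline,
            "fold_change_end_vs_baseline": self.fold_change_end_vs_baseline.value,
            "fold_change_from_zero": self.fold_change_end_vs_baseline.from_zero,
            "log10_reduction_over_period": self.log10_reduction_over_period,
            "classification": self.classification.value if self.classification else None,
        }
        if self.growth_fit is not None:
            d["growth_multiplier"] = self.growth_fit.estimate
            d["growth_multiplier_ci"] = [self.growth_fit.ci_low, self.growth_fit.ci_high]
            d["growth_fit_n_points"] = self.growth_fit.n_points
        if self.deviation is not None:
            d["deviation_measured_over_predicted"] = [
                (m / p) if p > 0 else None
                for m, p in zip(self.deviation.measured, self.deviation.predicted)
            ]
        return d


@dataclass
class EngraftmentReport:
    """Per-(compartment, phase) engraftment summaries for one bioreplicate."""

    bioreplicate: str
    series: list[SeriesReport]

    def to_dict(self) -> dict:
        return {
            "bioreplicate": self.bioreplicate,
            "series": [s.to_dict() for s in self.series],
        }


def _log10_reduction(values: np.ndarray) -> float:
    """log10 drop from the post-dose peak to the final measurement."""
    positive = values[values > 0]
    if positive.size == 0:
        return 0.0
    final = positive[-1]
    return float(np.log10(positive.max() / final))


def build_report(
    bioreplicate: str,
    series_list: list[QpcrSeries],
    chain: ReactorChain,
    schedule: FeedingSchedule,
    dose: DoseEvent,
    window: int = 6,
    factor: float = 2.0,
    n_bootstrap: int = 0,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> EngraftmentReport:
    """Full engraftment analysis for one bioreplicate.

    Luminal series are compared to the no-growth prediction, classified and
    fitted (in chain order); mucosal series are summarised descriptively
    (fold change and log10 reduction only), since the mass-balance model
    excludes the mucin phase.
    """
    prediction = simulate_with_growth(chain, schedule, dose, None, _horizon(series_list))
    lumen = {
        s.compartment: s
        for s in series_list
        if s.phase == "lumen" and s.compartment in chain.names
    }
    min_levels = {c: (s.baseline or 0.0) for c, s in lumen.items()}
    fits: dict[str, GrowthFit] = {}
    try:
        fits = fit_growth_chain(
            lumen, chain, schedule, dose,
            min_level=min_levels, n_bootstrap=n_bootstrap, seed=seed,
        )
    except ValueError:
        fits = {}
    reports = []
    for s in series_list:
        baseline = s.baseline or 0.0
        post = s.cycles >= dose.cycle
        final = float(s.cells_per_ml[post][-1]) if post.any() else 0.0
        fc = fold_change(final, baseline)
        classification = None
        fit = None
        deviation = None
        if s.phase == "lumen" and s.compartment in chain.names:
            pred = prediction.series(s.compartment)[s.cycles[post]]
            deviation = ComparisonSeries(
                s.cycles[post], s.cells_per_ml[post], pred, s.compartment, s.phase
            )
            try:
                classification = classify_engraftment(
                    deviation, window=window, factor=factor, min_predicted=baseline
                )
            except ValueError:
                classification = None
            fit = fits.get(s.compartment)
        reports.append(
            SeriesReport(
                compartment=s.compartment,
                phase=s.phase,
                baseline=baseline,
                fold_change_end_vs_baseline=fc,
                log10_reduction_over_period=_log10_reduction(s.cells_per_ml[post]),
                classification=classification,
                growth_fit=fit,
                deviation=deviation,
            )
        )
    return EngraftmentReport(bioreplicate=bioreplicate, series=reports)


def _horizon(series_list: list[QpcrSeries]) -> int:
    return int(max(int(s.cycles.max()) for s in series_list))
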