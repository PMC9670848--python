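"""Relative-rate kinetics for simulation-chamber decay data.

A compound in a smog chamber disappears by a sum of first-order processes:
reaction with an oxidant (here *OH), loss to the chamber walls, and possibly
photolysis.  Because every process is first order, the log-depletion
ln(C0/Ct) is additive in the individual rate terms.  The relative-rate
method exploits this: after subtracting the target's (and, if any, the
reference's) wall loss, the corrected log-depletions of target and reference
obey

    ln([T]0/[T]t) - k_WL,T (t - t0)
        = (k_T / k_ref) * [ ln([R]0/[R]t) - k_WL,R (t - t0) ]

for *any* oxidant concentration history shared by the two compounds, so an
ordinary least-squares fit of the corrected target curve against the
corrected reference curve yields the rate-constant ratio k_T/k_ref as its
slope.  Multiplying by a recommended literature value of k_ref converts the
ratio to a second-order rate constant, with the reference's own relative
uncertainty (conventionally 10%) propagated in quadrature.

This module provides the decay-series container, the first-order loss fit
(for wall loss and photolysis constants), the wall-loss correction, the
relative-rate regression, the ratio-to-rate-constant conversion, the
inverse-variance weighted average of determinations against several
references, and the control-experiment consistency check between two
reference compounds.  All regression uncertainties are 1 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SECONDS_PER_DAY",
    "DecaySeries",
    "ReferenceCompound",
    "FirstOrderLossFit",
    "RelativeRateFit",
    "RateConstant",
    "DegenerateFitError",
    "fit_first_order_loss",
    "corrected_log_loss",
    "relative_rate_fit",
    "ratio_to_rate_constant",
    "weighted_average",
    "reference_consistency_check",
    "ConsistencyCheck",
]

#: Exact conversion factor between the two first-order rate units.
SECONDS_PER_DAY = 86400.0

#: Unit tags accepted by :class:`RateConstant`.
_UNITS = ("cm^3 molecule^-1 s^-1", "s^-1", "day^-1")


class DegenerateFitError(ValueError):
    """The regression is degenerate (e.g. the reference shows no decay)."""


@dataclass
class DecaySeries:
    """One compound's concentration-time trace from a chamber run.

    Parameters
    ----------
    compound_id
        Text label for the compound.
    times
        Sample times in seconds, strictly increasing, at least 3 points.
        The first point defines ``t0`` and ``C0``.
    concentrations
        Concentrations in molecule cm^-3, all strictly positive.
    """

    compound_id: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.concentrations.ndim != 1:
            raise ValueError("times and concentrations must be 1-D")
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size < 3:
            raise ValueError("a decay series needs at least 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.concentrations > 0):
            raise ValueError("concentrations must all be positive")

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def c0(self) -> float:
        return float(self.concentrations[0])

    def log_depletion(self) -> np.ndarray:
        """ln(C0/Ct) for every sample; zero at the first point by construction."""
        return np.log(self.c0 / self.concentrations)


@dataclass(frozen=True)
class ReferenceCompound:
    """A reference compound with a recommended OH rate constant.

    ``rel_unc`` is the relative 1-sigma uncertainty attached to the
    recommended value (the conventional 10% unless a better estimate
    exists) and is propagated into every rate constant derived from a
    ratio against this reference.
    """

    name: str
    k_ref: float  # cm^3 molecule^-1 s^-1
    rel_unc: float = 0.10

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("k_ref must be positive")
        if not 0 <= self.rel_unc < 1:
            raise ValueError("rel_unc must be in [0, 1)")


@dataclass(frozen=True)
class FirstOrderLossFit:
    """Result of a first-order loss regression (wall loss, photolysis...)."""

    k_loss: float  # s^-1
    sigma_k: float  # 1-sigma standard error, s^-1
    intercept: float
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class RelativeRateFit:
    """Relative-rate regression: slope is the ratio k_target/k_reference."""

    slope: float
    sigma_slope: float  # 1 sigma
    intercept: float
    r_squared: float
    n_points: int = 0


@dataclass(frozen=True)
class RateConstant:
    """A rate constant with a 1-sigma uncertainty and a units tag."""

    value: float
    sigma: float
    units: str

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}")

    def to(self, units: str) -> "RateConstant":
        """Convert between the first-order units s^-1 and day^-1.

        Second-order (cm^3 molecule^-1 s^-1) constants cannot be converted.
        """
        if units == self.units:
            return self
        if {self.units, units} != {"s^-1", "day^-1"}:
            raise ValueError(f"cannot convert {self.units} to {units}")
        factor = SECONDS_PER_DAY if units == "day^-1" else 1.0 / SECONDS_PER_DAY
        return RateConstant(self.value * factor, self.sigma * factor, units)


@dataclass(frozen=True)
class ConsistencyCheck:
    """Control-experiment comparison of a measured vs literature ratio."""

    measured_ratio: float
    literature_ratio: float
    relative_deviation: float


def _linregress(x: np.ndarray, y: np.ndarray):
    """OLS with a free intercept; returns slope, stderr, intercept, r^2."""
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # zero-variance y (e.g. no decay at all)
        r2 = 0.0
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    return float(res.slope), float(stderr), float(res.intercept), float(r2)


def fit_first_order_loss(series: DecaySeries) -> FirstOrderLossFit:
    """Fit a single first-order loss constant to a decay trace.

    Regresses ln(C0/Ct) on (t - t0) by ordinary least squares with a free
    intercept; the slope is the first-order loss constant in s^-1 and
    ``sigma_k`` its 1-sigma standard error.  Used for wall-loss and
    photolysis characterization runs where one process dominates.
    """
    x = series.times - series.t0
    y = series.log_depletion()
    slope, stderr, intercept, r2 = _linregress(x, y)
    return FirstOrderLossFit(
        k_loss=slope,
        sigma_k=stderr,
        intercept=intercept,
        n_points=series.times.size,
        r_squared=r2,
    )


def corrected_log_loss(series: DecaySeries, k_extra: float = 0.0) -> np.ndarray:
    """Log-depletion corrected for a known extra first-order loss.

    Returns an array of (t, y) pairs with y(t) = ln(C0/Ct) - k_extra*(t-t0),
    the standard subtraction of a wall-loss (or photolysis) contribution
    before relative-rate fitting.  y(t0) = 0 exactly.
    """
    if k_extra < 0:
        raise ValueError("k_extra must be non-negative")
    t = series.times
    y = series.log_depletion() - k_extra * (t - series.t0)
    return np.column_stack([t, y])


def _common_subseries(a: DecaySeries, b: DecaySeries):
    """Restrict two series to their exactly shared timestamps."""
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size < 3:
        raise ValueError(
            "target and reference share fewer than 3 time points; "
            "series must be sampled on a common grid"
        )
    sub_a = DecaySeries(a.compound_id, a.times[ia], a.concentrations[ia])
    sub_b = DecaySeries(b.compound_id, b.times[ib], b.concentrations[ib])
    return sub_a, sub_b


def relative_rate_fit(
    target: DecaySeries,
    reference: DecaySeries,
    k_wl_target: float = 0.0,
    k_wl_reference: float = 0.0,
) -> RelativeRateFit:
    """Relative-rate regression of target vs reference log-depletion.

    Both series are first restricted to their exactly shared timestamps (no
    interpolation), wall-loss-corrected, and then the target curve is
    regressed on the reference curve by OLS with a free intercept.  The
    slope estimates k_target/k_reference and is independent of the shared
    oxidant concentration history.

    Raises
    ------
    ValueError
        If the grids share fewer than 3 points or a wall-loss constant is
        negative.
    DegenerateFitError
        If the corrected reference curve shows no decay (nothing to regress
        against).
    """
    if k_wl_target < 0 or k_wl_reference < 0:
        raise ValueError("wall-loss constants must be non-negative")
    sub_t, sub_r = _common_subseries(target, reference)
    y_t = corrected_log_loss(sub_t, k_wl_target)[:, 1]
    y_r = corrected_log_loss(sub_r, k_wl_reference)[:, 1]
    if np.max(np.abs(y_r)) < 1e-12:
        raise DegenerateFitError(
            "reference shows no decay after wall-loss correction"
        )
    slope, stderr, intercept, r2 = _linregress(y_r, y_t)
    return RelativeRateFit(
        slope=slope,
        sigma_slope=stderr,
        intercept=intercept,
        r_squared=r2,
        n_points=y_r.size,
    )


def ratio_to_rate_constant(
    fit: RelativeRateFit, ref: ReferenceCompound
) -> RateConstant:
    """Convert a fitted rate-constant ratio into a second-order rate constant.

    value = slope * k_ref.  The uncertainty combines the regression's
    relative error with the reference's own relative uncertainty in
    quadrature:  sigma = value * sqrt((sigma_slope/slope)^2 + rel_unc^2).
    """
    if fit.slope <= 0:
        raise ValueError("ratio must be positive to convert to a rate constant")
    value = fit.slope * ref.k_ref
    rel = np.hypot(fit.sigma_slope / fit.slope, ref.rel_unc)
    return RateConstant(value=value, sigma=value * rel, units=_UNITS[0])


def weighted_average(values: Sequence[RateConstant]) -> RateConstant:
    """Inverse-variance weighted mean of several rate-constant determinations.

    Weights w_i = 1/sigma_i^2; the combined value is sum(w v)/sum(w) and the
    combined uncertainty (sum w)^(-1/2).  All inputs must share units and
    have strictly positive sigma.
    """
    if len(values) == 0:
        raise ValueError("cannot average an empty list")
    units = {v.units for v in values}
    if len(units) != 1:
        raise ValueError(f"mixed units: {sorted(units)}")
    sigmas = np.array([v.sigma for v in values])
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be positive for inverse-variance weighting")
    vals = np.array([v.value for v in values])
    w = 1.0 / sigmas**2
    mean = float(np.sum(w * vals) / np.sum(w))
    # the weighted mean lies in the convex hull of the inputs; clamp away
    # the last-ulp rounding of the quotient so the invariant holds exactly
    mean = float(np.clip(mean, vals.min(), vals.max()))
    return RateConstant(
        value=mean,
        sigma=float(np.sum(w) ** -0.5),
        units=values[0].units,
    )


def reference_consistency_check(
    fit: RelativeRateFit, ref_a: ReferenceCompound, ref_b: ReferenceCompound
) -> ConsistencyCheck:
    """Compare a measured reference-vs-reference ratio with literature.

    In a control experiment one reference compound (a) is run against
    another (b); the fitted slope should reproduce the literature ratio
    k_a/k_b.  Returns the measured ratio, the literature ratio, and the
    relative deviation |measured - lit| / lit.
    """
    lit = ref_a.k_ref / ref_b.k_ref
    dev = abs(fit.slope - lit) / lit
    return ConsistencyCheck(
        measured_ratio=fit.slope, literature_ratio=lit, relative_deviation=dev
    )
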