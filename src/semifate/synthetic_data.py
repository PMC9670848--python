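"""Synthetic chamber experiments and fate-model observations.

Every fitting operation in this package has an exact generative inverse
here, so the whole pipeline is testable without any instrument data.

Chamber pairs are generated by exact integration of the first-order losses:
with a piecewise-constant OH history [OH]_i over each sampling interval,
the log-concentration of a compound with OH rate constant k and wall-loss
constant k_WL evolves as

    ln C(t_n) = ln C0 - k * X(t_n) - k_WL * t_n,
    X(t_n) = sum_i [OH]_i * dt_i      (cumulative OH exposure)

after which independent multiplicative lognormal noise (mean one,
coefficient of variation ``noise_cv``) is applied to every concentration,
mimicking positive, log-analyzed spectroscopic retrievals.  Defaults mirror
a NOx-free TME-ozonolysis run: 30 min duration sampled every 60 s, OH at
2e8 molecule cm^-3 (within the estimated chamber range), the measured
target wall-loss constant 3.1e-4 s^-1, and 2% noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .chamber_kinetics import DecaySeries
from .fate_model import FateScenario, TimeTrends, trends

__all__ = ["ChamberRecipe", "generate_chamber_pair", "generate_fate_observations"]


@dataclass
class ChamberRecipe:
    """Recipe for one synthetic target/reference chamber pair.

    ``true_ratio`` is the generating rate-constant ratio
    k_target/k_reference; ``oh_profile`` is either a constant OH
    concentration or one value per sampling interval (molecule cm^-3).
    """

    true_ratio: float
    k_ref_oh: float = 2.83e-12  # cm^3 molecule^-1 s^-1 (DME-like reference)
    oh_profile: Union[float, np.ndarray] = 2.0e8  # molecule cm^-3
    k_wl_target: float = 3.1e-4  # s^-1
    k_wl_reference: float = 0.0  # s^-1
    duration: float = 1800.0  # s
    sample_interval: float = 60.0  # s
    noise_cv: float = 0.02
    seed: int = 0
    c0_target: float = 5.0e13  # molecule cm^-3
    c0_reference: float = 6.0e13  # molecule cm^-3

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("duration and sample_interval must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def generate_chamber_pair(r: ChamberRecipe) -> tuple[DecaySeries, DecaySeries]:
    """Generate a (target, reference) decay pair; deterministic given seed."""
    times = np.arange(0.0, r.duration + 0.5 * r.sample_interval, r.sample_interval)
    n = times.size
    oh = np.broadcast_to(np.asarray(r.oh_profile, dtype=float), (n - 1,)).copy()
    if np.any(oh < 0):
        raise ValueError("oh_profile must be non-negative")
    # cumulative OH exposure integral, exact for a stepwise profile
    exposure = np.concatenate([[0.0], np.cumsum(oh * np.diff(times))])

    k_t = r.true_ratio * r.k_ref_oh
    ln_target = np.log(r.c0_target) - k_t * exposure - r.k_wl_target * times
    ln_ref = np.log(r.c0_reference) - r.k_ref_oh * exposure - r.k_wl_reference * times

    rng = np.random.default_rng(r.seed)
    target = np.exp(ln_target) * _lognormal_factors(rng, r.noise_cv, n)
    reference = np.exp(ln_ref) * _lognormal_factors(rng, r.noise_cv, n)
    return (
        DecaySeries("target", times, target),
        DecaySeries("reference", times, reference),
    )


def generate_fate_observations(
    s: FateScenario,
    t_grid,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> TimeTrends:
    """Analytic fate trends with multiplicative lognormal noise per species."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    clean = trends(s, t_grid)
    rng = np.random.default_rng(seed)
    n = clean.times.size
    return TimeTrends(
        times=clean.times,
        ibp_w=clean.ibp_w * _lognormal_factors(rng, noise_cv, n),
        ibap_w=clean.ibap_w * _lognormal_factors(rng, noise_cv, n),
        ibap_g=clean.ibap_g * _lognormal_factors(rng, noise_cv, n),
    )
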