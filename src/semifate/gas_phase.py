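"""Atmospheric descriptors derived from a second-order OH rate constant.

Given k2 = k(X + OH) in cm^3 molecule^-1 s^-1 and a (24 h averaged) OH
concentration, the pseudo-first-order loss rate is k_g = k2*[OH] and the
atmospheric lifetime is its reciprocal, tau = 1/(k2*[OH]).  The module also
estimates the steady-state OH concentration sustained in a dark chamber by
tetramethylethylene (TME) ozonolysis, the standard NOx-free OH source:
production Y*k(TME+O3)*[O3]*[TME] balanced against loss dominated by
TME itself, optionally diluted by other OH sinks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chamber_kinetics import SECONDS_PER_DAY, RateConstant

__all__ = [
    "OhField",
    "TmeSource",
    "pseudo_first_order",
    "atmospheric_lifetime",
    "oh_steady_state",
]


@dataclass(frozen=True)
class OhField:
    """A (24 h averaged) gas-phase OH radical concentration, molecule cm^-3."""

    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("OH concentration must be non-negative")


@dataclass(frozen=True)
class TmeSource:
    """Dark TME-ozonolysis OH source in a chamber.

    TME + O3 produces OH with near-unit yield Y; because TME reacts with OH
    about five orders of magnitude faster than with O3, TME itself is the
    dominant OH sink and the steady state is independent of [TME].
    ``extra_scavenging`` is the pseudo-first-order OH sink from everything
    else, expressed as a fraction of the TME sink (0 = TME only).
    """

    o3: float  # molecule cm^-3
    yield_Y: float = 1.0
    k_tme_o3: float = 1.1e-15  # cm^3 molecule^-1 s^-1
    k_tme_oh: float = 1.1e-10  # cm^3 molecule^-1 s^-1
    extra_scavenging: float = 0.0

    def __post_init__(self) -> None:
        if self.k_tme_o3 <= 0 or self.k_tme_oh <= 0:
            raise ValueError("rate constants must be positive")
        if not 0 < self.yield_Y <= 1:
            raise ValueError("yield_Y must be in (0, 1]")
        if self.o3 < 0 or self.extra_scavenging < 0:
            raise ValueError("o3 and extra_scavenging must be non-negative")


def pseudo_first_order(k2: float, oh: OhField) -> RateConstant:
    """Pseudo-first-order loss rate k_g = k2*[OH], returned in s^-1.

    Use ``.to("day^-1")`` for the day^-1 view (exact factor 86400).
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    return RateConstant(value=k2 * oh.concentration, sigma=0.0, units="s^-1")


def atmospheric_lifetime(k2: float, oh: OhField) -> float:
    """Atmospheric lifetime tau = 1/(k2*[OH]) in days.

    The exact reciprocal of :func:`pseudo_first_order`.  A zero OH field
    would mean an infinite lifetime; that is reported as an error rather
    than a silent ``inf``.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if oh.concentration == 0:
        raise ValueError("OH concentration is zero: lifetime is unbounded")
    return 1.0 / (k2 * oh.concentration) / SECONDS_PER_DAY


def oh_steady_state(src: TmeSource) -> float:
    """Steady-state [OH] from dark TME ozonolysis, molecule cm^-3.

    [OH]ss = Y * k(TME+O3) * [O3] / (k(TME+OH) * (1 + extra_scavenging)).
    Linear in [O3] and in Y; monotonically decreasing in extra_scavenging.
    """
    return (
        src.yield_Y
        * src.k_tme_o3
        * src.o3
        / (src.k_tme_oh * (1.0 + src.extra_scavenging))
    )
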