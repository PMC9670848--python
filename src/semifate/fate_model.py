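"""Two-media first-order fate model: parent in water -> semivolatile
transformation product in water -> {aqueous degradation | volatilization ->
gas-phase OH loss}.

The network is a linear first-order chain.  Writing P = [IBP_w],
A = [IBAP_w], G = [IBAP_g], all as fractions of the initial aqueous parent
concentration [IBP_w]0:

    dP/dt = -k_d P
    dA/dt =  k_f P - (k_vol + k_d') A
    dG/dt =  k_vol A - k_g G

with P(0) = 1, A(0) = G(0) = 0 and all rates in day^-1.  The closed-form
(Bateman) solutions are

    P(t) = exp(-k_d t)
    A(t) = k_f / (K - k_d) * (exp(-k_d t) - exp(-K t)),      K = k_vol + k_d'
    G(t) = k_f k_vol * sum_i exp(-k_i t) / prod_{j != i} (k_j - k_i)

where the sum in G runs over the three cascade rates {k_d, K, k_g} — the
second divided difference of x -> exp(-x t) on those nodes.  A(t) is
evaluated through expm1 so it stays accurate when K ~ k_d; G(t) switches to
a 3x3 matrix-exponential evaluation when any two cascade rates nearly
coincide, where the explicit sum would cancel catastrophically.

Summary fractions: f = k_f/k_d is the fraction of degraded parent converted
to the product; v = k_vol/(k_vol + k_d') is the fraction of aqueous product
removed by volatilization; and given a split of k_d' into aqueous pathway
rates, F_j = k_j / (k_vol + k_d') is the fraction degraded by each process
(F_vol = v).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "FateScenario",
    "TimeTrends",
    "FractionReport",
    "ibp_water",
    "ibap_water",
    "ibap_gas",
    "fractions",
    "simulate_ode",
    "trends",
]

#: Relative gap below which two cascade rates count as degenerate.
_DEGENERATE_RTOL = 1e-7


@dataclass(frozen=True)
class FateScenario:
    """The five first-order rate constants of the two-media network (day^-1).

    ``pathway_split`` optionally partitions the aqueous product degradation
    constant ``k_d_prime`` into named process rates (e.g. reaction with
    aqueous OH, triplet CDOM, direct photolysis); the components must sum
    to ``k_d_prime``.
    """

    k_d: float
    k_f: float
    k_d_prime: float
    k_vol: float
    k_g: float
    pathway_split: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("k_d", "k_f", "k_d_prime", "k_vol", "k_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_f > self.k_d:
            raise ValueError("k_f cannot exceed k_d (conversion fraction f <= 1)")
        if self.pathway_split is not None:
            split = dict(self.pathway_split)
            if any(v < 0 for v in split.values()):
                raise ValueError("pathway rates must be non-negative")
            total = sum(split.values())
            scale = max(abs(self.k_d_prime), 1e-300)
            if abs(total - self.k_d_prime) > 1e-9 * scale:
                raise ValueError(
                    "pathway_split must sum to k_d_prime "
                    f"({total} != {self.k_d_prime})"
                )
            object.__setattr__(self, "pathway_split", split)

    @property
    def k_total_ibap_w(self) -> float:
        """Total aqueous-product removal rate K = k_vol + k_d_prime."""
        return self.k_vol + self.k_d_prime


@dataclass
class TimeTrends:
    """Sampled trajectories, as fractions of the initial aqueous parent."""

    times: np.ndarray  # days
    ibp_w: np.ndarray
    ibap_w: np.ndarray
    ibap_g: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "ibp_w": self.ibp_w,
                "ibap_w": self.ibap_w,
                "ibap_g": self.ibap_g,
            }
        )


@dataclass(frozen=True)
class FractionReport:
    """Summary fractions f, v and (if a pathway split is given) F_j."""

    f: float
    v: float
    pathway_fractions: Optional[Mapping[str, float]] = None


def _check_times(t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _phi(x: float, y: float, t: np.ndarray) -> np.ndarray:
    """First divided difference (exp(-x t) - exp(-y t)) / (y - x).

    Evaluated as exp(-x t) * t * E(u) with u = (y - x) t and
    E(u) = -expm1(-u)/u, which is accurate for any gap including u -> 0
    (E -> 1, giving the confluent limit t exp(-x t)).  The expression is
    symmetric in (x, y); ordering x <= y keeps u >= 0 so expm1 cannot
    overflow.
    """
    if x > y:
        x, y = y, x
    u = (y - x) * t
    with np.errstate(invalid="ignore"):
        e = np.where(u == 0.0, 1.0, -np.expm1(-u) / np.where(u == 0.0, 1.0, u))
    return np.exp(-x * t) * t * e


def ibp_water(s: FateScenario, t) -> np.ndarray:
    """Aqueous parent fraction P(t) = exp(-k_d t)."""
    t = _check_times(t)
    return np.exp(-s.k_d * t)


def ibap_water(s: FateScenario, t) -> np.ndarray:
    """Aqueous product fraction A(t); expm1-stable for K ~ k_d."""
    t = _check_times(t)
    return s.k_f * _phi(s.k_d, s.k_total_ibap_w, t)


def _rate_matrix(s: FateScenario) -> np.ndarray:
    K = s.k_total_ibap_w
    return np.array(
        [
            [-s.k_d, 0.0, 0.0],
            [s.k_f, -K, 0.0],
            [0.0, s.k_vol, -s.k_g],
        ]
    )


def ibap_gas(s: FateScenario, t) -> np.ndarray:
    """Gas-phase product fraction G(t), the three-exponential cascade term.

    Uses the explicit divided-difference sum when the cascade rates
    {k_d, K, k_g} are well separated, and a matrix-exponential evaluation
    of the full 3x3 system when any pair nearly coincides.
    """
    t = _check_times(t)
    if s.k_vol == 0.0 or s.k_f == 0.0:
        return np.zeros_like(t)
    nodes = (s.k_d, s.k_total_ibap_w, s.k_g)
    scale = max(max(nodes), 1.0)
    gaps = [abs(a - b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    if min(gaps) < _DEGENERATE_RTOL * scale:
        m = _rate_matrix(s)
        return np.array([expm(m * ti)[2, 0] for ti in t])
    out = np.zeros_like(t)
    for i, xi in enumerate(nodes):
        denom = np.prod([xj - xi for j, xj in enumerate(nodes) if j != i])
        out += np.exp(-xi * t) / denom
    # the divided difference is non-negative (e^{-xt} is convex in x);
    # clear the ~eps cancellation residue near t = 0
    return np.maximum(s.k_f * s.k_vol * out, 0.0)


def fractions(s: FateScenario) -> FractionReport:
    """Summary fractions f = k_f/k_d, v = k_vol/K, and per-pathway F_j.

    F_j requires a ``pathway_split`` on the scenario; without one, f and v
    are still returned and ``pathway_fractions`` is None.
    """
    if s.k_d <= 0:
        raise ValueError("k_d must be positive to define f")
    if s.k_total_ibap_w <= 0:
        raise ValueError("k_vol + k_d_prime must be positive to define v")
    f = s.k_f / s.k_d
    K = s.k_total_ibap_w
    v = s.k_vol / K
    pf = None
    if s.pathway_split is not None:
        pf = {name: k / K for name, k in s.pathway_split.items()}
        pf["volatilization"] = v
        total = sum(pf.values())
        pf = {name: x / total for name, x in pf.items()}  # exact unit sum
    return FractionReport(f=f, v=v, pathway_fractions=pf)


def simulate_ode(s: FateScenario, t_grid) -> TimeTrends:
    """Numerical (stiff-safe) integration of the three-species network.

    Serves as the independent ground truth for the closed forms in tests;
    not used by :func:`trends`.
    """
    t_grid = _check_times(t_grid)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    m = _rate_matrix(s)
    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1.0
    sol = solve_ivp(
        lambda _, y: m @ y,
        (0.0, t_end),
        [1.0, 0.0, 0.0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-12,
        atol=1e-18,
        jac=lambda _, y: m,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return TimeTrends(
        times=t_grid, ibp_w=sol.y[0], ibap_w=sol.y[1], ibap_g=sol.y[2]
    )


def trends(s: FateScenario, t_grid) -> TimeTrends:
    """Evaluate the analytic solutions on a time grid (days)."""
    t_grid = _check_times(t_grid)
    return TimeTrends(
        times=t_grid,
        ibp_w=ibp_water(s, t_grid),
        ibap_w=ibap_water(s, t_grid),
        ibap_g=ibap_gas(s, t_grid),
    )
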