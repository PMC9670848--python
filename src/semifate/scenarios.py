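"""Curated parameter sets and reference data.

Holds the recommended OH rate constants of the chamber reference compounds,
the measured relative-rate ratios for the model contaminant
4-isobutylacetophenone (IBAP, the toxic transformation product of
ibuprofen), the aqueous photoreactivity parameters of ibuprofen (IBP) and
IBAP, and the two bounding fate scenarios:

* ``fast``  — shallow (1 m), low-DOC, high nitrate/nitrite water: fast
  aqueous photochemistry (k_d = 0.3, k_f = 0.05, k_d' = 0.4 day^-1).
* ``slow``  — deep (10 m), high-DOC, low nitrate/nitrite water: slow
  aqueous photochemistry (k_d = 0.02, k_f = 0.005, k_d' = 0.03 day^-1).

Both use the estimated volatilization constant k_vol = 0.052 day^-1 and the
gas-phase pseudo-first-order constant k_g = 0.46 day^-1 derived from the
measured k(IBAP+OH) and a 24 h average [OH] = 1.13e6 molecule cm^-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .chamber_kinetics import RateConstant, ReferenceCompound
from .fate_model import FateScenario

__all__ = [
    "REFERENCE_COMPOUNDS",
    "MEASURED_RATIOS",
    "CONTROL_RATIOS",
    "OH_24H_AVERAGE",
    "K2_IBAP_OH_NOMINAL",
    "WALL_LOSS_IBAP",
    "PHOTOLYSIS_254NM_IBAP",
    "PhotoreactivityParams",
    "PHOTOREACTIVITY",
    "BUILTIN_SCENARIOS",
    "YIELD_RANGE",
    "load_scenario",
    "save_scenario",
    "yield_range_check",
]

#: Recommended second-order OH rate constants of the reference compounds,
#: cm^3 molecule^-1 s^-1, each carrying the conventional 10% uncertainty.
REFERENCE_COMPOUNDS = {
    "DME": ReferenceCompound("DME", 2.83e-12),
    "CyHex": ReferenceCompound("CyHex", 6.38e-12),
    "p-Bq": ReferenceCompound("p-Bq", 4.60e-12),
}

#: Measured relative-rate ratios k(IBAP+OH)/k(ref+OH) with 1-sigma
#: regression uncertainties, by chamber condition.
MEASURED_RATIOS = {
    "nox": {"DME": (1.55, 0.11), "CyHex": (0.81, 0.07), "p-Bq": (1.01, 0.12)},
    "nox_free": {"DME": (1.04, 0.08), "CyHex": (0.45, 0.05)},
}

#: Control experiments: reference-vs-reference ratios measured against DME,
#: as (measured, sigma_measured, literature, sigma_literature).
CONTROL_RATIOS = {
    "CyHex/DME": (1.95, 0.23, 2.25, 0.32),
    "p-Bq/DME": (1.73, 0.12, 1.63, 0.23),
}

#: 24 h average tropospheric OH concentration, molecule cm^-3.
OH_24H_AVERAGE = 1.13e6

#: Nominal measured k(IBAP+OH) used for the fate-model conversion,
#: cm^3 molecule^-1 s^-1 (the NOx-condition weighted mean, rounded).
K2_IBAP_OH_NOMINAL = 4.7e-12

#: Measured IBAP first-order wall-loss constant (value, 1 sigma), s^-1.
WALL_LOSS_IBAP = RateConstant(3.1e-4, 0.2e-4, "s^-1")

#: Measured IBAP 254 nm photolysis constant (value, 1 sigma), s^-1.
PHOTOLYSIS_254NM_IBAP = RateConstant(7.5e-4, 0.2e-4, "s^-1")


@dataclass(frozen=True)
class PhotoreactivityParams:
    """Aqueous photoreactivity of a compound in sunlit freshwater.

    Direct-photolysis quantum yield (mol Einstein^-1), second-order rate
    constants with the photochemically produced reactive intermediates
    (M^-1 s^-1), and — for a transformation product — its formation yields
    from the parent along each pathway (dimensionless).
    """

    phi_dp: float
    k_oh_aq: float
    k_1o2: float
    k_3cdom: float
    yield_dp: float = 0.0
    yield_oh: float = 0.0
    yield_1o2: float = 0.0
    yield_3cdom: float = 0.0


#: Photoreactivity of the parent drug and its product.  The product-yield
#: entries on IBP are the IBP -> IBAP formation yields per pathway.
PHOTOREACTIVITY = {
    "IBP": PhotoreactivityParams(
        phi_dp=0.33,
        k_oh_aq=1.0e10,
        k_1o2=6.0e4,
        k_3cdom=1.5e9,
        yield_dp=0.25,
        yield_oh=0.023,
        yield_1o2=0.0,
        yield_3cdom=0.31,
    ),
    "IBAP": PhotoreactivityParams(
        phi_dp=5.0e-2, k_oh_aq=2.0e10, k_1o2=2.3e6, k_3cdom=3.2e9
    ),
}

BUILTIN_SCENARIOS = {
    "fast": FateScenario(k_d=0.3, k_f=0.05, k_d_prime=0.4, k_vol=0.052, k_g=0.46),
    "slow": FateScenario(k_d=0.02, k_f=0.005, k_d_prime=0.03, k_vol=0.052, k_g=0.46),
}

#: Range of the modeled parent-to-product conversion fraction f = k_f/k_d
#: across realistic water-column conditions.
YIELD_RANGE = (0.18, 0.26)

_FIELDS = ("k_d", "k_f", "k_d_prime", "k_vol", "k_g")


def load_scenario(name: Union[str, Path]) -> FateScenario:
    """Load a built-in scenario (``fast``/``slow``) or a YAML config file.

    A config file carries the day^-1 rate constants as top-level keys
    ``k_d, k_f, k_d_prime, k_vol, k_g`` and an optional ``pathway_split``
    mapping.
    """
    key = str(name)
    if key in BUILTIN_SCENARIOS:
        return BUILTIN_SCENARIOS[key]
    path = Path(name)
    if not path.exists():
        raise ValueError(
            f"unknown scenario {name!r}: available built-ins are "
            f"{sorted(BUILTIN_SCENARIOS)} (or pass a config file path)"
        )
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    missing = [k for k in _FIELDS if k not in raw]
    if missing:
        raise ValueError(f"scenario file {path} missing keys: {missing}")
    return FateScenario(
        **{k: float(raw[k]) for k in _FIELDS},
        pathway_split=raw.get("pathway_split"),
    )


def save_scenario(s: FateScenario, path: Union[str, Path]) -> None:
    """Write a scenario to a YAML config; round-trips bit-exactly."""
    doc = {k: getattr(s, k) for k in _FIELDS}
    if s.pathway_split is not None:
        doc["pathway_split"] = dict(s.pathway_split)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def yield_range_check(s: FateScenario) -> tuple[float, bool]:
    """Conversion fraction f = k_f/k_d and whether it falls in the modeled
    range ``YIELD_RANGE`` (informational flag)."""
    if s.k_d <= 0:
        raise ValueError("k_d must be positive")
    f = s.k_f / s.k_d
    lo, hi = YIELD_RANGE
    return f, lo <= f <= hi
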