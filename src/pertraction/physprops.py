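"""Physical-property estimation for two-phase extraction systems.

Molar volumes by Le Bas additive increments, liquid-phase diffusivities by
the Wilke–Chang correlation, dimensionless groups (Re, Sc, Gz), and partition
coefficients from two-phase equilibrium concentration data.

Units: all public functions take and return SI quantities (m, s, kg, K)
unless the argument name carries an explicit unit suffix.  Viscosities are
stored in mPa·s (= cP) on :class:`PhaseSpec` because that is how solvent
property tables are printed; conversion happens inside the correlations.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoluteSpec",
    "PhaseSpec",
    "PartitionSystem",
    "PartitionEstimate",
    "Diffusivity",
    "DimensionlessGroups",
    "le_bas_molar_volume",
    "parse_formula",
    "wilke_chang_diffusivity",
    "partition_coefficient",
    "estimate_partition",
    "reynolds_schmidt",
    "WATER",
]

# Le Bas additive atomic volume increments, cm³/mol.
_LE_BAS_INCREMENTS: dict[str, float] = {
    "C": 14.8,
    "H": 3.7,
    "N": 15.6,
    "S": 25.6,
    "F": 8.7,
    "Cl": 24.6,
    "Br": 27.0,
    "I": 37.0,
}

# Oxygen increment depends on its bonding environment.
_LE_BAS_OXYGEN: dict[str, float] = {
    "carbonyl": 7.4,         # aldehydes, ketones, doubly bonded O
    "methyl_ester_ether": 9.1,
    "ethyl_ester_ether": 9.9,
    "higher_ester_ether": 11.0,
    "acid": 12.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula ("C10H14O") into an element map."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def le_bas_molar_volume(
    formula: dict[str, int] | str, functional_context: str = "carbonyl"
) -> float:
    """Le Bas molar volume at the normal boiling point, cm³/mol.

    Sum of additive atomic increments; the oxygen increment is selected by
    ``functional_context`` (one of ``carbonyl``, ``methyl_ester_ether``,
    ``ethyl_ester_ether``, ``higher_ester_ether``, ``acid``).  No ring
    corrections are applied.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise ValueError("empty formula: no atoms to sum increments over")
    if functional_context not in _LE_BAS_OXYGEN:
        raise ValueError(
            f"unknown oxygen context {functional_context!r}; "
            f"choose from {sorted(_LE_BAS_OXYGEN)}"
        )
    total = 0.0
    for element, count in formula.items():
        if not (isinstance(count, (int, np.integer)) and count > 0):
            raise ValueError(f"count for element {element!r} must be a positive integer")
        if element == "O":
            total += count * _LE_BAS_OXYGEN[functional_context]
        elif element in _LE_BAS_INCREMENTS:
            total += count * _LE_BAS_INCREMENTS[element]
        else:
            raise ValueError(f"no Le Bas increment defined for element {element!r}")
    return total


@dataclass(frozen=True)
class SoluteSpec:
    """A solute to be extracted (e.g. a monoterpene).

    ``le_bas_volume`` (cm³/mol) may be given directly; otherwise it is
    computed from ``formula`` with :func:`le_bas_molar_volume` using
    ``oxygen_context``.
    """

    name: str
    formula: dict[str, int] = field(default_factory=dict)
    molar_mass: float = 0.0  # g/mol
    le_bas_volume: float | None = None  # cm³/mol
    oxygen_context: str = "carbonyl"

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if self.le_bas_volume is not None and self.le_bas_volume <= 0:
            raise ValueError("le_bas_volume must be positive when given")

    def molar_volume(self) -> float:
        """Solute molar volume V_A in cm³/mol (given or Le Bas)."""
        if self.le_bas_volume is not None:
            return self.le_bas_volume
        return le_bas_molar_volume(self.formula, self.oxygen_context)


@dataclass(frozen=True)
class PhaseSpec:
    """A bulk liquid phase (solvent or aqueous medium) and its properties.

    ``association_factor`` is the Wilke–Chang solvent association parameter
    φ (2.6 for water, 1.0 for non-associated organics).  ``water_miscible``
    marks solvents with appreciable mutual solubility with water, for which
    predicted partition coefficients are unreliable.
    """

    name: str
    molar_mass: float  # g/mol
    viscosity: float  # mPa·s at reference temperature
    density: float  # kg/m³
    vapour_pressure: float | None = None  # hPa
    toxicity_class: int | None = None  # ICH Q3C residual-solvent class
    association_factor: float | None = None
    water_miscible: bool = False

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.toxicity_class is not None and self.toxicity_class not in (1, 2, 3):
            raise ValueError("toxicity_class must be 1, 2 or 3")
        if self.association_factor is not None and self.association_factor < 1:
            raise ValueError("association_factor must be >= 1")


#: Water at 25 °C, the reference aqueous phase.
WATER = PhaseSpec(
    name="water",
    molar_mass=18.02,
    viscosity=0.89,
    density=997.0,
    association_factor=2.6,
)


@dataclass(frozen=True)
class Diffusivity:
    """A molecular diffusion coefficient with its provenance."""

    value: float  # m²/s
    solute: str
    phase: str
    temperature: float  # K

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("diffusivity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class DimensionlessGroups:
    reynolds: float
    schmidt: float
    sherwood: float | None = None
    graetz: float | None = None

    def __post_init__(self) -> None:
        for name in ("reynolds", "schmidt", "sherwood", "graetz"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


def wilke_chang_diffusivity(
    solute: SoluteSpec, phase: PhaseSpec, temperature: float = 298.15
) -> Diffusivity:
    """Wilke–Chang diffusion coefficient of ``solute`` in ``phase``, m²/s.

    D = 7.4e-8 · (φ·M)^0.5 · T / (μ · V^0.6)  [cm²/s]

    with φ the solvent association factor, M the solvent molar mass (g/mol),
    T in K, μ in cP and V the solute Le Bas molar volume (cm³/mol).
    Deterministic; scales linearly in T and inversely in μ.
    """
    if phase.association_factor is None:
        raise ValueError(
            f"phase {phase.name!r} has no association factor; set it to 1.0 for "
            "non-associated organic solvents or 2.6 for water"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    volume = solute.molar_volume()
    d_cm2_s = (
        7.4e-8
        * math.sqrt(phase.association_factor * phase.molar_mass)
        * temperature
        / (phase.viscosity * volume**0.6)
    )
    return Diffusivity(
        value=d_cm2_s * 1e-4, solute=solute.name, phase=phase.name, temperature=temperature
    )


def partition_coefficient(c_s: float, c_w: float) -> float:
    """Equilibrium partition coefficient P = c_s / c_w (organic over aqueous)."""
    if c_s < 0 or c_w < 0:
        raise ValueError("concentrations must be non-negative")
    if c_w == 0:
        raise ValueError("aqueous concentration is zero: partition ratio undefined")
    return c_s / c_w


@dataclass(frozen=True)
class PartitionSystem:
    """A solute / organic-solvent / aqueous-medium system with its measured P."""

    solute: SoluteSpec
    organic: PhaseSpec
    aqueous_medium: str
    P: float

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("partition coefficient must be positive")

    @property
    def logP(self) -> float:
        return math.log10(self.P)


@dataclass(frozen=True)
class PartitionEstimate:
    """Replicate summary of a two-phase equilibrium experiment."""

    mean_logP: float
    sd_logP: float  # sample SD over replicates (0.0 for a single replicate)
    n_replicates: int
    excluded: tuple[int, ...]  # replicate indices excluded (c_w == 0)
    closure: float | None  # mean recovered/expected mass fraction
    closure_ok: bool | None

    @property
    def mean_P(self) -> float:
        return 10.0**self.mean_logP


def estimate_partition(
    replicates,
    c_total_expected: float | None = None,
    phase_ratio: float = 1.0,
    closure_band: tuple[float, float] = (0.85, 1.15),
) -> PartitionEstimate:
    """Estimate logP (mean ± sample SD) from replicate (c_s, c_w) pairs.

    ``phase_ratio`` is V_organic/V_aqueous.  When ``c_total_expected`` (the
    initial aqueous concentration, same units as the replicates) is given, a
    mass-balance closure fraction (c_w + phase_ratio·c_s)/c_total is computed
    and flagged when outside ``closure_band``.  Replicates with c_w == 0 are
    excluded with a warning, never silently dropped.
    """
    pairs = [(float(c_s), float(c_w)) for c_s, c_w in replicates]
    if not pairs:
        raise ValueError("at least one replicate is required")
    if any(c_s < 0 or c_w < 0 for c_s, c_w in pairs):
        raise ValueError("concentrations must be non-negative")
    excluded = tuple(i for i, (_, c_w) in enumerate(pairs) if c_w == 0)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} replicate(s) with zero aqueous "
            f"concentration (indices {list(excluded)}): partition ratio undefined",
            stacklevel=2,
        )
    kept = [p for i, p in enumerate(pairs) if i not in excluded]
    if not kept:
        raise ValueError("all replicates have zero aqueous concentration")
    logps = np.log10([c_s / c_w for c_s, c_w in kept])
    mean = float(np.mean(logps))
    sd = float(np.std(logps, ddof=1)) if len(logps) > 1 else 0.0

    closure = closure_ok = None
    if c_total_expected is not None:
        if c_total_expected <= 0:
            raise ValueError("c_total_expected must be positive")
        recovered = [(c_w + phase_ratio * c_s) / c_total_expected for c_s, c_w in kept]
        closure = float(np.mean(recovered))
        closure_ok = closure_band[0] <= closure <= closure_band[1]
        if not closure_ok:
            warnings.warn(
                f"mass-balance closure {closure:.3f} outside band {closure_band}",
                stacklevel=2,
            )
    return PartitionEstimate(mean, sd, len(kept), excluded, closure, closure_ok)


def reynolds_schmidt(
    flow: float,
    characteristic_diameter: float,
    flow_area: float,
    phase: PhaseSpec,
    D: Diffusivity,
    length: float | None = None,
) -> DimensionlessGroups:
    """Reynolds, Schmidt and (when ``length`` is given) Graetz numbers.

    Re = ρ·v·d/μ with v = flow/flow_area; Sc = μ/(ρ·D); Gz = Re·Sc·d/L.
    ``flow`` in m³/s, diameters in m, ``flow_area`` in m².
    """
    if flow_area <= 0:
        raise ValueError("flow area must be positive")
    if flow <= 0 or characteristic_diameter <= 0:
        raise ValueError("flow and characteristic diameter must be positive")
    mu_pa_s = phase.viscosity * 1e-3
    velocity = flow / flow_area
    re = phase.density * velocity * characteristic_diameter / mu_pa_s
    sc = mu_pa_s / (phase.density * D.value)
    gz = re * sc * characteristic_diameter / length if length else None
    return DimensionlessGroups(reynolds=re, schmidt=sc, graetz=gz)
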