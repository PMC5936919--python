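"""Hollow-fibre membrane contactor geometry and mass-transfer coefficients.

The contactor immobilises the aqueous/organic interface in the pores of
hydrophobic (organic-wetted) hollow fibres.  The overall aqueous-side mass
transfer coefficient K_w follows a resistance-in-series model: aqueous film,
membrane and organic film resistances in series on a common diameter basis,
the organic and membrane terms damped by the partition coefficient P:

    1/(K_w·d_basis) = 1/(P·k_o·d_other) + 1/(P·k_m·d_lm) + 1/(k_w·d_basis)

Individual film coefficients come from the Lévêque solution (laminar lumen
flow), a parallel-flow shell correlation (Sh = β·d_h(1−θ)/L·Re^0.6·Sc^0.33,
β = 5.8 for hydrophobic membranes) and the porous-wall membrane expression
k_m = 2εD/(τ(d_o−d_i)).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .physprops import Diffusivity, PhaseSpec

__all__ = [
    "Mode",
    "MembraneModule",
    "OperatingPoint",
    "MassTransferBreakdown",
    "LowGraetzWarning",
    "log_mean_diameter",
    "graetz_number",
    "k_fibre_leveque",
    "k_shell_parallel_flow",
    "k_membrane",
    "overall_kw",
]

#: Graetz number below which the Lévêque solution loses accuracy.
GRAETZ_THRESHOLD = 4.0


class LowGraetzWarning(UserWarning):
    """Lumen flow is below the Graetz range where the Lévêque solution holds."""


class Mode(str, enum.Enum):
    """Which side the aqueous (donor) phase is pumped through."""

    AQUEOUS_IN_LUMEN = "in-out"
    AQUEOUS_IN_SHELL = "out-in"

    @classmethod
    def parse(cls, value: "Mode | str") -> "Mode":
        if isinstance(value, cls):
            return value
        for mode in cls:
            if value in (mode.value, mode.name):
                return mode
        raise ValueError(f"unknown operation mode {value!r}; use 'in-out' or 'out-in'")


def log_mean_diameter(d_i: float, d_o: float) -> float:
    """Log-mean diameter (d_o − d_i)/ln(d_o/d_i); continuous limit d at d_o = d_i."""
    if d_i <= 0 or d_o <= 0:
        raise ValueError("diameters must be positive")
    if d_o < d_i:
        raise ValueError("outer diameter must be >= inner diameter")
    if d_o == d_i:
        return d_i
    return (d_o - d_i) / math.log(d_o / d_i)


@dataclass(frozen=True)
class MembraneModule:
    """Geometry and membrane parameters of a hollow-fibre module.

    All lengths in metres.  ``shell_correlation_coefficient`` is the β factor
    of the parallel-flow shell correlation (5.8 for hydrophobic membranes).
    """

    n_fibres: int
    d_i: float
    d_o: float
    length: float
    pore_size: float | None = None
    porosity: float = 0.45
    tortuosity: float = 2.0
    shell_inner_diameter: float | None = None
    shell_correlation_coefficient: float = 5.8

    def __post_init__(self) -> None:
        if self.n_fibres < 1:
            raise ValueError("need at least one fibre")
        if not 0 < self.d_i < self.d_o:
            raise ValueError("require d_o > d_i > 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must be in (0, 1)")
        if self.tortuosity < 1:
            raise ValueError("tortuosity must be >= 1")
        if self.shell_inner_diameter is not None and not 0 < self.packing_fraction < 1:
            raise ValueError("fibre packing fraction must be in (0, 1): fibres exceed shell")

    @property
    def inner_area(self) -> float:
        """Total lumen-side interfacial area A_i = n·π·d_i·L, m²."""
        return self.n_fibres * math.pi * self.d_i * self.length

    @property
    def outer_area(self) -> float:
        """Total shell-side interfacial area A_o = n·π·d_o·L, m²."""
        return self.n_fibres * math.pi * self.d_o * self.length

    @property
    def log_mean_diameter(self) -> float:
        return log_mean_diameter(self.d_i, self.d_o)

    @property
    def packing_fraction(self) -> float:
        """θ = n·d_o²/D_shell², fraction of the shell cross-section filled by fibres."""
        self._require_shell()
        return self.n_fibres * self.d_o**2 / self.shell_inner_diameter**2

    @property
    def hydraulic_diameter(self) -> float:
        """d_h = (D_shell² − n·d_o²)/(n·d_o), wetted-perimeter form for fibres in a shell."""
        self._require_shell()
        return (self.shell_inner_diameter**2 - self.n_fibres * self.d_o**2) / (
            self.n_fibres * self.d_o
        )

    @property
    def shell_flow_area(self) -> float:
        """Free shell cross-section π/4·(D_shell² − n·d_o²), m²."""
        self._require_shell()
        return math.pi / 4 * (self.shell_inner_diameter**2 - self.n_fibres * self.d_o**2)

    @property
    def lumen_flow_area(self) -> float:
        """Single-fibre lumen cross-section π/4·d_i², m²."""
        return math.pi / 4 * self.d_i**2

    def area(self, mode: "Mode | str") -> float:
        """Interfacial area on the aqueous side of ``mode`` (inner for in-out)."""
        return (
            self.inner_area
            if Mode.parse(mode) is Mode.AQUEOUS_IN_LUMEN
            else self.outer_area
        )

    def _require_shell(self) -> None:
        if self.shell_inner_diameter is None:
            raise ValueError("shell_inner_diameter is required for shell-side quantities")


@dataclass(frozen=True)
class OperatingPoint:
    """Flows, reservoir volumes and initial condition of a recirculating run."""

    mode: Mode
    Q_lumen: float  # m³/s, total lumen-side flow (all fibres)
    Q_shell: float  # m³/s
    temperature: float = 298.15  # K
    V_w: float | None = None  # m³, aqueous reservoir
    V_s: float | None = None  # m³, organic reservoir
    c_w0: float | None = None  # kg/m³, initial aqueous solute concentration

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode.parse(self.mode))
        if self.Q_lumen <= 0 or self.Q_shell <= 0:
            raise ValueError("flows must be positive")
        for name in ("V_w", "V_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_w0 is not None and self.c_w0 < 0:
            raise ValueError("initial concentration must be non-negative")

    @property
    def Q_w(self) -> float:
        """Aqueous-stream flow for the configured mode."""
        return self.Q_lumen if self.mode is Mode.AQUEOUS_IN_LUMEN else self.Q_shell

    @property
    def Q_s(self) -> float:
        """Organic-stream flow for the configured mode."""
        return self.Q_shell if self.mode is Mode.AQUEOUS_IN_LUMEN else self.Q_lumen


def graetz_number(flow_per_fibre: float, d_i: float, length: float, D: Diffusivity) -> float:
    """Gz = Re·Sc·d_i/L = v·d_i²/(D·L) for laminar lumen flow."""
    velocity = flow_per_fibre / (math.pi / 4 * d_i**2)
    return velocity * d_i**2 / (D.value * length)


def k_fibre_leveque(
    D: Diffusivity, d_i: float, flow_per_fibre: float, length: float
) -> float:
    """Lumen-side film coefficient from the Lévêque solution, m/s.

    k = 1.62·(D/d_i)·(d_i²·v/(L·D))^(1/3), equivalent to Sh = 1.62·Gz^(1/3),
    with v the mean linear velocity in one fibre.  Warns (:class:`LowGraetzWarning`)
    when Gz < 4, outside the validity range of the Lévêque solution.
    """
    if flow_per_fibre <= 0:
        raise ValueError("flow must be positive")
    if d_i <= 0 or length <= 0:
        raise ValueError("geometry must be positive")
    gz = graetz_number(flow_per_fibre, d_i, length, D)
    if gz < GRAETZ_THRESHOLD:
        warnings.warn(
            f"Graetz number {gz:.3g} < {GRAETZ_THRESHOLD}: Lévêque solution may "
            "overestimate the lumen-side coefficient",
            LowGraetzWarning,
            stacklevel=2,
        )
    velocity = flow_per_fibre / (math.pi / 4 * d_i**2)
    return 1.62 * (D.value / d_i) * (d_i**2 * velocity / (length * D.value)) ** (1 / 3)


def k_shell_parallel_flow(
    D: Diffusivity, module: MembraneModule, shell_flow: float, phase: PhaseSpec
) -> float:
    """Shell-side film coefficient for flow parallel to the fibres, m/s.

    k = β·(D/d_h)·(1−θ)·(d_h/L)·Re^0.6·Sc^0.33 with Re on the hydraulic
    diameter and the superficial velocity over the free shell cross-section.
    """
    if shell_flow <= 0:
        raise ValueError("shell flow must be positive")
    theta = module.packing_fraction  # validates θ ∈ (0,1)
    d_h = module.hydraulic_diameter
    mu_pa_s = phase.viscosity * 1e-3
    velocity = shell_flow / module.shell_flow_area
    re = phase.density * velocity * d_h / mu_pa_s
    sc = mu_pa_s / (phase.density * D.value)
    beta = module.shell_correlation_coefficient
    return (
        beta * (D.value / d_h) * (1 - theta) * (d_h / module.length) * re**0.6 * sc**0.33
    )


def k_membrane(D_wetting: Diffusivity, module: MembraneModule) -> float:
    """Membrane coefficient k_m = 2εD/(τ·(d_o − d_i)), m/s.

    ``D_wetting`` is the diffusivity in the pore-wetting phase — the organic
    solvent for a hydrophobic membrane.
    """
    wall = module.d_o - module.d_i
    if wall <= 0:
        raise ValueError("zero membrane wall: d_o must exceed d_i")
    return 2 * module.porosity * D_wetting.value / (module.tortuosity * wall)


@dataclass(frozen=True)
class MassTransferBreakdown:
    """Overall aqueous-basis coefficient K_w and its resistance decomposition.

    ``resistance_fractions`` are (aqueous film, membrane, organic film)
    contributions to the total resistance; they sum to 1.
    """

    mode: Mode
    K_w: float  # m/s, overall on the aqueous-side diameter basis
    k_aqueous: float  # m/s, aqueous film (k_fibre in in-out, k_shell in out-in)
    k_organic: float  # m/s, organic film
    k_membrane: float  # m/s
    partition: float
    resistance_fractions: tuple[float, float, float]
    basis_diameter: float  # m (d_i for in-out, d_o for out-in)

    @property
    def k_fibre(self) -> float:
        return self.k_aqueous if self.mode is Mode.AQUEOUS_IN_LUMEN else self.k_organic

    @property
    def k_shell(self) -> float:
        return self.k_organic if self.mode is Mode.AQUEOUS_IN_LUMEN else self.k_aqueous


def overall_kw(
    P: float,
    k_w: float,
    k_o: float,
    k_m: float,
    module: MembraneModule,
    mode: Mode | str,
) -> MassTransferBreakdown:
    """Combine film coefficients into the overall aqueous-basis K_w.

    1/(K_w·d_basis) = 1/(P·k_o·d_other) + 1/(P·k_m·d_lm) + 1/(k_w·d_basis)

    where d_basis = d_i when the aqueous phase is in the lumen ("in-out")
    and d_o when it is in the shell ("out-in"); d_other is the opposite
    diameter.  The organic phase wets the hydrophobic membrane, so the
    organic and membrane resistances carry the partition coefficient P.
    """
    mode = Mode.parse(mode)
    if P <= 0:
        raise ValueError("partition coefficient must be positive")
    if min(k_w, k_o, k_m) <= 0:
        raise ValueError("film coefficients must be positive")
    if mode is Mode.AQUEOUS_IN_LUMEN:
        d_basis, d_other = module.d_i, module.d_o
    else:
        d_basis, d_other = module.d_o, module.d_i
    r_org = 1.0 / (P * k_o * d_other)
    r_mem = 1.0 / (P * k_m * module.log_mean_diameter)
    r_aq = 1.0 / (k_w * d_basis)
    total = r_aq + r_mem + r_org
    return MassTransferBreakdown(
        mode=mode,
        K_w=1.0 / (total * d_basis),
        k_aqueous=k_w,
        k_organic=k_o,
        k_membrane=k_m,
        partition=P,
        resistance_fractions=(r_aq / total, r_mem / total, r_org / total),
        basis_diameter=d_basis,
    )
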