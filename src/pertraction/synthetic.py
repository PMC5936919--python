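"""Synthetic data generation with known ground truth.

Everything the pipeline consumes can be generated here: equilibrium
partition replicates, concentration time courses (with measurement noise
and limit-of-quantification censoring), solvent property tables and a full
reference scenario (carvone extracted from water into n-heptane in a
three-fibre PTFE contactor).  All randomness is seeded; the ground truth is
always returned (and written) alongside the noisy data so estimators can be
validated without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contactor import MembraneModule, Mode, OperatingPoint
from .dynamics import (
    ExtractionFactors,
    TimeCourse,
    extraction_factor_E,
    reservoir_factor_R,
    simulate_timecourse,
)
from .physprops import WATER, PhaseSpec, SoluteSpec

__all__ = [
    "SyntheticConfig",
    "Scenario",
    "synth_partition_replicates",
    "synth_timecourse",
    "carvone_heptane_scenario",
    "DEFAULT_SCHEDULE_MIN",
]

#: Default sampling schedule, minutes (8-hour run, denser early sampling).
DEFAULT_SCHEDULE_MIN: tuple[float, ...] = (0, 15, 30, 60, 120, 240, 360, 480)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and noise model for synthetic data generation.

    ``noise_model`` is 'multiplicative' (c·(1 + sd·ε)) or 'additive'
    (c + sd·ε), ε ~ N(0,1).  ``loq`` censors concentrations below the limit
    of quantification to NaN.  A fixed seed gives bit-identical output.
    """

    logP: float = 2.8
    phi: float = 0.222
    schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN
    noise_model: str = "multiplicative"
    sd: float = 0.02
    loq: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError("noise_model must be 'multiplicative' or 'additive'")
        if len(self.schedule_min) and np.any(np.diff(self.schedule_min) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if not np.all(np.isfinite(self.schedule_min)):
            raise ValueError("schedule contains non-finite times")

    @property
    def P(self) -> float:
        return 10.0**self.logP


def _apply_noise(values: np.ndarray, config: SyntheticConfig, rng) -> np.ndarray:
    if config.sd == 0:
        return values.copy()
    eps = rng.standard_normal(values.shape)
    if config.noise_model == "multiplicative":
        noisy = values * (1.0 + config.sd * eps)
    else:
        noisy = values + config.sd * eps
    return np.clip(noisy, 0.0, None)


def _censor(values: np.ndarray, loq: float | None) -> np.ndarray:
    if loq is None:
        return values
    out = values.copy()
    out[out < loq] = np.nan
    return out


def synth_partition_replicates(
    config: SyntheticConfig,
    n_replicates: int = 3,
    c_total: float = 0.4,
    phase_ratio: float = 1.0,
):
    """Noisy two-phase equilibrium replicates at a known partition coefficient.

    With V_org/V_aq = ``phase_ratio`` and all solute initially in the aqueous
    phase at ``c_total`` (mg/ml), the noiseless equilibrium is
    c_w = c_total/(1 + P·phase_ratio), c_s = P·c_w — exact mass balance.
    Returns an (n, 2) array of (c_s, c_w) pairs.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if c_total <= 0 or phase_ratio <= 0:
        raise ValueError("c_total and phase_ratio must be positive")
    rng = np.random.default_rng(config.seed)
    P = config.P
    c_w = c_total / (1.0 + P * phase_ratio)
    c_s = P * c_w
    clean = np.tile([c_s, c_w], (n_replicates, 1))
    return _apply_noise(clean, config, rng)


def synth_timecourse(
    config: SyntheticConfig, operating: OperatingPoint
) -> tuple[TimeCourse, TimeCourse]:
    """A noisy, possibly censored time course plus its noiseless ground truth.

    Reservoir traces come from the closed-form recirculation solution at the
    configured (Φ, R); module-outlet stream concentrations follow the
    single-pass balance c_w,out = c_w·(1 − Φ) + (Φ/P)·c_s and the organic
    outlet from the stream mass balance.  Returns ``(noisy, truth)``.
    """
    for name in ("V_w", "V_s", "c_w0"):
        if getattr(operating, name) is None:
            raise ValueError(f"operating point must define {name}")
    P = config.P
    factors = ExtractionFactors(
        E=extraction_factor_E(P, operating.Q_s, operating.Q_w),
        R=reservoir_factor_R(P, operating.V_s, operating.V_w),
        phi=config.phi,
    )
    times = np.asarray(config.schedule_min, dtype=float) * 60.0
    truth = simulate_timecourse(
        factors, operating.Q_w, operating.V_w, operating.c_w0, operating.V_s, times
    )
    c_w_out = truth.c_w * (1.0 - config.phi) + (config.phi / P) * truth.c_s
    c_s_out = truth.c_s + (operating.Q_w / operating.Q_s) * (truth.c_w - c_w_out)
    truth = replace(truth, c_w_out=c_w_out, c_s_out=c_s_out)

    rng = np.random.default_rng(config.seed)
    noisy_blocks = [
        _apply_noise(np.asarray(block), config, rng)
        for block in (truth.c_w, truth.c_s, c_w_out, c_s_out)
    ]
    noisy = TimeCourse(
        times=times,
        c_w=_censor(noisy_blocks[0], config.loq),
        c_s=_censor(noisy_blocks[1], config.loq),
        c_w0=operating.c_w0,
        c_w_out=_censor(noisy_blocks[2], config.loq),
        c_s_out=_censor(noisy_blocks[3], config.loq),
        meta={"config": config, "truth": truth},
    )
    return noisy, truth


# --------------------------------------------------------------------------
# Reference scenario: carvone / water / n-heptane in the three-fibre module
# --------------------------------------------------------------------------

#: (S)-(+)-carvone, C10H14O, a cyclic monoterpene ketone.
CARVONE = SoluteSpec(
    name="(S)-(+)-carvone",
    formula={"C": 10, "H": 14, "O": 1},
    molar_mass=150.22,
    oxygen_context="carbonyl",
)

# Published property table of the candidate solvents (molar mass g/mol,
# viscosity mPa·s, density kg/m³, vapour pressure hPa, ICH Q3C class).
_SOLVENT_ROWS = [
    # name,        M,     mu,   rho, pvap, class, phi_assoc, miscible
    ("n-butanol", 72.1, 3.10, 808.0, 18.3, 3, 1.0, True),
    ("n-octanol", 130.2, 7.40, 827.0, 8.7, 3, 1.0, True),
    ("ethyl acetate", 88.1, 0.43, 894.0, 97.0, 3, 1.0, False),
    ("n-hexane", 86.2, 0.29, 655.0, 160.0, 2, 1.0, False),
    ("n-heptane", 100.2, 0.39, 684.0, 48.0, 3, 1.0, False),
]

# Synthetic logP table (carvone in solvent/water systems).  These are
# plausible stand-in values with the study's qualitative ordering, NOT
# measured data: the non-polar solvents predict well (|pred − exp| < 0.2)
# and the water-miscible alcohols do not.
_PARTITION_ROWS = [
    # solvent, medium, logP_pred, logP_exp
    ("n-butanol", "water", 1.10, 0.35),
    ("n-octanol", "water", 2.60, 2.45),
    ("ethyl acetate", "water", 2.95, 2.85),
    ("n-hexane", "water", 2.85, 2.75),
    ("n-heptane", "water", 2.85, 2.80),
]

ML = 1e-6  # m³
ML_MIN = 1e-6 / 60.0  # m³/s


@dataclass(frozen=True)
class Scenario:
    """A complete, self-consistent input set for the extraction pipeline."""

    solute: SoluteSpec
    aqueous: PhaseSpec
    organic: PhaseSpec
    solvents: dict[str, PhaseSpec]
    module: MembraneModule
    operating_in_out: OperatingPoint
    operating_out_in: OperatingPoint
    logP: float
    solvent_table: pd.DataFrame = field(repr=False)
    partition_table: pd.DataFrame = field(repr=False)

    @property
    def P(self) -> float:
        return 10.0**self.logP

    def operating(self, mode: Mode | str) -> OperatingPoint:
        return (
            self.operating_in_out
            if Mode.parse(mode) is Mode.AQUEOUS_IN_LUMEN
            else self.operating_out_in
        )


def carvone_heptane_scenario() -> Scenario:
    """The reference study conditions: carvone/water/n-heptane, 3-fibre module.

    Module: three PTFE fibres, 1 µm pores, 3 mm inner diameter, 20 cm
    length (≈56 cm² inner interfacial area).  Fibre outer diameter, shell
    inner diameter, porosity and tortuosity are not part of the printed
    record; the values used here (d_o = 4 mm, shell 10 mm, ε = 0.45,
    τ = 2.0) are documented assumptions typical of porous PTFE tubing.
    Flows: 3 ml/min lumen, 40 ml/min shell.  Reservoirs: 100 ml aqueous /
    50 ml organic (the 2:1 phase ratio; the absolute volumes are assumed).
    Initial aqueous carvone 0.15 mg/ml; carvone/n-heptane logP 2.8.
    """
    solvents = {
        name: PhaseSpec(
            name=name,
            molar_mass=m,
            viscosity=mu,
            density=rho,
            vapour_pressure=pvap,
            toxicity_class=cls,
            association_factor=assoc,
            water_miscible=misc,
        )
        for name, m, mu, rho, pvap, cls, assoc, misc in _SOLVENT_ROWS
    }
    module = MembraneModule(
        n_fibres=3,
        d_i=3e-3,
        d_o=4e-3,
        length=0.2,
        pore_size=1e-6,
        porosity=0.45,
        tortuosity=2.0,
        shell_inner_diameter=10e-3,
        shell_correlation_coefficient=5.8,
    )
    common = dict(
        Q_lumen=3 * ML_MIN,
        Q_shell=40 * ML_MIN,
        temperature=298.15,
        V_w=100 * ML,
        V_s=50 * ML,
        c_w0=0.15,
    )
    solvent_table = pd.DataFrame(
        [
            {
                "name": name,
                "molar_mass_g_mol": m,
                "viscosity_mPa_s": mu,
                "density_kg_m3": rho,
                "vapour_pressure_hPa": pvap,
                "toxicity_class": cls,
                "association_factor": assoc,
                "water_miscible": misc,
            }
            for name, m, mu, rho, pvap, cls, assoc, misc in _SOLVENT_ROWS
        ]
    )
    partition_table = pd.DataFrame(
        [
            {
                "solute": CARVONE.name,
                "solvent": solvent,
                "medium": medium,
                "logP_pred": pred,
                "logP_exp": exp,
            }
            for solvent, medium, pred, exp in _PARTITION_ROWS
        ]
    )
    return Scenario(
        solute=CARVONE,
        aqueous=WATER,
        organic=solvents["n-heptane"],
        solvents=solvents,
        module=module,
        operating_in_out=OperatingPoint(mode=Mode.AQUEOUS_IN_LUMEN, **common),
        operating_out_in=OperatingPoint(mode=Mode.AQUEOUS_IN_SHELL, **common),
        logP=2.8,
        solvent_table=solvent_table,
        partition_table=partition_table,
    )
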