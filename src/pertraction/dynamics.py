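"""Recirculating two-reservoir extraction dynamics.

Both streams are recycled through the contactor from stirred reservoirs, so
the driving force decays and no steady state exists.  The aqueous reservoir
balance

    dc_w/dt = −(Q_w·Φ/V_w)·[c_w·(1 + 1/R) − c_w0/R]

has the closed-form solution implemented here.  Φ is the single-pass module
extraction efficiency, E = P·Q_s/Q_w the module extraction factor and
R = P·V_s/V_w the reservoir extraction factor; c_w → c_w0/(1+R) at
equilibrium and the phases then satisfy c_s/c_w = P exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ExtractionFactors",
    "TimeCourse",
    "extraction_factor_E",
    "reservoir_factor_R",
    "module_efficiency_phi",
    "kw_from_phi",
    "simulate_timecourse",
    "mass_balance_metrics",
]


def extraction_factor_E(P: float, Q_s: float, Q_w: float) -> float:
    """Module extraction factor E = P·Q_s/Q_w."""
    if Q_w <= 0:
        raise ValueError("aqueous flow must be positive")
    if P <= 0 or Q_s <= 0:
        raise ValueError("P and organic flow must be positive")
    return P * Q_s / Q_w


def reservoir_factor_R(P: float, V_s: float, V_w: float) -> float:
    """Reservoir extraction factor R = P·V_s/V_w."""
    if V_w <= 0:
        raise ValueError("aqueous reservoir volume must be positive")
    if P <= 0 or V_s <= 0:
        raise ValueError("P and organic volume must be positive")
    return P * V_s / V_w


@dataclass(frozen=True)
class ExtractionFactors:
    """The three dimensionless groups governing the recirculating extraction."""

    E: float
    R: float
    phi: float

    def __post_init__(self) -> None:
        if self.E <= 0 or self.R <= 0:
            raise ValueError("extraction factors must be positive")
        if not 0 < self.phi < 1:
            raise ValueError("module efficiency must lie in (0, 1)")


# Relative half-width around E = 1 inside which the analytic limit is used.
_E_LIMIT_TOL = 1e-9


def module_efficiency_phi(K_w: float, A: float, Q_w: float, E: float) -> float:
    """Single-pass module extraction efficiency Φ ∈ [0, 1).

    With x = K_w·A/Q_w and a = 1 − 1/E:

        Φ = (1 − e^(−x·a)) / (1 − e^(−x·a)/E)

    At E = 1 the continuous limit Φ = x/(1 + x) is used.  Φ = 0 when K_w = 0
    and Φ → min(1, E) as x → ∞.
    """
    if K_w < 0:
        raise ValueError("K_w must be non-negative")
    if A <= 0 or Q_w <= 0 or E <= 0:
        raise ValueError("area, flow and E must be positive")
    x = K_w * A / Q_w
    if abs(E - 1.0) < _E_LIMIT_TOL:
        return x / (1.0 + x)
    a = 1.0 - 1.0 / E
    # -expm1 keeps precision for small x; guard overflow for strongly negative a·x
    exponent = -x * a
    if exponent > 700.0:  # E < 1 and large x: Φ → E
        return E if E < 1 else 1.0
    em = math.exp(exponent)
    return (1.0 - em) / (1.0 - em / E)


def kw_from_phi(phi: float, A: float, Q_w: float, E: float) -> float:
    """Invert :func:`module_efficiency_phi` for K_w at a measured Φ.

    Solves Φ(x) = phi for x = K_w·A/Q_w by bracketed root finding (Φ is
    strictly increasing in x) and returns K_w = x·Q_w/A.  Raises when ``phi``
    is at or above the supremum min(1, E) attainable at the given E.
    """
    if not 0 < phi < 1:
        raise ValueError("phi must lie strictly between 0 and 1")
    if A <= 0 or Q_w <= 0 or E <= 0:
        raise ValueError("area, flow and E must be positive")
    sup = min(1.0, E)
    if phi >= sup:
        raise ValueError(
            f"phi = {phi} is not attainable for E = {E}: the single-pass "
            f"efficiency is bounded by min(1, E) = {sup}"
        )
    f = lambda x: module_efficiency_phi(x * Q_w / A, A, Q_w, E) - phi
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"phi = {phi} too close to its supremum for E = {E}")
    x = brentq(f, 0.0, hi, xtol=1e-300, rtol=1e-14)
    return x * Q_w / A


@dataclass(frozen=True)
class TimeCourse:
    """Sampled reservoir (and optionally stream) concentrations over time.

    ``times`` in seconds, concentrations in kg/m³ (numerically equal to
    mg/ml).  ``c_w_out``/``c_s_out`` are module-outlet stream concentrations
    when available; NaN marks censored (below-LOQ) samples.
    """

    times: np.ndarray
    c_w: np.ndarray
    c_s: np.ndarray
    c_w0: float
    c_w_out: np.ndarray | None = None
    c_s_out: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "c_w", np.asarray(self.c_w, dtype=float))
        object.__setattr__(self, "c_s", np.asarray(self.c_s, dtype=float))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be one-dimensional and strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must start at or after zero")
        if len(self.c_w) != len(self.times) or len(self.c_s) != len(self.times):
            raise ValueError("concentration arrays must match times in length")
        if self.c_w0 < 0:
            raise ValueError("initial concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame: time_min, stream, location, conc_mg_ml."""
        rows = []
        t_min = self.times / 60.0
        blocks = [("aqueous", "reservoir", self.c_w), ("organic", "reservoir", self.c_s)]
        if self.c_w_out is not None:
            blocks.append(("aqueous", "outlet", np.asarray(self.c_w_out, dtype=float)))
        if self.c_s_out is not None:
            blocks.append(("organic", "outlet", np.asarray(self.c_s_out, dtype=float)))
        for stream, location, conc in blocks:
            for t, c in zip(t_min, conc):
                rows.append(
                    {"time_min": t, "stream": stream, "location": location, "conc_mg_ml": c}
                )
        return pd.DataFrame(rows)


def simulate_timecourse(
    factors: ExtractionFactors,
    Q_w: float,
    V_w: float,
    c_w0: float,
    V_s: float,
    times,
) -> TimeCourse:
    """Closed-form reservoir concentrations of the recirculating extraction.

    c_w(t) = c_w0·[1/R + exp(−(Q_w·Φ/V_w)·(1 + 1/R)·t)]/(1 + 1/R) and the
    organic reservoir follows by mass conservation,
    c_s(t) = (V_w/V_s)·(c_w0 − c_w(t)).
    """
    if Q_w <= 0 or V_w <= 0 or V_s <= 0:
        raise ValueError("flow and volumes must be positive")
    if c_w0 < 0:
        raise ValueError("initial concentration must be non-negative")
    t = np.asarray(times, dtype=float)
    R, phi = factors.R, factors.phi
    rate = (Q_w * phi / V_w) * (1.0 + 1.0 / R)
    c_w = c_w0 * (1.0 / R + np.exp(-rate * t)) / (1.0 + 1.0 / R)
    c_s = (V_w / V_s) * (c_w0 - c_w)
    return TimeCourse(
        times=t,
        c_w=c_w,
        c_s=c_s,
        c_w0=c_w0,
        meta={"factors": factors, "Q_w": Q_w, "V_w": V_w, "V_s": V_s},
    )


def mass_balance_metrics(
    course: TimeCourse, V_w: float, V_s: float, c_w0: float | None = None
) -> pd.DataFrame:
    """Per-time-point recovery, concentration factor and organic enrichment.

    recovery(t)       = (V_w·c_w + V_s·c_s)/(V_w·c_w0)  — fraction of the
                        initial solute found in either phase;
    conc_factor(t)    = c_s/c_w0                         — organic-phase
                        enrichment over the initial aqueous level;
    enrichment(t)     = V_s·c_s/(V_w·c_w0)               — fraction of the
                        initial amount residing in the organic phase.
    """
    if V_w <= 0 or V_s <= 0:
        raise ValueError("volumes must be positive")
    c_w0 = course.c_w0 if c_w0 is None else c_w0
    if c_w0 == 0:
        raise ValueError("initial concentration is zero: metrics undefined")
    total0 = V_w * c_w0
    return pd.DataFrame(
        {
            "time_s": course.times,
            "recovery": (V_w * course.c_w + V_s * course.c_s) / total0,
            "concentration_factor": course.c_s / c_w0,
            "enrichment": V_s * course.c_s / total0,
        }
    )
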