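"""Solvent ranking and prediction validation from partition-coefficient tables.

Predicted logP values (e.g. from quantum-chemistry-based solvation models)
are compared with experimental ones; solvents with appreciable mutual
miscibility with water are flagged as unreliable for prediction.  Candidate
solvents are then ranked by an explicit, configurable policy — by default
lexicographically on ICH Q3C residual-solvent class (class 3 = least toxic,
best), then logP (higher is better), then vapour pressure (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physprops import PhaseSpec

__all__ = ["SolventRecord", "RankingPolicy", "ValidationSummary", "validate_predictions", "rank_solvents"]


@dataclass(frozen=True)
class SolventRecord:
    """One candidate solvent with predicted and/or experimental logP."""

    phase: PhaseSpec
    logP_pred: float | None = None
    logP_exp: float | None = None

    @property
    def name(self) -> str:
        return self.phase.name

    @property
    def deviation(self) -> float | None:
        """|logP_pred − logP_exp| when both are present."""
        if self.logP_pred is None or self.logP_exp is None:
            return None
        return abs(self.logP_pred - self.logP_exp)

    @property
    def reliability_flag(self) -> str:
        """'polar-unreliable' for (partially) water-miscible solvents."""
        return "polar-unreliable" if self.phase.water_miscible else "reliable"

    @property
    def logP(self) -> float | None:
        """Best available logP: experimental when present, else predicted."""
        return self.logP_exp if self.logP_exp is not None else self.logP_pred


@dataclass(frozen=True)
class ValidationSummary:
    """Per-solvent deviation table plus aggregate accuracy measures."""

    table: pd.DataFrame
    mad: float  # mean absolute deviation over validatable records
    n_exceeding: int
    threshold: float
    unvalidatable: tuple[str, ...]


def validate_predictions(records, threshold: float = 0.2) -> ValidationSummary:
    """Compare predicted against experimental logP per solvent.

    Records lacking either value are listed as unvalidatable, not dropped
    silently.  ``threshold`` is the absolute logP deviation above which a
    prediction is flagged (0.2 log units is the accepted accuracy of
    solvation-model predictions for non-polar systems).
    """
    records = list(records)
    if not records:
        raise ValueError("no solvent records to validate")
    rows, devs, unval = [], [], []
    for rec in records:
        dev = rec.deviation
        rows.append(
            {
                "solvent": rec.name,
                "logP_pred": rec.logP_pred,
                "logP_exp": rec.logP_exp,
                "deviation": dev,
                "exceeds_threshold": (dev is not None and dev > threshold),
                "reliability": rec.reliability_flag,
            }
        )
        if dev is None:
            unval.append(rec.name)
        else:
            devs.append(dev)
    if not devs:
        raise ValueError("no record carries both predicted and experimental logP")
    table = pd.DataFrame(rows)
    return ValidationSummary(
        table=table,
        mad=float(np.mean(devs)),
        n_exceeding=int(table["exceeds_threshold"].sum()),
        threshold=threshold,
        unvalidatable=tuple(unval),
    )


# field name -> (accessor, better direction, unit label)
_FIELD_SPECS = {
    "toxicity_class": (lambda r: r.phase.toxicity_class, "desc", "ICH Q3C class"),
    "logP": (lambda r: r.logP, "desc", "log10"),
    "logP_pred": (lambda r: r.logP_pred, "desc", "log10"),
    "logP_exp": (lambda r: r.logP_exp, "desc", "log10"),
    "vapour_pressure": (lambda r: r.phase.vapour_pressure, "asc", "hPa"),
    "viscosity": (lambda r: r.phase.viscosity, "asc", "mPa·s"),
    "density": (lambda r: r.phase.density, "asc", "kg/m³"),
}


@dataclass(frozen=True)
class RankingPolicy:
    """How to order candidate solvents.

    ``keys``: lexicographic (field, direction) pairs, direction 'asc' or
    'desc' where 'desc' means larger-is-better.  When ``weights`` is given a
    weighted score over min-max-normalized fields is used instead; weights
    are relative and fields keep the direction from ``keys`` (or their
    conventional default).
    """

    keys: tuple[tuple[str, str], ...] = (
        ("toxicity_class", "desc"),
        ("logP", "desc"),
        ("vapour_pressure", "asc"),
    )
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, direction in self.keys:
            if name not in _FIELD_SPECS:
                raise ValueError(f"ranking policy references unknown field {name!r}")
            if direction not in ("asc", "desc"):
                raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
        if self.weights is not None:
            for name in self.weights:
                if name not in _FIELD_SPECS:
                    raise ValueError(f"ranking policy references unknown field {name!r}")


def _get(record: SolventRecord, name: str) -> float:
    value = _FIELD_SPECS[name][0](record)
    if value is None:
        raise ValueError(f"solvent {record.name!r} lacks field {name!r} required by the policy")
    return float(value)


def rank_solvents(records, policy: RankingPolicy | None = None) -> pd.DataFrame:
    """Rank candidate solvents under ``policy`` (default lexicographic).

    Returns a frame ordered best-first with columns rank, solvent, the policy
    fields, ties (names sharing identical key values) and a human-readable
    rationale per solvent.  The sort is stable: ties keep input order.
    """
    records = list(records)
    if not records:
        raise ValueError("no solvent records to rank")
    policy = policy or RankingPolicy()

    if policy.weights:
        order, scores = _weighted_order(records, policy)
    else:
        keyed = []
        for rec in records:
            key = tuple(
                (-_get(rec, name) if direction == "desc" else _get(rec, name))
                for name, direction in policy.keys
            )
            keyed.append(key)
        order = sorted(range(len(records)), key=lambda i: keyed[i])  # stable
        scores = None

    rows = []
    for rank, i in enumerate(order, start=1):
        rec = records[i]
        parts = []
        for name, direction in policy.keys:
            value = _get(rec, name)
            unit = _FIELD_SPECS[name][2]
            better = "higher better" if direction == "desc" else "lower better"
            parts.append(f"{name} = {value:g} {unit} ({better})")
        rationale = "; ".join(parts)
        if rec.reliability_flag == "polar-unreliable":
            rationale += "; CAUTION: water-miscible, predicted logP unreliable"
        ties = (
            [
                records[j].name
                for j in order
                if j != i and not policy.weights
                and all(_get(records[j], n) == _get(rec, n) for n, _ in policy.keys)
            ]
            if not policy.weights
            else []
        )
        row = {"rank": rank, "solvent": rec.name}
        for name, _ in policy.keys:
            row[name] = _get(rec, name)
        row["reliability"] = rec.reliability_flag
        row["ties"] = ",".join(ties)
        row["rationale"] = rationale
        if scores is not None:
            row["score"] = scores[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _weighted_order(records, policy: RankingPolicy):
    directions = dict(policy.keys)
    scores = np.zeros(len(records))
    for name, weight in policy.weights.items():
        values = np.array([_get(rec, name) for rec in records])
        span = values.max() - values.min()
        norm = (values - values.min()) / span if span > 0 else np.zeros_like(values)
        if directions.get(name, _FIELD_SPECS[name][1]) == "asc":
            norm = 1.0 - norm
        scores += weight * norm
    order = sorted(range(len(records)), key=lambda i: -scores[i])
    return order, scores
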