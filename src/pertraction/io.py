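"""Readers and writers for the package's plain-text interchange formats.

* module/operating configuration: flat ``key = value`` text with
  unit-suffixed keys (``d_i_mm``, ``flow_lumen_ml_min``, ...) so unit errors
  fail loudly at the boundary;
* time-course CSV: long format ``time_min, stream, location, conc_mg_ml``;
* solvent property and partition-coefficient CSV tables.

All internal computation is SI; conversion happens here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .contactor import MembraneModule, Mode, OperatingPoint
from .dynamics import TimeCourse
from .physprops import PhaseSpec
from .screening import SolventRecord

__all__ = [
    "FileFormatError",
    "read_module_config",
    "write_module_config",
    "read_timecourse",
    "write_timecourse",
    "read_properties_table",
    "read_partition_table",
    "solvent_records",
]


class FileFormatError(ValueError):
    """A file failed to parse; the message names the file and line."""


ML = 1e-6
ML_MIN = 1e-6 / 60.0

# config key -> (target, attribute, SI scale factor)
_CONFIG_KEYS = {
    "n_fibres": ("module", "n_fibres", None),
    "d_i_mm": ("module", "d_i", 1e-3),
    "d_o_mm": ("module", "d_o", 1e-3),
    "length_cm": ("module", "length", 1e-2),
    "pore_size_um": ("module", "pore_size", 1e-6),
    "porosity": ("module", "porosity", 1.0),
    "tortuosity": ("module", "tortuosity", 1.0),
    "shell_id_mm": ("module", "shell_inner_diameter", 1e-3),
    "shell_beta": ("module", "shell_correlation_coefficient", 1.0),
    "mode": ("operating", "mode", None),
    "flow_lumen_ml_min": ("operating", "Q_lumen", ML_MIN),
    "flow_shell_ml_min": ("operating", "Q_shell", ML_MIN),
    "temperature_c": ("operating", "temperature", None),
    "v_aqueous_ml": ("operating", "V_w", ML),
    "v_organic_ml": ("operating", "V_s", ML),
    "c_w0_mg_ml": ("operating", "c_w0", 1.0),
}

_REQUIRED_MODULE = ("n_fibres", "d_i_mm", "d_o_mm", "length_cm")


def read_module_config(path) -> tuple[MembraneModule, OperatingPoint | None]:
    """Parse a flat key-value configuration file.

    Lines are ``key = value``; ``#`` starts a comment.  Returns the module
    and, when flow keys are present, the operating point (else None).
    """
    module_kw: dict = {}
    op_kw: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FileFormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _CONFIG_KEYS:
                raise FileFormatError(f"{path}:{lineno}: unknown configuration key {key!r}")
            target, attr, scale = _CONFIG_KEYS[key]
            if key == "mode":
                parsed = Mode.parse(value)
            elif key == "n_fibres":
                parsed = int(value)
            elif key == "temperature_c":
                parsed = float(value) + 273.15
            else:
                try:
                    parsed = float(value) * scale
                except ValueError as exc:
                    raise FileFormatError(f"{path}:{lineno}: bad number {value!r}") from exc
            (module_kw if target == "module" else op_kw)[attr] = parsed
    missing = [k for k in _REQUIRED_MODULE if _CONFIG_KEYS[k][1] not in module_kw]
    if missing:
        raise FileFormatError(f"{path}: missing required module keys {missing}")
    module = MembraneModule(**module_kw)
    operating = None
    if "Q_lumen" in op_kw and "Q_shell" in op_kw:
        op_kw.setdefault("mode", Mode.AQUEOUS_IN_LUMEN)
        operating = OperatingPoint(**op_kw)
    return module, operating


def write_module_config(path, module: MembraneModule, operating: OperatingPoint | None = None) -> None:
    lines = [
        "# hollow-fibre membrane module geometry",
        f"n_fibres = {module.n_fibres}",
        f"d_i_mm = {module.d_i / 1e-3:g}",
        f"d_o_mm = {module.d_o / 1e-3:g}",
        f"length_cm = {module.length / 1e-2:g}",
        f"porosity = {module.porosity:g}",
        f"tortuosity = {module.tortuosity:g}",
        f"shell_beta = {module.shell_correlation_coefficient:g}",
    ]
    if module.pore_size is not None:
        lines.append(f"pore_size_um = {module.pore_size / 1e-6:g}")
    if module.shell_inner_diameter is not None:
        lines.append(f"shell_id_mm = {module.shell_inner_diameter / 1e-3:g}")
    if operating is not None:
        lines += [
            "# operating point",
            f"mode = {operating.mode.value}",
            f"flow_lumen_ml_min = {operating.Q_lumen / ML_MIN:g}",
            f"flow_shell_ml_min = {operating.Q_shell / ML_MIN:g}",
            f"temperature_c = {operating.temperature - 273.15:g}",
        ]
        if operating.V_w is not None:
            lines.append(f"v_aqueous_ml = {operating.V_w / ML:g}")
        if operating.V_s is not None:
            lines.append(f"v_organic_ml = {operating.V_s / ML:g}")
        if operating.c_w0 is not None:
            lines.append(f"c_w0_mg_ml = {operating.c_w0:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_TIMECOURSE_COLUMNS = ["time_min", "stream", "location", "conc_mg_ml"]


def read_timecourse(path, c_w0: float | None = None) -> TimeCourse:
    """Read a long-format time-course CSV into a :class:`TimeCourse`.

    The aqueous/organic reservoir rows become c_w/c_s; outlet rows, when
    present, become the stream concentrations.  ``c_w0`` defaults to the
    first aqueous reservoir sample.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FileFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}:1: missing column(s) {missing} in header")
    bad = ~df["stream"].isin(["aqueous", "organic"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise FileFormatError(f"{path}:{line}: stream must be 'aqueous' or 'organic'")

    def pivot(stream: str, location: str):
        sel = df[(df["stream"] == stream) & (df["location"] == location)]
        return sel.sort_values("time_min")

    aq = pivot("aqueous", "reservoir")
    org = pivot("organic", "reservoir")
    if aq.empty:
        raise FileFormatError(f"{path}: no aqueous reservoir rows")
    times = aq["time_min"].to_numpy(dtype=float) * 60.0
    c_w = aq["conc_mg_ml"].to_numpy(dtype=float)
    if not org.empty and len(org) != len(aq):
        raise FileFormatError(f"{path}: aqueous and organic reservoir rows differ in length")
    c_s = org["conc_mg_ml"].to_numpy(dtype=float) if not org.empty else np.zeros_like(c_w)
    kwargs = {}
    for stream, attr in (("aqueous", "c_w_out"), ("organic", "c_s_out")):
        out = pivot(stream, "outlet")
        if not out.empty and len(out) == len(aq):
            kwargs[attr] = out["conc_mg_ml"].to_numpy(dtype=float)
    if c_w0 is None:
        c_w0 = float(c_w[0]) if times[0] == 0 else float(np.nanmax(c_w))
    return TimeCourse(times=times, c_w=c_w, c_s=c_s, c_w0=c_w0, **kwargs)


def write_timecourse(path, course: TimeCourse) -> None:
    course.to_dataframe().to_csv(path, index=False)


def read_properties_table(path) -> dict[str, PhaseSpec]:
    """Read a solvent/solute property CSV into PhaseSpec records by name."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FileFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = ["name", "molar_mass_g_mol", "viscosity_mPa_s", "density_kg_m3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}:1: missing column(s) {missing} in header")

    def opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    phases = {}
    for i, row in df.iterrows():
        try:
            phases[row["name"]] = PhaseSpec(
                name=row["name"],
                molar_mass=float(row["molar_mass_g_mol"]),
                viscosity=float(row["viscosity_mPa_s"]),
                density=float(row["density_kg_m3"]),
                vapour_pressure=opt(row, "vapour_pressure_hPa"),
                toxicity_class=opt(row, "toxicity_class", int),
                association_factor=opt(row, "association_factor"),
                water_miscible=bool(opt(row, "water_miscible", int) or False),
            )
        except (ValueError, TypeError) as exc:
            raise FileFormatError(f"{path}:{int(i) + 2}: {exc}") from exc
    return phases


def read_partition_table(path) -> pd.DataFrame:
    """Read a partition-coefficient CSV (solute, solvent, medium, logP_pred, logP_exp)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FileFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in ("solvent", "logP_pred", "logP_exp") if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}:1: missing column(s) {missing} in header")
    return df


def solvent_records(
    partition: pd.DataFrame, phases: dict[str, PhaseSpec]
) -> list[SolventRecord]:
    """Join a partition table with solvent properties into screening records."""
    records = []
    for _, row in partition.iterrows():
        name = row["solvent"]
        if name not in phases:
            raise ValueError(f"partition table references unknown solvent {name!r}")

        def val(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        records.append(
            SolventRecord(phase=phases[name], logP_pred=val("logP_pred"), logP_exp=val("logP_exp"))
        )
    return records
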