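"""Model/Results interface for fitting the recirculating extraction model.

`ExtractionModel` holds the observed aqueous-reservoir trace together with
the operating configuration; `fit()` returns an `ExtractionResults` carrying
Φ, K_w, their bootstrap uncertainties and fit diagnostics, with `summary()`,
`predict()` and a linearization diagnostic plot.

Example
-------
>>> model = ExtractionModel.from_timecourse(course, operating=op, module=mod, partition=631.0)
>>> res = model.fit(bootstrap=1000, seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np

from . import inference
from .contactor import MembraneModule, OperatingPoint
from .dynamics import (
    ExtractionFactors,
    TimeCourse,
    extraction_factor_E,
    reservoir_factor_R,
    simulate_timecourse,
)

__all__ = ["ExtractionModel", "ExtractionResults"]


class ExtractionModel:
    """Recirculating two-reservoir extraction model bound to observed data.

    Parameters
    ----------
    times, c_w : array-like
        Sampling times (s) and aqueous-reservoir concentrations (kg/m³).
    c_w0 : float, optional
        Initial aqueous concentration; defaults to the first sample.
    operating : OperatingPoint
        Flows, mode, reservoir volumes.
    module : MembraneModule
        Contactor geometry (supplies the interfacial area).
    partition : float
        Partition coefficient P of the solute in the solvent system.
    area : float, optional
        Override the mode-consistent interfacial-area basis.
    """

    def __init__(
        self,
        times,
        c_w,
        *,
        operating: OperatingPoint,
        module: MembraneModule,
        partition: float,
        c_w0: float | None = None,
        area: float | None = None,
    ) -> None:
        times = np.asarray(times, dtype=float)
        c_w = np.asarray(c_w, dtype=float)
        if c_w0 is None:
            if times[0] != 0:
                raise ValueError("c_w0 is required when the trace does not start at t = 0")
            c_w0 = float(c_w[0])
        self.course = TimeCourse(times=times, c_w=c_w, c_s=np.zeros_like(c_w), c_w0=c_w0)
        self.operating = operating
        self.module = module
        self.partition = float(partition)
        self.area = area

    @classmethod
    def from_timecourse(
        cls,
        course: TimeCourse,
        *,
        operating: OperatingPoint,
        module: MembraneModule,
        partition: float,
        area: float | None = None,
    ) -> "ExtractionModel":
        model = cls.__new__(cls)
        model.course = course
        model.operating = operating
        model.module = module
        model.partition = float(partition)
        model.area = area
        return model

    @classmethod
    def from_dataframe(
        cls,
        df,
        *,
        operating: OperatingPoint,
        module: MembraneModule,
        partition: float,
        area: float | None = None,
    ) -> "ExtractionModel":
        """Build from a long-format frame (time_min, stream, location, conc_mg_ml).

        Uses the aqueous-reservoir rows; NaN concentrations are kept and
        excluded (with a reason) during fitting.
        """
        aq = df[(df["stream"] == "aqueous") & (df["location"] == "reservoir")]
        aq = aq.sort_values("time_min")
        if aq.empty:
            raise ValueError("no aqueous reservoir rows in the time-course table")
        times = aq["time_min"].to_numpy(dtype=float) * 60.0
        c_w = aq["conc_mg_ml"].to_numpy(dtype=float)
        return cls(
            times,
            c_w,
            operating=operating,
            module=module,
            partition=partition,
            area=area,
        )

    def fit(
        self, *, origin: bool = True, bootstrap: int = 0, seed: int | None = None
    ) -> "ExtractionResults":
        result = inference.fit_phi_kw(
            self.course,
            self.operating,
            self.module,
            self.partition,
            origin=origin,
            area=self.area,
            bootstrap=bootstrap,
            seed=seed,
        )
        return ExtractionResults(self, result)

    def simulate(self, phi: float, times=None) -> TimeCourse:
        """Forward-simulate the model at a given efficiency Φ."""
        op = self.operating
        factors = ExtractionFactors(
            E=extraction_factor_E(self.partition, op.Q_s, op.Q_w),
            R=reservoir_factor_R(self.partition, op.V_s, op.V_w),
            phi=phi,
        )
        t = self.course.times if times is None else np.asarray(times, dtype=float)
        return simulate_timecourse(factors, op.Q_w, op.V_w, self.course.c_w0, op.V_s, t)


class ExtractionResults:
    """Fit results: point estimates, uncertainty and diagnostics."""

    def __init__(self, model: ExtractionModel, result: inference.FitResult) -> None:
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def phi(self) -> float:
        """Fitted single-pass module extraction efficiency Φ."""
        return self._result.phi

    @property
    def kw(self) -> float:
        """Overall aqueous-basis mass transfer coefficient K_w, m/s."""
        return self._result.K_w

    @property
    def slope(self) -> float:
        """Slope of the linearized trace, 1/s."""
        return self._result.slope

    @property
    def rsquared(self) -> float:
        return self._result.r_squared

    @property
    def excluded_points(self):
        return self._result.excluded_points

    @property
    def fit_result(self) -> inference.FitResult:
        return self._result

    def conf_int(self) -> dict[str, tuple[float, float] | None]:
        """95% bootstrap percentile intervals for Φ and K_w (None without bootstrap)."""
        return {"phi": self._result.phi_ci, "kw": self._result.kw_ci}

    # -- diagnostics -------------------------------------------------------
    def predict(self, times=None) -> TimeCourse:
        """Fitted (closed-form) trajectory at the estimated Φ."""
        return self.model.simulate(self.phi, times)

    def linearized(self):
        """The (t, y) points the slope was fitted to."""
        t, y, _ = inference.linearize(self.model.course, self._result.R)
        return t, y

    def plot_linearization(self, ax=None):
        """Diagnostic plot of the linearized trace against the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, y = self.linearized()
        ax.plot(t / 60.0, y, "o", label="data")
        tt = np.linspace(0, t.max(), 50)
        ax.plot(
            tt / 60.0,
            self._result.slope * tt + self._result.intercept,
            "-",
            label=f"fit (Φ = {self.phi:.3f})",
        )
        ax.set_xlabel("time, min")
        ax.set_ylabel("ln[(1 + 1/R)·c_w/c_w0 − 1/R]")
        ax.legend()
        return ax

    def summary(self) -> str:
        r = self._result
        lines = [
            "Recirculating extraction fit",
            "=" * 46,
            f"{'observations used':<28}{r.n_points_used:>18}",
            f"{'excluded points':<28}{len(r.excluded_points):>18}",
            f"{'R-squared':<28}{r.r_squared:>18.6f}",
            f"{'partition coefficient P':<28}{self.model.partition:>18.4g}",
            f"{'extraction factor E':<28}{r.E:>18.4g}",
            f"{'reservoir factor R':<28}{r.R:>18.4g}",
            f"{'interfacial area A, m^2':<28}{r.area:>18.4g}",
            "-" * 46,
            f"{'slope, 1/s':<28}{r.slope:>18.6e}",
            f"{'efficiency Phi':<28}{r.phi:>18.6f}",
            f"{'K_w, m/s':<28}{r.K_w:>18.6e}",
        ]
        if r.phi_ci is not None:
            lines.append(
                f"{'Phi 95% CI':<28}[{r.phi_ci[0]:.6f}, {r.phi_ci[1]:.6f}]".rjust(0)
            )
            lines.append(
                f"{'K_w 95% CI, m/s':<28}[{r.kw_ci[0]:.4e}, {r.kw_ci[1]:.4e}]"
            )
        for idx, reason in r.excluded_points:
            lines.append(f"  excluded point {idx}: {reason}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ExtractionResults phi={self.phi:.4f} kw={self.kw:.3e} "
            f"r2={self.rsquared:.4f}>"
        )
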