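"""Model/Results front-end over the estimation pipeline.

``KickModel`` is built from a trip table (a DataFrame with ``duration_h``
and ``mean_speed_kmh`` columns, as produced by the simulators, the trip
extractor, or :func:`accelwalk.io.read_trips`).  ``fit()`` runs the full
pipeline — travel-time MLE, base-speed OLS, Methods-style binning and the
simultaneous kick fit — and returns a :class:`KickModelResults` carrying
the estimates, their uncertainties where available, the fitted parameter
set and prediction/simulation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting, simulate
from .params import KickModelParams, MIN_TRIP_DURATION_H

__all__ = ["KickModel", "KickModelResults"]


class KickModel:
    """The layered acceleration-kick model of trip speeds, bound to data."""

    def __init__(self, trips: pd.DataFrame,
                 t_min: float = MIN_TRIP_DURATION_H,
                 v_max: float = fitting.V_TOP_KMH):
        required = {"duration_h", "mean_speed_kmh"}
        missing = required - set(trips.columns)
        if missing:
            raise ValueError(f"trip table lacks columns {sorted(missing)}")
        self.trips = trips
        self.t_min = t_min
        self.v_max = v_max

    @classmethod
    def from_trips(cls, trips: pd.DataFrame, **kw) -> "KickModel":
        return cls(trips, **kw)

    from_dataframe = from_trips

    def fit(self, seed: int = 0, weighted: bool = True,
            model_eval: str = "bin_integral") -> "KickModelResults":
        """Run the full pipeline.  ``model_eval="lattice"`` selects the
        layer-lattice model column, appropriate when the trip speeds are
        lattice-valued (reduced-sampler populations)."""
        trips = self.trips
        tt = fitting.fit_travel_time(trips["duration_h"].to_numpy(),
                                     t_min=self.t_min)
        lin = fitting.fit_v0_accel(trips)
        surface = fitting.bin_speed_surface(trips, v0=lin.v0,
                                            v_max=self.v_max)
        kick = fitting.fit_kick_params(surface, v0=lin.v0, seed=seed,
                                       weighted=weighted,
                                       model_eval=model_eval)
        params = KickModelParams(v0=lin.v0, dv_half=kick.dv_half,
                                 p_half=kick.p_half, v_max=self.v_max,
                                 t_bar=tt.t_bar)
        return KickModelResults(model=self, params=params,
                                travel_time=tt, linear=lin, kick=kick,
                                surface=surface)


@dataclass
class KickModelResults:
    """Fitted kick-model parameters with their component fit diagnostics."""

    model: KickModel
    params: KickModelParams
    travel_time: fitting.TravelTimeFit
    linear: fitting.LinearSpeedFit
    kick: fitting.KickFitResult
    surface: fitting.SpeedSurface

    def predict_displacement(self, grid=None):
        """Predicted displacement distribution from the fitted parameters
        (no refitting)."""
        return fitting.predict_displacement_curve(
            self.params, grid=grid, t_min=self.model.t_min)

    def simulate(self, n: int, rng: np.random.Generator,
                 mode: str = "eq_speed") -> pd.DataFrame:
        """Draw a new trip population at the fitted parameters."""
        return simulate.simulate_population(n, self.params, rng, mode=mode,
                                            t_min=self.model.t_min)

    def plot_conditional_speeds(self, t_minutes=(5, 15, 30, 60, 120),
                                ax=None):
        """Overlay the binned conditional speed curves with the fitted
        analytic law for a few durations."""
        import matplotlib.pyplot as plt

        from . import model_core

        if ax is None:
            _, ax = plt.subplots()
        surf = self.surface
        v = surf.v_centers
        grid = np.linspace(self.params.v0, self.params.v_max, 600)
        for t_min in t_minutes:
            i = int(np.argmin(np.abs(surf.t_centers_min - t_min)))
            if surf.counts[i] == 0:
                continue
            line, = ax.plot(v, surf.freq[i], ".", ms=3,
                            label=f"t = {surf.t_centers_min[i]:.0f} min")
            pdf = model_core.conditional_speed_pdf(
                grid, surf.t_fit_min[i] / 60.0, self.params)
            ax.plot(grid, pdf, "-", color=line.get_color(), lw=1)
        ax.set_xlabel("mean speed (km/h)")
        ax.set_ylabel("P(v | t) per bin / per km/h")
        ax.set_yscale("log")
        ax.legend(fontsize=8)
        return ax

    def plot_displacement(self, sample=None, ax=None):
        """Predicted displacement distribution, optionally over a
        histogram of observed path lengths."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.predict_displacement()
        if sample is not None:
            bins = np.geomspace(max(np.min(sample), 1e-2),
                                np.max(sample), 60)
            ax.hist(sample, bins=bins, density=True, alpha=0.3,
                    label="observed")
        ax.plot(curve.grid, curve.density, "-", label="model prediction")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("displacement (km)")
        ax.set_ylabel("P(dr) per km")
        ax.legend(fontsize=8)
        return ax

    def params_frame(self) -> pd.DataFrame:
        tt, lin, kick = self.travel_time, self.linear, self.kick
        rows = [
            ("v0", "km/h", lin.v0, lin.v0_se),
            ("a", "km/h^2", lin.a, lin.a_se),
            ("p_half", "jumps/h", kick.p_half, np.nan),
            ("dv_half", "km/h", kick.dv_half, np.nan),
            ("t_bar", "h", tt.t_bar, tt.se),
        ]
        return pd.DataFrame(rows, columns=["param", "unit", "estimate", "se"])

    def summary(self) -> str:
        p = self.params
        lines = [
            "Acceleration-kick model of trip speeds",
            "=" * 46,
            f"trips fitted              {self.kick.n_trips:>12d}",
            f"duration bins             {int(self.surface.populated.sum()):>12d}",
            f"kick-fit SSE              {self.kick.sse:>12.4e}",
            "-" * 46,
        ]
        for _, row in self.params_frame().iterrows():
            se = "" if np.isnan(row.se) else f"  (se {row.se:.3g})"
            lines.append(f"{row.param:<9s}{row.estimate:>12.4g} "
                         f"{row.unit:<8s}{se}")
        lines += [
            "-" * 46,
            f"derived: p = {p.p:.4g} jumps/h, dv = {p.dv:.4g} km/h, "
            f"layers = {p.n_layers}",
        ]
        return "\n".join(lines)
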