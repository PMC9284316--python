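"""Time-dependent external drivers of the diurnal C/N model.

The ODE system is driven by measured quantities that sit outside the system
boundary: net CO2 exchange (photosynthesis), a constant mitochondrial dark
respiration, and the maximum activities of the three measured enzymes
(nitrate reductase NR, glutamine synthetase GS, hydroxypyruvate reductase
HPR).  Gas exchange is measured quasi-continuously over the light phase;
enzyme activities are assayed at four diurnal time points (start, middle and
end of the light phase, and the middle of the night) and interpolated.

All driver functions are periodic with a 24 h period; t = 0 is light-on and
the light phase spans [0, light_hours) with light_hours = 8 by default.

Units: fluxes and activities in umol g^-1 FW h^-1, metabolite contents in
umol g^-1 FW, concentrations in mM via the tissue-volume conversion
(1 g fresh weight occupies 0.77 ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

__all__ = [
    "TISSUE_VOLUME_ML_PER_G",
    "CYTOSOL_VOLUME_FRACTION",
    "ACTIVITY_NODE_TIMES",
    "DriverError",
    "GasExchangeSeries",
    "ActivitySeries",
    "DriverSet",
    "build_ps_spline",
    "build_vmax_spline",
    "content_to_concentration",
    "cytosolic_nitrate",
    "tabulate_drivers",
    "read_gas_exchange",
    "read_activities",
]

#: Specific volume of leaf tissue: 1 g fresh weight occupies 0.77 ml, so a
#: content of 0.77 umol/gFW corresponds to 1 mM.
TISSUE_VOLUME_ML_PER_G = 0.77

#: Fraction of total cell volume occupied by cytosol in mature leaves; only
#: this fraction of foliar nitrate is accessible to nitrate reductase.
CYTOSOL_VOLUME_FRACTION = 0.05

#: Clock times (h after light-on) of the four enzyme-activity assays:
#: start / middle / end of an 8-h light phase, and the middle of the night.
ACTIVITY_NODE_TIMES = (0.0, 4.0, 8.0, 16.0)


class DriverError(ValueError):
    """Invalid driver data or driver query."""


def content_to_concentration(content, volume_ml_per_g: float = TISSUE_VOLUME_ML_PER_G):
    """Convert a metabolite content (umol/gFW) to a tissue concentration (mM).

    umol per gram fresh weight divided by ml per gram fresh weight is
    umol/ml = mM.
    """
    if volume_ml_per_g <= 0:
        raise DriverError("tissue volume must be positive")
    return np.asarray(content, dtype=float) / volume_ml_per_g if np.ndim(content) else float(content) / volume_ml_per_g


def cytosolic_nitrate(
    no3_total: float,
    fraction: float = CYTOSOL_VOLUME_FRACTION,
    convention: str = "tissue",
) -> float:
    """Concentration (mM) of the NR-accessible nitrate fraction.

    Most foliar nitrate is vacuolar and invisible to nitrate reductase; only
    the cytosolic share (about 5% of cell volume) is substrate.  Two volume
    conventions are supported:

    - ``"tissue"`` (default): the 5% amount fraction diluted in the total
      tissue volume, (fraction * no3_total) / 0.77.
    - ``"cytosol"``: the same amount confined to the cytosolic volume,
      i.e. no3_total / 0.77 (the fraction cancels).
    """
    if no3_total < 0:
        raise DriverError("nitrate content must be non-negative")
    amount = fraction * no3_total
    if convention == "tissue":
        return amount / TISSUE_VOLUME_ML_PER_G
    if convention == "cytosol":
        return amount / (fraction * TISSUE_VOLUME_ML_PER_G)
    raise DriverError(f"unknown nitrate volume convention: {convention!r}")


@dataclass(frozen=True)
class GasExchangeSeries:
    """Measured net CO2 exchange over the diurnal cycle.

    ``flux`` is net uptake (positive in the light); ``rd`` is the dark
    respiration rate stored as a positive magnitude.  Net exchange in the
    dark equals -rd by convention.
    """

    times: np.ndarray
    flux: np.ndarray
    rd: float
    light_hours: float = 8.0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        flux = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flux", flux)
        if times.ndim != 1 or times.shape != flux.shape:
            raise DriverError("times and flux must be matching 1-d arrays")
        if np.any(np.diff(times) <= 0):
            raise DriverError("gas-exchange times must be strictly ascending")
        if times.size and (times[0] < 0 or times[-1] >= 24):
            raise DriverError("gas-exchange times must lie in [0, 24)")
        if self.rd < 0:
            raise DriverError("dark respiration must be a positive magnitude")
        if np.count_nonzero(times < self.light_hours) < 4:
            raise DriverError("need at least 4 light-phase gas-exchange points")

    @property
    def light_mask(self) -> np.ndarray:
        return self.times < self.light_hours


@dataclass(frozen=True)
class ActivitySeries:
    """Maximum activity of one enzyme at the four diurnal assay times."""

    enzyme: str
    times: np.ndarray = field(default_factory=lambda: np.array(ACTIVITY_NODE_TIMES))
    values: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        if self.enzyme not in ("NR", "GS", "HPR"):
            raise DriverError(f"unknown enzyme: {self.enzyme!r}")
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != (4,) or values.shape != (4,):
            raise DriverError("activity series needs exactly 4 nodes")
        if np.any(values < 0):
            raise DriverError("enzyme activities must be non-negative")


class _PeriodicPs:
    """Net CO2 exchange: cubic spline over the light phase, -rd in the dark."""

    def __init__(self, spline: CubicSpline, rd: float, light_hours: float):
        self._spline = spline
        self._rd = rd
        self._light_hours = light_hours

    def __call__(self, t):
        tt = np.asarray(t, dtype=float) % 24.0
        if tt.ndim == 0:
            return float(self._spline(tt)) if tt < self._light_hours else -self._rd
        out = np.where(tt < self._light_hours, self._spline(tt), -self._rd)
        return out


class _PeriodicVmax:
    """Shape-preserving periodic interpolant through the 4 activity nodes.

    For GS an optional multiplicative down-regulation factor is applied to
    dark-phase values (the in vitro assay overestimates nocturnal activity).
    """

    def __init__(self, interpolant: PchipInterpolator, night_factor: float, light_hours: float):
        self._interp = interpolant
        self._night_factor = night_factor
        self._light_hours = light_hours

    def __call__(self, t):
        tt = np.asarray(t, dtype=float) % 24.0
        base = self._interp(tt)
        if self._night_factor == 1.0:
            return float(base) if tt.ndim == 0 else base
        if tt.ndim == 0:
            return float(base) * (1.0 if tt < self._light_hours else self._night_factor)
        return np.where(tt < self._light_hours, base, base * self._night_factor)


def build_ps_spline(series: GasExchangeSeries) -> Callable[[float], float]:
    """Interpolate the photosynthesis time course.

    Light-phase measurements are joined by a cubic spline; dark-phase queries
    return -rd exactly (net exchange at night is respiration only).  The
    result is 24-h periodic.
    """
    mask = series.light_mask
    t_light = series.times[mask]
    f_light = series.flux[mask]
    spline = CubicSpline(t_light, f_light, extrapolate=True)
    return _PeriodicPs(spline, series.rd, series.light_hours)


def build_vmax_spline(
    series: ActivitySeries,
    f_gs_night: float = 1.0,
    light_hours: float = 8.0,
) -> Callable[[float], float]:
    """Interpolate an enzyme-activity time course through its 4 assay nodes.

    A monotone piecewise-cubic (PCHIP) interpolant is used so activities never
    overshoot the measured range between nodes; the node set is wrapped one
    period in each direction to make the interpolant 24-h periodic.

    ``f_gs_night`` multiplies dark-phase values and is only meaningful for
    GS; for other enzymes it must be left at 1.
    """
    if not (0 < f_gs_night <= 1):
        raise DriverError("f_gs_night must lie in (0, 1]")
    if f_gs_night != 1.0 and series.enzyme != "GS":
        raise DriverError("the nocturnal factor applies to GS only")
    t = series.times
    v = series.values
    t_ext = np.concatenate(([t[-1] - 24.0], t, t[:2] + 24.0))
    v_ext = np.concatenate(([v[-1]], v, v[:2]))
    interp = PchipInterpolator(t_ext, v_ext, extrapolate=True)
    return _PeriodicVmax(interp, f_gs_night, light_hours)


@dataclass
class DriverSet:
    """Bundle of all external drivers needed by the ODE right-hand side."""

    ps: Callable[[float], float]
    rd: float
    vmax_nr: Callable[[float], float]
    vmax_gs: Callable[[float], float]
    vmax_hpr: Callable[[float], float]
    co2: float
    gamma_star: float
    no3_total: float
    light_hours: float = 8.0
    nitrate_convention: str = "tissue"

    def __post_init__(self):
        if self.co2 <= 0:
            raise DriverError("ambient CO2 concentration must be positive")
        if self.gamma_star < 0:
            raise DriverError("gamma_star must be non-negative")
        if 2.0 * self.gamma_star / self.co2 > 1.0:
            raise DriverError(
                "oxygenation ratio 2*gamma_star/co2 exceeds 1 (carboxylation singularity)"
            )
        # NR sees a constant cytosolic nitrate pool (nitrate is outside the
        # system boundary); precompute its concentration once.
        self.no3_cytosolic_mM = cytosolic_nitrate(
            self.no3_total, convention=self.nitrate_convention
        )

    def is_light(self, t: float) -> bool:
        return (t % 24.0) < self.light_hours

    @classmethod
    def build(
        cls,
        gas: GasExchangeSeries,
        activities: Mapping[str, ActivitySeries],
        co2: float,
        gamma_star: float,
        no3_total: float,
        light_hours: float = 8.0,
        nitrate_convention: str = "tissue",
    ) -> "DriverSet":
        """Assemble a DriverSet from measurement series.

        Activity splines are built at assay scale (f_gs_night = 1); the
        nocturnal GS factor is a model parameter applied at flux evaluation.
        """
        missing = {"NR", "GS", "HPR"} - set(activities)
        if missing:
            raise DriverError(f"missing activity series for {sorted(missing)}")
        return cls(
            ps=build_ps_spline(gas),
            rd=gas.rd,
            vmax_nr=build_vmax_spline(activities["NR"], light_hours=light_hours),
            vmax_gs=build_vmax_spline(activities["GS"], light_hours=light_hours),
            vmax_hpr=build_vmax_spline(activities["HPR"], light_hours=light_hours),
            co2=co2,
            gamma_star=gamma_star,
            no3_total=no3_total,
            light_hours=light_hours,
            nitrate_convention=nitrate_convention,
        )


class _UniformTable:
    """Linear interpolation on a uniform time grid; scalar fast path.

    Used to replace spline evaluations inside optimization loops, where the
    same driver is queried hundreds of thousands of times.
    """

    __slots__ = ("_vals", "_dt", "_n")

    def __init__(self, func, dt: float):
        n = int(round(24.0 / dt))
        grid = np.arange(n + 1) * dt
        self._vals = np.array([float(func(t)) for t in grid])
        self._dt = dt
        self._n = n

    def __call__(self, t):
        x = (float(t) % 24.0) / self._dt
        i = int(x)
        if i >= self._n:
            i = self._n - 1
        frac = x - i
        v = self._vals
        return v[i] * (1.0 - frac) + v[i + 1] * frac


def tabulate_drivers(drivers: DriverSet, dt: float = 0.002) -> DriverSet:
    """Clone a DriverSet with its splines replaced by uniform lookup tables.

    The table step (default 0.002 h = 7.2 s) keeps the interpolation error
    far below solver tolerances while making each driver query ~10x faster.
    The light/dark discontinuity in ps(t) is preserved to within one step
    because integration is split at the phase boundary anyway.
    """
    return DriverSet(
        ps=_UniformTable(drivers.ps, dt),
        rd=drivers.rd,
        vmax_nr=_UniformTable(drivers.vmax_nr, dt),
        vmax_gs=_UniformTable(drivers.vmax_gs, dt),
        vmax_hpr=_UniformTable(drivers.vmax_hpr, dt),
        co2=drivers.co2,
        gamma_star=drivers.gamma_star,
        no3_total=drivers.no3_total,
        light_hours=drivers.light_hours,
        nitrate_convention=drivers.nitrate_convention,
    )


def read_gas_exchange(path, rd: float, light_hours: float = 8.0) -> GasExchangeSeries:
    """Read a gas-exchange CSV with columns time_h, flux."""
    df = pd.read_csv(path)
    required = {"time_h", "flux"}
    if not required.issubset(df.columns):
        raise DriverError(f"gas-exchange CSV needs columns {sorted(required)}")
    df = df.sort_values("time_h")
    return GasExchangeSeries(
        times=df["time_h"].to_numpy(),
        flux=df["flux"].to_numpy(),
        rd=rd,
        light_hours=light_hours,
    )


def read_activities(path) -> dict[str, ActivitySeries]:
    """Read an enzyme-activity CSV with columns enzyme, time_h, vmax."""
    df = pd.read_csv(path)
    required = {"enzyme", "time_h", "vmax"}
    if not required.issubset(df.columns):
        raise DriverError(f"activity CSV needs columns {sorted(required)}")
    out: dict[str, ActivitySeries] = {}
    for enzyme, grp in df.groupby("enzyme"):
        grp = grp.sort_values("time_h")
        out[str(enzyme)] = ActivitySeries(
            enzyme=str(enzyme),
            times=grp["time_h"].to_numpy(),
            values=grp["vmax"].to_numpy(),
        )
    return out
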