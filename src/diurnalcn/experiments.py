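"""Numerical experiments on fitted ensembles.

Three analyses mirror the study design: a stepwise nocturnal GS-inactivation
scan that locates the in vivo night-time GS activity as the factor
minimizing the fit error; extraction of instantaneous reaction fluxes along
each ensemble member's trajectory at the harvest times; and the diagnostic
flux ratios NR/GDC (share of de novo vs photorespiratory ammonium) and
HP2BMEXP/NR (carbon committed to biomass/export per unit of de novo
assimilated nitrogen), both over the light phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import DriverSet
from .estimation import (
    Ensemble,
    PsoSettings,
    ValidationError,
    fit_parameters,
)
from .model import FLUX_NAMES, KineticParams, evaluate_fluxes

__all__ = [
    "GsScanResult",
    "gs_inactivation_scan",
    "extract_fluxes",
    "flux_ratios",
]

DEFAULT_GS_FACTORS = tuple(np.round(np.arange(1.0, 0.05, -0.1), 10))


@dataclass
class GsScanResult:
    """Outcome of the nocturnal GS-inactivation scan."""

    factors: tuple[float, ...]
    errors: dict[float, list[float]]  # factor -> per-run objective errors (%)
    accepted: dict[float, int]  # factor -> number of accepted runs
    best_factor: float  # factor minimizing the median error

    def to_frame(self) -> pd.DataFrame:
        records = [
            (f, run, err)
            for f in self.factors
            for run, err in enumerate(self.errors[f])
        ]
        return pd.DataFrame(records, columns=["factor", "run", "error"])


def gs_inactivation_scan(
    observations: pd.DataFrame,
    drivers: DriverSet,
    bounds,
    runs_per_step: int = 10,
    factors=DEFAULT_GS_FACTORS,
    base_seed: int = 0,
    base_params: KineticParams | None = None,
    settings: PsoSettings | None = None,
    **fit_kwargs,
) -> GsScanResult:
    """Scan nocturnal GS activity from 100% down to 10% in 10% steps.

    At each factor f_gs_night is fixed (removed from the free parameters)
    and all remaining parameters are re-optimized ``runs_per_step`` times
    with distinct seeds.  The factor with the lowest median error across its
    runs is reported as the scan optimum; ties resolve to the largest
    factor (the first on the descending grid).
    """
    if runs_per_step < 1:
        raise ValidationError("runs_per_step must be at least 1")
    base = base_params or KineticParams()
    free = {n: b for n, b in dict(bounds).items() if n != "f_gs_night"}

    errors: dict[float, list[float]] = {}
    accepted: dict[float, int] = {}
    for step, factor in enumerate(factors):
        fixed = base.with_values(f_gs_night=float(factor))
        errs = []
        n_acc = 0
        for run in range(runs_per_step):
            result = fit_parameters(
                observations,
                drivers,
                free,
                seed=base_seed + 1000 * step + run,
                base_params=fixed,
                settings=settings,
                **fit_kwargs,
            )
            errs.append(result.objective)
            n_acc += int(result.accepted)
        errors[float(factor)] = errs
        accepted[float(factor)] = n_acc

    medians = {f: float(np.median(errors[f])) for f in errors}
    best = min(factors, key=lambda f: (medians[float(f)], -f))
    return GsScanResult(
        factors=tuple(float(f) for f in factors),
        errors=errors,
        accepted=accepted,
        best_factor=float(best),
    )


def extract_fluxes(
    ensemble: Ensemble,
    times,
    drivers: DriverSet,
    gating: bool = True,
    condition: str = "",
) -> pd.DataFrame:
    """Evaluate every reaction flux on each member's trajectory at ``times``.

    Tidy output columns: condition, run_id, time_h, flux,
    value_umol_per_gFW_per_h.  Times must lie on the stored trajectory grid
    and within [0, 24).
    """
    times = [float(t) for t in times]
    for t in times:
        if not (0.0 <= t < 24.0):
            raise ValidationError(f"time {t} outside [0, 24)")
    records = []
    for run_id, result in enumerate(ensemble.results):
        for t in times:
            state = result.trajectory.at(t)
            fluxes = evaluate_fluxes(state, t, result.params, drivers, gating=gating)
            records.extend(
                (condition, run_id, t, name, float(value))
                for name, value in zip(FLUX_NAMES, fluxes)
            )
    return pd.DataFrame(
        records,
        columns=["condition", "run_id", "time_h", "flux", "value_umol_per_gFW_per_h"],
    )


def flux_ratios(
    flux_table: pd.DataFrame,
    light_hours: float = 8.0,
    eps: float = 1e-9,
) -> tuple[pd.DataFrame, int]:
    """Light-phase NR/GDC and HP2BMEXP/NR ratios per run and time point.

    Rows whose denominator falls below ``eps`` are excluded; the count of
    exclusions is returned alongside the tidy ratio table (columns: run_id,
    time_h, ratio, value).
    """
    day = flux_table[flux_table["time_h"] < light_hours]
    wide = day.pivot_table(
        index=["run_id", "time_h"],
        columns="flux",
        values="value_umol_per_gFW_per_h",
    )
    records = []
    n_excluded = 0
    for (run_id, t), row in wide.iterrows():
        for name, num, den in (
            ("nr_over_gdc", row["v_nr"], row["v_gdc"]),
            ("hp2bmexp_over_nr", row["v_hp2bmexp"], row["v_nr"]),
        ):
            if den < eps:
                n_excluded += 1
                continue
            records.append((run_id, t, name, float(num / den)))
    if not records:
        import warnings

        warnings.warn("all ratio rows excluded (zero denominators)", RuntimeWarning)
    return (
        pd.DataFrame(records, columns=["run_id", "time_h", "ratio", "value"]),
        n_excluded,
    )
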