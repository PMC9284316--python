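"""Study-shaped synthetic datasets with known ground truth.

The generator emulates the study's measurement design — four conditions
(Col-0 and the hpr1-1 mutant at ambient and elevated CO2), diurnal
metabolite time courses sampled every 2 h at five replicates over an
8 h light / 16 h dark cycle, a gas-exchange series, and enzyme maximum
activities at four assay times — by forward-simulating the kinetic model
from a documented ground-truth parameter table and adding multiplicative
lognormal measurement noise.  The ground truth is embedded in every dataset
so that parameter-recovery tests can compare fitted against generating
values.

The light-phase gas-exchange curve is a half-sine arch whose mean equals the
condition's measured mean photosynthetic rate; the hpr1-1 lesion is emulated
solely by scaling the HPR activity series to 10% of wildtype.  Activity
series are written on the in vitro assay scale; the nocturnal GS
down-regulation factor acts inside the model, exactly as in fitting, so it
remains recoverable from the data.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drivers import (
    ACTIVITY_NODE_TIMES,
    ActivitySeries,
    DriverSet,
    GasExchangeSeries,
)
from .model import STATE_NAMES, KineticParams, Trajectory, integrate

__all__ = [
    "ConditionSpec",
    "SyntheticDataset",
    "load_ground_truth",
    "default_condition_specs",
    "simulate_condition",
    "sample_replicates",
    "generate_dataset",
    "write_dataset",
]


def load_ground_truth() -> dict:
    """Load the versioned default ground-truth table shipped with the package."""
    ref = importlib.resources.files("diurnalcn.configs") / "ground_truth_default.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ConditionSpec:
    """Ground truth for one genotype x CO2 condition."""

    name: str
    genotype: str
    co2_ppm: float
    ps_mean: float  # light-phase mean net CO2 exchange, umol/gFW/h
    rd: float
    gamma_star: float
    no3_total: float
    params: KineticParams
    activities: dict[str, tuple[float, float, float, float]]
    y0: np.ndarray
    light_hours: float = 8.0


@dataclass
class SyntheticDataset:
    """Four-condition synthetic study with its generating ground truth."""

    observations: pd.DataFrame  # condition, state, time_h, mean, sd, n
    replicates: pd.DataFrame  # condition, state, time_h, replicate, value
    gas_exchange: pd.DataFrame  # condition, time_h, flux
    activities: pd.DataFrame  # condition, enzyme, time_h, vmax
    truth: dict  # per-condition ground-truth record
    seed: int
    specs: dict[str, ConditionSpec] = field(default_factory=dict)


def default_condition_specs(
    overrides: dict | None = None,
) -> dict[str, ConditionSpec]:
    """The four study conditions with their documented ground truth.

    ``overrides`` maps condition name -> dict of KineticParams overrides,
    e.g. ``{"col0_ambient": {"f_gs_night": 0.3}}``.
    """
    cfg = load_ground_truth()
    base_params = KineticParams().with_values(**cfg.get("params", {}))
    specs: dict[str, ConditionSpec] = {}
    for name, c in cfg["conditions"].items():
        params = base_params
        if overrides and name in overrides:
            params = params.with_values(**overrides[name])
        y0 = np.array([c["initial_state"][s] for s in STATE_NAMES], dtype=float)
        specs[name] = ConditionSpec(
            name=name,
            genotype=c["genotype"],
            co2_ppm=float(c["co2_ppm"]),
            ps_mean=float(c["ps_mean"]),
            rd=float(c["rd"]),
            gamma_star=float(cfg["gamma_star_ppm"]),
            no3_total=float(c["no3_total"]),
            params=params,
            activities={e: tuple(v) for e, v in c["activities"].items()},
            y0=y0,
            light_hours=float(cfg["light_hours"]),
        )
    return specs


def _gas_series(spec: ConditionSpec) -> GasExchangeSeries:
    """Half-sine light-phase arch with the condition's mean, -rd at night."""
    t_light = np.arange(0.0, spec.light_hours, 0.5)
    # mean of sin over a half period is 2/pi, so the amplitude pi/2 * mean
    # gives a light-phase average equal to the printed condition mean
    arch = spec.ps_mean * (np.pi / 2.0) * np.sin(np.pi * t_light / spec.light_hours)
    t_dark = np.arange(spec.light_hours + 1.0, 24.0, 2.0)
    times = np.concatenate([t_light, t_dark])
    flux = np.concatenate([arch, np.full(t_dark.shape, -spec.rd)])
    return GasExchangeSeries(times=times, flux=flux, rd=spec.rd, light_hours=spec.light_hours)


def _activity_series(spec: ConditionSpec) -> dict[str, ActivitySeries]:
    return {
        e: ActivitySeries(enzyme=e, times=np.array(ACTIVITY_NODE_TIMES), values=np.array(v))
        for e, v in spec.activities.items()
    }


def build_drivers(spec: ConditionSpec) -> DriverSet:
    """Assemble the DriverSet implied by a condition spec."""
    return DriverSet.build(
        gas=_gas_series(spec),
        activities=_activity_series(spec),
        co2=spec.co2_ppm,
        gamma_star=spec.gamma_star,
        no3_total=spec.no3_total,
        light_hours=spec.light_hours,
    )


def simulate_condition(
    spec: ConditionSpec,
    interval_h: float = 2.0,
    warmup_cycles: int = 0,
    gating: bool = True,
) -> tuple[Trajectory, DriverSet]:
    """Noise-free ground-truth trajectory for one condition.

    The recorded cycle starts from the condition's tuned dawn state.  The
    wildtype conditions are near a repeating diurnal orbit there; the mutant
    at ambient CO2 is deliberately non-stationary (its serine pool builds by
    day and is recycled deep into the night).  Optional ``warmup_cycles``
    pre-runs relax the start state further towards periodicity.
    """
    drivers = build_drivers(spec)
    t_grid = np.round(np.arange(0.0, 24.0 + 1e-9, interval_h), 9)
    if t_grid[-1] < 24.0:
        t_grid = np.append(t_grid, 24.0)
    y0 = spec.y0.copy()
    for _ in range(warmup_cycles):
        warm = integrate(spec.params, drivers, y0, t_grid, gating=gating)
        y0 = warm.values[-1]
    return integrate(spec.params, drivers, y0, t_grid, gating=gating), drivers


def sample_replicates(
    trajectory: Trajectory,
    n: int = 5,
    cv: float = 0.1,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy replicate draws around a trajectory.

    At each grid time (< 24 h) and state, ``n`` multiplicative lognormal
    draws with coefficient of variation ``cv`` and mean equal to the
    trajectory value.  Returns (observations, replicates): observations has
    per-cell mean/sd/n, replicates the individual draws.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    if times is None:
        times = trajectory.times[trajectory.times < 24.0]
    sigma = np.sqrt(np.log1p(cv**2))
    obs_records = []
    rep_records = []
    for t in times:
        y = trajectory.at(float(t))
        for j, state in enumerate(STATE_NAMES):
            true = y[j]
            if cv == 0:
                draws = np.full(n, true)
            else:
                # mean-preserving lognormal: E[exp(sigma Z - sigma^2/2)] = 1
                draws = true * np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2.0)
            sd = float(np.std(draws, ddof=1)) if cv > 0 else 0.0
            obs_records.append((float(t), state, float(np.mean(draws)), sd, n))
            rep_records.extend(
                (float(t), state, r, float(v)) for r, v in enumerate(draws)
            )
    obs = pd.DataFrame(obs_records, columns=["time_h", "state", "mean", "sd", "n"])
    reps = pd.DataFrame(rep_records, columns=["time_h", "state", "replicate", "value"])
    return obs, reps


def generate_dataset(
    specs: dict[str, ConditionSpec] | None = None,
    cv: float = 0.1,
    seed: int = 0,
    n_replicates: int = 5,
    interval_h: float = 2.0,
    warmup_cycles: int = 0,
) -> SyntheticDataset:
    """Generate the full multi-condition synthetic study."""
    specs = specs or default_condition_specs()
    if not specs:
        raise ValueError("need at least one condition spec")
    obs_parts, rep_parts, gas_parts, act_parts = [], [], [], []
    truth: dict[str, dict] = {}
    for idx, (name, spec) in enumerate(sorted(specs.items())):
        trajectory, _ = simulate_condition(
            spec, interval_h=interval_h, warmup_cycles=warmup_cycles
        )
        obs, reps = sample_replicates(
            trajectory, n=n_replicates, cv=cv, seed=seed + idx
        )
        obs.insert(0, "condition", name)
        reps.insert(0, "condition", name)
        obs_parts.append(obs)
        rep_parts.append(reps)

        gas = _gas_series(spec)
        gas_parts.append(
            pd.DataFrame(
                {"condition": name, "time_h": gas.times, "flux": gas.flux}
            )
        )
        for enzyme, values in spec.activities.items():
            act_parts.append(
                pd.DataFrame(
                    {
                        "condition": name,
                        "enzyme": enzyme,
                        "time_h": list(ACTIVITY_NODE_TIMES),
                        "vmax": list(values),
                    }
                )
            )
        truth[name] = {
            "genotype": spec.genotype,
            "co2_ppm": spec.co2_ppm,
            "ps_mean": spec.ps_mean,
            "rd": spec.rd,
            "gamma_star": spec.gamma_star,
            "no3_total": spec.no3_total,
            "params": spec.params.to_dict(),
            "y0_start_of_cycle": [float(v) for v in trajectory.values[0]],
        }
    return SyntheticDataset(
        observations=pd.concat(obs_parts, ignore_index=True),
        replicates=pd.concat(rep_parts, ignore_index=True),
        gas_exchange=pd.concat(gas_parts, ignore_index=True),
        activities=pd.concat(act_parts, ignore_index=True),
        truth=truth,
        seed=seed,
        specs=dict(specs),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> list[Path]:
    """Write the dataset as the CSV schemata consumed by fitting, plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("observations.csv", dataset.observations),
        ("replicates.csv", dataset.replicates),
        ("gas_exchange.csv", dataset.gas_exchange),
        ("activities.csv", dataset.activities),
    ):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps({"seed": dataset.seed, "truth": dataset.truth}, indent=2, sort_keys=True)
    )
    written.append(manifest)
    return written
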