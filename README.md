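# diurnalcn

Kinetic modelling of the interplay between photorespiration and nitrate
assimilation in *Arabidopsis thaliana* rosettes over a diurnal cycle.

Elevated atmospheric CO₂ suppresses Rubisco oxygenation and with it the
photorespiratory (PR) pathway, which releases NH₄⁺ at glycine decarboxylase
and thereby loads the glutamine-synthetase / glutamine-oxoglutarate-
aminotransferase (GS/GOGAT) cycle.  Whether the lower nitrogen content of
plants grown at elevated CO₂ reflects inhibited nitrate assimilation or mere
dilution by extra carbon is best asked with a dynamic model that carries
both the C and the N side of the network.  `diurnalcn` implements such a
model for the classic 2×2 design — wildtype Col-0 and the peroxisomal
hydroxypyruvate-reductase mutant *hpr1-1*, each at ambient (450 ppm) and
elevated (1000 ppm) CO₂ — together with everything needed to use it:

* **core model** — a 10-pool ODE system (Gly, Ser, hexose-phosphates,
  malate+fumarate, citrate, α-ketoglutarate, Glu, Gln, free amino acids,
  NH₄⁺) driven by measured gas exchange and enzyme activities.  The PR input
  follows the Farquhar gas-exchange treatment: Φ = 2Γ*/C,
  v_o = (A_net + R_d)/(1/Φ − ½), and the glycine delivery is v_o/2 plus a
  dark summand α.  Mass-balance kinetics for carbon-skeleton transfers,
  Michaelis–Menten kinetics for enzymatic steps, SHMT capped by GDC,
  Glu→αKG = PR − HPR, Glu→AA = `correct`·NR.
* **drivers** — periodic splines from gas-exchange measurements (cubic) and
  four-point diurnal enzyme activities (shape-preserving PCHIP), plus the
  content→concentration conversion (0.77 ml g⁻¹ FW) and the cytosolic
  nitrate fraction (5%) seen by nitrate reductase.
* **estimation** — seeded particle-swarm ensemble fits minimizing the
  averaged percent error per state and time point, with acceptance inside
  the measured SD band, and the wildtype→mutant km_HPR lower-bound rule.
* **experiments** — the nocturnal GS-inactivation scan (the in vitro assay
  overestimates night GS; the scan finds the factor minimizing the fit
  error), flux extraction along fitted trajectories, and the diagnostic
  light-phase ratios NR/GDC and HP2BMEXP/NR.
* **synthetic data** — a generator that emulates the full measurement design
  (four conditions, 2-h sampling, five replicates, lognormal noise) from a
  documented ground truth, so every stage is testable without downloads.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Generate the synthetic wildtype-ambient condition and fit a small ensemble:

```python
from diurnalcn import default_condition_specs, simulate_condition, sample_replicates
from diurnalcn.estimation import PsoSettings, bounds_box, run_ensemble

spec = default_condition_specs()["col0_ambient"]
trajectory, drivers = simulate_condition(spec)          # noise-free cycle
obs, _ = sample_replicates(trajectory, n=5, cv=0.05, seed=1)

ens = run_ensemble(obs, drivers, bounds_box(spec.params, rel=0.5),
                   n_runs=2, base_seed=1, base_params=spec.params,
                   settings=PsoSettings(n_particles=24, iters=40))
best = ens.best
print(f"best objective: {best.objective:.2f}% "
      f"(accepted {ens.n_accepted}/2 within 1 SD)")
print(f"recovered f_gs_night = {best.params.f_gs_night:.2f} (truth 0.35), "
      f"km_hpr = {best.params.km_hpr:.2f} mM (truth 6.0)")
```

prints

```
best objective: 1.94% (accepted 0/2 within 1 SD)
recovered f_gs_night = 0.34 (truth 0.35), km_hpr = 6.01 mM (truth 6.0)
```

The objective is the averaged relative deviation between simulated and
observed pool means over all 10 states × 12 sampling times (1.94% here is
close to the sampling-noise floor of five replicates at cv = 0.05); the
nocturnal GS factor and the HPR Michaelis constant are recovered essentially
exactly.  Strict 1-SD acceptance is rarely met on noisy synthetic data
because the dawn state is itself noisy — the `sd_multiplier` option relaxes
the band for the synthetic regime.

The same stages are available from the shell:

```bash
diurnalcn synth --out data/ --seed 1 --cv 0.05
diurnalcn fit --observations obs.csv --gas-exchange gas.csv \
              --activities acts.csv --config cond.yaml --n-runs 20 --out fit/
diurnalcn scan-gs ... --runs-per-step 10 --out scan.csv
diurnalcn fluxes ... --out fluxes/
```

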