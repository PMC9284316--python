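# Methods

## The model

`diurnalcn` simulates the coupled carbon/nitrogen metabolism of an
*Arabidopsis thaliana* rosette over one 8 h light / 16 h dark cycle with an
ODE system in ten metabolite pools: glycine (gly), serine (ser), the
hexose-/triose-phosphate pool in hexose equivalents (hp), the combined
malate+fumarate pool (mf), citrate (cit), α-ketoglutarate (kg), glutamate
(glu), glutamine (gln), the remaining free amino acids (aa) and ammonium
(nh4).  Biomass, assimilate export, starch, nitrate, O₂ and CO₂ are outside
the system boundary.  All pools are contents in µmol g⁻¹ FW; enzyme rate
laws convert contents to concentrations with the tissue specific volume of
0.77 ml g⁻¹ FW (0.77 µmol g⁻¹ FW ≡ 1 mM).

Carbon enters through measured net photosynthesis.  The photorespiratory
(PR) input is derived from gas exchange in the Farquhar framework: the
oxygenation-to-carboxylation ratio is Φ = 2Γ*/C with Γ* the CO₂ compensation
point without day respiration and C the growth CO₂ concentration, and the
oxygenation rate is v_o = (A_net + R_d)/(1/Φ − ½), with dark respiration R_d
stored as a positive magnitude.  The PR flux delivering glycine is v_o/2
during the light phase plus a constant summand α that lets the pathway turn
over in darkness (important for the *hpr1-1* mutant, whose serine pool is
recycled far into the night).

Rate laws follow the network's published structure: first-order mass-balance
kinetics (k·donor) for the carbon-skeleton transfers HP→BM/EXP, HP→MF,
MF→Cit, Cit→MF, Cit→αKG, Ser→AA and AA→BM/EXP; Michaelis–Menten kinetics for
the enzymatic steps, using measured diurnal activity splines as v_max for
NR, GS and HPR, and fitted v_max for GDC, SHMT and GOGAT.  GS and GOGAT are
two-substrate multiplicative Michaelis–Menten forms (NH₄⁺·Glu and Gln·αKG);
that is the simplest saturable law consistent with both substrates being
required.  Three structural couplings close the nitrogen bookkeeping:

* SHMT is capped by GDC (it consumes the C1 unit GDC produces);
* Glu→αKG equals PR − HPR (all three are N₁ fluxes), clamped at zero;
* Glu→AA equals `correct`·NR with `correct` ∈ [0.5, 1], the share of de novo
  assimilated N routed into amino-acid synthesis; Ser→BM is fixed at 14% of
  AA→BM/EXP (the serine share of bulk protein).

Nocturnal GS activity is the in vitro spline multiplied by `f_gs_night`
∈ (0, 1]: protein extraction with dithiothreitol activates plastidial GS, so
the assay overestimates night-time activity and the factor is identified
from the data (the paper-scale optimum is 20–50%).

Stoichiometric conversions keep both balances closed and testable: HP gains
(A_net + R_d + v_GDC − 2·v_PR)/6 (gross fixation in hexose equivalents, with
GDC-released CO₂ added back and the 2 C per glycine diverted to PR removed),
0.5 HP per HPR unit (3C glycerate), 1 HP → 1.5 MF, 1.5 MF → 1 Cit,
1 Cit → 1.2 αKG, GOGAT yields two glutamates, GDC releases one NH₄⁺ and one
CO₂ per glycine (its C1 product is not modelled; the C balance carries the
v_GDC − v_SHMT residual explicitly).  Respiration drains MF at R_d/4
(a C4 acid fully oxidised).  Starch exchanges linearly: synthesis at `s_day`
during the light phase, degradation at `s_day`·(light/dark hours) at night,
so the daily starch budget closes.  Carboxylate gating reflects the diurnal
citrate strategy: MF→Cit runs only in darkness, Cit→αKG only in the light
(both switchable off via `gating=False`).

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` (LSODA), split at the light/dark
  transition so the stepper never straddles the driver discontinuity; the
  evaluation time is clamped just inside each segment so the endpoint never
  samples the other phase.  Defaults rtol 1e-6 / atol 1e-8; fitting uses
  rtol 1e-4 / atol 1e-5 (trajectory error ≲0.2%, far below the objective's
  noise level) plus drivers tabulated on a 0.002 h grid for speed.
* Non-negativity: rate laws treat negative excursions as empty pools; output
  states below −1e-12 are clipped to zero with a warning, and a run fails if
  more than 0.1% of grid values lie below −1e-6 µmol g⁻¹ FW (solver slack is
  of order atol; genuine blow-ups are orders of magnitude larger).
* Donor guards: the three balance-derived fluxes (Glu→αKG, Glu→AA, Ser→BM)
  do not depend on their donor pool, so each carries a saturation factor
  s/(s + 0.05 mM) that vanishes at an empty pool and is negligible (<1%) at
  healthy pool sizes.  The two constant-rate sinks (MF respiration, daytime
  starch synthesis) carry the same guard.  Without these, an empty glutamate
  pool would keep being consumed and the GS/GOGAT cycle would deadlock.
* Enzyme activity nodes sit at t = 0, 4, 8 and 16 h (start/mid/end of light,
  mid-night); activity splines are shape-preserving monotone cubics (PCHIP)
  wrapped periodically so they never overshoot the assayed range.  Gas
  exchange uses a periodic cubic spline over the light-phase measurements
  and equals −R_d exactly in darkness.
* Cytosolic nitrate: NR sees 5% of foliar nitrate (the cytosolic volume
  fraction), diluted in the total tissue volume by default; the alternative
  convention (full concentration in the cytosolic volume) is selectable.

## Parameter identification

The objective is the averaged percent error per state and time point,
100·mean(|sim − mean|/max(mean, ε)) with ε = 1e-3 µmol g⁻¹ FW, evaluated on
the 2-h sampling grid with the initial state pinned to the observed means at
t = 0 (only the dawn state is given to the model).  A fit is *accepted* when
the simulation lies within the measured standard deviation at every state
and time point (a k·SD multiplier is exposed for the synthetic regime).

Optimization is a hand-rolled global-best particle swarm (constricted
coefficients w = 0.7298, c₁ = c₂ = 1.49618, box-clipped), seeded through a
single `numpy.random.Generator` per run so every fit is reproducible.
Particle 0 starts at the reference parameter table clipped into the bounds —
the usual literature-values warm start — so a short swarm refines rather
than rediscovers; integration failures are penalized (1e6), not fatal.
Ensembles run n independent fits with seeds base_seed + i; the mutant
workflow takes the wildtype-ensemble minimum of km_HPR as the mutant's lower
bound (a protein's km should not change with the lesion), optionally opened
by a further 30%.

The GS-inactivation experiment fixes `f_gs_night` at each factor 1.0, 0.9,
…, 0.1 in turn, re-optimizes all other parameters several times per factor,
and reports the factor minimizing the median error (ties resolve to the
larger factor).

Desk-scale problem sizes used throughout (chosen as sensible defaults for a
single workstation core): ensembles of 2–3 fits with swarms of 12–32
particles and 15–80 iterations; the scan uses 10 factors × 3 runs.  One fit
is tens of seconds; the full scan a few minutes.

## The synthetic study

The generator emulates the measurement design — four conditions (Col-0 and
*hpr1-1* at 450 and 1000 ppm CO₂), metabolite time courses every 2 h at five
replicates, a gas-exchange series and four-node enzyme activities — by
forward-simulating a documented ground-truth table
(`configs/ground_truth_default.yaml`).  The light-phase gas-exchange curve
is a half-sine arch whose mean equals the condition's measured mean
photosynthetic rate (85.4 / 128.1 / 76.8 / 98.6 µmol g⁻¹ FW h⁻¹); darkness
is −R_d.  The mutant lesion is emulated solely by scaling the HPR activity
series to 10% of wildtype.  Noise is multiplicative lognormal with
mean-preserving draws (default cv = 0.1), seeded; written activity series
are on the in vitro assay scale so `f_gs_night` stays recoverable.

The ground-truth operating point was chosen for structural self-consistency.
Glutamate and α-ketoglutarate are pure integrators of the network, with
cycle-balance conditions ∮(Ser→AA + Ser→BM) ≈ (1 − correct)·∮NR and
1.2·∮(Cit→αKG) ≈ correct·∮NR; a single shared parameter table cannot make
all four conditions exactly periodic because the mutant's serine pool is an
order of magnitude above wildtype.  The defaults therefore use a small
k_ser2aa (0.01 h⁻¹), Γ* = 32 ppm (a reasonable value for the 22 °C growth
temperature), modest NR activities with a midday maximum and strong dark
inactivation, and per-condition dawn states tuned so the recorded cycle is
the first cycle from dawn.  The wildtype conditions are then near a
repeating orbit; the mutant at ambient CO₂ is deliberately non-stationary —
serine climbs ~15× wildtype by dusk and is recycled deep into the night —
like the stressed plant it mimics.

What the generator does *not* emulate: real replicate-to-replicate
autocorrelation, instrument drift, day-to-day biological variation, the
paper's absolute pool sizes (only their orders of magnitude and directions
of contrast), and a mutant glycine excess (within this rate structure,
glycine is produced by PR and consumed by genotype-independent GDC/SHMT
kinetics, so the mutant's lower photosynthesis gives it slightly *less*
glycine than wildtype; only serine accumulates).  Passing tests therefore
demonstrate internal consistency and recoverability under the stated noise
model, not agreement with any particular measured rosette.

## Known limitations

* The PR pathway between RuBP oxygenation and glyoxylate is unresolved; no
  C1/THF pool, no compartmented transport.
* The PR→Gly arrow carries one glycine (one N) per flux unit; the canonical
  two-glycines-per-cycle bookkeeping is intentionally not applied, matching
  the N₁-flux balance Glu→αKG = PR − HPR.
* When HPR exceeds PR (mutant nights), the clamp makes serine-bound N leave
  the modelled pools; the nitrogen-balance test carries this term exactly.
* The gross HP input can turn slightly negative at night when 2α exceeds the
  nocturnal GDC flux — the 2 C per dark-formed glycine are then drawn from
  the HP pool, which is the intended bookkeeping.
* The averaged-percent-error objective has a noise floor set by the
  replicate means (≈ √(2/π)·cv/√n for the exact generating trajectory, and
  higher once the dawn state is pinned to noisy means), so very small
  objective values are attainable only at very low noise.
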