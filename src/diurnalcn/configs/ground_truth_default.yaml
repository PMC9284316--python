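# Versioned ground-truth table for the synthetic-data generator.
#
# The four conditions reproduce the study design (Col-0 / hpr1-1 crossed with
# ambient 450 ppm / elevated 1000 ppm CO2, 8 h light / 16 h dark, sampling
# every 2 h at five replicates).  Light-phase photosynthesis means are the
# measured condition means; everything else (kinetic constants, initial pool
# sizes, enzyme activities) is a documented default chosen to give a
# self-consistent diurnal cycle with pool sizes of a realistic order of
# magnitude for Arabidopsis rosettes, NOT a reproduction of any measured
# value.  The kinetic constants shared by all conditions are the defaults of
# KineticParams; the hpr1-1 lesion is emulated solely by scaling the HPR
# activity series to 10% of wildtype.
version: 2
light_hours: 8.0
# CO2 compensation point without day respiration at the 22 degC growth
# temperature, in ppm (same unit as the growth CO2 concentration).
gamma_star_ppm: 32.0
sampling:
  interval_h: 2.0
  n_replicates: 5
  cv: 0.1

# Overrides of KineticParams defaults shared by all conditions (none: the
# dataclass defaults ARE the wildtype truth).
params: {}

# Dawn (light-on) pool sizes in umol/gFW, tuned per condition so that the
# recorded cycle starts near the condition's own quasi-repeating state.  The
# mutant at ambient CO2 is deliberately non-stationary (serine accumulates
# by day and is recycled far into the night), like the plant it emulates.
conditions:
  col0_ambient:
    genotype: Col-0
    co2_ppm: 450.0
    ps_mean: 85.4
    rd: 6.0
    no3_total: 20.0
    initial_state:
      {gly: 0.05, ser: 0.3, hp: 2.0, mf: 2.0, cit: 20.0, kg: 0.5, glu: 9.0, gln: 2.0, aa: 14.0, nh4: 0.3}
    activities:
      NR: [1.3, 2.0, 1.0, 0.15]
      GS: [20.0, 23.0, 21.5, 18.0]
      HPR: [28.0, 32.0, 30.0, 26.0]
  col0_eco2:
    genotype: Col-0
    co2_ppm: 1000.0
    ps_mean: 128.1
    rd: 6.0
    no3_total: 20.0
    initial_state:
      {gly: 0.05, ser: 0.3, hp: 2.0, mf: 5.0, cit: 35.0, kg: 1.0, glu: 18.0, gln: 2.0, aa: 18.0, nh4: 0.3}
    activities:
      NR: [1.45, 2.2, 1.1, 0.16]
      GS: [16.0, 18.4, 17.2, 14.4]
      HPR: [28.0, 32.0, 30.0, 26.0]
  hpr1_ambient:
    genotype: hpr1-1
    co2_ppm: 450.0
    ps_mean: 76.8
    rd: 6.0
    no3_total: 16.0
    initial_state:
      {gly: 0.05, ser: 6.0, hp: 2.0, mf: 2.0, cit: 14.0, kg: 8.0, glu: 14.0, gln: 2.0, aa: 16.0, nh4: 1.0}
    activities:
      NR: [1.05, 1.6, 0.8, 0.12]
      GS: [22.0, 25.3, 23.7, 19.8]
      HPR: [2.8, 3.2, 3.0, 2.6]
  hpr1_eco2:
    genotype: hpr1-1
    co2_ppm: 1000.0
    ps_mean: 98.6
    rd: 6.0
    no3_total: 18.0
    initial_state:
      {gly: 0.05, ser: 2.0, hp: 2.0, mf: 3.0, cit: 25.0, kg: 6.0, glu: 14.0, gln: 2.0, aa: 16.0, nh4: 0.3}
    activities:
      NR: [1.35, 2.0, 1.0, 0.15]
      GS: [17.6, 20.2, 18.9, 15.8]
      HPR: [2.8, 3.2, 3.0, 2.6]
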