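# Default synthetic-data parameters for the sea-lamprey stock-identification
# pipeline. This is a magnitudes-only emulation: per-character log-scale means,
# sex differences and the three-group structure match published group/sex
# summary tables for adult Petromyzon marinus from western Iberian rivers, but
# within-group covariances are diagonal and no real specimen data are encoded.
seed: 0
n_per_stratum: 14          # per (group, river, sex); 16 strata -> 224 specimens
tl_mean_mm: 864.0          # adult total length, mm
tl_sd_mm: 60.0
groups: [group1, group2, group3]
rivers:
  group1: [Minho, Lima, Cavado, Douro, Vouga, Mondego]
  group2: [Tagus]
  group3: [Guadiana]
sexes: [male, female]
# Length-mass allometry W = a * (TL_cm)^b (g), lognormal residual on log scale.
total_mass:
  male: [0.0898, 2.1209]
  female: [0.0568, 2.2342]
  resid_sd: 0.08
# Morphometric characters: natural-log-scale means at the reference length
# (sex-specific), allometric slope b of log(char) on log(TL), residual sd on
# the log scale, and additive group deviations (group1, group2, group3).
# Eye diameter O is uncorrelated with total length (slope 0). Only the three
# characters with documented between-group separation (O, lD2, B1-B7) carry
# group deviations by default.
characters:
  d:     {male: 3.978, female: 3.945, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_a:   {male: 6.449, female: 6.455, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  a_C:   {male: 5.463, female: 5.448, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  B7_C:  {male: 6.541, female: 6.545, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  B7_a:  {male: 6.133, female: 6.145, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_D1:  {male: 6.099, female: 6.104, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_eD1: {male: 6.313, female: 6.316, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_D2:  {male: 6.379, female: 6.384, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  D2_C:  {male: 5.643, female: 5.630, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  lD1:   {male: 4.671, female: 4.670, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  lD2:   {male: 5.385, female: 5.369, slope: 1.0, resid_sd: 0.05, group_dev: [0.0167, -0.0033, -0.0133]}
  D_D:   {male: 3.682, female: 3.710, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  H:     {male: 3.995, female: 4.068, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_O:   {male: 4.130, female: 4.093, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  O:     {male: 2.185, female: 2.176, slope: 0.0, resid_sd: 0.05, group_dev: [-0.0033, -0.0333, 0.0367]}
  O_B1:  {male: 3.023, female: 3.006, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  Hco:   {male: 3.790, female: 3.773, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_B1:  {male: 4.486, female: 4.457, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  B1_B7: {male: 4.470, female: 4.466, slope: 1.0, resid_sd: 0.05, group_dev: [-0.01, 0.01, 0.0]}
  d_B7:  {male: 5.165, female: 5.149, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  d_n:   {male: 4.010, female: 3.972, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  IO:    {male: 3.857, female: 3.832, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
  HW:    {male: 4.000, female: 3.990, slope: 1.0, resid_sd: 0.05, group_dev: [0.0, 0.0, 0.0]}
# Meristic counts: rounded-normal marginals (no group or sex effect).
meristics:
  Myo:     {mean: 73.1, sd: 1.6}
  TNteeth: {mean: 148.6, sd: 8.0}
  AFteeth: {mean: 39.5, sd: 3.8}
  LFteeth: {mean: 62.4, sd: 2.9}
  PFteeth: {mean: 37.2, sd: 2.7}
  TNrows:  {mean: 25.2, sd: 0.4}
  AFrows:  {mean: 7.0, sd: 0.0}
  LFrows:  {mean: 8.0, sd: 0.0}
  PFrows:  {mean: 9.2, sd: 0.4}
  IOcusps: {mean: 7.5, sd: 0.7}
# Heart-tissue fatty-acid mean compositions (% of total identified fatty
# acids) per group. A fatty acid absent from a group's mapping is structurally
# absent there (ND -> exact zero). The published tables cover only the major
# identified components, so each group's means sum below 100%; the loader adds
# a per-group "other" remainder component representing the unlisted minor
# fatty acids so every mean composition closes to exactly 100%.
fatty_acids:
  dispersion: 0.35          # sd of multiplicative log-normal noise per component
  means:
    group1:
      "C10:0": 2.84
      "C12:0": 0.08
      "C13:0": 7.51
      "C14:0": 1.50
      "C16:0": 15.92
      "C18:0": 7.06
      "C20:0": 0.20
      "C22:0": 0.22
      "C16:1": 9.92
      "C18:1ω9": 16.64
      "C20:1ω9": 0.49
      "C18:2ω6": 0.29
      "C20:2": 0.14
      "C20:3ω3": 2.69
      "C20:5ω3": 2.60
      "C22:2ω6": 0.12
      "C22:5ω3": 3.46
      "C22:6ω3": 8.21
    group2:
      "C10:0": 0.74
      "C12:0": 0.06
      "C13:0": 2.20
      "C14:0": 1.75
      "C16:0": 20.39
      "C18:0": 9.13
      "C20:0": 0.88
      "C22:0": 0.28
      "C14:1": 0.06
      "C16:1": 13.69
      "C18:1ω9": 22.95
      "C20:1ω9": 1.00
      "C22:1ω9": 0.14
      "C18:2ω6": 0.35
      "C20:2": 0.32
      "C20:3ω6": 0.16
      "C20:3ω3": 3.10
      "C20:4ω6": 0.19
      "C20:5ω3": 2.34
      "C22:5ω3": 3.45
      "C22:6ω3": 6.32
    group3:
      "C10:0": 3.36
      "C13:0": 13.47
      "C14:0": 0.70
      "C15:0": 0.15
      "C16:0": 10.97
      "C17:0": 0.90
      "C18:0": 5.55
      "C16:1": 6.09
      "C18:1ω9": 12.86
      "C20:1ω9": 0.28
      "C18:2ω6": 0.30
      "C20:3ω3": 3.15
      "C20:5ω3": 3.11
      "C22:5ω3": 4.25
      "C22:6ω3": 10.45
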