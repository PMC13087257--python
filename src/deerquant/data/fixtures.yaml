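# Ground-truth fixtures for round-trip validation of the full pipeline.
#
# Component geometry (means/SDs, nm) follows the in-silico predictions for
# the two cap-domain states of a K2P channel dimer: non-swapped (NS, short
# distance) and swapped (S, long distance). Component weights encode the
# fitted state populations at the two measurement temperatures.
fixtures:
  exp19C:
    description: "two-state ensemble at 19 C ambient temperature"
    components:
      - {mean: 3.3, sd: 0.5, weight: 0.43, state: NS}
      - {mean: 5.0, sd: 0.3, weight: 0.57, state: S}
  exp40C:
    description: "two-state ensemble at 40 C"
    components:
      - {mean: 3.3, sd: 0.5, weight: 0.34, state: NS}
      - {mean: 5.0, sd: 0.3, weight: 0.66, state: S}

# Trace-simulation defaults for acceptance-style runs: four dipolar
# evolution windows up to 7.5 us, modulation depth 0.3, homogeneous-3D
# background, white noise at 0.5% of V0.
trace_defaults:
  t_max_set: [2.0, 4.0, 6.0, 7.5]
  dt: 0.016
  lambda: 0.3
  background_k: 0.05
  background_d: 3.0
  noise_sd: 0.005
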