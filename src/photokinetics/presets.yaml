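# Measured kinetic and photophysical parameters of mSAASoti cysteine
# variants, transcribed as generator presets.
#
# Units: rates in 1e-3 s^-1 (the table convention; the loader converts to
# s^-1), epsilon in 1e3 M^-1 cm^-1, blue shift in nm per cycle.
# switch_cycle1/switch_cycle2: ratio = I2/I1; a null k2 with ratio 0 marks
# a mono-exponential cycle (the fields printed as dashes).
# Fields listed under `reconstructed` are illustrative defaults chosen for
# the generator (per-cycle fatigue, spectral shift); they are NOT measured
# values — no quantitative measurements exist for those quantities.
version: 1
defaults:
  emission_center_nm: 519.0
  emission_width_nm: 15.0
variants:
  mSAASoti:
    pka_green: 6.3
    epsilon_1e3: 75.0
    phi: 0.59
    conversion: {k1: 11.0, k2: 2.0}
    switch_cycle1: {ratio: 0.27, k1: 5.5, k2: 9.8, opposed: true}
    switch_cycle2: {ratio: 0.26, k1: 7.8, k2: 24.7, opposed: false}
    recovery: {k: 22.0}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C21N:
    pka_green: 6.4
    epsilon_1e3: 82.4
    phi: 0.61
    conversion: {k1: 14.0, k2: 2.0}
    switch_cycle1: {ratio: 0.27, k1: 5.7, k2: 15.7, opposed: true}
    switch_cycle2: {ratio: 0.76, k1: 5.3, k2: 13.7, opposed: false}
    recovery: {k: 9.5}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C105V:
    pka_green: 6.5
    epsilon_1e3: 61.0
    phi: 0.60
    conversion: {k1: 15.0, k2: 5.0}
    switch_cycle1: {ratio: 0.22, k1: 9.1, k2: 34.3, opposed: true}
    switch_cycle2: {ratio: 2.06, k1: 7.1, k2: 17.9, opposed: false}
    recovery: {k: 17.9}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C71V:
    pka_green: 6.5
    epsilon_1e3: 65.1
    phi: 0.63
    conversion: {k1: 21.0, k2: 1.0}
    switch_cycle1: {ratio: 0.14, k1: 4.5, k2: 14.2, opposed: true}
    switch_cycle2: {ratio: 0.4, k1: 5.1, k2: 15.0, opposed: false}
    recovery: {k: 15.5}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C117S:
    pka_green: 6.2
    epsilon_1e3: 66.3
    phi: 0.54
    conversion: {k1: 9.0, k2: 3.0}
    switch_cycle1: {ratio: 0.09, k1: 6.4, k2: 10.9, opposed: true}
    switch_cycle2: {ratio: 0.24, k1: 6.4, k2: 15.6, opposed: false}
    recovery: {k: 9.7}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C21N_C71V:
    pka_green: 6.3
    epsilon_1e3: 48.9
    phi: 0.58
    conversion: {k1: 22.0, k2: 1.0}
    switch_cycle1: {ratio: 0.26, k1: 6.8, k2: 15.6, opposed: true}
    switch_cycle2: {ratio: 0.2, k1: 7.4, k2: 22.8, opposed: false}
    recovery: {k: 12.5}
    fatigue: 1.0
    blue_shift_per_cycle_nm: -2.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C175A:
    pka_green: 6.7
    epsilon_1e3: 80.1
    phi: 0.55
    conversion: {k1: 15.0, k2: 3.0}
    switch_cycle1: {ratio: 0.0, k1: 3.5, k2: null, opposed: false}
    switch_cycle2: {ratio: 0.12, k1: 3.1, k2: 16.0, opposed: false}
    recovery: {k: 5.5}
    fatigue: 0.85
    blue_shift_per_cycle_nm: 0.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C21N_C175A:
    pka_green: 6.3
    epsilon_1e3: 65.4
    phi: 0.55
    conversion: {k1: 13.0, k2: 3.0}
    switch_cycle1: {ratio: 0.0, k1: 4.1, k2: null, opposed: false}
    switch_cycle2: {ratio: 0.98, k1: 1.5, k2: 7.5, opposed: false}
    recovery: {k: 2.5}
    fatigue: 0.85
    blue_shift_per_cycle_nm: 0.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
  C21N_C71G_C175A:
    pka_green: 6.4
    epsilon_1e3: 83.8
    phi: 0.60
    conversion: {k1: 46.0, k2: 9.0}
    switch_cycle1: {ratio: 0.0, k1: 4.0, k2: null, opposed: false}
    switch_cycle2: {ratio: 0.0, k1: 4.4, k2: null, opposed: false}
    recovery: {k: 4.5}
    fatigue: 0.80
    blue_shift_per_cycle_nm: 0.0
    reconstructed: [fatigue, blue_shift_per_cycle_nm]
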