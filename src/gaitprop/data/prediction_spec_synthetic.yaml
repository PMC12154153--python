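# SYNTHETIC demonstration prediction equations.
#
# These coefficients are NOT fitted to any control dataset; they are
# placeholder values of plausible magnitude so the pipeline runs end to end.
# Replace this file with published coefficients for real analyses.
#
# Sex encoding: M -> 0, F -> 1 (documented convention; models were trained
# elsewhere, so the encoding must match whatever file is supplied).
provenance: synthetic demonstration coefficients, not fitted to data
sex_encoding:
  M: 0
  F: 1
bounds:
  min_speed: 0.36        # m/s
  min_agrf: 18.2         # N
  min_step_length: 0.32  # m
models:
  step_length:           # metres
    intercept: 0.05
    coefficients:
      speed: 0.29        # m per m/s
      leg_length: 0.35   # m per m
      mass: 0.0
      sex: 0.01
      age: -0.0005
  agrf:                  # newtons
    intercept: -45.0
    coefficients:
      speed: 126.6       # N per m/s
      leg_length: 40.0
      mass: 0.6
      sex: -4.0
      age: -0.15
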