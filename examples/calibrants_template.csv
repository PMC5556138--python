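# Calibrant table template for `twimsccs calibrate --calibrants FILE`.
# One row per calibrant charge state, measured under the same instrument
# settings as the analytes. Columns:
#   label    free text, same label for all charge states of one species
#   mass_da  neutral average mass of the calibrant species, Da
#   charge   charge state z (positive integer)
#   ccs_A2   literature CCS of this charge state in Å² (from a published
#            CCS database measured in your drift gas)
#   drift_ms measured drift time in ms (uncorrected)
# Replace the placeholder rows below with your calibrant measurements.
label,mass_da,charge,ccs_A2,drift_ms
example_protein,36700,11,3290,5.21
example_protein,36700,12,3350,4.83
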