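# Simulated ABG curve shapes per diagnosis group (clinical grid),
# produced by the calibrated default model; regenerate with
# `otomech shapes`. Rescaled to published group means at load time.
diagnosis,frequency_hz,abg_db
otosclerosis,250.0,35.718
otosclerosis,500.0,32.123
otosclerosis,1000.0,28.621
otosclerosis,2000.0,26.726
otosclerosis,4000.0,24.677
attic_fixation,250.0,54.075
attic_fixation,500.0,53.027
attic_fixation,1000.0,49.492
attic_fixation,2000.0,36.427
attic_fixation,4000.0,31.68
is_discontinuity_trauma,250.0,9.482
is_discontinuity_trauma,500.0,5.267
is_discontinuity_trauma,1000.0,16.485
is_discontinuity_trauma,2000.0,19.91
is_discontinuity_trauma,4000.0,18.917
is_discontinuity_malformation,250.0,42.985
is_discontinuity_malformation,500.0,34.974
is_discontinuity_malformation,1000.0,49.351
is_discontinuity_malformation,2000.0,49.655
is_discontinuity_malformation,4000.0,47.898
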