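# Audiometric calibration table.
#   retspl_db_spl: reference equivalent threshold sound pressure levels for a
#     supra-aural earphone (ISO 389-1 lineage values, editable).
#   ear_canal_gain_db: smooth external/ear-canal pressure gain peaking near
#     2-3 kHz (literature-typical, editable).
# Because the structural model is linear, any consistent table cancels out of
# the simulated air-bone gap; these values only set absolute displacements.
reference_pressure_pa: 2.0e-5
frequencies_hz: [250, 500, 750, 1000, 1500, 2000, 3000, 4000]
retspl_db_spl: [25.5, 11.5, 8.0, 7.0, 6.5, 9.0, 10.0, 9.5]
ear_canal_gain_db: [1.0, 2.0, 2.5, 3.0, 5.0, 9.0, 12.0, 10.0]
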