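# Literature corridor for stapes-footplate displacement magnitude (m) under
# an 80 dB SPL tone at the eardrum. Bounds are generous envelopes around the
# span of published laser-Doppler / probe-tube measurements and middle-ear
# model studies (order 1e-9..1e-8 m below 1 kHz, mass-controlled roll-off
# above). Calibration aid only, never an acceptance oracle.
# columns: frequency_hz, lower_m, upper_m
frequency_hz,lower_m,upper_m
250,1.0e-9,5.0e-8
500,1.0e-9,5.0e-8
1000,5.0e-10,4.0e-8
2000,1.0e-10,2.0e-8
4000,2.0e-11,1.0e-8
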