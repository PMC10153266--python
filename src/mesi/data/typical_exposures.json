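{
 "description": "Irregular 15-step exposure ladder (seconds) spanning 50 us - 80 ms, following the 1-2.5-5 per-decade convention of the multi-exposure speckle imaging literature. Editable: replace with the ladder of your own instrument.",
 "times_s": [5.0e-5, 7.5e-5, 1.0e-4, 2.5e-4, 5.0e-4, 7.5e-4, 1.0e-3,
             2.5e-3, 5.0e-3, 7.5e-3, 1.0e-2, 2.5e-2, 4.0e-2, 6.0e-2, 8.0e-2]
}
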