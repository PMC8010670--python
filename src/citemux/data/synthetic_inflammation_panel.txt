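# Synthetic stand-in inflammation gene panel.
# Lists the generator's monocyte late (pro-inflammatory) activation-wave
# genes so inflammation scoring can be exercised without the proprietary panel.
G0275
G0276
G0277
G0278
G0279
G0280
G0281
G0282
G0283
G0284
G0285
G0286
G0287
G0288
G0289
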