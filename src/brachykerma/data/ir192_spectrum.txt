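# Ir-192 photon emission line spectrum (gamma lines plus grouped Os/Pt
# K X-rays), ENSDF-style evaluated intensities in photons per decay.
# Beta continua and conversion electrons are omitted: only photons are
# transported and dose is scored as collisional kerma.
# Format: energy_keV  intensity_per_decay
61.49    0.0120
63.00    0.0207
65.12    0.0263
66.83    0.0450
71.41    0.0050
73.36    0.0160
75.75    0.0104
77.83    0.0070
136.34   0.00199
201.31   0.00473
205.79   0.0334
283.27   0.00266
295.96   0.2871
308.46   0.2968
316.51   0.8286
374.49   0.00726
416.47   0.00670
468.07   0.4781
484.58   0.03189
489.06   0.00438
588.58   0.04517
604.41   0.0820
612.46   0.0534
884.54   0.00292
1061.48  0.00053
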