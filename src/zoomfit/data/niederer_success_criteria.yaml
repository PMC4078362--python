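# Success bands for fitting the Niederer-model to mouse twitch data at
# 37 C: measured error bars on the resting-length twitch descriptors,
# relative-change bands on peak tension at 110% and 90% resting length,
# and a cap on the standardized force-curve RMSD.
criteria:
- {metric: RT50, lambda: 1.0, min: 16.0, max: 30.0}
- {metric: RT90, lambda: 1.0, min: 41.0, max: 59.0}
- {metric: TTP,  lambda: 1.0, min: 26.0, max: 41.0}
- {metric: Peak, lambda: 1.0, min: 32.0, max: 52.0}
- {metric: Peak, lambda: 1.1, min: 73.0, max: 90.0}
- {metric: Min,  lambda: 1.1, max: 1.0, max_strict: true}
- {metric: Peak, lambda: 0.9, min: 12.0, max: 20.0}
- {metric: RMSDforce, lambda: 0.9, max: 0.15, max_strict: true}
- {metric: RMSDforce, lambda: 1.0, max: 0.15, max_strict: true}
- {metric: RMSDforce, lambda: 1.1, max: 0.15, max_strict: true}
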