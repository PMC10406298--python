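drift_amplitude: 1.0
drift_period: 128.0
ar_rho: 0.4
ar_sigma: 1.0
physio:
- - 0.2
  - 0.5
- - 1.17
  - 0.5
white_sigma: 1.0
snr: 1.0
seed: null
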