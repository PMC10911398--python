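# Demo run configuration: two conditions, a handful of cells each.
# Shorter spontaneous segments than a production run so the demo stays
# quick; raise spont_duration/n_cells for precise rate estimates.
conditions:
  - name: WT
    rates: {k1: 385.6, k_minus1: 0.0903, kf: 0.000844}
    seed: 1
    n_cells: 3
    spont_duration: 20.0
    protocol: {onset_time: 1.0, duration: 5.0, n_suc: 5000,
               baseline_shift: -20.0, exchange_time: 0.05}
  - name: D166Y
    rates: {k1: 37.68, k_minus1: 0.0294, kf: 0.03522}
    seed: 2
    n_cells: 3
    spont_duration: 20.0
    protocol: {onset_time: 1.0, duration: 5.0, n_suc: 5000,
               baseline_shift: -20.0, exchange_time: 0.05}
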