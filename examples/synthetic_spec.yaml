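# Synthetic assay spec for `ratedose simulate --spec ...`
# Ground-truth dose-response: r(C) = amplitude * exp(-decay * C) - floor
amplitude: 0.85      # days^-1
decay: 0.06          # per ug/mL
floor: 0.55          # days^-1 (magnitude of the negative high-dose plateau)
times: [0, 1, 2, 3]  # days
n_experiments: 3
n_replicates: 3
noise_sigma: 0.08    # SD of log-normal multiplicative noise on absorbance
seed: 42
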