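# Example hybcal configuration (pass via `hybcal <cmd> --config file.yaml`).
# All values shown are the package defaults; see docs/methods.md for the
# rationale behind the simulator ranges.

seed: 0
normalization: none          # none | location | location_scale
log_floor: 1.0               # raw intensities clipped here before log2
fdr_q: 0.01                  # strict q < cutoff for n_sig
sigma_floor: 1.0e-06
posterior_eps: 1.0e-06
n_subsamples: 100            # rank-stability subsamples
subsample_size: null         # null -> G // 4 genes per subsample
folds: loo                   # slide folds for cross-testing
top_share_threshold: 0.5     # winners: rank-1 share >= 0.5 * max share
entropy_threshold_bits: 1.5  # rank-1 entropy above this flags biased samples
adjacency_window_celsius: 2.0

# Chip-level overrides forwarded to the Langmuir simulator (make_chip):
#   xhyb_fraction: probes receiving 1-12 non-targets (0.1)
#   dh_range:      target duplex enthalpy, kJ/mol (-350, -250)
#   dg_ref_range:  target free energy at 324.15 K, kJ/mol (-18, -12);
#                  narrow by design -- a well designed probe set has similar
#                  binding strengths, which makes one compromise temperature
#                  meaningful
#   alpha_range:   cross-duplex amplitude relative to self binding (0.02, 0.2)
simulator: {}
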