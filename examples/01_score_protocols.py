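"""Score two competing hybridization protocols on a simulated calibration run.

Two dye-swap datasets measure the same planted biology, one with doubled
measurement noise. Every quality measure — Gaussian and naive-Bayes
log-likelihood, held-out accuracy, mean per-gene AUC and the mutual-
information bit rate — should prefer the low-noise protocol.
"""

import numpy as np

from hybcal import gaussian_group_dataset, score_protocol

rng = np.random.default_rng(0)
base, _ = gaussian_group_dataset(n_per_group=50, noise_sd=0.0, rng=rng)
protocols = {
    label: base.copy(values=base.values + rng.normal(0, sd, base.values.shape))
    for label, sd in (("51C", 0.3), ("52C", 0.6))
}

scores = score_protocol(protocols, fdr_cutoff=0.01)
print(f"{'K':>4} {'acc%':>7} {'I bits':>7} {'logL_nb':>9} {'AUC':>6} {'n_sig':>6}")
for s in scores:
    print(
        f"{s.protocol:>4} {s.accuracy_pct:7.2f} {s.bitrate:7.3f} "
        f"{s.loglik_nb:9.1f} {s.mean_auc:6.3f} {s.n_sig:6d}"
    )
print(
    "\nHigher accuracy, bit rate, log-likelihood and n_sig all identify the "
    "low-noise protocol (51C) as the more informative hybridization."
)
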