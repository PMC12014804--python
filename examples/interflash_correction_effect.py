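"""Why the inter-flash correction matters when probing the S2 state.

During the 10 ms spent in S3 between 100 Hz turnover flashes the fast
substrate water keeps exchanging, so part of the fast phase is already
labeled at time zero.  Fitting such data with the correction disabled (b = 1)
biases the fast rate; with the correction the truth is recovered.  Both fits
run on the same simulated traces.
"""

import numpy as np

from mimsfit import (
    EnrichmentSpec,
    ExchangeParams,
    FitConfig,
    FlashProtocol,
    MimsSimConfig,
    global_fit,
    preprocess,
    simulate_mims,
)

truth = ExchangeParams(k_f=111.0, k_s=0.93)
enrichment = EnrichmentSpec(alpha_i=0.0007, alpha_f=0.13)
protocol = FlashProtocol(probed_state="S2", flash_frequency=100.0, k_f_s3=29.0)

with_b = FitConfig(enrichment=enrichment, protocol=protocol)
without_b = FitConfig(
    enrichment=enrichment, protocol=protocol, fix_b_from_protocol=False
)

kf_corrected, kf_uncorrected = [], []
for seed in range(10):
    cfg = MimsSimConfig(
        truth=truth, enrichment=enrichment, protocol=protocol,
        noise_sigma=0.01, seed=seed,
    )
    clean = preprocess(simulate_mims(cfg), residual_estimate=None)
    kf_corrected.append(global_fit(clean, with_b).estimates.k_f)
    kf_uncorrected.append(global_fit(clean, without_b).estimates.k_f)

print(f"true fast rate                 k_f = {truth.k_f:.0f} 1/s")
print(f"median fit with b-correction   k_f = {np.median(kf_corrected):6.1f} 1/s")
print(f"median fit with b forced to 1  k_f = {np.median(kf_uncorrected):6.1f} 1/s")
print("ignoring the inter-flash exchange leaves a systematic error in the "
      "fast phase; the correction removes it.")
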