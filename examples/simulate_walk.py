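"""Generate one pseudo-real sEMG walk and describe what was built.

A ground-truth synergy set (here 5 synergies over 12 muscles, 150 gait
cycles) defines noiseless muscle envelopes W @ C; the raw-looking signal
modulates each envelope with a unit-variance Gaussian carrier and adds
background noise at 20 dB SNR.
"""

import numpy as np

from choosyn import generate_ground_truth, synthesize_emg

truth = generate_ground_truth(true_n=5, m=12, n_cycles=150, seed=42)
recording = synthesize_emg(truth, snr_db=20.0, carrier_seed=1, noise_seed=2)

print(f"weights           : {truth.weights.shape}  (muscles x synergies)")
print(f"coefficients      : {truth.coefficients.shape}  (synergies x samples)")
print(f"signal            : {recording.signal.shape}  (samples x muscles)")
print(f"cycles            : {truth.n_cycles} of {truth.cycle_length} samples")
print(f"noise sigma       : {10 ** (-20.0 / 20.0):.3f} a.u. (20 dB SNR)")
envelope_rank = np.linalg.matrix_rank(truth.weights @ truth.coefficients)
print(f"envelope rank     : {envelope_rank} (equals the true synergy number)")
# The envelope matrix is exactly rank true_n: every selection criterion
# downstream is trying to recover that number from the noisy signal.
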