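"""Estimate the energy-scaling parameter lambda for a motif.

Builds the classic worked example — a six-column motif that always
prefers A (counts 8,0,0,0 per column) against a uniform background —
computes its exact background score distribution, and applies the
lambda equation: lambda = (S_max - S_top0.1%) / E_maxMismatch with
E_maxMismatch = 6 bits * If / 13.2 bits.
"""

import numpy as np

from pwmscale import (
    BACKGROUND_PRESETS,
    PFM,
    build_pwm,
    estimate_lambda,
    exact_distribution,
)

counts = np.zeros((4, 6))
counts[0] = 8.0  # row order A, C, G, T
pfm = PFM(counts=counts, n_sequences=8, motif_id="A6")
pwm = build_pwm(pfm, BACKGROUND_PRESETS["uniform"])

dist = exact_distribution(pwm)  # all 4^6 k-mers, probability-weighted
est = estimate_lambda(pwm, dist)

print(f"information content If = {est.information_content:.5f} bits")
print(f"consensus score  S_max = {est.s_max:.5f} bits")
print(f"top-0.1% score   S_top = {est.s_top:.5f} bits")
print(f"max mismatch energy    = {est.e_max_mismatch:.5f} bits")
print(f"lambda                 = {est.lam:.5f}")
print()
print("lambda converts score drops from the consensus into mismatch")
print("energy: a site 1 bit below S_max costs", f"{1/est.lam:.3f}",
      "bits of binding energy for this TF.")
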