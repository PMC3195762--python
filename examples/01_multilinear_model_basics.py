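"""Fit a multilinear texture model and recover a known low-rank structure.

Builds a cohort of 20 tensors that are exactly multilinear-rank (8, 8, 4),
fits per-mode bases at the true ranks, and shows that the subspaces and the
samples are recovered to numerical precision — the regime where alternating
per-mode eigen-updates are exact.
"""

import numpy as np

from gndpca import FitConfig, cost, fit, frobenius_norm, project, reconstruct, tucker_reconstruct

rng = np.random.default_rng(0)
shape, ranks, m = (32, 32, 16), (8, 8, 4), 20

factors = [np.linalg.qr(rng.standard_normal((s, r)))[0] for s, r in zip(shape, ranks)]
samples = [tucker_reconstruct(rng.standard_normal(ranks), factors) for _ in range(m)]

model = fit(samples, FitConfig(ranks=ranks))
energy = sum(frobenius_norm(s) ** 2 for s in samples)

print(f"sweeps run              : {len(model.fit_history)}")
print(f"relative residual cost  : {cost(model, samples) / energy:.3e}")
rec = reconstruct(model, project(model, samples[0]))
print(f"sample recon rel error  : {frobenius_norm(rec - samples[0]) / frobenius_norm(samples[0]):.3e}")
print()
print("A residual near machine precision means the fitted per-mode bases")
print("span the generating subspaces: each 32x32x16 volume is represented")
print("exactly by an 8x8x4 core tensor (256 numbers instead of 16384).")
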