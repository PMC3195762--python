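"""Few-sample generalization: multilinear bases vs vectorized PCA.

Fifteen texture phantoms train both models; a sixteenth, never seen, is
reconstructed by each.  Vectorized ("eigenface") PCA can only reproduce
combinations of its 14 training deviations, so it overfits; the per-mode
subspaces generalize, and held-out quality climbs with the core size.
"""

from gndpca import (
    CohortSpec,
    FitConfig,
    fit,
    fit_eigenface,
    frobenius_norm,
    normalized_correlation,
    project,
    reconstruct,
    reconstruct_eigenface,
    sample_volume,
)

spec = CohortSpec(n_normal=16, shape=(48, 48, 24), shape_deform_sd=0.0, seed=0)
samples = [sample_volume(spec, i).data for i in range(16)]
train, held = samples[:15], samples[15]

eig = fit_eigenface(train)
rec_eig = reconstruct_eigenface(eig, held)
print(f"eigenface (all {eig.n_components} bases): "
      f"corr = {normalized_correlation(rec_eig, held):.3f}, "
      f"err = {frobenius_norm(rec_eig - held):.1f}")

for ranks in [(2, 2, 1), (5, 5, 2), (10, 10, 4), (16, 16, 8), (24, 24, 12)]:
    model = fit(train, FitConfig(ranks=ranks, max_iter=20))
    rec = reconstruct(model, project(model, held))
    print(f"multilinear core {str(ranks):>12}: "
          f"corr = {normalized_correlation(rec, held):.3f}, "
          f"err = {frobenius_norm(rec - held):.1f}")
print()
print("The multilinear model overtakes the eigenface baseline once the core")
print("grows past a few hundred coefficients, despite both seeing the same")
print("15 samples: per-mode bases impose structure the baseline cannot.")
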