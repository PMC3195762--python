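"""Shape-normalize a deformed phantom and check texture preservation.

Generates one liver-like phantom with a random smooth shape deformation,
registers it to the undeformed template (rigid + cubic-B-spline FFD), and
reports foreground overlap before/after plus the round-trip texture
correlation — the evidence that normalization removes shape variability
without destroying texture.
"""

import numpy as np

from gndpca import CohortSpec, make_template, normalize_to, roundtrip_check, sample_volume

SHAPE, GRID = (48, 48, 24), (5, 5, 3)
spec = CohortSpec(shape=SHAPE, seed=1)
moving = sample_volume(spec, 0)
template = make_template(SHAPE, spec.spacing)


def dice(a, b):
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


warped, transform = normalize_to(moving, template, GRID)
tm = template.data > 1.0
print(f"foreground Dice before normalization : {dice(moving.data > 1.0, tm):.3f}")
print(f"foreground Dice after  normalization : {dice(warped.data > 1.0, tm):.3f}")
print(f"FFD SSD reduced {transform.ffd.meta['initial_ssd'] / transform.ffd.meta['final_ssd']:.0f}x "
      f"in {transform.ffd.meta['n_iter']} iterations")

corr = roundtrip_check(moving, template, GRID)
print(f"round-trip texture correlation       : {corr:.4f}")
print()
print("Dice near 1 shows the phantom now shares the template's shape;")
print("a round-trip correlation near 1 shows the two interpolating warps")
print("lost almost no texture information.")
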