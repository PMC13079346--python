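"""Generate a multi-sequence brain phantom and inspect its ground truth.

The phantom renders one shared anatomy (skull ring, cortex, white matter,
ventricles, small blobs) under four contrast look-up tables, so every
downstream task has exact ground truth.
"""

import numpy as np

from maefew.phantom import PhantomSpec, brain_coverage, generate_phantom

spec = PhantomSpec(grid_size=64, noise_sd=0.02, seed=0)
volumes = generate_phantom(spec)

for vol in volumes:
    alphas = [brain_coverage(vol.brain_mask[:, :, i]) for i in range(64)]
    print(
        f"{vol.sequence:6s} image range [{vol.image.min():.2f}, {vol.image.max():.2f}]"
        f"  tissue classes {sorted(int(v) for v in np.unique(vol.labels))}"
        f"  axial coverage 0.00-{max(alphas):.2f}"
    )

# All sequences share one anatomy; only the rendering differs.
same = all(np.array_equal(v.labels, volumes[0].labels) for v in volumes)
print(f"\nsequences share anatomy: {same}")
print("Coverage spans empty to ~1/3 of the slice: the spread that drives the")
print("coverage-weighted pretraining loss.")
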