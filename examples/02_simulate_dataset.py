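"""Simulate an acoustic-telemetry dataset and summarise what was observed.

Uses a small version of the benchmark design: tags signalling every
Uniform(1, 2) time units, moving by Brownian motion (sigma_u = 0.25) over a
10x10 unit-spaced receiver grid with half-normal detection.
"""

import numpy as np

from mvlocate import SimConfig, simulate_dataset

config = SimConfig(n_individuals=5, duration=75.0, seed=1)
ds = simulate_dataset(config)

print(f"receivers: {ds.array.n_receivers}, state space: "
      f"[{ds.space.xmin:.2f}, {ds.space.xmax:.2f}]^2")
for tag in ds.tags:
    counts = tag.detection_counts
    print(
        f"tag {tag.tag_id}: {len(tag.schedule):3d} signals emitted, "
        f"{(counts > 0).sum():3d} detected at >=1 receiver, "
        f"max simultaneous detections {counts.max()}"
    )

all_counts = np.concatenate([t.detection_counts for t in ds.tags])
print("\ndetections-per-signal histogram (0..max):",
      np.bincount(all_counts).tolist())
print(
    "\nSignals emitted inside the array are heard by up to ~6 receivers;\n"
    "signals emitted in the buffered margin are mostly missed - those are\n"
    "the occasions the movement-assisted models can still localize."
)
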