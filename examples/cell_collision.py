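"""Two cells collide head-on at a shared attractant source.

Hertzian repulsion and displacement projection flatten the facing
membranes without interpenetration; after the source is engulfed both
cells relax back toward circular shape.
"""

from dataclasses import replace

import numpy as np

from morphocell import default_config, run_collision_scenario

cfg = replace(default_config("collision"), sigma_rw=0.0, t_end=16.0)
res = run_collision_scenario(cfg)

sep = np.linalg.norm(res.centres[:, 0] - res.centres[:, 1], axis=1)
print(f"centre separation start/min/final : {sep[0]:.2f} / {sep.min():.2f} /"
      f" {sep[-1]:.2f} um")
print(f"minimum membrane gap (node level) : {res.extras['min_gap']:.3f} um")
print(f"shape index minimum (flattening)  : {res.csi.min():.3f}")
print(f"final shape indices               : {np.round(res.csi[-1], 4)}")
# The negative-free gap shows the projection keeping the membranes apart at
# node resolution; the CSI dip below ~0.9 is the mutual flattening, and the
# final values near 1 are the post-collision recovery.
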