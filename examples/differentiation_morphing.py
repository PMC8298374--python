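"""Fibroblasts differentiate into myofibroblasts near a TGF-beta source.

Cells that sense a concentration above the threshold morph from an
elliptic to a hypocycloid (astroid) equilibrium shape with progress
ω(t) = 1 − exp(−λ_ω (t − t_ω)) and double their traction, deforming the
substrate visibly more.
"""

from dataclasses import replace

import numpy as np

from morphocell import default_config, run_differentiation_scenario

cfg = replace(default_config("differentiation"), sigma_rw=0.0, t_end=5.0)
res = run_differentiation_scenario(cfg)

print(f"differentiation onsets (min) : {res.extras['t_onset']}")
print(f"morphing progress at t_end   : "
      f"{np.round(res.extras['omega'][-1], 3)}")
print(f"phenotypes                   : {[c.phenotype for c in res.cells]}")
print(f"mean substrate displacement near cells : "
      f"{res.extras['u_near'][-1].mean():.4f} um")

baseline = replace(cfg, traction_factor=1.0)
res0 = run_differentiation_scenario(baseline)
print(f"same, without the traction increase    : "
      f"{res0.extras['u_near'][-1].mean():.4f} um")
# The displacement ratio shows the differentiated cells pulling the matrix
# substantially harder than undifferentiated fibroblasts would.
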