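"""Estimate local resolution from half-maps and project it onto a model.

Builds a synthetic two-domain test case (rigid half resolved at 4 A,
mobile half at 10 A), runs the windowed-FSC estimator on the half-map
pair, and projects the result onto the target structure.
"""

import numpy as np

from cryofit import local_resolution, make_bundle, mean_local_resolution, project_locres

bundle = make_bundle(n_res=48, pattern="two_domain", seed=0)
locres_grid = local_resolution(bundle.half1, bundle.half2)

track = project_locres(locres_grid, bundle.target, per="residue")
mean_res = mean_local_resolution(bundle.target, locres_grid)

rigid = [v for (chain, seq, icode), v in track.items() if seq <= 24]
mobile = [v for (chain, seq, icode), v in track.items() if seq > 24]

print(f"mean local resolution over the model: {mean_res:.2f} A")
print(f"rigid domain  (true 4 A):  mean {np.mean(rigid):.2f} A")
print(f"mobile domain (true 10 A): mean {np.mean(mobile):.2f} A")
print("Larger values mean worse resolution; the mobile domain should read")
print("clearly coarser than the rigid one, recovering the imposed pattern.")
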