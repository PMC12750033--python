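"""Correlate prediction-ensemble flexibility with local resolution.

Generates a 5-model ensemble whose per-residue fluctuation profile also
shaped the half-maps' resolution pattern, then runs the headline
analysis: accuracy gating, alignment of models 2-5 onto model 1,
per-residue RMSF, and its Pearson correlation with projected local
resolution.

On this small toy the mobile domain is so flexible relative to the chain
length that the ensemble fails the strict TM > 0.8 gate (TM-score's d0 is
tight for short chains) -- the gated report shows that honestly, and the
ungated run shows the flexibility-resolution correlation itself.
"""

from cryofit import local_resolution, make_bundle, rmsf_locres_report

bundle = make_bundle(n_res=48, pattern="two_domain", seed=2)
locres_grid = local_resolution(bundle.half1, bundle.half2)

gated = rmsf_locres_report([bundle.ensemble], bundle.target, locres_grid)
print("with the accuracy gate (lDDT > 0.7, TM > 0.8, all 5 models):")
print(gated.to_string(index=False))
print()

report = rmsf_locres_report(
    [bundle.ensemble], bundle.target, locres_grid, apply_gate=False
)
row = report.iloc[0]
print("without the gate:")
print(report.to_string(index=False))
print()
print(f"PCC(RMSF, LocRes) = {row.pcc:.2f} over {row.n} residues.")
print("A high signed correlation means the ensemble's spread mirrors the")
print("map's poorly resolved (flexible) regions, as designed here.")
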