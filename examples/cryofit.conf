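# Example cryofit configuration file.
#
# Format: one "subcommand.parameter = value" per line; '#' starts a
# comment.  Values here become defaults for the named subcommand and are
# overridden by command-line flags.  Pass with:
#
#     cryofit --config cryofit.conf <subcommand> ...

# windowed-FSC local resolution
locres.threshold = 0.5        # FSC threshold (0.143 for global-style reporting)
locres.step = 4               # sampling-lattice spacing in voxels

# sliding-window fit scoring
smoc.window = 11              # residues per window (odd)
smoc.resolution = 4.0         # simulation resolution in Angstrom
smoc.radius = 2.5             # voxel-footprint radius around atoms, Angstrom

# fragment-aligned scoring
delta-smoc.window = 11        # 5 for the high-resolution backbone/sidechain variant
delta-smoc.locres-exclude = 2.5   # drop residues resolved worse than this, Angstrom

# ensemble accuracy gate
gate.lddt-min = 0.7
gate.tm-min = 0.8
gate.ips-min = 0.8

# synthetic bundles
synth.n-res = 48
synth.pattern = two_domain
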