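# Methods

This note records the models and procedures implemented in `cryofit`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Scope and data model

`cryofit` assesses atomic models (experimental targets and predicted
structures) against cryo-EM data at *residue* granularity.  All analyses
produce a `ResidueTrack` — an ordered map from `(chain, seq_id,
insertion_code)` to a scalar — so local resolution, RMSF, fit scores and
accuracy estimates compose directly.  Missing values are genuinely absent
entries, never zeros: a zero is a meaningful score (e.g. for dSMOC), so
correlations and filters operate on key intersections.

Coordinates are orthogonal Å in the model frame.  Density grids are stored
in canonical `(z, y, x)` array order with the center of voxel `(0,0,0)` at
`origin`; all real↔voxel conversions pass through one pair of functions on
`DensityGrid`.  Maps read from MRC/CCP4 files are normalized from any
on-disk axis permutation; non-orthogonal cells are rejected (cryo-EM maps
are orthogonal in practice).  Hydrogens are ignored by every scoring
operation, since predictions vary in whether they include them.  When a
file carries alternate locations, the alphabetically first altloc of each
atom is used; zero-occupancy atoms are kept.

## Density simulation

SMOC-type scores compare the experimental map with a model-derived map.
Each non-hydrogen atom contributes an isotropic Gaussian with

    sigma = sigma_coeff × resolution,    amplitude ∝ atomic number Z,

truncated at 4 sigma.  `sigma_coeff` defaults to 0.356, the widely used
blurring convention in the Manders-overlap lineage.  Simple Z-weighting
stands in for full scattering factors; for an overlap *correlation* this
is adequate, since the score is invariant to global scaling.  There is no
B-factor-dependent blurring.  The simulated-map resolution for fit scoring
defaults to 4 Å (a typical mid-resolution reconstruction) and should be
set to the map's reported global resolution in real use.

## Local resolution

Local resolution is estimated from two *unfiltered* half-maps by windowed
Fourier shell correlation:

1. On a lattice with `step`-voxel spacing (default 4), a soft spherical
   window is applied to both half-maps around each lattice point.
2. The FSC between the windowed volumes is computed in equal-width
   frequency shells up to the Nyquist frequency;
   `FSC(s) = Re Σ F1·F2* / sqrt(Σ|F1|² Σ|F2|²)`.
3. The resolution at that point is the reciprocal of the first downward
   crossing of the threshold (0.5 by default, the local-resolution
   convention; 0.143 is available for global reporting), linearly
   interpolated between shells.  Curves that never drop below the
   threshold report the Nyquist resolution; curves that never reach it
   report the worst bound.
4. Lattice values are interpolated trilinearly to every voxel and clamped
   to `[2 × voxel, 2 × window_radius]`.

**Window choice.**  The windowed spectrum is the true spectrum convolved
with the mask transform, so a window that is small or sharp-edged smears
the band edge of the signal outward and reports optimistically fine
values.  Measured on the synthetic generator (band-limited 8 Å signal,
SNR 1), a flat-topped 10 Å window biased the recovered median to ~4.7 Å,
while a full-taper raised-cosine (Hann) window of radius 16 × voxel
recovers 6.3–6.4 Å — within the ±25% contract of this estimator.  The
defaults are therefore a full-taper spherical window of radius 16 × the
voxel size; both the radius and the edge fraction are parameters.  A
phase-randomization correction in the style of masked global-FSC
post-processing was evaluated and rejected: the residual bias comes from
in-band signal leakage, which phase randomization beyond the
mask-smearing band cannot remove.  The estimator's contract is rank-order
correctness and ±25% absolute recovery, not bit-identity with any
particular reconstruction package; externally computed local-resolution
maps (e.g. Relion output) are accepted interchangeably by every
downstream step.

**Projection.**  Local resolution is projected onto a model by nearest
voxel (midpoint ties break toward the lower index): per atom for the mean
local resolution (the unweighted all-atom mean, i.e. an average over the
region the model occupies, not over the whole map), and per residue at
the representative atom — Cα for amino acids, C4′ for nucleotides — so
that RMSF and local resolution sample the same point.  Atoms outside the
grid are missing, not errors.

## SMOC and fragment-aligned dSMOC

**SMOC.**  The model is blurred once onto the experimental grid.  For each
sliding window of `window` residues (default 11) along a chain, the
Manders overlap coefficient

    MOC(a, b) = Σ aᵢbᵢ / sqrt(Σ aᵢ² · Σ bᵢ²)

is evaluated between experimental and simulated values over the window's
voxel footprint — all voxels within `radius` (default 2.5 Å) of any
window atom — and assigned to the central residue.  Windows shrink at
chain ends (minimum half a window) so every residue is scored; chains
shorter than half a window are skipped with a warning.  An all-zero
footprint yields a missing value.

**dSMOC.**  A locally well-modeled fragment can fit poorly in place
because of a domain-level placement error.  dSMOC removes global pose
from the comparison: for each prediction window with at least half its
residues matched in the target,

1. the fragment is rigidly superposed (Kabsch) onto the corresponding
   target residues using matched backbone atoms (protein N/Cα/C/O;
   nucleic P/O5′/C5′/C4′/C3′/O3′; representative-atom fallback below
   3 matches),
2. the SMOC of the transformed fragment and of the corresponding target
   residues are computed, each fragment simulated *in isolation* over its
   own footprint, and
3. `dSMOC = fragment SMOC − target SMOC` is assigned to the central
   residue.

Positive values mean the prediction explains the local density better
than the target.  The score is invariant to any global rigid transform of
the prediction, and is identically zero when prediction and target
coincide (identical windows short-circuit the superposition so the zero
is exact).  Simulating fragments in isolation ignores density occlusion
by neighbouring residues; this keeps the two terms of the difference
strictly comparable and is the documented choice.

**Backbone/sidechain variant.**  For maps resolved well enough to show
sidechains, 5-residue fragments are used and the overlap footprint is
restricted to the central residue's backbone atoms (N, Cα, C, O; Cβ
counts as sidechain) or its sidechain atoms, giving separate backbone and
sidechain dSMOC tracks.  Glycine has no sidechain entry.  Residues with
local resolution worse than a cutoff (default 2.5 Å) can be excluded with
`exclude_by_locres` before aggregating such high-resolution analyses.

**Residue correspondence.**  Author numbering is trusted when prediction
and target share keys (the CASP convention).  Chains with disjoint
numbering are paired by global sequence alignment with identity scoring
and affine gaps.

## Ensemble flexibility and accuracy gating

For a 5-model submission, models 2–5 are superposed onto model 1 by
least squares over the shared representative atoms, and the per-residue
RMSF is

    RMSF_i = sqrt( (1/m) Σ_m |r_m − r̄|² ),

the population-form fluctuation of the representative atom about the
ensemble mean (m = number of models; residues absent from any model are
missing).  Aligning onto model 1 rather than the target preserves the
convention that the ensemble's internal spread, not its accuracy, is
being measured.  Note that fitting a rigid transform absorbs roughly
`6/(3N)` of the displacement variance for N shared residues; closed-form
checks of the generator are therefore run in the generator's common
frame.

Groups enter the flexibility analysis only if **all** models pass a
strict accuracy gate: lDDT > 0.7 and TM-score > 0.8, plus interface
similarity > 0.8 for multimers.  Equality fails.  The scores:

* **lDDT** — over all heavy-atom pairs of the reference from different
  residues within 15 Å, the fraction whose model distance matches within
  t, averaged over t ∈ {0.5, 1, 2, 4} Å; each pair contributes to both of
  its residues' per-residue scores.  No stereochemistry penalty.
* **TM-score** — `(1/L_ref) Σ 1/(1 + (dᵢ/d₀)²)` with
  `d₀ = max(0.5, 1.24 (L_ref − 15)^{1/3} − 1.8)`, maximized by iterative
  superposition with a distance-cutoff inlier refinement (max 20
  iterations).  Correspondence is sequence-dependent — the gate operates
  on same-sequence predictions, so no structural alignment search is
  needed.
* **IPS** — the Jaccard index of inter-chain residue contact sets at a
  5 Å heavy-atom cutoff.  No community-standard formula exists for this
  quantity; contact-set Jaccard is the package's documented choice.

The headline analysis correlates RMSF with projected local resolution
(signed Pearson, key intersection, n reported; undefined below 3 shared
residues or at zero variance).

## Local accuracy estimates

Per-residue accuracy estimates are read from the B-factor column at the
representative atom.  The scale is auto-detected from the value range —
≤ 1.001: unit pLDDT-like score; ≤ 100.5: percent, converted to unit;
larger: positional error in Å, direction lower-is-better — and can be
overridden.  Because conventions differ in direction, the correlation
against local resolution is reported as |Pearson r|.  A model with an
all-zero B-field raises a distinguishable "absent" condition (RNA
predictions often omit estimates) that pipelines must report as
not-assessable, never as zero.

## Synthetic generators

The generators produce complete, seed-deterministic test cases so every
analysis runs without experimental downloads.

* `make_polymer` — poly-alanine (N, Cα, C, O, Cβ) on ideal α-helix
  geometry (rise 1.5 Å, 100°/residue, radius chosen so consecutive
  Cα–Cα = 3.8 Å) or a seeded self-avoiding coil.
* `make_ensemble` — each model displaces every residue rigidly by a
  zero-mean Gaussian vector with per-residue scale σᵢ from a
  `FlexProfile` (constant, linear gradient, or two-domain).  Residue-rigid
  displacement keeps fragment superposition meaningful at small
  amplitudes and gives the closed form `E[RMSF²] = 3σ²(m−1)/m`.
* `make_halfmaps` — the target is blurred at a base resolution, space is
  partitioned by nearest residue, and each zone is low-passed at its
  entry of a per-residue resolution pattern; zones are blended with
  soft-edged masks (Gaussian-smoothed indicators, ~3-voxel edge) to avoid
  ringing.  Independent white Gaussian noise with standard deviation
  `noise_sigma × RMS(signal)` is added to each half, so `noise_sigma = 1`
  is an SNR≈1 condition; under it, the *global* FSC of a uniform-8 Å pair
  crosses 0.5 at 8.0 Å, anchoring the generator's ground truth.
* `make_local_error` — constructed local discrepancies: `loop_shift`
  displaces whole residues of a region along a smooth bump (≈0 at the
  region edges, peak amplitude at the center); `sidechain_flip` moves
  only sidechain atoms.  These drive the dSMOC discrepancy-detection
  tests: a pristine prediction scored against a loop-shifted reference
  goes positive exactly where the reference is wrong, and a flipped
  sidechain registers on the sidechain track while the backbone track
  stays within ±0.02 of zero.
* `make_bundle` — the standard end-to-end case: a 48-residue helix, a
  flexibility profile, half-maps whose resolution pattern follows the
  profile linearly (4 Å for rigid up to 10 Å for the most mobile), and
  optionally a seeded permutation of the profile for the ensemble while
  the maps keep the original spatial pattern (the matched/shuffled
  contrast).  Grid geometry derives from the model bounding box plus
  14 Å padding at 1 Å voxels (≈100 voxels along the helix axis), sized so
  analyses finish in seconds on one CPU.

**What the generators do not emulate:** electron-optics noise (CTF,
beam-induced motion), solvent background, B-factor variation, realistic
secondary-structure diversity, or correlated conformational modes.
Passing tests therefore demonstrate the *estimators'* correctness and the
internal consistency of the pipeline — recovery of known patterns,
oracle equivalence, invariances — not performance on experimental maps.

## Numerical choices

* Nearest-voxel ties break toward the lower index on each axis.
* FSC shells are equal-width up to the Nyquist of the coarsest axis;
  zero-power shells are missing (NaN), never zero.
* The low-pass filter uses a raised-cosine amplitude edge over the band
  `[(1−w)/R, 1/R]` (default w = 0.1) and preserves the DC component
  exactly; `w = 0` is an ideal projection and exactly idempotent.
* Kabsch superposition enforces a proper rotation (det = +1) via the SVD
  sign correction and rejects point sets with a rank-deficient covariance
  (collinear inputs).
* Problem sizes in the test-suite simulations (48-residue bundles, 20-seed
  recovery loops, 500-seed fluctuation statistics) were chosen so each
  statistical check is stable at its stated tolerance while the whole
  suite runs in minutes.

## Known limitations

* The windowed-FSC estimator retains a fine-ward bias of up to ~20% for
  features near half the window radius; rank order across regions is
  much more robust than absolute values.
* dSMOC fragments are simulated without neighbouring density context, so
  absolute fragment SMOC values are not comparable to whole-model SMOC
  values (their *difference* is the designed quantity).
* TM-score assumes same-sequence correspondence; it is not a structural
  aligner.
* The IPS definition (contact Jaccard) is one reasonable choice among
  several used by assessors.
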