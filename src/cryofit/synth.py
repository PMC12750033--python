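"""Synthetic structures, ensembles and half-map pairs with known ground
truth, so every analysis in the package can be exercised without any
experimental download.

The generators emulate the study conditions of an ensemble-vs-map
assessment: a toy polymer target, a 5-model prediction ensemble whose
per-residue fluctuation follows a chosen flexibility profile, and a pair
of half-maps whose spatially varying resolution follows the same profile
(flexible regions are blurred and noisier, as in a real reconstruction
averaged over conformations).  Everything is a pure function of its
inputs and the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .core import Atom, AtomicModel, DensityGrid, Residue, ResidueTrack
from .ensemble import PredictionSet
from .mapsim import SimulationParams, lowpass_filter, simulate_density

__all__ = [
    "FlexProfile",
    "SynthBundle",
    "make_polymer",
    "make_ensemble",
    "make_halfmaps",
    "make_local_error",
    "make_bundle",
]

# ideal alpha-helix: rise 1.5 Å and 100 deg per residue; the radius below
# makes consecutive Ca-Ca distances come out at 3.8 Å
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.279


@dataclass
class FlexProfile:
    """Per-residue displacement scales (Å) with a named spatial pattern."""

    sigmas: np.ndarray
    pattern: str = "constant"  # constant | linear_gradient | two_domain

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(self.sigmas < 0):
            raise ValueError("FlexProfile sigmas must be non-negative")

    @classmethod
    def constant(cls, n_res: int, sigma: float = 0.5) -> "FlexProfile":
        return cls(np.full(n_res, sigma), "constant")

    @classmethod
    def linear_gradient(
        cls, n_res: int, sigma_min: float = 0.2, sigma_max: float = 1.5
    ) -> "FlexProfile":
        return cls(np.linspace(sigma_min, sigma_max, n_res), "linear_gradient")

    @classmethod
    def two_domain(
        cls, n_res: int, sigma_rigid: float = 0.25, sigma_mobile: float = 1.25
    ) -> "FlexProfile":
        s = np.full(n_res, sigma_rigid)
        s[n_res // 2 :] = sigma_mobile
        return cls(s, "two_domain")


@dataclass
class SynthBundle:
    """A complete synthetic test case: target, ensemble, half-maps and the
    ground-truth per-residue resolution pattern that generated them."""

    target: AtomicModel
    ensemble: PredictionSet
    half1: DensityGrid
    half2: DensityGrid
    true_locres_pattern: ResidueTrack
    profile: FlexProfile
    seed: int


def _make_residue(chain_id: str, seq_id: int, ca: np.ndarray, prev_dir: np.ndarray,
                  next_dir: np.ndarray, outward: np.ndarray) -> Residue:
    """Poly-alanine residue (N, CA, C, O, CB) built around a Ca position."""
    n_pos = ca + 1.46 * prev_dir
    c_pos = ca + 1.52 * next_dir
    o_pos = c_pos + 1.23 * outward
    cb_pos = ca + 1.53 * outward
    atoms = [
        Atom("N", "N", n_pos),
        Atom("CA", "C", ca),
        Atom("C", "C", c_pos),
        Atom("O", "O", o_pos),
        Atom("CB", "C", cb_pos),
    ]
    return Residue(chain_id, seq_id, "", "ALA", atoms, kind="amino")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def make_polymer(n_res: int, kind: str = "helix", seed: int = 0,
                 chain_id: str = "A") -> AtomicModel:
    """A poly-alanine backbone on ideal helix geometry or a seeded
    self-avoiding coil.  Residues numbered from 1."""
    if n_res < 5:
        raise ValueError("make_polymer: need at least 5 residues")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        omega = np.deg2rad(HELIX_TWIST_DEG)
        t = np.arange(n_res)
        ca = np.stack(
            [
                HELIX_RADIUS * np.cos(omega * t),
                HELIX_RADIUS * np.sin(omega * t),
                HELIX_RISE * t,
            ],
            axis=1,
        )
    elif kind == "coil":
        ca = [np.zeros(3)]
        direction = _unit(rng.normal(size=3))
        for _ in range(n_res - 1):
            for _attempt in range(200):
                step = _unit(direction + 0.8 * rng.normal(size=3))
                cand = ca[-1] + 3.8 * step
                dists = np.linalg.norm(np.array(ca[:-1]) - cand, axis=1) if len(ca) > 1 else [99]
                if np.min(dists) > 4.0:
                    break
            ca.append(cand)
            direction = step
        ca = np.array(ca)
    else:
        raise ValueError(f"unknown polymer kind {kind!r}")

    residues = []
    for i in range(n_res):
        prev_dir = _unit(ca[i - 1] - ca[i]) if i > 0 else _unit(ca[i] - ca[i + 1])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < n_res - 1 else _unit(ca[i] - ca[i - 1])
        if kind == "helix":
            outward = _unit(np.array([ca[i][0], ca[i][1], 0.0]))
        else:
            outward = _unit(np.cross(prev_dir, next_dir))
            if np.linalg.norm(np.cross(prev_dir, next_dir)) < 1e-6:
                outward = _unit(np.cross(prev_dir, np.array([0.0, 0.0, 1.0])))
        residues.append(_make_residue(chain_id, i + 1, ca[i], prev_dir, next_dir, outward))
    model = AtomicModel(f"polymer-{kind}-{n_res}", {chain_id: residues})
    model.provenance = "target"
    return model


def make_ensemble(
    target: AtomicModel,
    profile: FlexProfile,
    n_models: int = 5,
    seed: int = 0,
    group_id: str = "synthetic",
) -> PredictionSet:
    """An ensemble of perturbed copies of the target.

    Each model displaces every residue rigidly (all atoms together) by a
    zero-mean Gaussian vector with per-coordinate standard deviation
    sigma_i from the profile — residue-rigid so that fragment superposition
    stays meaningful at small amplitudes.
    """
    if n_models < 2:
        raise ValueError("make_ensemble: need at least 2 models")
    residues = list(target.residues())
    if len(profile.sigmas) != len(residues):
        raise ValueError("profile length must match the number of residues")
    rng = np.random.default_rng(seed)
    models = []
    for m in range(n_models):
        copy = target.copy(model_id=f"{group_id}-m{m + 1}")
        copy.provenance = "prediction"
        for res, sigma in zip(copy.residues(), profile.sigmas):
            shift = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
            for a in res.atoms:
                a.position = a.position + shift
        models.append(copy)
    return PredictionSet(group_id, models, target_id=target.model_id)


def _blend_resolution_zones(
    signal: DensityGrid,
    per_voxel_res: np.ndarray,
    edge_voxels: float = 3.0,
    max_levels: int = 6,
) -> DensityGrid:
    """Impose a spatially varying resolution by blending low-passed copies.

    The per-voxel resolution field is quantized into at most ``max_levels``
    levels; each level's indicator is softened with a Gaussian of
    ``edge_voxels`` voxels (raised-cosine-like edge) and used to mix the
    full-grid low-pass at that level's resolution.
    """
    levels = np.unique(np.round(per_voxel_res, 3))
    if len(levels) > max_levels:
        qs = np.linspace(0, 100, max_levels + 1)
        edges = np.percentile(per_voxel_res, qs)
        centers = 0.5 * (edges[:-1] + edges[1:])
        idx = np.clip(np.searchsorted(edges[1:-1], per_voxel_res), 0, max_levels - 1)
        per_voxel_res = centers[idx]
        levels = np.unique(np.round(centers, 3))
    blended = np.zeros_like(signal.data)
    wsum = np.zeros_like(signal.data)
    for level in levels:
        mask = (np.abs(per_voxel_res - level) < 1e-6).astype(float)
        soft = gaussian_filter(mask, sigma=edge_voxels / 2.0)
        lp = lowpass_filter(signal, float(level))
        blended += soft * lp.data
        wsum += soft
    wsum[wsum == 0] = 1.0
    return signal.like(blended / wsum)


def make_halfmaps(
    target: AtomicModel,
    base_resolution: float,
    locres_pattern: np.ndarray,
    noise_sigma: float = 1.0,
    voxel_size: float = 1.0,
    seed: int = 0,
    padding: float = 14.0,
    sigma_coeff: float = 0.356,
) -> tuple[DensityGrid, DensityGrid]:
    """A pair of half-maps sharing a signal with known local resolution.

    The target is blurred at ``base_resolution``; space is partitioned by
    the nearest residue and each zone low-passed at that residue's entry in
    ``locres_pattern`` (soft-edged blending avoids ringing across zone
    boundaries).  Independent white Gaussian noise of standard deviation
    ``noise_sigma`` x RMS(signal) is then added to each half — the halves
    share signal and differ only in noise, as real half-maps do.
    """
    residues = list(target.residues())
    locres_pattern = np.asarray(locres_pattern, dtype=float)
    if len(locres_pattern) != len(residues):
        raise ValueError("locres_pattern length must match the number of residues")
    if np.any(locres_pattern < 2.0 * voxel_size):
        raise ValueError("locres_pattern is finer than the Nyquist limit of the grid")

    params = SimulationParams(
        resolution=base_resolution, voxel_size=voxel_size, padding=padding,
        sigma_coeff=sigma_coeff,
    )
    signal = simulate_density(target, params)

    # per-voxel target resolution from the nearest residue
    anchors = np.array(
        [
            (r.representative_atom.position if r.representative_atom is not None
             else np.mean([a.position for a in r.atoms], axis=0))
            for r in residues
        ]
    )
    tree = cKDTree(anchors)
    nz, ny, nx = signal.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    centers = signal.index_to_position(np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1))
    _, nearest = tree.query(centers)
    per_voxel_res = np.maximum(locres_pattern[nearest].reshape(nz, ny, nx), base_resolution)

    blended = _blend_resolution_zones(signal, per_voxel_res)
    rms = float(np.sqrt(np.mean(blended.data**2)))
    rng = np.random.default_rng(seed)
    noise_std = noise_sigma * rms
    h1 = blended.like(blended.data + rng.normal(0.0, noise_std, blended.shape))
    h2 = blended.like(blended.data + rng.normal(0.0, noise_std, blended.shape))
    h1.label = h2.label = "map"
    return h1, h2


def make_local_error(
    target: AtomicModel,
    region: tuple[int, int],
    mode: str = "loop_shift",
    amplitude: float = 4.0,
    seed: int = 0,
    chain_id: str | None = None,
) -> AtomicModel:
    """A copy of the target with a constructed local error.

    ``loop_shift`` displaces whole residues of ``region`` (inclusive author
    seq-id range) by a smooth bump of the given peak amplitude, pushing a
    loop out of its density; ``sidechain_flip`` displaces only sidechain
    atoms, leaving the backbone untouched.  The displacement direction is
    drawn from the seed.
    """
    if mode not in ("loop_shift", "sidechain_flip"):
        raise ValueError(f"unknown error mode {mode!r}")
    lo, hi = region
    if hi < lo:
        raise ValueError("region must be (first_seq_id, last_seq_id) with first <= last")
    cid = chain_id or next(iter(target.chains))
    chain = target.chains[cid]
    seq_ids = [r.seq_id for r in chain]
    if lo not in seq_ids or hi not in seq_ids:
        raise ValueError(f"region {region} outside chain {cid!r}")
    n_region = hi - lo + 1
    touches_end = lo == seq_ids[0] or hi == seq_ids[-1]
    if touches_end and n_region < 3:
        raise ValueError("a region at a chain terminus must span at least 3 residues")

    rng = np.random.default_rng(seed)
    direction = _unit(rng.normal(size=3))
    corrupted = target.copy(model_id=f"{target.model_id}-{mode}")
    for res in corrupted.chains[cid]:
        if not (lo <= res.seq_id <= hi):
            continue
        j = res.seq_id - lo
        bump = np.sin(np.pi * (j + 1) / (n_region + 1))  # smooth, ~0 at region edges
        shift = amplitude * bump * direction
        atoms = res.atoms if mode == "loop_shift" else res.sidechain_atoms()
        for a in atoms:
            a.position = a.position + shift
    return corrupted


def make_bundle(
    n_res: int = 48,
    pattern: str = "two_domain",
    n_models: int = 5,
    seed: int = 0,
    voxel_size: float = 1.0,
    base_resolution: float = 4.0,
    noise_sigma: float = 1.0,
    shuffle_profile: bool = False,
) -> SynthBundle:
    """The standard end-to-end test case.

    A helical target with a flexibility profile of the requested pattern;
    the half-map resolution pattern follows the profile (resolution
    worsens linearly with flexibility, 4 Å for rigid up to 10 Å for the
    most mobile residues).  With ``shuffle_profile`` the ensemble is built
    from a seeded permutation of the profile while the maps keep the
    original spatial pattern — the matched/shuffled contrast behind the
    flexibility-correlation analyses.
    """
    target = make_polymer(n_res, kind="helix", seed=seed)
    if pattern == "two_domain":
        profile = FlexProfile.two_domain(n_res)
    elif pattern == "linear_gradient":
        profile = FlexProfile.linear_gradient(n_res)
    elif pattern == "constant":
        profile = FlexProfile.constant(n_res)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    smax = float(profile.sigmas.max())
    if pattern == "constant":
        locres_pattern = np.full(n_res, 8.0)
    else:
        locres_pattern = 4.0 + 6.0 * profile.sigmas / (smax if smax > 0 else 1.0)

    rng = np.random.default_rng(seed)
    ens_profile = profile
    if shuffle_profile:
        perm = rng.permutation(n_res)
        ens_profile = FlexProfile(profile.sigmas[perm], profile.pattern + "-shuffled")

    ensemble = make_ensemble(target, ens_profile, n_models=n_models, seed=seed + 1)
    half1, half2 = make_halfmaps(
        target, base_resolution, locres_pattern,
        noise_sigma=noise_sigma, voxel_size=voxel_size, seed=seed + 2,
    )
    truth = ResidueTrack(name="true_locres", units="angstrom")
    for res, val in zip(target.residues(), locres_pattern):
        truth[res.key] = float(val)
    return SynthBundle(target, ensemble, half1, half2, truth, ens_profile, seed)
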