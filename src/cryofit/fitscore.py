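"""Local fit-to-density scoring: SMOC sliding windows and the
fragment-aligned dSMOC score.

SMOC (Segment-based Manders' Overlap Coefficient) scores how well each
residue's neighbourhood fits an experimental map: the Manders overlap
between experimental and model-simulated density is computed over the
voxels near a sliding window of residues and assigned to the window's
central residue.

dSMOC decouples local fit from global placement errors: each prediction
fragment (11 residues by default) is least-squares superposed onto the
corresponding target residues before scoring, and the score is the
difference

    dSMOC = SMOC(aligned prediction fragment) - SMOC(target residues).

Positive values mean the prediction's fragment explains the experimental
density better than the target does locally.  A 5-residue variant splits
the central residue's footprint into backbone and sidechain atoms for
high-resolution maps, and residues in regions with local resolution worse
than a cutoff (2.5 Å by default) can be excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Atom, AtomicModel, DensityGrid, Residue, ResidueTrack, ResidueKey
from .ensemble import kabsch_superpose, residue_correspondence
from .mapsim import SimulationParams, simulate_atoms, simulate_density

__all__ = [
    "Fragment",
    "moc",
    "segment_voxels",
    "smoc",
    "delta_smoc",
    "backbone_sidechain_smoc",
    "exclude_by_locres",
    "DEFAULT_SEGMENT_RADIUS",
    "DEFAULT_LOCRES_CUTOFF",
]

DEFAULT_SEGMENT_RADIUS = 2.5  # Å around atoms defining a window's voxel footprint
DEFAULT_LOCRES_CUTOFF = 2.5  # Å; worse-resolved residues excluded from sidechain analyses


@dataclass(frozen=True)
class Fragment:
    """A contiguous window of residues from one chain, scored at its center."""

    residues: tuple[ResidueKey, ...]
    central: ResidueKey
    atom_selection: str = "all"  # all | backbone | sidechain
    length: int = 11

    def __post_init__(self) -> None:
        if self.central not in self.residues:
            raise ValueError("central residue must belong to the fragment")


def moc(values_a: np.ndarray, values_b: np.ndarray) -> float | None:
    """Manders' overlap coefficient: Σab / sqrt(Σa²·Σb²), in [-1, 1].

    Returns ``None`` (missing) when either vector is all-zero — a window
    with no density support has no defined overlap.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("moc: inputs must be equal-length and non-empty")
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return None
    return float(a @ b) / denom


def segment_voxels(grid: DensityGrid, atoms: list[Atom], radius: float) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` Å of any atom.

    Returns a lexicographically sorted, duplicate-free ``(n, 3)`` integer
    array of (z, y, x) indices — the deterministic footprint over which a
    window's overlap is evaluated.  May be empty.
    """
    nz, ny, nx = grid.shape
    vx, vy, vz = grid.voxel_size
    ox, oy, oz = grid.origin
    pieces = []
    r2 = radius * radius
    for atom in atoms:
        if atom.is_hydrogen:
            continue
        px, py, pz = atom.position
        ix0 = max(0, int(np.ceil((px - radius - ox) / vx)))
        ix1 = min(nx - 1, int(np.floor((px + radius - ox) / vx)))
        iy0 = max(0, int(np.ceil((py - radius - oy) / vy)))
        iy1 = min(ny - 1, int(np.floor((py + radius - oy) / vy)))
        iz0 = max(0, int(np.ceil((pz - radius - oz) / vz)))
        iz1 = min(nz - 1, int(np.floor((pz + radius - oz) / vz)))
        if ix0 > ix1 or iy0 > iy1 or iz0 > iz1:
            continue
        zz = oz + np.arange(iz0, iz1 + 1) * vz - pz
        yy = oy + np.arange(iy0, iy1 + 1) * vy - py
        xx = ox + np.arange(ix0, ix1 + 1) * vx - px
        d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        kz, ky, kx = np.nonzero(d2 <= r2)
        if kz.size:
            pieces.append(np.stack([kz + iz0, ky + iy0, kx + ix0], axis=1))
    if not pieces:
        return np.empty((0, 3), dtype=int)
    all_idx = np.concatenate(pieces, axis=0)
    return np.unique(all_idx, axis=0)


def _values_at(grid: DensityGrid, voxels: np.ndarray) -> np.ndarray:
    return grid.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]


def _window_bounds(i: int, n: int, window: int) -> tuple[int, int]:
    """Sliding-window bounds centered at ``i``, truncated at chain ends."""
    h = window // 2
    return max(0, i - h), min(n, i + h + 1)


def _check_window(window: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd number, got {window}")


def smoc(
    model: AtomicModel,
    exp_map: DensityGrid,
    window: int = 11,
    sim: SimulationParams | None = None,
    radius: float = DEFAULT_SEGMENT_RADIUS,
) -> ResidueTrack:
    """Sliding-window SMOC of a model against an experimental map.

    The whole model is blurred once onto the map geometry; each window of
    ``window`` residues per chain is scored as the Manders overlap between
    experimental and simulated values over the window's voxel footprint and
    the score is assigned to the central residue.  Windows shrink at chain
    ends so every residue gets a score; chains shorter than half a window
    are skipped with a warning.
    """
    _check_window(window)
    if sim is None:
        sim = SimulationParams(resolution=4.0)
    sim_map = simulate_density(model, sim, onto=exp_map)
    min_len = (window + 1) // 2
    track = ResidueTrack(name="SMOC", units="score")
    for chain_id, residues in model.chains.items():
        n = len(residues)
        if n < min_len:
            warnings.warn(
                f"smoc: chain {chain_id!r} has {n} residues (< {min_len}); skipped",
                stacklevel=2,
            )
            continue
        for i, res in enumerate(residues):
            lo, hi = _window_bounds(i, n, window)
            atoms = [a for r in residues[lo:hi] for a in r.heavy_atoms()]
            voxels = segment_voxels(exp_map, atoms, radius)
            if voxels.shape[0] == 0:
                continue  # missing, never zero
            score = moc(_values_at(exp_map, voxels), _values_at(sim_map, voxels))
            if score is not None:
                track[res.key] = score
    return track


# ---------------------------------------------------------------------------
# fragment-aligned dSMOC


def _matched_superposition_atoms(
    frag_residues: list[Residue], target_map: dict[ResidueKey, Residue]
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (prediction, target) for fragment
    superposition; falls back to representative atoms when fewer than three
    backbone pairs match."""
    mob, ref = [], []
    for res in frag_residues:
        tres = target_map.get(res.key)
        if tres is None:
            continue
        t_by_name = {a.name: a for a in tres.backbone_atoms()}
        for a in res.backbone_atoms():
            t = t_by_name.get(a.name)
            if t is not None:
                mob.append(a.position)
                ref.append(t.position)
    if len(mob) < 3:
        mob, ref = [], []
        for res in frag_residues:
            tres = target_map.get(res.key)
            if tres is None or res.representative_atom is None:
                continue
            trep = tres.representative_atom
            if trep is not None:
                mob.append(res.representative_atom.position)
                ref.append(trep.position)
    return np.array(mob, dtype=float), np.array(ref, dtype=float)


def _transformed_atoms(atoms: list[Atom], R: np.ndarray, t: np.ndarray) -> list[Atom]:
    return [
        Atom(a.name, a.element, R @ a.position + t, a.occupancy, a.bfield, a.altloc)
        for a in atoms
    ]


def _fragment_score(
    atoms: list[Atom],
    footprint_atoms: list[Atom],
    exp_map: DensityGrid,
    sim: SimulationParams,
    radius: float,
) -> float | None:
    """SMOC of a set of atoms simulated in isolation, evaluated over the
    footprint of ``footprint_atoms``."""
    voxels = segment_voxels(exp_map, footprint_atoms, radius)
    if voxels.shape[0] == 0:
        return None
    sim_grid = simulate_atoms(atoms, sim, exp_map)
    return moc(_values_at(exp_map, voxels), _values_at(sim_grid, voxels))


def _coords_identical(a: list[Atom], b: list[Atom]) -> bool:
    if len(a) != len(b):
        return False
    return all(
        x.name == y.name and np.array_equal(x.position, y.position) for x, y in zip(a, b)
    )


def _delta_smoc_windows(
    prediction: AtomicModel,
    target: AtomicModel,
    exp_map: DensityGrid,
    window: int,
    sim: SimulationParams,
    radius: float,
    footprint: str,
) -> ResidueTrack:
    """Shared engine for dSMOC variants.

    ``footprint`` selects the voxels the overlap is evaluated on:
    ``"window"`` (all fragment atoms), ``"central_backbone"`` or
    ``"central_sidechain"`` (central residue only).
    """
    _check_window(window)
    min_corr = (window + 1) // 2
    corr = residue_correspondence(prediction, target)
    target_map = target.residue_map()
    name = {
        "window": "dSMOC",
        "central_backbone": "backbone_dSMOC",
        "central_sidechain": "sidechain_dSMOC",
    }[footprint]
    track = ResidueTrack(name=name, units="score")

    for chain_id, residues in prediction.chains.items():
        n = len(residues)
        for i, res in enumerate(residues):
            lo, hi = _window_bounds(i, n, window)
            frag = residues[lo:hi]
            matched_keys = [r.key for r in frag if corr.get(r.key) in target_map]
            if len(matched_keys) < min_corr:
                continue
            tgt_res = [target_map[corr[k]] for k in matched_keys]
            frag_matched = [r for r in frag if r.key in set(matched_keys)]

            frag_atoms = [a for r in frag_matched for a in r.heavy_atoms()]
            tgt_atoms = [a for r in tgt_res for a in r.heavy_atoms()]
            if not frag_atoms or not tgt_atoms:
                continue

            # exact-identity fast path: identical coordinates score a literal 0
            if _coords_identical(frag_atoms, tgt_atoms) and footprint == "window":
                track[res.key] = 0.0
                continue

            tgt_by_key = {r.key: target_map[corr[r.key]] for r in frag_matched}
            mob, ref = _matched_superposition_atoms(frag_matched, {
                r.key: tgt_by_key[r.key] for r in frag_matched
            })
            if len(mob) < 3:
                warnings.warn(
                    f"delta_smoc: window at {res.key} has <3 matched atoms; skipped",
                    stacklevel=2,
                )
                continue
            if np.array_equal(mob, ref):
                R, t = np.eye(3), np.zeros(3)
            else:
                R, t, _ = kabsch_superpose(mob, ref)
            moved = _transformed_atoms(frag_atoms, R, t)

            if footprint == "window":
                frag_fp, tgt_fp = moved, tgt_atoms
            else:
                central_moved = _transformed_atoms(
                    (res.backbone_atoms() if footprint == "central_backbone"
                     else res.sidechain_atoms()),
                    R, t,
                )
                tcentral = tgt_by_key.get(res.key)
                if tcentral is None or not central_moved:
                    continue  # e.g. glycine sidechain -> missing
                tgt_fp = (
                    tcentral.backbone_atoms()
                    if footprint == "central_backbone"
                    else tcentral.sidechain_atoms()
                )
                if not tgt_fp:
                    continue
                frag_fp = central_moved

            s_frag = _fragment_score(moved, frag_fp, exp_map, sim, radius)
            s_tgt = _fragment_score(tgt_atoms, tgt_fp, exp_map, sim, radius)
            if s_frag is None or s_tgt is None:
                continue
            track[res.key] = s_frag - s_tgt
    return track


def delta_smoc(
    prediction: AtomicModel,
    target: AtomicModel,
    exp_map: DensityGrid,
    window: int = 11,
    sim: SimulationParams | None = None,
    radius: float = DEFAULT_SEGMENT_RADIUS,
) -> ResidueTrack:
    """Fragment-aligned dSMOC of a prediction against a target and map.

    For every sliding window of the prediction with at least half its
    residues matched in the target: the fragment is rigidly superposed onto
    the corresponding target residues (matched backbone atoms, Kabsch), the
    SMOC of the transformed fragment and of the target residues are computed
    with each set simulated in isolation, and their difference is assigned
    to the central residue.  The score is invariant to any global rigid
    transform of the prediction.
    """
    if sim is None:
        sim = SimulationParams(resolution=4.0)
    return _delta_smoc_windows(prediction, target, exp_map, window, sim, radius, "window")


def backbone_sidechain_smoc(
    prediction: AtomicModel,
    target: AtomicModel,
    exp_map: DensityGrid,
    sim: SimulationParams | None = None,
    radius: float = DEFAULT_SEGMENT_RADIUS,
    window: int = 5,
) -> tuple[ResidueTrack, ResidueTrack]:
    """High-resolution dSMOC variant: 5-residue fragments, with the overlap
    footprint restricted to the central residue's backbone (N/Cα/C/O) or
    sidechain atoms.  Glycines have no sidechain entry.  Returns
    ``(backbone_track, sidechain_track)``.
    """
    if sim is None:
        sim = SimulationParams(resolution=2.5)
    bb = _delta_smoc_windows(
        prediction, target, exp_map, window, sim, radius, "central_backbone"
    )
    sc = _delta_smoc_windows(
        prediction, target, exp_map, window, sim, radius, "central_sidechain"
    )
    return bb, sc


def exclude_by_locres(
    track: ResidueTrack, locres_track: ResidueTrack, cutoff: float = DEFAULT_LOCRES_CUTOFF
) -> ResidueTrack:
    """Retain entries whose local resolution is at least as good as
    ``cutoff`` (value <= cutoff; smaller is better)."""
    out = ResidueTrack(name=track.name, units=track.units)
    for key, value in track.items():
        lr = locres_track.get(key)
        if lr is not None and lr <= cutoff:
            out[key] = value
    if len(out) == 0:
        warnings.warn(
            f"exclude_by_locres: no residue at resolution better than {cutoff} Å",
            stacklevel=2,
        )
    return out
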