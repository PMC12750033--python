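"""Shared domain types: atomic models, density grids, per-residue tracks.

Conventions used throughout the package:

* Coordinates are orthogonal Å in the model frame.
* ``DensityGrid.data`` is indexed ``(z, y, x)`` (canonical axis order);
  ``voxel_size`` and ``origin`` are ``(x, y, z)`` vectors in Å, and the
  *center* of voxel ``(0, 0, 0)`` sits at ``origin``.
* Residues are keyed by ``(chain_id, seq_id, icode)`` — author numbering.
* Hydrogens are ignored by every scoring operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "AtomicModel",
    "DensityGrid",
    "ResidueTrack",
    "FSCCurve",
    "ResidueKey",
]

ResidueKey = tuple[str, int, str]

#: representative atom per residue kind (the per-residue anchor for tracks)
REPRESENTATIVE_ATOM = {"amino": "CA", "nucleic": "C4'"}

#: backbone atom names used for fragment superposition and backbone scoring
PROTEIN_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})
NUCLEIC_BACKBONE = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})


@dataclass
class Atom:
    """A single atom with orthogonal coordinates in Å.

    ``bfield`` carries whatever the source file stored in the B-factor /
    isotropic-displacement column: a crystallographic B for experimental
    models, a confidence estimate (e.g. pLDDT) for predictions.  Its
    interpretation is resolved downstream (see :mod:`cryofit.lae`).
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfield: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            warnings.warn(
                f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]; clamping",
                stacklevel=2,
            )
            self.occupancy = min(1.0, max(0.0, self.occupancy))

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "other"  # amino | nucleic | other

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def representative_atom(self) -> Atom | None:
        """Cα for amino residues, C4′ for nucleic; ``None`` otherwise."""
        want = REPRESENTATIVE_ATOM.get(self.kind)
        return self.get_atom(want) if want else None

    @property
    def usable(self) -> bool:
        """True if the residue can participate in per-residue track analyses."""
        return self.representative_atom is not None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def backbone_atoms(self) -> list[Atom]:
        names = PROTEIN_BACKBONE if self.kind == "amino" else NUCLEIC_BACKBONE
        return [a for a in self.heavy_atoms() if a.name in names]

    def sidechain_atoms(self) -> list[Atom]:
        names = PROTEIN_BACKBONE if self.kind == "amino" else NUCLEIC_BACKBONE
        return [a for a in self.heavy_atoms() if a.name not in names]


@dataclass
class AtomicModel:
    """A hierarchical model: ordered chains of ordered residues.

    ``chains`` maps chain id to its residue list in author order.  Residue
    keys must be unique across the model; duplicates raise at construction.
    """

    model_id: str
    chains: dict[str, list[Residue]]
    provenance: str = "prediction"  # target | prediction

    def __post_init__(self) -> None:
        if not self.chains or not any(self.chains.values()):
            raise ValueError(f"model {self.model_id!r} is empty")
        seen: set[ResidueKey] = set()
        for res in self.residues():
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key} in model {self.model_id!r}")
            seen.add(res.key)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if not a.is_hydrogen]

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues()}

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms()], dtype=float)

    def copy(self, model_id: str | None = None) -> "AtomicModel":
        chains = {
            cid: [
                Residue(
                    r.chain_id,
                    r.seq_id,
                    r.icode,
                    r.res_name,
                    [
                        Atom(a.name, a.element, a.position.copy(), a.occupancy, a.bfield, a.altloc)
                        for a in r.atoms
                    ],
                    r.kind,
                )
                for r in reslist
            ]
            for cid, reslist in self.chains.items()
        }
        return AtomicModel(model_id or self.model_id, chains, self.provenance)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply ``x -> R x + t`` to every atom, in place."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in self.atoms():
            a.position = R @ a.position + t


@dataclass
class DensityGrid:
    """A 3D scalar field on a regular orthogonal grid.

    Used interchangeably for experimental maps, simulated maps and
    local-resolution maps (``label`` records which).
    """

    data: np.ndarray  # (nz, ny, nx)
    voxel_size: np.ndarray  # (x, y, z) Å
    origin: np.ndarray  # (x, y, z) Å, center of voxel (0,0,0)
    label: str = "map"  # map | locres | simulated

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("grid data must be 3-dimensional")
        self.voxel_size = np.broadcast_to(np.asarray(self.voxel_size, float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    # -- the single real<->voxel conversion pair --------------------------

    def position_to_fractional_index(self, position: np.ndarray) -> np.ndarray:
        """Map an (x, y, z) Å position to a fractional (z, y, x) voxel index."""
        p = np.asarray(position, float)
        return ((p - self.origin) / self.voxel_size)[..., ::-1]

    def index_to_position(self, index: np.ndarray) -> np.ndarray:
        """Map a (z, y, x) voxel index to the (x, y, z) Å position of its center."""
        idx = np.asarray(index, float)
        return idx[..., ::-1] * self.voxel_size + self.origin

    def nearest_index(self, position: np.ndarray) -> tuple[int, int, int] | None:
        """Nearest voxel (z, y, x) index, or None when outside the grid.

        Midpoint ties break toward the lower index on each axis.
        """
        frac = self.position_to_fractional_index(position)
        idx = np.ceil(frac - 0.5).astype(int)  # nearest; ties -> lower index
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return None
        return tuple(int(i) for i in idx)

    def nearest_voxel_value(self, position: np.ndarray) -> float | None:
        """Value of the voxel whose center is nearest ``position`` (Å, x/y/z).

        Positions outside the grid return ``None`` (missing), not an error.
        """
        idx = self.nearest_index(position)
        return None if idx is None else float(self.data[idx])

    def like(self, data: np.ndarray, label: str | None = None) -> "DensityGrid":
        """A new grid with the same geometry and new values."""
        return DensityGrid(data, self.voxel_size.copy(), self.origin.copy(), label or self.label)

    def same_geometry(self, other: "DensityGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


class ResidueTrack:
    """An ordered map from residue key to a scalar — the common currency of
    all per-residue analyses (LocRes, RMSF, SMOC, dSMOC, LAE).

    Keys are unique (duplicates raise).  Values are finite floats; a residue
    with no computable value is simply absent, and correlations operate on
    the key intersection of two tracks.
    """

    def __init__(
        self,
        entries: dict[ResidueKey, float] | list[tuple[ResidueKey, float]] | None = None,
        name: str = "",
        units: str = "dimensionless",
    ) -> None:
        self.name = name
        self.units = units
        self.entries: dict[ResidueKey, float] = {}
        if entries:
            items = entries.items() if isinstance(entries, dict) else entries
            for key, value in items:
                self[key] = value

    def __setitem__(self, key: ResidueKey, value: float) -> None:
        if key in self.entries:
            raise ValueError(f"duplicate residue key {key} in track {self.name!r}")
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"non-finite value for residue {key} in track {self.name!r}")
        self.entries[key] = value

    def __getitem__(self, key: ResidueKey) -> float:
        return self.entries[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ResidueKey]:
        return iter(self.entries)

    def get(self, key: ResidueKey, default: float | None = None) -> float | None:
        return self.entries.get(key, default)

    def keys(self) -> list[ResidueKey]:
        return list(self.entries)

    def values(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)

    def items(self) -> Iterator[tuple[ResidueKey, float]]:
        return iter(self.entries.items())

    def shared_keys(self, other: "ResidueTrack") -> list[ResidueKey]:
        return [k for k in self.entries if k in other.entries]

    def aligned_values(self, other: "ResidueTrack") -> tuple[np.ndarray, np.ndarray]:
        keys = self.shared_keys(other)
        a = np.array([self.entries[k] for k in keys], dtype=float)
        b = np.array([other.entries[k] for k in keys], dtype=float)
        return a, b

    def __repr__(self) -> str:
        return f"ResidueTrack(name={self.name!r}, n={len(self)}, units={self.units!r})"


@dataclass
class FSCCurve:
    """Per-shell Fourier shell correlation.

    ``correlations`` may contain NaN for shells with zero power (recorded as
    missing, never dropped — shell indexing stays aligned with frequencies).
    """

    frequencies: np.ndarray  # shell centers, 1/Å, strictly increasing
    correlations: np.ndarray  # FSC per shell in [-1, 1] or NaN
    shell_counts: np.ndarray  # Fourier voxels per shell

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.correlations = np.asarray(self.correlations, float)
        self.shell_counts = np.asarray(self.shell_counts, int)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("FSC shell frequencies must be strictly increasing")
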