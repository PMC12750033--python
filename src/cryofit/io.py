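"""Reading and writing atomic models (PDB/mmCIF) and density maps (MRC/CCP4).

Maps are normalized on read to canonical ``(z, y, x)`` array order whatever
the on-disk MAPC/MAPR/MAPS permutation says, and the origin is taken from
the ORIGIN header words when any is non-zero, otherwise from the start
indices times the voxel size.  Written maps are always canonical-order
MRC 2014 with the ORIGIN words set.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .core import Atom, AtomicModel, DensityGrid, Residue

__all__ = ["read_model", "write_model", "read_map", "write_map"]

# MRC modes holding a single scalar per voxel (2014 dialect)
_SCALAR_MODES = {0, 1, 2, 6, 12}


def _residue_kind(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name)
    if info is not None:
        if info.is_amino_acid():
            return "amino"
        if info.is_nucleic_acid():
            return "nucleic"
    return "other"


def _select_first_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep, for each atom name, the conformer with the alphabetically first
    altloc tag (the empty tag counts as first of all)."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or (atom.altloc or "") < (prev.altloc or ""):
            chosen[atom.name] = atom
    # preserve file order of the surviving atoms
    kept = set(id(a) for a in chosen.values())
    return [a for a in residue if id(a) in kept]


def read_model(path: str, format: str = "auto", model_id: str | None = None) -> AtomicModel:
    """Read an atomic model from PDB or mmCIF.

    Author chain ids and author residue numbering are preserved.  The
    B-factor / isotropic-displacement column populates ``Atom.bfield``.
    When a residue carries alternate locations, the alphabetically first
    altloc of each atom is kept for analysis (``first_altloc_only=True``
    behaviour; all altlocs are never scored together).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
        elif fmt == "auto":
            st = gemmi.read_structure(path)
        else:
            raise ValueError(f"unknown model format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"no models in file {path}")
    gm = st[0]

    chains: dict[str, list[Residue]] = {}
    for chain in gm:
        reslist = chains.setdefault(chain.name, [])
        for gres in chain:
            atoms = []
            for ga in _select_first_altloc(gres):
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=float(ga.occ),
                        bfield=float(ga.b_iso),
                        altloc=ga.altloc or "",
                    )
                )
            reslist.append(
                Residue(
                    chain_id=chain.name,
                    seq_id=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    res_name=gres.name,
                    atoms=atoms,
                    kind=_residue_kind(gres.name),
                )
            )
    if not any(chains.values()):
        raise ValueError(f"model file {path} contains no residues")
    return AtomicModel(model_id or os.path.basename(path), chains)


_KIND_TO_ELEMENT_FALLBACK = {"C": "C", "N": "N", "O": "O", "P": "P", "S": "S"}


def write_model(model: AtomicModel, path: str) -> None:
    """Write a model as PDB (plumbing for the synth generators and CLI)."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for cid, reslist in model.chains.items():
        chain = gemmi.Chain(cid)
        for res in reslist:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.bfield
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            chain.add_residue(gres)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(path)


def read_map(path: str) -> DensityGrid:
    """Read an MRC/CCP4 2014 map into canonical (z, y, x) order.

    The raw file-order array is transposed according to the file's
    axis-correspondence words; data are never wrapped or padded.  Origin
    comes from the ORIGIN header record when non-zero, else from
    NXSTART/NYSTART/NZSTART × voxel size.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"map file not found: {path}")
    try:
        m = gemmi.read_ccp4_map(path)
    except RuntimeError as exc:
        raise ValueError(f"cannot parse map file {path}: {exc}") from exc

    mode = m.header_i32(4)
    if mode not in _SCALAR_MODES:
        raise ValueError(f"unsupported MRC mode {mode} in {path} (not a scalar map)")

    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3 and abs(cell.gamma - 90) < 1e-3
    ):
        raise ValueError(f"non-orthogonal unit cell in {path}: unsupported for cryo-EM maps")

    # sampling intervals along crystallographic x, y, z
    mx, my, mz = (m.header_i32(i) for i in (8, 9, 10))
    if min(mx, my, mz) <= 0:
        raise ValueError(f"invalid grid sampling in {path}")
    voxel = np.array([cell.a / mx, cell.b / my, cell.c / mz], dtype=float)

    # raw array is file order: axes (columns, rows, sections);
    # axis_positions() gives the file-axis position of crystallographic x, y, z
    raw = np.array(m.grid, copy=True)
    ax_pos = list(m.axis_positions())
    data_xyz = np.transpose(raw, axes=ax_pos)  # -> indexed (x, y, z)
    data = np.ascontiguousarray(data_xyz.transpose(2, 1, 0)).astype(float)  # (z, y, x)

    origin_words = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.any(origin_words != 0.0):
        origin = origin_words
    else:
        # start indices are stored per file axis; map them back to x, y, z
        starts_file = [m.header_i32(i) for i in (5, 6, 7)]
        starts_xyz = np.array([starts_file[ax_pos[i]] for i in range(3)], dtype=float)
        origin = starts_xyz * voxel

    if not np.all(np.isfinite(data)):
        raise ValueError(f"map {path} contains non-finite values")
    return DensityGrid(data=data, voxel_size=voxel, origin=origin, label="map")


def write_map(grid: DensityGrid, path: str) -> None:
    """Write a grid as a canonical-order MRC 2014 file.

    Voxel size goes into the cell/grid words, the grid origin into the
    ORIGIN record (start indices written as zero), and the density
    statistics header fields are updated from the data.
    """
    nz, ny, nx = grid.shape
    fg = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(fg, copy=False)
    arr[...] = grid.data.transpose(2, 1, 0).astype(np.float32)  # (x, y, z) file layout
    fg.spacegroup = gemmi.SpaceGroup("P1")
    fg.set_unit_cell(
        gemmi.UnitCell(
            nx * grid.voxel_size[0], ny * grid.voxel_size[1], nz * grid.voxel_size[2], 90, 90, 90
        )
    )
    m = gemmi.Ccp4Map()
    m.grid = fg
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(value))
    try:
        m.write_ccp4_map(path)
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc
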