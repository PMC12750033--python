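"""Prediction-ensemble analysis: superposition, per-residue RMSF,
accuracy gating (lDDT / TM-score / interface similarity) and correlation
of ensemble flexibility with local resolution.

The flexibility analysis follows the CASP convention for 5-model
submissions: models 2-5 are least-squares superposed onto model 1 on the
shared representative atoms (Cα for protein, C4′ for nucleic), the RMSF of
each representative atom across the aligned set is computed, and groups
whose models are not accurate enough (lDDT <= 0.7, TM or interface
similarity <= 0.8) are excluded before correlating RMSF with local
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AtomicModel, DensityGrid, ResidueTrack, ResidueKey

__all__ = [
    "PredictionSet",
    "AccuracyScores",
    "GroupCorrelation",
    "kabsch_superpose",
    "residue_correspondence",
    "align_ensemble",
    "rmsf",
    "lddt",
    "tm_score",
    "ips",
    "gate_group",
    "gate_decision",
    "pearson",
    "rmsf_locres_report",
    "LDDT_GATE",
    "TM_GATE",
    "IPS_GATE",
]

LDDT_GATE = 0.7
TM_GATE = 0.8
IPS_GATE = 0.8
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)  # Å
LDDT_INCLUSION_RADIUS = 15.0  # Å
CONTACT_CUTOFF = 5.0  # Å


@dataclass
class PredictionSet:
    """A group's prediction ensemble for one target (normally 5 models)."""

    group_id: str
    models: list[AtomicModel]
    target_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("PredictionSet needs at least one model")
        if len(self.models) != 5:
            warnings.warn(
                f"group {self.group_id!r}: {len(self.models)} models (expected 5)",
                stacklevel=2,
            )


@dataclass
class AccuracyScores:
    """Accuracy of one model against the reference target."""

    lddt_global: float
    lddt_per_residue: ResidueTrack
    tm: float
    ips: float | None = None  # None for monomers / undefined interfaces


@dataclass
class GroupCorrelation:
    group_id: str
    pcc: float | None
    n_residues: int
    passed_gate: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1) and
    ``t`` such that ``R @ mobile + t`` best fits ``reference``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("kabsch_superpose: need matching (n>=3, 3) coordinate arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise ValueError("kabsch_superpose: degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def residue_correspondence(
    model: AtomicModel, reference: AtomicModel
) -> dict[ResidueKey, ResidueKey]:
    """Map model residue keys to reference residue keys.

    Author numbering is trusted when it matches (the CASP convention:
    predictions use target numbering).  For chains with no key overlap the
    residue sequences are globally aligned (identity scoring, affine gaps)
    and aligned positions are paired.
    """
    ref_keys = set(r.key for r in reference.residues())
    out: dict[ResidueKey, ResidueKey] = {}
    for chain_id, residues in model.chains.items():
        direct = [r.key for r in residues if r.key in ref_keys]
        if direct:
            for k in direct:
                out[k] = k
            continue
        ref_chain = reference.chains.get(chain_id)
        if not ref_chain:
            continue
        out.update(_align_chains(residues, ref_chain))
    return out


def _align_chains(model_res: list, ref_res: list) -> dict[ResidueKey, ResidueKey]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # residue names as the alignment alphabet, one synthetic letter each
    names = sorted({r.res_name for r in model_res} | {r.res_name for r in ref_res})
    code = {n: chr(0x41 + i) for i, n in enumerate(names)}
    s1 = "".join(code[r.res_name] for r in model_res)
    s2 = "".join(code[r.res_name] for r in ref_res)
    aln = aligner.align(s1, s2)[0]
    mapping: dict[ResidueKey, ResidueKey] = {}
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            mapping[model_res[i].key] = ref_res[j].key
    return mapping


def _shared_representative_keys(models: list[AtomicModel]) -> list[ResidueKey]:
    keysets = []
    for m in models:
        keysets.append({r.key for r in m.residues() if r.representative_atom is not None})
    shared = set.intersection(*keysets)
    # preserve the first model's order
    return [r.key for r in models[0].residues() if r.key in shared]


def align_ensemble(pset: PredictionSet) -> PredictionSet:
    """Superpose models 2..n onto model 1 on shared representative atoms.

    Model 1 is untouched; extra residues of other models are carried along
    by the rigid transform.  Returns a new PredictionSet of copies.
    """
    ref = pset.models[0]
    shared = _shared_representative_keys(pset.models)
    if len(shared) < 3:
        raise ValueError("align_ensemble: fewer than 3 shared representative atoms")
    ref_map = ref.residue_map()
    ref_xyz = np.array([ref_map[k].representative_atom.position for k in shared])
    aligned = [ref.copy()]
    for m in pset.models[1:]:
        mmap = m.residue_map()
        mob_xyz = np.array([mmap[k].representative_atom.position for k in shared])
        R, t, _ = kabsch_superpose(mob_xyz, ref_xyz)
        mc = m.copy()
        mc.transform(R, t)
        aligned.append(mc)
    return PredictionSet(pset.group_id, aligned, pset.target_id)


def rmsf(pset: PredictionSet) -> ResidueTrack:
    """Per-residue RMSF of the representative atom across aligned models.

    RMSF_i = sqrt( (1/m) Σ_m |r_m - r̄|² ) — fluctuation about the ensemble
    mean position (population form).  Residues absent (or without a
    representative atom) in any model are missing.
    """
    shared = _shared_representative_keys(pset.models)
    maps = [m.residue_map() for m in pset.models]
    track = ResidueTrack(name="RMSF", units="angstrom")
    for key in shared:
        xyz = np.array([mm[key].representative_atom.position for mm in maps])
        mean = xyz.mean(axis=0)
        track[key] = float(np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=1))))
    return track


# ---------------------------------------------------------------------------
# accuracy scores


def _heavy_atom_table(model: AtomicModel) -> dict[tuple[ResidueKey, str], np.ndarray]:
    table = {}
    for res in model.residues():
        for a in res.heavy_atoms():
            table[(res.key, a.name)] = a.position
    return table


def lddt(
    model: AtomicModel,
    reference: AtomicModel,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    thresholds: tuple[float, ...] = LDDT_THRESHOLDS,
) -> AccuracyScores:
    """Local Distance Difference Test (superposition-free local accuracy).

    All heavy-atom pairs of the *reference* from different residues within
    ``inclusion_radius`` are collected; the score is the fraction of pairs
    whose distance is preserved in the model within tolerance t, averaged
    over t in ``thresholds``.  Each pair contributes to the per-residue
    score of both of its residues.  TM and IPS are not computed here
    (returned as 0/None placeholders).
    """
    corr = residue_correspondence(model, reference)
    model_table = _heavy_atom_table(model)
    inv = {v: k for k, v in corr.items()}

    ref_atoms = []  # (ref_key, name, pos) present in both structures
    for res in reference.residues():
        mk = inv.get(res.key)
        if mk is None:
            continue
        for a in res.heavy_atoms():
            if (mk, a.name) in model_table:
                ref_atoms.append((res.key, mk, a.name, a.position))
    if len(ref_atoms) < 2:
        raise ValueError("lddt: no matched atom pairs")

    pos_ref = np.array([a[3] for a in ref_atoms])
    pos_mod = np.array([model_table[(a[1], a[2])] for a in ref_atoms])
    res_ids = [a[0] for a in ref_atoms]
    uniq = {k: i for i, k in enumerate(dict.fromkeys(res_ids))}
    rid = np.array([uniq[k] for k in res_ids])

    d_ref = np.sqrt(np.sum((pos_ref[:, None, :] - pos_ref[None, :, :]) ** 2, axis=-1))
    d_mod = np.sqrt(np.sum((pos_mod[:, None, :] - pos_mod[None, :, :]) ** 2, axis=-1))
    iu, ju = np.triu_indices(len(ref_atoms), k=1)
    keep = (rid[iu] != rid[ju]) & (d_ref[iu, ju] <= inclusion_radius)
    iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        raise ValueError("lddt: no inter-residue pairs within the inclusion radius")
    diff = np.abs(d_mod[iu, ju] - d_ref[iu, ju])

    frac = np.zeros(iu.size)
    for t in thresholds:
        frac += (diff < t).astype(float)
    frac /= len(thresholds)

    global_score = float(np.mean(frac))
    per_res = ResidueTrack(name="lDDT", units="score")
    rev = {i: k for k, i in uniq.items()}
    for ridx in range(len(uniq)):
        mask = (rid[iu] == ridx) | (rid[ju] == ridx)
        if np.any(mask):
            per_res[rev[ridx]] = float(np.mean(frac[mask]))
    return AccuracyScores(global_score, per_res, tm=0.0, ips=None)


def tm_score(model: AtomicModel, reference: AtomicModel) -> float:
    """TM-score with sequence-dependent correspondence.

    TM = (1/L_ref) Σ 1/(1 + (d_i/d0)²) with d0 = 1.24·(L_ref−15)^{1/3} − 1.8
    (floored at 0.5 Å), maximized by iterative superposition: start from the
    full common set, re-superpose on residues with d_i below the cutoff
    until the inlier set repeats (at most 20 iterations).
    """
    corr = residue_correspondence(model, reference)
    ref_map = reference.residue_map()
    mod_map = model.residue_map()
    ref_reps = [r.key for r in reference.residues() if r.representative_atom is not None]
    L_ref = len(ref_reps)
    pairs = []
    for mk, rk in corr.items():
        mres = mod_map.get(mk)
        rres = ref_map.get(rk)
        if mres is None or rres is None:
            continue
        ma, ra = mres.representative_atom, rres.representative_atom
        if ma is not None and ra is not None:
            pairs.append((ma.position, ra.position))
    if len(pairs) < 15:
        raise ValueError("tm_score: need at least 15 corresponding residues")
    P = np.array([p for p, _ in pairs])
    Q = np.array([q for _, q in pairs])
    d0 = max(0.5, 1.24 * (L_ref - 15) ** (1.0 / 3.0) - 1.8)
    cutoff = max(d0, 4.5)

    inliers = np.ones(len(pairs), dtype=bool)
    best = 0.0
    seen: set[bytes] = set()
    for _ in range(20):
        if inliers.sum() < 3:
            break
        R, t, _ = kabsch_superpose(P[inliers], Q[inliers])
        d = np.sqrt(np.sum((P @ R.T + t - Q) ** 2, axis=1))
        best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_ref))
        new = d < cutoff
        tag = new.tobytes()
        if tag in seen or not new.any():
            break
        seen.add(tag)
        inliers = new
    return best


def _contact_set(model: AtomicModel, cutoff: float) -> set[frozenset]:
    chains = list(model.chains)
    contacts: set[frozenset] = set()
    per_chain = {
        cid: [(r.key, np.array([a.position for a in r.heavy_atoms()])) for r in reslist]
        for cid, reslist in model.chains.items()
    }
    for i, ci in enumerate(chains):
        for cj in chains[i + 1 :]:
            for ki, ai in per_chain[ci]:
                if ai.size == 0:
                    continue
                for kj, aj in per_chain[cj]:
                    if aj.size == 0:
                        continue
                    d2 = np.sum((ai[:, None, :] - aj[None, :, :]) ** 2, axis=-1)
                    if np.any(d2 < cutoff * cutoff):
                        contacts.add(frozenset((ki, kj)))
    return contacts


def ips(
    model: AtomicModel, reference: AtomicModel, contact_cutoff: float = CONTACT_CUTOFF
) -> float | None:
    """Interface similarity: Jaccard index of inter-chain residue contact
    sets (heavy-atom distance < cutoff), with model residues mapped onto
    reference numbering.  ``None`` when the reference has no inter-chain
    contacts."""
    if len(model.chains) < 2 or len(reference.chains) < 2:
        raise ValueError("ips: both structures must have at least 2 chains")
    ref_contacts = _contact_set(reference, contact_cutoff)
    if not ref_contacts:
        return None
    corr = residue_correspondence(model, reference)
    mod_contacts_raw = _contact_set(model, contact_cutoff)
    mod_contacts = set()
    for pair in mod_contacts_raw:
        mapped = frozenset(corr.get(k, k) for k in pair)
        if len(mapped) == 2:
            mod_contacts.add(mapped)
    union = ref_contacts | mod_contacts
    inter = ref_contacts & mod_contacts
    return len(inter) / len(union)


def gate_decision(
    scores: list[AccuracyScores],
    lddt_min: float = LDDT_GATE,
    tm_min: float = TM_GATE,
    ips_min: float = IPS_GATE,
    is_multimer: bool = False,
) -> bool:
    """Strict-inequality gate: every model must have lDDT > lddt_min and
    TM > tm_min and, for multimers, IPS > ips_min.  A model exactly at a
    threshold fails; IPS is ignored for monomers."""
    for sc in scores:
        if not (sc.lddt_global > lddt_min and sc.tm > tm_min):
            return False
        if is_multimer and sc.ips is not None and not (sc.ips > ips_min):
            return False
    return True


def gate_group(
    pset: PredictionSet,
    target: AtomicModel,
    lddt_min: float = LDDT_GATE,
    tm_min: float = TM_GATE,
    ips_min: float = IPS_GATE,
    is_multimer: bool | None = None,
) -> tuple[bool, list[AccuracyScores]]:
    """Score every model of a group against the target and apply the
    strict accuracy gate (see :func:`gate_decision`)."""
    if is_multimer is None:
        is_multimer = len(target.chains) > 1
    scores = []
    for m in pset.models:
        sc = lddt(m, target)
        sc.tm = tm_score(m, target)
        if is_multimer:
            sc.ips = ips(m, target)
        scores.append(sc)
    return gate_decision(scores, lddt_min, tm_min, ips_min, is_multimer), scores


# ---------------------------------------------------------------------------
# correlation


def pearson(
    a: ResidueTrack, b: ResidueTrack, absolute: bool = False
) -> tuple[float | None, int]:
    """Sample Pearson correlation over the key intersection of two tracks.

    Returns ``(r, n)``; ``r`` is ``None`` with fewer than 3 shared residues
    or when either side has zero variance.
    """
    va, vb = a.aligned_values(b)
    n = len(va)
    if n < 3:
        return None, n
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return None, n
    r = float(stats.pearsonr(va, vb).statistic)
    return (abs(r) if absolute else r), n


def rmsf_locres_report(
    psets: list[PredictionSet],
    target: AtomicModel,
    locres_grid: DensityGrid,
    lddt_min: float = LDDT_GATE,
    tm_min: float = TM_GATE,
    ips_min: float = IPS_GATE,
    is_multimer: bool | None = None,
    apply_gate: bool = True,
) -> pd.DataFrame:
    """Per-group correlation between ensemble RMSF and local resolution.

    Each group is gated on accuracy, its ensemble aligned, the RMSF
    computed, the local-resolution grid projected onto the target per
    residue, and the signed Pearson correlation taken over the shared
    residues.  Rows are sorted by correlation, gated-out groups last with
    no correlation reported.
    """
    from .locres import project_locres

    locres_track = project_locres(locres_grid, target, per="residue")
    rows = []
    for pset in psets:
        if apply_gate:
            passed, scores = gate_group(pset, target, lddt_min, tm_min, ips_min, is_multimer)
        else:
            passed, scores = True, []
        if not passed:
            rows.append(
                {
                    "group": pset.group_id,
                    "n": 0,
                    "passed": False,
                    "pcc": np.nan,
                    "reason": "failed accuracy gate",
                }
            )
            continue
        aligned = align_ensemble(pset)
        flex = rmsf(aligned)
        r, n = pearson(flex, locres_track, absolute=False)
        rows.append(
            {
                "group": pset.group_id,
                "n": n,
                "passed": True,
                "pcc": np.nan if r is None else r,
                "reason": "" if r is not None else "undefined correlation (n<3 or zero variance)",
            }
        )
    df = pd.DataFrame(rows, columns=["group", "n", "passed", "pcc", "reason"])
    return df.sort_values(["passed", "pcc"], ascending=[False, False], na_position="last").reset_index(
        drop=True
    )
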