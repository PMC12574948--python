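"""Superposition and RMSD: whole/region TCR RMSD and interface RMSD.

Superposition uses the Kabsch algorithm (SVD with a reflection guard, so the
result is always a proper rotation).  Residue correspondence between two
TCRs is by IMGT number, which makes region selections (e.g. align on the
frameworks, measure over CDR3) well-defined across structures with
different author numbering; MHC and peptide chains correspond by global
sequence alignment.  Interface RMSD follows the CAPRI convention: interface
residues are those of either binding partner with any heavy atom within a
cutoff (default 10 A) of the other partner *in the reference structure*,
and the RMSD is taken over their backbone atoms (N, CA, C, O) after
superposing the pose onto the reference on those same atoms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._align import align_pair
from .annotation import number_domain, region_of, REGIONS
from .errors import CorrespondenceError, InterfaceError
from .model import Chain, Residue, TCRComplex

BACKBONE = ("N", "CA", "C", "O")
DEFAULT_INTERFACE_CUTOFF = 10.0


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float              # Angstrom
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(coordsA: np.ndarray, coordsB: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of B onto A.

    Returns rotation R and translation t with  a ~ R b + t  minimizing the
    RMSD.  det(R) = +1 always (reflections are excluded); collinear inputs
    still yield the optimal proper rotation.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate arrays must both be Nx3, got "
                         f"{A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atoms to superpose, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    resid = A - (B @ R.T + t)
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


# ----------------------------------------------------- TCR-to-TCR RMSD

def _ensure_numbered(chain: Chain) -> None:
    if any(r.imgt is None for r in chain.standard_residues):
        number_domain(chain)


def _residue_atoms(resA: Residue, resB: Residue, atoms: str) -> list[str]:
    if atoms == "CA":
        names = ["CA"]
    elif atoms == "backbone":
        names = list(BACKBONE)
    elif atoms == "all":
        inA = {a.name for a in resA.atoms}
        names = sorted(n for n in inA if resB.atom(n) is not None)
    else:
        raise ValueError(f"unknown atom selection {atoms!r}")
    return [n for n in names
            if resA.atom(n) is not None and resB.atom(n) is not None]


def _region_correspondence(chainA: Chain, chainB: Chain,
                           region_set: set[str], atoms: str
                           ) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """IMGT-matched atom pairs over a region selection; returns coordinate
    lists plus the number of residues skipped for missing counterparts."""
    _ensure_numbered(chainA)
    _ensure_numbered(chainB)
    ptsA, ptsB, skipped = [], [], 0
    byB = {r.imgt: r for r in chainB.standard_residues if r.imgt}
    for resA in chainA.standard_residues:
        if not resA.imgt or region_of(resA.imgt) not in region_set:
            continue
        resB = byB.get(resA.imgt)
        if resB is None:
            skipped += 1
            continue
        names = _residue_atoms(resA, resB, atoms)
        if not names:
            skipped += 1
            continue
        for nm in names:
            ptsA.append(resA.atom(nm).coords)
            ptsB.append(resB.atom(nm).coords)
    return ptsA, ptsB, skipped


def tcr_rmsd(tcrA: TCRComplex, tcrB: TCRComplex,
             align_on: set[str] | list[str] = ("FR1", "FR2", "FR3", "FR4"),
             measure_on: set[str] | list[str] = REGIONS,
             atoms: str = "CA",
             return_details: bool = False):
    """RMSD between two TCRs: superpose on ``align_on`` regions, measure
    over ``measure_on`` regions without refitting.

    Residues correspond by IMGT number across both chains; positions missing
    from either side are skipped and counted in the coverage report
    (``return_details=True`` returns a dict with rmsd, atom and skip counts).
    """
    align_set, measure_set = set(align_on), set(measure_on)
    aA, aB, skipped_a = [], [], 0
    mA, mB, skipped_m = [], [], 0
    for cA, cB in ((tcrA.alpha_like, tcrB.alpha_like),
                   (tcrA.beta_like, tcrB.beta_like)):
        x, y, s = _region_correspondence(cA, cB, align_set, atoms)
        aA += x; aB += y; skipped_a += s
        x, y, s = _region_correspondence(cA, cB, measure_set, atoms)
        mA += x; mB += y; skipped_m += s
    if len(aA) < 3 or not mA:
        raise CorrespondenceError(
            f"correspondence too small: {len(aA)} alignment atoms, "
            f"{len(mA)} measurement atoms")
    sup = kabsch(np.vstack(aA), np.vstack(aB))
    moved = sup.apply(np.vstack(mB))
    resid = np.vstack(mA) - moved
    value = float(np.sqrt((resid ** 2).sum() / len(mA)))
    if return_details:
        return {"rmsd": value, "n_align_atoms": len(aA),
                "n_measure_atoms": len(mA),
                "skipped_align": skipped_a, "skipped_measure": skipped_m}
    return value


# ------------------------------------------------------- interface RMSD

def _heavy_coords(res: Residue) -> np.ndarray:
    pts = [a.coords for a in res.atoms if a.element.upper() != "H"]
    return np.vstack(pts) if pts else np.empty((0, 3))


def _interface_residues(complex: TCRComplex, cutoff: float
                        ) -> list[tuple[Chain, Residue]]:
    """Residues of either partner with any heavy atom within ``cutoff`` of
    the other partner (TCR side vs antigen side)."""
    tcr_side = [complex.alpha_like, complex.beta_like]
    ag_side = complex.antigen_chains
    if not ag_side:
        raise InterfaceError("complex has no antigen chains")

    def flat(chains):
        entries, pts = [], []
        for ch in chains:
            for r in ch.standard_residues:
                xyz = _heavy_coords(r)
                if xyz.shape[0]:
                    entries.append((ch, r, xyz.shape[0]))
                    pts.append(xyz)
        return entries, (np.vstack(pts) if pts else np.empty((0, 3)))

    t_entries, t_pts = flat(tcr_side)
    a_entries, a_pts = flat(ag_side)
    if not t_pts.shape[0] or not a_pts.shape[0]:
        raise InterfaceError("missing heavy atoms on one side of the interface")
    t_tree, a_tree = cKDTree(t_pts), cKDTree(a_pts)

    out = []
    for entries, tree in ((t_entries, a_tree), (a_entries, t_tree)):
        for ch, r, _n in entries:
            d, _ = tree.query(_heavy_coords(r), k=1)
            if float(np.min(d)) <= cutoff:
                out.append((ch, r))
    return out


def _match_chain(reference: TCRComplex, pose: TCRComplex, ref_chain: Chain
                 ) -> Chain:
    if ref_chain is reference.alpha_like:
        return pose.alpha_like
    if ref_chain is reference.beta_like:
        return pose.beta_like
    if ref_chain is reference.peptide and pose.peptide is not None:
        return pose.peptide
    for ch in pose.mhc_chains:
        if ch.chain_type == ref_chain.chain_type:
            return ch
    raise CorrespondenceError(
        f"no pose chain corresponds to reference chain {ref_chain.id} "
        f"({ref_chain.chain_type.value})")


def _seq_residue_map(ref_chain: Chain, pose_chain: Chain
                     ) -> dict[str, Residue]:
    """reference residue key -> pose residue, by global sequence alignment."""
    refs = ref_chain.standard_residues
    poss = pose_chain.standard_residues
    pairs, _, _ = align_pair(ref_chain.sequence, pose_chain.sequence)
    return {refs[i].key: poss[j] for i, j in pairs}


def interface_rmsd(pose: TCRComplex, reference: TCRComplex,
                   cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                   return_details: bool = False):
    """Backbone interface RMSD of a pose against a reference complex.

    Interface membership is decided on the reference at the given heavy-atom
    cutoff; the pose is superposed onto the reference over the interface
    backbone atoms and the RMSD is reported over those same atoms.
    """
    iface = _interface_residues(reference, cutoff)
    if not iface:
        raise InterfaceError(f"no interface residues at cutoff {cutoff} A")
    maps: dict[str, dict[str, Residue]] = {}
    ref_pts, pose_pts = [], []
    n_res = 0
    for ch, res in iface:
        pose_chain = _match_chain(reference, pose, ch)
        if ch.id not in maps:
            maps[ch.id] = _seq_residue_map(ch, pose_chain)
        pres = maps[ch.id].get(res.key)
        if pres is None:
            continue
        names = [n for n in BACKBONE
                 if res.atom(n) is not None and pres.atom(n) is not None]
        if not names:
            continue
        n_res += 1
        for nm in names:
            ref_pts.append(res.atom(nm).coords)
            pose_pts.append(pres.atom(nm).coords)
    if len(ref_pts) < 3:
        raise InterfaceError(
            f"interface correspondence too small ({len(ref_pts)} atoms) at "
            f"cutoff {cutoff} A")
    A, B = np.vstack(ref_pts), np.vstack(pose_pts)
    sup = kabsch(A, B)
    if return_details:
        return {"irmsd": sup.rmsd, "n_interface_residues": n_res,
                "n_atoms": sup.n_atoms}
    return sup.rmsd
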