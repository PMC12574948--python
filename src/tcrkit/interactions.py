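"""Geometric detection of interface interactions.

Hydrogen bonds, salt bridges, hydrophobic contacts and aromatic stacking are
detected from heavy-atom geometry alone (crystallographic and predicted
structures rarely carry hydrogens), using per-residue chemistry tables and
distance/angle rules comparable to the defaults of standard profilers:

* hydrogen bond — donor heavy atom to acceptor heavy atom <= 3.5 A;
* salt bridge — cationic group centroid (Lys NZ; Arg NE/NH1/NH2;
  His ND1/NE2) to anionic group centroid (Asp OD1/OD2; Glu OE1/OE2)
  <= 5.5 A;
* hydrophobic — apolar carbon (carbon with no N/O/S neighbour) to apolar
  carbon <= 4.0 A, shortest pair per residue pair;
* pi-stacking — aromatic ring centroids (Phe/Tyr/Trp/His) <= 5.5 A with
  inter-plane angle <= 30 deg (parallel) or 60-90 deg (T-shaped).

His participates both as a cation and as an aromatic ring; that double
counting across kinds is intentional.  Residues adjacent in sequence are
never paired (their contacts are covalent geometry, not interactions).
All cutoffs are overridable through :class:`InteractionConfig`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import TCRKitError
from .model import Chain, Residue, TCRComplex

# ------------------------------------------------------- chemistry tables

#: Side-chain hydrogen-bond donor heavy atoms (backbone N added per residue).
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "SER": ("OG",),
    "THR": ("OG1",), "TRP": ("NE1",), "TYR": ("OH",),
}
#: Side-chain acceptor heavy atoms (backbone O/OXT added per residue).
SIDECHAIN_ACCEPTORS = {
    "ASN": ("OD1",), "ASP": ("OD1", "OD2"), "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",),
}
CATIONIC_GROUPS = {
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
}
ANIONIC_GROUPS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}
#: Carbon atoms whose covalent neighbours are carbons/hydrogens only.
APOLAR_CARBONS = {
    "ALA": ("CB",), "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"), "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG"), "MET": ("CB",), "ASP": ("CB",), "ASN": ("CB",),
    "GLU": ("CB", "CG"), "GLN": ("CB", "CG"), "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"), "THR": ("CG2",), "HIS": ("CB",),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass
class InteractionConfig:
    hbond_max: float = 3.5            # donor-acceptor heavy-atom distance, A
    saltbridge_max: float = 5.5       # charged-group centroid distance, A
    hydrophobic_max: float = 4.0      # apolar C-C distance, A
    pistack_max: float = 5.5          # ring centroid distance, A
    pistack_parallel_max: float = 30.0    # deg
    pistack_tshape_range: tuple[float, float] = (60.0, 90.0)
    version: str = "1"

    @property
    def prune_radius(self) -> float:
        return max(self.hbond_max, self.saltbridge_max,
                   self.hydrophobic_max, self.pistack_max)


@dataclass
class Interaction:
    kind: str                  # hbond | saltbridge | hydrophobic | pistack
    chainA: str
    chainB: str
    residueA: str              # residue key (author number + icode)
    residueB: str
    resnameA: str
    resnameB: str
    atomA: str                 # atom name or group descriptor
    atomB: str
    distance: float            # A
    angle: Optional[float] = None   # deg, pi-stacking only


@dataclass
class InteractionTable:
    rows: list[Interaction] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    chain_residues: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        cols = ["kind", "chainA", "residueA", "resnameA", "atomA",
                "chainB", "residueB", "resnameB", "atomB",
                "distance", "angle"]
        if not self.rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([vars(r) for r in self.rows])[cols]


# ----------------------------------------------------------- rule helpers

def _donors(res: Residue) -> list[str]:
    names = list(SIDECHAIN_DONORS.get(res.name, ()))
    if res.name != "PRO" and res.atom("N") is not None:
        names.append("N")
    return [n for n in names if res.atom(n) is not None]


def _acceptors(res: Residue) -> list[str]:
    names = list(SIDECHAIN_ACCEPTORS.get(res.name, ()))
    for bb in ("O", "OXT"):
        if res.atom(bb) is not None:
            names.append(bb)
    return [n for n in names if res.atom(n) is not None]


def _group_centroid(res: Residue, names: tuple[str, ...]) -> Optional[np.ndarray]:
    pts = [res.atom(n).coords for n in names if res.atom(n) is not None]
    return np.mean(pts, axis=0) if pts else None


def _ring(res: Residue) -> Optional[tuple[np.ndarray, np.ndarray]]:
    names = AROMATIC_RINGS.get(res.name)
    if not names:
        return None
    pts = [res.atom(n).coords for n in names if res.atom(n) is not None]
    if len(pts) < 4:
        return None
    pts = np.vstack(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]      # plane normal = smallest principal axis


def _pair_interactions(e1, e2, cfg: InteractionConfig) -> list[Interaction]:
    """All interactions between two residues (order-normalized)."""
    (ch1, r1), (ch2, r2) = e1, e2
    # normalize order so the table is independent of traversal order
    if (ch2.id, r2.key) < (ch1.id, r1.key):
        ch1, r1, ch2, r2 = ch2, r2, ch1, r1
    out: list[Interaction] = []

    def rec(kind, atomA, atomB, dist, angle=None):
        out.append(Interaction(
            kind=kind, chainA=ch1.id, chainB=ch2.id,
            residueA=r1.key, residueB=r2.key,
            resnameA=r1.name, resnameB=r2.name,
            atomA=atomA, atomB=atomB, distance=float(dist), angle=angle))

    # hydrogen bonds: donor->acceptor both directions, unordered-pair dedup
    seen: set[frozenset] = set()
    for (dres, dch), (ares, ach) in (((r1, ch1), (r2, ch2)),
                                     ((r2, ch2), (r1, ch1))):
        for dn in _donors(dres):
            for an in _acceptors(ares):
                d = float(np.linalg.norm(dres.atom(dn).coords
                                         - ares.atom(an).coords))
                if d <= cfg.hbond_max:
                    key = frozenset([(dch.id, dres.key, dn),
                                     (ach.id, ares.key, an)])
                    if key not in seen:
                        seen.add(key)
                        a1, a2 = (dn, an) if dres is r1 else (an, dn)
                        rec("hbond", a1, a2, d)

    # salt bridge: one per residue pair, group centroids
    for cat_res, ani_res, flip in ((r1, r2, False), (r2, r1, True)):
        cat_names = CATIONIC_GROUPS.get(cat_res.name)
        ani_names = ANIONIC_GROUPS.get(ani_res.name)
        if not cat_names or not ani_names:
            continue
        cat = _group_centroid(cat_res, cat_names)
        ani = _group_centroid(ani_res, ani_names)
        if cat is None or ani is None:
            continue
        d = float(np.linalg.norm(cat - ani))
        if d <= cfg.saltbridge_max:
            a_cat, a_ani = "+".join(cat_names), "+".join(ani_names)
            rec("saltbridge", a_ani if flip else a_cat,
                a_cat if flip else a_ani, d)

    # hydrophobic: shortest apolar C-C pair per residue pair
    c1 = [(n, r1.atom(n).coords) for n in APOLAR_CARBONS.get(r1.name, ())
          if r1.atom(n) is not None]
    c2 = [(n, r2.atom(n).coords) for n in APOLAR_CARBONS.get(r2.name, ())
          if r2.atom(n) is not None]
    best = None
    for (n1, p1), (n2, p2) in itertools.product(c1, c2):
        d = float(np.linalg.norm(p1 - p2))
        if d <= cfg.hydrophobic_max and (best is None or d < best[0]):
            best = (d, n1, n2)
    if best:
        rec("hydrophobic", best[1], best[2], best[0])

    # pi-stacking: ring centroid distance + inter-plane angle
    ring1, ring2 = _ring(r1), _ring(r2)
    if ring1 and ring2:
        d = float(np.linalg.norm(ring1[0] - ring2[0]))
        if d <= cfg.pistack_max:
            cosang = abs(float(ring1[1] @ ring2[1]))
            ang = float(np.degrees(np.arccos(min(1.0, cosang))))
            lo, hi = cfg.pistack_tshape_range
            if ang <= cfg.pistack_parallel_max or lo <= ang <= hi:
                rec("pistack", "ring", "ring", d, angle=ang)
    return out


# --------------------------------------------------------------- detection

def detect_interactions(complex: TCRComplex, scope: str = "interchain",
                        config: Optional[InteractionConfig] = None
                        ) -> InteractionTable:
    """Detect all interface interactions of a complex.

    ``scope='interchain'`` restricts to contacts between different chains;
    ``scope='all'`` adds intra-chain contacts (never between residues
    adjacent in sequence).  An empty complex yields an empty table.
    """
    if scope not in ("interchain", "all"):
        raise TCRKitError(f"unknown scope {scope!r}")
    cfg = config or InteractionConfig()
    entries: list[tuple[Chain, Residue, int]] = []
    for ch in complex.chains:
        for idx, res in enumerate(ch.standard_residues):
            entries.append((ch, res, idx))
    table = InteractionTable(
        provenance={"source": complex.source, "scope": scope,
                    "parameters_version": cfg.version},
        chain_residues={ch.id: [r.key for r in ch.standard_residues]
                        for ch in complex.chains})
    if not entries:
        return table

    # prune candidate residue pairs on heavy-atom proximity
    pts, owner = [], []
    for i, (_ch, res, _idx) in enumerate(entries):
        for a in res.atoms:
            if a.element.upper() != "H":
                pts.append(a.coords)
                owner.append(i)
    tree = cKDTree(np.vstack(pts))
    owner = np.array(owner)
    cand: set[tuple[int, int]] = set()
    for ai, bi in tree.query_pairs(r=cfg.prune_radius + 4.0):
        i, j = owner[ai], owner[bi]
        if i != j:
            cand.add((min(i, j), max(i, j)))

    for i, j in sorted(cand):
        ch1, r1, i1 = entries[i]
        ch2, r2, i2 = entries[j]
        same_chain = ch1.id == ch2.id
        if scope == "interchain" and same_chain:
            continue
        if same_chain and abs(i1 - i2) <= 1:
            continue
        table.rows.extend(_pair_interactions((ch1, r1), (ch2, r2), cfg))
    table.rows.sort(key=lambda r: (r.chainA, r.residueA, r.chainB,
                                   r.residueB, r.kind, r.atomA, r.atomB))
    return table


# ------------------------------------------------------- heatmap & export

@dataclass
class HeatmapMatrix:
    matrix: pd.DataFrame       # rows: chain A residues, cols: chain B residues

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def to_csv(self, path: str) -> None:
        self.matrix.to_csv(path)

    def to_png(self, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(4, self.matrix.shape[1] * 0.3),
                                        max(3, self.matrix.shape[0] * 0.3)))
        im = ax.imshow(self.matrix.to_numpy(), cmap="Greys", aspect="auto")
        ax.set_xticks(range(self.matrix.shape[1]),
                      self.matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(self.matrix.shape[0]),
                      self.matrix.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="interactions")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def interaction_heatmap(table: InteractionTable, chainA: str, chainB: str
                        ) -> HeatmapMatrix:
    """Residue-by-residue interaction count matrix between two chains.

    Rows and columns cover every residue of the two chains (zeros included);
    the cell sum equals the number of interactions between the chain pair.
    """
    for cid in (chainA, chainB):
        if cid not in table.chain_residues:
            raise TCRKitError(f"chain {cid!r} not present in this table")
    rows = table.chain_residues[chainA]
    cols = table.chain_residues[chainB]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for r in table.rows:
        if r.chainA == chainA and r.chainB == chainB:
            mat.loc[r.residueA, r.residueB] += 1
        elif r.chainA == chainB and r.chainB == chainA:
            mat.loc[r.residueB, r.residueA] += 1
    return HeatmapMatrix(matrix=mat)


def export_interactions(table: InteractionTable, path: str,
                        format: str = "csv") -> None:
    """Write the table as CSV, one row per interaction."""
    if format != "csv":
        raise TCRKitError(f"unsupported export format {format!r}")
    table.to_frame().to_csv(path, index=False)


def read_interactions(path: str) -> InteractionTable:
    """Read a CSV written by :func:`export_interactions`."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     float_precision="round_trip",
                     dtype={"chainA": str, "chainB": str,
                            "residueA": str, "residueB": str})
    rows = []
    for rec in df.to_dict("records"):
        ang = rec.get("angle")
        rec["angle"] = None if ang is None or (isinstance(ang, float)
                                               and np.isnan(ang)) else float(ang)
        rows.append(Interaction(**rec))
    return InteractionTable(rows=rows)
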