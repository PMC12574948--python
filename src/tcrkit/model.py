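"""Hierarchical structure model: StructureModel -> Model -> Chain -> Residue -> Atom.

A deliberately small, library-neutral container.  Structures are parsed into
this model by :mod:`tcrkit.structure_io` (via gemmi) and everything downstream
(annotation, geometry, RMSD, interactions, graphs) operates on it.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in STANDARD_AA3.items()}


class ChainType(enum.Enum):
    TCR_ALPHA = "TCR_ALPHA"
    TCR_BETA = "TCR_BETA"
    TCR_GAMMA = "TCR_GAMMA"
    TCR_DELTA = "TCR_DELTA"
    MHC1_HEAVY = "MHC1_HEAVY"
    B2M = "B2M"
    MHC2_ALPHA = "MHC2_ALPHA"
    MHC2_BETA = "MHC2_BETA"
    PEPTIDE = "PEPTIDE"
    UNKNOWN = "UNKNOWN"


TCR_TYPES = {ChainType.TCR_ALPHA, ChainType.TCR_BETA, ChainType.TCR_GAMMA, ChainType.TCR_DELTA}
ALPHA_LIKE = {ChainType.TCR_ALPHA, ChainType.TCR_GAMMA}
BETA_LIKE = {ChainType.TCR_BETA, ChainType.TCR_DELTA}
MHC_TYPES = {ChainType.MHC1_HEAVY, ChainType.B2M, ChainType.MHC2_ALPHA, ChainType.MHC2_BETA}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray          # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@dataclass
class Residue:
    name: str                   # 3-letter code (or hetero code)
    number: int                 # author residue number
    icode: str = ""             # author insertion code
    atoms: list[Atom] = field(default_factory=list)
    imgt: Optional[str] = None  # IMGT number+icode as string, e.g. "111A"

    @property
    def key(self) -> str:
        return f"{self.number}{self.icode}"

    @property
    def one_letter(self) -> Optional[str]:
        return STANDARD_AA3.get(self.name)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA3

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    chain_type: ChainType = ChainType.UNKNOWN

    @property
    def sequence(self) -> str:
        """1-letter sequence over the standard amino-acid residues, in order."""
        return "".join(r.one_letter for r in self.residues if r.is_standard)

    @property
    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard]

    def ca_coords(self, residues: Optional[list[Residue]] = None) -> np.ndarray:
        res = self.standard_residues if residues is None else residues
        pts = [r.ca.coords for r in res if r.ca is not None]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def residue_by_key(self, key: str) -> Optional[Residue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def residue_by_imgt(self, imgt: str) -> Optional[Residue]:
        for r in self.residues:
            if r.imgt == imgt:
                return r
        return None


@dataclass
class Model:
    index: int
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"model {self.index}: duplicate chain ids {ids}")

    def chain(self, cid: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == cid:
                return c
        return None


@dataclass
class StructureModel:
    id: str
    models: list[Model] = field(default_factory=list)

    def __iter__(self) -> Iterator[Model]:
        return iter(self.models)

    @property
    def first(self) -> Model:
        return self.models[0]


@dataclass
class TCRComplex:
    """One TCR copy (paired variable domains) plus its distance-assigned antigen.

    ``alpha_like`` holds a TCR alpha or gamma chain, ``beta_like`` a beta or
    delta chain.  ``mhc_chains`` holds 0-2 MHC chains (class I heavy + beta-2
    microglobulin, or class II alpha + beta); ``peptide`` the presented
    antigen, when bound.
    """
    alpha_like: Chain
    beta_like: Chain
    mhc_chains: list[Chain] = field(default_factory=list)
    peptide: Optional[Chain] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.alpha_like.chain_type not in ALPHA_LIKE:
            raise ValueError(
                f"alpha_like chain {self.alpha_like.id} has type "
                f"{self.alpha_like.chain_type.value}, expected TCR_ALPHA/TCR_GAMMA")
        if self.beta_like.chain_type not in BETA_LIKE:
            raise ValueError(
                f"beta_like chain {self.beta_like.id} has type "
                f"{self.beta_like.chain_type.value}, expected TCR_BETA/TCR_DELTA")

    @property
    def is_apo(self) -> bool:
        return not self.mhc_chains and self.peptide is None

    @property
    def antigen_chains(self) -> list[Chain]:
        out = list(self.mhc_chains)
        if self.peptide is not None:
            out.append(self.peptide)
        return out

    @property
    def chains(self) -> list[Chain]:
        return [self.alpha_like, self.beta_like] + self.antigen_chains
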