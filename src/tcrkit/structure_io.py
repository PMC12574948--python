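"""Reading, writing, chain classification and TCR:pMHC complex assembly.

Structures are parsed with gemmi (PDB and mmCIF) into the lightweight
hierarchical model of :mod:`tcrkit.model`.  Chains are classified by global
alignment against packaged reference sequences, and TCR:pMHC copies are
assembled by spatial proximity: each alpha-like chain pairs with its nearest
beta-like chain, and every antigen chain (MHC, peptide) is assigned to the
nearest TCR pair by variable-domain centroid distance.
"""
from __future__ import annotations

import logging
import os
import re
import shutil
import tempfile
import urllib.request
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from ._align import align_pair
from .errors import ClassificationError, FetchError, FormatError, ParseError
from .model import (ALPHA_LIKE, BETA_LIKE, MHC_TYPES, Atom, Chain, ChainType,
                    Model, Residue, StructureModel, TCR_TYPES)
from .refs import all_references

logger = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 0.30     # minimum identity over aligned columns for a hit
MIN_ALIGNED_FRACTION = 0.5    # a hit must cover at least half the reference
PEPTIDE_MAX_LEN = 25          # presented peptides are 8-15-mers; generous margin
VDOMAIN_RESIDUES = 125        # leading residues taken as the variable domain
PAIRING_TIE_TOL = 0.1         # Angstrom; nearer than this counts as a tie


# ---------------------------------------------------------------- reading

def _detect_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if ".pdb" in suffixes or ".ent" in suffixes:
        return "pdb"
    if ".cif" in suffixes or ".mmcif" in suffixes:
        return "mmcif"
    raise FormatError(f"cannot infer format from filename {path.name!r}; "
                      "pass format='pdb' or 'mmcif'")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken toward altloc 'A' (then alphabetical)
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def read_structure(path: str | os.PathLike, format: str = "auto",
                   exclude_waters: bool = True) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are represented; waters are excluded by default.
    Alternate locations are collapsed to the highest-occupancy conformer.
    Multi-model (NMR-style) files produce one model record per MODEL block.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format if format != "auto" else _detect_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {fmt!r}; expected pdb/mmcif/auto")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    sm = StructureModel(id=st.name.lower() if st.name else path.stem)
    for mi, gm in enumerate(st):
        chains = []
        for gch in gm:
            residues = []
            for gres in gch:
                if exclude_waters and gres.is_water():
                    continue
                by_name: dict[str, list[gemmi.Atom]] = {}
                for ga in gres:
                    by_name.setdefault(ga.name, []).append(ga)
                atoms = []
                for name, group in by_name.items():
                    ga = _pick_altloc(group)
                    atoms.append(Atom(
                        name=name,
                        element=ga.element.name or "X",
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc or "",
                        is_hetero=gres.het_flag == "H",
                    ))
                if atoms:
                    residues.append(Residue(
                        name=gres.name,
                        number=gres.seqid.num,
                        icode=(gres.seqid.icode or "").strip(),
                        atoms=atoms,
                    ))
            if residues:
                chains.append(Chain(id=gch.name, residues=residues))
        sm.models.append(Model(index=mi, chains=chains))
    if not sm.models or all(not m.chains for m in sm.models):
        raise ParseError(f"{path}: no atom records found")
    return sm


def _to_gemmi(structure: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    for m in structure.models:
        gm = gemmi.Model(m.index + 1)
        for ch in m.chains:
            gch = gemmi.Chain(ch.id)
            for res in ch.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
                gres.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.altloc = "\0" if not a.altloc else a.altloc
                    gres.add_atom(ga)
                gch.add_residue(gres)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(structure: StructureModel, path: str | os.PathLike) -> None:
    """Write a StructureModel as a PDB file (fixed-width, 1e-3 A precision)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: StructureModel, path: str | os.PathLike) -> None:
    """Write a StructureModel as mmCIF (atom_site category)."""
    doc = _to_gemmi(structure).make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------- classification

from functools import lru_cache


@lru_cache(maxsize=4096)
def _classify_sequence(seq: str) -> tuple[ChainType, float]:
    best: tuple[float, float, Optional[ChainType]] = (-np.inf, 0.0, None)
    for ctype, ref in all_references().items():
        pairs, identity, score = align_pair(seq, ref)
        covered = len(pairs) >= MIN_ALIGNED_FRACTION * len(ref)
        if identity >= IDENTITY_THRESHOLD and covered and score > best[0]:
            best = (score, identity, ctype)
    if best[2] is not None:
        return best[2], best[1]
    if len(seq) <= PEPTIDE_MAX_LEN:
        return ChainType.PEPTIDE, 0.0
    return ChainType.UNKNOWN, 0.0


def classify_chain(chain: Chain) -> tuple[ChainType, float]:
    """Classify a chain by alignment to the packaged references.

    Returns the best-scoring reference class and the alignment identity.
    Chains without a reference hit are PEPTIDE when they have at most
    25 standard residues, UNKNOWN otherwise.  Results are memoized by
    sequence.
    """
    seq = chain.sequence
    if not seq:
        raise ClassificationError(f"chain {chain.id}: no standard residues")
    return _classify_sequence(seq)


def classify_model(model: Model) -> Model:
    """Classify every chain of a model in place (and return it)."""
    for ch in model.chains:
        try:
            ch.chain_type, _ = classify_chain(ch)
        except ClassificationError:
            ch.chain_type = ChainType.UNKNOWN
    return model


# -------------------------------------------------------------- assembly

def _vdomain_centroid(chain: Chain) -> np.ndarray:
    """Centroid of the Calpha atoms of the (approximate) variable domain:
    the first 125 standard residues."""
    res = chain.standard_residues[:VDOMAIN_RESIDUES]
    pts = chain.ca_coords(res)
    if pts.shape[0] == 0:
        raise ClassificationError(f"chain {chain.id}: no Calpha atoms")
    return pts.mean(axis=0)


def _chain_centroid(chain: Chain) -> np.ndarray:
    pts = chain.ca_coords()
    if pts.shape[0] == 0:
        pts = np.vstack([a.coords for r in chain.residues for a in r.atoms])
    return pts.mean(axis=0)


def assemble_complexes(model: Model, structure_id: str = "",
                       model_index: int = 0) -> list["TCRComplex"]:
    """Group classified chains into TCRComplex objects by spatial proximity.

    Each alpha-like chain is paired with the nearest unpaired beta-like chain
    (variable-domain Calpha centroid distance).  Each antigen chain is then
    assigned to the nearest TCR pair; ties closer than 0.1 A are broken by
    the TCR alpha-chain id.  Unpaired or unknown chains are logged, never
    silently dropped.
    """
    from .model import TCRComplex

    alphas = [c for c in model.chains if c.chain_type in ALPHA_LIKE]
    betas = [c for c in model.chains if c.chain_type in BETA_LIKE]
    if not alphas or not betas:
        logger.warning("model %d of %s: no complete TCR (alpha-like=%d, "
                       "beta-like=%d)", model.index, structure_id or "?",
                       len(alphas), len(betas))
        return []

    # greedy nearest pairing, globally shortest distance first
    dist = {(a.id, b.id): float(np.linalg.norm(
        _vdomain_centroid(a) - _vdomain_centroid(b)))
        for a in alphas for b in betas}
    pairs: list[tuple[Chain, Chain]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for (aid, bid), _ in sorted(dist.items(), key=lambda kv: (kv[1], kv[0])):
        if aid in used_a or bid in used_b:
            continue
        pairs.append((next(a for a in alphas if a.id == aid),
                      next(b for b in betas if b.id == bid)))
        used_a.add(aid)
        used_b.add(bid)
    for ch in alphas + betas:
        if ch.id not in used_a | used_b:
            logger.warning("chain %s (%s) left unpaired", ch.id,
                           ch.chain_type.value)

    complexes = [TCRComplex(alpha_like=a, beta_like=b,
                            source=f"{structure_id}/model{model_index}")
                 for a, b in pairs]
    tcr_centroids = [(_vdomain_centroid(a) + _vdomain_centroid(b)) / 2.0
                     for a, b in pairs]

    for ch in model.chains:
        if ch.chain_type in TCR_TYPES:
            continue
        if ch.chain_type is ChainType.UNKNOWN:
            logger.warning("chain %s left unassigned (UNKNOWN type)", ch.id)
            continue
        c = _chain_centroid(ch)
        dists = np.array([np.linalg.norm(c - tc) for tc in tcr_centroids])
        order = np.argsort(dists, kind="stable")
        best = order[0]
        # tie-break by alpha chain id when two TCRs are equally near
        ties = [i for i in order if dists[i] - dists[best] < PAIRING_TIE_TOL]
        best = min(ties, key=lambda i: complexes[i].alpha_like.id)
        if ch.chain_type in MHC_TYPES:
            complexes[best].mhc_chains.append(ch)
        elif ch.chain_type is ChainType.PEPTIDE:
            if complexes[best].peptide is not None:
                logger.warning("complex %d already has a peptide; chain %s "
                               "left unassigned", best, ch.id)
            else:
                complexes[best].peptide = ch
    return complexes


def load_complexes(path: str | os.PathLike, format: str = "auto",
                   all_models: bool = False) -> list["TCRComplex"]:
    """One-call pipeline: read, classify and assemble.  By default only the
    first model of a multi-model file is used."""
    sm = read_structure(path, format=format)
    models = sm.models if all_models else sm.models[:1]
    out = []
    for m in models:
        classify_model(m)
        out.extend(assemble_complexes(m, structure_id=sm.id,
                                      model_index=m.index))
    return out


# --------------------------------------------------------------- fetching

_URL_TEMPLATES = {
    "pdb": "https://files.rcsb.org/download/{pdb_id}.pdb",
    "stcrdab": ("https://opig.stats.ox.ac.uk/webapps/stcrdab-stcrpred/"
                "pdb/{pdb_id_lower}"),
}


def default_cache_dir() -> Path:
    env = os.environ.get("TCRKIT_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "tcrkit"


def fetch_structure(pdb_id: str, source: str = "pdb",
                    cache_dir: Optional[str | os.PathLike] = None) -> Path:
    """Download a structure by 4-character PDB code, with a local cache.

    The download goes to a temporary file first, so a failed transfer never
    leaves a partial file in the cache.
    """
    if not re.fullmatch(r"[0-9][A-Za-z0-9]{3}", pdb_id or ""):
        raise FetchError(f"invalid PDB id {pdb_id!r} (must be 4 characters, "
                         "digit first)")
    if source not in _URL_TEMPLATES:
        raise FetchError(f"unknown source {source!r}")
    cache = Path(cache_dir) if cache_dir else default_cache_dir()
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{pdb_id.lower()}_{source}.pdb"
    if dest.exists():
        return dest
    url = _URL_TEMPLATES[source].format(pdb_id=pdb_id.upper(),
                                        pdb_id_lower=pdb_id.lower())
    tmp_fd, tmp_path = tempfile.mkstemp(dir=cache, suffix=".part")
    os.close(tmp_fd)
    try:
        with urllib.request.urlopen(url, timeout=60) as resp, \
                open(tmp_path, "wb") as out:
            shutil.copyfileobj(resp, out)
        shutil.move(tmp_path, dest)
    except Exception as exc:
        if os.path.exists(tmp_path):
            os.unlink(tmp_path)
        raise FetchError(f"failed to fetch {pdb_id} from {source}: {exc}") from exc
    return dest
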