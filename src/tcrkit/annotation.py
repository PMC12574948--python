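"""IMGT numbering and region annotation of TCR variable domains.

Numbers are transferred by global alignment to a packaged IMGT-numbered
consensus for the chain's locus (the consensus occupies every position
1-128, so alignment columns map directly onto IMGT numbers).  CDR3 is
renumbered by the IMGT loop convention: positions fill from both ends
(105.. and ..117) toward the top of the loop, gaps open at 111/112 for
short loops, and insertions take letter codes symmetrically around
111/112 (111A, ... / ..., 112A) for long loops.

Region delimitations (IMGT): FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65,
FR3 66-104, CDR3 105-117, FR4 118-128.  Conserved cysteines sit at 23 and
104.  Residues beyond FR4 are labelled CONSTANT.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from ._align import align_pair
from .errors import AnchorError, NumberingError
from .model import Chain, Residue, TCR_TYPES
from .refs import v_consensus

IDENTITY_THRESHOLD = 0.30

#: IMGT region boundaries, inclusive ranges over positions 1-128.
REGION_BOUNDS = (
    ("FR1", 1, 26), ("CDR1", 27, 38), ("FR2", 39, 55), ("CDR2", 56, 65),
    ("FR3", 66, 104), ("CDR3", 105, 117), ("FR4", 118, 128),
)

REGIONS = tuple(name for name, _, _ in REGION_BOUNDS)


def region_of(imgt: int | str) -> str:
    """Region label for an IMGT number (int, or string like '111A').

    Numbers outside 1-128 return 'NONE'.
    """
    if isinstance(imgt, str):
        num = int("".join(ch for ch in imgt if ch.isdigit()))
    else:
        num = int(imgt)
    for name, lo, hi in REGION_BOUNDS:
        if lo <= num <= hi:
            return name
    return "NONE"


def cdr3_numbering(length: int) -> list[str]:
    """IMGT numbers, in chain order, for a CDR3 of the given length.

    Length 13 uses 105-117 exactly; shorter loops leave gaps at the top
    (112 side first); longer loops insert 111A.. / ..112A letter codes,
    the odd extra position going to the 112 side.
    """
    if length < 1:
        return []
    base = list(range(105, 118))            # 13 canonical positions
    if length <= 13:
        n_left = (length + 1) // 2          # 105 side fills first
        n_right = length // 2
        return [str(n) for n in base[:n_left]] + \
               [str(n) for n in base[13 - n_right:]]
    n_ins = length - 13
    n111 = n_ins // 2
    n112 = n_ins - n111                     # odd extra goes to the 112 side
    letters = string.ascii_uppercase
    ins111 = [f"111{letters[i]}" for i in range(n111)]
    ins112 = [f"112{letters[i]}" for i in reversed(range(n112))]
    return [str(n) for n in range(105, 112)] + ins111 + ins112 + \
           [str(n) for n in range(112, 118)]


@lru_cache(maxsize=4096)
def _cached_alignment(seq: str, ref: str) -> tuple[tuple[tuple[int, int], ...], float]:
    pairs, identity, _ = align_pair(seq, ref)
    return tuple(pairs), identity


@dataclass
class NumberedDomain:
    """Per-residue IMGT numbering of one variable domain.

    ``mapping`` pairs author residue keys (number+icode) with IMGT numbers;
    ``regions`` gives one region label per residue of the chain, including
    CONSTANT for residues beyond FR4 and NONE for unnumbered residues.
    """
    chain: Chain
    mapping: list[tuple[str, str]] = field(default_factory=list)
    regions: dict[str, str] = field(default_factory=dict)
    identity: float = 0.0

    def residues_in(self, region_set: set[str] | list[str]) -> list[Residue]:
        wanted = set(region_set)
        return [r for r in self.chain.standard_residues
                if self.regions.get(r.key) in wanted]

    def to_frame(self) -> pd.DataFrame:
        imgt_by_key = dict(self.mapping)
        rows = [{
            "chain": self.chain.id,
            "author_number": r.number,
            "icode": r.icode,
            "residue": r.name,
            "imgt": imgt_by_key.get(r.key, ""),
            "region": self.regions.get(r.key, "NONE"),
        } for r in self.chain.standard_residues]
        return pd.DataFrame(rows)


def number_domain(chain: Chain) -> NumberedDomain:
    """Assign IMGT numbers and region labels to a TCR chain's variable domain.

    Raises NumberingError when the alignment identity to the locus consensus
    is below 0.30 (the chain is probably misclassified).  The assignment is
    also written onto the chain's residues (``Residue.imgt``) so downstream
    modules can look residues up by IMGT number.
    """
    if chain.chain_type not in TCR_TYPES:
        raise NumberingError(
            f"chain {chain.id} has type {chain.chain_type.value}; "
            "only TCR chains can be IMGT-numbered")
    cons = v_consensus()[chain.chain_type]
    residues = chain.standard_residues
    seq = chain.sequence
    pairs, identity = _cached_alignment(seq, cons.sequence)
    if identity < IDENTITY_THRESHOLD:
        raise NumberingError(
            f"chain {chain.id}: alignment identity {identity:.2f} to "
            f"{chain.chain_type.value} consensus is below "
            f"{IDENTITY_THRESHOLD}")

    ref_of = dict(pairs)                     # query idx -> consensus idx (0-based)
    q_at_ref = {ri: qi for qi, ri in pairs}  # consensus idx -> query idx

    # CDR3 block: query residues strictly between the residues anchored at
    # IMGT 104 and IMGT 118 are renumbered by loop length.
    q104 = q_at_ref.get(103)
    q118 = q_at_ref.get(117)
    cdr3_q: list[int] = []
    if q104 is not None and q118 is not None and q118 > q104 + 1:
        cdr3_q = list(range(q104 + 1, q118))
    cdr3_nums = cdr3_numbering(len(cdr3_q))
    cdr3_map = dict(zip(cdr3_q, cdr3_nums))

    imgt_of: dict[int, str] = {}
    prev_num: str | None = None
    ins_count = 0
    for qi in range(len(residues)):
        if qi in cdr3_map:
            imgt_of[qi] = cdr3_map[qi]
            prev_num, ins_count = cdr3_map[qi], 0
        elif qi in ref_of:
            imgt_of[qi] = str(ref_of[qi] + 1)
            prev_num, ins_count = imgt_of[qi], 0
        else:
            # insertion relative to the consensus outside CDR3: letter code
            # on the preceding number; unaligned N-terminal overhang and the
            # constant-domain tail stay unnumbered.
            q_after_last = all(qi > q for q in ref_of)
            if prev_num is not None and not q_after_last:
                ins_count += 1
                imgt_of[qi] = f"{prev_num}{string.ascii_uppercase[ins_count - 1]}"

    mapping: list[tuple[str, str]] = []
    regions: dict[str, str] = {}
    last_numbered_q = max(imgt_of, default=-1)
    for qi, res in enumerate(residues):
        if qi in imgt_of:
            num = imgt_of[qi]
            res.imgt = num
            mapping.append((res.key, num))
            regions[res.key] = "CDR3" if qi in cdr3_map else region_of(num)
        else:
            res.imgt = None
            regions[res.key] = "CONSTANT" if qi > last_numbered_q else "NONE"
    return NumberedDomain(chain=chain, mapping=mapping, regions=regions,
                          identity=identity)


def anchor_residues(domain: NumberedDomain) -> tuple[Residue, Residue]:
    """The conserved-cysteine anchor residues at IMGT 23 and 104."""
    out = []
    for pos in ("23", "104"):
        res = domain.chain.residue_by_imgt(pos)
        if res is None:
            raise AnchorError(
                f"chain {domain.chain.id}: no residue at IMGT {pos}")
        out.append(res)
    return out[0], out[1]


def export_annotation(domains: list[NumberedDomain], path: str) -> None:
    """Write per-residue annotations of one or more domains to CSV."""
    frames = [d.to_frame() for d in domains]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
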