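"""Global pairwise alignment helper shared by chain classification,
IMGT number transfer, and cross-structure residue correspondence.

BLOSUM62 with affine gaps (open 10, extend 1), Needleman-Wunsch global mode.
"""
from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    # free end gaps: a variable-domain reference may sit inside a full-length
    # chain (constant domain present) without terminal-gap penalties
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


def align_pair(query: str, reference: str) -> tuple[list[tuple[int, int]], float, float]:
    """Globally align ``query`` to ``reference``.

    Returns ``(pairs, identity, score)`` where ``pairs`` are aligned index
    pairs (query_idx, ref_idx) and ``identity`` is the fraction of identical
    residues over aligned (non-gap) columns.  Empty inputs raise ValueError.
    """
    if not query or not reference:
        raise ValueError("cannot align empty sequence")
    aln = _aligner().align(query, reference)[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    for (qs, qe), (rs, re) in zip(aln.aligned[0], aln.aligned[1]):
        for qi, ri in zip(range(qs, qe), range(rs, re)):
            pairs.append((qi, ri))
            if query[qi] == reference[ri]:
                n_ident += 1
    identity = n_ident / len(pairs) if pairs else 0.0
    return pairs, identity, float(aln.score)
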