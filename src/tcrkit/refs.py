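"""Packaged reference sequences.

Two plain-text resources ship with the package:

* ``tcr_v_consensus.csv`` — one IMGT-numbered consensus V-domain per TCR
  locus (alpha, beta, gamma, delta).  Each consensus occupies every IMGT
  position 1-128, so alignment column -> IMGT number transfer is direct.
  Conserved cysteines sit at IMGT 23 and 104.  These are idealized
  (synthetic) consensus scaffolds, not germline gene sequences.
* ``mhc_references.fasta`` — G-domain-level reference sequences for MHC
  class I heavy chain (alpha1+alpha2), beta-2 microglobulin, and the MHC
  class II alpha1 / beta1 domains.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio import SeqIO

from .model import ChainType


@dataclass(frozen=True)
class VConsensus:
    locus: ChainType
    sequence: str              # length 128
    imgt_numbers: tuple[int, ...]
    regions: tuple[str, ...]   # per-position region label


def _data_path(name: str):
    return resources.files("tcrkit").joinpath("data", name)


@lru_cache(maxsize=1)
def v_consensus() -> dict[ChainType, VConsensus]:
    rows: dict[str, list[tuple[int, str, str]]] = {}
    with _data_path("tcr_v_consensus.csv").open() as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["locus"], []).append(
                (int(rec["imgt_number"]), rec["region"], rec["aa"]))
    out = {}
    for locus, recs in rows.items():
        recs.sort()
        ct = ChainType(locus)
        out[ct] = VConsensus(
            locus=ct,
            sequence="".join(aa for _, _, aa in recs),
            imgt_numbers=tuple(n for n, _, _ in recs),
            regions=tuple(reg for _, reg, _ in recs),
        )
    return out


@lru_cache(maxsize=1)
def mhc_references() -> dict[ChainType, str]:
    out = {}
    with _data_path("mhc_references.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[ChainType(rec.id)] = str(rec.seq)
    return out


@lru_cache(maxsize=1)
def all_references() -> dict[ChainType, str]:
    """All classification references: V-domain consensus plus MHC domains."""
    refs = {ct: vc.sequence for ct, vc in v_consensus().items()}
    refs.update(mhc_references())
    return refs
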