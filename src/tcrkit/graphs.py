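"""Residue-level graphs for machine-learning pipelines.

Each standard residue with a Calpha atom becomes a node; edges connect
residues within a Calpha-Calpha distance cutoff (default 10 A) or by
k-nearest-neighbour rule (symmetrized).  Node features default to a 20-dim
amino-acid one-hot plus the Calpha coordinates; edge features default to
the Euclidean distance.  Selector, featurizer and label rules are plug-in
registries keyed by name, so bespoke implementations can be passed without
touching the core.

Graphs serialize to a flat, framework-neutral container: one zip per graph
holding ``nodes.csv``, ``edges.csv`` and ``meta.json``.  The writer pins
zip timestamps, so identical inputs and configuration produce byte-identical
datasets.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DatasetError, GraphError
from .model import Chain, ChainType, Residue, TCRComplex, STANDARD_AA3

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: chain type -> node region label (beta-2 microglobulin counts as MHC)
REGION_LABEL = {
    ChainType.TCR_ALPHA: "TCRalpha", ChainType.TCR_GAMMA: "TCRalpha",
    ChainType.TCR_BETA: "TCRbeta", ChainType.TCR_DELTA: "TCRbeta",
    ChainType.PEPTIDE: "peptide",
    ChainType.MHC1_HEAVY: "MHC", ChainType.B2M: "MHC",
    ChainType.MHC2_ALPHA: "MHC", ChainType.MHC2_BETA: "MHC",
}


# ------------------------------------------------------------- registries

def _select_all(chain: Chain, res: Residue) -> bool:
    return True

NODE_SELECTORS: dict[str, Callable[[Chain, Residue], bool]] = {
    "all": _select_all,
}


def _feat_onehot(chain: Chain, res: Residue) -> list[float]:
    vec = [0.0] * len(AA_ORDER)
    aa = STANDARD_AA3.get(res.name)
    if aa in AA_ORDER:
        vec[AA_ORDER.index(aa)] = 1.0
    return vec


def _feat_ca(chain: Chain, res: Residue) -> list[float]:
    return [float(x) for x in res.ca.coords]

NODE_FEATURIZERS: dict[str, Callable[[Chain, Residue], list[float]]] = {
    "aa_onehot": _feat_onehot,
    "ca_coords": _feat_ca,
}

EDGE_FEATURIZERS: dict[str, Callable[[np.ndarray, np.ndarray], list[float]]] = {
    "distance": lambda pi, pj: [float(np.linalg.norm(pi - pj))],
}


def region_labels(complex: TCRComplex,
                  unknown_label: Optional[str] = None) -> dict[str, str]:
    """Per-chain node label: TCRalpha, TCRbeta, peptide or MHC.

    UNKNOWN chains raise unless ``unknown_label`` maps them explicitly.
    """
    out = {}
    for ch in complex.chains:
        lab = REGION_LABEL.get(ch.chain_type)
        if lab is None:
            if unknown_label is None:
                raise GraphError(
                    f"chain {ch.id} has UNKNOWN type and no label mapping")
            lab = unknown_label
        out[ch.id] = lab
    return out

LABEL_RULES: dict[str, Callable[[TCRComplex], dict[str, str]]] = {
    "region": region_labels,
    "none": lambda cx: {ch.id: "" for ch in cx.chains},
}


def register(registry: dict, name: str, fn: Callable) -> None:
    """Plug-in point: register a custom selector/featurizer/label rule."""
    registry[name] = fn


# ------------------------------------------------------------------ config

@dataclass
class GraphConfig:
    node_selector: str = "all"
    node_features: tuple[str, ...] = ("aa_onehot", "ca_coords")
    edge_rule: str = "cutoff"              # "cutoff" | "knn"
    edge_cutoff: float = 10.0              # A, Calpha-Calpha
    edge_k: int = 10
    edge_features: tuple[str, ...] = ("distance",)
    label_rule: str = "region"

    def __post_init__(self) -> None:
        self.node_features = tuple(self.node_features)
        self.edge_features = tuple(self.edge_features)
        if self.edge_rule not in ("cutoff", "knn"):
            raise ConfigError(f"unknown edge_rule {self.edge_rule!r}")
        if self.edge_rule == "cutoff" and self.edge_cutoff <= 0:
            raise ConfigError("edge_cutoff must be > 0")
        if self.edge_rule == "knn" and self.edge_k < 1:
            raise ConfigError("edge_k must be >= 1")
        if len(set(self.node_features)) != len(self.node_features):
            raise ConfigError("node feature names must be unique")
        if self.node_selector not in NODE_SELECTORS:
            raise ConfigError(f"unknown node_selector {self.node_selector!r}")
        for f in self.node_features:
            if f not in NODE_FEATURIZERS:
                raise ConfigError(f"unknown node featurizer {f!r}")
        for f in self.edge_features:
            if f not in EDGE_FEATURIZERS:
                raise ConfigError(f"unknown edge featurizer {f!r}")
        if self.label_rule not in LABEL_RULES:
            raise ConfigError(f"unknown label_rule {self.label_rule!r}")

    @property
    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResidueGraph:
    nodes: pd.DataFrame          # chain, residue, resname, label, x0..xN
    edges: np.ndarray            # (E, 2) int, i < j
    edge_features: np.ndarray    # (E, F) float
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}


# ------------------------------------------------------------ construction

def build_graph(complex: TCRComplex, config: Optional[GraphConfig] = None
                ) -> ResidueGraph:
    """Build a residue graph from a complex under a configuration.

    Node order is content-based (chain id, then residue number + insertion
    code), so graphs are invariant to chain order in the input file.
    Residues without a Calpha atom are skipped and counted in the metadata.
    """
    cfg = config or GraphConfig()
    selector = NODE_SELECTORS[cfg.node_selector]
    labels = LABEL_RULES[cfg.label_rule](complex)

    picked: list[tuple[Chain, Residue]] = []
    skipped = 0
    for ch in sorted(complex.chains, key=lambda c: c.id):
        for res in sorted(ch.standard_residues,
                          key=lambda r: (r.number, r.icode)):
            if not selector(ch, res):
                continue
            if res.ca is None:
                skipped += 1
                continue
            picked.append((ch, res))
    if not picked:
        raise GraphError("no selectable residues with Calpha atoms")

    coords = np.vstack([res.ca.coords for _, res in picked])
    rows = []
    for ch, res in picked:
        row = {"chain": ch.id, "residue": res.key, "resname": res.name,
               "label": labels[ch.id]}
        feats: list[float] = []
        for fname in cfg.node_features:
            feats.extend(NODE_FEATURIZERS[fname](ch, res))
        for k, v in enumerate(feats):
            row[f"x{k}"] = v
        rows.append(row)
    nodes = pd.DataFrame(rows)

    if cfg.edge_rule == "cutoff":
        tree = cKDTree(coords)
        pairs = sorted((min(i, j), max(i, j))
                       for i, j in tree.query_pairs(r=cfg.edge_cutoff))
    else:
        k = min(cfg.edge_k + 1, len(picked))
        _, idx = cKDTree(coords).query(coords, k=k)
        pairs = sorted({(min(i, int(j)), max(i, int(j)))
                        for i, row in enumerate(idx) for j in row if int(j) != i})
    edges = np.array(pairs, dtype=int).reshape(-1, 2)
    efeats = []
    for i, j in pairs:
        vec: list[float] = []
        for fname in cfg.edge_features:
            vec.extend(EDGE_FEATURIZERS[fname](coords[i], coords[j]))
        efeats.append(vec)
    if efeats:
        edge_features = np.array(efeats, dtype=float)
    else:
        edge_features = np.zeros((0, len(cfg.edge_features)))

    meta = {"source": complex.source, "config_hash": cfg.hash,
            "config": asdict(cfg), "n_nodes": len(picked),
            "n_edges": len(pairs), "skipped_no_ca": skipped}
    return ResidueGraph(nodes=nodes, edges=edges,
                        edge_features=edge_features, metadata=meta)


# ----------------------------------------------------------- serialization

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)    # pinned for byte-determinism


def _write_member(zf: zipfile.ZipFile, name: str, text: str) -> None:
    info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, text)


def save_graph(graph: ResidueGraph, path: str | Path) -> None:
    edf = pd.DataFrame(graph.edges, columns=["i", "j"])
    for k in range(graph.edge_features.shape[1]):
        edf[f"e{k}"] = graph.edge_features[:, k]
    with zipfile.ZipFile(path, "w") as zf:
        _write_member(zf, "nodes.csv", graph.nodes.to_csv(index=False))
        _write_member(zf, "edges.csv", edf.to_csv(index=False))
        _write_member(zf, "meta.json",
                      json.dumps(graph.metadata, sort_keys=True, indent=1))


def load_graph(path: str | Path) -> ResidueGraph:
    with zipfile.ZipFile(path) as zf:
        nodes = pd.read_csv(StringIO(zf.read("nodes.csv").decode()),
                            dtype={"chain": str, "residue": str},
                            keep_default_na=False,
                            float_precision="round_trip")
        edf = pd.read_csv(StringIO(zf.read("edges.csv").decode()),
                          float_precision="round_trip")
        meta = json.loads(zf.read("meta.json").decode())
    ecols = [c for c in edf.columns if c.startswith("e")]
    edges = edf[["i", "j"]].to_numpy(dtype=int).reshape(-1, 2)
    efeat = edf[ecols].to_numpy(dtype=float).reshape(len(edf), len(ecols))
    nodes["label"] = nodes["label"].astype(str).replace("nan", "")
    return ResidueGraph(nodes=nodes, edges=edges, edge_features=efeat,
                        metadata=meta)


def build_dataset(paths: list[str | Path], config: Optional[GraphConfig] = None,
                  labels: Optional[dict[str, str]] = None,
                  out_dir: str | Path = "graph_dataset") -> dict:
    """Convert structure files into an on-disk graph dataset.

    One graph zip is written per assembled complex; per-file failures are
    logged and recorded in the manifest, not fatal.  ``labels`` optionally
    maps structure stems to an external graph-level label stored in the
    metadata.  Raises DatasetError when every input fails.
    """
    from .structure_io import load_complexes

    cfg = config or GraphConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "config_hash": cfg.hash, "entries": []}
    n_ok = 0
    for p in paths:
        p = Path(p)
        entry = {"input": p.name, "status": "ok", "graphs": [], "error": ""}
        try:
            complexes = load_complexes(p)
            if not complexes:
                raise GraphError("no TCR complexes assembled")
            for ci, cx in enumerate(complexes):
                g = build_graph(cx, cfg)
                if labels and p.stem in labels:
                    g.metadata["external_label"] = labels[p.stem]
                gname = f"{p.stem}_{ci}.graph.zip"
                save_graph(g, out / gname)
                entry["graphs"].append(gname)
            n_ok += 1
        except Exception as exc:     # batch semantics: log, record, continue
            logger.warning("dataset build failed for %s: %s", p, exc)
            entry["status"] = "error"
            entry["error"] = str(exc)
        manifest["entries"].append(entry)
    if n_ok == 0:
        raise DatasetError("all dataset inputs failed")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
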