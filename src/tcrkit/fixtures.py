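"""Synthetic toy TCR:pMHC structures with exact known geometry.

The generator builds an idealized complex in which every quantity the rest
of the package computes is known by construction:

* the MHC platform is a planar Calpha cloud in z = 0 whose principal axes
  are exactly x (groove axis) and z (plane normal): the two flanking
  "helices" are straight, x-symmetric lines at y = +/-8 (helix residue
  ranges match the Singh-style groove selection), the floor a symmetric
  grid between them;
* the peptide runs along +x (N- to C-terminus) just above the platform;
* the two pseudo-domains carry the packaged Valpha/Vbeta consensus
  sequences (so classification and IMGT numbering recover the identity
  mapping, with the disulfide anchors at positions 23 and 104), and their
  anchor centroids realize a requested (scanning, pitch, distance) exactly
  when noise is zero.

These are not physically realistic structures: residues are Calpha-centred
stubs with schematic backbone atoms and no side chains beyond what the
sequence implies.  They exist to make every module testable without
downloads.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import FixtureError, ParameterError
from .geometry import GeometryDescriptor
from .model import (AA1_TO_AA3, Atom, Chain, Model, Residue, StructureModel)
from .refs import mhc_references, v_consensus
from .model import ChainType

#: chain ids per complex copy: (alpha, beta, peptide, mhc1, mhc2)
_COPY_IDS = [("A", "B", "C", "M", "N"), ("E", "F", "G", "P", "Q"),
             ("H", "I", "J", "R", "S"), ("K", "L", "O", "T", "U")]

ANCHOR_HALF_SPAN = 10.0    # A, half distance between the two domain anchors


@dataclass
class ToyComplexSpec:
    scanning: float = 40.0       # degrees, (-180, 180]
    pitch: float = 10.0          # degrees, [0, 90]
    distance: float = 25.0       # A
    n_copies: int = 1
    mhc_class: str = "I"         # "I" | "II"
    apo: bool = False
    seed: int = 0
    noise_sigma: float = 0.0     # A, isotropic Gaussian on every atom
    tcr_below: bool = False      # mirror fixture: TCR on the -z face

    def validate(self) -> None:
        if not (-180.0 < self.scanning <= 180.0):
            raise FixtureError(f"scanning {self.scanning} outside (-180, 180]")
        if not (0.0 <= self.pitch <= 90.0):
            raise FixtureError(f"pitch {self.pitch} outside [0, 90]")
        if self.distance < 0:
            raise FixtureError(f"distance {self.distance} must be >= 0")
        if self.noise_sigma < 0:
            raise FixtureError("noise_sigma must be >= 0")
        if self.mhc_class not in ("I", "II"):
            raise FixtureError(f"mhc_class {self.mhc_class!r} not in (I, II)")
        if not (1 <= self.n_copies <= len(_COPY_IDS)):
            raise FixtureError(f"n_copies must be 1-{len(_COPY_IDS)}")


def _symmetric_line(n: int, y: float, z: float = 0.0,
                    half_span: float = 17.5) -> np.ndarray:
    x = np.linspace(-half_span, half_span, n)
    return np.column_stack([x, np.full(n, y), np.full(n, z)])


def _backbone_atoms(ca: np.ndarray) -> list[Atom]:
    """Schematic backbone: CA plus N/C/O at fixed local offsets."""
    return [
        Atom(name="N", element="N", coords=ca + np.array([-0.45, 0.35, 0.0])),
        Atom(name="CA", element="C", coords=ca.copy()),
        Atom(name="C", element="C", coords=ca + np.array([0.45, 0.35, 0.0])),
        Atom(name="O", element="O", coords=ca + np.array([0.55, 1.05, 0.0])),
    ]


def _make_chain(cid: str, sequence: str, coords: np.ndarray,
                start_number: int = 1) -> Chain:
    assert len(sequence) == coords.shape[0]
    residues = []
    for i, (aa, ca) in enumerate(zip(sequence, coords)):
        residues.append(Residue(name=AA1_TO_AA3[aa],
                                number=start_number + i,
                                atoms=_backbone_atoms(np.asarray(ca, float))))
    return Chain(id=cid, residues=residues)


def _mhc1_coords() -> np.ndarray:
    """180 Calpha positions; helices (50-85, 140-175) at y=+/-8, floor grid
    between, all in z=0; every row is x-symmetric and the +y/-y point counts
    balance, so the cloud centroid is exactly the groove midline."""
    coords = np.zeros((180, 3))
    # half-spans avoid residue spacings that are divisors of common cutoffs,
    # so no atom pair sits exactly on a detection threshold
    coords[49:85] = _symmetric_line(36, y=8.0, half_span=17.3)   # alpha1, 50-85
    coords[139:175] = _symmetric_line(36, y=-8.0, half_span=17.3)  # alpha2, 140-175
    floor_idx = [i for i in range(180) if not (49 <= i < 85 or 139 <= i < 175)]
    xs = np.linspace(-17.5, 17.5, 12)                 # 108 = 12 x 9 grid
    ys = np.linspace(-6.0, 6.0, 9)
    grid = np.array([(x, y, 0.0) for y in ys for x in xs])
    coords[floor_idx] = grid
    return coords


def _mhc2_coords() -> tuple[np.ndarray, np.ndarray]:
    """Class II: alpha (84 res, helix 45-78 at y=+8) and beta (90 res,
    helix 50-83 at y=-8); floor rows at y=+/-4 (50 points each) and the
    6 spare beta residues on the y=0 centerline, keeping the joint
    centroid exactly on the groove midline."""
    a = np.zeros((84, 3))
    a[44:78] = _symmetric_line(34, y=8.0)
    rest = [i for i in range(84) if not 44 <= i < 78]
    a[rest] = _symmetric_line(len(rest), y=4.0)
    b = np.zeros((90, 3))
    b[49:83] = _symmetric_line(34, y=-8.0)
    rest = [i for i in range(90) if not 49 <= i < 83]
    b[rest[:50]] = _symmetric_line(50, y=-4.0)
    b[rest[50:]] = _symmetric_line(6, y=0.0, half_span=10.0)
    return a, b


def _perpendicular(u: np.ndarray) -> np.ndarray:
    t = np.array([0.0, 0.0, 1.0])
    if abs(float(u @ t)) > 0.9:
        t = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, t)
    return v / np.linalg.norm(v)


def _domain_coords(anchor: np.ndarray, u: np.ndarray, phase: float,
                   down: np.ndarray) -> np.ndarray:
    """128 Calpha positions around ``anchor``; residues 23 and 104 sit at
    anchor +/- w so their centroid is exactly the anchor, and the CDR3 loop
    (105-117) descends toward the antigen so bound complexes have a real
    interface."""
    e1 = _perpendicular(u)
    e2 = np.cross(u, e1)
    coords = np.zeros((128, 3))
    for i in range(128):
        theta = phase + 2.0 * math.pi * i / 16.0
        axial = (i - 63.5) / 128.0 * 8.0
        coords[i] = anchor + 4.0 * (math.cos(theta) * e1
                                    + math.sin(theta) * e2) + axial * u
    for i in range(104, 117):                       # CDR3 stalk, IMGT 105-117
        t = (i - 104) / 12.0
        depth = 21.0 * math.sin(math.pi * t)
        coords[i] = anchor + (t - 0.5) * 6.0 * e1 + depth * down
    w = 3.0 * e1
    coords[22] = anchor + w      # IMGT 23
    coords[103] = anchor - w     # IMGT 104
    return coords


def make_toy_complex(spec: ToyComplexSpec) -> tuple[StructureModel, dict]:
    """Build a toy complex realizing the requested geometry exactly.

    Returns the structure and a ground-truth record (requested descriptors,
    chain roles per copy, the identity IMGT mapping of the V domains).  At
    ``noise_sigma=0`` all three geometry methods recover scanning, pitch and
    distance to numerical precision: the TCR center sits on the groove
    normal, where the Euclidean and normal-projected distances coincide.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cons = v_consensus()
    mhc_refs = mhc_references()

    g = np.array([1.0, 0.0, 0.0])
    n = np.array([0.0, 0.0, 1.0])
    if spec.tcr_below:
        n = -n
    s, p = math.radians(spec.scanning), math.radians(spec.pitch)
    u = (math.cos(p) * (math.cos(s) * g + math.sin(s) * np.cross(n, g))
         + math.sin(p) * n)

    chains: list[Chain] = []
    copies = []
    for copy_i in range(spec.n_copies):
        ids = _COPY_IDS[copy_i]
        shift = np.array([150.0 * copy_i, 0.0, 0.0])
        center = shift + spec.distance * n
        a_anchor = center - ANCHOR_HALF_SPAN * u
        b_anchor = center + ANCHOR_HALF_SPAN * u
        chains.append(_make_chain(
            ids[0], cons[ChainType.TCR_ALPHA].sequence,
            _domain_coords(a_anchor, u, phase=0.0, down=-n)))
        chains.append(_make_chain(
            ids[1], cons[ChainType.TCR_BETA].sequence,
            _domain_coords(b_anchor, u, phase=1.0, down=-n)))
        roles = {ids[0]: "TCR_ALPHA", ids[1]: "TCR_BETA"}
        if not spec.apo:
            pep_coords = _symmetric_line(9, y=0.0, z=2.5, half_span=8.2) + shift
            chains.append(_make_chain(ids[2], "GILGFVFTL", pep_coords))
            roles[ids[2]] = "PEPTIDE"
            if spec.mhc_class == "I":
                chains.append(_make_chain(
                    ids[3], mhc_refs[ChainType.MHC1_HEAVY],
                    _mhc1_coords() + shift))
                b2m = _symmetric_line(99, y=0.0, z=-8.0, half_span=12.0) + shift
                chains.append(_make_chain(
                    ids[4], mhc_refs[ChainType.B2M], b2m))
                roles[ids[3]] = "MHC1_HEAVY"
                roles[ids[4]] = "B2M"
            else:
                ca, cb = _mhc2_coords()
                chains.append(_make_chain(
                    ids[3], mhc_refs[ChainType.MHC2_ALPHA], ca + shift))
                chains.append(_make_chain(
                    ids[4], mhc_refs[ChainType.MHC2_BETA], cb + shift))
                roles[ids[3]] = "MHC2_ALPHA"
                roles[ids[4]] = "MHC2_BETA"
        copies.append(roles)

    if spec.noise_sigma > 0:
        for ch in chains:
            for res in ch.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(
                        0.0, spec.noise_sigma, 3)

    sm = StructureModel(id=f"toy_{spec.seed}",
                        models=[Model(index=0, chains=chains)])
    truth = {
        "spec": asdict(spec),
        "scanning": spec.scanning, "pitch": spec.pitch,
        "distance": spec.distance,
        "polarity": "canonical" if abs(spec.scanning) <= 90.0 else "reverse",
        "copies": copies,
        "imgt_mapping": {str(i): str(i) for i in range(1, 129)},
        "anchor_author_numbers": [23, 104],
    }
    return sm, truth


def write_toy_complex(spec: ToyComplexSpec, out_dir: str | Path,
                      stem: str | None = None) -> tuple[Path, Path]:
    """Write a toy complex as PDB plus a JSON ground-truth sidecar."""
    from .structure_io import write_pdb
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sm, truth = make_toy_complex(spec)
    stem = stem or sm.id
    pdb_path = out / f"{stem}.pdb"
    write_pdb(sm, pdb_path)
    json_path = out / f"{stem}.truth.json"
    with open(json_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return pdb_path, json_path


# ---------------------------------------------------------- descriptor pools

def sample_descriptor_pool(params, n: int, seed: int,
                           method: str = "adapted") -> list[GeometryDescriptor]:
    """Draw i.i.d. descriptors from the reference distributions of
    ``params`` (Normal scanning, Gamma pitch, Gaussian-mixture distance)."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    scan = rng.normal(params.scan_mu, params.scan_sigma, n)
    pitch = stats.gamma.rvs(a=params.pitch_shape, loc=params.pitch_loc,
                            scale=params.pitch_scale, size=n,
                            random_state=rng)
    comp = rng.choice(len(params.dist_weights), size=n,
                      p=np.asarray(params.dist_weights))
    dist = rng.normal(np.asarray(params.dist_means)[comp],
                      np.asarray(params.dist_sigmas)[comp])
    out = []
    for sc, pi, di in zip(scan, pitch, dist):
        out.append(GeometryDescriptor(
            scanning_angle=float(sc), pitch=float(pi),
            distance=float(abs(di)),
            polarity="canonical" if abs(sc) <= 90.0 else "reverse",
            method=method))
    return out


def decoy_parameters(params):
    """Shift every location parameter by three standard deviations: the
    decoy pool for the ranking property."""
    from .scoring import ScoreParameters
    gamma_sd = math.sqrt(params.pitch_shape) * params.pitch_scale
    return ScoreParameters(
        scan_mu=params.scan_mu + 3.0 * params.scan_sigma,
        scan_sigma=params.scan_sigma,
        pitch_shape=params.pitch_shape, pitch_scale=params.pitch_scale,
        pitch_loc=params.pitch_loc + 3.0 * gamma_sd,
        dist_weights=params.dist_weights,
        dist_means=tuple(m + 3.0 * sg for m, sg in
                         zip(params.dist_means, params.dist_sigmas)),
        dist_sigmas=params.dist_sigmas,
        alphas=params.alphas,
    )
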