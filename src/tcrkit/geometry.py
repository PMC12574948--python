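"""TCR-to-pMHC binding geometry: scanning angle, pitch, distance, polarity.

The MHC peptide-binding groove defines a right-handed reference frame:

* ``origin`` — centroid of the groove Calpha atoms;
* ``groove_axis`` — first principal component of the groove Calpha cloud,
  oriented from the peptide N-terminus toward its C-terminus;
* ``plane_normal`` — third principal component, oriented toward the TCR.

The TCR contributes a pseudo-axis through the two variable-domain disulfide
anchors (centroid of the Calpha atoms at IMGT 23 and 104 per domain),
pointing from the alpha-like to the beta-like domain.  Geometry descriptors:

* scanning angle — signed in-plane angle between the TCR axis (projected
  onto the groove plane) and the groove axis, sign by the right-hand rule
  about the plane normal; range (-180, 180] degrees;
* pitch — out-of-plane tilt of the TCR axis, [0, 90] degrees;
* distance — TCR center to groove origin, in Angstrom.

Three method variants are provided.  ``rudolph`` and ``singh`` follow the
two classical scanning-angle constructions (full Euclidean center-to-origin
distance; ``singh`` restricts the groove fit to the helical segments),
``adapted`` projects the distance onto the groove normal, making it a pure
elevation above the platform.  All three share the angular construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotation import number_domain
from .errors import AnchorError, FrameError, GeometryError
from .model import Chain, ChainType, TCRComplex

METHODS = ("rudolph", "singh", "adapted")

#: Groove residue ranges (author numbering) per MHC chain type; the class I
#: G-domain (alpha1+alpha2) spans residues 1-180, class II splits across its
#: two chains.  The Singh-style variant fits only the helix segments.
GROOVE_RANGES = {
    ChainType.MHC1_HEAVY: [(1, 180)],
    ChainType.MHC2_ALPHA: [(1, 85)],
    ChainType.MHC2_BETA: [(1, 90)],
}
GROOVE_RANGES_HELIX = {
    ChainType.MHC1_HEAVY: [(50, 85), (140, 175)],
    ChainType.MHC2_ALPHA: [(45, 78)],
    ChainType.MHC2_BETA: [(50, 83)],
}

MIN_GROOVE_CA = 20
DEGENERATE_TOL = 1e-6


@dataclass
class MHCFrame:
    origin: np.ndarray         # groove Calpha centroid, Angstrom
    groove_axis: np.ndarray    # unit vector along the groove long axis
    plane_normal: np.ndarray   # unit vector, toward the TCR side
    handedness: int = 1

    def __post_init__(self) -> None:
        for name in ("groove_axis", "plane_normal"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(self.groove_axis @ self.plane_normal)) > 1e-9:
            raise ValueError("groove_axis and plane_normal must be orthogonal")


@dataclass
class TCRAxis:
    alpha_anchor: np.ndarray   # Valpha disulfide centroid
    beta_anchor: np.ndarray    # Vbeta disulfide centroid
    axis: np.ndarray           # unit vector alpha_anchor -> beta_anchor
    tcr_centroid: np.ndarray   # midpoint of the two anchors


@dataclass
class GeometryDescriptor:
    scanning_angle: float      # degrees, signed, (-180, 180]
    pitch: float               # degrees, [0, 90]
    distance: float            # Angstrom, >= 0
    polarity: str              # "canonical" | "reverse"
    method: str                # "rudolph" | "singh" | "adapted"


def _groove_ca(complex: TCRComplex, helix_only: bool) -> np.ndarray:
    ranges = GROOVE_RANGES_HELIX if helix_only else GROOVE_RANGES
    pts = []
    for ch in complex.mhc_chains:
        for lo, hi in ranges.get(ch.chain_type, []):
            for res in ch.standard_residues:
                if lo <= res.number <= hi and res.ca is not None:
                    pts.append(res.ca.coords)
    if len(pts) < MIN_GROOVE_CA:
        raise FrameError(
            f"only {len(pts)} groove Calpha atoms found (need "
            f">= {MIN_GROOVE_CA}); cannot build the MHC frame")
    return np.vstack(pts)


def _tcr_ca_centroid(complex: TCRComplex) -> np.ndarray:
    pts = np.vstack([complex.alpha_like.ca_coords(
                        complex.alpha_like.standard_residues[:125]),
                     complex.beta_like.ca_coords(
                        complex.beta_like.standard_residues[:125])])
    return pts.mean(axis=0)


def compute_mhc_frame(complex: TCRComplex, method: str = "adapted") -> MHCFrame:
    """Fit the MHC groove reference frame by PCA of the groove Calpha cloud.

    Principal axes are sign-ambiguous; the groove axis is oriented along the
    peptide N->C direction (chain direction of the platform when no peptide
    is bound) and the plane normal toward the TCR centroid.
    """
    if not complex.mhc_chains:
        raise GeometryError("no pMHC: complex has no MHC chains")
    pts = _groove_ca(complex, helix_only=(method == "singh"))
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    groove_axis, plane_normal = vt[0], vt[2]

    if complex.peptide is not None and len(complex.peptide.standard_residues) >= 2:
        pep = complex.peptide.standard_residues
        ref = pep[-1].ca.coords - pep[0].ca.coords
    else:
        # chain (N->C) direction of the platform itself
        ref = pts[-1] - pts[0]
    if float(groove_axis @ ref) < 0:
        groove_axis = -groove_axis
    if float(plane_normal @ (_tcr_ca_centroid(complex) - origin)) < 0:
        plane_normal = -plane_normal
    return MHCFrame(origin=origin, groove_axis=groove_axis,
                    plane_normal=plane_normal)


def _domain_anchor(chain: Chain, use_sg: bool = False) -> np.ndarray:
    if any(r.imgt is None for r in chain.standard_residues):
        number_domain(chain)
    dom_res = []
    for pos in ("23", "104"):
        res = chain.residue_by_imgt(pos)
        if res is None:
            raise AnchorError(f"chain {chain.id}: no residue at IMGT {pos}")
        dom_res.append(res)
    atoms = []
    for res in dom_res:
        atom = res.atom("SG") if use_sg and res.atom("SG") else res.ca
        if atom is None:
            raise AnchorError(
                f"chain {chain.id}: residue {res.key} (IMGT {res.imgt}) "
                "has no Calpha atom")
        atoms.append(atom.coords)
    return np.mean(atoms, axis=0)


def compute_tcr_axis(complex: TCRComplex, use_sg: bool = False) -> TCRAxis:
    """Axis through the two variable-domain disulfide anchors.

    Each anchor is the centroid of the Calpha atoms at IMGT 23 and 104 of
    that domain (``use_sg=True`` switches to the disulfide Sgamma atoms when
    present).  Domains are IMGT-numbered on the fly if needed.
    """
    a = _domain_anchor(complex.alpha_like, use_sg)
    b = _domain_anchor(complex.beta_like, use_sg)
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise GeometryError("degenerate TCR axis: anchors coincide")
    return TCRAxis(alpha_anchor=a, beta_anchor=b, axis=d / n,
                   tcr_centroid=(a + b) / 2.0)


def calculate_geometry(complex: TCRComplex, method: str = "adapted",
                       use_sg: bool = False) -> GeometryDescriptor:
    """Compute the scanning angle, pitch, distance and polarity of a pose."""
    if method not in METHODS:
        raise GeometryError(f"unknown method {method!r}; expected one of {METHODS}")
    if not complex.mhc_chains:
        raise GeometryError("no pMHC: cannot compute binding geometry of an "
                            "apo TCR")
    frame = compute_mhc_frame(complex, method=method)
    tcr = compute_tcr_axis(complex, use_sg=use_sg)
    g, n = frame.groove_axis, frame.plane_normal

    a_par = tcr.axis - float(tcr.axis @ n) * n
    norm_par = np.linalg.norm(a_par)
    if norm_par < DEGENERATE_TOL:
        raise GeometryError(
            "degenerate geometry: TCR axis is parallel to the groove normal; "
            "the scanning angle is undefined")
    a_hat = a_par / norm_par
    scanning = math.degrees(math.atan2(float(n @ np.cross(g, a_hat)),
                                       float(g @ a_hat)))
    if scanning <= -180.0:
        scanning += 360.0
    pitch = math.degrees(math.asin(min(1.0, abs(float(tcr.axis @ n)))))
    v = tcr.tcr_centroid - frame.origin
    distance = abs(float(v @ n)) if method == "adapted" else float(np.linalg.norm(v))
    polarity = "canonical" if abs(scanning) <= 90.0 else "reverse"
    return GeometryDescriptor(scanning_angle=scanning, pitch=pitch,
                              distance=distance, polarity=polarity,
                              method=method)


def geometry_table(complexes, method: str = "adapted"):
    """Batch descriptor table: one row per complex (CSV-ready DataFrame)."""
    import pandas as pd
    rows = []
    for cx in complexes:
        d = calculate_geometry(cx, method=method)
        rows.append({
            "source": cx.source,
            "alpha_chain": cx.alpha_like.id,
            "beta_chain": cx.beta_like.id,
            "method": d.method,
            "scanning_angle": d.scanning_angle,
            "pitch": d.pitch,
            "distance": d.distance,
            "polarity": d.polarity,
        })
    return pd.DataFrame(rows)
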