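"""Knowledge-based geometry score eta.

A pose's descriptor x = (scanning angle, pitch, distance) is scored against
reference distributions fitted to signalling-competent complexes:

    eta = - alpha_scan * log N(scanning | mu, sigma)
          - alpha_pitch * log Gamma(pitch | shape, scale, loc)
          - alpha_dist * log GMM(distance | w, m, s)

Lower eta means a more canonical, signalling-compatible pose.  A pitch below
the Gamma location offset has zero density, giving eta = +inf (the sentinel
for "outside the support"); reverse-polarity poses are scored with the same
formula but carry their polarity flag so they can be filtered separately.

Fitting: Normal and Gamma terms by maximum likelihood (Gamma location fixed
at 0), the distance mixture by expectation-maximization with k-means++
initialization.  The EM log-likelihood trace is checked to be non-decreasing
at every iteration.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import ConfigError, FitError, ParameterError
from .geometry import GeometryDescriptor

EM_TOL = 1e-8
EM_MAX_ITER = 500
_VAR_FLOOR = 1e-12


@dataclass
class ScoreParameters:
    scan_mu: float
    scan_sigma: float
    pitch_shape: float
    pitch_scale: float
    pitch_loc: float = 0.0
    dist_weights: tuple[float, ...] = (1.0,)
    dist_means: tuple[float, ...] = (25.0,)
    dist_sigmas: tuple[float, ...] = (3.0,)
    alphas: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.dist_weights = tuple(float(w) for w in self.dist_weights)
        self.dist_means = tuple(float(m) for m in self.dist_means)
        self.dist_sigmas = tuple(float(s) for s in self.dist_sigmas)
        self.alphas = tuple(float(a) for a in self.alphas)
        if self.scan_sigma <= 0:
            raise ParameterError("scan_sigma must be > 0")
        if self.pitch_shape <= 0 or self.pitch_scale <= 0:
            raise ParameterError("pitch_shape and pitch_scale must be > 0")
        if self.pitch_loc < 0:
            raise ParameterError("pitch_loc must be >= 0")
        k = len(self.dist_weights)
        if k < 1 or len(self.dist_means) != k or len(self.dist_sigmas) != k:
            raise ParameterError("dist_weights/means/sigmas must have equal "
                                 "length K >= 1")
        if any(w <= 0 for w in self.dist_weights):
            raise ParameterError("every mixture weight must be > 0")
        if abs(sum(self.dist_weights) - 1.0) > 1e-6:
            raise ParameterError(
                f"dist_weights must sum to 1 (got {sum(self.dist_weights)})")
        if any(s <= 0 for s in self.dist_sigmas):
            raise ParameterError("every mixture sigma must be > 0")
        if len(self.alphas) != 3 or any(a < 0 for a in self.alphas):
            raise ParameterError("alphas must be 3 non-negative weights")

    @property
    def k_components(self) -> int:
        return len(self.dist_weights)


def log_densities(desc: GeometryDescriptor, params: ScoreParameters
                  ) -> tuple[float, float, float]:
    """Per-term log densities (scanning, pitch, distance) of a descriptor."""
    l_scan = stats.norm.logpdf(desc.scanning_angle, params.scan_mu,
                               params.scan_sigma)
    l_pitch = stats.gamma.logpdf(desc.pitch, a=params.pitch_shape,
                                 loc=params.pitch_loc,
                                 scale=params.pitch_scale)
    w = np.log(params.dist_weights)
    comp = stats.norm.logpdf(desc.distance, np.array(params.dist_means),
                             np.array(params.dist_sigmas))
    l_dist = float(logsumexp(w + comp))
    return float(l_scan), float(l_pitch), l_dist


def score_geometry(desc: GeometryDescriptor, params: ScoreParameters) -> float:
    """eta = sum_i -alpha_i log p_i(x).  Lower is more canonical.

    Returns +inf when any weighted term has zero density (e.g. pitch below
    the Gamma location offset).
    """
    for name in ("scanning_angle", "pitch", "distance"):
        if not math.isfinite(getattr(desc, name)):
            raise ParameterError(f"descriptor field {name} is not finite")
    terms = log_densities(desc, params)
    eta = 0.0
    for alpha, logp in zip(params.alphas, terms):
        if alpha == 0.0:
            continue
        if not math.isfinite(logp):
            return math.inf
        eta -= alpha * logp
    return eta


def score_table(descriptors: Sequence[GeometryDescriptor],
                params: ScoreParameters):
    """Batch scoring DataFrame: descriptor columns + eta + polarity flag."""
    import pandas as pd
    rows = []
    for d in descriptors:
        rows.append({
            "scanning_angle": d.scanning_angle, "pitch": d.pitch,
            "distance": d.distance, "method": d.method,
            "polarity": d.polarity,
            "eta": score_geometry(d, params),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ fitting

def fit_gmm_1d(data: np.ndarray, k: int, seed: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """1-D Gaussian mixture by EM; k-means++ initialization from ``seed``.

    Returns (weights, means, sigmas, log-likelihood trace).  The trace is
    verified non-decreasing at every iteration; convergence when the gain
    drops below 1e-8 or after 500 iterations.
    """
    x = np.asarray(data, dtype=float)
    if len(np.unique(x)) < k:
        raise FitError(f"need at least {k} distinct values to fit a "
                       f"{k}-component mixture")
    centers, _ = kmeans_plusplus(x.reshape(-1, 1), n_clusters=k,
                                 random_state=seed)
    means = np.sort(centers.ravel())
    var = max(float(np.var(x)), _VAR_FLOOR)
    sigmas = np.full(k, math.sqrt(var))
    weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    prev = -np.inf
    for _ in range(EM_MAX_ITER):
        logcomp = (np.log(weights)[:, None]
                   + stats.norm.logpdf(x[None, :], means[:, None],
                                       sigmas[:, None]))
        lognorm = logsumexp(logcomp, axis=0)
        ll = float(lognorm.sum())
        if ll < prev - 1e-9:
            raise FitError("EM log-likelihood decreased; fit is unstable")
        trace.append(ll)
        if ll - prev < EM_TOL:
            break
        prev = ll
        resp = np.exp(logcomp - lognorm[None, :])
        nk = resp.sum(axis=1)
        weights = nk / nk.sum()
        means = (resp @ x) / nk
        sigmas = np.sqrt(np.maximum(
            (resp @ x**2) / nk - means**2, _VAR_FLOOR))
    order = np.argsort(means)
    return weights[order], means[order], sigmas[order], trace


def fit_parameters(descriptors: Sequence[GeometryDescriptor],
                   k_components: int = 2, seed: int = 0) -> ScoreParameters:
    """Fit the reference distributions from a set of canonical geometries.

    Requires at least 10 descriptors, all of canonical polarity (the score
    models the signalling-compatible binding mode).
    """
    if len(descriptors) < 10:
        raise FitError(f"need >= 10 descriptors to fit, got {len(descriptors)}")
    n_rev = sum(1 for d in descriptors if d.polarity != "canonical")
    if n_rev:
        raise FitError(f"{n_rev} descriptors have reverse polarity; fit on "
                       "canonical-polarity references only")
    scan = np.array([d.scanning_angle for d in descriptors])
    pitch = np.array([d.pitch for d in descriptors])
    dist = np.array([d.distance for d in descriptors])

    shape, _, scale = stats.gamma.fit(pitch, floc=0.0)
    weights, means, sigmas, _ = fit_gmm_1d(dist, k_components, seed)
    return ScoreParameters(
        scan_mu=float(scan.mean()),
        scan_sigma=float(scan.std(ddof=0)),
        pitch_shape=float(shape), pitch_scale=float(scale), pitch_loc=0.0,
        dist_weights=tuple(weights), dist_means=tuple(means),
        dist_sigmas=tuple(sigmas),
    )


# -------------------------------------------------------------- persistence

_SCHEMA_FIELDS = ("scan_mu", "scan_sigma", "pitch_shape", "pitch_scale",
                  "pitch_loc", "dist_weights", "dist_means", "dist_sigmas",
                  "alphas")


def save_parameters(params: ScoreParameters, path: str) -> None:
    payload = asdict(params)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_parameters(path: str) -> ScoreParameters:
    """Load score parameters from JSON; schema violations raise ConfigError
    naming the offending field."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    for fname in _SCHEMA_FIELDS:
        if fname not in payload:
            raise ConfigError(f"{path}: missing field {fname!r}")
    extra = set(payload) - set(_SCHEMA_FIELDS) - {"note", "version"}
    if extra:
        raise ConfigError(f"{path}: unknown fields {sorted(extra)}")
    try:
        return ScoreParameters(**{f: payload[f] for f in _SCHEMA_FIELDS})
    except ParameterError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def default_parameters() -> ScoreParameters:
    """Package-default parameters (see data/default_score_parameters.json).

    These are defaults fitted to the package's synthetic canonical reference
    pool and are meant as a starting point; users scoring real poses should
    fit parameters on their own curated reference set with
    :func:`fit_parameters`.
    """
    from importlib import resources
    path = resources.files("tcrkit").joinpath(
        "data", "default_score_parameters.json")
    with resources.as_file(path) as p:
        return load_parameters(str(p))
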