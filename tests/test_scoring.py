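"""The eta score, distribution fitting, parameter persistence."""
import math

import numpy as np
import pytest

from tcrkit.errors import ConfigError, FitError, ParameterError
from tcrkit.fixtures import decoy_parameters, sample_descriptor_pool
from tcrkit.geometry import GeometryDescriptor
from tcrkit.scoring import (ScoreParameters, fit_gmm_1d, fit_parameters,
                            load_parameters, save_parameters, score_geometry)

REF = ScoreParameters(scan_mu=40.0, scan_sigma=10.0, pitch_shape=2.0,
                      pitch_scale=5.0, dist_weights=(0.5, 0.5),
                      dist_means=(25.0, 31.0), dist_sigmas=(2.0, 2.0))


def desc(scan=40.0, pitch=10.0, dist=25.0):
    return GeometryDescriptor(scanning_angle=scan, pitch=pitch, distance=dist,
                              polarity="canonical" if abs(scan) <= 90 else "reverse",
                              method="adapted")


# independent density oracle: explicit closed-form formulas, no scipy
def _norm_pdf(x, mu, sigma):
    return math.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def _gamma_pdf(x, shape, scale, loc=0.0):
    z = x - loc
    if z <= 0:
        return 0.0
    return (z ** (shape - 1) * math.exp(-z / scale)
            / (math.gamma(shape) * scale ** shape))


def _gmm_pdf(x, weights, means, sigmas):
    return sum(w * _norm_pdf(x, m, s) for w, m, s in zip(weights, means, sigmas))


def eta_oracle(d, p):
    return -(p.alphas[0] * math.log(_norm_pdf(d.scanning_angle, p.scan_mu, p.scan_sigma))
             + p.alphas[1] * math.log(_gamma_pdf(d.pitch, p.pitch_shape,
                                                 p.pitch_scale, p.pitch_loc))
             + p.alphas[2] * math.log(_gmm_pdf(d.distance, p.dist_weights,
                                               p.dist_means, p.dist_sigmas)))


class TestEta:
    def test_zero_alphas_give_zero(self):
        p = ScoreParameters(scan_mu=40, scan_sigma=10, pitch_shape=2,
                            pitch_scale=5, alphas=(0, 0, 0))
        assert score_geometry(desc(), p) == 0.0
        assert score_geometry(desc(scan=179, pitch=89, dist=100), p) == 0.0

    def test_closed_form_at_normal_mode(self):
        p = ScoreParameters(scan_mu=40, scan_sigma=10, pitch_shape=2,
                            pitch_scale=5, alphas=(1, 0, 0))
        assert score_geometry(desc(scan=40.0), p) == pytest.approx(
            math.log(10 * math.sqrt(2 * math.pi)), abs=1e-12)

    def test_term_by_term_oracle_on_grid(self):
        """eta equals an independent closed-form evaluation on a grid."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = desc(scan=rng.uniform(-80, 80), pitch=rng.uniform(1, 60),
                     dist=rng.uniform(18, 38))
            assert score_geometry(d, REF) == pytest.approx(
                eta_oracle(d, REF), abs=1e-12)

    def test_linear_in_alphas(self):
        d = desc(scan=55, pitch=12, dist=28)
        base = [score_geometry(d, ScoreParameters(
            scan_mu=40, scan_sigma=10, pitch_shape=2, pitch_scale=5,
            dist_weights=REF.dist_weights, dist_means=REF.dist_means,
            dist_sigmas=REF.dist_sigmas, alphas=a))
            for a in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        mixed = score_geometry(d, ScoreParameters(
            scan_mu=40, scan_sigma=10, pitch_shape=2, pitch_scale=5,
            dist_weights=REF.dist_weights, dist_means=REF.dist_means,
            dist_sigmas=REF.dist_sigmas, alphas=(2.0, 0.5, 3.0)))
        assert mixed == pytest.approx(2.0 * base[0] + 0.5 * base[1]
                                      + 3.0 * base[2], rel=1e-12)

    def test_monotone_in_scanning_deviation(self):
        etas = [score_geometry(desc(scan=40 + delta), REF)
                for delta in (0, 5, 10, 20, 40, 80)]
        assert all(b > a for a, b in zip(etas, etas[1:]))
        # symmetric about the mean
        assert score_geometry(desc(scan=30), REF) == pytest.approx(
            score_geometry(desc(scan=50), REF), rel=1e-12)

    def test_pitch_below_support_gives_inf(self):
        p = ScoreParameters(scan_mu=40, scan_sigma=10, pitch_shape=2,
                            pitch_scale=5, pitch_loc=5.0)
        assert score_geometry(desc(pitch=2.0), p) == math.inf
        assert math.isfinite(score_geometry(desc(pitch=10.0), p))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ScoreParameters(scan_mu=0, scan_sigma=0, pitch_shape=2, pitch_scale=5)
        with pytest.raises(ParameterError):
            ScoreParameters(scan_mu=0, scan_sigma=1, pitch_shape=2,
                            pitch_scale=5, dist_weights=(0.7, 0.2))
        with pytest.raises(ParameterError):
            ScoreParameters(scan_mu=0, scan_sigma=1, pitch_shape=2,
                            pitch_scale=5, alphas=(1, 1))


class TestFitting:
    def test_parameter_recovery_within_5_percent(self):
        pool = sample_descriptor_pool(REF, 5000, seed=7)
        fit = fit_parameters(pool, k_components=2, seed=7)
        assert fit.scan_mu == pytest.approx(REF.scan_mu, rel=0.05)
        assert fit.scan_sigma == pytest.approx(REF.scan_sigma, rel=0.05)
        assert fit.pitch_shape == pytest.approx(REF.pitch_shape, rel=0.05)
        assert fit.pitch_scale == pytest.approx(REF.pitch_scale, rel=0.05)
        for got, want in zip(fit.dist_weights, REF.dist_weights):
            assert got == pytest.approx(want, rel=0.05)
        for got, want in zip(fit.dist_means, REF.dist_means):
            assert got == pytest.approx(want, rel=0.05)
        for got, want in zip(fit.dist_sigmas, REF.dist_sigmas):
            assert got == pytest.approx(want, rel=0.05)

    def test_em_loglik_non_decreasing(self):
        rng = np.random.default_rng(3)
        data = np.concatenate([rng.normal(25, 2, 300), rng.normal(31, 2, 300)])
        _, _, _, trace = fit_gmm_1d(data, 2, seed=3)
        assert len(trace) >= 2
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_single_component_reduces_to_normal_mle(self):
        rng = np.random.default_rng(4)
        data = rng.normal(28, 3, 1000)
        w, m, s, _ = fit_gmm_1d(data, 1, seed=0)
        assert w[0] == pytest.approx(1.0, abs=1e-12)
        assert m[0] == pytest.approx(data.mean(), abs=1e-9)
        assert s[0] == pytest.approx(data.std(ddof=0), abs=1e-9)

    def test_identical_distances_with_k2_raise(self):
        pool = sample_descriptor_pool(REF, 50, seed=1)
        for d in pool:
            d.distance = 25.0
        with pytest.raises(FitError):
            fit_parameters(pool, k_components=2, seed=0)

    def test_too_few_descriptors_raise(self):
        with pytest.raises(FitError):
            fit_parameters(sample_descriptor_pool(REF, 5, seed=0))

    def test_reverse_polarity_references_rejected(self):
        pool = sample_descriptor_pool(REF, 50, seed=2)
        pool[0].polarity = "reverse"
        with pytest.raises(FitError):
            fit_parameters(pool)

    def test_em_agrees_with_sklearn(self):
        """Cross-check the hand EM against scikit-learn's GaussianMixture."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(8)
        data = np.concatenate([rng.normal(25, 2, 500), rng.normal(33, 2, 500)])
        w, m, s, _ = fit_gmm_1d(data, 2, seed=8)
        gm = GaussianMixture(n_components=2, covariance_type="spherical",
                             tol=1e-8, max_iter=500, n_init=5,
                             random_state=8).fit(data.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(m, gm.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(w, gm.weights_[order], atol=0.02)
        np.testing.assert_allclose(
            s, np.sqrt(gm.covariances_[order]), atol=0.05)


class TestRanking:
    def test_natives_score_below_decoys(self):
        natives = sample_descriptor_pool(REF, 200, seed=11)
        decoys = sample_descriptor_pool(decoy_parameters(REF), 200, seed=12)
        eta_n = np.array([score_geometry(d, REF) for d in natives])
        eta_d = np.array([score_geometry(d, REF) for d in decoys])
        assert eta_n.mean() < eta_d.mean()
        assert (eta_n < np.median(eta_d)).mean() > 0.9


class TestPersistence:
    def test_round_trip_lossless(self, tmp_path):
        p = tmp_path / "params.json"
        save_parameters(REF, str(p))
        back = load_parameters(str(p))
        assert back == REF

    def test_bad_weight_sum_names_field(self, tmp_path):
        import json
        from dataclasses import asdict
        payload = asdict(REF)
        payload["dist_weights"] = [0.5, 0.4]
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(payload))
        with pytest.raises(ConfigError, match="dist_weights"):
            load_parameters(str(p))

    def test_missing_field_named(self, tmp_path):
        p = tmp_path / "missing.json"
        p.write_text('{"scan_mu": 40}')
        with pytest.raises(ConfigError, match="scan_sigma"):
            load_parameters(str(p))

    def test_minimal_handwritten_file(self, tmp_path):
        p = tmp_path / "min.json"
        p.write_text("""{
          "scan_mu": 40, "scan_sigma": 15,
          "pitch_shape": 2, "pitch_scale": 5, "pitch_loc": 0,
          "dist_weights": [1.0], "dist_means": [25.0], "dist_sigmas": [3.0],
          "alphas": [1, 1, 1]}""")
        params = load_parameters(str(p))
        assert params.k_components == 1

    def test_packaged_defaults_load(self):
        from tcrkit.scoring import default_parameters
        p = default_parameters()
        assert p.scan_sigma > 0 and sum(p.dist_weights) == pytest.approx(1.0)
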