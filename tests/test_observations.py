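import math

import numpy as np
import pytest
from scipy import stats

from cssmkit import observations as obs
from cssmkit.observations import (
    ClassObservationSpec,
    FEATURE_NAMES,
    GaussianClassModel,
    LocationSensorModel,
    extract_features,
    fit_gaussian_models,
    generate_observations,
    make_class_spec,
    pca_reduce,
    scramble,
)


def test_extract_features_constant_signal():
    x = np.full((256, 1), 3.0)
    ts, frames = extract_features(x, window=128, overlap=0.0, sampling_rate=128.0)
    assert frames.shape == (2, 6)
    mean, var, skew, kurt, peak, energy = frames[0]
    assert mean == pytest.approx(3.0)
    assert var == pytest.approx(0.0)
    assert skew == 0.0 and kurt == 0.0  # zero-variance convention
    assert peak == pytest.approx(3.0)
    assert energy == pytest.approx(9.0)
    assert ts[0] == pytest.approx((128 - 1) / 2 / 128.0)


def test_extract_features_matches_scipy_moments():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((128, 1))
    _, frames = extract_features(x, window=128, overlap=0.0)
    w = x[:, 0]
    assert frames[0, 0] == pytest.approx(w.mean())
    assert frames[0, 1] == pytest.approx(w.var())
    assert frames[0, 2] == pytest.approx(stats.skew(w))
    assert frames[0, 3] == pytest.approx(stats.kurtosis(w))  # excess kurtosis
    assert frames[0, 4] == pytest.approx(np.abs(w).max())
    assert frames[0, 5] == pytest.approx(np.mean(w ** 2))


def test_extract_features_multichannel_and_overlap():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((512, 5))
    ts, frames = extract_features(x, window=128, overlap=0.75)
    # hop = 32 samples -> (512 - 128)/32 + 1 = 13 frames; 5 channels x 6 feats
    assert frames.shape == (13, 30)
    assert len(ts) == 13
    assert np.allclose(np.diff(ts), 32 / 120.0)


def test_extract_features_validation():
    with pytest.raises(ValueError):
        extract_features(np.zeros((10, 1)), window=3)
    with pytest.raises(ValueError):
        extract_features(np.zeros((10, 1)), window=8, overlap=1.0)


def test_pca_reduce_round_trip():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((200, 10)) * np.arange(1, 11)
    tf, reduced = pca_reduce(x, k=4)
    assert reduced.shape == (200, 4)
    assert np.allclose(tf.apply(x), reduced)
    evr = np.asarray(tf.explained_variance_ratio)
    assert np.all(np.diff(evr) <= 1e-12)
    back = type(tf).from_dict(tf.to_dict())
    assert np.allclose(back.apply(x), reduced)


def test_pca_zero_variance_column():
    x = np.ones((50, 3))
    x[:, 1] = np.random.default_rng(0).standard_normal(50)
    with pytest.raises(ValueError):
        pca_reduce(x, k=2)


def test_fit_gaussian_models_recovers():
    rng = np.random.default_rng(3)
    means = {"A": np.array([0.0, 0.0]), "B": np.array([4.0, 4.0])}
    x = np.vstack([rng.standard_normal((400, 2)) + means["A"],
                   rng.standard_normal((400, 2)) + means["B"]])
    labels = ["A"] * 400 + ["B"] * 400
    m = fit_gaussian_models(x, labels)
    assert m.classes == ("A", "B")
    for c in m.classes:
        i = m.class_index[c]
        assert np.allclose(m.means[i], means[c], atol=0.2)
    # log-likelihood agrees with scipy's multivariate normal
    p = np.array([1.0, -0.5])
    ref = stats.multivariate_normal(m.means[0], m.covariances[0]).logpdf(p)
    assert m.log_likelihood_vector(p)[0] == pytest.approx(ref, abs=1e-9)
    mat = m.log_likelihood_matrix(np.vstack([p, p]))
    assert np.allclose(mat[0], m.log_likelihood_vector(p))


def test_unseen_class_gets_zero_prior():
    x = np.random.default_rng(0).standard_normal((20, 2))
    m = fit_gaussian_models(x, ["A"] * 20, class_alphabet=["A", "B"])
    assert m.priors[m.class_index["B"]] == 0.0
    assert "B" in m.unseen


def test_scramble_preserves_class_multisets():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((60, 3))
    labels = ["A"] * 20 + ["B"] * 25 + ["A"] * 15
    y = scramble(x, labels, seed=7)
    assert y.shape == x.shape
    labels = np.asarray(labels)
    for c in ("A", "B"):
        a = np.sort(x[labels == c], axis=0)
        b = np.sort(y[labels == c], axis=0)
        assert np.allclose(a, b)
    # deterministic and actually permuting
    assert np.allclose(scramble(x, labels, seed=7), y)
    assert not np.allclose(x, y)


def test_location_sensor_model(tiny_domain):
    m = LocationSensorModel(domain=tiny_domain,
                            slot_names=("loc(cup)", "stove"), epsilon=0.1)
    s = tiny_domain.initial
    # exhaustive sum over the observation space is 1
    total = 0.0
    for v1 in ("shelf", "table"):
        for v2 in ("off", "on"):
            total += math.exp(m.log_likelihood_state((v1, v2), s))
    assert total == pytest.approx(1.0)
    exact = LocationSensorModel(domain=tiny_domain, slot_names=("stove",), epsilon=0.0)
    assert exact.log_likelihood_state(("off",), s) == 0.0
    assert exact.log_likelihood_state(("on",), s) == -math.inf
    rng = np.random.default_rng(0)
    draws = [m.observe(s, rng) for _ in range(200)]
    frac_correct = np.mean([d[0] == "shelf" for d in draws])
    assert 0.8 < frac_correct < 0.98


def test_generate_observations_stats():
    spec = make_class_spec(("A", "B"), dim=4, separation=3.0, sigma=0.5)
    labels = ["A"] * 2000 + ["B"] * 2000
    x = generate_observations(labels, spec, seed=9)
    ia = spec.class_index["A"]
    assert np.allclose(x[:2000].mean(axis=0), spec.means[ia], atol=0.1)
    assert np.allclose(x[:2000].std(axis=0), 0.5, atol=0.05)
    assert np.allclose(generate_observations(labels, spec, seed=9), x)


def test_drift_pushes_run_edges():
    spec = make_class_spec(("A",), dim=3, separation=0.0, sigma=1e-9, drift=2.0)
    x = generate_observations(["A"] * 11, spec, seed=1)
    centre = np.linalg.norm(x[5] - spec.means[0])
    edge = np.linalg.norm(x[0] - spec.means[0])
    assert edge > centre
    p0 = 0.5 / 11  # first-frame midpoint position
    assert edge == pytest.approx(2.0 * 4 * (p0 - 0.5) ** 2, abs=1e-6)


def test_spec_to_gaussian_model():
    spec = make_class_spec(("A", "B", "C"), dim=5, separation=2.0, sigma=0.7)
    m = spec.to_gaussian_model()
    assert m.classes == ("A", "B", "C")
    assert np.allclose(m.priors, 1.0 / 3)
    i = m.class_index["B"]
    assert np.allclose(m.covariances[i], 0.49 * np.eye(5))
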