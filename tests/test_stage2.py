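"""Stage-2 features, Minkowski metrics and k-NN voting vs independent oracles."""

import numpy as np
import pytest
import scipy.spatial.distance as ssd
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from cddmclass.core import CDDM
from cddmclass.labels import HeartStateLabel
from cddmclass.stage2 import (
    N_FEATURES,
    PairParams,
    classify_pair,
    distance,
    extract_features,
    knn_vote,
    load_default_registry,
    normalize_metric,
)

from conftest import random_cddm

A, B = HeartStateLabel.LVH1, HeartStateLabel.MDAM


class TestExtractFeatures:
    def test_length_is_32(self, rng):
        assert extract_features(random_cddm(rng)).shape == (N_FEATURES,)

    def test_constant_channel_convention(self):
        cddm = CDDM(magnitude=np.ones((4, 4)), angle=np.zeros((4, 4)))
        feats = extract_features(cddm)
        for q in range(4):
            # magnitude channel of quadrant q: mean 1, var/kurt/skew 0
            np.testing.assert_allclose(feats[8 * q : 8 * q + 4], [1, 0, 0, 0])
            # angle channel: all zeros
            np.testing.assert_allclose(feats[8 * q + 4 : 8 * q + 8], [0, 0, 0, 0])

    def test_two_point_quadrant_moments(self):
        # quadrant values (0, 0, 1, 1): mean .5, var .25, kurt 1, skew 0
        mag = np.array(
            [[0.0, 0.0, 1, 1], [1.0, 1.0, 1, 1], [1, 1, 1, 1], [1, 1, 1, 1]]
        )
        cddm = CDDM(magnitude=mag, angle=np.zeros((4, 4)))
        mean, var, kurt, skew = extract_features(cddm)[:4]
        assert (mean, var) == pytest.approx((0.5, 0.25))
        assert kurt == pytest.approx(1.0)
        assert skew == pytest.approx(0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_moments_match_scipy_population_conventions(self, seed):
        cddm = random_cddm(np.random.default_rng(seed))
        feats = extract_features(cddm)
        from cddmclass.core import split_quadrants

        expected = []
        for mag_q, ang_q in split_quadrants(cddm):
            for ch in (mag_q, ang_q):
                v = ch.ravel()
                expected.extend(
                    [
                        v.mean(),
                        v.var(),  # population variance, divisor N
                        scipy.stats.kurtosis(v, fisher=False, bias=True),
                        scipy.stats.skew(v, bias=True),
                    ]
                )
        np.testing.assert_allclose(feats, expected, atol=1e-10)

    def test_normalization_does_not_change_shape_moments(self, rng):
        raw = rng.uniform(0.1, 5.0, (10, 10))
        ang = rng.uniform(-3, 3, (10, 10))
        a = CDDM(magnitude=raw, angle=ang)  # normalized on construction
        b = CDDM(magnitude=raw / raw.max(), angle=ang)
        fa, fb = extract_features(a), extract_features(b)
        np.testing.assert_allclose(fa, fb, atol=1e-12)
        # skewness/kurtosis of magnitude channels are scale-invariant anyway:
        # check against a *differently scaled* (unnormalized) input
        scaled_moments = []
        from cddmclass.core import split_quadrants
        from cddmclass.stage2 import _moments

        for mag_q, _ in split_quadrants(a):
            scaled_moments.append(_moments(mag_q * 7.3)[2:])
        for (mag_q, _), (kurt, skew) in zip(split_quadrants(a), scaled_moments):
            m = _moments(mag_q)
            assert m[2] == pytest.approx(kurt, abs=1e-9)
            assert m[3] == pytest.approx(skew, abs=1e-9)


class TestDistance:
    def test_known_values(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 4, 0])
        assert distance(x, y, "cityblock") == pytest.approx(6.0)
        assert distance(x, y, "chebyshev") == pytest.approx(3.0)
        assert distance(x, y, "euclidean") == pytest.approx(np.sqrt(14.0))

    def test_identity_of_indiscernibles(self, rng):
        x = rng.normal(size=32)
        for metric in ("euclidean", "cityblock", "chebyshev"):
            assert distance(x, x, metric) == 0.0

    def test_aliases_normalized(self):
        assert normalize_metric("Manhattan") == "cityblock"
        assert normalize_metric("Eucledian") == "euclidean"
        assert normalize_metric("Chebychev") == "chebyshev"
        with pytest.raises(ValueError):
            normalize_metric("cosine")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=32), rng.normal(size=32)
        assert distance(x, y, "euclidean") == pytest.approx(ssd.euclidean(x, y))
        assert distance(x, y, "cityblock") == pytest.approx(ssd.cityblock(x, y))
        assert distance(x, y, "chebyshev") == pytest.approx(ssd.chebyshev(x, y))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_ordering_and_axioms(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=16), rng.normal(size=16), rng.normal(size=16)
        d_inf = distance(x, y, "chebyshev")
        d_2 = distance(x, y, "euclidean")
        d_1 = distance(x, y, "cityblock")
        assert d_inf <= d_2 + 1e-12 and d_2 <= d_1 + 1e-12  # L∞ ≤ L2 ≤ L1
        for metric in ("euclidean", "cityblock", "chebyshev"):
            dxy = distance(x, y, metric)
            assert dxy >= 0
            assert dxy == pytest.approx(distance(y, x, metric))
            assert dxy <= distance(x, z, metric) + distance(z, y, metric) + 1e-9

    def test_permutation_symmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        perm = rng.permutation(12)
        for metric in ("euclidean", "cityblock", "chebyshev"):
            assert distance(x[perm], y[perm], metric) == pytest.approx(
                distance(x, y, metric)
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance(np.ones(3), np.ones(4), "euclidean")


def knn_oracle(query, training, k, metric):
    """Independent brute-force k-NN: full distance list + counting."""
    dists = [ssd.minkowski(query, f, {"cityblock": 1, "euclidean": 2}.get(metric, np.inf))
             if metric != "chebyshev" else ssd.chebyshev(query, f)
             for f, _ in training]
    order = sorted(range(len(training)), key=lambda i: (dists[i], i))
    top = [training[i][1] for i in order[:k]]
    counts = {}
    for lab in top:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else top[0]


class TestKnnVote:
    def _training(self, rng, n=20, spread=1.0):
        feats_a = rng.normal(0, 1, (n // 2, 32))
        feats_b = rng.normal(spread, 1, (n - n // 2, 32))
        return [(f, A) for f in feats_a] + [(f, B) for f in feats_b]

    def test_k1_returns_label_of_identical_point(self, rng):
        training = self._training(rng)
        query = training[3][0].copy()
        assert knn_vote(query, training, 1, "euclidean") == training[3][1]

    def test_majority_rule(self):
        training = [
            (np.array([0.0]), A),
            (np.array([0.1]), A),
            (np.array([0.2]), B),
            (np.array([5.0]), B),
        ]
        assert knn_vote(np.array([0.0]), training, 3, "euclidean") == A

    def test_even_split_resolved_by_nearest(self):
        training = [
            (np.array([0.0]), B),
            (np.array([1.0]), A),
            (np.array([2.0]), B),
            (np.array([3.0]), A),
        ]
        # k=4: two of each label; nearest neighbour (B at 0.0) decides
        assert knn_vote(np.array([-0.5]), training, 4, "euclidean") == B

    @pytest.mark.parametrize("metric", ["euclidean", "cityblock", "chebyshev"])
    def test_agrees_with_brute_force_oracle(self, metric):
        rng = np.random.default_rng(
            {"euclidean": 11, "cityblock": 22, "chebyshev": 33}[metric]
        )
        for trial in range(200):
            training = self._training(rng, n=15, spread=0.5)
            query = rng.normal(0.25, 1, 32)
            k = int(rng.integers(1, 8))
            assert knn_vote(query, training, k, metric) == knn_oracle(
                query, training, k, metric
            ), f"{metric} trial {trial} k={k}"

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_odd_k_agrees_with_sklearn(self, k, rng):
        from sklearn.neighbors import KNeighborsClassifier

        for _ in range(20):
            training = self._training(rng, n=16, spread=1.0)
            X = np.stack([f for f, _ in training])
            y = np.array([0 if lab == A else 1 for _, lab in training])
            clf = KNeighborsClassifier(n_neighbors=k, metric="cityblock").fit(X, y)
            query = rng.normal(0.5, 1, 32)
            ours = knn_vote(query, training, k, "cityblock")
            theirs = A if clf.predict(query[None])[0] == 0 else B
            assert ours == theirs

    def test_validation_errors(self, rng):
        training = self._training(rng, n=6)
        with pytest.raises(ValueError):
            knn_vote(rng.normal(size=32), training, 7, "euclidean")  # k > n
        with pytest.raises(ValueError):
            knn_vote(rng.normal(size=32), [], 1, "euclidean")
        three_labels = training + [(rng.normal(size=32), HeartStateLabel.CAD1)]
        with pytest.raises(ValueError):
            knn_vote(rng.normal(size=32), three_labels, 1, "euclidean")


class TestPairParamsRegistry:
    def test_listed_pairs(self):
        registry = load_default_registry()
        p = registry.lookup(HeartStateLabel.CAD2, HeartStateLabel.LVH3)
        assert (p.metric, p.k) == ("cityblock", 3)
        p = registry.lookup(HeartStateLabel.CAD1, HeartStateLabel.CAD2)
        assert (p.metric, p.k) == ("chebyshev", 7)
        # symmetric lookup
        p = registry.lookup(HeartStateLabel.LVH3, HeartStateLabel.CAD2)
        assert (p.metric, p.k) == ("cityblock", 3)

    def test_unlisted_pair_falls_back_to_default(self):
        registry = load_default_registry()
        p = registry.lookup(HeartStateLabel.CAD5, HeartStateLabel.NORM1)
        assert (p.metric, p.k) == ("cityblock", 1)

    def test_registry_size_and_same_label_rejected(self):
        registry = load_default_registry()
        assert len(registry) == 23
        with pytest.raises(ValueError):
            registry.lookup(HeartStateLabel.CAD1, HeartStateLabel.CAD1)


class TestClassifyPair:
    def test_identical_reference_map_wins_k1(self, clean_reference):
        query = next(m for m in clean_reference if m.label == A)
        params = PairParams(pair=frozenset((A, B)), metric="cityblock", k=1)
        assert classify_pair(query, clean_reference, (A, B), params) == A

    def test_low_noise_query_recovers_class(self, clean_reference):
        from cddmclass import synthetic

        config = synthetic.default_config(
            separation=1.0, magnitude_noise_sd=0.005, angle_noise_sd=0.01,
            per_group_count=4, seed=31,
        )
        query = synthetic.sample_map(
            config.template_for(A), config, np.random.default_rng(8), map_id="q"
        )
        params = PairParams(pair=frozenset((A, B)), metric="cityblock", k=3)
        assert classify_pair(query, clean_reference, (A, B), params) == A

    def test_insufficient_training_rejected(self, clean_reference, rng):
        few = [m for m in clean_reference if m.label in (A, B)][:2]
        params = PairParams(pair=frozenset((A, B)), metric="cityblock", k=5)
        with pytest.raises(ValueError):
            classify_pair(random_cddm(rng), few, (A, B), params)
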