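"""Enrollment, Mahalanobis distances, verification/identification, voting."""

import numpy as np
import pytest

from dopplerauth import (
    MahalanobisAuthenticator,
    enroll,
    identify_beat,
    identify_voted,
    mahalanobis,
    verify_beat,
    verify_voted,
)


@pytest.fixture
def gallery():
    rng = np.random.default_rng(0)
    latents = {
        1: np.array([[0.0, 0.0], [2.0, 0.0]]),
        4: np.array([[5.0, 5.0], [5.0, 7.0], [5.0, 6.0]]),
    }
    g = enroll(latents)
    g.set_threshold(1, 2.0)
    g.set_threshold(4, 2.0)
    return g


class TestEnroll:
    def test_hand_computed_center_and_variance(self, gallery):
        e = gallery[1]
        assert np.allclose(e.center, [1.0, 0.0])
        # sample variance (n-1): [2, 0] with the 0 floored at epsilon
        assert e.diag_covariance[0] == pytest.approx(2.0)
        assert e.diag_covariance[1] == pytest.approx(1e-6)
        assert e.n_enrolled == 2

    def test_identical_points_floor_variance(self):
        g = enroll({0: np.ones((3, 2))})
        assert np.all(g[0].diag_covariance == 1e-6)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((10, 4))
        a = enroll({0: Z})
        b = enroll({0: Z[::-1]})
        assert np.allclose(a[0].center, b[0].center)
        assert np.allclose(a[0].diag_covariance, b[0].diag_covariance)

    def test_single_point_rejected_with_subject_named(self):
        with pytest.raises(ValueError, match="7"):
            enroll({7: np.zeros((1, 2))})


class TestMahalanobis:
    def test_center_gives_zero(self, gallery):
        assert mahalanobis(gallery[1].center, gallery[1]) == 0.0

    def test_unit_variance_reduces_to_euclidean(self):
        g = enroll({0: np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])})
        g[0].diag_covariance[:] = 1.0
        assert mahalanobis(np.array([3.0, 4.0]), g[0]) == pytest.approx(5.0)

    def test_variance_scaled_distance(self):
        g = enroll({0: np.zeros((2, 2)) + [[0, 0], [0.1, 0.1]]})
        g[0].center[:] = 0
        g[0].diag_covariance[:] = [9.0, 1.0]
        assert mahalanobis(np.array([3.0, 0.0]), g[0]) == pytest.approx(1.0)

    def test_scaling_dimension_and_variance_leaves_distance(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((20, 3))
        g = enroll({0: Z})
        z = rng.standard_normal(3)
        d0 = mahalanobis(z, g[0])
        c = 4.0
        g2 = enroll({0: Z * [c, 1, 1]})
        assert mahalanobis(z * [c, 1, 1], g2[0]) == pytest.approx(d0, rel=1e-9)


class TestVerification:
    def test_zero_distance_accepts(self, gallery):
        ok, d = verify_beat(gallery[1].center, 1, gallery)
        assert ok and d == 0.0

    def test_distance_equal_to_threshold_rejects(self, gallery):
        e = gallery[1]
        z = e.center + [np.sqrt(e.diag_covariance[0]) * 2.0, 0]
        ok, d = verify_beat(z, 1, gallery)
        assert d == pytest.approx(2.0)
        assert not ok

    def test_acceptance_monotone_in_threshold(self, gallery):
        rng = np.random.default_rng(3)
        zs = rng.standard_normal((30, 2)) * 3
        prev = None
        for thr in [0.5, 1.0, 2.0, 4.0, 8.0]:
            acc = {i for i, z in enumerate(zs) if verify_beat(z, 1, gallery, thr)[0]}
            if prev is not None:
                assert prev <= acc
            prev = acc

    def test_unknown_claim_rejected(self, gallery):
        with pytest.raises(KeyError):
            verify_beat(np.zeros(2), 99, gallery)

    def test_missing_threshold_is_error(self):
        g = enroll({0: np.random.default_rng(0).standard_normal((4, 2))})
        with pytest.raises(ValueError):
            verify_beat(np.zeros(2), 0, g)


class TestVoting:
    def test_three_of_five_accepts(self, gallery):
        e = gallery[1]
        near, far = e.center, e.center + [50.0, 0]
        out = verify_voted(np.stack([near, near, near, far, far]), 1, gallery)
        assert out.accepted and out.votes_for == 3

    def test_two_of_five_rejects(self, gallery):
        e = gallery[1]
        near, far = e.center, e.center + [50.0, 0]
        out = verify_voted(np.stack([near, near, far, far, far]), 1, gallery)
        assert not out.accepted and out.votes_for == 2

    def test_all_zero_distances(self, gallery):
        out = verify_voted(np.tile(gallery[1].center, (5, 1)), 1, gallery)
        assert out.accepted and out.votes_for == 5
        assert np.all(out.distances == 0)

    def test_unanimous_vote_equals_per_beat_decision(self, gallery):
        z = gallery[4].center
        out = verify_voted(np.tile(z, (5, 1)), 4, gallery)
        per_beat = verify_beat(z, 4, gallery)[0]
        assert out.accepted == per_beat

    def test_wrong_group_size_rejected(self, gallery):
        with pytest.raises(ValueError):
            verify_voted(np.zeros((4, 2)), 1, gallery)


class TestIdentification:
    def test_center_identifies_owner(self, gallery):
        assert identify_beat(gallery[4].center, gallery) == 4

    def test_equidistant_tie_takes_lowest_id(self):
        g = enroll({1: np.array([[0.0, 1], [0, -1]]), 4: np.array([[2.0, 1], [2, -1]])})
        assert identify_beat(np.array([1.0, 0.0]), g) == 1

    def test_single_subject_gallery(self):
        g = enroll({3: np.random.default_rng(0).standard_normal((5, 2))})
        assert identify_beat(np.array([100.0, 100.0]), g) == 3

    def test_voted_mode(self, gallery):
        z1, z4 = gallery[1].center, gallery[4].center
        assert identify_voted(np.stack([z1, z1, z1, z4, z4]), gallery) == 1

    def test_voted_tie_broken_by_mean_distance(self, gallery):
        z1, z4 = gallery[1].center, gallery[4].center
        mid = np.stack([z1, z1, z4, z4, 0.9 * z1 + 0.1 * z4])
        winner = identify_voted(mid, gallery)
        assert winner in (1, 4)
        # the fifth latent is nearer subject 1's cluster, so 1 must win the
        # 2-2(+1) mode tie on mean distance
        assert winner == 1

    def test_gallery_insertion_order_invariance(self):
        rng = np.random.default_rng(5)
        a = {0: rng.standard_normal((5, 3)), 1: rng.standard_normal((5, 3))}
        g1 = enroll(a)
        g2 = enroll(dict(reversed(list(a.items()))))
        z = rng.standard_normal(3)
        assert identify_beat(z, g1) == identify_beat(z, g2)


class TestEstimator:
    def test_fit_predict_protocol(self):
        rng = np.random.default_rng(0)
        Z = np.concatenate([rng.standard_normal((20, 3)), 10 + rng.standard_normal((20, 3))])
        y = np.repeat([2, 5], 20)
        clf = MahalanobisAuthenticator().fit(Z, y)
        assert list(np.unique(clf.predict(Z))) == [2, 5]
        assert (clf.predict(Z) == y).mean() == 1.0
        clf.set_threshold(2, 5.0)
        assert clf.verify(Z[:5], 2).all()
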