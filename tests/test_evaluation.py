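"""Splits, LOOCV task assembly, FRR/FAR sweeps, EER and metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopplerauth import (
    BeatSpectrogram,
    DopplerRecording,
    ScoredTrial,
    build_loocv_task,
    compute_eer,
    identification_metrics,
    split_train_test,
    sweep_frr_far,
    verification_metrics,
)


def trials(gen, imp):
    return [ScoredTrial(float(d), True, 0, 0) for d in gen] + [
        ScoredTrial(float(d), False, 1, 0) for d in imp
    ]


def brute_force_eer(gen, imp):
    """Independent oracle: dense scan over all inter-score segments of the
    piecewise-linear FRR/FAR interpolants, minimizing |FRR - FAR|."""
    gen, imp = np.asarray(gen, float), np.asarray(imp, float)
    taus = np.concatenate([[-np.inf], np.unique(np.concatenate([gen, imp])), [np.inf]])
    frr = np.array([(gen >= t).mean() for t in taus])
    far = np.array([(imp < t).mean() for t in taus])
    best = (np.inf, None)
    for i in range(len(taus)):
        d = abs(frr[i] - far[i])
        if d < best[0]:
            best = (d, 0.5 * (frr[i] + far[i]))
    for i in range(1, len(taus)):
        d0, d1 = frr[i - 1] - far[i - 1], frr[i] - far[i]
        if d0 * d1 < 0:
            s = d0 / (d0 - d1)
            rate = frr[i - 1] + s * (frr[i] - frr[i - 1])
            best = min(best, (0.0, rate), key=lambda b: b[0])
    return best[1]


class TestSplit:
    def make_rec(self, duration=60.0, peaks=(), fs=250.0):
        return DopplerRecording(
            0, fs, np.arange(int(duration * fs), dtype=float),
            rpeak_indices=np.asarray(peaks, dtype=np.int64) if len(peaks) else None,
        )

    def test_sample_counts_48_12(self):
        tr, te = split_train_test(self.make_rec(), 48, 12)
        assert len(tr.samples) == 12000 and len(te.samples) == 3000

    def test_boundary_peak_goes_to_test(self):
        rec = self.make_rec(peaks=[11999, 12000, 14000])
        tr, te = split_train_test(rec, 48, 12)
        assert list(tr.rpeak_indices) == [11999]
        assert list(te.rpeak_indices) == [0, 2000]  # shifted into test time

    def test_insufficient_duration_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self.make_rec(duration=50), 48, 12)


def spectro_dataset(n_subjects=5, n_train=22, n_test=8):
    rng = np.random.default_rng(0)
    ds = {}
    for sid in range(n_subjects):
        ds[sid] = {
            "train": [
                BeatSpectrogram(sid, rng.random((4, 4)), "train", order=i)
                for i in range(n_train)
            ],
            "test": [
                BeatSpectrogram(sid, rng.random((4, 4)), "test", order=i)
                for i in range(n_test)
            ],
        }
    return ds


class TestLoocvTask:
    def test_impostor_fraction_and_labels(self):
        ds = spectro_dataset(5, n_train=22)
        task = build_loocv_task(ds, held_out_subject=0, target_subject=1, seed=3)
        # K=5 -> each of the 3 other subjects contributes floor(22/3)=7
        assert int((task.y_train == 1).sum()) == 22
        assert int((task.y_train == 0).sum()) == 3 * 7
        assert set(task.impostor_probes) == {0, 2, 3, 4}
        assert set(task.genuine_probes) == {1}

    def test_held_out_subject_excluded_from_training(self):
        ds = spectro_dataset(4)
        held_values = np.stack([s.values for s in ds[2]["train"]])
        task = build_loocv_task(ds, held_out_subject=2, target_subject=0, seed=0)
        for row in task.X_train:
            assert not any(np.array_equal(row, hv) for hv in held_values)

    def test_seeded_subsample_is_deterministic(self):
        ds = spectro_dataset(5)
        a = build_loocv_task(ds, 0, 1, seed=9)
        b = build_loocv_task(ds, 0, 1, seed=9)
        assert np.array_equal(a.X_train, b.X_train)

    def test_invalid_subjects_rejected(self):
        ds = spectro_dataset(3)
        with pytest.raises(ValueError):
            build_loocv_task(ds, 0, 0, seed=0)
        with pytest.raises(ValueError):
            build_loocv_task(ds, 9, 0, seed=0)


class TestSweep:
    def test_hand_counted_separated_case(self):
        taus, frr, far = sweep_frr_far(trials([1, 2], [3, 4]))
        eer, thr = compute_eer(taus, frr, far)
        assert eer == 0.0
        assert 2 < thr <= 3  # any threshold between the populations works

    def test_accept_all_and_reject_all_limits(self):
        taus, frr, far = sweep_frr_far(trials([1, 2], [3, 4]))
        assert frr[0] == 1.0 and far[0] == 0.0  # tau -> -inf
        assert frr[-1] == 0.0 and far[-1] == 1.0  # tau -> +inf

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            sweep_frr_far(trials([1, 2], []))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=25),
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=25),
    )
    def test_curve_monotonicity(self, gen, imp):
        taus, frr, far = sweep_frr_far(trials(gen, imp))
        assert np.all(np.diff(frr) <= 1e-12)
        assert np.all(np.diff(far) >= -1e-12)


class TestEer:
    def test_identical_score_sets_give_half(self):
        taus, frr, far = sweep_frr_far(trials([1, 2, 3], [1, 2, 3]))
        eer, _ = compute_eer(taus, frr, far)
        assert eer == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_g, n_i = rng.integers(2, 25, size=2)
            gen = rng.gamma(2, 1, n_g)
            imp = rng.gamma(2, 1, n_i) + rng.uniform(0, 2)
            taus, frr, far = sweep_frr_far(trials(gen, imp))
            eer, _ = compute_eer(taus, frr, far)
            assert eer == pytest.approx(brute_force_eer(gen, imp), abs=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ScoredTrial(-1.0, True, 0, 0)


class TestMetricIdentities:
    def test_hand_confusion_fixture(self):
        dec = [(True, True)] * 9 + [(True, False)] + [(False, False)] * 8 + [
            (False, True)
        ] * 2
        m = verification_metrics(dec)
        assert m["bac"] == pytest.approx(0.85)
        assert m["tp"] == 9 and m["fn"] == 1 and m["tn"] == 8 and m["fp"] == 2
        assert m["f1"] == pytest.approx(2 * 9 / (2 * 9 + 2 + 1))

    def test_perfect_and_chance_decisions(self):
        perfect = [(True, True)] * 5 + [(False, False)] * 5
        m = verification_metrics(perfect)
        assert m["bac"] == 1.0 and m["f1"] == 1.0
        all_accept = [(True, True)] * 5 + [(False, True)] * 5
        assert verification_metrics(all_accept)["bac"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            verification_metrics([(True, True)])

    def test_identification_accuracies(self):
        assert identification_metrics([1, 2, 3], [1, 2, 3])["acc"] == 1.0
        m = identification_metrics([1, 1, 1, 1], [1, 1, 2, 2])
        assert m["macro_acc"] == pytest.approx(0.5)
        m3 = identification_metrics([0, 0, 1, 2, 9, 9], [0, 0, 1, 1, 2, 2])
        assert m3["macro_acc"] == pytest.approx(np.mean([1.0, 0.5, 0.0]))
        with pytest.raises(ValueError):
            identification_metrics([1], [1, 2])


def test_voted_trial_reduces_to_median_distance():
    """3-of-5 voting at threshold tau accepts exactly when the median of the
    five distances is below tau."""
    from dopplerauth import enroll, verify_voted

    rng = np.random.default_rng(4)
    g = enroll({0: rng.standard_normal((10, 3))})
    for _ in range(20):
        Z = rng.standard_normal((5, 3)) * rng.uniform(0.5, 3)
        tau = rng.uniform(0.2, 4)
        g.set_threshold(0, tau)
        out = verify_voted(Z, 0, g)
        assert out.accepted == (np.median(out.distances) < tau)
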