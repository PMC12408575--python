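"""Morlet CWT, spectrogram normalization, five-beat averaging, augmentation."""

import numpy as np
import pytest

from dopplerauth import (
    BeatSpectrogram,
    CwtGrid,
    augment,
    cwt_morlet,
    moving_average_5,
    to_spectrogram,
)
from dopplerauth.wavelet import MORLET_OMEGA0, cwt_morlet_batch, _time_shift


def quadrature_cwt(x, grid):
    """Independent oracle: direct Riemann sum of the CWT integral with the
    Morlet mother wavelet, scale by scale and shift by shift."""
    n = len(x)
    out = np.zeros((grid.n_freq, n), dtype=complex)
    for i, a in enumerate(grid.scales):
        for b in range(n):
            u = (np.arange(n) - b) / a
            psi = np.pi ** (-0.25) * np.exp(1j * MORLET_OMEGA0 * u) * np.exp(-u**2 / 2)
            out[i, b] = np.sum(x * np.conj(psi)) / np.sqrt(a)
    return out


class TestCwt:
    def test_scale_frequency_relation(self):
        grid = CwtGrid()
        expected = MORLET_OMEGA0 * grid.fs / (2 * np.pi * np.asarray(grid.frequencies))
        assert np.allclose(grid.scales, expected)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            CwtGrid(fs=125.0, frequencies=(70.0, 30.0))

    def test_sinusoid_maps_to_matching_row(self):
        grid = CwtGrid()
        t = np.arange(64) / 125.0
        W = cwt_morlet(np.sin(2 * np.pi * 30 * t), grid)
        row = int(np.argmax(np.mean(np.abs(W), axis=1)))
        nearest = int(np.argmin(np.abs(np.asarray(grid.frequencies) - 30.0)))
        assert abs(row - nearest) <= 1

    def test_zero_input_zero_output(self):
        assert np.all(cwt_morlet(np.zeros(64)) == 0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        Wx, Wy, Wxy = cwt_morlet(x), cwt_morlet(y), cwt_morlet(x + y)
        assert np.max(np.abs(Wxy - Wx - Wy)) <= 1e-10 * np.max(np.abs(Wxy))

    def test_agrees_with_quadrature_oracle_on_chirp(self):
        grid = CwtGrid(n_freq=16)
        t = np.arange(64) / 125.0
        chirp = np.sin(2 * np.pi * (15 * t + 25 * t**2))
        W = cwt_morlet(chirp, grid)
        O = quadrature_cwt(chirp, grid)
        assert np.max(np.abs(W - O)) / np.max(np.abs(O)) < 0.01

    def test_batch_matches_single(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 64))
        batch = cwt_morlet_batch(X)
        for i in range(3):
            assert np.allclose(batch[i], cwt_morlet(X[i]))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            cwt_morlet(np.zeros(4))


class TestSpectrogram:
    def test_minmax_contract(self):
        rng = np.random.default_rng(0)
        v = to_spectrogram(rng.standard_normal((8, 64)) + 1j)
        assert v.min() == 0.0 and v.max() == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((8, 64)) + 1j * rng.standard_normal((8, 64))
        assert np.allclose(to_spectrogram(W), to_spectrogram(10 * W))

    def test_constant_input_guarded_to_zeros(self):
        assert np.all(to_spectrogram(np.full((8, 64), 3.0 + 0j)) == 0)

    def test_time_axis_resampling(self):
        rng = np.random.default_rng(0)
        assert to_spectrogram(rng.random((8, 100)), n_time=64).shape == (8, 64)


class TestMovingAverage:
    def test_five_identical_inputs_pass_through(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        out = moving_average_5([img] * 5)
        assert len(out) == 1
        # pass-through up to the re-normalization of the mean
        expected = (img - img.min()) / (img.max() - img.min())
        assert np.allclose(out[0], expected)

    def test_output_length_arithmetic(self):
        rng = np.random.default_rng(0)
        assert len(moving_average_5([rng.random((4, 4)) for _ in range(6)])) == 2
        assert moving_average_5([rng.random((4, 4)) for _ in range(4)]) == []

    def test_alternating_extremes_average_to_two_fifths(self):
        """zeros/ones/zeros/ones/zeros -> elementwise mean 0.4, which the
        re-normalization guard then maps to the all-zero image."""
        seq = [np.zeros((4, 4)), np.ones((4, 4))] * 2 + [np.zeros((4, 4))]
        assert np.mean(np.stack(seq), axis=0) == pytest.approx(0.4)
        out = moving_average_5(seq)
        assert len(out) == 1 and np.all(out[0] == 0.0)


class TestAugment:
    def make_set(self, n=3, subjects=(0, 0, 1)):
        rng = np.random.default_rng(5)
        return [
            BeatSpectrogram(subjects[i], rng.random((8, 8)), order=i)
            for i in range(n)
        ]

    def test_each_input_spawns_at_least_four_copies(self):
        items = self.make_set()
        out = augment(items, seed=0)
        originals = [s for s in out if not s.augmented]
        created = [s for s in out if s.augmented]
        assert originals == items
        # subject 1 is a single-member class: no mixup for it
        assert len(created) >= 4 * len(items)

    def test_single_member_class_skips_mixup(self):
        items = [BeatSpectrogram(7, np.random.default_rng(0).random((8, 8)))]
        out = augment(items, seed=0)
        assert len(out) == 1 + 4  # shifts x2, stretch, noise; no mixup

    def test_shift_bookkeeping(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 8))
        back = _time_shift(_time_shift(v, +2), -2)
        assert np.allclose(back[:, :-4], v[:, :-4])  # interior columns intact
        assert np.allclose(back[:, -3:], back[:, [-3]])  # replicated edge

    def test_mixup_outputs_within_pair_envelope(self):
        items = self.make_set(4, subjects=(0, 0, 0, 0))
        out = augment(items, seed=1)
        lo = np.min([s.values for s in items], axis=0)
        hi = np.max([s.values for s in items], axis=0)
        # each input emits 5 augmented copies in order; the mixup is the 5th
        mix = [out[len(items) + 5 * i + 4] for i in range(len(items))]
        for s in mix:
            assert np.all(s.values >= lo - 1e-12) and np.all(s.values <= hi + 1e-12)

    def test_values_stay_in_unit_interval_and_deterministic(self):
        items = self.make_set()
        a = augment(items, seed=3)
        b = augment(items, seed=3)
        assert len(a) == len(b)
        for s, t in zip(a, b):
            assert np.array_equal(s.values, t.values)
            assert s.values.min() >= 0.0 and s.values.max() <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            augment([], seed=0)


def test_energy_localizes_at_template_frequencies():
    """For a pure damped-sinusoid beat, spectrogram mass concentrates in the
    rows covering the atom frequency +- 5 Hz."""
    from dopplerauth import SubjectProfile, render_beat_template

    # the Morlet's relative bandwidth is 1/w0 (~f/6), so a +-5 Hz band can
    # hold >= 80% of the energy only for atoms near the low band edge where
    # the wavelet line width stays inside the window
    p = SubjectProfile(0, ((18.0, 1.0, 0.05, 0.08),), 0.9, 0.0, 0.3, 5.0)
    beat = render_beat_template(p, 125.0)[:64]
    grid = CwtGrid()
    energy = np.abs(cwt_morlet(beat, grid)) ** 2
    freqs = np.asarray(grid.frequencies)
    band = (freqs >= 13.0) & (freqs <= 23.0)
    assert energy[band].sum() / energy.sum() >= 0.8
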