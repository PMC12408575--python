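"""Morlet CWT beat spectrograms, five-beat averaging, and augmentation.

Each gated beat segment is transformed with the continuous wavelet transform

    W(a, b) = |a|^(-1/2) * sum_t x[t] * conj(psi((t - b) / a))

using the Morlet mother wavelet psi(t) = pi^(-1/4) exp(i w0 t) exp(-t^2 / 2)
with center angular frequency w0 = 6.  The scale for a target frequency f is
a = w0 * fs / (2 * pi * f) (in samples), so each row of the coefficient
matrix reads out one frequency.  Magnitudes are min-max scaled to [0, 1] per
beat and resampled to a fixed time axis, giving square images for the
convolutional encoder.  The CWT is preferred over the STFT here because a
fixed STFT window cannot resolve both the short beat transient in time and
the 15-50 Hz band in frequency at once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MORLET_OMEGA0",
    "CwtGrid",
    "BeatSpectrogram",
    "cwt_morlet",
    "cwt_morlet_batch",
    "to_spectrogram",
    "moving_average_5",
    "augment",
]

logger = logging.getLogger(__name__)

#: Morlet center angular frequency (dimensionless, in units of 1/samples
#: after scaling); 6 gives a good time-frequency resolution trade-off and is
#: the standard admissibility-safe choice.
MORLET_OMEGA0 = 6.0


@dataclass(frozen=True)
class CwtGrid:
    """Frequency grid of the transform.

    Frequencies are stored descending (row 0 = highest frequency) and must
    lie strictly below the Nyquist rate.  The default covers 10-60 Hz at
    125 Hz sampling with 64 log-spaced rows: the 15-50 Hz heartbeat band
    plus margins on both sides.
    """

    fs: float = 125.0
    frequencies: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    f_min: float = 10.0
    f_max: float = 60.0
    n_freq: int = 64

    def __post_init__(self) -> None:
        if self.frequencies is None:
            freqs = np.geomspace(self.f_max, self.f_min, self.n_freq)
            object.__setattr__(self, "frequencies", tuple(float(f) for f in freqs))
        else:
            object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
            object.__setattr__(self, "n_freq", len(self.frequencies))
        for f in self.frequencies:
            if not (0 < f < self.fs / 2):
                raise ValueError(f"grid frequency {f} Hz outside (0, Nyquist={self.fs/2})")

    @property
    def scales(self) -> np.ndarray:
        """Morlet scale (in samples) for each grid frequency."""
        f = np.asarray(self.frequencies)
        return MORLET_OMEGA0 * self.fs / (2 * np.pi * f)


def _morlet_conj(u: np.ndarray) -> np.ndarray:
    return np.pi ** (-0.25) * np.exp(-1j * MORLET_OMEGA0 * u) * np.exp(-(u ** 2) / 2.0)


_KERNEL_CACHE: dict[tuple, np.ndarray] = {}


def _grid_kernel(grid: CwtGrid, n: int) -> np.ndarray:
    """(n_freq * n, n) matrix applying the discretized CWT to one segment."""
    key = (grid.fs, grid.frequencies, n)
    if key not in _KERNEL_CACHE:
        scales = grid.scales  # samples
        t = np.arange(n)
        # K[f, b, t] = conj(psi((t-b)/a_f)) / sqrt(a_f)
        u = (t[None, None, :] - t[None, :, None]) / scales[:, None, None]
        K = _morlet_conj(u) / np.sqrt(scales)[:, None, None]
        _KERNEL_CACHE[key] = K.reshape(grid.n_freq * n, n).astype(np.complex128)
    return _KERNEL_CACHE[key]


def cwt_morlet(segment: np.ndarray, grid: CwtGrid | None = None) -> np.ndarray:
    """Morlet CWT of one beat segment -> complex (n_freq, n_samples) matrix.

    The integral is discretized as a plain Riemann sum over the segment
    support (the signal is taken as zero outside the window), which keeps the
    transform exactly linear and identical to direct quadrature.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("segment must be 1-D with at least 8 samples")
    grid = grid or CwtGrid()
    K = _grid_kernel(grid, x.size)
    return (K @ x).reshape(grid.n_freq, x.size)


def cwt_morlet_batch(segments: np.ndarray, grid: CwtGrid | None = None) -> np.ndarray:
    """Vectorized CWT of (n_segments, n_samples) -> (n_segments, n_freq, n_samples)."""
    X = np.asarray(segments, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 8:
        raise ValueError("segments must be (n_segments, n_samples >= 8)")
    grid = grid or CwtGrid()
    K = _grid_kernel(grid, X.shape[1])
    W = (K @ X.T).reshape(grid.n_freq, X.shape[1], X.shape[0])
    return np.ascontiguousarray(W.transpose(2, 0, 1))


@dataclass
class BeatSpectrogram:
    """One normalized time-frequency image of a beat, with its label."""

    subject_id: int
    values: np.ndarray  # (n_freq, n_time) in [0, 1]
    split_tag: str = "train"
    augmented: bool = False
    order: int = 0  # chronological index within the subject's split


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo == 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def to_spectrogram(coefficients: np.ndarray, n_time: int = 64) -> np.ndarray:
    """Magnitude + per-image min-max scaling + time-axis resampling.

    A constant coefficient matrix maps to all zeros (guarded division).
    """
    mag = np.abs(np.asarray(coefficients))
    if mag.shape[1] != n_time:
        old = np.linspace(0.0, 1.0, mag.shape[1])
        new = np.linspace(0.0, 1.0, n_time)
        mag = np.stack([np.interp(new, old, row) for row in mag])
    return _minmax(mag)


def moving_average_5(spectrograms: list[np.ndarray] | np.ndarray) -> list[np.ndarray]:
    """Sliding five-beat elementwise mean over time-ordered same-subject beats.

    Averaging over five consecutive beats suppresses beat-to-beat noise while
    keeping the subject's morphology; output length is ``len - 4`` (an input
    shorter than five beats yields an empty list).  Each averaged image is
    re-scaled to [0, 1].
    """
    arr = [np.asarray(s) for s in spectrograms]
    if len(arr) < 5:
        return []
    stack = np.stack(arr)
    kernel_view = np.lib.stride_tricks.sliding_window_view(stack, 5, axis=0)
    means = kernel_view.mean(axis=-1)
    return [_minmax(m) for m in means]


def _time_shift(v: np.ndarray, shift: int) -> np.ndarray:
    """Shift columns by ``shift`` (positive = later), replicating edge columns."""
    out = np.empty_like(v)
    if shift > 0:
        out[:, shift:] = v[:, :-shift]
        out[:, :shift] = v[:, [0]]
    elif shift < 0:
        out[:, :shift] = v[:, -shift:]
        out[:, shift:] = v[:, [-1]]
    else:
        out[...] = v
    return out


def _time_stretch(v: np.ndarray, factor: float) -> np.ndarray:
    """Rescale the time axis by ``factor`` then resample back to n_time."""
    n_time = v.shape[1]
    stretched_len = max(8, int(round(n_time * factor)))
    old = np.linspace(0.0, 1.0, n_time)
    mid = np.linspace(0.0, 1.0, stretched_len)
    stretched = np.stack([np.interp(mid, old, row) for row in v])
    back = np.stack([np.interp(old, mid, row) for row in stretched])
    return np.clip(back, 0.0, 1.0)


def augment(
    spectrograms: list[BeatSpectrogram],
    seed: int,
    stretch_range: tuple[float, float] = (0.9, 1.1),
    noise_sd: float = 0.05,
    mixup_alpha: float = 0.2,
    mixup_cross_class: bool = False,
) -> list[BeatSpectrogram]:
    """Enlarge a training spectrogram set; originals are retained.

    Per input item: two time-shift copies (+-2 columns, edge replication),
    one time-stretch copy (factor uniform in ``stretch_range``), one additive
    white-noise copy (sd ``noise_sd``, clipped to [0, 1]), and one mixup copy
    lambda*A + (1-lambda)*B with lambda ~ Beta(alpha, alpha).  Mixup partners
    are drawn within the same subject label (the latent prior is conditioned
    on the label, so cross-class mixing would corrupt the conditional target)
    unless ``mixup_cross_class`` is set; single-member classes skip mixup.
    """
    if not spectrograms:
        raise ValueError("augment requires a non-empty spectrogram set")
    rng = np.random.default_rng(int(seed))
    by_label: dict[int, list[int]] = {}
    for i, s in enumerate(spectrograms):
        by_label.setdefault(s.subject_id, []).append(i)

    out = list(spectrograms)

    def emit(src: BeatSpectrogram, values: np.ndarray) -> None:
        out.append(
            BeatSpectrogram(
                subject_id=src.subject_id,
                values=np.clip(values, 0.0, 1.0),
                split_tag=src.split_tag,
                augmented=True,
                order=src.order,
            )
        )

    for i, s in enumerate(spectrograms):
        v = s.values
        emit(s, _time_shift(v, +2))
        emit(s, _time_shift(v, -2))
        emit(s, _time_stretch(v, float(rng.uniform(*stretch_range))))
        emit(s, v + rng.normal(0.0, noise_sd, size=v.shape))
        pool = (
            list(range(len(spectrograms)))
            if mixup_cross_class
            else by_label[s.subject_id]
        )
        partners = [j for j in pool if j != i]
        if not partners:
            logger.info(
                "mixup skipped for subject %s: single-member class", s.subject_id
            )
            continue
        j = int(rng.choice(partners))
        lam = float(rng.beta(mixup_alpha, mixup_alpha))
        emit(s, lam * v + (1.0 - lam) * spectrograms[j].values)
    return out
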