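"""Band-limiting, downsampling, beat segmentation and SNR gating.

The heartbeat micro-vibration sits in the 15-50 Hz band, respiration below
10 Hz, power-line interference at 60 Hz.  A zero-phase 15-50 Hz band-pass
therefore isolates the cardiac component; the filtered waveform is decimated
to 125 Hz, cut into fixed windows centered on each beat, scored by a simple
peak-to-mean SNR and gated (>= 4 to enter the training split, >= 6 for the
test split - the stricter test gate keeps evaluation beats clean while the
looser training gate deliberately admits noisier examples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from dopplerauth.synth import DopplerRecording

__all__ = [
    "FilterSpec",
    "BeatSegment",
    "bandpass",
    "downsample_to_125",
    "segment_beats",
    "segment_snr",
    "gate_segments",
    "TRAIN_SNR_THRESHOLD",
    "TEST_SNR_THRESHOLD",
]

TRAIN_SNR_THRESHOLD = 4.0
TEST_SNR_THRESHOLD = 6.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification.  Defaults give the 15-50 Hz heartbeat band.

    The filter is a Chebyshev-II band-pass applied forward-backward
    (zero phase).  The order is chosen from the stopband requirement:
    >= 40 dB of two-pass attenuation at 0.3 Hz and at 60 Hz with < 1 dB of
    passband loss at 30 Hz.  A low-order Butterworth cannot reach 40 dB at
    60 Hz from a 50 Hz band edge, hence the equiripple-stopband design.
    """

    low_cut: float = 15.0
    high_cut: float = 50.0
    order: int | None = None  # None -> order from cheb2ord for the spec below
    zero_phase: bool = True
    # stopband edges / one-pass attenuation used when order is None
    stop_low: float = 7.5
    stop_high: float = 60.0
    gstop_db: float = 21.0
    gpass_db: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    if fs <= 2 * spec.high_cut:
        raise ValueError(
            f"fs={fs} Hz too low for a {spec.high_cut} Hz band edge (need fs > {2*spec.high_cut})"
        )
    wp = [spec.low_cut, spec.high_cut]
    ws = [spec.stop_low, min(spec.stop_high, 0.499 * fs)]
    if spec.order is None:
        order, wn = signal.cheb2ord(wp, ws, spec.gpass_db, spec.gstop_db, fs=fs)
    else:
        order, wn = spec.order, ws
    return signal.cheby2(order, spec.gstop_db, wn, btype="bandpass", output="sos", fs=fs)


def bandpass(recording: DopplerRecording, spec: FilterSpec | None = None) -> DopplerRecording:
    """Zero-phase band-pass; output length equals input length.

    Peak annotations are carried through unchanged (zero phase means beat
    instants do not move).
    """
    spec = spec or FilterSpec()
    sos = _design_sos(spec, recording.fs)
    x = recording.samples
    if spec.zero_phase:
        y = signal.sosfiltfilt(sos, x)
    else:
        y = signal.sosfilt(sos, x)
    return DopplerRecording(
        subject_id=recording.subject_id,
        fs=recording.fs,
        samples=np.asarray(y),
        rpeak_indices=None if recording.rpeak_indices is None else recording.rpeak_indices.copy(),
    )


def downsample_to_125(recording: DopplerRecording) -> DopplerRecording:
    """Anti-aliased decimation 250 Hz -> 125 Hz with remapped peak indices.

    Only the 250 Hz acquisition path is supported.  Peak indices map as
    ``i -> i // 2`` (round-half-down) and the output length is ``n // 2``.
    """
    if recording.fs != 250.0:
        raise ValueError(f"unsupported sampling rate {recording.fs}; expected 250 Hz")
    n = len(recording.samples)
    # zero-phase anti-alias low-pass at the new Nyquist, then take every 2nd
    sos = signal.cheby1(8, 0.05, 0.8 * 62.5, btype="low", output="sos", fs=250.0)
    y = signal.sosfiltfilt(sos, recording.samples)[: 2 * (n // 2) : 2]
    peaks = None
    if recording.rpeak_indices is not None:
        # peaks one sample apart at 250 Hz can collide at 125 Hz: dedupe
        peaks = np.unique(recording.rpeak_indices // 2)
        peaks = peaks[peaks < n // 2]
    return DopplerRecording(
        subject_id=recording.subject_id, fs=125.0, samples=y, rpeak_indices=peaks
    )


@dataclass
class BeatSegment:
    """A fixed-length window around one detected beat peak."""

    subject_id: int
    center_index: int
    samples: np.ndarray
    snr: float = np.nan
    split_tag: str = "train"


def segment_beats(
    recording: DopplerRecording,
    peak_indices: np.ndarray | None = None,
    window_len: int = 64,
    split_tag: str = "train",
) -> list[BeatSegment]:
    """Cut one window per peak, centered on the peak.

    Peaks closer than ``window_len // 2`` to either edge are dropped rather
    than padded; padding would distort both the SNR score and the wavelet
    transform at the edges.  SNR is filled in by :func:`segment_snr`.
    """
    if window_len % 2 != 0:
        raise ValueError("window_len must be even")
    if peak_indices is None:
        peak_indices = recording.rpeak_indices
    if peak_indices is None or len(peak_indices) == 0:
        return []
    half = window_len // 2
    x = recording.samples
    segments = []
    for p in np.asarray(peak_indices, dtype=np.int64):
        lo, hi = p - half, p + half
        if lo < 0 or hi > len(x):
            continue
        seg = BeatSegment(
            subject_id=recording.subject_id,
            center_index=int(p),
            samples=x[lo:hi].copy(),
            split_tag=split_tag,
        )
        seg.snr = segment_snr(seg)
        segments.append(seg)
    return segments


def segment_snr(segment: BeatSegment | np.ndarray) -> float:
    """Peak-to-mean SNR: max(|x|) / mean(|x|) over the window.

    The beat's peak excursion is the signal; the mean rectified amplitude of
    the whole window stands in for the noise floor.
    """
    x = segment.samples if isinstance(segment, BeatSegment) else np.asarray(segment)
    if x.size == 0:
        raise ValueError("empty segment")
    a = np.abs(x)
    m = a.mean()
    if m == 0:
        raise ValueError("degenerate all-zero segment")
    return float(a.max() / m)


def gate_segments(
    segments: list[BeatSegment], split_tag: str, threshold: float | None = None
) -> list[BeatSegment]:
    """Keep segments whose SNR clears the split's gate (train >= 4, test >= 6).

    ``threshold`` overrides the split's default gate when given.
    """
    if split_tag == "train":
        thr = TRAIN_SNR_THRESHOLD if threshold is None else threshold
    elif split_tag == "test":
        thr = TEST_SNR_THRESHOLD if threshold is None else threshold
    else:
        raise ValueError(f"unknown split tag {split_tag!r}")
    return [s for s in segments if s.snr >= thr]
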