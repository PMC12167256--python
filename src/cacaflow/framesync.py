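"""Image-derived cardiac-phase synchronization.

The ECG is usually not exportable from angiography equipment, so an
ECG-like surrogate is derived from the images themselves: for each frame
k the normalized Euclidean distance to the first frame,

    S_k = ||f_0 - f_k||_F / (||f_0||_F + ||f_k||_F),

which oscillates with the cardiac cycle (the triangle inequality bounds
it to [0, 1]).  The fundamental frequency of S_k is estimated with an
FFT, restricted to a plausible heart-rate band, and its reciprocal gives
the cardiac period in frames.  Annotated non-contrast frames are then
paired with the first congruent (same phase modulo the period)
contrast-enhanced frame.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import FrameSequence

__all__ = ["SyncResult", "distance_signal", "estimate_period", "pair_frames", "synchronize"]

# Plausible heart-rate band for the spectral peak, in Hz (30-180 bpm).
HEART_RATE_BAND_HZ = (0.5, 3.0)


@dataclasses.dataclass
class SyncResult:
    signal: np.ndarray                     # S_k for k = 1 .. n_frames-1
    fundamental_frequency: float           # cycles per frame
    period: int                            # frames, >= 2
    pairs: list[tuple[int, int]]           # (non_contrast_index, contrast_index)


def distance_signal(seq: FrameSequence) -> np.ndarray:
    """Normalized frame-to-reference distance S_k for k = 1..N-1."""
    frames = np.asarray(seq.frames, dtype=np.float64)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    f0 = frames[0]
    norm0 = np.linalg.norm(f0)
    diffs = frames[1:] - f0[None]
    num = np.sqrt((diffs * diffs).sum(axis=(1, 2)))
    normk = np.sqrt((frames[1:] ** 2).sum(axis=(1, 2)))
    den = norm0 + normk
    out = np.zeros(frames.shape[0] - 1, dtype=np.float64)
    nonzero = den > 0
    if not nonzero.all():
        warnings.warn("all-zero frame pair(s): distance defined as 0 there")
    out[nonzero] = num[nonzero] / den[nonzero]
    return out


def estimate_period(
    signal: np.ndarray,
    fps: float,
    band_hz: tuple[float, float] = HEART_RATE_BAND_HZ,
) -> tuple[float, int]:
    """Estimate the fundamental frequency (cycles/frame) and integer period.

    The mean is removed (the raw signal has a large DC offset), the
    discrete Fourier transform taken, and the positive-frequency bin of
    maximum magnitude selected inside the heart-rate band.  The period is
    the reciprocal peak frequency rounded to the nearest integer number
    of frames, ties rounding down.
    """
    s = np.asarray(signal, dtype=np.float64)
    if s.size < 4:
        raise ValueError("signal too short for period estimation")
    ac = s - s.mean()
    if np.allclose(ac, 0.0):
        raise ValueError("no periodicity detected: signal is constant")
    spectrum = np.abs(np.fft.rfft(ac))
    freqs = np.fft.rfftfreq(s.size)                   # cycles per frame
    in_band = (freqs * fps >= band_hz[0]) & (freqs * fps <= band_hz[1])
    in_band[0] = False                                # never the DC bin
    if not in_band.any():
        raise ValueError(
            f"no FFT bins inside the heart-rate band {band_hz} Hz at fps={fps}"
        )
    candidates = np.flatnonzero(in_band)
    peak = candidates[np.argmax(spectrum[candidates])]
    if spectrum[peak] <= 0:
        raise ValueError("no periodicity detected in the heart-rate band")
    f_peak = float(freqs[peak])
    period = int(np.ceil(1.0 / f_peak - 0.5))         # half-integers round down
    period = max(period, 2)
    return f_peak, period


def pair_frames(
    seq: FrameSequence, period: int, annotated: list[int]
) -> list[tuple[int, int]]:
    """Pair each annotated non-contrast frame with the smallest
    phase-congruent contrast-enhanced frame index."""
    if period < 2:
        raise ValueError("period must be >= 2 frames")
    onset, n = seq.contrast_onset, len(seq)
    pairs = []
    for k in annotated:
        if not 0 <= k < onset:
            raise ValueError(f"annotated frame {k} is not a non-contrast frame (onset {onset})")
        partner = onset + (-(onset - k)) % period
        if partner >= n:
            raise ValueError(
                f"no contrast frame congruent to annotated frame {k} modulo "
                f"{period} exists in a {n}-frame sequence"
            )
        pairs.append((k, partner))
    return pairs


def synchronize(
    seq: FrameSequence,
    annotated: list[int] | None = None,
    use_noncontrast_only: bool = True,
) -> SyncResult:
    """Full synchronization: signal, period, and frame pairs.

    By default the period is estimated from the non-contrast portion of
    the signal only, because contrast inflow distorts the oscillation;
    set use_noncontrast_only=False to use the whole signal.
    """
    signal = distance_signal(seq)
    segment = signal[: seq.contrast_onset - 1] if use_noncontrast_only else signal
    freq, period = estimate_period(segment, seq.fps)
    if annotated is None:
        annotated = list(range(seq.contrast_onset))
    pairs = pair_frames(seq, period, annotated)
    return SyncResult(signal=signal, fundamental_frequency=freq, period=period, pairs=pairs)
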