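"""Vibration-side features: RMS envelope, scalar descriptors, and MFCC.

The RMS envelope is the vibration analogue of the uroflow curve; from it
come the four scalars mirrored on the uroflow parameters (RMS magnitude,
Mmax, signal time, time to Mmax). The MFCC spectrogram is the fixed-size
time-frequency representation consumed by the CNN classifier.

All times are in seconds with 0 at record start; envelope and frame ``i``
are stamped at their window centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal.windows import hann

from .errors import InvalidConfigError, NoSignalError, TooShortSignalError
from .types import (MfccSpectrogram, RmsEnvelope, VibrationFeatures,
                    VibrationRecord, config_digest)

__all__ = ["MfccConfig", "compute_rms_envelope", "extract_vibration_features",
           "compute_mfcc", "mel_filterbank"]


def compute_rms_envelope(v: VibrationRecord, window: float = 0.1,
                         hop: float = 0.05) -> RmsEnvelope:
    """Windowed root-mean-square envelope.

    ``values[i]`` is the RMS over the window starting at ``i * hop``;
    timestamps are window centers. The 100 ms / 50 ms defaults resolve the
    4-62 s clinical voiding-time range with at least ~80 envelope points.
    """
    win_n = int(round(window * v.fs))
    hop_n = max(1, int(round(hop * v.fs)))
    if win_n < 2:
        raise InvalidConfigError("window must cover at least 2 samples")
    if v.samples.size < win_n:
        raise TooShortSignalError(
            f"record of {v.samples.size} samples is shorter than one "
            f"{win_n}-sample window")
    x2 = v.samples.astype(float) ** 2
    frames = np.lib.stride_tricks.sliding_window_view(x2, win_n)[::hop_n]
    values = np.sqrt(frames.mean(axis=1))
    return RmsEnvelope(hop=hop_n / v.fs, window=win_n / v.fs,
                       values=values, t0=win_n / (2 * v.fs))


def extract_vibration_features(env: RmsEnvelope, onset_frac: float = 0.05,
                               rms_stat: str = "integral") -> VibrationFeatures:
    """Scalar features of the active segment of an RMS envelope.

    The active segment spans the first to last envelope point at or above
    ``floor + onset_frac * (Mmax - floor)``, where the floor is the 5th
    percentile of the envelope — a noise-floor-compensated threshold that
    reduces to the plain ``onset_frac * Mmax`` rule on noiseless records.
    Ties in the maximum resolve to the earlier point.

    ``rms_stat`` selects the headline RMS scalar over the active segment:
    ``"integral"`` (envelope area in amplitude-seconds, the default),
    ``"rms"`` (RMS of envelope values) or ``"mean"``. The integral is the
    default because it is the vibration-side analogue of voided volume —
    under a linear flow-amplitude coupling it is the only reading whose
    correlation with voided volume survives cohorts where low-flow voiders
    still void normal volumes.
    """
    vals = env.values
    if not np.any(vals > 0):
        raise NoSignalError("envelope is identically zero")
    mmax = float(vals.max())
    floor = float(np.percentile(vals, 5))
    thr = floor + onset_frac * (mmax - floor)
    active = np.nonzero(vals >= thr)[0]
    i0, i1 = int(active[0]), int(active[-1])
    seg = vals[i0:i1 + 1]
    i_peak = int(np.argmax(vals))  # first maximum on ties
    if rms_stat == "rms":
        rms = float(np.sqrt(np.mean(seg ** 2)))
    elif rms_stat == "mean":
        rms = float(seg.mean())
    elif rms_stat == "integral":
        rms = float(seg.sum() * env.hop)
    else:
        raise InvalidConfigError(f"unknown rms_stat {rms_stat!r}")
    return VibrationFeatures(
        rms_magnitude=rms, mmax=mmax,
        signal_time=(i1 - i0) * env.hop,
        time_to_mmax=max(0.0, (i_peak - i0) * env.hop),
    )


# --- MFCC ---------------------------------------------------------------------

@dataclass(frozen=True)
class MfccConfig:
    """MFCC extraction parameters.

    The 64 s canvas (6400 frames at a 10 ms hop) accommodates the longest
    printed clinical voiding time (62 s) plus pads; shorter records are
    padded with silence frames, longer ones truncated, so every session in
    an experiment yields the same matrix shape.
    """

    frame_s: float = 0.025
    hop_s: float = 0.010
    n_mels: int = 26
    n_mfcc: int = 13
    fmin: float = 20.0
    fmax: Optional[float] = None       # defaults to fs / 2
    log_floor: float = 1e-10
    canvas_s: float = 64.0
    pre_emphasis: float = 0.0

    @property
    def n_frames(self) -> int:
        return int(round(self.canvas_s / self.hop_s))


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float,
                   fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank (n_mels x (n_fft // 2 + 1))."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = hz_pts / (fs / 2) * (n_fft // 2)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    grid = np.arange(n_fft // 2 + 1)
    for i in range(n_mels):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        up = (grid - lo) / max(mid - lo, 1e-12)
        down = (hi - grid) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def compute_mfcc(v: VibrationRecord,
                 cfg: MfccConfig = MfccConfig()) -> MfccSpectrogram:
    """Mel-frequency cepstral coefficients on a fixed-size canvas.

    Standard pipeline: optional pre-emphasis, framing, Hann window, power
    spectrum, triangular mel filterbank, log with floor, DCT-II (ortho),
    keep ``n_mfcc`` coefficients. The waveform is zero-padded or truncated
    to the canvas before framing, so padding frames equal genuine silence
    frames (every coefficient row of an all-zero record is the log-floor
    frame).
    """
    fs = v.fs
    fmax = cfg.fmax if cfg.fmax is not None else fs / 2
    if fmax > fs / 2 + 1e-9:
        raise InvalidConfigError(
            f"mel upper edge {fmax} Hz exceeds Nyquist {fs / 2} Hz")
    if cfg.fmin < 0 or cfg.fmin >= fmax:
        raise InvalidConfigError("require 0 <= fmin < fmax")

    frame_n = int(round(cfg.frame_s * fs))
    hop_n = int(round(cfg.hop_s * fs))
    n_frames = cfg.n_frames
    need = (n_frames - 1) * hop_n + frame_n

    x = v.samples.astype(np.float64)
    if cfg.pre_emphasis > 0:
        x = np.concatenate([[x[0]], x[1:] - cfg.pre_emphasis * x[:-1]])
    if x.size < need:
        x = np.pad(x, (0, need - x.size))
    else:
        x = x[:need]

    frames = np.lib.stride_tricks.sliding_window_view(x, frame_n)[::hop_n]
    frames = frames[:n_frames] * hann(frame_n, sym=False)

    n_fft = 1 << (frame_n - 1).bit_length()
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mels, n_fft, fs, cfg.fmin, fmax)
    mel_e = power @ fb.T
    log_e = np.log(np.maximum(mel_e, cfg.log_floor))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :cfg.n_mfcc]

    digest = config_digest({"cfg": cfg, "fs": fs})
    return MfccSpectrogram(coeffs=coeffs.astype(np.float32),
                           frame_hop=hop_n / fs, config_digest=digest)
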