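"""Domain containers shared across the pipeline.

Units follow clinical uroflowmetry conventions throughout: flow rate in mL/s,
volume in mL, time in seconds, vibration samples in arbitrary linear units at
a fixed sampling rate in Hz.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Optional

import numpy as np

from .errors import CorruptInputError

__all__ = [
    "PatternLabel",
    "FlowCurve",
    "VibrationRecord",
    "VibrationModel",
    "CohortSpec",
    "SessionRecord",
    "RmsEnvelope",
    "VibrationFeatures",
    "MfccSpectrogram",
    "FlowParameters",
    "REFERENCE_CLASS_COUNTS",
    "config_digest",
]

#: Per-class session counts of the reference clinical cohort (n = 76),
#: used as the packaged default fixture.
REFERENCE_CLASS_COUNTS: dict[int, int] = {0: 18, 1: 38, 2: 4, 3: 5, 4: 9, 5: 2}


class PatternLabel(IntEnum):
    """The six uroflow-curve morphologies used as diagnostic classes."""

    NORMAL = 0        # bell-shaped, Qmax >= 15 mL/s
    DECREASED = 1     # prolonged voiding with a low peak flow
    FLATTENED = 2     # low and near-constant flow until the end
    INTERMITTENT = 3  # flow drops to zero and rises again
    SAWTOOTH = 4      # large fluctuations that never reach zero
    TALL_PEAK = 5     # high peak reached quickly, declining soon after


@dataclass(frozen=True)
class FlowCurve:
    """Uniformly sampled urine flow rate versus time.

    Parameters
    ----------
    dt : float
        Seconds per sample (> 0). Time origin is at voiding onset.
    flow : np.ndarray
        Flow rate in mL/s. Non-negative; first and last samples are zero.
    """

    dt: float
    flow: np.ndarray

    def __post_init__(self):
        flow = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "flow", flow)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if flow.ndim != 1 or flow.size < 3:
            raise ValueError("flow must be a 1-D sequence of length >= 3")
        if not np.all(np.isfinite(flow)):
            raise CorruptInputError("flow contains non-finite values")
        if np.any(flow < 0):
            raise ValueError("flow values must be non-negative")
        if flow[0] != 0 or flow[-1] != 0:
            raise ValueError("flow curve must start and end at zero flow")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.flow.size) * self.dt

    @property
    def duration(self) -> float:
        """Total curve duration in seconds."""
        return (self.flow.size - 1) * self.dt


@dataclass(frozen=True)
class VibrationRecord:
    """Raw accelerometer-like waveform at a fixed sampling rate."""

    fs: float
    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise CorruptInputError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class VibrationModel:
    """Flow-to-vibration coupling law.

    The waveform is white noise amplitude-modulated by ``gain * Q(t)**alpha``,
    shaped by a second-order resonator (the container resonance) mixed with a
    broadband direct path (turbulent impact noise), plus stationary background
    noise. ``gain`` is calibrated so a flow of 50 mL/s maps to unit amplitude.
    """

    alpha: float = 1.0
    resonator_hz: float = 600.0
    resonator_q: float = 5.0
    direct_fraction: float = 0.85     # power fraction of the broadband path
    direct_band_hz: tuple[float, float] = (150.0, 1800.0)
    pad_s: float = 1.0                # pre/post silence pads
    qmax_unit: float = 50.0           # flow (mL/s) mapping to unit amplitude
    #: lognormal sigma of a slow per-session coupling-gain drift (the stream's
    #: impact point wandering on the container wall). 0 disables it; enabling
    #: it injects peak-timing jitter while leaving durations intact.
    coupling_drift_sigma: float = 0.0
    coupling_drift_corr_s: float = 5.0

    @property
    def gain(self) -> float:
        return 1.0 / self.qmax_unit ** self.alpha


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort draw."""

    class_counts: Mapping[int, int] = field(
        default_factory=lambda: dict(REFERENCE_CLASS_COUNTS))
    seed: int = 0
    noise_snr_db: float = 20.0
    sampling_rate: float = 4000.0
    flow_dt: float = 0.05
    vibration: VibrationModel = field(default_factory=VibrationModel)

    def __post_init__(self):
        counts = {int(k): int(v) for k, v in self.class_counts.items()}
        object.__setattr__(self, "class_counts", counts)
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(counts.values()) < 1:
            raise ValueError("total cohort size must be >= 1")
        if any(k not in range(6) for k in counts):
            raise ValueError("class labels must be in 0..5")
        # Nyquist must clear the highest excitation frequency of the model.
        top = max(self.vibration.resonator_hz, self.vibration.direct_band_hz[1])
        if not self.sampling_rate > 2 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} must exceed twice the "
                f"highest excitation frequency ({top} Hz)")

    @property
    def n_sessions(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class SessionRecord:
    """One voiding session: vibration record plus optional ground truth."""

    session_id: str
    vibration: VibrationRecord
    flow: Optional[FlowCurve] = None
    label: Optional[PatternLabel] = None
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flow is not None and self.vibration is not None:
            pad = float(self.generator_params.get("pad_s", 0.0))
            drift = abs(self.vibration.duration - 2 * pad - self.flow.duration)
            if drift > 0.06:  # one envelope hop (50 ms) plus rounding
                raise ValueError(
                    f"flow and vibration durations disagree by {drift:.3f} s")


@dataclass(frozen=True)
class RmsEnvelope:
    """Windowed RMS envelope of a vibration record."""

    hop: float
    window: float
    values: np.ndarray
    t0: float = 0.0   # time of the first window center

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")
        if values.ndim != 1 or values.size == 0:
            raise ValueError("envelope must be a non-empty 1-D sequence")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("envelope values must be finite and >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.hop


@dataclass(frozen=True)
class VibrationFeatures:
    """The four vibration-side scalars mirrored on the uroflow parameters."""

    rms_magnitude: float   # RMS over the active segment (signal units)
    mmax: float            # maximum envelope value
    signal_time: float     # active-segment duration, s
    time_to_mmax: float    # onset -> envelope maximum, s

    def __post_init__(self):
        if self.mmax < 0 or self.rms_magnitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not -1e-9 <= self.time_to_mmax <= self.signal_time + 1e-9:
            raise ValueError("time_to_mmax must lie within the active segment")


@dataclass(frozen=True)
class MfccSpectrogram:
    """Fixed-size mel-frequency cepstral coefficient matrix."""

    coeffs: np.ndarray     # n_frames x n_mfcc
    frame_hop: float       # seconds between frame centers
    config_digest: str

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs)
        object.__setattr__(self, "coeffs", coeffs)
        if coeffs.ndim != 2:
            raise ValueError("coeffs must be 2-D (frames x coefficients)")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coeffs must be finite")


@dataclass(frozen=True)
class FlowParameters:
    """Clinical uroflow parameters derived from a flow curve."""

    qmax: float           # mL/s
    voided_volume: float  # mL
    voiding_time: float   # s
    time_to_qmax: float   # s

    def __post_init__(self):
        if min(self.qmax, self.voided_volume,
               self.voiding_time, self.time_to_qmax) < 0:
            raise ValueError("uroflow parameters must be >= 0")
        if self.time_to_qmax > self.voiding_time + 1e-9:
            raise ValueError("time_to_qmax cannot exceed voiding_time")


def config_digest(obj) -> str:
    """Stable short hash of a configuration mapping/dataclass (provenance)."""

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]
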