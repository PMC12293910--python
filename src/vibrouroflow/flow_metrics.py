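"""Uroflow parameters and rule-based pattern labeling.

The labeler stands in for the physician's visual read of the uroflow curve.
It is an explicit decision cascade over curve morphology; the only threshold
with a clinical citation is the normal-flow rule Qmax >= 15 mL/s, all other
thresholds are package defaults exposed in :class:`PatternRuleConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyVoidError
from .types import FlowCurve, FlowParameters, PatternLabel

__all__ = ["PatternRuleConfig", "flow_parameters", "classify_pattern"]


@dataclass(frozen=True)
class PatternRuleConfig:
    """Thresholds of the pattern-rule cascade.

    ``qmax_normal_min`` is the clinical bell-shape rule (15 mL/s); the rest
    separate the six archetypes and are deliberately configurable. Temporal
    thresholds are relative to voiding time except ``min_gap``, which is an
    absolute pause duration (a 1 s pause reads as intermittency regardless of
    how long the void is).
    """

    qmax_normal_min: float = 15.0        # mL/s, normal-bell rule
    zero_flow_cutoff: float = 0.5        # mL/s, "zero flow" for gap detection
    min_gap: float = 1.0                 # s, minimum intra-void pause
    sawtooth_prominence_frac: float = 0.25  # dip prominence, fraction of Qmax
    sawtooth_min_dips: int = 2
    plateau_cv_max: float = 0.25         # CV over the central 60 %
    tall_peak_qmax_min: float = 25.0     # mL/s
    tall_peak_ttq_frac_max: float = 0.2  # time-to-Qmax / voiding-time

    def __post_init__(self):
        if min(self.qmax_normal_min, self.zero_flow_cutoff, self.min_gap,
               self.sawtooth_prominence_frac, self.plateau_cv_max,
               self.tall_peak_qmax_min, self.tall_peak_ttq_frac_max) <= 0:
            raise ValueError("all rule thresholds must be positive")
        if self.sawtooth_min_dips < 1:
            raise ValueError("sawtooth_min_dips must be >= 1")


def _active_bounds(flow: np.ndarray, cutoff: float) -> tuple[int, int]:
    above = np.nonzero(flow > cutoff)[0]
    if above.size == 0:
        raise EmptyVoidError("flow curve never exceeds the zero-flow cutoff")
    return int(above[0]), int(above[-1])


def flow_parameters(f: FlowCurve, zero_flow_cutoff: float = 0.0) -> FlowParameters:
    """Compute Qmax, voided volume, voiding time and time to Qmax.

    Voiding time spans the first to last sample above ``zero_flow_cutoff``
    (intra-void pauses are included, consistent with intermittent voiders
    having long voiding times). Voided volume is the trapezoidal integral of
    the full curve. Time to Qmax is measured from voiding onset to the first
    global maximum (earlier peak wins on ties).
    """
    i0, i1 = _active_bounds(f.flow, zero_flow_cutoff)
    qmax = float(f.flow.max())
    # np.argmax returns the first occurrence: the documented tie-break.
    i_peak = int(np.argmax(f.flow))
    return FlowParameters(
        qmax=qmax,
        voided_volume=float(np.trapezoid(f.flow, dx=f.dt)),
        voiding_time=(i1 - i0) * f.dt,
        time_to_qmax=max(0.0, (i_peak - i0) * f.dt),
    )


def classify_pattern(f: FlowCurve,
                     cfg: PatternRuleConfig = PatternRuleConfig()) -> PatternLabel:
    """Assign one of the six uroflow-curve patterns.

    Decision cascade, first match wins:

    1. *intermittent* — an interior run below the zero-flow cutoff lasting at
       least ``min_gap`` (flow drops to zero and rises again);
    2. *sawtooth* — at least ``sawtooth_min_dips`` interior dips of prominence
       >= ``sawtooth_prominence_frac * Qmax``, none reaching zero;
    3. *tall-peak* — Qmax >= ``tall_peak_qmax_min`` reached within
       ``tall_peak_ttq_frac_max`` of the voiding time;
    4. *flattened* — Qmax below the normal rule and a near-constant central
       segment (CV of the central 60 % <= ``plateau_cv_max``);
    5. *normal* — bell with Qmax >= ``qmax_normal_min``;
    6. otherwise *decreased*.

    Intermittency outranks everything because a true pause is the most
    specific visual feature; the classes are treated as mutually exclusive.
    """
    flow = f.flow
    cutoff = cfg.zero_flow_cutoff
    i0, i1 = _active_bounds(flow, cutoff)
    active = flow[i0:i1 + 1]
    params = flow_parameters(f, zero_flow_cutoff=cutoff)
    qmax = params.qmax

    # (1) intermittent: interior zero-flow run of >= min_gap
    below = active <= cutoff
    if below.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        if np.any((ends - starts) * f.dt >= cfg.min_gap):
            return PatternLabel.INTERMITTENT

    # (2) sawtooth: repeated deep dips that never reach zero
    dips, _ = find_peaks(-active, prominence=cfg.sawtooth_prominence_frac * qmax)
    if dips.size >= cfg.sawtooth_min_dips and active.min() > cutoff:
        return PatternLabel.SAWTOOTH

    # (3) tall peak reached quickly
    if (qmax >= cfg.tall_peak_qmax_min
            and params.voiding_time > 0
            and params.time_to_qmax <= cfg.tall_peak_ttq_frac_max * params.voiding_time):
        return PatternLabel.TALL_PEAK

    # (4) flattened: low and near-constant central segment
    if qmax < cfg.qmax_normal_min:
        lo = i0 + int(round(0.2 * (i1 - i0)))
        hi = i0 + int(round(0.8 * (i1 - i0)))
        central = flow[lo:hi + 1]
        if central.size >= 2 and central.mean() > 0:
            cv = central.std() / central.mean()
            if cv <= cfg.plateau_cv_max:
                return PatternLabel.FLATTENED

    # (5) normal bell
    if qmax >= cfg.qmax_normal_min:
        return PatternLabel.NORMAL

    # (6) decreased flow
    return PatternLabel.DECREASED
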