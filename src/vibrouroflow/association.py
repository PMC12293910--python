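"""Correlation analysis between vibration features and uroflow parameters.

Four named pairs mirror the vibration-side scalars onto their flow-side
counterparts: voided volume <-> RMS magnitude, Qmax <-> Mmax, voiding time
<-> signal time, and time to Qmax <-> time to Mmax. Pearson's product-moment
correlation is used, with two-sided p-values from the t-distribution on
n - 2 degrees of freedom; p < 0.05 is flagged significant.

Exact p-values are stored; any "p < 0.001" style formatting belongs to
rendering, never to the stored numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError
from .types import FlowParameters, VibrationFeatures

__all__ = ["PairResult", "CorrelationReport", "pearson", "correlation_report",
           "PAIR_NAMES"]

logger = logging.getLogger(__name__)

PAIR_NAMES = (
    "voided_volume_vs_rms",
    "qmax_vs_mmax",
    "voiding_time_vs_signal_time",
    "time_to_qmax_vs_time_to_mmax",
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class PairResult:
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n,
                "significant": self.significant}


@dataclass(frozen=True)
class CorrelationReport:
    pairs: dict  # pair name -> PairResult
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {"pairs": {k: v.to_dict() for k, v in self.pairs.items()},
                "n_excluded": self.n_excluded}


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson's r with a two-sided p-value (t-distribution, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 observations, got {x.size}")
    if math.isclose(float(np.var(x)), 0.0) or math.isclose(float(np.var(y)), 0.0):
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_report(
        flow_params: Sequence[Optional[FlowParameters]],
        vib_feats: Sequence[Optional[VibrationFeatures]]) -> CorrelationReport:
    """The four named flow-vibration correlations over a cohort.

    Sessions missing either feature set are excluded (with a logged count).
    Raises :class:`UndefinedCorrelationError` when fewer than 3 complete
    sessions remain.
    """
    if len(flow_params) != len(vib_feats):
        raise ValueError("feature sequences must be parallel")
    rows = [(fp, vf) for fp, vf in zip(flow_params, vib_feats)
            if fp is not None and vf is not None]
    n_excluded = len(flow_params) - len(rows)
    if n_excluded:
        logger.warning("excluded %d sessions with missing features", n_excluded)
    if len(rows) < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 complete sessions, got {len(rows)}")

    columns = {
        "voided_volume_vs_rms": (
            [fp.voided_volume for fp, _ in rows],
            [vf.rms_magnitude for _, vf in rows]),
        "qmax_vs_mmax": (
            [fp.qmax for fp, _ in rows], [vf.mmax for _, vf in rows]),
        "voiding_time_vs_signal_time": (
            [fp.voiding_time for fp, _ in rows],
            [vf.signal_time for _, vf in rows]),
        "time_to_qmax_vs_time_to_mmax": (
            [fp.time_to_qmax for fp, _ in rows],
            [vf.time_to_mmax for _, vf in rows]),
    }
    pairs = {}
    for name in PAIR_NAMES:
        r, p = pearson(*columns[name])
        pairs[name] = PairResult(r=r, p=p, n=len(rows))
    return CorrelationReport(pairs=pairs, n_excluded=n_excluded)
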