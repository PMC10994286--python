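"""Field-level evaluation metrics: point-wise RMSE and mean deviation."""

from __future__ import annotations

import numpy as np

from .grid import GridSpec
from .fields import VisualField

#: severity cutoffs on mean deviation, dB
MD_MILD_CUTOFF = -6.0
MD_SEVERE_CUTOFF = -12.0


def _values(f) -> np.ndarray:
    v = f.values if isinstance(f, VisualField) else np.asarray(f, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D field vector")
    return v


def pointwise_rmse(truth, estimate) -> float:
    """Root-mean-square error across all locations of a field estimate.

    ``sqrt(mean_i (x_i - xhat_i)^2)`` over all 54 locations, blind spot
    included (the low-rank models explicitly capture the blind spot, so it
    participates in reconstruction error).
    """
    t, e = _values(truth), _values(estimate)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def mean_deviation(field, normative, grid: GridSpec) -> float:
    """Unweighted mean of (threshold - normative) over non-blind-spot locations.

    Used only to stratify fields by glaucoma severity (mild MD > -6 dB,
    moderate -12 < MD <= -6, severe MD <= -12); no age correction.
    """
    v, n = _values(field), _values(normative)
    keep = np.array([i not in grid.blind_spot for i in range(len(v))])
    return float(np.mean((v - n)[keep]))


def severity_class(md: float) -> str:
    """Map mean deviation to {mild, moderate, severe}; boundaries go down."""
    if md <= MD_SEVERE_CUTOFF:
        return "severe"
    if md <= MD_MILD_CUTOFF:
        return "moderate"
    return "mild"


def normative_hill(training) -> np.ndarray:
    """Per-location mean of the training thresholds (empirical hill of vision)."""
    X = training.X
    if X.shape[1] < 1:
        raise ValueError("need at least one training field")
    return X.mean(axis=1)
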