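"""Audiometric pattern analytics.

Implements the clinical decision rules used to read conductive
audiograms: slope classification over the five clinical frequencies,
shoulder (local notch) detection at 1000 Hz, the Carhart correction of
otosclerotic bone-conduction thresholds at 2000 Hz, the 1000-Hz
discriminant that separates attic fixation from stapes-footplate
fixation, and ROC analysis with a Youden-optimal cutoff.

Slope rule: with a = mean HL at 250-500 Hz and b = mean HL at
2000-4000 Hz, an audiogram slopes when |a - b| > 10 dB and the
1000-Hz value lies between a and b (inclusive). The discriminant is
D = HL(1000) - mean(HL(250), HL(4000)); sustained (sigmoidal) curves
score higher than curves already falling at 1 kHz (exponential).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .audiogram import Audiogram, CLINICAL_FREQUENCIES_HZ

__all__ = [
    "SlopeClass",
    "RocResult",
    "classify_slope",
    "detect_shoulder",
    "carhart_correct",
    "discriminant_statistic",
    "roc_analysis",
]

#: Slope classes (exhaustive, mutually exclusive).
SLOPE_UP = "up"
SLOPE_DOWN = "down"
SLOPE_NONE = "none"
SlopeClass = str


class InputError(ValueError):
    """Audiogram lacks a frequency or has the wrong kind for an operation."""


def _value(a: Audiogram, freq: float) -> float:
    try:
        return a.at(freq)
    except KeyError as exc:
        raise InputError(str(exc)) from exc


def classify_slope(a: Audiogram) -> SlopeClass:
    """Classify an audiogram as 'up', 'down' or 'none'.

    Requires the five clinical frequencies. An audiogram is up-sloping
    (worse at low frequencies) when mean(250, 500) exceeds
    mean(2000, 4000) by more than 10 dB with the 1000-Hz value between
    the two means (inclusive), and symmetrically for down-sloping.
    """
    v = {f: _value(a, f) for f in CLINICAL_FREQUENCIES_HZ}
    lo = 0.5 * (v[250.0] + v[500.0])
    hi = 0.5 * (v[2000.0] + v[4000.0])
    mid = v[1000.0]
    between = min(lo, hi) <= mid <= max(lo, hi)
    if lo - hi > 10.0 and between:
        return SLOPE_UP
    if hi - lo > 10.0 and between:
        return SLOPE_DOWN
    return SLOPE_NONE


def detect_shoulder(a: Audiogram, at: float = 1000.0) -> bool:
    """True when the value at ``at`` sits >= 10 dB below its neighbours' mean.

    Neighbours are the adjacent grid points of the audiogram itself
    (the clinical 5-frequency grid by default usage); the target must
    have a neighbour on each side.
    """
    freqs = a.frequencies
    idx = np.flatnonzero(np.isclose(freqs, at))
    if idx.size == 0:
        raise InputError(f"frequency {at} Hz not in audiogram")
    i = int(idx[0])
    if i == 0 or i == freqs.size - 1:
        raise InputError(f"frequency {at} Hz lacks two neighbours for shoulder test")
    neighbours = 0.5 * (a.values[i - 1] + a.values[i + 1])
    return bool(a.values[i] <= neighbours - 10.0)


def carhart_correct(bc: Audiogram) -> Audiogram:
    """Correct the otosclerotic bone-conduction notch at 2000 Hz.

    Replaces the 2000-Hz bone-conduction threshold by the mean of the
    1000- and 4000-Hz thresholds, undoing the mechanical (Carhart)
    artifact so the residual reflects cochlear reserve. Idempotent.
    """
    if bc.kind != "bone_conduction":
        raise InputError(f"carhart_correct requires bone conduction, got {bc.kind!r}")
    v1000 = _value(bc, 1000.0)
    v4000 = _value(bc, 4000.0)
    _value(bc, 2000.0)
    out = bc.copy()
    out.values[np.isclose(out.frequencies, 2000.0)] = 0.5 * (v1000 + v4000)
    return out


def discriminant_statistic(a: Audiogram) -> float:
    """D = ABG(1000) - mean(ABG(250), ABG(4000)), in dB."""
    return _value(a, 1000.0) - 0.5 * (_value(a, 250.0) + _value(a, 4000.0))


@dataclass(frozen=True)
class RocResult:
    """ROC summary: AUC, Youden-optimal cutoff and its operating point.

    ``operating_points`` rows are (cutoff, true-positive rate,
    false-positive rate) for the rule "score >= cutoff is positive",
    ordered by ascending cutoff (TPR/FPR therefore non-increasing).
    """

    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    operating_points: tuple[tuple[float, float, float], ...]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "operating_points": [list(p) for p in self.operating_points],
        }


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC analysis of a score that is higher in the positive class.

    AUC is the rank-sum (Mann-Whitney) probability with ties counted
    one half, which equals trapezoidal integration of the ROC curve
    over all threshold operating points. The optimal cutoff maximizes
    Youden's J = sensitivity + specificity - 1; ties in J are broken
    toward the cutoff with higher sensitivity (the lower cutoff).
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise InputError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("roc_analysis requires both classes present")

    pos = s[y == 1]
    neg = s[y == 0]
    # rank-sum AUC with ties counted 1/2
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (n_pos * n_neg)

    cutoffs = np.unique(s)
    points = []
    best = None
    for c in cutoffs:
        tpr = float((pos >= c).mean())
        fpr = float((neg >= c).mean())
        points.append((float(c), tpr, fpr))
        j = tpr - fpr
        # strict improvement, or equal J with higher sensitivity (lower cutoff
        # wins because cutoffs ascend and we keep the first maximum)
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), tpr, 1.0 - fpr)
    assert best is not None
    return RocResult(
        auc=float(auc),
        optimal_cutoff=best[1],
        sensitivity=best[2],
        specificity=best[3],
        operating_points=tuple(points),
    )
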