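"""Inter-observer agreement utilities.

Provided as plumbing for users who hold their own manual annotations:
percent agreement, unweighted Cohen's kappa, and the conventional
Landis-Koch-style strength label (kappa <= 0.20 bad, 0.21-0.40 fair,
0.41-0.60 moderate, 0.61-0.80 good, 0.81-1.00 very good).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .errors import DimensionError

__all__ = ["AgreementResult", "agreement", "kappa_strength"]


@dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    kappa: float
    strength: str


def kappa_strength(kappa: float) -> str:
    """Conventional verbal strength band for a Cohen's kappa value."""
    if kappa <= 0.20:
        return "bad"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "good"
    return "very good"


def agreement(scores_a, scores_b) -> AgreementResult:
    """Percent agreement and Cohen's kappa between two score vectors."""
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError(
            f"score vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    percent = float(100.0 * np.mean(a == b))
    if np.array_equal(a, b):
        kappa = 1.0  # cohen_kappa_score is NaN when a single label is present
    else:
        kappa = float(cohen_kappa_score(a, b))
    return AgreementResult(
        percent_agreement=percent, kappa=kappa, strength=kappa_strength(kappa)
    )
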