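"""Per-image intensity features for scoring, plus two classical pixel-wise
comparison scores (ATM score and pixel-wise H-score).

The three scoring features are built on the stain concentration matrix of
the separated image and its relation to the trial's 5+ control:

* ``f1`` — mean DAB concentration, the size-normalized 1-norm of the DAB
  concentration row.  Threshold-free.
* ``f2 = N2`` — the DAB normalization factor: the ratio of the 99th
  percentile ("robust pseudo maximum") of the control's DAB row to that of
  the image.  Large when the image expresses little DAB relative to the
  control.
* ``f3`` — combines the DAB and hematoxylin factors, ``N2 * N1`` by default
  (a ratio variant ``N2 / N1`` is exposed as a configuration switch).

``N1``/``N2`` are invariant to any common rescaling of a color vector with
compensating concentration rescale, so they do not depend on the color
bases found during separation — they capture relative stain intensity the
way an observer comparing an image against the control would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray

from .errors import ParameterError
from .od import RGBImage
from .separation import StainDecomposition

__all__ = [
    "FeatureVector",
    "ComparisonFeatures",
    "feature_f1",
    "normalization_factors",
    "feature_vector",
    "atm_score",
    "pix_h_score",
]

#: features are floored here so the negative-beta clustering divergence
#: (which needs strictly positive inputs) is always defined
FEATURE_FLOOR = 1e-12
#: percentile defining the robust pseudo maximum of a concentration row
ROBUST_MAX_PERCENTILE = 99.0
#: DAB concentration below this is treated as unstained background when
#: classifying low-DAB pixels for the pixel-wise H-score
PIX_H_BACKGROUND = 0.05


@dataclass(frozen=True)
class FeatureVector:
    """The (f1, f2, f3) triple for one image plus its normalization factors."""

    image_id: str
    f1: float
    f2: float
    f3: float
    n1: float
    n2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])


@dataclass(frozen=True)
class ComparisonFeatures:
    """Classical pixel-wise scores computed for comparison purposes."""

    atm: float
    pix_h: float
    thr_dab_high: float
    thr_dab_low: float
    thr_h: float


def feature_f1(dec: StainDecomposition) -> float:
    """Mean DAB concentration: ``(1/N) * sum_i H(2, i)``.

    Requires no thresholds or other parameters.
    """
    return float(dec.dab.mean())


def _robust_max(row: np.ndarray, percentile: float) -> float:
    return float(np.percentile(row, percentile))


def normalization_factors(
    dec: StainDecomposition,
    dec_ref: StainDecomposition,
    percentile: float = ROBUST_MAX_PERCENTILE,
) -> tuple[float, float]:
    """Per-stain normalization factors against the 5+ control.

    ``N_j = RM(H_ref(j, :)) / RM(H(j, :))`` where RM is the robust pseudo
    maximum (the ``percentile``-th percentile, 99 by default) of a
    concentration row and the reference is the high-score control.  The
    1e-16 concentration floor guarantees a finite (if large) factor even
    when a stain is essentially absent.
    """
    factors = []
    for j in range(2):
        ref = _robust_max(dec_ref.h[j], percentile)
        own = _robust_max(dec.h[j], percentile)
        # the 1e-16 concentration floor keeps the denominator positive
        factors.append(ref / max(own, 1e-16))
    return factors[0], factors[1]


def feature_vector(
    dec: StainDecomposition,
    dec_ref: StainDecomposition,
    image_id: str = "",
    f3_convention: str = "product",
    percentile: float = ROBUST_MAX_PERCENTILE,
) -> FeatureVector:
    """Assemble the (f1, f2, f3) feature triple for one image.

    ``f2 = N2`` and ``f3 = N2 * N1`` (product convention, the default) or
    ``f3 = N2 / N1`` (ratio convention).  The control scored against itself
    yields ``f2 = f3 = 1`` exactly under either convention.
    """
    if f3_convention not in ("product", "ratio"):
        raise ParameterError(f"unknown f3 convention {f3_convention!r}")
    n1, n2 = normalization_factors(dec, dec_ref, percentile)
    f1 = feature_f1(dec)
    f2 = n2
    f3 = n2 * n1 if f3_convention == "product" else n2 / n1
    return FeatureVector(
        image_id=image_id,
        f1=max(f1, FEATURE_FLOOR),
        f2=max(f2, FEATURE_FLOOR),
        f3=max(f3, FEATURE_FLOOR),
        n1=n1,
        n2=n2,
    )


def atm_score(dab_plane_rgb: RGBImage) -> float:
    """Average threshold (ATM) score of a rendered DAB plane, in [0, 1].

    The rendered plane is converted to grayscale (standard luma weights),
    inverted to a stain strength ``s = I0 - gray`` so that darker brown
    means stronger stain, and the score is the average over thresholds
    ``k = 1 .. I0`` of the proportion of pixels with ``s >= k``.
    """
    i0 = dab_plane_rgb.i0
    gray = rgb2gray(np.asarray(dab_plane_rgb.pixels, dtype=np.float64) / i0) * i0
    strength = (i0 - gray).ravel()
    n = strength.size
    ks = np.arange(1, int(round(i0)) + 1, dtype=np.float64)
    # proportion with strength >= k, via a sorted lookup
    srt = np.sort(strength)
    ps = 1.0 - np.searchsorted(srt, ks, side="left") / n
    return float(ps.sum() / i0)


def pix_h_score(
    dec: StainDecomposition,
    thr_dab: tuple[float, float] = (2.5, 0.7),
    thr_h: float = 0.7,
    background: float = PIX_H_BACKGROUND,
) -> float:
    """Pixel-wise H-score in [0, 300].

    DAB concentrations are classified as high (>= ``thr_dab[0]``), medium
    (``[thr_dab[1], thr_dab[0])``) or low (``(background, thr_dab[1])``);
    hematoxylin-positive pixels are those with H concentration >=
    ``thr_h``.  The score is ``100 * (3 HP + 2 MP + LP) / (HP + MP + LP +
    NP)`` with HP/MP/LP/NP the four areas.  Returns 0 (with a warning) when
    no pixel falls in any class.
    """
    hi, lo = thr_dab
    if not hi > lo > background:
        raise ParameterError(
            f"thresholds must satisfy high > low > background, got {hi}, {lo}, {background}"
        )
    dab = dec.dab
    hp = int(np.count_nonzero(dab >= hi))
    mp = int(np.count_nonzero((dab >= lo) & (dab < hi)))
    lp = int(np.count_nonzero((dab > background) & (dab < lo)))
    np_ = int(np.count_nonzero(dec.hematoxylin >= thr_h))
    denom = hp + mp + lp + np_
    if denom == 0:
        warnings.warn("no stained pixels found; pixel-wise H-score set to 0")
        return 0.0
    return 100.0 * (3 * hp + 2 * mp + lp) / denom
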