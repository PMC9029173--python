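"""Two-stage stain separation: eigendecomposition initialization followed by
beta-divergence NMF refinement.

The observed OD image is modeled as ``Y = W H`` where ``W`` (3 x 2) holds the
unit-l1-norm color vectors of hematoxylin and DAB and ``H`` (2 x N) their
per-pixel concentrations.  The trial's high-score (5+) control image — the
one where both stains are well expressed — is used to estimate a shared
initial ``W``: the OD scatter of a two-stain image lies essentially in the
plane spanned by the two stain vectors, which is recovered as the top-2
eigenplane of the autocorrelation matrix.  Within that plane the stain
directions sit at the angular edges of the scatter, because nuclei are
mostly hematoxylin-only and cytoplasm mostly DAB-only, so each stain
contributes a population of (near) single-stain pixels.  Every image in the
trial is then deconvolved against this shared ``W_init`` and refined
per-image by multiplicative NMF under the beta divergence (beta = 0.5 by
default, inside the (0, 1) range where monotone descent of the updates is
guaranteed).  Sharing the initialization is what keeps separation stable on
low-expression images, where single-image estimators fail.

Finally rows/columns are permuted so hematoxylin is stain 1 and DAB stain 2,
decided by the mean magenta of each reconstructed single-stain plane in the
CMYK model (the blue/purple hematoxylin plane carries more magenta than the
brown DAB plane).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .divergence import beta_divergence
from .errors import DegenerateImageError, ParameterError, SingularMatrixError
from .od import ODImage, RGBImage, rgb_to_od

__all__ = [
    "EigenInitResult",
    "StainDecomposition",
    "eigen_init",
    "deconvolve",
    "nmf_beta",
    "order_stains",
    "separate_trial",
]

#: concentrations below this are clamped up after deconvolution (molar
#: concentrations must be positive)
H_FLOOR = 1e-16
#: guard for denominators and model entries inside the multiplicative updates
EPS = 1e-12
#: fallback stain angles as fractions of the observed angular range, used
#: when the angle histogram does not show two peaks
FALLBACK_FRACTIONS = (0.18, 0.55)
N_ANGLE_BINS = 1000
SMOOTH_WINDOW = 20
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class EigenInitResult:
    """Outcome of the eigendecomposition-based initialization.

    Attributes
    ----------
    q : (3, 3) orthonormal eigenvector matrix of the OD autocorrelation,
        columns ordered by descending eigenvalue.
    z : (2, N) coordinates of the control image in the top-2 eigenplane.
    phi : per-pixel angles of the ``z`` columns (radians).
    nu : 1000-bin envelope of max ``||z||`` per angular bin, after smoothing.
    phi1, phi2 : estimated stain angles, ``phi1 < phi2``.
    v1, v2 : unit 2-vectors at those angles (stain coordinates in the plane).
    w_init : (3, 2) initial color-vector matrix ``[q1, q2] @ [v1, v2]`` with
        residual negative entries floored at zero.
    fallback_used : True when fewer than two envelope peaks were found and
        the fallback angles were used instead.
    """

    q: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    nu: np.ndarray
    phi1: float
    phi2: float
    v1: np.ndarray
    v2: np.ndarray
    w_init: np.ndarray
    fallback_used: bool


@dataclass(frozen=True)
class StainDecomposition:
    """A factorization ``Y ~ W H`` of one image.

    ``w`` is 3 x 2 with non-negative unit-l1-norm columns; ``h`` is 2 x N
    with entries >= 1e-16.  Once ``ordered`` is True, column/row 0 is
    hematoxylin and column/row 1 is DAB.  ``divergence_trace`` holds the
    beta divergence before refinement and after each NMF iteration.
    """

    w: np.ndarray
    h: np.ndarray
    shape: tuple[int, int]
    i0: float
    beta: float
    divergence_trace: np.ndarray
    ordered: bool = False

    @property
    def stain_order(self) -> tuple[str, str]:
        if not self.ordered:
            return ("unassigned", "unassigned")
        return ("hematoxylin", "dab")

    @property
    def hematoxylin(self) -> np.ndarray:
        """Concentration row of the nuclear counterstain."""
        return self.h[0]

    @property
    def dab(self) -> np.ndarray:
        """Concentration row of the DAB chromogen."""
        return self.h[1]


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with a window that shrinks at the edges.

    Bin ``k`` averages ``x[max(0, k - window//2) : k + window//2]``, i.e. a
    full window of ``window`` samples in the interior.
    """
    n = x.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n)
    return (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)


def eigen_init(y5: ODImage) -> EigenInitResult:
    """Estimate the initial color-vector matrix from the 5+ control image.

    Eigendecomposes ``R = Y Y^T / N``, projects onto the top-2 eigenplane,
    and locates the two stain directions as the first and last peaks of a
    smoothed angular envelope of the projected scatter: the angle range is
    split into 1000 bins, each bin takes the maximum projected norm of its
    pixels, and the envelope is smoothed with a centered 20-bin moving mean.
    If fewer than two peaks emerge the stain angles default to 18% and 55%
    of the angular range and ``fallback_used`` is set.
    """
    y = y5.matrix
    n = y.shape[1]
    r = y @ y.T / n
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    q = eigvecs[:, order]
    if eigvals[1] <= 1e-12 * max(eigvals[0], EPS):
        raise DegenerateImageError(
            "image scatter is rank deficient: fewer than two distinct stain colors"
        )

    z = q[:, :2].T @ y
    # resolve eigenvector sign ambiguity: orient so each row of Z has
    # non-negative mean (OD data lives in the positive orthant)
    for row in range(2):
        if z[row].mean() < 0:
            z[row] *= -1
            q[:, row] *= -1

    phi = np.arctan2(z[1], z[0])
    norms = np.hypot(z[0], z[1])
    lo, hi = float(phi.min()), float(phi.max())
    if hi - lo <= 0:
        raise DegenerateImageError("all pixels share a single stain direction")

    idx = np.minimum(
        ((phi - lo) / (hi - lo) * N_ANGLE_BINS).astype(np.intp), N_ANGLE_BINS - 1
    )
    nu = np.zeros(N_ANGLE_BINS)
    np.maximum.at(nu, idx, norms)
    nu_smooth = _moving_mean(nu, SMOOTH_WINDOW)

    # zero-pad so a maximum in the first or last bin — where the
    # single-stain populations live — counts as a peak
    padded = np.concatenate([[0.0], nu_smooth, [0.0]])
    peaks, _ = signal.find_peaks(
        padded, prominence=PEAK_PROMINENCE_FRACTION * nu_smooth.max()
    )
    peaks = peaks - 1
    centers = lo + (np.arange(N_ANGLE_BINS) + 0.5) * (hi - lo) / N_ANGLE_BINS
    if len(peaks) >= 2:
        phi1 = float(centers[peaks[0]])
        phi2 = float(centers[peaks[-1]])
        fallback = False
    else:
        phi1 = lo + FALLBACK_FRACTIONS[0] * (hi - lo)
        phi2 = lo + FALLBACK_FRACTIONS[1] * (hi - lo)
        fallback = True

    v1 = np.array([np.cos(phi1), np.sin(phi1)])
    v2 = np.array([np.cos(phi2), np.sin(phi2)])
    w_init = q[:, :2] @ np.column_stack([v1, v2])
    w_init = np.maximum(w_init, 0.0)
    return EigenInitResult(
        q=q,
        z=z,
        phi=phi,
        nu=nu_smooth,
        phi1=phi1,
        phi2=phi2,
        v1=v1,
        v2=v2,
        w_init=w_init,
        fallback_used=fallback,
    )


def deconvolve(y: ODImage | np.ndarray, w: np.ndarray) -> np.ndarray:
    """Color deconvolution: ``H = (W^T W)^-1 W^T Y`` with positivity floor.

    The Moore-Penrose pseudo-inverse of the 3 x 2 color-vector matrix
    un-mixes concentrations per pixel; entries below 1e-16 (negative least
    squares solutions are unphysical) are clamped to 1e-16.
    """
    matrix = y.matrix if isinstance(y, ODImage) else np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    sv = np.linalg.svd(w, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise SingularMatrixError("color-vector matrix is rank deficient")
    h = np.linalg.solve(w.T @ w, w.T @ matrix)
    return np.maximum(h, H_FLOOR)


def nmf_beta(
    y: ODImage,
    w0: np.ndarray,
    h0: np.ndarray,
    beta: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> StainDecomposition:
    """Refine a factorization by multiplicative beta-divergence NMF.

    Alternates the multiplicative updates

        h_jt <- h_jt * sum_i w_ij q_it^(b-1) p_it / sum_i w_ij q_it^b
        w_ij <- w_ij * sum_t h_jt q_it^(b-1) p_it / sum_t h_jt q_it^b

    with ``q = (W H)`` recomputed from the current factors.  After each
    iteration the columns of ``W`` are rescaled to unit l1 norm with the
    inverse scale pushed into the rows of ``H`` (leaving ``W H`` unchanged),
    so concentration maps are comparable across images even when hue or
    saturation drifts.  Iteration stops at ``max_iter`` or when the relative
    divergence decrease falls below ``tol``.  For ``beta`` in (0, 1) the
    divergence trace is non-increasing.
    """
    p = y.matrix
    w0 = np.asarray(w0, dtype=np.float64)
    h0 = np.asarray(h0, dtype=np.float64)
    # a factor with no positive mass cannot escape zero under
    # multiplicative updates, so flooring it would be meaningless
    if (w0.max(axis=0) <= 0).any() or (h0.max(axis=1) <= 0).any():
        raise ParameterError(
            "NMF initialization must have positive mass in every stain component"
        )
    w = np.maximum(w0, EPS).copy()
    h = np.maximum(h0, EPS).copy()

    trace = [beta_divergence(p, w @ h, beta)]
    for _ in range(max_iter):
        q = np.maximum(w @ h, EPS)
        h *= (w.T @ (q ** (beta - 1.0) * p)) / np.maximum(w.T @ q**beta, EPS)
        q = np.maximum(w @ h, EPS)
        w *= ((q ** (beta - 1.0) * p) @ h.T) / np.maximum(q**beta @ h.T, EPS)
        # unit-l1 columns of W, compensated in H so W @ H is unchanged
        scale = np.maximum(w.sum(axis=0), EPS)
        w /= scale
        h *= scale[:, None]
        d = beta_divergence(p, w @ h, beta)
        trace.append(d)
        prev = trace[-2]
        if prev - d < tol * max(abs(prev), EPS):
            break

    return StainDecomposition(
        w=w,
        h=np.maximum(h, H_FLOOR),
        shape=y.shape,
        i0=y.i0,
        beta=beta,
        divergence_trace=np.asarray(trace),
    )


def _magenta(rgb01: np.ndarray) -> np.ndarray:
    """Magenta channel of RGB values in [0, 1] under the naive CMYK model:
    ``K = 1 - max(R, G, B)``, ``M = (1 - G - K) / (1 - K)`` (0 where K = 1).
    """
    rgb01 = np.atleast_2d(rgb01)
    k = 1.0 - rgb01.max(axis=-1)
    denom = 1.0 - k
    return np.where(
        denom > EPS, (1.0 - rgb01[..., 1] - k) / np.maximum(denom, EPS), 0.0
    )


def _stain_magenta(w_col: np.ndarray) -> float:
    """CMYK magenta of a stain's pure color rendered at unit concentration."""
    return float(_magenta(np.power(10.0, -w_col))[0])


def order_stains(dec: StainDecomposition) -> StainDecomposition:
    """Permute the factorization so hematoxylin is stain 1 and DAB stain 2.

    Each stain's color vector is rendered to RGB at unit concentration and
    its CMYK magenta compared; the stain with the larger magenta is
    hematoxylin (blue/purple renders with more magenta than brown).  The
    comparison is made at a common concentration because magenta grows with
    stain amount — a densely stained brown plane can out-magenta a lightly
    stained blue one — and the unit-l1-norm columns make unit concentration
    comparable between the stains.  On an exact tie the stain with the
    larger blue-channel OD weight wins the hematoxylin slot.
    """
    scale = dec.w.sum(axis=0)
    w_unit = dec.w / np.maximum(scale, EPS)  # robust if called pre-normalization
    magentas = [_stain_magenta(w_unit[:, j]) for j in range(2)]
    if magentas[0] == magentas[1]:
        hema = int(np.argmax(dec.w[2]))  # tie-break: larger blue OD weight
    else:
        hema = int(np.argmax(magentas))
    perm = [hema, 1 - hema]
    return replace(dec, w=dec.w[:, perm], h=dec.h[perm, :], ordered=True)


def separate_trial(
    images: list[RGBImage],
    control5_index: int,
    beta: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> list[StainDecomposition]:
    """Separate every image of a trial with a shared initialization.

    Runs :func:`eigen_init` on the 5+ control only; deconvolves each image
    against the shared ``W_init``; refines each per-image with
    :func:`nmf_beta`; orders stains hematoxylin-first.
    """
    if not 0 <= control5_index < len(images):
        raise ParameterError(
            f"control index {control5_index} outside trial of {len(images)} images"
        )
    init = eigen_init(rgb_to_od(images[control5_index]))
    decs = []
    for img in images:
        y = rgb_to_od(img)
        h0 = deconvolve(y, init.w_init)
        dec = nmf_beta(y, init.w_init, h0, beta=beta, max_iter=max_iter, tol=tol)
        decs.append(order_stains(dec))
    return decs
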