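"""Score prediction: beta-divergence k-means anchored to the control images.

Scores are ordinal categories 1+ .. K+ (K = 5 by default).  Rather than
fixing hard boundaries in feature space, images are clustered with a
k-means algorithm whose dissimilarity is the beta divergence (beta = -0.5
by default) and whose centroids are initialized systematically from the two
researcher-designated controls:

* centroid 1 and centroid K are the feature vectors of the 1+ and 5+
  controls themselves;
* the f1 coordinates of the intermediate centroids are placed at fixed
  percentages (15%, 40%, 70% by default) of the f1 gap between the
  controls;
* their f2/f3 coordinates come from a two-term exponential model
  ``y(x) = a exp(bx) + c exp(dx)`` fitted to the trial's (f1, f2) and
  (f1, f3) point clouds — the relation between mean DAB concentration and
  the normalization factors is exponential rather than linear.

Iteration is capped (3 by default) so final centroids stay close to the
systematic initialization even when some categories are under-represented
in the trial.  The whole path is deterministic: no random initialization
anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .divergence import beta_divergence
from .errors import ControlOrderError, InsufficientDataError, ParameterError
from .features import FEATURE_FLOOR, FeatureVector, feature_vector
from .od import RGBImage
from .separation import StainDecomposition, separate_trial

__all__ = [
    "CentroidSet",
    "ScoreResult",
    "fit_two_term_exponential",
    "init_centroids",
    "kmeans_beta",
    "score_trial",
]

DEFAULT_PERCENTAGES = (15.0, 40.0, 70.0)


@dataclass(frozen=True)
class CentroidSet:
    """Initial centroids for the K score categories.

    ``centroids`` is K x 3 in (f1, f2, f3) space, row k the centroid of
    score k+1.  ``exp_fit`` maps feature index (2 or 3) to the fitted
    (a, b, c, d) parameters; ``fit_ok`` records whether the exponential fit
    succeeded for that feature or the linear fallback between the control
    features was used instead.
    """

    centroids: np.ndarray
    percentages: tuple[float, ...]
    exp_fit: dict = field(default_factory=dict)
    fit_ok: dict = field(default_factory=dict)

    @property
    def n_categories(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ScoreResult:
    """Predicted scores for one trial.

    ``scores`` are integers 1 .. K; ``divergences`` is M x K with the beta
    divergence of each image's features to each (final-iteration) centroid;
    ``centroids`` are the centroids at the last executed iteration.
    """

    scores: np.ndarray
    divergences: np.ndarray
    centroids: np.ndarray
    iterations_run: int
    init: CentroidSet
    features: list[FeatureVector]


def _two_term_exp(x, a, b, c, d):
    return a * np.exp(b * x) + c * np.exp(d * x)


def fit_two_term_exponential(
    f1_values: np.ndarray, ft_values: np.ndarray
) -> tuple[float, float, float, float, bool]:
    """Fit ``y = a exp(bx) + c exp(dx)`` by multi-start nonlinear least squares.

    Five deterministic initializations are tried and the lowest-residual
    solution kept.  ``fit_ok`` is False when every start fails or the
    fitted curve is non-monotone over the data range (an interpolant for
    ordered centroids must be monotone); callers then fall back to linear
    interpolation between the control features.

    Raises
    ------
    InsufficientDataError
        With fewer than 4 points (the model has 4 parameters).
    """
    x = np.asarray(f1_values, dtype=np.float64)
    y = np.asarray(ft_values, dtype=np.float64)
    if x.size < 4:
        raise InsufficientDataError(
            f"need at least 4 points to fit a two-term exponential, got {x.size}"
        )
    if x.min() <= 0:
        raise ParameterError("f1 values must be strictly positive")

    span = float(x.max() - x.min())
    rate = 1.0 / span if span > 0 else 1.0
    y0, y1 = float(y[np.argmin(x)]), float(y[np.argmax(x)])
    # single-exponential decay/growth rate suggested by the endpoints
    if y0 > 0 and y1 > 0 and span > 0:
        r0 = float(np.log(y1 / y0) / span)
    else:
        r0 = -rate
    ybar = float(np.mean(np.abs(y))) or 1.0
    starts = [
        (y0, r0, 0.0, 0.0),
        (ybar, r0, ybar / 10.0, r0 / 2.0),
        (ybar / 2.0, -rate, ybar / 2.0, -3.0 * rate),
        (y1, rate, y0, -rate),
        (ybar, 0.0, 0.0, r0),
    ]

    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_two_term_exp, x, y, p0=p0, maxfev=20000)
        except (RuntimeError, TypeError, ValueError):
            continue
        resid = y - _two_term_exp(x, *popt)
        sse = float(resid @ resid)
        if np.isfinite(sse) and sse < best_sse:
            best_sse = sse
            best = popt

    if best is None:
        return 0.0, 0.0, 0.0, 0.0, False
    a, b, c, d = (float(v) for v in best)
    grid = np.linspace(x.min(), x.max(), 256)
    curve = _two_term_exp(grid, a, b, c, d)
    diffs = np.diff(curve)
    monotone = bool(np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12))
    ok = monotone and bool(np.all(np.isfinite(curve)))
    return a, b, c, d, ok


def init_centroids(
    features: list[FeatureVector],
    idx1: int,
    idx5: int,
    percentages: tuple[float, ...] = DEFAULT_PERCENTAGES,
) -> CentroidSet:
    """Place K = len(percentages) + 2 centroids anchored at the controls.

    Centroid 1 and K are the control feature vectors.  Intermediate f1
    coordinates sit at the given percentages of the controls' f1 gap; the
    matching f2/f3 coordinates are predicted by the two-term exponential
    fit (or, if it fails or there are too few images, by linear
    interpolation between the control features).
    """
    pcts = tuple(float(p) for p in percentages)
    if any(not 0 <= p <= 100 for p in pcts) or list(pcts) != sorted(pcts):
        raise ParameterError(f"percentages must be sorted within [0, 100], got {pcts}")
    f_lo = features[idx1]
    f_hi = features[idx5]
    if f_hi.f1 <= f_lo.f1:
        raise ControlOrderError(
            "the 5+ control must have larger mean DAB concentration (f1) than "
            f"the 1+ control (got {f_hi.f1:.4g} <= {f_lo.f1:.4g}); check the "
            "control designations"
        )

    k = len(pcts) + 2
    cents = np.empty((k, 3))
    cents[0] = f_lo.as_array()
    cents[-1] = f_hi.as_array()
    f1_mid = f_lo.f1 + np.asarray(pcts) / 100.0 * (f_hi.f1 - f_lo.f1)
    cents[1:-1, 0] = f1_mid

    x_all = np.array([f.f1 for f in features])
    exp_fit: dict[int, tuple[float, float, float, float]] = {}
    fit_ok: dict[int, bool] = {}
    for t, attr in ((2, "f2"), (3, "f3")):
        y_all = np.array([getattr(f, attr) for f in features])
        try:
            a, b, c, d, ok = fit_two_term_exponential(x_all, y_all)
        except InsufficientDataError:
            a = b = c = d = 0.0
            ok = False
        exp_fit[t] = (a, b, c, d)
        fit_ok[t] = ok
        if ok:
            pred = _two_term_exp(f1_mid, a, b, c, d)
        else:  # monotone linear interpolation between the two controls
            pred = np.interp(
                f1_mid,
                [f_lo.f1, f_hi.f1],
                [getattr(f_lo, attr), getattr(f_hi, attr)],
            )
        cents[1:-1, t - 1] = pred

    cents = np.maximum(cents, FEATURE_FLOOR)
    return CentroidSet(centroids=cents, percentages=pcts, exp_fit=exp_fit, fit_ok=fit_ok)


def kmeans_beta(
    features: list[FeatureVector],
    init: CentroidSet,
    beta: float = -0.5,
    max_iter: int = 3,
) -> ScoreResult:
    """Cluster feature vectors by k-means under the beta divergence.

    Each iteration assigns every image to the centroid minimizing
    ``D_B(f || c)`` (data first — the divergence is asymmetric) and then
    replaces each centroid by the arithmetic mean of its assigned images;
    centroids of empty clusters are kept.  Ties in the assignment go to the
    lower score.  Iteration stops when assignments repeat or after
    ``max_iter`` rounds (3 by default, keeping final centroids near the
    systematic initialization).
    """
    f = np.array([fv.as_array() for fv in features])
    f = np.maximum(f, FEATURE_FLOOR)
    cents = init.centroids.copy()
    k = cents.shape[0]
    m = f.shape[0]

    assign = np.full(m, -1)
    div = np.zeros((m, k))
    iterations = 0
    for it in range(max_iter):
        for i in range(m):
            for j in range(k):
                div[i, j] = beta_divergence(f[i], cents[j], beta)
        new_assign = div.argmin(axis=1)  # argmin takes the first (lower score) tie
        iterations = it + 1
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = f[assign == j]
            if members.size:
                cents[j] = members.mean(axis=0)

    return ScoreResult(
        scores=assign + 1,
        divergences=div.copy(),
        centroids=cents,
        iterations_run=iterations,
        init=init,
        features=list(features),
    )


def score_trial(
    images: list[RGBImage],
    idx1: int,
    idx5: int,
    beta_nmf: float = 0.5,
    beta_kmeans: float = -0.5,
    nmf_max_iter: int = 50,
    nmf_tol: float = 1e-6,
    kmeans_max_iter: int = 3,
    percentages: tuple[float, ...] = DEFAULT_PERCENTAGES,
    f3_convention: str = "product",
    percentile: float = 99.0,
    image_ids: list[str] | None = None,
) -> tuple[ScoreResult, list[StainDecomposition]]:
    """Run the full pipeline on a trial and score every image.

    Separation -> feature extraction (normalized against the 5+ control) ->
    systematic centroid initialization -> capped beta-divergence k-means.
    Deterministic for fixed inputs and settings.
    """
    if len(images) < 2:
        raise ParameterError("a trial needs at least the two control images")
    if idx1 == idx5:
        raise ParameterError("the two controls must be distinct images")
    ids = image_ids or [f"image_{i:03d}" for i in range(len(images))]
    decs = separate_trial(
        images, control5_index=idx5, beta=beta_nmf, max_iter=nmf_max_iter, tol=nmf_tol
    )
    feats = [
        feature_vector(
            dec, decs[idx5], image_id=ids[i], f3_convention=f3_convention,
            percentile=percentile,
        )
        for i, dec in enumerate(decs)
    ]
    cents = init_centroids(feats, idx1, idx5, percentages)
    result = kmeans_beta(feats, cents, beta=beta_kmeans, max_iter=kmeans_max_iter)
    return result, decs
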