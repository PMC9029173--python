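"""Seeded synthetic IHC trials with known ground truth.

A phantom emulates a dual-stained brightfield field of view under the
Beer-Lambert forward model: a hematoxylin concentration map made of
nucleus-like disks, a diffuse cytoplasmic DAB map scaled by a per-image
dose, mixing through a ground-truth 3 x 2 OD color-vector matrix, additive
truncated Gaussian noise in OD space, and rendering back to RGB.  Because
every phantom exposes its true ``W`` and ``H``, each pipeline stage can be
tested for recovery without any real slide.

The default color vectors are the widely published hematoxylin and DAB OD
triplets (blue-dominant and brown-dominant respectively), l1-normalized.
Nuclei outside DAB regions contribute (near) single-stain hematoxylin
pixels, and DAB regions outside nuclei contribute single-stain DAB pixels
— the populations the angle-histogram initialization relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .od import RGBImage, od_to_rgb

__all__ = ["PhantomSpec", "Trial", "generate_phantom", "generate_trial", "DEFAULT_W"]


def _l1_columns(w: np.ndarray) -> np.ndarray:
    return w / w.sum(axis=0, keepdims=True)


#: hematoxylin (blue-dominant) and DAB (brown-dominant) OD color vectors,
#: l1-normalized; the classical published triplets
DEFAULT_W = _l1_columns(
    np.array(
        [
            [0.650, 0.269],
            [0.704, 0.568],
            [0.286, 0.778],
        ]
    )
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic dual-stained image.

    ``dab_dose`` multiplies the DAB concentration map; a graded series of
    doses emulates a trial spanning expression levels 1+ .. 5+.
    ``colocalization_fraction`` is the share of DAB signal overlapping
    nuclei (cytoplasmic staining wraps around nuclei in real tissue).
    ``noise_sigma`` is the standard deviation of additive OD noise,
    truncated so OD stays non-negative.
    """

    width: int = 96
    height: int = 96
    w_true: np.ndarray = field(default_factory=lambda: DEFAULT_W.copy())
    n_nuclei: int = 40
    nucleus_radius: tuple[float, float] = (3.0, 6.0)
    h_peak: float = 1.0
    dab_peak: float = 1.2
    dab_dose: float = 1.0
    colocalization_fraction: float = 0.35
    noise_sigma: float = 0.02
    i0: float = 255.0
    quantize: bool = True
    seed: int = 0
    #: separate seed for the additive noise; None draws noise from the same
    #: stream as the structure, so two specs differing only here share their
    #: nucleus and cytoplasm maps exactly
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w_true, dtype=np.float64)
        if w.shape != (3, 2) or w.min() < 0:
            raise ParameterError("w_true must be a non-negative 3 x 2 matrix")
        w = _l1_columns(w)
        cos = float(w[:, 0] @ w[:, 1] / (np.linalg.norm(w[:, 0]) * np.linalg.norm(w[:, 1])))
        if np.degrees(np.arccos(np.clip(cos, -1, 1))) < 10.0:
            raise ParameterError("stain vectors must be separated by at least 10 degrees")
        if self.dab_dose < 0:
            raise ParameterError("dab_dose must be non-negative")
        if not 0 <= self.colocalization_fraction <= 1:
            raise ParameterError("colocalization_fraction must lie in [0, 1]")
        if self.width < 8 or self.height < 8:
            raise ParameterError("phantom must be at least 8 x 8 pixels")
        object.__setattr__(self, "w_true", w)


@dataclass(frozen=True)
class Trial:
    """A synthetic trial: images, designated controls and intended scores."""

    images: list[RGBImage]
    doses: np.ndarray
    idx1: int
    idx5: int
    intended_scores: np.ndarray
    w_true: np.ndarray
    h_true: list[np.ndarray]
    image_ids: list[str]


def _nucleus_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of soft-edged disks at random centers: the hematoxylin map."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    h_map = np.zeros((spec.height, spec.width))
    r_lo, r_hi = spec.nucleus_radius
    for _ in range(spec.n_nuclei):
        cy = rng.uniform(0, spec.height)
        cx = rng.uniform(0, spec.width)
        r = rng.uniform(r_lo, r_hi)
        amp = spec.h_peak * rng.uniform(0.7, 1.0)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        profile = np.clip(1.0 - d2 / r**2, 0.0, 1.0)  # parabolic soft disk
        h_map = np.maximum(h_map, amp * profile)
    return h_map


def _dab_map(
    spec: PhantomSpec, nuclei: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Diffuse cytoplasmic DAB field with controlled nuclear overlap."""
    base = gaussian_filter(rng.standard_normal((spec.height, spec.width)), sigma=6.0)
    base -= base.min()
    if base.max() > 0:
        base /= base.max()
    region = base > np.quantile(base, 0.55)  # diffuse cytoplasmic patches
    strength = np.where(region, 0.4 + 0.6 * base, 0.0)

    nuc_mask = nuclei > 0.05 * spec.h_peak
    coloc = spec.colocalization_fraction
    weight = np.where(nuc_mask, coloc, 1.0 - coloc) * 2.0
    dab = spec.dab_peak * spec.dab_dose * strength * weight
    # a handful of strongly stained pure-DAB clumps so the angle histogram
    # has a clear DAB-edge population even at low dose
    clump = gaussian_filter(rng.standard_normal((spec.height, spec.width)), sigma=2.0)
    clump_mask = (clump > np.quantile(clump, 0.97)) & ~nuc_mask
    dab = np.where(
        clump_mask, spec.dab_peak * max(spec.dab_dose, 0.0) * 1.0, dab
    )
    return dab


def generate_phantom(spec: PhantomSpec) -> tuple[RGBImage, np.ndarray, np.ndarray]:
    """Generate one phantom; returns the image, ``W_true`` and ``H_true``.

    ``H_true`` is 2 x N (hematoxylin row first), matching the row-major
    pixel linearization of :func:`ihcscore.od.rgb_to_od`.  With
    ``noise_sigma = 0`` and ``quantize = False`` the rendered image's OD is
    exactly ``W_true @ H_true``.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _nucleus_map(spec, rng)
    dab = _dab_map(spec, nuclei, rng)
    h_true = np.vstack([nuclei.ravel(), dab.ravel()])
    y = spec.w_true @ h_true
    if spec.noise_sigma > 0:
        noise_rng = (
            rng if spec.noise_seed is None else np.random.default_rng(spec.noise_seed)
        )
        y = np.clip(y + spec.noise_sigma * noise_rng.standard_normal(y.shape), 0.0, None)
    img = od_to_rgb(y, i0=spec.i0, shape=(spec.height, spec.width))
    if spec.quantize:
        img = RGBImage(
            pixels=np.round(img.pixels).astype(np.uint8), i0=spec.i0
        )
    return img, spec.w_true.copy(), h_true


def generate_trial(
    n_images: int,
    dose_schedule,
    seed: int = 0,
    n_categories: int = 5,
    base_spec: PhantomSpec | None = None,
    vary_structure: bool = True,
) -> Trial:
    """Generate a trial of phantoms sharing ``W_true`` with per-image doses.

    The minimum- and maximum-dose images are designated the 1+ and 5+
    controls.  Intended scores are the dose quantile bins: images are
    ranked by dose and split into ``n_categories`` equal-count bins, so a
    graded schedule maps onto the ordinal scale the pipeline should
    recover.

    With ``vary_structure=True`` (the default) every image draws its own
    nucleus and cytoplasm maps, emulating different fields of view.  With
    ``vary_structure=False`` all images share one tissue structure and only
    the DAB dose (and the noise realization) differs — a dilution-series
    setting in which dose-monotonicity of downstream quantities is exact by
    construction.
    """
    doses = np.asarray(dose_schedule, dtype=np.float64)
    if n_images < 2:
        raise ParameterError("a trial needs at least two images")
    if doses.size != n_images:
        raise ParameterError(
            f"dose schedule has {doses.size} entries for {n_images} images"
        )
    base = base_spec or PhantomSpec()

    images: list[RGBImage] = []
    h_true: list[np.ndarray] = []
    for i, dose in enumerate(doses):
        if vary_structure:
            spec = replace(base, dab_dose=float(dose), seed=seed + i)
        else:
            spec = replace(base, dab_dose=float(dose), seed=seed, noise_seed=seed + i + 1)
        img, _, h = generate_phantom(spec)
        images.append(img)
        h_true.append(h)

    idx1 = int(np.argmin(doses))
    idx5 = int(np.argmax(doses))
    ranks = np.argsort(np.argsort(doses, kind="stable"), kind="stable")
    intended = 1 + (ranks * n_categories) // n_images
    return Trial(
        images=images,
        doses=doses,
        idx1=idx1,
        idx5=idx5,
        intended_scores=intended.astype(int),
        w_true=base.w_true.copy(),
        h_true=h_true,
        image_ids=[f"phantom_{i:03d}" for i in range(n_images)],
    )
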