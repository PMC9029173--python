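"""Optical-density model for brightfield RGB images.

Under the Beer-Lambert proxy the transmitted intensity ``i`` of a channel
relates to stain amount through the optical density ``y = -log10(i / I0)``,
where ``I0`` is the illuminating light intensity (255 for 8-bit images).
Optical density is approximately linear in the amount of absorbed stain,
which is what makes linear un-mixing of hematoxylin and DAB possible.  DAB
scatters as well as absorbs light, so OD is only a semi-quantitative proxy
for it; no scattering model is attempted here.

Pixels are linearized row-major (C order), identically in every channel, so
an image of height H and width W becomes a 3 x (H*W) matrix whose column
``t`` is the pixel at ``(t // W, t % W)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, DomainError, FormatError, ParameterError

__all__ = ["RGBImage", "ODImage", "rgb_to_od", "od_to_rgb"]


@dataclass(frozen=True)
class RGBImage:
    """A brightfield RGB image plus its illuminant intensity.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array with channel values in ``[0, i0]``.
        Integer or float; float pixels are accepted so synthetic images
        can carry sub-quantization detail.
    i0
        Illuminating light intensity. 255 for 8-bit acquisitions.
    """

    pixels: np.ndarray
    i0: float = 255.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected a (height, width, 3) RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must contain at least one pixel")
        if self.i0 <= 0:
            raise ParameterError(f"illuminant intensity must be positive, got {self.i0}")
        if px.min() < 0 or px.max() > self.i0:
            raise FormatError(
                f"channel values must lie in [0, {self.i0}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0] * self.pixels.shape[1]


@dataclass(frozen=True)
class ODImage:
    """Optical densities of an image as a 3 x N matrix (pixels as columns).

    ``matrix`` rows are the R, G, B channels; entries are finite and >= 0.
    ``shape`` is the (height, width) of the source image and fixes the
    row-major linearization convention.
    """

    matrix: np.ndarray
    shape: tuple[int, int]
    i0: float = 255.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != 3:
            raise DimensionError(f"OD matrix must be 3 x N, got shape {m.shape}")
        h, w = self.shape
        if m.shape[1] != h * w:
            raise DimensionError(
                f"OD matrix has {m.shape[1]} columns but shape {self.shape} "
                f"implies {h * w} pixels"
            )
        if not np.all(np.isfinite(m)) or m.min() < 0:
            raise DomainError("OD entries must be finite and non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]


def rgb_to_od(img: RGBImage) -> ODImage:
    """Convert an RGB image to optical densities, ``y = -log10(i / I0)``.

    Intensities are clipped to a minimum of 1 before the logarithm so that
    an all-black pixel maps to the finite maximum OD ``log10(I0)`` instead
    of infinity.  Each channel is linearized row-major into a row of the
    returned 3 x N matrix.
    """
    px = np.asarray(img.pixels, dtype=np.float64)
    i = np.clip(px, 1.0, img.i0)
    y = -np.log10(i / img.i0)
    matrix = y.reshape(-1, 3).T  # row-major pixel stacking, channels as rows
    return ODImage(matrix=matrix, shape=img.shape, i0=img.i0)


def od_to_rgb(
    od: ODImage | np.ndarray,
    i0: float | None = None,
    shape: tuple[int, int] | None = None,
) -> RGBImage:
    """Invert the OD transform: ``i = I0 * 10**(-y)``, clipped to ``[0, I0]``.

    Used to render separated stain planes back to viewable RGB and to feed
    the CMYK-based stain ordering.  Round-tripping ``rgb_to_od`` then
    ``od_to_rgb`` reproduces the input exactly (up to quantization) for all
    pixels with intensity >= 1.

    Accepts either an :class:`ODImage` (carrying its own ``i0``/``shape``)
    or a bare 3 x N array, in which case ``i0`` and ``shape`` are required.
    """
    if isinstance(od, ODImage):
        matrix = od.matrix
        i0 = od.i0 if i0 is None else i0
        shape = od.shape if shape is None else shape
    else:
        matrix = np.asarray(od, dtype=np.float64)
        if i0 is None or shape is None:
            raise ParameterError("i0 and shape are required for a bare OD matrix")
    if matrix.ndim != 2 or matrix.shape[0] != 3:
        raise DimensionError(f"OD matrix must be 3 x N, got shape {matrix.shape}")
    h, w = shape
    if matrix.shape[1] != h * w:
        raise DimensionError(
            f"shape {shape} implies {h * w} pixels, OD matrix has {matrix.shape[1]}"
        )
    if matrix.min() < 0:
        raise DomainError("OD entries must be non-negative")
    intensities = i0 * np.power(10.0, -matrix)
    pixels = np.clip(intensities.T.reshape(h, w, 3), 0.0, i0)
    return RGBImage(pixels=pixels, i0=i0)
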