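"""Reading trial manifests and 8-bit RGB images; writing scores, reports
and rendered stain planes."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError
from .od import RGBImage

__all__ = [
    "TrialManifest",
    "read_image",
    "write_image",
    "read_manifest",
    "write_scores",
    "write_report",
]

ROLE_LOW = "control_1plus"
ROLE_HIGH = "control_5plus"


@dataclass(frozen=True)
class TrialManifest:
    """Image paths plus the indices of the designated control images."""

    paths: list[Path]
    image_ids: list[str]
    idx1: int
    idx5: int


def read_image(path: str | Path, i0: float = 255.0) -> RGBImage:
    """Read an 8-bit RGB TIFF/PNG; alpha channels are dropped."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path} is not a 3-channel RGB image (shape {arr.shape})")
    return RGBImage(pixels=arr, i0=i0)


def write_image(path: str | Path, img: RGBImage) -> None:
    """Write an image as 8-bit PNG/TIFF (values rounded to integers)."""
    path = Path(path)
    arr = np.clip(np.round(np.asarray(img.pixels, dtype=np.float64)), 0, 255)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.uint8))
    else:
        iio.imwrite(path, arr.astype(np.uint8))


def read_manifest(
    path: str | Path,
    control_low: str | None = None,
    control_high: str | None = None,
) -> TrialManifest:
    """Parse a trial manifest CSV.

    Columns: ``path`` (required), ``image_id`` (optional; defaults to the
    file stem) and ``role`` (optional; ``control_1plus`` / ``control_5plus``).
    Explicit ``control_low`` / ``control_high`` ids override the role column.
    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "path" not in df.columns:
        raise ParameterError(f"manifest {path} lacks a 'path' column")
    paths = [
        (p if p.is_absolute() else path.parent / p)
        for p in (Path(str(v)) for v in df["path"])
    ]
    if "image_id" in df.columns:
        ids = [str(v) for v in df["image_id"]]
    else:
        ids = [p.stem for p in paths]
    if len(set(ids)) != len(ids):
        raise ParameterError("image ids in the manifest must be unique")

    roles = [str(v).strip().lower() if not pd.isna(v) else "" for v in df["role"]] \
        if "role" in df.columns else [""] * len(ids)

    def _find(designation: str, override: str | None, role_name: str) -> int:
        if override is not None:
            if override not in ids:
                raise ParameterError(f"control id {override!r} not in manifest")
            return ids.index(override)
        matches = [i for i, r in enumerate(roles) if r == role_name]
        if len(matches) != 1:
            raise ParameterError(
                f"manifest must designate exactly one {designation} control "
                f"(role '{role_name}' or an explicit id); found {len(matches)}"
            )
        return matches[0]

    idx1 = _find("low-score", control_low, ROLE_LOW)
    idx5 = _find("high-score", control_high, ROLE_HIGH)
    if idx1 == idx5:
        raise ParameterError("the two controls must be distinct images")
    return TrialManifest(paths=paths, image_ids=ids, idx1=idx1, idx5=idx5)


def write_scores(path: str | Path, image_ids: list[str], scores) -> None:
    """Write the per-image scores CSV with stable formatting."""
    df = pd.DataFrame({"image_id": image_ids, "score": np.asarray(scores, dtype=int)})
    df.to_csv(path, index=False, lineterminator="\n")


def write_report(path: str | Path, report: dict) -> None:
    """Write the JSON run report (centroids, fits, divergence traces...)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default, sort_keys=True))
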