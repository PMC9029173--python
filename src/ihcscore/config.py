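"""Trial configuration: every constant of the pipeline as an overridable
default, loadable from flat YAML."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["TrialConfig"]


@dataclass
class TrialConfig:
    """All tunable pipeline parameters.

    Attributes
    ----------
    beta_nmf
        Beta-divergence shape parameter of the NMF refinement; 0.5 sits in
        the (0, 1) range where the multiplicative updates descend
        monotonically.
    beta_kmeans
        Shape parameter of the clustering divergence (-0.5 by default).
    nmf_max_iter, nmf_tol
        NMF iteration budget and relative-decrease stopping tolerance.
    kmeans_max_iter
        Cap on k-means iterations; 3 keeps final centroids near the
        systematic initialization.
    percentages
        f1 placement of the intermediate centroids, as percentages of the
        control gap.
    f3_convention
        'product' (f3 = N2 * N1) or 'ratio' (f3 = N2 / N1).
    percentile
        Percentile defining the robust pseudo maximum (99).
    pix_h_thr_dab, pix_h_thr_h
        Concentration thresholds of the pixel-wise H-score.
    i0
        Illuminant intensity (255 for 8-bit images).
    seed
        Used only by the synthetic-trial subcommand.
    """

    beta_nmf: float = 0.5
    beta_kmeans: float = -0.5
    nmf_max_iter: int = 50
    nmf_tol: float = 1e-6
    kmeans_max_iter: int = 3
    percentages: tuple[float, ...] = (15.0, 40.0, 70.0)
    f3_convention: str = "product"
    percentile: float = 99.0
    pix_h_thr_dab: tuple[float, float] = (2.5, 0.7)
    pix_h_thr_h: float = 0.7
    i0: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.percentages = tuple(float(p) for p in self.percentages)
        self.pix_h_thr_dab = tuple(float(t) for t in self.pix_h_thr_dab)
        if not all(0 < p < 100 for p in self.percentages):
            raise ParameterError(
                f"centroid percentages must lie strictly in (0, 100), got {self.percentages}"
            )
        if list(self.percentages) != sorted(set(self.percentages)):
            raise ParameterError("centroid percentages must be strictly increasing")
        if self.f3_convention not in ("product", "ratio"):
            raise ParameterError(f"unknown f3 convention {self.f3_convention!r}")
        if self.kmeans_max_iter > 3:
            warnings.warn(
                "kmeans_max_iter > 3: final centroids may drift far from the "
                "systematic initialization"
            )

    @property
    def n_categories(self) -> int:
        return len(self.percentages) + 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["percentages"] = list(self.percentages)
        data["pix_h_thr_dab"] = list(self.pix_h_thr_dab)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
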