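"""Domain containers and the two normalizations applied before patch statistics.

A spatial transcriptomics sample is a set of M spots (capture locations or
segmented cells) in 2D or 3D, each carrying an expression vector over N genes.
Before any patch computation two normalizations are applied:

* expression is min-max scaled per gene to [0, 1] across spots, and
* coordinates are rescaled by the spot density so the typical spot-to-spot
  spacing is about one unit, which gives the patch radii a sample-independent
  meaning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "BoundingBox",
    "BspConfig",
    "minmax_normalize_expression",
    "normalize_coordinates",
]


@dataclass
class SpatialDataset:
    """Spot-level expression with spot coordinates.

    Parameters
    ----------
    coords
        ``(M, d)`` array of spot positions, ``d`` in {2, 3}. Arbitrary physical
        units on input; "normalized units" after :func:`normalize_coordinates`.
    expr
        ``(M, N)`` array, expression of gene ``j`` at spot ``i``. Row order
        matches ``coords``.
    gene_ids, spot_ids
        Labels; generated if omitted.
    """

    coords: np.ndarray
    expr: np.ndarray
    gene_ids: np.ndarray = None
    spot_ids: np.ndarray = None
    expr_normalized: bool = False
    coords_normalized: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (1, 2, 3):
            raise ValueError(f"coords must be (M, d) with d in {{2, 3}}, got {self.coords.shape}")
        if self.expr.ndim != 2:
            raise ValueError("expr must be a 2D (spots x genes) array")
        if self.expr.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"row mismatch: {self.expr.shape[0]} expression rows vs "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 spots")
        if self.expr.shape[1] < 1:
            raise ValueError("need at least 1 gene")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain missing/non-finite values")
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{j}" for j in range(self.n_genes)], dtype=object)
        else:
            self.gene_ids = np.asarray(self.gene_ids, dtype=object)
            if self.gene_ids.shape[0] != self.n_genes:
                raise ValueError("gene_ids length mismatch")
        if self.spot_ids is None:
            self.spot_ids = np.array([f"spot_{i}" for i in range(self.n_spots)], dtype=object)
        else:
            self.spot_ids = np.asarray(self.spot_ids, dtype=object)
            if self.spot_ids.shape[0] != self.n_spots:
                raise ValueError("spot_ids length mismatch")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            coords=self.coords.copy(),
            expr=self.expr.copy(),
            gene_ids=self.gene_ids.copy(),
            spot_ids=self.spot_ids.copy(),
            expr_normalized=self.expr_normalized,
            coords_normalized=self.coords_normalized,
        )


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned bounding box of the spot cloud; per-dimension ranges."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "BoundingBox":
        coords = np.asarray(coords, dtype=float)
        return cls(mins=coords.min(axis=0), maxs=coords.max(axis=0))

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins

    @property
    def measure(self) -> float:
        """Area (2D) or volume (3D) of the box."""
        return float(np.prod(self.ranges))


@dataclass(frozen=True)
class BspConfig:
    """Parameters of the big-small patch pipeline.

    ``d1`` and ``d2`` are the small- and big-patch radii in normalized
    coordinate units (after density rescaling one unit is roughly one
    spot-to-spot spacing). ``include_center`` controls whether a spot belongs
    to its own patch; including it makes the variance of local means vanish
    exactly once a patch covers the whole sample.
    """

    d1: float = 1.0
    d2: float = 3.0
    alpha: float = 0.05
    null_augmentation_threshold: int = 1000
    null_pool_size: int = 10000
    include_center: bool = True
    weighting: str = "max_normalized"  # or "expression_variance"
    adjust: bool = True
    call_on_adjusted: bool = False
    free_beta_support: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.d1 < self.d2):
            raise ValueError(f"need 0 < d1 < d2, got d1={self.d1}, d2={self.d2}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def minmax_normalize_expression(dataset: SpatialDataset) -> SpatialDataset:
    """Scale each gene to [0, 1] across spots: ``(x - min) / (max - min)``.

    Constant genes (zero range) map to all zeros; they carry no spatial signal
    and receive p = 1 downstream. Idempotent.
    """
    expr = dataset.expr
    lo = expr.min(axis=0)
    hi = expr.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    out = (expr - lo) / safe
    out[:, rng == 0] = 0.0
    ds = dataset.copy()
    ds.expr = out
    ds.expr_normalized = True
    return ds


def normalize_coordinates(dataset: SpatialDataset) -> SpatialDataset:
    """Rescale coordinates by spot density so mean spacing is ~1 unit.

    All coordinates are multiplied by ``s = (M / V)^(1/d)`` where ``V`` is the
    area (2D) or volume (3D) of the axis-aligned bounding box. A dimension with
    zero range (e.g. a single z-plane passed as 3D) is dropped with a warning,
    since it contributes nothing to the density. Raises if all spots coincide.
    """
    coords = dataset.coords
    box = BoundingBox.from_coords(coords)
    nonzero = box.ranges > 0
    if not nonzero.any():
        raise ValueError("all spots coincide: bounding box has zero measure")
    ds = dataset.copy()
    if not nonzero.all():
        dropped = [i for i, keep in enumerate(nonzero) if not keep]
        warnings.warn(
            f"dropping degenerate coordinate dimension(s) {dropped} with zero range",
            stacklevel=2,
        )
        coords = coords[:, nonzero]
        box = BoundingBox.from_coords(coords)
    d = coords.shape[1]
    scale = (dataset.n_spots / box.measure) ** (1.0 / d)
    ds.coords = coords * scale
    ds.coords_normalized = True
    logger.info("coordinate normalization: d=%d, scale=%.6g", d, scale)
    return ds
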