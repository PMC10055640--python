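"""3D benchmark simulator: stacked sections with random-walk sphere patterns.

The emulated assay cryosections a tissue into ``n_sections`` slices, places a
fixed number of cells per slice by a uniform Poisson point pattern, and stacks
the slices with the section index as the z-coordinate. A 3D spatial pattern is
the union of spheres of radius ``r`` around the centers of a random walk with
fixed step length; three geometries are produced by constraining the walk's
direction signs:

* Pattern I ("curved stick")  — monotone in two axes (x and z),
* Pattern II ("thin plate")   — monotone in z only,
* Pattern III ("irregular lump") — unconstrained.

Marked cells (inside the pattern) draw expression from the upper quantile of
a reference expression pool, unmarked cells from the full pool; each SVG
spawns 9 spot-permuted null genes, and Gaussian noise scaled to the average
per-gene standard deviation is added to the whole matrix last, so nulls and
SVGs carry identical noise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import SpatialDataset
from .sim2d import SimulatedReplicate

__all__ = [
    "Sim3DConfig",
    "poisson_sections",
    "walk_centers",
    "mark_cells",
    "default_expression_pool",
    "quantile_for_fold_change",
    "sample_svg_expression",
    "add_noise",
    "simulate_replicate_3d",
]

PATTERNS_3D = ("I", "II", "III")

#: axes with a fixed positive direction sign, per pattern
_MONOTONE_AXES = {"I": (0, 2), "II": (2,), "III": ()}


@dataclass(frozen=True)
class Sim3DConfig:
    """Study conditions of one 3D replicate.

    The x-y window side is chosen so the cell density is ~1 per unit area per
    section (225 cells in a 15 x 15 window), making the sphere radii r = 1.5,
    2.0, 2.5 and the walk step length 2 directly comparable to the ~1-unit
    cell spacing. Signal strength is set by the pool quantile ``q`` (marked
    cells draw from values above it): q = 0.66, 0.80, 0.88 correspond to
    marked/unmarked fold changes of about 2, 2.5, 3 for the default log-normal
    pool. ``sigma_multiplier`` scales the Gaussian noise relative to the
    average per-gene standard deviation.
    """

    n_sections: int = 10
    cells_per_section: int = 225
    window: float = 15.0
    step_length: float = 2.0
    n_steps: int = 10
    radius: float = 2.0
    pattern: str = "I"
    quantile: float = 0.80
    sigma_multiplier: float = 1.0
    n_svg: int = 1000
    n_permutations: int = 9
    pool_size: int = 10000
    shared_pattern: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_sections < 1:
            raise ValueError("need at least 1 section")
        if self.radius <= 0 or self.step_length <= 0:
            raise ValueError("radius and step_length must be positive")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")
        if self.sigma_multiplier < 0:
            raise ValueError("sigma_multiplier must be nonnegative")
        if self.pattern not in PATTERNS_3D:
            raise ValueError(f"pattern must be one of {PATTERNS_3D}")


def poisson_sections(
    n_sections: int = 10,
    cells_per_section: int = 225,
    window: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Stacked uniform point patterns; z is the 1-based section index."""
    rng = np.random.default_rng(seed)
    sections = []
    for z in range(1, n_sections + 1):
        xy = rng.uniform(0.0, window, size=(cells_per_section, 2))
        sections.append(np.column_stack([xy, np.full(cells_per_section, float(z))]))
    return np.concatenate(sections, axis=0)


def walk_centers(
    pattern: str,
    step_length: float = 2.0,
    n_steps: int = 10,
    window: float = 15.0,
    n_sections: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Sphere centers from a fixed-step random walk with sign constraints.

    Directions are uniform on the sphere with the constrained axes forced
    positive (component sign flipped), so consecutive centers are at distance
    exactly ``step_length`` and constrained coordinates increase strictly.
    Constrained axes start near their low bound and are never reflected;
    unconstrained axes start at the window center and reflect at the bounds,
    keeping the pattern inside the observed volume. Returns ``n_steps + 1``
    centers including the start.
    """
    if pattern not in PATTERNS_3D:
        raise ValueError(f"pattern must be one of {PATTERNS_3D}")
    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 0.0, 0.5])
    hi = np.array([window, window, n_sections + 0.5])
    mono = _MONOTONE_AXES[pattern]
    start = (lo + hi) / 2.0
    for ax in mono:
        start[ax] = lo[ax] + 0.05 * (hi[ax] - lo[ax])
    centers = [start.copy()]
    pos = start.copy()
    for _ in range(n_steps):
        u = rng.standard_normal(3)
        norm = np.linalg.norm(u)
        while norm == 0:  # pragma: no cover - probability zero
            u = rng.standard_normal(3)
            norm = np.linalg.norm(u)
        u /= norm
        for ax in mono:
            u[ax] = abs(u[ax])
        pos = pos + step_length * u
        for ax in range(3):
            if ax in mono:
                continue
            # reflect into [lo, hi]
            span = hi[ax] - lo[ax]
            t = (pos[ax] - lo[ax]) % (2 * span)
            pos[ax] = lo[ax] + (t if t <= span else 2 * span - t)
        centers.append(pos.copy())
    return np.array(centers)


def mark_cells(coords: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    """Cells within distance < radius of any sphere center."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        raise ValueError("centers must be nonempty")
    d, _ = cKDTree(centers).query(np.asarray(coords, dtype=float))
    return d < radius


def default_expression_pool(size: int = 10000, seed: int = 0) -> np.ndarray:
    """Synthetic reference expression pool: log-normal(meanlog 0, sdlog 1).

    A stand-in for an empirical single-cell expression distribution; any
    observed value vector can be passed wherever a pool is accepted.
    """
    return np.random.default_rng(seed).lognormal(0.0, 1.0, size=size)


def quantile_for_fold_change(pool: np.ndarray, fold_change: float, tol: float = 1e-6) -> float:
    """Solve for the pool quantile q giving a target marked/unmarked mean ratio.

    The marked-cell mean is the mean of pool values above the q-quantile, the
    unmarked mean is the full-pool mean; their ratio is continuous and
    increasing in q, so bisection applies.
    """
    pool = np.sort(np.asarray(pool, dtype=float))
    full_mean = pool.mean()

    def ratio(q: float) -> float:
        thr = np.quantile(pool, q)
        upper = pool[pool > thr]
        if upper.size == 0:
            return pool[-1] / full_mean
        return upper.mean() / full_mean

    lo, hi = 1e-6, 1.0 - 1e-6
    if fold_change <= ratio(lo):
        return lo
    if fold_change >= ratio(hi):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ratio(mid) < fold_change:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_svg_expression(
    pool: np.ndarray,
    mask: np.ndarray,
    q: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One SVG gene: marked cells draw from the pool's upper q-tail.

    Marked cells draw uniformly with replacement from pool values strictly
    above the q-quantile; unmarked cells draw from the full pool. Raises if
    the upper-quantile slice is empty.
    """
    pool = np.asarray(pool, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pool.size < 100:
        raise ValueError("expression pool must hold at least 100 values")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    thr = np.quantile(pool, q)
    upper = pool[pool > thr]
    if upper.size == 0:
        raise ValueError("upper-quantile slice of the pool is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.choice(pool, size=mask.size, replace=True)
    values[mask] = rng.choice(upper, size=int(mask.sum()), replace=True)
    return values


def add_noise(expr: np.ndarray, sigma_multiplier: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add N(0, (sigma_multiplier * sbar)^2) per entry.

    ``sbar`` is the average over genes of the per-gene standard deviation, so
    the multiplier expresses noise relative to the typical expression spread.
    ``sigma_multiplier=0`` returns the input unchanged.
    """
    expr = np.asarray(expr, dtype=float)
    if sigma_multiplier == 0:
        return expr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sbar = expr.std(axis=0).mean()
    return expr + rng.normal(0.0, sigma_multiplier * sbar, size=expr.shape)


def simulate_replicate_3d(config: Sim3DConfig | None = None) -> SimulatedReplicate:
    """One labeled 3D replicate: SVGs, 9x permutation nulls, then noise.

    By default all SVGs share one random-walk pattern per replicate, the way
    one tissue structure drives many genes; ``shared_pattern=False`` draws an
    independent walk (hence mask) per gene.
    """
    config = config or Sim3DConfig()
    rng = np.random.default_rng(config.seed)
    coords = poisson_sections(
        config.n_sections, config.cells_per_section, config.window, seed=config.seed
    )
    pool = default_expression_pool(config.pool_size, seed=config.seed + 1)

    def one_mask(walk_seed: int) -> np.ndarray:
        centers = walk_centers(
            config.pattern, config.step_length, config.n_steps,
            config.window, config.n_sections, seed=walk_seed,
        )
        return mark_cells(coords, centers, config.radius)

    m = coords.shape[0]
    shared_mask = one_mask(config.seed + 2) if config.shared_pattern else None

    svg = np.empty((m, config.n_svg))
    for j in range(config.n_svg):
        mask = shared_mask if config.shared_pattern else one_mask(config.seed + 2 + j)
        svg[:, j] = sample_svg_expression(pool, mask, config.quantile, seed=rng)

    n_null = config.n_svg * config.n_permutations
    null = np.empty((m, n_null))
    for j in range(config.n_svg):
        for k in range(config.n_permutations):
            null[:, j * config.n_permutations + k] = rng.permutation(svg[:, j])

    expr = np.concatenate([svg, null], axis=1)
    expr = add_noise(expr, config.sigma_multiplier, seed=rng)

    gene_ids = np.array(
        [f"svg_{j:05d}" for j in range(config.n_svg)]
        + [f"null_{j:05d}" for j in range(n_null)],
        dtype=object,
    )
    labels = ["svg"] * config.n_svg + ["null"] * n_null
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels, "pattern": config.pattern})
    dataset = SpatialDataset(coords=coords, expr=expr, gene_ids=gene_ids)
    mask_out = shared_mask if config.shared_pattern else np.zeros(m, dtype=bool)
    return SimulatedReplicate(dataset=dataset, truth=truth, marked_mask=mask_out, config=config)
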