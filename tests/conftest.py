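import numpy as np
import pytest

from bsp.core import SpatialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_dataset(rng):
    """50 spots, 12 genes, raw (unnormalized) coordinates and expression."""
    coords = rng.uniform(0, 8, size=(50, 2))
    expr = rng.gamma(2.0, 3.0, size=(50, 12))
    return SpatialDataset(coords=coords, expr=expr)


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately naive: all-pairs loops, explicit formulas
# ---------------------------------------------------------------------------

def brute_neighbor_sets(coords, radius, include_center=False):
    coords = np.asarray(coords, float)
    m = coords.shape[0]
    sets = []
    for i in range(m):
        members = []
        for l in range(m):
            if l == i:
                if include_center:
                    members.append(l)
                continue
            if np.sqrt(((coords[i] - coords[l]) ** 2).sum()) < radius:
                members.append(l)
        sets.append(sorted(members))
    return sets


def brute_local_means(expr, sets):
    expr = np.asarray(expr, float)
    m, n = expr.shape
    lm = np.empty((m, n))
    for i, members in enumerate(sets):
        lm[i] = expr[list(members)].mean(axis=0) if members else expr[i]
    return lm


def brute_variance(values):
    values = np.asarray(values, float)
    mu = values.mean(axis=0)
    return ((values - mu) ** 2).mean(axis=0)


def brute_bsp_scores(coords, expr, d1, d2, include_center=True):
    """Naive end-to-end score computation mirroring the published definitions."""
    coords = np.asarray(coords, float)
    expr = np.asarray(expr, float)
    m, n = expr.shape
    # min-max per gene
    norm = np.empty_like(expr)
    for j in range(n):
        lo, hi = expr[:, j].min(), expr[:, j].max()
        norm[:, j] = (expr[:, j] - lo) / (hi - lo) if hi > lo else 0.0
    # density rescaling
    ranges = coords.max(axis=0) - coords.min(axis=0)
    scale = (m / np.prod(ranges)) ** (1.0 / coords.shape[1])
    scaled = coords * scale
    sigmas = []
    for d in (d1, d2):
        sets = brute_neighbor_sets(scaled, d, include_center=include_center)
        sigmas.append(brute_variance(brute_local_means(norm, sets)))
    s1, s2 = sigmas
    scores = np.zeros(n)
    ok = s1 > 0
    if s1.max() > 0 and s2.max() > 0:
        scores[ok] = (s2[ok] / s2.max()) / (s1[ok] / s1.max())
    return s1, s2, scores


def brute_morans_i(x, w):
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    m = x.size
    xc = x - x.mean()
    num = sum(w[i, l] * xc[i] * xc[l] for i in range(m) for l in range(m))
    return (m / w.sum()) * num / (xc ** 2).sum()
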