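"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's computational paths: areas come
from weighted Monte-Carlo point sampling on the sphere, field assignment
from direct nearest-center tests on sampled points, and the
Kruskal-Wallis statistic from the textbook rank-sum formula evaluated
over exhaustive permutations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import shapely


def sphere_weights(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Equidistant-chart area weights sin(eps)/eps at chart points (deg)."""
    eps = np.hypot(xs, ys)
    # np.sinc(x) = sin(pi x)/(pi x); eps/180 deg -> radians argument
    return np.sinc(eps / 180.0)


def mc_spherical_area(geom, mm_per_degree: float, n: int, seed: int) -> float:
    """Monte-Carlo spherical surface area (mm^2) of a chart region."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = shapely.contains_xy(geom, xs, ys)
    w = sphere_weights(xs, ys)
    box_area = (maxx - minx) * (maxy - miny)
    deg2 = box_area * float((w * inside).mean())
    return deg2 * mm_per_degree**2


def mc_field_fractions(poly, layout, n: int, seed: int) -> tuple[np.ndarray, float]:
    """Monte-Carlo per-field area fractions of a lesion polygon.

    Samples sphere-weighted points inside the polygon, assigns in-union
    points to the nearest field center and returns (fractions[7], outside).
    """
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    keep = shapely.contains_xy(poly, xs, ys)
    xs, ys = xs[keep], ys[keep]
    w = sphere_weights(xs, ys)
    total = w.sum()
    in_union = shapely.contains_xy(layout.union, xs, ys)
    centers = np.array([f.center for f in layout.fields])
    d2 = (xs[:, None] - centers[None, :, 0]) ** 2 + (ys[:, None] - centers[None, :, 1]) ** 2
    assign = np.argmin(d2, axis=1)
    fractions = np.array([w[(assign == i) & in_union].sum() for i in range(len(centers))]) / total
    outside = float(w[~in_union].sum() / total)
    return fractions, outside


def kw_statistic_textbook(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H via the classic rank-sum formula."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    rank_vals = np.empty(len(pooled))
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rank_vals[i:j] = 0.5 * (i + 1 + j)
        i = j
    ranks[order] = rank_vals
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kw_permutation_distribution(groups: list[np.ndarray]) -> tuple[float, np.ndarray]:
    """Observed H plus its exact permutation distribution (small n only)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    observed = kw_statistic_textbook(groups)
    n = len(pooled)
    stats = []
    indices = list(range(n))
    for combo in itertools.permutations(indices):
        vals = pooled[list(combo)]
        split, start = [], 0
        for s in sizes:
            split.append(vals[start : start + s])
            start += s
        stats.append(kw_statistic_textbook(split))
    return observed, np.array(stats)
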