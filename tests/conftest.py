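"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import heapq

import numpy as np
import pytest

import starchseg as ss


@pytest.fixture
def disk_mask():
    """Factory: boolean mask with one or more filled disks."""

    def _make(shape, disks):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        m = np.zeros(shape, dtype=bool)
        for cy, cx, r in disks:
            m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        return m

    return _make


@pytest.fixture
def single_disk_scene():
    """Factory: one-granule synthetic scene with given radius/seed."""

    def _make(radius=20.0, seed=0, noise=ss.SceneSpec().noise_sigma, size=128, ratio=(1.0, 1.0)):
        spec = ss.SceneSpec(
            n_granules=1,
            radius_range=(radius, radius),
            image_size=(size, size),
            noise_sigma=noise,
            axis_ratio_range=ratio,
            seed=seed,
        )
        return ss.generate_scene(spec)

    return _make


# ---------------------------------------------------------------- oracles


def isodata_oracle(pixels: np.ndarray, t0: float, eps: float) -> float:
    """Plain re-iteration of the class-mean-midpoint update on raw pixels."""
    vals = np.sort(np.asarray(pixels, dtype=float).ravel())
    t = float(t0)
    for _ in range(10_000):
        lo = vals[vals < t]
        hi = vals[vals >= t]
        mu1 = lo.mean() if lo.size else t
        mu2 = hi.mean() if hi.size else t
        t_new = (mu1 + mu2) / 2.0
        if abs(t_new - t) < eps:
            return t_new
        t = t_new
    return t


def chamfer_dijkstra_oracle(mask: np.ndarray, weights=(3, 4)) -> np.ndarray:
    """Shortest chamfer-graph path from any background pixel (incl. the
    out-of-image ring) to each foreground pixel; small masks only."""
    a, b = weights
    m = np.pad(np.asarray(mask, bool), 1, constant_values=False)
    h, w = m.shape
    dist = np.where(m, np.inf, 0.0)
    heap = [(0.0, i, j) for i in range(h) for j in range(w) if not m[i, j]]
    heapq.heapify(heap)
    steps = [(-1, -1, b), (-1, 0, a), (-1, 1, b), (0, -1, a), (0, 1, a), (1, -1, b), (1, 0, a), (1, 1, b)]
    while heap:
        d, i, j = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        for di, dj, wt in steps:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and d + wt < dist[ni, nj]:
                dist[ni, nj] = d + wt
                heapq.heappush(heap, (d + wt, ni, nj))
    return dist[1:-1, 1:-1] / a


def euclidean_oracle(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel (incl. the
    out-of-image ring), by exhaustive nearest-neighbour search."""
    from scipy.spatial import cKDTree

    m = np.pad(np.asarray(mask, bool), 1, constant_values=False)
    bg = np.argwhere(~m)
    fg = np.argwhere(m)
    out = np.zeros(m.shape)
    if fg.size:
        d, _ = cKDTree(bg).query(fg)
        out[tuple(fg.T)] = d
    return out[1:-1, 1:-1]


def descending_flood_oracle(dist: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Steepest-descent flooding: assign foreground pixels in order of
    decreasing distance; a pixel inherits the label of its highest
    already-assigned 8-neighbour, or starts a new basin if none exists."""
    labels = np.zeros(dist.shape, dtype=int)
    order = np.argwhere(mask)
    order = order[np.lexsort((order[:, 1], order[:, 0], -dist[tuple(order.T)]))]
    nxt = 1
    h, w = dist.shape
    for i, j in order:
        best = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and labels[ni, nj] > 0:
                    if best is None or dist[ni, nj] > best[0]:
                        best = (dist[ni, nj], labels[ni, nj])
        if best is None:
            labels[i, j] = nxt
            nxt += 1
        else:
            labels[i, j] = best[1]
    return labels


# Published per-segment data of the reference micrograph: 15 watershed
# segments (segment 1 = background), their roundness values and whether a
# GVF critical point was found near the segment centre.
TABLE1_ROUNDNESS = {
    1: 0.654, 2: 0.761, 3: 0.16, 4: 0.352, 5: 0.26, 6: 0.26, 7: 0.911,
    8: 0.785, 9: 0.877, 10: 0.771, 11: 0.357, 12: 0.748, 13: 0.208,
    14: 0.749, 15: 0.907,
}
TABLE1_CRITICAL = {2, 7, 8, 9, 10, 14, 15}
TABLE1_BACKGROUND = 1
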