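"""Small voxel-geometry helpers: closed Euclidean balls on the integer grid."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: 6-connected (face-neighbor) structuring element used for dilation,
#: boundary detection, and surface counting.
CROSS_STRUCT = np.array(
    [
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
    ],
    dtype=bool,
)


@lru_cache(maxsize=64)
def ball_offsets(radius: float) -> np.ndarray:
    """Integer (dz, dy, dx) offsets of the closed ball of the given radius.

    Offsets are sorted by (squared distance, dz, dy, dx), so the first entry
    is always (0, 0, 0); this ordering implements the tie-breaking rules for
    brightest-voxel shifting.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    rng = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(rng, rng, rng, indexing="ij")
    d2 = dz**2 + dy**2 + dx**2
    keep = d2 <= radius**2
    offs = np.stack([dz[keep], dy[keep], dx[keep]], axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], (offs**2).sum(axis=1)))
    out = offs[order]
    out.setflags(write=False)
    return out


def clip_ball_voxels(
    center: tuple[int, int, int], radius: float, shape: tuple[int, int, int]
) -> np.ndarray:
    """Absolute (z, y, x) voxel coordinates of the closed ball, clipped to bounds."""
    offs = ball_offsets(radius)
    pts = offs + np.asarray(center)
    inside = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    return pts[inside]


def pairwise_min_distance(points: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance among row-vector points (inf if < 2)."""
    if len(points) < 2:
        return float("inf")
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min())
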