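"""Independent brute-force oracles for the surface-distance metrics.

Everything here is O(n²) enumeration on voxel coordinate lists — no
distance transforms, no shared code with the package implementation.
"""

import numpy as np


def brute_surface_points(mask):
    """Coordinates of mask voxels with a 6-connected background/outside
    neighbour, by direct neighbour enumeration."""
    mask = np.asarray(mask, dtype=bool)
    pts = []
    for p in np.argwhere(mask):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = p + d
            if (q < 0).any() or (q >= mask.shape).any() or not mask[tuple(q)]:
                pts.append(tuple(p))
                break
    return np.array(pts, dtype=float)


def brute_directed(src_pts, dst_pts, spacing):
    """All-pairs nearest distances in mm from each src point to dst."""
    s = np.asarray(spacing, dtype=float)
    d = (src_pts[:, None, :] - dst_pts[None, :, :]) * s
    return np.sqrt((d ** 2).sum(-1)).min(axis=1)


def brute_hd95(a, b, spacing, q=95.0):
    sa, sb = brute_surface_points(a), brute_surface_points(b)
    return max(np.percentile(brute_directed(sa, sb, spacing), q),
               np.percentile(brute_directed(sb, sa, spacing), q))


def brute_hd100(a, b, spacing):
    sa, sb = brute_surface_points(a), brute_surface_points(b)
    return max(brute_directed(sa, sb, spacing).max(),
               brute_directed(sb, sa, spacing).max())


def brute_asd(a, b, spacing):
    sa, sb = brute_surface_points(a), brute_surface_points(b)
    dab = brute_directed(sa, sb, spacing)
    dba = brute_directed(sb, sa, spacing)
    return (dab.sum() + dba.sum()) / (len(dab) + len(dba))


def brute_dsc(a, b):
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    inter = sum(1 for p in np.argwhere(a) if b[tuple(p)])
    return 1.0 if (a.sum() + b.sum()) == 0 else 2.0 * inter / (int(a.sum()) + int(b.sum()))


def random_mask_pair(rng, max_side=16, p_fg=0.25):
    """A random non-empty blob-ish mask pair on a common grid."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    while True:
        a = rng.random(shape) < p_fg
        b = rng.random(shape) < p_fg
        if a.any() and b.any():
            return a, b
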