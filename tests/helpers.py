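"""Shared independent oracles for the test suite."""

import numpy as np


def brute_force_bbox(img):
    """Exhaustive per-pixel scan for the nonzero bounding box."""
    nz = [(r, c) for r in range(img.shape[0]) for c in range(img.shape[1])
          if img[r, c] > 0]
    rows = [r for r, _ in nz]
    cols = [c for _, c in nz]
    return min(rows), max(rows), min(cols), max(cols)


def brute_force_knn(points, i, k):
    """All-pairs Euclidean sort, ties broken by lower index."""
    points = np.asarray(points, dtype=np.float64)
    dists = [(float(np.linalg.norm(points[j] - points[i])), j)
             for j in range(len(points)) if j != i]
    dists.sort()
    return [j for _, j in dists[:k]]
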