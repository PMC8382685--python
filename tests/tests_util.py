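"""Small helpers shared by the test modules (independent of the package)."""
import numpy as np


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_rigid(rng, scale: float = 20.0):
    """Random rotation + translation."""
    return random_rotation(rng), rng.standard_normal(3) * scale


def brute_force_average_linkage(d: np.ndarray, cutoff: float) -> list[frozenset]:
    """O(n^3) unweighted average-linkage agglomeration, merge while the
    minimum average inter-cluster distance is <= cutoff.  Independent
    oracle for the clustering module."""
    d = np.asarray(d, float)
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        if best[0] > cutoff:
            break
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return clusters


def partition_from_labels(labels) -> set[frozenset]:
    out = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}
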