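"""Independent brute-force oracles shared by the test modules."""
import itertools

import numpy as np

from cgfold.trajectory_analysis import RMSDMatrix


def planted_matrix(blob_sizes, sep=100.0, spread=1.0, seed=0):
    """Synthetic RMSD matrix with planted 1-D blobs far apart, plus random
    frame energies and the ground-truth blob labels."""
    rng = np.random.default_rng(seed)
    pts = []
    for b, size in enumerate(blob_sizes):
        for _ in range(size):
            pts.append(b * sep + rng.uniform(0, spread))
    pts = np.array(pts)
    M = np.abs(pts[:, None] - pts[None, :])
    np.fill_diagonal(M, 0.0)
    labels = np.repeat(np.arange(len(blob_sizes)), blob_sizes)
    energies = rng.normal(0, 1, len(pts))
    keys = [(0, 0, k) for k in range(len(pts))]
    return RMSDMatrix(keys, M, True), energies, labels


def brute_force_d(M, energies, threshold, max_clusters=5):
    """Literal max-neighborhood iteration with explicit tie rules."""
    remaining = list(range(len(M)))
    clusters, reps = [], []
    while remaining and len(clusters) < max_clusters:
        best = None
        for p in remaining:
            nbrs = [q for q in remaining if M[p, q] <= threshold]
            key = (-len(nbrs), energies[p], p)
            if best is None or key < best[0]:
                best = (key, p, nbrs)
        clusters.append(sorted(best[2]))
        reps.append(best[1])
        remaining = [q for q in remaining if q not in set(best[2])]
    return clusters, reps


def brute_force_e(M, energies, threshold, max_clusters=5):
    """Literal best-energy-seeded iteration."""
    remaining = list(range(len(M)))
    clusters, reps = [], []
    while remaining and len(clusters) < max_clusters:
        seed = min(remaining, key=lambda p: (energies[p], p))
        members = sorted(q for q in remaining
                         if q == seed or M[seed, q] < threshold)
        clusters.append(members)
        reps.append(seed)
        remaining = [q for q in remaining if q not in set(members)]
    return clusters, reps


def max_clique_under_diameter(M, remaining, threshold):
    """Exhaustive largest subset with all pairwise distances < threshold
    (ties resolved by smaller total intra-cluster distance)."""
    best, best_intra = (), None
    for r in range(len(remaining), 0, -1):
        for sub in itertools.combinations(remaining, r):
            if all(M[a, b] < threshold
                   for a, b in itertools.combinations(sub, 2)):
                intra = sum(M[a, b]
                            for a, b in itertools.combinations(sub, 2))
                if len(sub) > len(best) or (
                    len(sub) == len(best) and intra < best_intra
                ):
                    best, best_intra = sub, intra
        if best:
            return list(best)
    return []
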