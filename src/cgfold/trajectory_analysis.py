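"""Post-simulation analysis.

Selection of the best-scored frames, all-against-all RMSD with or without
superposition, three clustering schemes, representative extraction and
base-pair Matthews-correlation evaluation.  Everything here operates on
stored trajectories, so an analysis can be rerun with different parameters
without re-simulating.

"Best-scored" always means lowest total energy.  Ties are broken everywhere
the same way: lower energy first, then the earlier frame in (replica, step)
order (runs in the order they were given, when several trajectories are
pooled).

Clustering options:

* **D** (classic): the frame that attracts the most frames within the RMSD
  threshold becomes a cluster representative; its neighborhood is extracted
  and the procedure recurses on the remainder.
* **C** (quality threshold): every cluster member must stay within the
  threshold of every other member (complete diameter); the representative is
  the member minimizing the cumulative RMSD to its co-members — tight,
  low-variability clusters.
* **E**: the best-scored remaining frame seeds a cluster of everything
  within the threshold of it; iterate.

At most five clusters are reported; remaining frames stay unassigned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .cg_model_io import (
    CGConformation,
    Trajectory,
    TrajectoryFrame,
    frame_to_conformation,
    write_structure,
)

BACKBONE_BEADS = (0, 1)  # P, C4'


@dataclass
class FrameRecord:
    """A frame plus enough context to order it and rebuild a conformation."""

    run: int
    frame: TrajectoryFrame
    traj: Trajectory

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.run, self.frame.replica, self.frame.step)

    @property
    def energy(self) -> float:
        return self.frame.energy_total

    def coords(self) -> np.ndarray:
        return self.frame.coordinates.reshape(-1, 3)


@dataclass
class RMSDMatrix:
    frame_keys: list[tuple[int, int, int]]
    matrix: np.ndarray
    superposed: bool

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-9) or np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("RMSD matrix must be symmetric with zero diagonal")


@dataclass
class Clustering:
    method: str                       # C | D | E
    threshold: float
    clusters: list[list[int]]         # member positions into the frame list
    representatives: list[int]        # one position per cluster
    frame_keys: list[tuple[int, int, int]] = field(default_factory=list)


def select_top_frames(
    trajs: Trajectory | list[Trajectory], percent: float
) -> list[FrameRecord]:
    """The best ``percent`` of pooled frames, sorted ascending by energy."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    pool = [
        FrameRecord(run, f, t)
        for run, t in enumerate(trajs)
        for f in t.frames
    ]
    if not pool:
        raise ValueError("no frames to select from")
    pool.sort(key=lambda r: r.key)          # tie order: earlier frame first
    pool.sort(key=lambda r: r.energy)       # stable: ties keep frame order
    k = math.ceil(percent / 100.0 * len(pool))
    return pool[:k]


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def raw_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Root-mean-square coordinate deviation with no superposition."""
    X = np.asarray(X, float).reshape(-1, 3)
    Y = np.asarray(Y, float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape} vs {Y.shape}")
    d = X - Y
    return float(np.sqrt((d * d).sum() / len(X)))


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimal RMSD over proper rotations and translations (no reflection)."""
    X = np.asarray(X, float).reshape(-1, 3)
    Y = np.asarray(Y, float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape} vs {Y.shape}")
    if len(X) < 3:
        raise ValueError("need at least 3 points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = (U * np.array([1.0, 1.0, d])) @ Vt
    diff = Xc @ R - Yc
    return float(np.sqrt((diff * diff).sum() / len(X)))


def _subset_indices(n_res: int, subset) -> np.ndarray:
    if subset is None or subset == "all":
        return np.arange(5 * n_res)
    if subset == "backbone":
        return (5 * np.arange(n_res)[:, None] + np.array(BACKBONE_BEADS)).ravel()
    return np.asarray(subset, dtype=int)


def rmsd_matrix(
    frames: list[FrameRecord],
    superpose: bool = True,
    subset=None,
) -> RMSDMatrix:
    """All-against-all RMSD over the selected frames.

    With ``superpose=False`` the raw coordinate deviation is used — for runs
    with a frozen core this makes the matrix reflect only the mobile-region
    dynamics relative to that fixed core.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    n_res = frames[0].frame.coordinates.size // 15
    idx = _subset_indices(n_res, subset)
    X = np.stack([f.coords()[idx] for f in frames])
    F = len(frames)
    M = np.zeros((F, F))
    fn = kabsch_rmsd if superpose else raw_rmsd
    for i in range(F):
        for j in range(i + 1, F):
            M[i, j] = M[j, i] = fn(X[i], X[j])
    return RMSDMatrix([f.key for f in frames], M, superpose)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _order_key(energies, pos):
    return (energies[pos], pos)


def cluster_option_d(
    matrix: RMSDMatrix,
    energies,
    threshold: float,
    max_clusters: int = 5,
) -> Clustering:
    """Max-neighborhood clustering (the classic default)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    M = matrix.matrix
    energies = np.asarray(energies, float)
    remaining = list(range(len(M)))
    clusters, reps = [], []
    while remaining and len(clusters) < max_clusters:
        best, best_nbrs = None, None
        for p in remaining:
            nbrs = [q for q in remaining if M[p, q] <= threshold]
            if best is None or len(nbrs) > len(best_nbrs) or (
                len(nbrs) == len(best_nbrs)
                and _order_key(energies, p) < _order_key(energies, best)
            ):
                best, best_nbrs = p, nbrs
        clusters.append(sorted(best_nbrs))
        reps.append(best)
        remaining = [q for q in remaining if q not in set(best_nbrs)]
    return Clustering("D", threshold, clusters, reps, matrix.frame_keys)


def cluster_option_e(
    matrix: RMSDMatrix,
    energies,
    threshold: float,
    max_clusters: int = 5,
) -> Clustering:
    """Best-energy-seeded clustering: the best-scored remaining frame seeds a
    cluster of everything within the threshold of it."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    M = matrix.matrix
    energies = np.asarray(energies, float)
    remaining = list(range(len(M)))
    clusters, reps = [], []
    while remaining and len(clusters) < max_clusters:
        seed = min(remaining, key=lambda p: _order_key(energies, p))
        members = sorted(q for q in remaining if q == seed or M[seed, q] < threshold)
        clusters.append(members)
        reps.append(seed)
        remaining = [q for q in remaining if q not in set(members)]
    return Clustering("E", threshold, clusters, reps, matrix.frame_keys)


def _grow_qt_cluster(seed, remaining, M, threshold):
    members = [seed]
    candidates = [q for q in remaining if q != seed and M[seed, q] < threshold]
    while True:
        best, best_sum = None, None
        for q in candidates:
            if all(M[q, m] < threshold for m in members):
                s = sum(M[q, m] for m in members)
                if best is None or s < best_sum or (s == best_sum and q < best):
                    best, best_sum = q, s
        if best is None:
            return members
        members.append(best)
        candidates.remove(best)


def cluster_option_c(
    matrix: RMSDMatrix,
    threshold: float,
    max_clusters: int = 5,
    energies=None,
) -> Clustering:
    """Quality-threshold clustering under a complete-diameter constraint."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    M = matrix.matrix
    remaining = list(range(len(M)))
    clusters, reps = [], []
    while remaining and len(clusters) < max_clusters:
        best_members = None
        for seed in remaining:
            members = _grow_qt_cluster(seed, remaining, M, threshold)
            if best_members is None or len(members) > len(best_members) or (
                len(members) == len(best_members)
                and _intra_sum(members, M) < _intra_sum(best_members, M)
            ):
                best_members = members
        members = sorted(best_members)
        rep = min(
            members,
            key=lambda p: (sum(M[p, q] for q in members), p),
        )
        clusters.append(members)
        reps.append(rep)
        remaining = [q for q in remaining if q not in set(members)]
    return Clustering("C", threshold, clusters, reps, matrix.frame_keys)


def _intra_sum(members, M) -> float:
    return float(sum(M[a, b] for a, b in combinations(members, 2)))


# ---------------------------------------------------------------------------
# base-pair MCC
# ---------------------------------------------------------------------------

def mcc_basepairs(ref_pairs, pred_pairs, n_residues: int) -> float:
    """Matthews correlation coefficient over the universe of i<j residue
    pairs; 0 by convention when any contingency marginal is zero (e.g. an
    unfolded prediction sharing no pairs with the reference)."""
    def norm(pairs):
        out = set()
        for i, j in pairs:
            if not (0 <= i < n_residues and 0 <= j < n_residues and i != j):
                raise ValueError(f"pair ({i}, {j}) out of range")
            out.add((min(i, j), max(i, j)))
        return out

    ref = norm(ref_pairs)
    pred = norm(pred_pairs)
    universe = n_residues * (n_residues - 1) // 2
    tp = len(ref & pred)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = universe - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


# ---------------------------------------------------------------------------
# model extraction
# ---------------------------------------------------------------------------

def extract_models(
    frames: list[FrameRecord],
    clustering: Clustering,
    out_dir: str | Path,
    format: str = "pdb",
) -> list[Path]:
    """Write the overall best-scored frame plus one representative per
    cluster, ordered by cluster size."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"pdb": "pdb", "mmcif": "cif"}[format]
    paths = []

    best = min(range(len(frames)), key=lambda p: (frames[p].energy, p))
    conf = frame_to_conformation(frames[best].traj, frames[best].frame)
    p = out_dir / f"best_model.{ext}"
    write_structure(conf, p, format)
    paths.append(p)

    order = sorted(
        range(len(clustering.clusters)),
        key=lambda k: (-len(clustering.clusters[k]), k),
    )
    for rank, k in enumerate(order, 1):
        rep = clustering.representatives[k]
        conf = frame_to_conformation(frames[rep].traj, frames[rep].frame)
        p = out_dir / f"cluster_{rank:02d}_model.{ext}"
        write_structure(conf, p, format)
        paths.append(p)
    return paths


def cluster_report(
    frames: list[FrameRecord], clustering: Clustering, matrix: RMSDMatrix
) -> str:
    """Tab-separated cluster summary: id, size, representative, mean intra-RMSD."""
    lines = ["cluster\tsize\trepresentative\tmean_intra_rmsd"]
    order = sorted(
        range(len(clustering.clusters)),
        key=lambda k: (-len(clustering.clusters[k]), k),
    )
    for rank, k in enumerate(order, 1):
        members = clustering.clusters[k]
        rep = clustering.representatives[k]
        if len(members) > 1:
            mean = _intra_sum(members, matrix.matrix) / (
                len(members) * (len(members) - 1) / 2
            )
        else:
            mean = 0.0
        key = frames[rep].key
        lines.append(
            f"{rank}\t{len(members)}\trun{key[0]}:rep{key[1]}:step{key[2]}\t{mean:.3f}"
        )
    return "\n".join(lines) + "\n"
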