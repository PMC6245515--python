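"""Trajectory pooling, RMSD clustering, and model selection.

The folding stage produces many short trajectories; model selection pools
the tail frames of every trajectory (last 50 by default), clusters the pool
by pairwise CA-RMSD with the Daura greedy neighbor-count algorithm, and
reports the centroids of the largest clusters — the centroid of the biggest
cluster being the blind prediction.  When a reference structure is supplied,
models are scored by CA-RMSD after Kabsch superposition and by TM-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cg_sampler import BackboneConformation, Trajectory


@dataclass
class StructurePool:
    """Pooled conformations with (trajectory, frame) provenance."""

    conformations: list[BackboneConformation]
    provenance: list[tuple[int, int]]
    energies: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.conformations)


def pool_frames(trajectories: list[Trajectory], last_n: int = 50) -> StructurePool:
    """Pool the last ``last_n`` captured frames of every trajectory."""
    confs, prov, energies = [], [], []
    for t_id, traj in enumerate(trajectories):
        if traj.n_frames < last_n:
            raise ValueError(
                f"trajectory {t_id} has only {traj.n_frames} frames "
                f"(need {last_n})"
            )
        start = traj.n_frames - last_n
        for f_id in range(start, traj.n_frames):
            confs.append(traj.frames[f_id])
            prov.append((t_id, f_id))
            energies.append(traj.energies[f_id])
    return StructurePool(conformations=confs, provenance=prov,
                         energies=np.array(energies))


# ---------------------------------------------------------------------------
# Structure comparison


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between coordinate sets after optimal rigid superposition.

    Standard Kabsch algorithm: center both sets, rotate by the SVD-derived
    proper rotation, measure root-mean-square deviation.  Symmetric in its
    arguments and zero for rigid-transformed copies.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate shapes differ: {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    V, S, Wt = np.linalg.svd(A0.T @ B0)
    d = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, d])
    R = V @ D @ Wt
    # explicit residuals rather than the trace identity: numerically exact
    # for near-identical inputs where the cancellation form loses precision
    return float(np.sqrt(((A0 @ R - B0) ** 2).sum(axis=1).mean()))


def _superpose(mobile: np.ndarray, target: np.ndarray,
               subset: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` using ``subset`` indices."""
    mc = mobile[subset].mean(axis=0)
    tc = target[subset].mean(axis=0)
    V, S, Wt = np.linalg.svd((mobile[subset] - mc).T @ (target[subset] - tc))
    d = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, d])
    R = V @ D @ Wt
    return (mobile - mc) @ R + tc


def tm_score(model: np.ndarray, reference: np.ndarray) -> float:
    """Template-modeling score of CA traces of equal length.

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i/d0)^2) with
    d0 = 1.24 (L-15)^(1/3) - 1.8.  The maximization follows the standard
    iterative scheme: superpose on a seed fragment, rescore, re-superpose on
    the residues currently within d0, iterate; the best value over several
    seed fragments is returned.  For chains of 15 or fewer residues the
    formula turns nonpositive and d0 is floored at 0.5 with a warning.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError("model and reference lengths differ")
    L = model.shape[0]
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8 if L > 15 else 0.0
    if d0 < 0.5:
        if L <= 15:
            warnings.warn(f"chain of {L} residues: flooring d0 at 0.5",
                          stacklevel=2)
        d0 = 0.5

    def score(sup: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(sup - reference, axis=1)
        return float((1.0 / (1.0 + (d / d0) ** 2)).mean()), d

    best = 0.0
    seed_len = max(4, L // 4)
    starts = sorted({0, max(0, (L - seed_len) // 2), max(0, L - seed_len)})
    for s in starts:
        subset = np.arange(s, min(L, s + seed_len))
        for _ in range(20):
            sup = _superpose(model, reference, subset)
            val, d = score(sup)
            best = max(best, val)
            new_subset = np.nonzero(d < max(d0, 1.0))[0]
            if new_subset.size < 3 or np.array_equal(new_subset, subset):
                break
            subset = new_subset
    # Full-length superposition as a further candidate.
    sup = _superpose(model, reference, np.arange(L))
    best = max(best, score(sup)[0])
    return best


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterResult:
    """Partition of the pool, clusters ordered by size (ties: lower centroid
    energy, then discovery order)."""

    labels: np.ndarray                 # cluster id per pool member, -1 never occurs
    clusters: list[np.ndarray]         # member indices per cluster, ordered
    centroids: list[int]               # pool index of each cluster's centroid
    tightness: list[float]             # mean intra-cluster pairwise RMSD
    cutoff: float


def pairwise_rmsd_matrix(pool: StructurePool, stride: int = 1) -> np.ndarray:
    """Dense CA-RMSD matrix of the (optionally strided) pool; O(N^2)."""
    coords = [c.ca_coords() for c in pool.conformations[::stride]]
    n = len(coords)
    if n > 5000:
        warnings.warn(
            f"pairwise RMSD over {n} structures is O(N^2); "
            "consider the stride option", stacklevel=2,
        )
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = kabsch_rmsd(coords[i], coords[j])
    return M


def cluster(pool: StructurePool, cutoff: float = 3.5,
            rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Daura greedy clustering on the pairwise CA-RMSD matrix.

    Repeatedly take the structure with the most unassigned neighbors within
    ``cutoff`` (ties: lowest index) as a cluster center, assign it and its
    neighbors, remove them, and repeat.  The reported centroid of each
    cluster is the member minimizing mean RMSD to its cluster.  Deterministic.
    """
    n = len(pool)
    if n < 1:
        raise ValueError("empty pool")
    M = rmsd_matrix if rmsd_matrix is not None else pairwise_rmsd_matrix(pool)
    neighbor = M <= cutoff
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    clusters: list[np.ndarray] = []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))
        members = np.nonzero(neighbor[center] & unassigned)[0]
        labels[members] = len(clusters)
        clusters.append(members)
        unassigned[members] = False

    centroids, tight = [], []
    for members in clusters:
        sub = M[np.ix_(members, members)]
        mean_to_others = sub.mean(axis=1)
        centroids.append(int(members[np.argmin(mean_to_others)]))
        m = len(members)
        tight.append(float(sub.sum() / (m * (m - 1))) if m > 1 else 0.0)

    order = sorted(
        range(len(clusters)),
        key=lambda k: (
            -len(clusters[k]),
            pool.energies[centroids[k]] if pool.energies is not None else 0.0,
            k,
        ),
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[x] for x in labels])
    return ClusterResult(
        labels=labels,
        clusters=[clusters[k] for k in order],
        centroids=[centroids[k] for k in order],
        tightness=[tight[k] for k in order],
        cutoff=cutoff,
    )


def top_clusters(result: ClusterResult, k: int = 5) -> list[int]:
    """Pool indices of the top-k cluster centroids (clamped with a warning)."""
    if len(result.clusters) < k:
        warnings.warn(
            f"only {len(result.clusters)} clusters available (requested {k})",
            stacklevel=2,
        )
    return result.centroids[:k]


# ---------------------------------------------------------------------------
# Reporting


@dataclass
class ModelReport:
    """Summary of the selected models (the largest-cluster centroid is the
    blind prediction; best-RMSD model only exists when a reference is given)."""

    centroid_index: int
    centroid_rmsd: float | None
    centroid_tm: float | None
    best_index: int | None
    best_rmsd: float | None
    best_tm: float | None
    cluster_sizes: list[int]
    cluster_tightness: list[float]


def report(
    pool: StructurePool,
    clusters: ClusterResult,
    reference: np.ndarray | None = None,
) -> ModelReport:
    """Score the selected models, optionally against a reference CA trace."""
    centroid = clusters.centroids[0]
    centroid_rmsd = centroid_tm = best_rmsd = best_tm = None
    best_index = None
    if reference is not None:
        centroid_ca = pool.conformations[centroid].ca_coords()
        centroid_rmsd = kabsch_rmsd(centroid_ca, reference)
        centroid_tm = tm_score(centroid_ca, reference)
        rmsds = [kabsch_rmsd(c.ca_coords(), reference)
                 for c in pool.conformations]
        best_index = int(np.argmin(rmsds))
        best_rmsd = float(rmsds[best_index])
        best_tm = tm_score(pool.conformations[best_index].ca_coords(), reference)
    return ModelReport(
        centroid_index=centroid,
        centroid_rmsd=centroid_rmsd,
        centroid_tm=centroid_tm,
        best_index=best_index,
        best_rmsd=best_rmsd,
        best_tm=best_tm,
        cluster_sizes=[len(c) for c in clusters.clusters],
        cluster_tightness=list(clusters.tightness),
    )


def write_report_tsv(rep: ModelReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"centroid_index\t{rep.centroid_index}\n")
        if rep.centroid_rmsd is not None:
            fh.write(f"centroid_rmsd\t{rep.centroid_rmsd:.3f}\n")
            fh.write(f"centroid_tm\t{rep.centroid_tm:.3f}\n")
            fh.write(f"best_index\t{rep.best_index}\n")
            fh.write(f"best_rmsd\t{rep.best_rmsd:.3f}\n")
            fh.write(f"best_tm\t{rep.best_tm:.3f}\n")
        for k, (size, tight) in enumerate(
            zip(rep.cluster_sizes, rep.cluster_tightness)
        ):
            fh.write(f"cluster_{k}\t{size},{tight:.3f}\n")
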