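"""Tertiary-structure summaries: contact maps and conformational clustering.

Clustering operates on a pairwise backbone-RMSD matrix with DBSCAN using
the standard density-reachability semantics: a core point has at least
``min_pts`` neighbours within ``eps`` (itself included), clusters are the
connected components of core points plus any border points, and
unreachable points are noise.  Border points touching several clusters are
assigned to the cluster of their lowest-index core neighbour, which makes
the labelling deterministic.  A frame sieve (stride) bounds the O(n^2)
matrix; sieved-out frames can be assigned post hoc to the nearest medoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from mptraj.traj_model import StructureError, Trajectory

__all__ = [
    "ContactMap",
    "ClusterResult",
    "contact_map",
    "pairwise_rmsd_matrix",
    "dbscan",
    "cluster_representatives",
    "assign_sieved_frames",
]


@dataclass
class ContactMap:
    matrix: np.ndarray          # (n_res, n_res) mean C-alpha distances, angstrom
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def contact_map(traj: Trajectory) -> ContactMap:
    """Mean C-alpha--C-alpha distance matrix over all frames."""
    top = traj.topology
    try:
        ca = [top.atom_index(r.index, "CA") for r in top.peptide_residues]
    except StructureError:
        raise StructureError("every residue needs a CA atom for a contact map")
    x = traj.coords[:, ca, :]
    d = np.linalg.norm(x[:, :, None, :] - x[:, None, :, :], axis=3)
    return ContactMap(matrix=d.mean(axis=0),
                      labels=[r.label for r in top.peptide_residues])


def pairwise_rmsd_matrix(traj: Trajectory, indices=None,
                         stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric frame-by-frame Kabsch RMSD matrix on strided frames.

    Returns ``(matrix, frame_positions)`` where ``frame_positions`` are the
    trajectory frame indices the rows correspond to.  Each entry is the
    minimum RMSD over rigid superpositions (reflections corrected).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    if indices is None:
        indices = [a.index for a in top.atoms if a.is_backbone]
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty atom selection")
    positions = np.arange(0, traj.n_frames, stride)
    x = traj.coords[np.ix_(positions, indices)]
    x = x - x.mean(axis=1, keepdims=True)
    gram = (x ** 2).sum(axis=(1, 2))
    n_sel = indices.size
    m = len(positions)
    out = np.zeros((m, m))
    for a in range(m):
        if a + 1 >= m:
            break
        cov = np.einsum("ni,bnj->bij", x[a], x[a + 1:])
        s = np.linalg.svd(cov, compute_uv=False)
        dets = np.linalg.det(cov)
        trace = s.sum(axis=1) - 2 * np.where(dets < 0, s[:, -1], 0.0)
        msd = (gram[a] + gram[a + 1:] - 2 * trace) / n_sel
        out[a, a + 1:] = out[a + 1:, a] = np.sqrt(np.maximum(msd, 0.0))
    return out, positions


@dataclass
class ClusterResult:
    labels: np.ndarray                    # per-point cluster id, -1 = noise
    populations: dict = field(default_factory=dict)   # cluster id -> % (+ "noise")
    medoid_frames: dict = field(default_factory=dict)  # cluster id -> point index


def dbscan(matrix: np.ndarray, eps_A: float, min_pts: int) -> ClusterResult:
    """DBSCAN on a precomputed distance matrix.

    Core iff >= ``min_pts`` points within ``eps_A`` (self included);
    clusters are connected components of core points plus border points;
    the rest is noise.  Cluster ids are ordered by descending population
    (ties by lowest member index) and the deterministic border tie-break
    assigns a border point to its lowest-index core neighbour's cluster.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if eps_A <= 0 or min_pts < 1:
        raise ValueError("eps_A must be positive and min_pts >= 1")
    n = matrix.shape[0]
    within = matrix <= eps_A
    neighbour_counts = within.sum(axis=1)       # self included (diagonal is 0)
    core = neighbour_counts >= min_pts
    labels = np.full(n, -1, dtype=int)
    core_idx = np.flatnonzero(core)
    if core_idx.size:
        adj = within[np.ix_(core_idx, core_idx)]
        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        labels[core_idx] = comp
        for i in np.flatnonzero(~core):
            core_neigh = core_idx[within[i, core_idx]]
            if core_neigh.size:
                labels[i] = labels[core_neigh.min()]
    result = ClusterResult(labels=labels)
    _relabel_by_population(result)
    result.populations, result.medoid_frames = cluster_representatives(
        result, matrix)
    return result


def _relabel_by_population(result: ClusterResult) -> None:
    labels = result.labels
    ids = [c for c in np.unique(labels) if c >= 0]
    sizes = {c: (labels == c).sum() for c in ids}
    firsts = {c: int(np.flatnonzero(labels == c)[0]) for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[c], firsts[c]))
    remap = {old: new for new, old in enumerate(order)}
    result.labels = np.array([remap.get(l, -1) for l in labels])


def cluster_representatives(result: ClusterResult,
                            matrix: np.ndarray) -> tuple[dict, dict]:
    """Populations (percent, descending) and medoid point per cluster.

    The medoid is the member minimising the summed intra-cluster distance;
    populations plus the noise fraction total 100.
    """
    labels = result.labels
    n = len(labels)
    ids = [c for c in np.unique(labels) if c >= 0]
    populations: dict = {}
    medoids: dict = {}
    for c in ids:
        members = np.flatnonzero(labels == c)
        sub = matrix[np.ix_(members, members)]
        medoids[int(c)] = int(members[np.argmin(sub.sum(axis=1))])
        populations[int(c)] = 100.0 * len(members) / n
    populations = dict(sorted(populations.items(), key=lambda kv: -kv[1]))
    populations["noise"] = 100.0 * (labels == -1).sum() / n
    if not ids:
        warnings.warn("all points classified as noise; no representatives")
    return populations, medoids


def assign_sieved_frames(traj: Trajectory, result: ClusterResult,
                         positions: np.ndarray, indices=None,
                         eps_A: float = 2.0) -> np.ndarray:
    """Assign every trajectory frame a cluster label using the sieve medoids.

    Strided frames keep their DBSCAN label; other frames take the label of
    the nearest medoid within ``eps_A`` (by backbone RMSD), else noise.
    """
    from mptraj.geometry import kabsch_superpose

    top = traj.topology
    if indices is None:
        indices = [a.index for a in top.atoms if a.is_backbone]
    full = np.full(traj.n_frames, -1, dtype=int)
    full[positions] = result.labels
    medoid_pos = {c: positions[m] for c, m in result.medoid_frames.items()}
    unassigned = np.setdiff1d(np.arange(traj.n_frames), positions)
    for f in unassigned:
        best, best_d = -1, np.inf
        for c, mpos in medoid_pos.items():
            d = kabsch_superpose(traj.coords[f], traj.coords[mpos], indices).rmsd
            if d < best_d:
                best, best_d = c, d
        if best_d <= eps_A:
            full[f] = best
    return full
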