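"""Independent oracles used to cross-check the package's implementations.

Each routine here deliberately takes a different algorithmic path from the
code under test: quaternion-eigenvalue superposition instead of SVD,
exhaustive density-reachability closure instead of graph components, and
brute-force all-pairs recounts for interaction detection.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    n = x.shape[0]
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = ((x ** 2).sum() + (y ** 2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def dbscan_reachability(matrix: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Brute-force DBSCAN labels via explicit density-reachability closure.

    Returns labels with -1 for noise; cluster ids are arbitrary (compare up
    to label permutation).
    """
    n = matrix.shape[0]
    within = matrix <= eps
    core = within.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != -1:
            continue
        # expand the reachability closure from this core point
        members = {seed}
        frontier = [seed]
        while frontier:
            p = frontier.pop()
            if not core[p]:
                continue
            for q in np.flatnonzero(within[p]):
                if q not in members:
                    members.add(int(q))
                    if core[q]:
                        frontier.append(int(q))
        for p in members:
            if labels[p] == -1:
                labels[p] = cluster
        cluster += 1
    return labels


def same_partition_up_to_labels(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two labelings induce the same clusters (noise fixed at -1)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
        if reverse.setdefault(int(y), int(x)) != x:
            return False
    return True


def salt_bridge_recount(traj, cutoff: float = 3.2) -> dict:
    """Exhaustive per-pair incidence recount over all O/N atom pairs."""
    top = traj.topology
    out = {}
    acidic = [r for r in top.peptide_residues if r.charge_class == "acidic"]
    basic = [r for r in top.peptide_residues if r.charge_class == "basic"]
    for ra in acidic:
        for rb in basic:
            hits = 0
            for f in range(traj.n_frames):
                found = False
                for i in ra.sidechain_polar_atoms:
                    for j in rb.sidechain_polar_atoms:
                        d = np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                        if d < cutoff:
                            found = True
                if found:
                    hits += 1
            out[(ra.index, rb.index)] = 100.0 * hits / traj.n_frames
    return out
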