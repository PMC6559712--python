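"""Core structural descriptors.

Optimal rigid superposition (Kabsch, SVD with reflection correction), RMSD
time series, per-residue RMSF, radius of gyration, torsion angles in the
IUPAC sign convention and Ramachandran histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptraj.traj_model import Frame, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "SuperpositionResult",
    "SeriesStats",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "rg_series",
    "dihedral",
    "phi_psi",
    "ramachandran_histogram",
]


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate for a well-defined result (collinear, coincident)."""


@dataclass
class SeriesStats:
    """Ave/SD/Min/Max summary of a series (population SD, ddof = 0)."""

    ave: float
    sd: float
    min: float
    max: float

    @classmethod
    def from_values(cls, values) -> "SeriesStats":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot summarise an empty series")
        return cls(float(v.mean()), float(v.std(ddof=0)), float(v.min()), float(v.max()))

    def as_dict(self) -> dict:
        return {"Ave": self.ave, "SD": self.sd, "Min": self.min, "Max": self.max}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # (3, 3), proper (det = +1)
    translation: np.ndarray    # (3,)
    rmsd: float                # angstrom, over the fitted atoms

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     indices=None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The returned rotation is proper (a reflection in the SVD solution is
    corrected by flipping the smallest singular direction), and the RMSD is
    the global minimum over rigid transforms for the selected atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if indices is not None:
        mobile = mobile[np.asarray(indices)]
        reference = reference[np.asarray(indices)]
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    # collinear point sets leave the rotation about the line undetermined
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError("selected atoms are (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    resid = x @ rotation.T - y
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_series(traj: Trajectory, reference: Frame | int, indices) -> pd.Series:
    """RMSD (angstrom) of every frame against a reference after superposition."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty atom selection for RMSD")
    if isinstance(reference, int):
        reference = traj.frame(reference)
    ref = reference.coords
    values = [
        kabsch_superpose(traj.coords[i], ref, indices).rmsd
        for i in range(traj.n_frames)
    ]
    return pd.Series(values, index=pd.Index(traj.times_ns, name="time_ns"),
                     name="rmsd_A")


def _superpose_all(coords: np.ndarray, ref: np.ndarray, indices) -> np.ndarray:
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        sup = kabsch_superpose(coords[i], ref, indices)
        out[i] = sup.apply(coords[i])
    return out


def rmsf_per_residue(traj: Trajectory, indices=None, align_to: str = "mean",
                     n_iter: int = 2) -> pd.Series:
    """Per-residue RMSF (angstrom) about the mean structure.

    Frames are first superposed onto the average structure, iterating the
    (align, re-average) pair ``n_iter`` times to remove global drift; with
    ``align_to='first'`` the initial reference is frame 0 without iteration.
    The per-residue value is the mean of the per-atom RMSF over that
    residue's selected atoms.  ``align_to='none'`` skips superposition
    entirely (useful when frames are already in a common frame).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    top = traj.topology
    if indices is None:
        indices = [a.index for a in top.atoms if a.is_backbone]
    indices = np.asarray(indices)
    coords = traj.coords
    if align_to == "none":
        pass
    elif align_to == "first":
        coords = _superpose_all(coords, coords[0], indices)
    else:
        ref = coords[0]
        for _ in range(n_iter):
            aligned = _superpose_all(coords, ref, indices)
            ref = aligned.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    labels = []
    values = []
    for res in top.peptide_residues:
        res_atoms = [i for i in indices if top.atoms[i].residue_index == res.index]
        if not res_atoms:
            continue
        labels.append(res.label)
        values.append(float(per_atom[res_atoms].mean()))
    return pd.Series(values, index=pd.Index(labels, name="residue"), name="rmsf_A")


def radius_of_gyration(frame: Frame, topology=None, indices=None,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration (angstrom) over the selected atoms.

    Defaults to mass-weighting over all atoms; pass a heavy-atom selection
    to exclude hydrogens where they are present.
    """
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame)
    if indices is not None:
        indices = np.asarray(indices)
        if indices.size == 0:
            raise ValueError("empty atom selection for Rg")
        coords = coords[indices]
    if mass_weighted:
        if topology is None:
            raise ValueError("mass weighting requires a topology")
        masses = topology.masses(indices)
    else:
        masses = np.ones(coords.shape[0])
    centroid = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    sq = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def rg_series(traj: Trajectory, indices=None, mass_weighted: bool = True) -> pd.Series:
    values = [
        radius_of_gyration(traj.frame(i), traj.topology, indices, mass_weighted)
        for i in range(traj.n_frames)
    ]
    return pd.Series(values, index=pd.Index(traj.times_ns, name="time_ns"),
                     name="rg_A")


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC convention: cis = 0, trans = 180.

    The result lies in (-180, 180].
    """
    return float(_dihedrals(*(np.asarray(p)[None, :] for p in (p1, p2, p3, p4)))[0])


def _dihedrals(p1, p2, p3, p4) -> np.ndarray:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    norms = (np.linalg.norm(b1, axis=-1), np.linalg.norm(b2, axis=-1),
             np.linalg.norm(b3, axis=-1))
    if any(np.any(n < 1e-9) for n in norms):
        raise DegenerateGeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2, axis=-1, keepdims=True), n1)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 to +180 so trans is reported positively
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang


def phi_psi(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Backbone (phi, psi) in degrees for every frame and residue.

    Returns two (n_frames, n_residues) arrays; phi of the first residue and
    psi of the last are NaN (undefined at chain termini).
    """
    top = traj.topology
    n_res = top.n_residues
    n_idx = [top.atom_index(r, "N") for r in range(1, n_res + 1)]
    ca_idx = [top.atom_index(r, "CA") for r in range(1, n_res + 1)]
    c_idx = [top.atom_index(r, "C") for r in range(1, n_res + 1)]
    c = traj.coords
    phi = np.full((traj.n_frames, n_res), np.nan)
    psi = np.full((traj.n_frames, n_res), np.nan)
    for r in range(n_res):
        if r > 0:
            phi[:, r] = _dihedrals(c[:, c_idx[r - 1]], c[:, n_idx[r]],
                                   c[:, ca_idx[r]], c[:, c_idx[r]])
        if r < n_res - 1:
            psi[:, r] = _dihedrals(c[:, n_idx[r]], c[:, ca_idx[r]],
                                   c[:, c_idx[r]], c[:, n_idx[r + 1]])
    return phi, psi


def ramachandran_histogram(traj: Trajectory, bin_deg: float = 10.0):
    """2-D count histogram over (phi, psi) for interior residues.

    The grid covers (-180, 180] x (-180, 180] with ``bin_deg`` wide bins;
    only residues with both angles defined contribute, so the total count is
    (n_residues - 2) * n_frames.  Returns ``(counts, edges)``.
    """
    if not np.isclose(360.0 / bin_deg, round(360.0 / bin_deg)):
        raise ValueError("bin_deg must divide 360")
    phi, psi = phi_psi(traj)
    mask = ~(np.isnan(phi) | np.isnan(psi))
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    counts, _, _ = np.histogram2d(phi[mask], psi[mask], bins=(edges, edges))
    return counts, edges
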