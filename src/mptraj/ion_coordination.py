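"""Ion--oxygen coordination analysis.

Distance monitoring of every candidate oxygen around a single bound metal
ion, per-atom contact statistics, mono/bi-dentate classification of
carboxylate binding, and a radial distribution function with its
integrated (cumulative) coordination number.

These are implicit-solvent, finite-system ensembles with no periodic box,
so the bulk-density normalisation of a conventional liquid-state RDF is
undefined.  g(r) is therefore normalised against the mean density of the
finite candidate-oxygen set within ``r_max``, while every quantitative
claim (coordination numbers) uses direct cumulative counts, which are
normalisation-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptraj.traj_model import Residue, Trajectory

__all__ = [
    "ContactStats",
    "RDFResult",
    "candidate_oxygens",
    "ion_distance_table",
    "contact_stats",
    "classify_denticity",
    "rdf_ion_oxygen",
    "coordination_number",
    "suggest_cutoff",
]


@dataclass
class ContactStats:
    label: str            # e.g. "Glu3 sidechain O (OE1)"
    atom_name: str
    mean_A: float
    sd_A: float
    min_A: float


@dataclass
class RDFResult:
    bin_edges_A: np.ndarray    # (n_bins + 1,)
    g_r: np.ndarray            # (n_bins,)
    n_cum: np.ndarray          # (n_bins + 1,) mean count with distance <= edge
    n_candidates: int


def _single_ion(traj: Trajectory) -> int:
    ions = traj.topology.ion_indices
    if len(ions) != 1:
        raise ValueError(f"trajectory must contain exactly one ion, found {len(ions)}")
    return ions[0]


def candidate_oxygens(traj: Trajectory) -> list[int]:
    """All peptide oxygen atoms (backbone and side chain)."""
    return [a.index for a in traj.topology.atoms
            if a.element.upper() == "O" and not a.is_ion]


def _atom_label(traj: Trajectory, index: int) -> str:
    atom = traj.topology.atoms[index]
    res = traj.topology.residue(atom.residue_index)
    moiety = "backbone" if atom.is_backbone else "sidechain"
    suffix = "" if atom.is_backbone else f" ({atom.name})"
    return f"{res.label} {moiety} O{suffix}"


def ion_distance_table(traj: Trajectory, oxygen_selection=None) -> pd.DataFrame:
    """Per-frame ion--oxygen Euclidean distances (angstrom).

    One row per frame (indexed by time in ns), one column per candidate
    oxygen, labelled in the "Glu3 sidechain O" style.
    """
    ion = _single_ion(traj)
    if oxygen_selection is None:
        oxygen_selection = candidate_oxygens(traj)
    oxygen_selection = list(oxygen_selection)
    if not oxygen_selection:
        raise ValueError("empty oxygen selection")
    d = np.linalg.norm(
        traj.coords[:, oxygen_selection, :] - traj.coords[:, [ion], :], axis=2)
    columns = [_atom_label(traj, i) for i in oxygen_selection]
    table = pd.DataFrame(d, columns=columns,
                         index=pd.Index(traj.times_ns, name="time_ns"))
    table.attrs["atom_indices"] = oxygen_selection
    return table


def contact_stats(table: pd.DataFrame) -> list[ContactStats]:
    """Mean, SD (population) and minimum per oxygen, sorted by mean distance."""
    if table.empty:
        raise ValueError("empty distance table")
    out = []
    for col in table.columns:
        v = table[col].to_numpy()
        name = col.split("(")[-1].rstrip(")") if "(" in col else "O"
        out.append(ContactStats(label=col, atom_name=name,
                                mean_A=float(v.mean()),
                                sd_A=float(v.std(ddof=0)),
                                min_A=float(v.min())))
    return sorted(out, key=lambda s: s.mean_A)


def classify_denticity(table: pd.DataFrame, residue: Residue,
                       inner_cutoff_A: float = 2.6):
    """Per-frame mono/bi/outer binding of a carboxylate residue.

    ``bi`` iff both carboxylate oxygens are within the inner-shell cutoff,
    ``mono`` iff exactly one, ``outer`` otherwise.  Returns the per-frame
    label series and the summary fractions (which sum to 1).
    """
    if residue.charge_class != "acidic" or len(residue.sidechain_polar_atoms) != 2:
        raise ValueError(f"{residue.label} is not a two-oxygen carboxylate residue")
    cols = [c for c in table.columns
            if c.startswith(f"{residue.label} sidechain O")]
    if len(cols) != 2:
        raise ValueError(
            f"distance table lacks both carboxylate oxygens of {residue.label}")
    within = (table[cols] <= inner_cutoff_A).sum(axis=1)
    labels = within.map({0: "outer", 1: "mono", 2: "bi"})
    labels.name = "denticity"
    fractions = {
        k: float((labels == k).mean()) for k in ("mono", "bi", "outer")
    }
    return labels, fractions


def rdf_ion_oxygen(traj: Trajectory, oxygen_selection=None, dr_A: float = 0.05,
                   r_max_A: float = 6.0) -> RDFResult:
    """Ion--oxygen radial distribution function and cumulative count.

    ``g(r)`` is the mean shell count over frames divided by shell volume
    times the mean candidate density within ``r_max``; ``n_cum`` is the
    mean number of candidate oxygens with distance <= r, obtained by direct
    counting (never by integrating g).
    """
    if dr_A <= 0:
        raise ValueError("dr_A must be positive")
    if r_max_A < 3 * dr_A:
        raise ValueError("r_max_A must span several bins")
    ion = _single_ion(traj)
    if oxygen_selection is None:
        oxygen_selection = candidate_oxygens(traj)
    oxygen_selection = list(oxygen_selection)
    d = np.linalg.norm(
        traj.coords[:, oxygen_selection, :] - traj.coords[:, [ion], :], axis=2)
    n_bins = int(round(r_max_A / dr_A))
    edges = np.linspace(0.0, n_bins * dr_A, n_bins + 1)
    counts = np.zeros(n_bins)
    for f in range(d.shape[0]):
        counts += np.histogram(d[f], bins=edges)[0]
    mean_counts = counts / d.shape[0]
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = len(oxygen_selection) / (4.0 / 3.0 * np.pi * edges[-1] ** 3)
    g_r = mean_counts / (shell_vol * rho)
    n_cum = np.array([(d <= r).sum(axis=1).mean() for r in edges])
    return RDFResult(bin_edges_A=edges, g_r=g_r, n_cum=n_cum,
                     n_candidates=len(oxygen_selection))


def coordination_number(rdf: RDFResult, cutoff_A: float) -> float:
    """Mean ligating-oxygen count at the bin edge nearest the cutoff."""
    edges = rdf.bin_edges_A
    if cutoff_A < 0 or cutoff_A > edges[-1]:
        raise ValueError("cutoff outside RDF range")
    idx = int(np.argmin(np.abs(edges - cutoff_A)))
    return float(rdf.n_cum[idx])


def suggest_cutoff(rdf: RDFResult, smooth: int = 3) -> float | None:
    """First local minimum of g(r) after the first peak (inner-shell edge).

    Returns None when no peak-then-minimum structure exists.
    """
    g = rdf.g_r
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        g = np.convolve(g, kernel, mode="same")
    centers = 0.5 * (rdf.bin_edges_A[1:] + rdf.bin_edges_A[:-1])
    peak = None
    for i in range(1, len(g) - 1):
        if peak is None:
            if g[i] > 0 and g[i] >= g[i - 1] and g[i] > g[i + 1]:
                peak = i
        else:
            if g[i] <= g[i - 1] and g[i] < g[i + 1]:
                return float(centers[i])
    return None
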