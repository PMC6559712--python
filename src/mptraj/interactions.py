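"""Hydrogen-bond and salt-bridge detection and incidence accounting.

Hydrogen bonds use a geometric criterion: heavy-atom donor--acceptor
distance below a cutoff (default 3.5 angstrom) plus a D-H-A angle
criterion (default 135 degrees) evaluated with the reconstructed amide
hydrogen for backbone donors; side-chain donors carry rotatable or
symmetric hydrogens, so for them the angle criterion is relaxed to an
antecedent--donor--acceptor plausibility check (>= 90 degrees).

Salt bridges follow the standard contact definition for charged residues:
any side-chain oxygen--nitrogen pair of an acidic/basic residue pair at a
distance strictly less than 3.2 angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptraj.geometry import SeriesStats
from mptraj.secondary_structure import place_amide_hydrogens
from mptraj.traj_model import Frame, Topology, Trajectory

__all__ = [
    "HBond",
    "HBondIncidence",
    "find_hbonds",
    "hbond_incidence",
    "classify_helical",
    "enumerate_possible_salt_bridges",
    "salt_bridge_incidence",
]

# Side-chain donor atoms (atom name -> antecedent heavy atom), per residue.
SIDECHAIN_DONORS = {
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "TRP": {"NE1": "CD1"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
}

# Side-chain acceptor atoms per residue.
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}


@dataclass
class HBond:
    donor_atom: int
    acceptor_atom: int
    donor_res: int
    acceptor_res: int
    distance_A: float          # heavy-atom D--A
    angle_deg: float | None    # D-H-A; None for side-chain donors
    kind: str                  # backbone-backbone | backbone-sidechain | ...
    helical_class: str         # i+3 | i+4 | i+5 | other

    @property
    def donor_moiety(self) -> str:
        return self.kind.split("-")[0]

    @property
    def acceptor_moiety(self) -> str:
        return self.kind.split("-")[1]


def _donor_list(topology: Topology, include_amide_sidechains: bool = True):
    """(atom index, residue, moiety, antecedent index or None) donors."""
    donors = []
    for res in topology.peptide_residues:
        if res.index > 1 and res.name3 != "PRO":
            donors.append((topology.atom_index(res.index, "N"), res.index,
                           "backbone", None))
        table = SIDECHAIN_DONORS.get(res.name3, {})
        for name, antecedent in table.items():
            if res.name3 in ("ASN", "GLN") and not include_amide_sidechains:
                continue
            try:
                idx = topology.atom_index(res.index, name)
            except Exception:
                continue
            try:
                ant = topology.atom_index(res.index, antecedent)
            except Exception:
                ant = None
            donors.append((idx, res.index, "sidechain", ant))
    return donors


def _acceptor_list(topology: Topology, include_amide_sidechains: bool = True):
    acceptors = []
    for res in topology.peptide_residues:
        acceptors.append((topology.atom_index(res.index, "O"), res.index,
                          "backbone"))
        for name in SIDECHAIN_ACCEPTORS.get(res.name3, ()):
            if res.name3 in ("ASN", "GLN") and not include_amide_sidechains:
                continue
            try:
                idx = topology.atom_index(res.index, name)
            except Exception:
                continue
            acceptors.append((idx, res.index, "sidechain"))
    return acceptors


def find_hbonds(frame: Frame, topology: Topology, dist_cutoff_A: float = 3.5,
                angle_cutoff_deg: float = 135.0,
                include_amide_sidechains: bool = True) -> list[HBond]:
    """Detect hydrogen bonds in one frame.

    Intra-residue backbone-to-sidechain bonds are allowed (they occur for
    Glu/Asp); same-moiety pairs within one residue and the covalent
    peptide-bond pair N(i)...O(i-1) are excluded.
    """
    donors = _donor_list(topology, include_amide_sidechains)
    acceptors = _acceptor_list(topology, include_amide_sidechains)
    if not donors or not acceptors:
        return []
    h = place_amide_hydrogens(frame, topology)
    coords = frame.coords
    out: list[HBond] = []
    for d_idx, d_res, d_moi, d_ant in donors:
        d_pos = coords[d_idx]
        for a_idx, a_res, a_moi in acceptors:
            if a_idx == d_idx:
                continue
            if d_res == a_res and d_moi == a_moi:
                continue
            if d_moi == "backbone" and a_moi == "backbone" and a_res == d_res - 1:
                continue  # covalent peptide-bond neighbour
            dist = float(np.linalg.norm(coords[a_idx] - d_pos))
            if dist > dist_cutoff_A:
                continue
            angle = None
            if d_moi == "backbone":
                h_pos = h[d_res - 1]
                if np.isnan(h_pos[0]):
                    continue
                v1 = d_pos - h_pos
                v2 = coords[a_idx] - h_pos
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < angle_cutoff_deg:
                    continue
            elif d_ant is not None:
                v1 = coords[d_ant] - d_pos
                v2 = coords[a_idx] - d_pos
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 90.0:
                    continue
            sep = d_res - a_res
            helical = (
                f"i+{sep}" if (d_moi == a_moi == "backbone" and sep in (3, 4, 5))
                else "other"
            )
            out.append(HBond(
                donor_atom=d_idx, acceptor_atom=a_idx, donor_res=d_res,
                acceptor_res=a_res, distance_A=dist, angle_deg=angle,
                kind=f"{d_moi}-{a_moi}", helical_class=helical,
            ))
    return out


@dataclass
class HBondIncidence:
    table: pd.DataFrame          # per merged (donor, acceptor) pair incidence %
    per_frame_counts: np.ndarray
    count_stats: SeriesStats
    n_distinct: int


def hbond_incidence(traj: Trajectory, dist_cutoff_A: float = 3.5,
                    angle_cutoff_deg: float = 135.0,
                    include_amide_sidechains: bool = True,
                    atom_level: bool = False) -> HBondIncidence:
    """Incidence of each distinct hydrogen bond over a trajectory.

    Bonds are identified at residue+moiety granularity by default ("His14
    sidechain -> Glu11 backbone"), merging symmetry-equivalent atom pairs
    such as the two carboxylate oxygens; ``atom_level=True`` keeps atom
    identities.  Per-frame counts are raw detections (one per atom pair).
    """
    top = traj.topology
    labels = {r.index: r.label for r in top.peptide_residues}
    present: dict[tuple, np.ndarray] = {}
    counts = np.zeros(traj.n_frames, dtype=int)
    extras: dict[tuple, tuple] = {}
    for f in range(traj.n_frames):
        bonds = find_hbonds(traj.frame(f), top, dist_cutoff_A,
                            angle_cutoff_deg, include_amide_sidechains)
        counts[f] = len(bonds)
        for b in bonds:
            if atom_level:
                key = (b.donor_res, b.donor_atom, b.acceptor_res, b.acceptor_atom)
            else:
                key = (b.donor_res, b.donor_moiety, b.acceptor_res,
                       b.acceptor_moiety)
            if key not in present:
                present[key] = np.zeros(traj.n_frames, dtype=bool)
                extras[key] = (b.kind, b.helical_class)
            present[key][f] = True
    rows = []
    for key, mask in present.items():
        kind, helical = extras[key]
        if atom_level:
            d_res, d_atom, a_res, a_atom = key
            donor = f"{labels[d_res]}:{top.atoms[d_atom].name}"
            acceptor = f"{labels[a_res]}:{top.atoms[a_atom].name}"
        else:
            d_res, d_moi, a_res, a_moi = key
            donor = f"{labels[d_res]} {d_moi}"
            acceptor = f"{labels[a_res]} {a_moi}"
        rows.append({
            "donor": donor, "acceptor": acceptor, "kind": kind,
            "helical_class": helical,
            "donor_res": key[0], "acceptor_res": key[2],
            "incidence_pct": 100.0 * mask.mean(),
        })
    table = pd.DataFrame(
        rows, columns=["donor", "acceptor", "kind", "helical_class",
                       "donor_res", "acceptor_res", "incidence_pct"])
    if not table.empty:
        table = table.sort_values("incidence_pct", ascending=False,
                                  kind="stable").reset_index(drop=True)
    return HBondIncidence(
        table=table,
        per_frame_counts=counts,
        count_stats=SeriesStats.from_values(counts),
        n_distinct=len(table),
    )


def classify_helical(incidence: HBondIncidence,
                     min_pct: float = 5.0) -> dict:
    """Tally distinct i+3/i+4/i+5 backbone-backbone bonds.

    Reports, per class, the number of distinct bonds observed at all and
    the number present in at least ``min_pct`` percent of frames.
    """
    out = {}
    t = incidence.table
    for cls in ("i+3", "i+4", "i+5"):
        if t.empty:
            out[cls] = {"total": 0, f"ge_{min_pct:g}pct": 0}
            continue
        sub = t[(t["helical_class"] == cls) & (t["kind"] == "backbone-backbone")]
        out[cls] = {
            "total": int(len(sub)),
            f"ge_{min_pct:g}pct": int((sub["incidence_pct"] >= min_pct).sum()),
        }
    return out


def enumerate_possible_salt_bridges(topology: Topology) -> list[tuple[int, int]]:
    """All (acidic residue, basic residue) pairs, ordered by residue index.

    Acidic = Asp/Glu side chains, basic = Arg/Lys; His and the chain
    termini are excluded, the convention under which a 16-residue
    amyloid-beta fragment has 8 possible bridges and the 40/42-residue
    peptides 18.
    """
    acidic = [r.index for r in topology.peptide_residues
              if r.charge_class == "acidic"]
    basic = [r.index for r in topology.peptide_residues
             if r.charge_class == "basic"]
    return [(a, b) for a in acidic for b in basic]


def salt_bridge_incidence(traj: Trajectory, cutoff_A: float = 3.2) -> pd.DataFrame:
    """Percent of frames in which each possible salt bridge is formed.

    A bridge is formed in a frame iff the minimum side-chain
    oxygen--nitrogen distance over the pair is strictly less than the
    cutoff.
    """
    top = traj.topology
    pairs = enumerate_possible_salt_bridges(top)
    rows = []
    for a_res, b_res in pairs:
        o_idx = top.residue(a_res).sidechain_polar_atoms
        n_idx = top.residue(b_res).sidechain_polar_atoms
        if not o_idx or not n_idx:
            raise ValueError(
                f"missing side-chain polar atoms for pair "
                f"{top.residue(a_res).label}-{top.residue(b_res).label}")
        d = np.linalg.norm(
            traj.coords[:, o_idx, None, :] - traj.coords[:, None, n_idx, :],
            axis=3)
        min_d = d.reshape(traj.n_frames, -1).min(axis=1)
        rows.append({
            "acidic": top.residue(a_res).label,
            "basic": top.residue(b_res).label,
            "acidic_res": a_res, "basic_res": b_res,
            "incidence_pct": 100.0 * float((min_d < cutoff_A).mean()),
            "min_ON_A": float(min_d.min()),
        })
    return pd.DataFrame(rows, columns=["acidic", "basic", "acidic_res",
                                       "basic_res", "incidence_pct", "min_ON_A"])
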