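"""Secondary-structure assignment per Kabsch and Sander (DSSP).

Backbone hydrogen bonds are scored with the classic electrostatic
four-distance energy and a -0.5 kcal/mol threshold; helices arise from
consecutive n-turns (n = 3, 4, 5 -> G, H, I), strands from bridge ladders
(B/E), with turns (T) and bends (S) filling in, at the original priority
H > E > B > G > I > T > S.  Amide hydrogens are reconstructed geometrically
when the input carries none, as is routine for trajectory analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptraj.traj_model import Frame, StructureError, Topology, Trajectory

__all__ = [
    "KS_Q", "KS_THRESHOLD", "KS_CLAMP",
    "SSAssignment",
    "place_amide_hydrogens",
    "ks_energy",
    "hbond_matrix",
    "assign_dssp",
    "ss_occupancy",
]

KS_Q = 0.084 * 332.0          # kcal/mol * angstrom, coupling constant
KS_THRESHOLD = -0.5           # kcal/mol; bonded iff E < threshold
KS_CLAMP = -9.9               # kcal/mol; short-contact clamp
CHAIN_BREAK_A = 2.5           # C(i-1)-N(i) beyond this is a chain break

DSSP_LETTERS = ("H", "G", "I", "E", "B", "T", "S", "C")


def _backbone_arrays(frame: Frame, topology: Topology):
    n_res = topology.n_residues
    out = {}
    for name in ("N", "CA", "C", "O"):
        idx = []
        for r in range(1, n_res + 1):
            try:
                idx.append(topology.atom_index(r, name))
            except StructureError:
                raise StructureError(
                    f"residue {topology.residue(r).label} lacks backbone atom {name}"
                ) from None
        out[name] = frame.coords[idx]
    return out


def place_amide_hydrogens(frame: Frame, topology: Topology) -> np.ndarray:
    """Amide H coordinates per residue; NaN rows where no H exists.

    The hydrogen sits 1.0 angstrom from N along the inverted carbonyl
    direction of the preceding residue (the classic DSSP construction).
    Residue 1, prolines and chain-break starts carry no amide H.
    """
    bb = _backbone_arrays(frame, topology)
    n_res = topology.n_residues
    h = np.full((n_res, 3), np.nan)
    for r in range(1, n_res):
        if topology.peptide_residues[r].name3 == "PRO":
            continue
        if np.linalg.norm(bb["N"][r] - bb["C"][r - 1]) > CHAIN_BREAK_A:
            continue
        direction = bb["C"][r - 1] - bb["O"][r - 1]
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        h[r] = bb["N"][r] + direction / norm
    return h


def ks_energy(c, o, n, h) -> float:
    """Kabsch--Sander hydrogen-bond energy (kcal/mol) of one C=O...H-N pair."""
    c, o, n, h = (np.asarray(p, dtype=float) for p in (c, o, n, h))
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return KS_CLAMP
    e = KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(e, KS_CLAMP))


def hbond_matrix(frame: Frame, topology: Topology) -> np.ndarray:
    """Boolean matrix hb[d, a]: the amide of residue d donates to the C=O of a.

    Same-residue pairs and the peptide-bond neighbour (a = d - 1) are
    excluded; residues without an amide hydrogen never donate.
    """
    bb = _backbone_arrays(frame, topology)
    h = place_amide_hydrogens(frame, topology)
    n_res = topology.n_residues
    hb = np.zeros((n_res, n_res), dtype=bool)
    has_h = ~np.isnan(h[:, 0])
    donors = np.flatnonzero(has_h)
    if donors.size == 0:
        return hb
    # vectorised four-distance energy for all donor/acceptor pairs
    nd = bb["N"][donors][:, None, :]
    hd = h[donors][:, None, :]
    ca_ = bb["C"][None, :, :]
    oa = bb["O"][None, :, :]
    r_on = np.linalg.norm(oa - nd, axis=2)
    r_ch = np.linalg.norm(ca_ - hd, axis=2)
    r_oh = np.linalg.norm(oa - hd, axis=2)
    r_cn = np.linalg.norm(ca_ - nd, axis=2)
    with np.errstate(divide="ignore"):
        e = KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    too_close = np.minimum(np.minimum(r_on, r_ch), np.minimum(r_oh, r_cn)) < 0.5
    e = np.where(too_close, KS_CLAMP, np.maximum(e, KS_CLAMP))
    bonded = e < KS_THRESHOLD
    for k, d in enumerate(donors):
        for a in np.flatnonzero(bonded[k]):
            if a == d or a == d - 1:
                continue
            hb[d, a] = True
    return hb


def _bridges(hb: np.ndarray):
    """Parallel/antiparallel bridge pairs (i, j, kind) with |i - j| >= 3."""
    n = hb.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 3, n):
            para = False
            anti = False
            if 0 <= i - 1 and i + 1 < n:
                para |= hb[j, i - 1] and hb[i + 1, j]
                anti |= (j + 1 < n) and hb[j + 1, i - 1] and hb[i + 1, j - 1]
            if 0 <= j - 1 and j + 1 < n:
                para |= hb[i, j - 1] and hb[j + 1, i]
            anti |= hb[i, j] and hb[j, i]
            if para:
                out.append((i, j, "P"))
            elif anti:
                out.append((i, j, "A"))
    return out


def assign_dssp(frame: Frame, topology: Topology,
                return_sheet_types: bool = False):
    """Per-residue DSSP letters for one frame.

    Chains shorter than 5 residues are all coil (with a warning).  With
    ``return_sheet_types`` a parallel/antiparallel marker per E/B residue
    is returned alongside.
    """
    n_res = topology.n_residues
    sheet_type = np.array([""] * n_res, dtype=object)
    if n_res < 5:
        warnings.warn("chain shorter than 5 residues: assigning all coil")
        letters = np.array(["C"] * n_res)
        return (letters, sheet_type) if return_sheet_types else letters

    hb = hbond_matrix(frame, topology)
    turn = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if hb[i + n, i]:
                turn[n][i] = True

    helix = {3: np.zeros(n_res, dtype=bool), 4: np.zeros(n_res, dtype=bool),
             5: np.zeros(n_res, dtype=bool)}
    for n in (3, 4, 5):
        for i in range(1, n_res - n):
            if turn[n][i - 1] and turn[n][i]:
                helix[n][i:i + n] = True

    bridges = _bridges(hb)
    is_bridge = np.zeros(n_res, dtype=bool)
    in_ladder = np.zeros(n_res, dtype=bool)
    bridge_set = {(i, j): kind for i, j, kind in bridges}
    for i, j, kind in bridges:
        is_bridge[i] = is_bridge[j] = True
        sheet_type[i] = sheet_type[j] = kind
        neighbours = (
            [(i + 1, j + 1), (i - 1, j - 1)] if kind == "P"
            else [(i + 1, j - 1), (i - 1, j + 1)]
        )
        for a, b in neighbours:
            key = (min(a, b), max(a, b))
            if bridge_set.get(key) == kind:
                in_ladder[i] = in_ladder[j] = True
                in_ladder[min(a, b)] = in_ladder[max(a, b)] = True

    is_turn = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in np.flatnonzero(turn[n]):
            is_turn[i + 1:i + n] = True

    ca = _backbone_arrays(frame, topology)["CA"]
    is_bend = np.zeros(n_res, dtype=bool)
    for i in range(2, n_res - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            is_bend[i] = True

    letters = np.array(["C"] * n_res, dtype=object)
    # priority H > E > B > G > I > T > S, applied low-to-high
    letters[is_bend] = "S"
    letters[is_turn] = "T"
    letters[helix[5]] = "I"
    letters[helix[3]] = "G"
    letters[is_bridge & ~in_ladder] = "B"
    letters[in_ladder] = "E"
    letters[helix[4]] = "H"
    sheet_type[~((letters == "E") | (letters == "B"))] = ""
    letters = letters.astype(str)
    return (letters, sheet_type) if return_sheet_types else letters


@dataclass
class SSAssignment:
    letters: np.ndarray              # (n_frames, n_res) DSSP letters
    per_residue: pd.DataFrame        # % occupancy per residue per letter
    aggregate: dict                  # Helix/Sheet/Other percentages
    sheet_subtype: dict              # parallel/antiparallel % of sheet states


def ss_occupancy(traj: Trajectory) -> SSAssignment:
    """Per-residue occupancy percentages and Helix/Sheet/Other aggregation.

    Helix = H + G + I, Sheet = E + B, Other = remainder; the three
    aggregates close to 100 by construction.  The parallel/antiparallel
    composition of sheet states is tallied separately.
    """
    if traj.n_frames < 1:
        raise ValueError("occupancy requires at least one frame")
    top = traj.topology
    n_res = top.n_residues
    all_letters = np.empty((traj.n_frames, n_res), dtype="<U1")
    para = anti = 0
    for f in range(traj.n_frames):
        letters, stypes = assign_dssp(traj.frame(f), top, return_sheet_types=True)
        all_letters[f] = letters
        para += int(np.sum(stypes == "P"))
        anti += int(np.sum(stypes == "A"))
    labels = [r.label for r in top.peptide_residues]
    pct = {
        letter: (all_letters == letter).mean(axis=0) * 100.0
        for letter in DSSP_LETTERS
    }
    per_residue = pd.DataFrame(pct, index=pd.Index(labels, name="residue"))
    helix = float(np.isin(all_letters, ("H", "G", "I")).mean() * 100.0)
    sheet = float(np.isin(all_letters, ("E", "B")).mean() * 100.0)
    aggregate = {"Helix": helix, "Sheet": sheet, "Other": 100.0 - helix - sheet}
    total_sheet = para + anti
    sheet_subtype = {
        "parallel": 100.0 * para / total_sheet if total_sheet else 0.0,
        "antiparallel": 100.0 * anti / total_sheet if total_sheet else 0.0,
    }
    return SSAssignment(all_letters, per_residue, aggregate, sheet_subtype)
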