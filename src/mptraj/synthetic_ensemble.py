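"""Synthetic peptide conformational ensembles with known ground truth.

The generator builds reduced-representation peptides (backbone N/CA/C/O,
C-beta, and the charged-group polar atoms of Asp/Glu/Lys/Arg) from
per-residue backbone torsions using standard peptide stereochemistry, adds
per-frame Gaussian dihedral noise with an optional decaying "drift" phase
emulating pre-equilibration relaxation, and can tether a single metal ion
to chosen side-chain oxygens by distance-restraint relaxation.  It is a
geometry generator, not a simulator: there is no force field and no
dynamics, which is precisely what makes every downstream analysis testable
against construction-time ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mptraj.traj_model import (
    AA_1TO3,
    Atom,
    Frame,
    Residue,
    Topology,
    Trajectory,
    element_mass,
)

__all__ = [
    "SS_TARGETS",
    "SegmentSpec",
    "IonSpec",
    "DriftSpec",
    "EnsembleSpec",
    "build_backbone",
    "generate_ensemble",
    "attach_ion",
]

# Canonical backbone torsion targets (degrees) per secondary-structure class.
SS_TARGETS = {
    "alpha": (-57.0, -47.0),
    "three10": (-49.0, -26.0),
    "strand": (-139.0, 135.0),
    "ppII": (-75.0, 145.0),
}

# Broad allowed basins used for coil sampling: (phi, psi, intra-basin sigma).
COIL_BASINS = [(-63.0, -43.0, 15.0), (-120.0, 130.0, 15.0), (60.0, 45.0, 15.0)]
COIL_WEIGHTS = [0.5, 0.4, 0.1]

# Standard bond lengths (angstrom) and angles (degrees).
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O, A_N_CA_CB = 121.7, 111.2, 116.6, 120.5, 110.5
OMEGA = 180.0  # trans peptide bond throughout

# Reduced side-chain construction beyond C-beta:
# (name, element, (ref1, ref2, ref3), bond, angle, torsion); refs name
# previously placed atoms of the same residue.
_SIDECHAINS = {
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.4, -30.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.4, 150.0),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.4, -30.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.4, 150.0),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.52, 112.6, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, 180.0),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.46, 111.9, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
}


def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C by internal coordinates.

    ``angle`` is the B-C-D valence angle and ``torsion`` the A-B-C-D
    dihedral, both in degrees, signed per the IUPAC convention used by
    :func:`mptraj.geometry.dihedral`.
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class SegmentSpec:
    """A contiguous residue range with a target secondary-structure class."""

    start: int                 # 1-based, inclusive
    stop: int                  # 1-based, inclusive
    ss_target: str             # alpha | three10 | strand | ppII | coil

    def __post_init__(self) -> None:
        if self.ss_target not in SS_TARGETS and self.ss_target != "coil":
            raise ValueError(f"unknown ss_target {self.ss_target!r}")
        if self.stop < self.start or self.start < 1:
            raise ValueError("invalid segment range")

    @property
    def residues(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass
class IonSpec:
    """A single metal ion tethered to side-chain oxygen anchors.

    ``tether_length`` is the target ion--anchor distance (the 1.9 angstrom
    default reproduces a first-shell Al--O carboxylate contact);
    ``outer_length`` is where non-anchor sibling carboxylate oxygens are
    oriented in the anchor-pulling mode, emulating an outer coordination
    sphere.
    """

    anchor_atoms: list[tuple[int, str]]   # (residue index, atom name)
    tether_length: float = 1.9
    tether_sigma: float = 0.03
    outer_length: float = 3.8
    outer_sigma: float = 0.2
    element: str = "Al"

    def __post_init__(self) -> None:
        if self.tether_length <= 0:
            raise ValueError("tether_length must be positive")


@dataclass
class DriftSpec:
    """Decaying extra dihedral noise emulating pre-equilibration drift.

    Extra noise of ``amplitude_deg`` at t = 0 falls linearly to zero at
    ``t0_ns`` (the true equilibration onset), producing the familiar
    rising-then-flat RMSD profile with a controllable ground truth.
    """

    t0_ns: float
    amplitude_deg: float


@dataclass
class EnsembleSpec:
    sequence: str
    segments: list[SegmentSpec] = field(default_factory=list)
    dihedral_noise_deg: float = 8.0
    n_frames: int = 100
    dt_ns: float = 0.1
    seed: int = 0
    drift: DriftSpec | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.dihedral_noise_deg < 0:
            raise ValueError("dihedral noise must be non-negative")
        seen: set[int] = set()
        for seg in self.segments:
            if seg.stop > len(self.sequence):
                raise ValueError(
                    f"segment {seg.start}-{seg.stop} exceeds sequence length"
                )
            overlap = seen & set(seg.residues)
            if overlap:
                raise ValueError(f"overlapping segments at residues {sorted(overlap)}")
            seen |= set(seg.residues)

    def target_for(self, resid: int) -> str:
        for seg in self.segments:
            if resid in seg.residues:
                return seg.ss_target
        return "coil"


def _build_topology(sequence: str) -> tuple[Topology, list[dict]]:
    """Topology plus, per residue, the name -> atom-index map used in building."""
    residues = []
    atoms = []
    maps: list[dict] = []
    idx = 0
    for i, letter in enumerate(sequence, start=1):
        if letter not in AA_1TO3:
            raise ValueError(f"non-standard residue letter {letter!r}")
        name3 = AA_1TO3[letter]
        residues.append(Residue(index=i, name3=name3))
        names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        if name3 != "GLY":
            names.append(("CB", "C"))
        names += [(n, el) for n, el, *_ in _SIDECHAINS.get(name3, [])]
        amap = {}
        for name, el in names:
            atoms.append(Atom(
                index=idx, name=name, element=el, mass=element_mass(el),
                residue_index=i,
                is_backbone=name in ("N", "CA", "C", "O"),
            ))
            amap[name] = idx
            idx += 1
        maps.append(amap)
    return Topology(residues, atoms), maps


def build_backbone(sequence: str, phi_psi) -> tuple[Topology, Frame]:
    """Build one conformation from per-residue (phi, psi) degree pairs.

    Standard trans-peptide stereochemistry is used throughout (omega fixed
    at 180, standard bond lengths/angles); side chains are reduced to
    C-beta plus the charged-group atoms of Asp/Glu/Lys/Arg at idealised
    geometry.  phi of residue 1 and psi of the last residue orient virtual
    neighbours only.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_res = len(sequence)
    if phi_psi.shape != (n_res, 2):
        raise ValueError("phi_psi must provide one (phi, psi) pair per residue")
    topology, maps = _build_topology(sequence)
    coords = np.zeros((topology.n_atoms, 3))

    # virtual previous-residue atoms anchoring the first phi
    v_c = np.array([-B_C_N, 0.0, 0.0])
    ang = np.deg2rad(A_CA_C_N)
    v_ca = v_c + B_CA_C * np.array([-np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])

    prev_n = prev_ca = prev_c = None
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i == 0:
            n = np.zeros(3)
            ca = _nerf(v_ca, v_c, n, B_N_CA, A_C_N_CA, OMEGA)
            c = _nerf(v_c, n, ca, B_CA_C, A_N_CA_C, phi)
            ref_c_prev = v_c
        else:
            n = _nerf(prev_n, prev_ca, prev_c, B_C_N, A_CA_C_N, phi_psi[i - 1, 1])
            ca = _nerf(prev_ca, prev_c, n, B_N_CA, A_C_N_CA, OMEGA)
            c = _nerf(prev_c, n, ca, B_CA_C, A_N_CA_C, phi)
            ref_c_prev = prev_c
        amap = maps[i]
        coords[amap["N"]] = n
        coords[amap["CA"]] = ca
        coords[amap["C"]] = c
        # carbonyl O anti to the next amide N
        coords[amap["O"]] = _nerf(n, ca, c, B_C_O, A_CA_C_O, psi - 180.0)
        if "CB" in amap:
            coords[amap["CB"]] = _nerf(ref_c_prev, n, ca, B_CA_CB, A_N_CA_CB,
                                       phi + 122.6)
        placed = {"N": n, "CA": ca, "C": c}
        if "CB" in amap:
            placed["CB"] = coords[amap["CB"]]
        name3 = AA_1TO3[sequence[i]]
        for name, _el, refs, bond, angle, torsion in _SIDECHAINS.get(name3, []):
            pos = _nerf(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                        bond, angle, torsion)
            coords[amap[name]] = pos
            placed[name] = pos
        prev_n, prev_ca, prev_c = n, ca, c
    return topology, Frame(coords)


def _sample_phi_psi(spec: EnsembleSpec, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    n_res = len(spec.sequence)
    out = np.empty((n_res, 2))
    for r in range(n_res):
        target = spec.target_for(r + 1)
        if target == "coil":
            if sigma == 0.0:
                # noise-free limit must be deterministic: pin coil to the
                # dominant (alpha) basin centre
                centre = COIL_BASINS[0]
                out[r] = centre[:2]
                continue
            k = rng.choice(len(COIL_BASINS), p=COIL_WEIGHTS)
            cphi, cpsi, cwidth = COIL_BASINS[k]
            out[r] = (cphi + rng.normal(0, cwidth), cpsi + rng.normal(0, cwidth))
        else:
            out[r] = SS_TARGETS[target]
        out[r] += rng.normal(0.0, sigma, size=2) if sigma > 0 else 0.0
    return out


def generate_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Generate a trajectory of independently perturbed conformations.

    Frame t draws per-residue torsions as segment target + N(0, sigma_t^2)
    with sigma_t = dihedral_noise_deg + amplitude_deg * max(0, 1 - t/t0)
    when a drift phase is configured.  Output is bit-reproducible from
    (spec, seed); changing the seed changes coordinates, never topology.
    """
    rng = np.random.default_rng(spec.seed)
    topology = None
    coords = None
    for f in range(spec.n_frames):
        t = f * spec.dt_ns
        sigma = spec.dihedral_noise_deg
        if spec.drift is not None and spec.drift.t0_ns > 0:
            sigma += spec.drift.amplitude_deg * max(0.0, 1.0 - t / spec.drift.t0_ns)
        angles = _sample_phi_psi(spec, sigma, rng)
        top, frame = build_backbone(spec.sequence, angles)
        if coords is None:
            topology = top
            coords = np.empty((spec.n_frames, top.n_atoms, 3))
        coords[f] = frame.coords
    return Trajectory(topology, coords, dt_ns=spec.dt_ns)


def attach_ion(traj: Trajectory, ion: IonSpec, seed: int = 0,
               pull_anchors: bool = False, n_steps: int = 50,
               ) -> tuple[Trajectory, list[int]]:
    """Add a single ion tethered to the anchor atoms in every frame.

    The ion starts at the anchor centroid and is relaxed by ``n_steps``
    rounds of simple distance-restraint corrections toward per-frame target
    distances tether_length + N(0, tether_sigma^2).  By default only the
    ion moves and frames whose anchors cannot all be satisfied (residual
    > 0.05 angstrom) are reported in the returned flagged-frame list.

    With ``pull_anchors=True`` the anchor side-chain groups (atoms beyond
    C-beta of each anchor residue) share the corrections, emulating the ion
    drawing its ligating carboxylates together; non-anchor sibling
    carboxylate oxygens are then oriented away from the ion at
    ``outer_length``, creating an outer-sphere feature.
    """
    rng = np.random.default_rng(seed)
    top = traj.topology
    anchor_idx = [top.atom_index(r, name) for r, name in ion.anchor_atoms]
    for i in anchor_idx:
        if top.atoms[i].element.upper() != "O":
            raise ValueError(f"anchor atom {top.atoms[i].name} is not an oxygen")

    tail_groups = []
    for r, _name in ion.anchor_atoms:
        tail = [a.index for a in top.atoms
                if a.residue_index == r and a.name not in ("N", "CA", "C", "O", "CB")]
        tail_groups.append(tail)

    # siblings: the other carboxylate oxygen of a mono-dentate anchor
    carboxylate_pairs = {"OD1": "OD2", "OD2": "OD1", "OE1": "OE2", "OE2": "OE1"}
    anchor_set = set(anchor_idx)
    siblings = []
    for (r, name), a_idx in zip(ion.anchor_atoms, anchor_idx):
        sib = None
        other = carboxylate_pairs.get(name)
        if other is not None:
            try:
                cand = top.atom_index(r, other)
                if cand not in anchor_set:
                    sib = cand
            except Exception:
                sib = None
        siblings.append(sib)

    sibling_set = {s for s in siblings if s is not None}
    other_oxygens = [
        a.index for a in top.atoms
        if a.element.upper() == "O" and a.index not in anchor_set
        and a.index not in sibling_set
    ]

    n_anchor = len(anchor_idx)
    exclusion = ion.outer_length - 0.3
    new_coords = np.concatenate(
        [traj.coords, np.zeros((traj.n_frames, 1, 3))], axis=1)
    ion_slot = top.n_atoms
    flagged: list[int] = []
    for f in range(traj.n_frames):
        frame_xyz = new_coords[f]
        targets = ion.tether_length + (
            rng.normal(0.0, ion.tether_sigma, size=n_anchor)
            if ion.tether_sigma > 0 else np.zeros(n_anchor))
        anchors = frame_xyz[anchor_idx]
        x = anchors.mean(axis=0)
        if pull_anchors:
            # start the ion outside the peptide envelope so the relaxed
            # ion/carboxylate assembly forms on the surface, keeping
            # non-anchor oxygens out of the inner shell
            outward = x - frame_xyz[:ion_slot].mean(axis=0)
            nrm = np.linalg.norm(outward)
            if nrm > 1e-6:
                x = x + 4.0 * outward / nrm
        settle_after = int(0.8 * n_steps)
        for step in range(n_steps):
            corrections = np.zeros(3)
            for k in range(n_anchor):
                a = frame_xyz[anchor_idx[k]]
                v = x - a
                d = np.linalg.norm(v)
                if d < 1e-9:
                    v = np.array([1.0, 0.0, 0.0])
                    d = 1e-9
                err = d - targets[k]
                u = v / d
                if pull_anchors:
                    # the light ion barely moves; the flexible side-chain
                    # tails do most of the travelling
                    x = x - 0.2 * err * u
                    frame_xyz[tail_groups[k]] += 0.8 * err * u
                else:
                    corrections -= err * u
            if not pull_anchors:
                x = x + corrections / n_anchor
            elif other_oxygens and step < settle_after:
                # exclusion restraint: non-anchor oxygens stay outside the
                # inner shell; switched off for the final sweeps so the
                # tethers settle exactly even when the two restraints fight
                d_other = np.linalg.norm(frame_xyz[other_oxygens] - x, axis=1)
                j = int(np.argmin(d_other))
                if d_other[j] < exclusion:
                    away = x - frame_xyz[other_oxygens[j]]
                    away /= max(np.linalg.norm(away), 1e-9)
                    x = x + 0.5 * (exclusion - d_other[j]) * away
        if pull_anchors and n_anchor == 3 and other_oxygens:
            # Three satisfied tethers leave a two-fold ambiguity: the mirror
            # position across the anchor plane has identical tether
            # distances.  Pick the side farther from the non-anchor
            # oxygens so only the anchor triad occupies the inner shell.
            a0, a1, a2 = frame_xyz[anchor_idx]
            normal = np.cross(a1 - a0, a2 - a0)
            nn = np.linalg.norm(normal)
            if nn > 1e-6:
                normal /= nn
                x_mirror = x - 2.0 * np.dot(x - a0, normal) * normal
                others = frame_xyz[other_oxygens]
                d_here = np.linalg.norm(others - x, axis=1).min()
                d_there = np.linalg.norm(others - x_mirror, axis=1).min()
                if d_there > d_here:
                    x = x_mirror
        dists = np.linalg.norm(x - frame_xyz[anchor_idx], axis=1)
        if np.max(np.abs(dists - targets)) > 0.05:
            flagged.append(f)
        if pull_anchors:
            for k, sib in enumerate(siblings):
                if sib is None:
                    continue
                a = frame_xyz[anchor_idx[k]]
                u = a - x
                u /= np.linalg.norm(u)
                outer = ion.outer_length + (
                    rng.normal(0.0, ion.outer_sigma) if ion.outer_sigma > 0 else 0.0)
                frame_xyz[sib] = x + outer * u
        frame_xyz[ion_slot] = x

    el = ion.element
    ion_res = Residue(index=len(top.residues) + 1, name3=el.upper())
    ion_atom = Atom(index=ion_slot, name=el.upper(), element=el,
                    mass=element_mass(el), residue_index=ion_res.index,
                    is_backbone=False, is_ion=True)
    new_top = Topology(top.residues + [ion_res], top.atoms + [ion_atom])
    return Trajectory(new_top, new_coords, traj.dt_ns, times_ns=traj.times_ns), flagged
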