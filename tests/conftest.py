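import numpy as np
import pytest

from mptraj.synthetic_ensemble import (
    DriftSpec,
    EnsembleSpec,
    IonSpec,
    SegmentSpec,
    attach_ion,
    build_backbone,
    generate_ensemble,
)
from mptraj.traj_model import Frame, Trajectory

AB16 = "DAEFRHDSGYEVHHQK"
AB40 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
AB42 = AB40 + "IA"


@pytest.fixture(scope="session")
def ab16_topology():
    top, _ = build_backbone(AB16, np.tile([-70.0, 150.0], (16, 1)))
    return top


@pytest.fixture(scope="session")
def alpha12():
    """Noise-free 12-residue ideal alpha helix (topology, frame)."""
    return build_backbone("A" * 12, np.tile([-57.0, -47.0], (12, 1)))


@pytest.fixture(scope="session")
def three10_12():
    return build_backbone("A" * 12, np.tile([-49.0, -26.0], (12, 1)))


@pytest.fixture(scope="session")
def alpha_ensemble():
    """Noise-free trajectory of the ideal alpha helix (3 identical frames)."""
    top, frame = build_backbone("A" * 12, np.tile([-57.0, -47.0], (12, 1)))
    return Trajectory(top, np.repeat(frame.coords[None], 3, axis=0))


@pytest.fixture(scope="session")
def sheet_frame():
    """Two antiparallel 6-residue strands on one 12-residue topology.

    The second strand is a rigid copy of the first, chain direction
    reversed (180 degrees about y) and offset so that mutual backbone
    hydrogen bonds form; the offset was located by a coarse alignment scan
    and frozen.  The covalent break between residues 6 and 7 acts as a
    chain break.
    """
    n = 6
    top12, fr12 = build_backbone("A" * 12, np.tile([-139.0, 135.0], (12, 1)))
    _, frA = build_backbone("A" * n, np.tile([-139.0, 135.0], (n, 1)))
    a = frA.coords
    center = a.mean(axis=0)
    rot = np.diag([-1.0, 1.0, -1.0])
    b = (a - center) @ rot.T + center + np.array([-1.25, 4.1, 0.0])
    coords = fr12.coords.copy()
    coords[: 5 * n] = a
    coords[5 * n:] = b
    return top12, Frame(coords)


@pytest.fixture(scope="session")
def tethered_triad():
    """Amyloid-beta-16-like ensemble with an ion tethered to the acidic triad.

    500 frames, tether 1.9 +/- 0.03 angstrom on Glu3/Asp7/Glu11 side-chain
    oxygens; in the anchor-pulling mode all other oxygens remain outside
    ~3.5 angstrom of the ion.
    """
    spec = EnsembleSpec(
        sequence=AB16,
        segments=[SegmentSpec(6, 10, "three10"), SegmentSpec(11, 16, "alpha")],
        dihedral_noise_deg=8.0,
        n_frames=500,
        dt_ns=0.1,
        seed=42,
    )
    traj = generate_ensemble(spec)
    ion = IonSpec(anchor_atoms=[(3, "OE1"), (7, "OD1"), (11, "OE1")],
                  tether_sigma=0.03)
    traj, flagged = attach_ion(traj, ion, seed=7, pull_anchors=True)
    assert not flagged
    return traj


@pytest.fixture(scope="session")
def drifted_ensemble():
    """Drifted ensemble with true equilibration onset at 20 ns."""
    spec = EnsembleSpec(
        sequence=AB16,
        segments=[SegmentSpec(1, 8, "alpha"), SegmentSpec(9, 16, "strand")],
        dihedral_noise_deg=8.0,
        n_frames=500,
        dt_ns=0.1,
        seed=11,
        drift=DriftSpec(t0_ns=20.0, amplitude_deg=60.0),
    )
    return generate_ensemble(spec)


def random_cloud(rng, n=6, scale=5.0):
    return rng.normal(0.0, scale, size=(n, 3))


def random_rigid(rng):
    """A random proper rotation and translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(0.0, 10.0, size=3)
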