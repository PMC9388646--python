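"""Backbone construction and optimal-superposition RMSD.

Peptide backbones (N, CA, C, O per residue) are grown from internal
coordinates with standard bond lengths and angles; ideal secondary structures
come from fixed (phi, psi) pairs: alpha helix (-57, -47), anti-parallel beta
strand (-139, 135), fully extended (180, 180).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .frames import Frame

# Engh/Huber-style backbone geometry (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0  # trans peptide bond

IDEAL_HELIX_PHI_PSI = (-57.0, -47.0)
IDEAL_STRAND_PHI_PSI = (-139.0, 135.0)
EXTENDED_PHI_PSI = (180.0, 180.0)

#: Backbone atoms used for secondary-structure blocks (complete for glycine).
BACKBONE_ATOMS = ("N", "CA", "C", "O")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position atom D given chain A-B-C, |CD|, angle(BCD) and dihedral(ABCD).

    Standard natural-extension (NeRF) placement.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral),
         np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]],
    chain_id: str = "A",
    residue_name: str = "ALA",
    first_residue_index: int = 1,
) -> Frame:
    """Backbone frame from per-residue (phi, psi) in degrees.

    The first residue's phi and the last residue's psi are realized through
    the placement of flanking atoms where possible; psi of the last residue
    still orients its carbonyl oxygen.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")

    coords: list[np.ndarray] = []
    names: list[str] = []
    resi: list[int] = []

    # Seed residue 1: N at origin, CA on x, C in the xy-plane.
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c1 = ca1 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    prev = {"N": n1, "CA": ca1, "C": c1}
    for i, (phi, psi) in enumerate(phi_psi):
        if i > 0:
            n_i = place_atom(
                prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, prev_psi
            )
            ca_i = place_atom(
                prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA
            )
            c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
            cur = {"N": n_i, "CA": ca_i, "C": c_i}
        else:
            cur = prev
        # Carbonyl O: anti to the next residue's N across the C, i.e. at
        # dihedral psi + 180 about the CA-C bond.
        o_i = place_atom(
            cur["N"], cur["CA"], cur["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
        for name, xyz in (("N", cur["N"]), ("CA", cur["CA"]),
                          ("C", cur["C"]), ("O", o_i)):
            coords.append(xyz)
            names.append(name)
            resi.append(first_residue_index + i)
        prev = cur
        prev_psi = psi

    n_atoms = len(coords)
    return Frame(
        np.array(coords),
        names,
        np.array(resi),
        [residue_name] * n_atoms,
        [chain_id] * n_atoms,
    )


def build_ideal_helix(n_res: int, chain_id: str = "A") -> Frame:
    """Ideal alpha-helical backbone (phi = -57°, psi = -47°).

    Consecutive CA-CA distances come out ≈ 3.8 Å; every window of the helix
    superposes exactly onto every other window of the same length (screw
    symmetry), which is what makes it usable as a switched-RMSD reference.
    """
    if n_res < 1:
        raise ValueError(f"n_res must be >= 1, got {n_res}")
    return build_backbone([IDEAL_HELIX_PHI_PSI] * n_res, chain_id=chain_id)


def build_extended_chain(n_res: int, chain_id: str = "A") -> Frame:
    """Fully extended backbone (phi = psi = 180°)."""
    if n_res < 1:
        raise ValueError(f"n_res must be >= 1, got {n_res}")
    return build_backbone([EXTENDED_PHI_PSI] * n_res, chain_id=chain_id)


def build_ideal_antiparallel_sheet(
    strand_separation: float = 4.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Two 3-residue strands in ideal anti-parallel arrangement.

    Returns the (12, 3) backbone coordinate arrays of each strand (atom order
    N, CA, C, O per residue).  Strand 2 runs in the opposite sequence
    direction and is offset by ``strand_separation`` Å, the typical
    inter-strand spacing of an anti-parallel sheet.
    """
    strand = build_backbone([IDEAL_STRAND_PHI_PSI] * 3)
    xyz = strand.coords
    xyz = xyz - xyz.mean(axis=0)
    # Anti-parallel partner: rotate 180° about the axis perpendicular to the
    # mean strand direction in the sheet plane, then offset across the sheet.
    direction = xyz[4 * 2 + 1] - xyz[1]  # CA3 - CA1
    direction /= np.linalg.norm(direction)
    # Build an orthonormal frame (d, u, w); rotate about u.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    rot = Rotation.from_rotvec(np.pi * u).as_matrix()
    partner = xyz @ rot.T + strand_separation * u
    return xyz, partner


def kabsch_rmsd(
    moving: np.ndarray, reference: np.ndarray, units: str = "angstrom"
) -> float:
    """Minimum RMSD between two coordinate sets over all rigid transforms.

    Both sets are centered and the optimal proper rotation is found by
    quaternion/SVD superposition.  Inputs are Å; ``units`` selects the scale
    of the returned value ("angstrom" or "nm").  Symmetric in its arguments.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: {moving.shape} vs {reference.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("coordinate sets must be (n, 3)")
    if len(moving) < 2:
        raise ValueError("degenerate input: need at least 2 atoms")
    x = moving - moving.mean(axis=0)
    y = reference - reference.mean(axis=0)
    with warnings.catch_warnings():
        # Collinear/planar sets leave the rotation non-unique but the RMSD
        # minimum well defined; silence scipy's uniqueness warning.
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(y, x)
    diff = x @ rot.as_matrix().T - y
    rmsd = float(np.sqrt((diff**2).sum() / len(x)))
    if units == "nm":
        return rmsd / 10.0
    if units == "angstrom":
        return rmsd
    raise ValueError(f"unknown units {units!r}")


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a translation in [-10, 10]³ Å."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-10.0, 10.0, size=3)
    return rot, trans
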