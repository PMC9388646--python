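"""Two-chain interface fixtures and synthetic trajectories.

The fixture emulates, at toy scale, a substrate helix whose C-terminal
residues unwind against a receptor: a 12-residue "substrate" chain (helical
N-terminal part, strand-like C-terminal part), a short "receptor" strand that
can pair anti-parallel with the substrate's C-terminal strand, and two
carboxylate-like acceptor groups mimicking a catalytic aspartate dyad.  The
backbone NH of the substrate's last residue is a labelled hydrogen-bond
donor whose donor-acceptor distance and deviation-from-linearity angle are
set exactly to requested values, so geometric trajectory statistics have
constructed ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame, Trajectory
from .geometry import IDEAL_HELIX_PHI_PSI, build_backbone, build_ideal_antiparallel_sheet

N_H_BOND = 1.01  # amide N-H length, Å
MIN_HBOND_DISTANCE = 1.5  # Å, below which the request is sterically impossible


@dataclass
class TwoChainFixture:
    """A substrate/receptor frame with labelled hydrogen-bond geometry.

    ``donors`` are (donor, hydrogen) atom index pairs; ``acceptors`` are
    acceptor atom indices; ``scissile_pairs`` are (C, N) backbone atom index
    pairs flanking the two candidate cleavage sites.
    """

    frame: Frame
    donors: list[tuple[int, int]]
    acceptors: list[int]
    scissile_pairs: list[tuple[int, int]]
    hbond_distance: float
    hbond_angle: float
    sheet_registered: bool


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_two_chain_fixture(
    hbond_distance: float = 2.8,
    hbond_angle: float = 10.0,
    sheet_registered: bool = True,
) -> TwoChainFixture:
    """Build the substrate/receptor fixture with exact donor geometry.

    ``hbond_distance`` is the donor(N)-acceptor distance in Å and
    ``hbond_angle`` the deviation of the D-H...A angle from linearity in
    degrees; both are realized to better than 1e-3.  With
    ``sheet_registered`` the substrate's last three residues and the
    receptor strand are placed exactly in the ideal anti-parallel sheet
    arrangement; otherwise the receptor strand is displaced 30 Å away.
    """
    if hbond_distance < MIN_HBOND_DISTANCE:
        raise ValueError(
            f"hbond_distance {hbond_distance} Å is sterically impossible "
            f"(< {MIN_HBOND_DISTANCE} Å)"
        )
    if not 0.0 <= hbond_angle <= 180.0:
        raise ValueError("hbond_angle must be in [0, 180] degrees")

    # Substrate: 9 helical residues, then 3 strand residues taken verbatim
    # from the ideal anti-parallel reference (guarantees sheet registry).
    helix = build_backbone([IDEAL_HELIX_PHI_PSI] * 9, chain_id="A")
    s1, s2 = build_ideal_antiparallel_sheet()
    helix_end = helix.coords[helix.atom_index("A", 9, "C")]
    shift = helix_end + np.array([3.0, 0.0, 0.0]) - s1[0]
    s1 = s1 + shift
    s2 = s2 + shift
    if not sheet_registered:
        s2 = s2 + np.array([0.0, 0.0, 30.0])

    coords: list[np.ndarray] = list(helix.coords)
    names: list[str] = list(helix.atom_names)
    resi: list[int] = list(helix.residue_indices)
    resnames: list[str] = list(helix.residue_names)
    chains: list[str] = list(helix.chain_ids)

    def add_atom(xyz, name, residue, resname, chain):
        coords.append(np.asarray(xyz, dtype=float))
        names.append(name)
        resi.append(residue)
        resnames.append(resname)
        chains.append(chain)

    backbone = ("N", "CA", "C", "O")
    for r in range(3):  # substrate residues 10-12
        for a_i, a in enumerate(backbone):
            add_atom(s1[4 * r + a_i], a, 10 + r, "ALA", "A")
    for r in range(3):  # receptor strand, chain B residues 1-3
        for a_i, a in enumerate(backbone):
            add_atom(s2[4 * r + a_i], a, r + 1, "GLY", "B")

    # Donor: backbone NH of substrate residue 12.
    n12 = s1[4 * 2 + 0]
    ca12 = s1[4 * 2 + 1]
    c11 = s1[4 * 1 + 2]
    u = _unit(n12 - 0.5 * (ca12 + c11))  # amide-H direction off the backbone
    h12 = n12 + N_H_BOND * u
    add_atom(h12, "H", 12, "ALA", "A")

    # Acceptor: solve for A with |D-A| = d and D-H...A deviating by the
    # requested angle from linearity.
    dev = np.deg2rad(hbond_angle)
    p = _unit(np.cross(u, ca12 - c11))
    w = u * np.cos(dev) + p * np.sin(dev)
    disc = N_H_BOND**2 * (np.cos(dev) ** 2 - 1.0) + hbond_distance**2
    t = -N_H_BOND * np.cos(dev) + np.sqrt(disc)
    acceptor = h12 + t * w
    # Carboxylate-like acceptor group (residue ASP 4 of chain B).
    cg1 = acceptor + 1.25 * w
    od2 = cg1 + 1.25 * _unit(np.cross(w, p))
    add_atom(cg1, "CG", 4, "ASP", "B")
    add_atom(acceptor, "OD1", 4, "ASP", "B")
    add_atom(od2, "OD2", 4, "ASP", "B")
    # Second, distal aspartate (not positioned for bonding).
    far = acceptor + np.array([8.0, 0.0, 0.0])
    add_atom(far, "CG", 5, "ASP", "B")
    add_atom(far + np.array([1.25, 0.0, 0.0]), "OD1", 5, "ASP", "B")
    add_atom(far + np.array([0.0, 1.25, 0.0]), "OD2", 5, "ASP", "B")

    frame = Frame(np.array(coords), names, np.array(resi), resnames, chains)

    don = (frame.atom_index("A", 12, "N"), frame.atom_index("A", 12, "H"))
    acc = [frame.atom_index("B", 4, "OD1"), frame.atom_index("B", 5, "OD1")]
    scissile = [
        (frame.atom_index("A", 10, "C"), frame.atom_index("A", 11, "N")),
        (frame.atom_index("A", 11, "C"), frame.atom_index("A", 12, "N")),
    ]

    # Verify the realized geometry against the request.
    d_realized = float(np.linalg.norm(frame.coords[don[0]] - frame.coords[acc[0]]))
    v1 = frame.coords[don[0]] - frame.coords[don[1]]
    v2 = frame.coords[acc[0]] - frame.coords[don[1]]
    ang = np.degrees(np.arccos(np.clip(_unit(v1) @ _unit(v2), -1.0, 1.0)))
    dev_realized = 180.0 - ang
    if abs(d_realized - hbond_distance) > 1e-3 or abs(dev_realized - hbond_angle) > 1e-3:
        raise RuntimeError(
            "fixture geometry solver failed: "
            f"d = {d_realized:.4f} Å, deviation = {dev_realized:.4f}°"
        )

    return TwoChainFixture(
        frame=frame,
        donors=[don],
        acceptors=acc,
        scissile_pairs=scissile,
        hbond_distance=hbond_distance,
        hbond_angle=hbond_angle,
        sheet_registered=sheet_registered,
    )


def generate_synthetic_trajectory(
    frames_spec: list[tuple[Frame | TwoChainFixture, int]],
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Concatenate (frame, repeat-count) entries into a timed trajectory.

    All entries must share a topology.  At ``noise_sd`` = 0 the occupancy of
    any labelled geometric event equals the spec proportions exactly; with
    noise, independent Gaussian displacements (Å) are drawn per frame from
    the seeded generator.
    """
    if not frames_spec:
        raise ValueError("frames_spec must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    frames = []
    for entry, count in frames_spec:
        frame = entry.frame if isinstance(entry, TwoChainFixture) else entry
        if count < 1:
            raise ValueError("repeat counts must be >= 1")
        frames.extend([frame] * count)
    top = frames[0]
    for f in frames[1:]:
        if (
            f.atom_names != top.atom_names
            or f.chain_ids != top.chain_ids
            or not np.array_equal(f.residue_indices, top.residue_indices)
        ):
            raise ValueError("all frames must share a topology")
    coords = np.stack([f.coords for f in frames])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    times = np.arange(len(coords)) * dt_ps
    return Trajectory(top.copy(), coords, times)
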