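"""Collective variables over coordinate frames.

Implements the switched-RMSD secondary-structure scores (AlphaRMSD /
AntiBetaRMSD and the residual helicity derived from them), the soft
native-contact fraction Q, and the rational coordination number CN between
two atom groups.

Conventions
-----------
* Switched-RMSD scores work on 6-residue alpha blocks or 3+3-residue
  anti-parallel beta blocks of backbone atoms (N, CA, C, O), with block RMSD
  measured in nm and the switching function

      n(x) = (1 - (x/0.1)^8) / (1 - (x/0.1)^12)

  whose removable singularity at RMSD = 0.1 nm has the limit 2/3.  The code
  evaluates the equivalent factorized form (1 + u^4) / (1 + u^4 + u^8) with
  u = x/0.1, which is singularity-free.
* Native contacts use beta = 50 nm^-1 and lambda = 1.5 with pair distances in
  nm; pairs are selected from a reference structure at r0 < 0.45 nm.
* Coordination numbers use r0 = 4.5 Å with exponents n = 6, m = 12 unless
  overridden; at r = r0 the switching value is the limit n/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .frames import Frame
from .geometry import (
    BACKBONE_ATOMS,
    build_ideal_antiparallel_sheet,
    build_ideal_helix,
    kabsch_rmsd,
)

#: Length scale of the secondary-structure switching function (nm).
SS_SWITCH_R0_NM = 0.1
ALPHA_BLOCK_LEN = 6
BETA_STRAND_LEN = 3


def ss_switch(rmsd_nm: float | np.ndarray) -> float | np.ndarray:
    """Secondary-structure switching function n(RMSD), RMSD in nm.

    Continuous on [0, inf): n(0) = 1, strictly decreasing, -> 0, with
    n(0.1) = 2/3 (the analytic limit at the removable singularity).
    """
    u4 = (np.asarray(rmsd_nm, dtype=float) / SS_SWITCH_R0_NM) ** 4
    out = (1.0 + u4) / (1.0 + u4 + u4 * u4)
    return float(out) if np.isscalar(rmsd_nm) else out


def rational_switch(
    r: np.ndarray, r0: float, n_exp: int = 6, m_exp: int = 12
) -> np.ndarray:
    """Rational switching (1 - (r/r0)^n) / (1 - (r/r0)^m), limit n/m at r = r0."""
    y = np.asarray(r, dtype=float) / r0
    if m_exp == 2 * n_exp:
        # Exact factorization: (1 - y^n)/(1 - y^2n) = 1/(1 + y^n).
        return 1.0 / (1.0 + y**n_exp)
    yn = y**n_exp
    ym = y**m_exp
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 - yn) / (1.0 - ym)
    singular = np.isclose(y, 1.0, rtol=0.0, atol=1e-12)
    return np.where(singular, n_exp / m_exp, out)


@dataclass
class SegmentLibrary:
    """Ideal secondary-structure reference block.

    ``reference_coordinates`` hold the ideal-block backbone positions in Å
    (atom order: residue-major, N/CA/C/O); ``block_length`` counts residues in
    a block (6 for alpha, 3+3 for antibeta).
    """

    block_kind: str  # "alpha" | "antibeta"
    reference_coordinates: np.ndarray
    block_length: int
    atom_set: tuple[str, ...] = BACKBONE_ATOMS

    @classmethod
    def alpha(cls) -> "SegmentLibrary":
        helix = build_ideal_helix(ALPHA_BLOCK_LEN)
        return cls("alpha", helix.coords.copy(), ALPHA_BLOCK_LEN)

    @classmethod
    def antibeta(cls) -> "SegmentLibrary":
        s1, s2 = build_ideal_antiparallel_sheet()
        return cls("antibeta", np.vstack([s1, s2]), 2 * BETA_STRAND_LEN)


@dataclass
class SSRMSDScore:
    """Switched-RMSD secondary-structure score.

    ``S`` sums the switching function over candidate blocks; ``per_block``
    lists (block residue description, RMSD in nm, n(RMSD)) per block.
    Invariant: 0 <= S <= number of blocks.
    """

    S: float
    per_block: list[tuple[tuple[int, ...], float, float]]


@dataclass
class HelicityResult:
    """Residual helicity f_H = S / S_Max of a residue window."""

    f_H: float
    S: float
    S_Max: float


def _block_coords(
    frame: Frame,
    chain_id: str,
    residues: list[int],
    atom_set: tuple[str, ...],
) -> np.ndarray:
    coords = []
    for r in residues:
        for a in atom_set:
            try:
                coords.append(frame.coords[frame.atom_index(chain_id, r, a)])
            except KeyError:
                raise KeyError(
                    f"missing atom {a!r} in residue {r} chain {chain_id!r}"
                ) from None
    return np.array(coords)


def alpha_rmsd(
    frame: Frame,
    residue_window: tuple[int, int],
    library: SegmentLibrary | None = None,
    chain_id: str = "A",
) -> SSRMSDScore:
    """AlphaRMSD score S of a residue window (inclusive, 1-based).

    Sums n(RMSD) over all contiguous 6-residue blocks in the window, RMSD
    taken against the ideal alpha-helix block after optimal superposition.
    An ideal 12-residue helix scores S = 7 (one per window position).
    """
    if library is None:
        library = SegmentLibrary.alpha()
    if library.block_kind != "alpha":
        raise ValueError("alpha_rmsd needs an alpha SegmentLibrary")
    lo, hi = residue_window
    window = list(range(lo, hi + 1))
    if len(window) < library.block_length:
        raise ValueError(
            f"window {residue_window} shorter than one {library.block_length}"
            "-residue block"
        )
    per_block = []
    s = 0.0
    for start in range(len(window) - library.block_length + 1):
        residues = window[start : start + library.block_length]
        xyz = _block_coords(frame, chain_id, residues, library.atom_set)
        r_nm = kabsch_rmsd(xyz, library.reference_coordinates, units="nm")
        n_val = ss_switch(r_nm)
        per_block.append((tuple(residues), r_nm, n_val))
        s += n_val
    return SSRMSDScore(S=s, per_block=per_block)


def residual_helicity(
    frame: Frame,
    residue_window: tuple[int, int],
    library: SegmentLibrary | None = None,
    chain_id: str = "A",
) -> HelicityResult:
    """Residual helicity f_H = S / S_Max of a residue window.

    S_Max = window_length - 6 + 1 is the score of the window in the ideal
    all-helical state; f_H is clamped to [0, 1] and approximates the
    fraction of ideal alpha-helix content.
    """
    lo, hi = residue_window
    if library is None:
        library = SegmentLibrary.alpha()
    s_max = (hi - lo + 1) - library.block_length + 1
    if s_max < 1:
        raise ValueError("window shorter than one block")
    score = alpha_rmsd(frame, residue_window, library, chain_id=chain_id)
    f_h = min(1.0, max(0.0, score.S / s_max))
    return HelicityResult(f_H=f_h, S=score.S, S_Max=float(s_max))


def antibeta_rmsd(
    frame: Frame,
    segments: list[tuple[str, int, int]],
    library: SegmentLibrary | None = None,
) -> SSRMSDScore:
    """AntiBetaRMSD score over candidate 3+3-residue anti-parallel blocks.

    ``segments`` are (chain_id, first_residue, last_residue) ranges, each at
    least 3 residues, mutually non-overlapping, at least two of them.  Every
    ordered pair of 3-residue windows drawn from two distinct segments forms a
    candidate block (windows on the same chain must be separated by at least
    one intervening residue); each block contributes n(RMSD) against the
    ideal anti-parallel reference.
    """
    if library is None:
        library = SegmentLibrary.antibeta()
    if library.block_kind != "antibeta":
        raise ValueError("antibeta_rmsd needs an antibeta SegmentLibrary")
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    for chain, lo, hi in segments:
        if hi - lo + 1 < BETA_STRAND_LEN:
            raise ValueError(f"segment {(chain, lo, hi)} shorter than 3 residues")
    for i, (ci, li, hi_i) in enumerate(segments):
        for cj, lj, hj in segments[i + 1 :]:
            if ci == cj and not (hi_i < lj or hj < li):
                raise ValueError("segments overlap")

    def windows(seg: tuple[str, int, int]) -> list[tuple[str, list[int]]]:
        chain, lo, hi = seg
        return [
            (chain, list(range(s, s + BETA_STRAND_LEN)))
            for s in range(lo, hi - BETA_STRAND_LEN + 2)
        ]

    per_block = []
    s = 0.0
    for i, seg_a in enumerate(segments):
        for j, seg_b in enumerate(segments):
            if i == j:
                continue
            for chain_a, res_a in windows(seg_a):
                for chain_b, res_b in windows(seg_b):
                    if chain_a == chain_b:
                        gap = max(res_a[0], res_b[0]) - min(res_a[-1], res_b[-1]) - 1
                        if gap < 1:
                            continue
                    xyz = np.vstack(
                        [
                            _block_coords(frame, chain_a, res_a, library.atom_set),
                            _block_coords(frame, chain_b, res_b, library.atom_set),
                        ]
                    )
                    r_nm = kabsch_rmsd(
                        xyz, library.reference_coordinates, units="nm"
                    )
                    n_val = ss_switch(r_nm)
                    per_block.append((tuple(res_a + res_b), r_nm, n_val))
                    s += n_val
    return SSRMSDScore(S=s, per_block=per_block)


@dataclass
class NativeContactSpec:
    """Reference contact pairs for the soft native-contact fraction Q.

    ``pairs`` maps (atom index i, atom index j) to the reference distance
    r_ij0 in nm; only pairs with r_ij0 below the selection cutoff belong here.
    """

    pairs: list[tuple[int, int]]
    r0_nm: np.ndarray
    beta_per_nm: float = 50.0
    lam: float = 1.5

    def __post_init__(self) -> None:
        self.r0_nm = np.asarray(self.r0_nm, dtype=float)
        if len(self.r0_nm) != len(self.pairs):
            raise ValueError("one reference distance per pair required")
        if np.any(self.r0_nm <= 0):
            raise ValueError("reference distances must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def extract_contact_pairs(
    reference: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff_nm: float = 0.45,
    beta_per_nm: float = 50.0,
    lam: float = 1.5,
) -> NativeContactSpec:
    """Select native-contact pairs from a reference structure.

    All inter-group heavy-atom pairs with reference distance strictly smaller
    than ``cutoff_nm`` (default 0.45 nm = 4.5 Å) are selected; the reference
    distances are stored as the pairs' equilibrium distances r_ij0.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("empty atom selection")
    heavy = set(reference.heavy_atom_indices().tolist())
    if not set(group_a) <= heavy or not set(group_b) <= heavy:
        raise ValueError("contact selections must contain heavy atoms only")
    d_nm = cdist(reference.coords[group_a], reference.coords[group_b]) / 10.0
    ii, jj = np.nonzero(d_nm < cutoff_nm)
    pairs = [(int(group_a[i]), int(group_b[j])) for i, j in zip(ii, jj)]
    return NativeContactSpec(
        pairs=pairs, r0_nm=d_nm[ii, jj], beta_per_nm=beta_per_nm, lam=lam
    )


def native_contacts(frame: Frame, spec: NativeContactSpec) -> float:
    """Soft native-contact fraction Q of a frame against a reference spec.

    Q = (1/N) sum over pairs of 1 / (1 + exp[beta (r_ij - lambda r_ij0)]),
    distances in nm.  Q -> 1 when all pairs sit at their reference distance
    and -> 0 when all are broken; Q = 0.5 when every pair sits exactly at
    lambda * r_ij0.
    """
    if spec.n_pairs == 0:
        raise ValueError("native-contact spec has no pairs (undefined average)")
    idx_a = np.array([p[0] for p in spec.pairs])
    idx_b = np.array([p[1] for p in spec.pairs])
    r_nm = np.linalg.norm(frame.coords[idx_a] - frame.coords[idx_b], axis=1) / 10.0
    x = spec.beta_per_nm * (r_nm - spec.lam * spec.r0_nm)
    return float(np.mean(1.0 / (1.0 + np.exp(x))))


@dataclass
class CoordinationSpec:
    """Atom groups and switching parameters for a coordination number."""

    group_a: np.ndarray
    group_b: np.ndarray
    r0_angstrom: float = 4.5
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError("empty atom selection")
        if set(self.group_a.tolist()) & set(self.group_b.tolist()):
            raise ValueError("coordination groups must be disjoint")
        if self.r0_angstrom <= 0:
            raise ValueError("r0 must be positive")
        if not self.n_exp < self.m_exp:
            raise ValueError("need n_exp < m_exp")


def coordination_number(frame: Frame, spec: CoordinationSpec) -> float:
    """Coordination number CN between two atom groups.

    CN = sum over (i in A, j in B) of the rational switch
    (1 - (r_ij/r0)^n) / (1 - (r_ij/r0)^m); each term is 1 well inside r0,
    n/m at exactly r0 and decays to 0 beyond, so CN softly counts contacts.
    """
    r = cdist(frame.coords[spec.group_a], frame.coords[spec.group_b])
    return float(
        rational_switch(r, spec.r0_angstrom, spec.n_exp, spec.m_exp).sum()
    )
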