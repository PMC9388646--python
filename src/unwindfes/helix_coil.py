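"""Exactly solvable 12-site helix-coil chain and its Cartesian embedding.

Each of the n sites is helical (H) or coil (C).  The energy is Ising-like:

    E(s) = delta_e * (# helical sites)  -  J * (# equal neighbour pairs)

with delta_e the per-site helix stabilization (kcal/mol; negative favours
helix) and J >= 0 a nearest-neighbour cooperativity coupling.  For n <= 20
the 2^n states are enumerated exactly, giving Boltzmann weights, the
per-helix-count free-energy profile F(k), and an independent transfer-matrix
partition function for cross-checking.  States can be embedded as 3D
backbones (ideal helical dihedrals on H sites, extended-ish coil dihedrals on
C sites) so the geometric residual-helicity CV can be evaluated on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kt
from .frames import Frame
from .geometry import IDEAL_HELIX_PHI_PSI, build_backbone

#: Coil dihedrals: fixed (not random) so fixtures are reproducible.
COIL_PHI_PSI = (-120.0, 120.0)

MAX_ENUM_SITES = 20


@dataclass
class HelixCoilModel:
    """Two-state helix-coil chain with nearest-neighbour coupling."""

    n_sites: int = 12
    delta_e: float = -0.5  # kcal/mol per helical site
    J: float = 0.5  # kcal/mol per like-state neighbour pair
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    def energy(self, state: np.ndarray) -> float:
        """Energy (kcal/mol) of a 0/1 helix-indicator state vector."""
        s = np.asarray(state)
        k = int(s.sum())
        matches = int(np.sum(s[:-1] == s[1:]))
        return self.delta_e * k - self.J * matches

    def flip_energy_change(self, state: np.ndarray, site: int) -> float:
        """Energy change of flipping one site; O(1) in chain length."""
        s = state
        old = s[site]
        new = 1 - old
        de = self.delta_e * (new - old)
        for nb in (site - 1, site + 1):
            if 0 <= nb < self.n_sites:
                de -= self.J * (int(s[nb] == new) - int(s[nb] == old))
        return float(de)

    def helix_fraction(self, state: np.ndarray) -> float:
        """Fraction of helical sites, the chain's residual-helicity analogue."""
        return float(np.mean(state))

    def neighbor_alignment(self, state: np.ndarray) -> float:
        """Fraction of equal-state neighbour pairs (a contact-like CV)."""
        s = np.asarray(state)
        return float(np.mean(s[:-1] == s[1:]))

    #: CV names resolvable by the sampler.
    CV_FUNCS = {
        "helix_fraction": helix_fraction,
        "neighbor_alignment": neighbor_alignment,
    }

    def cv_value(self, name: str, state: np.ndarray) -> float:
        try:
            return self.CV_FUNCS[name](self, state)
        except KeyError:
            raise ValueError(f"unknown CV {name!r} for HelixCoilModel") from None


def enumerate_helix_coil(model: HelixCoilModel) -> pd.DataFrame:
    """Exact state table of a helix-coil chain.

    Returns one row per state with columns ``state`` (H/C string), ``energy``
    (kcal/mol), ``weight`` (normalized Boltzmann weight), ``k`` (helical-site
    count) and ``f_H`` (= k / n_sites).  Weights sum to 1.
    """
    n = model.n_sites
    if n > MAX_ENUM_SITES:
        raise ValueError(
            f"n_sites = {n} too large for exact enumeration "
            f"(limit {MAX_ENUM_SITES}); use transfer_matrix_log_z instead"
        )
    codes = np.arange(2**n, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    k = bits.sum(axis=1)
    matches = np.sum(bits[:, :-1] == bits[:, 1:], axis=1)
    energy = model.delta_e * k - model.J * matches
    w = np.exp(-(energy - energy.min()) / model.kt)
    w /= w.sum()
    labels = ["".join("H" if b else "C" for b in row) for row in bits]
    return pd.DataFrame(
        {"state": labels, "energy": energy, "weight": w, "k": k, "f_H": k / n}
    )


def free_energy_profile(model: HelixCoilModel) -> pd.DataFrame:
    """Exact free energy F(k) over helical-site count, min-shifted to 0.

    F(k) = -k_B T ln sum of weights of states with k helical sites.
    """
    table = enumerate_helix_coil(model)
    by_k = table.groupby("k")["weight"].sum()
    f = -model.kt * np.log(by_k.to_numpy())
    f -= f.min()
    return pd.DataFrame(
        {"k": by_k.index.to_numpy(), "f_H": by_k.index.to_numpy() / model.n_sites,
         "F": f}
    )


def transfer_matrix_log_z(model: HelixCoilModel) -> float:
    """log of the partition function via the 2x2 transfer matrix.

    Independent of :func:`enumerate_helix_coil`; usable beyond the
    enumeration limit.  The energy zero matches ``model.energy``.
    """
    beta = 1.0 / model.kt
    h = np.array([0.0, model.delta_e])  # site term by state (C=0, H=1)
    v = np.exp(-beta * h)  # first-site weights
    m = np.empty((2, 2))
    for s in (0, 1):
        for s2 in (0, 1):
            m[s, s2] = np.exp(-beta * (h[s2] - model.J * (s == s2)))
    vec = v.copy()
    log_scale = 0.0
    for _ in range(model.n_sites - 1):
        vec = vec @ m
        scale = vec.max()
        vec /= scale
        log_scale += np.log(scale)
    return float(np.log(vec.sum()) + log_scale)


def enumeration_log_z(model: HelixCoilModel) -> float:
    """log Z by direct summation over the enumerated state energies."""
    n = model.n_sites
    codes = np.arange(2**n, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    energy = model.delta_e * bits.sum(axis=1) - model.J * np.sum(
        bits[:, :-1] == bits[:, 1:], axis=1
    )
    e0 = energy.min()
    return float(-e0 / model.kt + np.log(np.exp(-(energy - e0) / model.kt).sum()))


def state_from_label(label: str) -> np.ndarray:
    """Parse an H/C string into a 0/1 indicator vector."""
    if set(label) - {"H", "C"}:
        raise ValueError(f"state labels must be H/C strings, got {label!r}")
    return np.array([1 if c == "H" else 0 for c in label], dtype=np.int8)


def embed_chain_state(
    state: np.ndarray | str,
    noise_sd: float = 0.0,
    seed: int = 0,
    chain_id: str = "A",
) -> Frame:
    """Embed a helix/coil state as a 3D backbone frame.

    Helical sites get ideal alpha dihedrals, coil sites the fixed coil
    dihedrals; optional isotropic Gaussian coordinate noise of ``noise_sd`` Å
    is added with the given seed (deterministic per (state, noise_sd, seed)).
    """
    if isinstance(state, str):
        state = state_from_label(state)
    state = np.asarray(state)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    phi_psi = [
        IDEAL_HELIX_PHI_PSI if s else COIL_PHI_PSI for s in state
    ]
    frame = build_backbone(phi_psi, chain_id=chain_id)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame.coords = frame.coords + rng.normal(
            0.0, noise_sd, size=frame.coords.shape
        )
    return frame
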