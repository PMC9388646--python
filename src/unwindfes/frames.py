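"""Coordinate containers: single frames and trajectories.

A :class:`Frame` is a light structure-of-arrays holding one conformation of a
(poly)peptide system: per-atom coordinates in Å plus atom name, residue index
(1-based, PDB convention), residue name and chain id.  A :class:`Trajectory`
shares one topology (the per-atom metadata of a template frame) across an
ordered stack of coordinate sets with timestamps in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Frame:
    """One conformation with minimal PDB-style metadata.

    Invariants: coordinates are finite; residue indices are non-decreasing
    within a chain; atom names are unique within a residue.
    """

    coords: np.ndarray  # (n_atoms, 3), Å
    atom_names: list[str]
    residue_indices: np.ndarray  # (n_atoms,), 1-based
    residue_names: list[str]
    chain_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        n = len(self.coords)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        for name, seq in (
            ("atom_names", self.atom_names),
            ("residue_indices", self.residue_indices),
            ("residue_names", self.residue_names),
            ("chain_ids", self.chain_ids),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} has length {len(seq)}, expected {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._check_invariants()

    def _check_invariants(self) -> None:
        for chain in dict.fromkeys(self.chain_ids):
            mask = [c == chain for c in self.chain_ids]
            resi = self.residue_indices[mask]
            if np.any(np.diff(resi) < 0):
                raise ValueError(
                    f"residue indices decrease within chain {chain!r}"
                )
        seen: set[tuple[str, int, str]] = set()
        for name, resi, chain in zip(
            self.atom_names, self.residue_indices, self.chain_ids
        ):
            key = (chain, int(resi), name)
            if key in seen:
                raise ValueError(
                    f"duplicate atom {name!r} in residue {resi} chain {chain!r}"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        """Index of a uniquely identified atom; KeyError if absent."""
        for i in range(self.n_atoms):
            if (
                self.chain_ids[i] == chain_id
                and self.residue_indices[i] == residue_index
                and self.atom_names[i] == atom_name
            ):
                return i
        raise KeyError(f"atom {atom_name} of residue {residue_index} chain {chain_id}")

    def select(
        self,
        chain_id: str | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: list[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters (inclusive residue range)."""
        keep = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            keep &= np.array([c == chain_id for c in self.chain_ids])
        if residue_range is not None:
            lo, hi = residue_range
            keep &= (self.residue_indices >= lo) & (self.residue_indices <= hi)
        if atom_names is not None:
            wanted = set(atom_names)
            keep &= np.array([a in wanted for a in self.atom_names])
        return np.nonzero(keep)[0]

    def heavy_atom_indices(self) -> np.ndarray:
        """Indices of non-hydrogen atoms (element guessed from the atom name)."""
        return np.array(
            [i for i, a in enumerate(self.atom_names) if _element(a) != "H"],
            dtype=int,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Copy with coordinates rigidly transformed: x -> R x + t."""
        return Frame(
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            list(self.atom_names),
            self.residue_indices.copy(),
            list(self.residue_names),
            list(self.chain_ids),
        )

    def copy(self) -> "Frame":
        return Frame(
            self.coords.copy(),
            list(self.atom_names),
            self.residue_indices.copy(),
            list(self.residue_names),
            list(self.chain_ids),
        )


def _element(atom_name: str) -> str:
    """Element symbol guessed from a PDB-style atom name (first letter)."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


@dataclass
class Trajectory:
    """An ordered stack of conformations sharing one topology.

    ``topology`` supplies the per-atom metadata; ``coords`` is
    (n_frames, n_atoms, 3) in Å; ``times`` is (n_frames,) in ps.
    """

    topology: Frame
    coords: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise ValueError(
                "coords must be (n_frames, n_atoms, 3) matching the topology"
            )
        if self.times is None:
            self.times = np.arange(len(self.coords), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.coords):
            raise ValueError("times length must match the frame count")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> Frame:
        """Materialize frame ``i`` as a standalone :class:`Frame`."""
        f = self.topology.copy()
        f.coords = self.coords[i].copy()
        return f

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def concatenate(trajectories: list[Trajectory]) -> Trajectory:
    """Concatenate trajectories sharing a topology; times are re-strided."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    top = trajectories[0].topology
    for t in trajectories[1:]:
        if t.topology.atom_names != top.atom_names:
            raise ValueError("trajectories must share a topology")
    coords = np.concatenate([t.coords for t in trajectories])
    return Trajectory(top, coords)
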