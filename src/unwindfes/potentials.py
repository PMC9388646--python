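"""Analytic toy potentials with exact gradients and quadrature oracles.

These low-dimensional energy surfaces (kcal/mol over Å) are the controlled
substrate for the enhanced-sampling machinery: their Boltzmann statistics are
computable by direct quadrature, so free-energy estimates from metadynamics
can be checked against closed-form or numerically exact references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import kt


@dataclass
class HarmonicWell:
    """V(x) = 0.5 * k * (x - x0)^2 per dimension (kcal/mol, Å)."""

    k: float = 2.0  # kcal/mol/Å^2
    x0: float = 0.0
    dim: int = 1
    domain: tuple[float, float] = (-8.0, 8.0)

    def energy(self, x: np.ndarray) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return float(0.5 * self.k * np.sum((x - self.x0) ** 2))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.k * (x - self.x0)

    def grad1d(self, x: float) -> float:
        return self.k * (x - self.x0)

    def equilibrium_variance(self, temperature: float) -> float:
        """Equipartition: var(x) = k_B T / k per dimension."""
        return kt(temperature) / self.k


@dataclass
class DoubleWell1D:
    """Tilted quartic double well V(x) = h ((x/a)^2 - 1)^2 + t x / a.

    ``h`` sets the barrier height of the symmetric part (kcal/mol), ``a`` the
    well positions (±a Å at t = 0), and ``t`` a linear tilt that makes the
    wells inequivalent (the right well at x ≈ +a is destabilized for t > 0).
    """

    h: float = 3.0
    a: float = 1.0
    t: float = 0.8
    domain: tuple[float, float] = (-2.5, 2.5)
    dim: int = 1

    def energy(self, x: np.ndarray) -> float:
        u = float(np.atleast_1d(x)[0]) / self.a
        return self.h * (u * u - 1.0) ** 2 + self.t * u

    def gradient(self, x: np.ndarray) -> np.ndarray:
        u = float(np.atleast_1d(x)[0]) / self.a
        return np.array([(4.0 * self.h * u * (u * u - 1.0) + self.t) / self.a])

    def grad1d(self, x: float) -> float:
        u = x / self.a
        return (4.0 * self.h * u * (u * u - 1.0) + self.t) / self.a

    def basin_free_energies(self, temperature: float) -> tuple[float, float]:
        """(F_left, F_right) from Boltzmann quadrature over each basin.

        Basins are separated at the barrier top (the local maximum of V
        between the wells); F_basin = -k_B T ln ∫ exp(-V/k_B T) dx, reported
        min-shifted so the deeper basin is 0.
        """
        kbt = kt(temperature)
        xs = np.linspace(*self.domain, 20001)
        vs = np.array([self.energy(np.array([x])) for x in xs])
        mid = (xs > -self.a) & (xs < self.a)
        barrier_x = xs[mid][np.argmax(vs[mid])]

        def boltz(x: float) -> float:
            return np.exp(-self.energy(np.array([x])) / kbt)

        z_left, _ = quad(boltz, self.domain[0], barrier_x, limit=200)
        z_right, _ = quad(boltz, barrier_x, self.domain[1], limit=200)
        f = -kbt * np.log(np.array([z_left, z_right]))
        f -= f.min()
        return float(f[0]), float(f[1])


@dataclass
class TwoBasin2D:
    """Two Gaussian basins on a flat background (2D).

    V(x, y) = -d1 exp(-|r - c1|^2 / (2 w^2)) - d2 exp(-|r - c2|^2 / (2 w^2))
    plus a weak confining quadratic wall keeping samples on the domain.
    """

    depth1: float = 3.0
    depth2: float = 2.0
    center1: tuple[float, float] = (-1.5, 0.0)
    center2: tuple[float, float] = (1.5, 0.0)
    width: float = 0.7
    wall_k: float = 0.5
    domain: tuple[float, float] = (-4.0, 4.0)
    dim: int = 2

    def _basins(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        c1 = np.array(self.center1)
        c2 = np.array(self.center2)
        g1 = np.exp(-np.sum((x - c1) ** 2) / (2 * self.width**2))
        g2 = np.exp(-np.sum((x - c2) ** 2) / (2 * self.width**2))
        return c1, c2, g1, g2

    def energy(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        _, _, g1, g2 = self._basins(x)
        wall = 0.5 * self.wall_k * float(np.sum(x**2))
        return float(-self.depth1 * g1 - self.depth2 * g2 + wall)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c1, c2, g1, g2 = self._basins(x)
        grad = self.wall_k * x
        grad += self.depth1 * g1 * (x - c1) / self.width**2
        grad += self.depth2 * g2 * (x - c2) / self.width**2
        return grad


@dataclass
class FlatPotential1D:
    """Zero potential on a bounded interval (reflecting walls in the sampler)."""

    domain: tuple[float, float] = (0.0, 1.0)
    dim: int = 1

    def energy(self, x: np.ndarray) -> float:
        return 0.0

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.zeros(1)

    def grad1d(self, x: float) -> float:
        return 0.0


POTENTIALS = {
    "harmonic": HarmonicWell,
    "double_well_1d": DoubleWell1D,
    "two_basin_2d": TwoBasin2D,
    "flat_1d": FlatPotential1D,
}


def make_potential(kind: str, **params):
    """Factory for analytic potentials by config name."""
    try:
        cls = POTENTIALS[kind]
    except KeyError:
        raise ValueError(
            f"unknown potential {kind!r}; known: {sorted(POTENTIALS)}"
        ) from None
    return cls(**params)
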