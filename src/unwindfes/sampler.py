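"""Overdamped Langevin / Metropolis sampling with well-tempered
bias-exchange metadynamics.

Replicas of one toy model run in parallel; each biased replica accumulates a
well-tempered history-dependent bias of Gaussian hills along its assigned
collective variable, with hill heights decaying as exp(-V/(k_B ΔT)),
ΔT = (γ - 1) T.  One replica may stay neutral (no bias).  At fixed intervals
configurations of neighbouring replicas are swapped by a Metropolis rule in
which the model energy cancels and only the two bias potentials enter.

Continuous models (the analytic potentials) are propagated by first-order
(overdamped) Euler-Maruyama Langevin dynamics with unit effective mass:
mobility μ = 1/friction, step  dx = -μ ∇(U+V) dt + sqrt(2 k_B T μ dt) ξ.
The discrete helix-coil chain is propagated by single-site Metropolis flips
against model-plus-bias energy, which obeys detailed balance exactly.

Deposition and exchange cadences default to the 4 ps / 10 ps bookkeeping of
the bias-exchange protocol this package emulates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import K_B
from .helix_coil import HelixCoilModel

logger = logging.getLogger(__name__)

COORD_CV_NAMES = ("x", "y", "z")


@dataclass
class ThermoParams:
    """Thermodynamic and integrator parameters."""

    temperature: float = 310.0  # K
    k_B: float = K_B  # kcal/mol/K
    friction: float = 1.0  # 1/ps
    timestep: float = 0.002  # ps

    def __post_init__(self) -> None:
        for name in ("temperature", "k_B", "friction", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kt(self) -> float:
        return self.k_B * self.temperature


@dataclass
class Hill:
    """One deposited Gaussian: center and width in CV space, height in kcal/mol."""

    center: np.ndarray
    sigma: np.ndarray
    height: float
    deposit_time: float

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0) or self.height <= 0:
            raise ValueError("hill sigma and height must be positive")


class BiasPotential:
    """Accumulated well-tempered metadynamics bias along one or more CVs.

    ``gamma`` is the bias factor (> 1, or ``math.inf`` for standard,
    non-tempered metadynamics); ``h0`` the initial hill height (kcal/mol);
    ``sigma`` the per-CV hill width; ``cv_names`` names the CV(s) this bias
    reads.  V(s) >= 0 everywhere and hill heights at a revisited point are
    non-increasing for finite gamma.
    """

    def __init__(
        self,
        cv_names: tuple[str, ...] | str,
        sigma: float | np.ndarray = 0.1,
        h0: float = 0.3,
        gamma: float = 10.0,
    ) -> None:
        if isinstance(cv_names, str):
            cv_names = (cv_names,)
        self.cv_names = tuple(cv_names)
        self.dim = len(self.cv_names)
        self.sigma = np.broadcast_to(
            np.atleast_1d(np.asarray(sigma, dtype=float)), (self.dim,)
        ).copy()
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if h0 <= 0:
            raise ValueError("h0 must be positive")
        if not gamma > 1:
            raise ValueError("bias factor gamma must be > 1 (or inf)")
        self.h0 = float(h0)
        self.gamma = float(gamma)
        self.hills: list[Hill] = []
        self._centers = np.empty((0, self.dim))
        self._heights = np.empty(0)
        # Optional grid cache for fast per-step lookups (1D only).
        self._grid: np.ndarray | None = None
        self._grid_v: np.ndarray | None = None
        self._grid_dv: np.ndarray | None = None

    # -- evaluation ---------------------------------------------------------

    def energy(self, s: float | np.ndarray) -> float:
        """Bias energy V(s) in kcal/mol (exact sum over hills)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite CV value")
        if len(self.hills) == 0:
            return 0.0
        z = (s[None, :] - self._centers) / self.sigma[None, :]
        return float(np.sum(self._heights * np.exp(-0.5 * np.sum(z * z, axis=1))))

    def energy_many(self, points: np.ndarray) -> np.ndarray:
        """V at many CV points, shape (n,) from points shape (n, dim) or (n,)."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if len(self.hills) == 0:
            return np.zeros(len(pts))
        z = (pts[:, None, :] - self._centers[None, :, :]) / self.sigma[None, None, :]
        return np.sum(
            self._heights[None, :] * np.exp(-0.5 * np.sum(z * z, axis=2)), axis=1
        )

    def gradient(self, s: float | np.ndarray) -> np.ndarray:
        """dV/ds, exact analytic derivative of the Gaussian sum."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite CV value")
        if len(self.hills) == 0:
            return np.zeros(self.dim)
        z = (s[None, :] - self._centers) / self.sigma[None, :]
        g = self._heights[:, None] * np.exp(
            -0.5 * np.sum(z * z, axis=1, keepdims=True)
        )
        return np.sum(-g * z / self.sigma[None, :], axis=0)

    # -- deposition ---------------------------------------------------------

    def next_height(self, s: float | np.ndarray, thermo: ThermoParams) -> float:
        """Well-tempered height of a hill deposited at CV value ``s``."""
        if math.isinf(self.gamma):
            return self.h0
        delta_t = (self.gamma - 1.0) * thermo.temperature
        return self.h0 * math.exp(-self.energy(s) / (thermo.k_B * delta_t))

    def add_hill(self, s: float | np.ndarray, time: float, thermo: ThermoParams) -> Hill:
        """Deposit one hill at CV value ``s`` and update caches."""
        height = self.next_height(s, thermo)
        hill = Hill(np.atleast_1d(np.asarray(s, dtype=float)), self.sigma, height, time)
        self.hills.append(hill)
        self._centers = np.vstack([self._centers, hill.center[None, :]])
        self._heights = np.append(self._heights, height)
        if self._grid is not None:
            z = (self._grid - hill.center[0]) / self.sigma[0]
            g = height * np.exp(-0.5 * z * z)
            self._grid_v += g
            self._grid_dv += -g * z / self.sigma[0]
        return hill

    # -- grid cache (sampler acceleration, 1D) ------------------------------

    def attach_grid(self, points: np.ndarray) -> None:
        """Cache V and dV/ds on a fixed 1D grid, kept current on deposits."""
        if self.dim != 1:
            raise ValueError("grid cache supports 1D biases only")
        self._grid = np.asarray(points, dtype=float)
        self._grid_v = self.energy_many(self._grid)
        z = (self._grid[:, None] - self._centers[None, :, 0]) / self.sigma[0]
        if len(self.hills):
            self._grid_dv = np.sum(
                -self._heights[None, :] * np.exp(-0.5 * z * z) * z / self.sigma[0],
                axis=1,
            )
        else:
            self._grid_dv = np.zeros_like(self._grid)

    def to_hills_frame(self) -> pd.DataFrame:
        """HILLS record: time, center(s), sigma(s), height, biasf."""
        cols: dict[str, list] = {"time": [h.deposit_time for h in self.hills]}
        for d, name in enumerate(self.cv_names):
            cols[name] = [h.center[d] for h in self.hills]
        for d, name in enumerate(self.cv_names):
            cols[f"sigma_{name}"] = [h.sigma[d] for h in self.hills]
        cols["height"] = [h.height for h in self.hills]
        cols["biasf"] = [self.gamma] * len(self.hills)
        return pd.DataFrame(cols)


def deposit_hill(
    bias: BiasPotential, cv_value: float | np.ndarray, time: float, thermo: ThermoParams
) -> BiasPotential:
    """Well-tempered hill deposition (mutates and returns ``bias``).

    The new hill's height is h0 * exp(-V(s)/(k_B ΔT)) with ΔT = (γ-1) T;
    for γ = inf the height stays h0 (standard metadynamics).
    """
    if not np.all(np.isfinite(np.atleast_1d(cv_value))):
        raise ValueError("non-finite CV value")
    bias.add_hill(cv_value, time, thermo)
    return bias


def bias_energy(bias: BiasPotential | None, cv_value) -> float:
    """V(s) of a bias; 0 for a neutral (None) bias."""
    return 0.0 if bias is None else bias.energy(cv_value)


def bias_gradient(bias: BiasPotential | None, cv_value) -> np.ndarray:
    """dV/ds of a bias; zeros for a neutral (None) bias."""
    if bias is None:
        return np.zeros(np.atleast_1d(np.asarray(cv_value)).shape)
    return bias.gradient(cv_value)


# ---------------------------------------------------------------------------
# Langevin dynamics on continuous models


def langevin_step(
    model,
    state: np.ndarray,
    thermo: ThermoParams,
    bias: BiasPotential | None = None,
    rng: np.random.Generator | None = None,
    bias_coords: tuple[int, ...] | None = None,
) -> np.ndarray:
    """One overdamped Euler-Maruyama step.

    ``bias_coords`` maps the bias's CV dimensions onto coordinate indices of
    the model (identity CVs); by default the first ``bias.dim`` coordinates.
    """
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    x = np.atleast_1d(np.asarray(state, dtype=float))
    force = -np.asarray(model.gradient(x), dtype=float)
    if bias is not None:
        idx = bias_coords if bias_coords is not None else tuple(range(bias.dim))
        force[list(idx)] -= bias.gradient(x[list(idx)])
    if not np.all(np.isfinite(force)):
        bad = int(np.nonzero(~np.isfinite(force))[0][0])
        raise FloatingPointError(f"non-finite force on coordinate {bad}")
    mu = 1.0 / thermo.friction
    dt = thermo.timestep
    noise = rng.standard_normal(x.shape)
    return x + mu * force * dt + math.sqrt(2.0 * thermo.kt * mu * dt) * noise


# ---------------------------------------------------------------------------
# Replica exchange


@dataclass
class Replica:
    """One member of a bias-exchange ensemble."""

    state: np.ndarray
    bias: BiasPotential | None  # None = neutral replica
    cv_name: str | None
    rng: np.random.Generator

    def cv_of(self, model, state: np.ndarray) -> float:
        if self.cv_name is None:
            raise ValueError("neutral replica has no bias CV")
        return _cv_value(model, self.cv_name, state)


def _cv_value(model, name: str, state: np.ndarray) -> float:
    if isinstance(model, HelixCoilModel):
        return model.cv_value(name, state)
    try:
        idx = COORD_CV_NAMES.index(name)
    except ValueError:
        raise ValueError(f"unknown CV {name!r} for a continuous model") from None
    return float(np.atleast_1d(state)[idx])


def _replica_bias_energy(model, replica: Replica, state: np.ndarray) -> float:
    if replica.bias is None:
        return 0.0
    return replica.bias.energy(replica.cv_of(model, state))


def attempt_exchange(
    replica_a: Replica,
    replica_b: Replica,
    model,
    thermo: ThermoParams,
    rng: np.random.Generator,
) -> bool:
    """Metropolis configuration swap between two replicas.

    Acceptance p = min(1, exp[(V_a(x_a) + V_b(x_b) - V_a(x_b) - V_b(x_a)) /
    k_B T]); a neutral replica contributes V = 0.  On acceptance the
    configurations swap while the biases stay with their replicas.
    """
    xa, xb = replica_a.state, replica_b.state
    delta = (
        _replica_bias_energy(model, replica_a, xa)
        + _replica_bias_energy(model, replica_b, xb)
        - _replica_bias_energy(model, replica_a, xb)
        - _replica_bias_energy(model, replica_b, xa)
    )
    accept = delta >= 0 or rng.random() < math.exp(delta / thermo.kt)
    if accept:
        replica_a.state, replica_b.state = xb.copy(), xa.copy()
    return bool(accept)


# ---------------------------------------------------------------------------
# Full bias-exchange runs


@dataclass
class SamplerSchedule:
    """Run length and event cadences (ps units follow the protocol defaults)."""

    n_steps: int = 200_000
    hill_interval_ps: float = 4.0
    exchange_interval_ps: float = 10.0
    output_stride: int = 100  # steps between COLVAR rows
    equilibration_fraction: float = 0.2  # consumed downstream, recorded here


@dataclass
class HillParams:
    """Hill shape defaults: standard magnitudes that converge on toy systems."""

    h0: float = 0.3  # kcal/mol
    sigma: float = 0.1  # in the CV's native units
    gamma: float = 10.0


@dataclass
class ReplicaResult:
    """Per-replica outputs of a bias-exchange run."""

    colvar: pd.DataFrame
    hills: pd.DataFrame
    cv_name: str | None
    swap_log: pd.DataFrame


def _intervals_to_steps(schedule: SamplerSchedule, thermo: ThermoParams) -> tuple[int, int]:
    hill_steps = int(round(schedule.hill_interval_ps / thermo.timestep))
    exch_steps = int(round(schedule.exchange_interval_ps / thermo.timestep))
    for label, steps, ps in (
        ("hill", hill_steps, schedule.hill_interval_ps),
        ("exchange", exch_steps, schedule.exchange_interval_ps),
    ):
        if steps < 1 or abs(steps * thermo.timestep - ps) > 1e-9:
            raise ValueError(f"{label} interval must be a positive multiple of the timestep")
    if exch_steps < hill_steps:
        logger.info("exchange interval shorter than hill interval (allowed)")
    return hill_steps, exch_steps


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflecting walls keep trajectories on the potential's stated domain
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        if x > hi:
            x = 2.0 * hi - x
    return x


def _run_continuous_segment(
    model, x: np.ndarray, thermo: ThermoParams, bias: BiasPotential | None,
    n_steps: int, rng: np.random.Generator,
) -> np.ndarray:
    """Advance a continuous replica ``n_steps``; fast scalar path in 1D."""
    mu = 1.0 / thermo.friction
    dt = thermo.timestep
    amp = math.sqrt(2.0 * thermo.kt * mu * dt)
    lo, hi = model.domain
    if model.dim == 1 and (bias is None or bias._grid is not None):
        xi = float(x[0])
        noises = rng.standard_normal(n_steps)
        if bias is not None:
            grid, dv = bias._grid, bias._grid_dv
            g0 = grid[0]
            inv_dx = (len(grid) - 1) / (grid[-1] - g0)
        grad1d = getattr(model, "grad1d", None)
        for i in range(n_steps):
            if grad1d is not None:
                f = -grad1d(xi)
            else:
                f = -float(model.gradient(np.array([xi]))[0])
            if bias is not None:
                p = (xi - g0) * inv_dx
                j = int(p)
                if j < 0:
                    j, p = 0, 0.0
                elif j >= len(grid) - 1:
                    j, p = len(grid) - 2, float(len(grid) - 1)
                w = p - j
                f -= dv[j] * (1.0 - w) + dv[j + 1] * w
            if f != f:  # NaN
                raise FloatingPointError("non-finite force on coordinate 0")
            xi = _reflect(xi + mu * f * dt + amp * noises[i], lo, hi)
        return np.array([xi])
    for _ in range(n_steps):
        x = langevin_step(model, x, thermo, bias, rng)
        for d in range(model.dim):
            x[d] = _reflect(x[d], lo, hi)
    return x


def _run_discrete_segment(
    model: HelixCoilModel, state: np.ndarray, kt_val: float,
    bias_table: np.ndarray | None, cv_name: str | None,
    n_steps: int, rng: np.random.Generator,
) -> np.ndarray:
    """Single-site Metropolis flips against model + bias energy."""
    n = model.n_sites
    s = state.copy()
    sites = rng.integers(0, n, size=n_steps)
    us = rng.random(n_steps)
    k = int(s.sum())
    matches = int(np.sum(s[:-1] == s[1:]))
    for i in range(n_steps):
        site = sites[i]
        old = s[site]
        new = 1 - old
        de = model.delta_e * (new - old)
        dm = 0
        if site > 0:
            dm += int(s[site - 1] == new) - int(s[site - 1] == old)
        if site < n - 1:
            dm += int(s[site + 1] == new) - int(s[site + 1] == old)
        de -= model.J * dm
        if bias_table is not None:
            if cv_name == "helix_fraction":
                de += bias_table[k + (new - old)] - bias_table[k]
            else:  # neighbor_alignment
                de += bias_table[matches + dm] - bias_table[matches]
        if de <= 0 or us[i] < math.exp(-de / kt_val):
            s[site] = new
            k += new - old
            matches += dm
    return s


def _discrete_cv_points(model: HelixCoilModel, cv_name: str) -> np.ndarray:
    if cv_name == "helix_fraction":
        return np.arange(model.n_sites + 1) / model.n_sites
    if cv_name == "neighbor_alignment":
        return np.arange(model.n_sites) / (model.n_sites - 1)
    raise ValueError(f"unknown CV {cv_name!r}")


def run_bemetad(
    model,
    replica_cvs: list[str | None],
    thermo: ThermoParams,
    schedule: SamplerSchedule,
    seed: int = 0,
    hill_params: HillParams | None = None,
    initial_states: list[np.ndarray] | None = None,
) -> list[ReplicaResult]:
    """Run a bias-exchange well-tempered metadynamics ensemble.

    ``replica_cvs`` assigns each replica its biased CV name (``None`` for the
    neutral replica).  Hills are deposited every ``hill_interval_ps``,
    neighbour swaps attempted every ``exchange_interval_ps`` (alternating
    even/odd pairs), and CV rows recorded every ``output_stride`` steps.  The
    entire output is a pure function of (model, configuration, seed).

    Each COLVAR record carries the model's CVs, the instantaneous bias
    ``bias_inst`` felt when the row was written, and ``bias``: the final
    ("last-bias") potential re-evaluated at the row's CV value, which is what
    last-bias reweighting consumes.  Returns one :class:`ReplicaResult` per
    replica.
    """
    if len(replica_cvs) < 1:
        raise ValueError("need at least one replica")
    if hill_params is None:
        hill_params = HillParams()
    hill_steps, exch_steps = _intervals_to_steps(schedule, thermo)
    discrete = isinstance(model, HelixCoilModel)

    seeds = np.random.SeedSequence(seed).spawn(len(replica_cvs) + 1)
    exchange_rng = np.random.default_rng(seeds[-1])

    replicas: list[Replica] = []
    bias_tables: list[np.ndarray | None] = []
    for r, cv in enumerate(replica_cvs):
        rng = np.random.default_rng(seeds[r])
        if initial_states is not None:
            state = np.asarray(initial_states[r]).copy()
        elif discrete:
            state = rng.integers(0, 2, size=model.n_sites).astype(np.int8)
        else:
            lo, hi = model.domain
            state = rng.uniform(lo, hi, size=model.dim)
        bias = None
        if cv is not None:
            bias = BiasPotential(
                cv, sigma=hill_params.sigma, h0=hill_params.h0,
                gamma=hill_params.gamma,
            )
            if discrete:
                bias.attach_grid(_discrete_cv_points(model, cv))
            elif model.dim == 1:
                lo, hi = model.domain
                bias.attach_grid(np.linspace(lo, hi, 2001))
        replicas.append(Replica(state=state, bias=bias, cv_name=cv, rng=rng))
        bias_tables.append(None if bias is None else bias._grid_v)

    cv_names = (
        list(model.CV_FUNCS) if discrete else list(COORD_CV_NAMES[: model.dim])
    )
    colvar_rows: list[list[list[float]]] = [[] for _ in replicas]
    pairs = [(i, i + 1) for i in range(len(replicas) - 1)]
    swap_counts = {p: [0, 0] for p in pairs}

    dt = thermo.timestep
    step = 0
    parity = 0
    while step < schedule.n_steps:
        next_event = min(
            ((step // hill_steps) + 1) * hill_steps,
            ((step // exch_steps) + 1) * exch_steps,
            ((step // schedule.output_stride) + 1) * schedule.output_stride,
            schedule.n_steps,
        )
        seg = next_event - step
        for r, rep in enumerate(replicas):
            if discrete:
                rep.state = _run_discrete_segment(
                    model, rep.state, thermo.kt, bias_tables[r], rep.cv_name,
                    seg, rep.rng,
                )
            else:
                rep.state = _run_continuous_segment(
                    model, rep.state, thermo, rep.bias, seg, rep.rng
                )
        step = next_event
        time = step * dt
        if step % schedule.output_stride == 0 or step == schedule.n_steps:
            for r, rep in enumerate(replicas):
                cvs = [_cv_value(model, name, rep.state) for name in cv_names]
                v_inst = (
                    0.0 if rep.bias is None
                    else rep.bias.energy(rep.cv_of(model, rep.state))
                )
                colvar_rows[r].append([time, *cvs, v_inst])
        if step % hill_steps == 0:
            for r, rep in enumerate(replicas):
                if rep.bias is not None:
                    s_val = rep.cv_of(model, rep.state)
                    rep.bias.add_hill(s_val, time, thermo)
                    bias_tables[r] = rep.bias._grid_v
        if step % exch_steps == 0 and pairs:
            for p in pairs[parity % 2 :: 2]:
                a, b = p
                accepted = attempt_exchange(
                    replicas[a], replicas[b], model, thermo, exchange_rng
                )
                swap_counts[p][0] += 1
                swap_counts[p][1] += int(accepted)
            parity += 1

    swap_log = pd.DataFrame(
        {
            "pair": [f"{a}-{b}" for a, b in pairs],
            "attempts": [swap_counts[p][0] for p in pairs],
            "accepted": [swap_counts[p][1] for p in pairs],
        }
    )
    results = []
    for r, rep in enumerate(replicas):
        df = pd.DataFrame(
            colvar_rows[r], columns=["time", *cv_names, "bias_inst"]
        )
        if rep.bias is not None:
            df["bias"] = rep.bias.energy_many(df[rep.cv_name].to_numpy())
            hills_df = rep.bias.to_hills_frame()
        else:
            df["bias"] = 0.0
            hills_df = pd.DataFrame(
                columns=["time", "height", "biasf"]
            )
        results.append(
            ReplicaResult(
                colvar=df, hills=hills_df, cv_name=rep.cv_name, swap_log=swap_log
            )
        )
    return results


def sample_langevin(
    model,
    thermo: ThermoParams,
    n_steps: int,
    seed: int = 0,
    bias: BiasPotential | None = None,
    stride: int = 100,
    initial_state: np.ndarray | None = None,
    burn_in: int = 0,
) -> np.ndarray:
    """Plain (optionally frozen-bias) Langevin sampling of a continuous model.

    No hills are deposited; an existing ``bias`` contributes its fixed
    potential, so the stationary density is Boltzmann(model + bias).  Returns
    the sampled states, one row every ``stride`` steps after ``burn_in``.
    """
    rng = np.random.default_rng(seed)
    if initial_state is None:
        lo, hi = model.domain
        x = rng.uniform(lo, hi, size=model.dim)
    else:
        x = np.asarray(initial_state, dtype=float).copy()
    if bias is not None and model.dim == 1 and bias._grid is None:
        lo, hi = model.domain
        bias.attach_grid(np.linspace(lo, hi, 2001))
    if burn_in > 0:
        x = _run_continuous_segment(model, x, thermo, bias, burn_in, rng)
    out = []
    done = 0
    while done < n_steps:
        seg = min(stride, n_steps - done)
        x = _run_continuous_segment(model, x, thermo, bias, seg, rng)
        out.append(x.copy())
        done += seg
    return np.array(out)


def run_wtmetad(
    model,
    cv_name: str,
    thermo: ThermoParams,
    schedule: SamplerSchedule,
    seed: int = 0,
    hill_params: HillParams | None = None,
    initial_state: np.ndarray | None = None,
) -> ReplicaResult:
    """Single-replica well-tempered metadynamics (no exchanges)."""
    init = None if initial_state is None else [initial_state]
    return run_bemetad(
        model, [cv_name], thermo, schedule, seed=seed,
        hill_params=hill_params, initial_states=init,
    )[0]
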