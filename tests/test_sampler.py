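"""Langevin/Metropolis propagation, hill deposition, and replica exchange."""

import math

import numpy as np
import pytest

from unwindfes.constants import K_B
from unwindfes.helix_coil import HelixCoilModel
from unwindfes.potentials import DoubleWell1D, FlatPotential1D, HarmonicWell
from unwindfes.sampler import (
    BiasPotential,
    Replica,
    SamplerSchedule,
    ThermoParams,
    attempt_exchange,
    bias_energy,
    bias_gradient,
    deposit_hill,
    langevin_step,
    run_bemetad,
    run_wtmetad,
    sample_langevin,
)


THERMO = ThermoParams()


class TestLangevinStep:
    def test_cold_harmonic_decays_monotonically(self):
        model = HarmonicWell(k=2.0)
        thermo = ThermoParams(temperature=1e-9)
        rng = np.random.default_rng(0)
        x = np.array([3.0])
        values = [x[0]]
        for _ in range(2000):
            x = langevin_step(model, x, thermo, rng=rng)
            values.append(x[0])
        assert np.all(np.diff(values) < 0)
        assert abs(values[-1]) < 0.05

    def test_equipartition_variance(self):
        model = HarmonicWell(k=2.0)
        samples = sample_langevin(
            model, THERMO, n_steps=1_000_000, seed=4, stride=100,
            burn_in=10_000, initial_state=np.array([0.0]),
        )
        expected = model.equilibrium_variance(310.0)
        assert np.var(samples[:, 0]) == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self):
        model = DoubleWell1D()
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            x = np.array([0.5])
            for _ in range(100):
                x = langevin_step(model, x, THERMO, rng=rng)
            runs.append(x[0])
        assert runs[0] == runs[1]

    def test_nonfinite_force_names_coordinate(self):
        class Broken:
            dim = 1
            domain = (-1.0, 1.0)

            def gradient(self, x):
                return np.array([np.nan])

        with pytest.raises(FloatingPointError, match="coordinate 0"):
            langevin_step(Broken(), np.array([0.0]), THERMO,
                          rng=np.random.default_rng(0))


class TestHillDeposition:
    def test_first_hill_has_initial_height(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        deposit_hill(bias, 0.5, 4.0, THERMO)
        assert bias.hills[0].height == pytest.approx(0.3)

    def test_second_hill_well_tempered_decay(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        deposit_hill(bias, 0.5, 4.0, THERMO)
        deposit_hill(bias, 0.5, 8.0, THERMO)
        delta_t = 9.0 * 310.0
        expected = 0.3 * math.exp(-0.3 / (K_B * delta_t))
        assert bias.hills[1].height == pytest.approx(expected, rel=1e-12)

    def test_standard_metad_heights_constant(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=math.inf)
        for i in range(100):
            deposit_hill(bias, 0.0, 4.0 * i, THERMO)
        assert bias.energy(0.0) == pytest.approx(100 * 0.3, rel=1e-12)

    def test_heights_non_increasing_at_revisited_point(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=5.0)
        for i in range(50):
            deposit_hill(bias, 0.2, 4.0 * i, THERMO)
        heights = [h.height for h in bias.hills]
        assert np.all(np.diff(heights) < 0)
        # repeated deposition at one point grows at most logarithmically
        delta_t = (5.0 - 1.0) * 310.0
        bound = 0.3 + K_B * delta_t * math.log(
            1.0 + 50 * 0.3 / (K_B * delta_t)
        )
        assert bias.energy(0.2) < bound + 0.3

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            BiasPotential("x", gamma=1.0)


class TestBiasEvaluation:
    def test_lone_hill_center(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        deposit_hill(bias, 1.0, 0.0, THERMO)
        assert bias_energy(bias, 1.0) == pytest.approx(bias.hills[0].height)
        assert bias_gradient(bias, 1.0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_far_field_vanishes(self):
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        deposit_hill(bias, 0.0, 0.0, THERMO)
        assert bias_energy(bias, 1.0) < 1e-10 * 0.3  # 10 sigma away

    def test_gradient_matches_finite_differences(self, rng):
        bias = BiasPotential("x", sigma=0.15, h0=0.25, gamma=8.0)
        for _ in range(20):
            deposit_hill(bias, rng.uniform(-1, 1), 0.0, THERMO)
        eps = 1e-6
        for x in rng.uniform(-1, 1, size=10):
            fd = (bias.energy(x + eps) - bias.energy(x - eps)) / (2 * eps)
            grad = bias.gradient(x)[0]
            assert grad == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_neutral_bias_is_zero(self):
        assert bias_energy(None, 0.3) == 0.0
        assert bias_gradient(None, 0.3)[0] == 0.0


def _replica(state, bias, cv="x", seed=0):
    return Replica(
        state=np.atleast_1d(np.asarray(state, dtype=float)),
        bias=bias,
        cv_name=None if bias is None else cv,
        rng=np.random.default_rng(seed),
    )


class TestExchange:
    def test_identical_biases_always_accept(self, rng):
        model = HarmonicWell()
        for _ in range(20):
            bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
            deposit_hill(bias, 0.4, 0.0, THERMO)
            a = _replica(rng.normal(), bias)
            b = _replica(rng.normal(), bias)
            assert attempt_exchange(a, b, model, THERMO, rng)

    def test_neutral_swap_same_state_accepts(self, rng):
        model = HarmonicWell()
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        deposit_hill(bias, 0.0, 0.0, THERMO)
        a = _replica(0.7, bias)
        b = _replica(0.7, None)
        assert attempt_exchange(a, b, model, THERMO, rng)

    def test_unfavorable_swap_accepts_at_boltzmann_rate(self):
        # Δ = -2 k_BT by construction: acceptance ≈ e^-2 over many attempts
        model = HarmonicWell()
        kbt = THERMO.kt
        rng = np.random.default_rng(99)
        accepted = 0
        n = 10_000
        bias = BiasPotential("x", sigma=0.1, h0=2.0 * kbt, gamma=math.inf)
        deposit_hill(bias, 0.0, 0.0, THERMO)  # V_b peaks at x = 0
        for _ in range(n):
            a = _replica(0.0, None)  # x_a sits on replica b's hill
            b = _replica(10.0, bias)  # V_b(x_b) = 0 ten sigma away
            accepted += attempt_exchange(a, b, model, THERMO, rng)
        p = math.exp(-2.0)
        sigma = math.sqrt(p * (1 - p) / n)
        assert accepted / n == pytest.approx(p, abs=3 * sigma)

    def test_swap_moves_configurations_not_biases(self):
        model = HarmonicWell()
        bias = BiasPotential("x", sigma=0.1, h0=0.3, gamma=10.0)
        a = _replica(1.0, bias)
        b = _replica(-1.0, None)
        rng = np.random.default_rng(0)
        assert attempt_exchange(a, b, model, THERMO, rng)
        assert a.state[0] == -1.0 and b.state[0] == 1.0
        assert a.bias is bias and b.bias is None


class TestBEMetaDProtocol:
    SCHED = SamplerSchedule(n_steps=20_000, output_stride=200)

    def test_single_replica_reduces_to_wtmetad(self):
        model = DoubleWell1D()
        a = run_bemetad(model, ["x"], THERMO, self.SCHED, seed=5)[0]
        b = run_wtmetad(model, "x", THERMO, self.SCHED, seed=5)
        assert a.colvar.equals(b.colvar)
        assert a.hills.equals(b.hills)

    def test_ensemble_seed_determinism(self):
        model = HelixCoilModel(12, -0.5, 0.5)
        first = run_bemetad(
            model, [None, "helix_fraction"], THERMO, self.SCHED, seed=21
        )
        second = run_bemetad(
            model, [None, "helix_fraction"], THERMO, self.SCHED, seed=21
        )
        for a, b in zip(first, second):
            assert a.colvar.equals(b.colvar)
            assert a.swap_log.equals(b.swap_log)

    def test_neutral_flat_model_histogram_uniform(self):
        model = FlatPotential1D()
        sched = SamplerSchedule(n_steps=200_000, output_stride=20)
        res = run_bemetad(model, [None], THERMO, sched, seed=8)[0]
        x = res.colvar["x"].to_numpy()
        counts, _ = np.histogram(x, bins=5, range=(0.0, 1.0))
        n = counts.sum()
        expected = n / 5
        sigma = math.sqrt(n * 0.2 * 0.8)
        # diffusive samples are correlated; allow 3 sigma on top of an
        # autocorrelation inflation factor estimated from the stride
        assert np.all(np.abs(counts - expected) < 6 * sigma)

    def test_zero_replicas_rejected(self):
        with pytest.raises(ValueError, match="at least one replica"):
            run_bemetad(HarmonicWell(), [], THERMO, self.SCHED, seed=0)

    def test_exchange_log_counts_attempts(self):
        model = HelixCoilModel(12, 0.0, 0.0)
        res = run_bemetad(
            model, [None, "helix_fraction", "neighbor_alignment"],
            THERMO, self.SCHED, seed=3,
        )
        log = res[0].swap_log
        assert list(log["pair"]) == ["0-1", "1-2"]
        # 4 exchange epochs at 10 ps over 40 ps, alternating even/odd pairs
        assert log["attempts"].sum() == 4
        assert (log["accepted"] <= log["attempts"]).all()

    def test_colvar_carries_last_bias_column(self):
        model = DoubleWell1D()
        res = run_wtmetad(model, "x", THERMO, self.SCHED, seed=2)
        v_end = res.colvar["bias"].to_numpy()
        recomputed = np.zeros_like(v_end)
        x = res.colvar["x"].to_numpy()
        for _, row in res.hills.iterrows():
            recomputed += row["height"] * np.exp(
                -0.5 * ((x - row["x"]) / row["sigma_x"]) ** 2
            )
        np.testing.assert_allclose(v_end, recomputed, rtol=1e-10)
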