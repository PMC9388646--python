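"""Collective variables: switching identities, scores, contacts, coordination.

Each CV is checked against an independent direct-loop oracle that re-derives
the defining sums from scratch (its only shared dependency is the brute-force
superposition oracle from test_geometry).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unwindfes.cvs import (
    CoordinationSpec,
    NativeContactSpec,
    SegmentLibrary,
    alpha_rmsd,
    antibeta_rmsd,
    coordination_number,
    extract_contact_pairs,
    native_contacts,
    rational_switch,
    residual_helicity,
    ss_switch,
)
from unwindfes.frames import Frame
from unwindfes.geometry import (
    build_extended_chain,
    build_ideal_antiparallel_sheet,
    build_ideal_helix,
    random_rigid_transform,
)

from test_geometry import brute_force_min_rmsd


# ---------------------------------------------------------------------------
# Independent loop-over-definitions oracles


def oracle_ss_switch(rmsd_nm: float) -> float:
    x = rmsd_nm / 0.1
    if abs(x - 1.0) < 1e-12:
        return 2.0 / 3.0
    return (1.0 - x**8) / (1.0 - x**12)


def oracle_alpha_score(frame, window, library, chain="A"):
    lo, hi = window
    total = 0.0
    for start in range(lo, hi - 4):  # all 6-residue blocks, inclusive range
        xyz = []
        for r in range(start, start + 6):
            for a in ("N", "CA", "C", "O"):
                xyz.append(frame.coords[frame.atom_index(chain, r, a)])
        r_nm = brute_force_min_rmsd(
            np.array(xyz), library.reference_coordinates
        ) / 10.0
        total += oracle_ss_switch(r_nm)
    return total


def oracle_native_contacts(frame, spec):
    total = 0.0
    for (i, j), r0 in zip(spec.pairs, spec.r0_nm):
        r = np.linalg.norm(frame.coords[i] - frame.coords[j]) / 10.0
        total += 1.0 / (1.0 + np.exp(spec.beta_per_nm * (r - spec.lam * r0)))
    return total / spec.n_pairs


def oracle_coordination(frame, spec):
    total = 0.0
    for i in spec.group_a:
        for j in spec.group_b:
            y = np.linalg.norm(frame.coords[i] - frame.coords[j]) / spec.r0_angstrom
            if abs(y - 1.0) < 1e-12:
                total += spec.n_exp / spec.m_exp
            else:
                total += (1.0 - y**spec.n_exp) / (1.0 - y**spec.m_exp)
    return total


# ---------------------------------------------------------------------------


class TestSwitchingFunction:
    def test_identities(self):
        assert ss_switch(0.0) == pytest.approx(1.0, abs=1e-12)
        assert ss_switch(0.1) == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert ss_switch(0.2) == pytest.approx(255.0 / 4095.0, abs=1e-12)

    def test_continuous_strictly_decreasing_to_zero(self):
        xs = np.concatenate(
            [np.linspace(0.0, 0.5, 2001), [0.1 - 1e-9, 0.1, 0.1 + 1e-9]]
        )
        xs = np.unique(xs)  # the grid hits 0.1 exactly; drop the duplicate
        ys = ss_switch(xs)
        assert np.all(np.diff(ys) <= 0)
        # strictly decreasing wherever the decrement is representable
        strict = xs >= 0.02
        assert np.all(np.diff(ys[strict]) < 0)
        assert np.all(np.abs(np.diff(ys)) < 1e-2)  # no jump at the singularity
        assert ss_switch(5.0) < 1e-4

    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(0.0, 1.0))
    def test_matches_printed_form(self, x):
        assert ss_switch(x) == pytest.approx(oracle_ss_switch(x), abs=1e-10)

    def test_rational_switch_limit_and_values(self):
        assert rational_switch(np.array([4.5]), 4.5, 6, 12)[0] == pytest.approx(
            0.5, abs=1e-12
        )
        assert rational_switch(np.array([2.25]), 4.5, 6, 12)[0] == pytest.approx(
            4032.0 / 4095.0, abs=1e-12
        )
        # general (n, m) path with its removable singularity
        assert rational_switch(np.array([1.0]), 1.0, 4, 10)[0] == pytest.approx(
            0.4, abs=1e-10
        )


class TestAlphaRMSD:
    def test_ideal_helix_scores_seven(self, ideal_helix_12, alpha_library):
        score = alpha_rmsd(ideal_helix_12, (1, 12), alpha_library)
        assert score.S == pytest.approx(7.0, abs=1e-9)
        assert all(r < 1e-6 for _, r, _ in score.per_block)

    def test_extended_chain_scores_near_zero(self, extended_12, alpha_library):
        score = alpha_rmsd(extended_12, (1, 12), alpha_library)
        assert score.S < 0.05
        assert all(r > 0.1 for _, r, _ in score.per_block)

    def test_score_bounded_by_block_count(self, ideal_helix_12, alpha_library):
        score = alpha_rmsd(ideal_helix_12, (1, 12), alpha_library)
        assert 0.0 <= score.S <= len(score.per_block)
        assert all(0.0 <= n <= 1.0 for _, _, n in score.per_block)

    def test_matches_direct_loop_oracle(self, alpha_library):
        # half helix / half extended: a nontrivial mixed case
        frame = _half_helix_frame()
        ours = alpha_rmsd(frame, (1, 12), alpha_library).S
        oracle = oracle_alpha_score(frame, (1, 12), alpha_library)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_missing_atom_reported(self, ideal_helix_12, alpha_library):
        keep = [i for i, a in enumerate(ideal_helix_12.atom_names)
                if not (a == "O" and ideal_helix_12.residue_indices[i] == 3)]
        frame = Frame(
            ideal_helix_12.coords[keep],
            [ideal_helix_12.atom_names[i] for i in keep],
            ideal_helix_12.residue_indices[keep],
            [ideal_helix_12.residue_names[i] for i in keep],
            [ideal_helix_12.chain_ids[i] for i in keep],
        )
        with pytest.raises(KeyError, match="'O' in residue 3"):
            alpha_rmsd(frame, (1, 12), alpha_library)

    def test_window_too_short_raises(self, ideal_helix_12, alpha_library):
        with pytest.raises(ValueError, match="shorter"):
            alpha_rmsd(ideal_helix_12, (1, 5), alpha_library)


def _half_helix_frame():
    from unwindfes.helix_coil import embed_chain_state

    return embed_chain_state("HHHHHHCCCCCC")


class TestResidualHelicity:
    def test_ideal_helix_is_one(self, ideal_helix_12):
        res = residual_helicity(ideal_helix_12, (1, 12))
        assert res.f_H == pytest.approx(1.0, abs=1e-9)
        assert res.S_Max == 7.0

    def test_extended_chain_near_zero(self, extended_12):
        assert residual_helicity(extended_12, (1, 12)).f_H < 0.01

    def test_equals_per_window_oracle(self, alpha_library):
        frame = _half_helix_frame()
        res = residual_helicity(frame, (1, 12), alpha_library)
        oracle = oracle_alpha_score(frame, (1, 12), alpha_library) / 7.0
        assert res.f_H == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_bounded_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        frame = _half_helix_frame()
        rot, trans = random_rigid_transform(rng)
        moved = frame.transformed(rot, trans)
        f0 = residual_helicity(frame, (1, 12)).f_H
        f1 = residual_helicity(moved, (1, 12)).f_H
        assert 0.0 <= f0 <= 1.0
        assert f1 == pytest.approx(f0, abs=1e-9)


def _sheet_frame(separation=None):
    s1, s2 = build_ideal_antiparallel_sheet()
    if separation is not None:
        s2 = s2 + np.array([0.0, 0.0, separation])
    coords = np.vstack([s1, s2])
    names, resi, chains = [], [], []
    for chain in ("A", "B"):
        for r in range(1, 4):
            for a in ("N", "CA", "C", "O"):
                names.append(a)
                resi.append(r)
                chains.append(chain)
    return Frame(coords, names, np.array(resi), ["ALA"] * 24, chains)


class TestAntiBetaRMSD:
    def test_ideal_pair_scores_at_least_one(self, antibeta_library):
        frame = _sheet_frame()
        score = antibeta_rmsd(frame, [("A", 1, 3), ("B", 1, 3)], antibeta_library)
        assert score.S >= 1.0
        assert max(n for _, _, n in score.per_block) == pytest.approx(1.0, abs=1e-9)

    def test_separated_strands_score_near_zero(self, antibeta_library):
        frame = _sheet_frame(separation=30.0)
        score = antibeta_rmsd(frame, [("A", 1, 3), ("B", 1, 3)], antibeta_library)
        assert score.S < 0.01
        assert all(r > 0.1 for _, r, _ in score.per_block)

    def test_single_segment_raises(self, antibeta_library):
        with pytest.raises(ValueError, match="two segments"):
            antibeta_rmsd(_sheet_frame(), [("A", 1, 3)], antibeta_library)

    def test_overlapping_segments_raise(self, antibeta_library):
        helix = build_ideal_helix(8)
        with pytest.raises(ValueError, match="overlap"):
            antibeta_rmsd(helix, [("A", 1, 4), ("A", 3, 6)], antibeta_library)


class TestNativeContacts:
    def test_pair_selection_cutoff(self):
        frame = _pair_frame([4.0, 4.6, 4.5])
        spec = extract_contact_pairs(
            frame, np.array([0, 2, 4]), np.array([1, 3, 5])
        )
        # strictly-smaller-than rule: 4.0 in, 4.6 and exactly 4.5 out
        assert spec.pairs == [(0, 1)]
        assert spec.r0_nm[0] == pytest.approx(0.40, abs=1e-12)

    def test_empty_selection_raises(self, ideal_helix_12):
        with pytest.raises(ValueError, match="empty"):
            extract_contact_pairs(ideal_helix_12, np.array([]), np.array([0]))

    def test_reference_frame_scores_near_one(self):
        frame = _pair_frame([4.5])
        spec = NativeContactSpec(pairs=[(0, 1)], r0_nm=np.array([0.45]))
        expected = 1.0 / (1.0 + np.exp(-11.25))  # beta * (r0 - 1.5 r0) = -11.25
        assert native_contacts(frame, spec) == pytest.approx(expected, abs=1e-12)

    def test_logistic_midpoint(self, rng):
        r0 = rng.uniform(0.2, 0.44, size=6)
        frame = _pair_frame(15.0 * r0)  # r = 1.5 r0 (in Å)
        spec = NativeContactSpec(
            pairs=[(2 * i, 2 * i + 1) for i in range(6)], r0_nm=r0
        )
        assert native_contacts(frame, spec) == pytest.approx(0.5, abs=1e-9)

    def test_broken_contacts(self):
        r0 = 0.40
        frame = _pair_frame([10 * (1.5 * r0 + 0.2)])
        spec = NativeContactSpec(pairs=[(0, 1)], r0_nm=np.array([r0]))
        assert native_contacts(frame, spec) == pytest.approx(
            1.0 / (1.0 + np.exp(10.0)), rel=1e-9
        )

    def test_no_pairs_raises(self):
        spec = NativeContactSpec(pairs=[], r0_nm=np.array([]))
        with pytest.raises(ValueError, match="no pairs"):
            native_contacts(_pair_frame([4.0]), spec)

    def test_matches_direct_loop_oracle(self, rng):
        n = 5
        dists = rng.uniform(3.0, 8.0, size=n)
        frame = _pair_frame(dists)
        spec = NativeContactSpec(
            pairs=[(2 * i, 2 * i + 1) for i in range(n)],
            r0_nm=rng.uniform(0.25, 0.44, size=n),
        )
        assert native_contacts(frame, spec) == pytest.approx(
            oracle_native_contacts(frame, spec), abs=1e-10
        )


def _pair_frame(distances, spacing=40.0):
    """Frame of isolated atom pairs at the given distances (Å), well separated."""
    coords, names, resi, chains = [], [], [], []
    for k, d in enumerate(distances):
        base = np.array([0.0, 0.0, spacing * k])
        coords += [base, base + np.array([d, 0.0, 0.0])]
        names += ["C1", "C2"]
        resi += [k + 1, k + 1]
        chains += ["A", "A"]
    return Frame(np.array(coords), names, np.array(resi), ["LIG"] * len(names), chains)


class TestCoordinationNumber:
    def test_far_pairs_vanish(self):
        frame = _pair_frame([50.0])
        spec = CoordinationSpec(group_a=[0], group_b=[1])
        assert coordination_number(frame, spec) < 1e-6

    def test_contact_limit_and_close_pair(self):
        frame = _pair_frame([4.5])
        spec = CoordinationSpec(group_a=[0], group_b=[1])
        assert coordination_number(frame, spec) == pytest.approx(0.5, abs=1e-10)
        frame = _pair_frame([2.25])
        assert coordination_number(frame, spec) == pytest.approx(
            4032.0 / 4095.0, abs=1e-10
        )

    def test_overlapping_groups_raise(self):
        with pytest.raises(ValueError, match="disjoint"):
            CoordinationSpec(group_a=[0, 1], group_b=[1, 2])

    def test_monotone_in_distance(self):
        ds = np.linspace(1.0, 12.0, 40)
        vals = [
            coordination_number(
                _pair_frame([d]), CoordinationSpec(group_a=[0], group_b=[1])
            )
            for d in ds
        ]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_additive_over_disjoint_pair_sets(self, rng):
        dists = rng.uniform(2.0, 8.0, size=4)
        frame = _pair_frame(dists, spacing=500.0)
        whole = coordination_number(
            frame, CoordinationSpec(group_a=[0, 2, 4, 6], group_b=[1, 3, 5, 7])
        )
        # the 500 Å spacing between pair groups makes cross terms ~1e-12
        parts = sum(
            coordination_number(
                frame, CoordinationSpec(group_a=[2 * i], group_b=[2 * i + 1])
            )
            for i in range(4)
        )
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_matches_direct_loop_oracle(self, rng):
        coords = rng.uniform(0, 10, size=(8, 3))
        frame = Frame(
            coords, [f"C{i}" for i in range(8)], np.arange(1, 9),
            ["LIG"] * 8, ["A"] * 8,
        )
        spec = CoordinationSpec(group_a=[0, 1, 2], group_b=[4, 5, 6, 7])
        assert coordination_number(frame, spec) == pytest.approx(
            oracle_coordination(frame, spec), abs=1e-10
        )

    def test_rigid_invariance_q_and_cn(self, rng):
        frame = _pair_frame(rng.uniform(3.0, 6.0, size=3))
        rot, trans = random_rigid_transform(rng)
        moved = frame.transformed(rot, trans)
        spec_cn = CoordinationSpec(group_a=[0, 2], group_b=[1, 3])
        assert coordination_number(moved, spec_cn) == pytest.approx(
            coordination_number(frame, spec_cn), abs=1e-9
        )
        spec_q = NativeContactSpec(
            pairs=[(0, 1), (2, 3)], r0_nm=np.array([0.4, 0.35])
        )
        assert native_contacts(moved, spec_q) == pytest.approx(
            native_contacts(frame, spec_q), abs=1e-9
        )
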