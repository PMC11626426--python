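"""Geometric descriptors against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from confdesc.geometry import (
    BONDI_RADII,
    RadiiTable,
    buried_volume,
    point_charge_dipole,
    pyramidalization,
    sasa_and_volume,
    sterimol,
)
from tests.conftest import random_rigid_motion

UNIT_RADII = RadiiTable({"C": 1.70, "H": 1.20, "X": 1.00}, scale=1.0)


def brute_force_b1(q2d, radii, step_deg=0.1):
    """0.1-degree direction scan oracle for the minimum perpendicular extent."""
    thetas = np.radians(np.arange(0.0, 360.0, step_deg))
    v = np.column_stack([np.cos(thetas), np.sin(thetas)])
    vals = (q2d @ v.T) + radii[:, None]
    return vals.max(axis=0).min()


class TestRadii:
    def test_unknown_element_is_an_error(self):
        with pytest.raises(KeyError, match="Uuo"):
            RadiiTable()["Uuo"]

    def test_scale_applies(self):
        assert RadiiTable(scale=1.17)["C"] == pytest.approx(1.17 * BONDI_RADII["C"])

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            RadiiTable({"C": -1.0})


class TestSterimol:
    def test_single_on_axis_hydrogen(self):
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        st = sterimol(coords, ["C", "H"], 0, 1, radii=UNIT_RADII, substituent=[1])
        assert st.L == pytest.approx(2.30)
        assert st.B1 == pytest.approx(1.20)
        assert st.B5 == pytest.approx(1.20)

    def test_two_atom_worked_example(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.4, 0]])
        st = sterimol(coords, ["C", "C", "H"], 0, 1, radii=UNIT_RADII,
                      substituent=[1, 2])
        assert st.B5 == pytest.approx(2.60)
        assert st.B1 == pytest.approx(1.70)

    def test_substituent_derived_from_bonds(self):
        # ethane C0-C1, H on each carbon; substituent of C1 excludes C0's H
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [-0.6, 0.9, 0], [2.1, 0.9, 0.0]])
        bonds = [(0, 1), (0, 2), (1, 3)]
        st = sterimol(coords, ["C", "C", "H", "H"], 0, 1, radii=UNIT_RADII,
                      bonds=bonds)
        st_explicit = sterimol(coords, ["C", "C", "H", "H"], 0, 1, radii=UNIT_RADII,
                               substituent=[1, 3])
        assert st == st_explicit

    def test_degenerate_inputs_raise(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            sterimol(coords, ["C", "C"], 0, 0, radii=UNIT_RADII, substituent=[1])
        with pytest.raises(ValueError):
            sterimol(coords, ["C", "C"], 0, 1, radii=UNIT_RADII, substituent=[])

    def test_b1_matches_brute_force_scan_on_random_substituents(self, rng):
        """Analytic candidate enumeration vs 0.1-degree scan, 100 toys."""
        for _ in range(100):
            n = rng.integers(1, 8)
            # perpendicular offsets within 1 A keep the scan oracle's own
            # kink error (<= |q| * 0.05 deg in radians) below the tolerance
            q2d = rng.normal(scale=0.45, size=(n, 2))
            q2d = q2d / np.maximum(1.0, np.linalg.norm(q2d, axis=1))[:, None]
            radii = rng.uniform(0.8, 2.2, size=n)
            coords = np.zeros((n + 2, 3))
            coords[1] = [1.0, 0, 0]
            coords[2:, 0] = 1.0 + rng.uniform(0.2, 2.0, size=n)
            coords[2:, 1] = q2d[:, 0]
            coords[2:, 2] = q2d[:, 1]
            table = RadiiTable({f"E{i}": r for i, r in enumerate(radii)} | {"C": 1.7})
            st = sterimol(coords, ["C", "C"] + [f"E{i}" for i in range(n)],
                          0, 1, radii=table, substituent=list(range(1, n + 2)))
            # oracle on the same perpendicular projections (first atom on-axis)
            full_q = np.vstack([[0.0, 0.0], q2d])
            full_r = np.concatenate([[1.7], radii])
            ref = brute_force_b1(full_q, full_r)
            assert st.B1 == pytest.approx(ref, abs=1e-3)

    def test_rigid_motion_invariance(self, rng):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.4, 0], [2.5, -1.0, 0.8]])
        args = (["C", "C", "H", "X"], 0, 1)
        st0 = sterimol(coords, *args, radii=UNIT_RADII, substituent=[1, 2, 3])
        for _ in range(5):
            R, t = random_rigid_motion(rng)
            st = sterimol(coords @ R.T + t, *args, radii=UNIT_RADII,
                          substituent=[1, 2, 3])
            assert st.L == pytest.approx(st0.L, abs=1e-9)
            assert st.B1 == pytest.approx(st0.B1, abs=1e-9)
            assert st.B5 == pytest.approx(st0.B5, abs=1e-9)

    def test_verloop_correction_is_optional(self):
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        st = sterimol(coords, ["C", "H"], 0, 1, radii=UNIT_RADII, substituent=[1],
                      l_correction=0.40)
        assert st.L == pytest.approx(2.70)


def mc_buried_volume(coords, radii_list, center_idx, sphere_r, n_samples, seed):
    """Monte-Carlo oracle: uniform samples in the probe sphere."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_samples, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= sphere_r * rng.uniform(size=n_samples)[:, None] ** (1 / 3)
    pts += coords[center_idx]
    inside = np.zeros(n_samples, dtype=bool)
    for i, (pos, r) in enumerate(zip(coords, radii_list)):
        if i == center_idx:
            continue
        inside |= ((pts - pos) ** 2).sum(1) <= r * r
    return 100.0 * inside.mean()


class TestBuriedVolume:
    def test_isolated_atom_is_unburied(self):
        assert buried_volume(np.zeros((1, 3)), ["C"], 0) == 0.0

    def test_fully_contained_neighbor_closed_form(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        table = RadiiTable({"C": 1.7, "X": 1.0}, scale=1.0)
        got = buried_volume(coords, ["C", "X"], 0, sphere_r=3.5, radii=table,
                            grid=0.05)
        assert got == pytest.approx(100 * 1.0**3 / 3.5**3, abs=0.05)

    def test_distant_neighbor_contributes_nothing(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        table = RadiiTable({"C": 1.7, "X": 1.0}, scale=1.0)
        assert buried_volume(coords, ["C", "X"], 0, radii=table, grid=0.1) == 0.0

    def test_agrees_with_monte_carlo_on_random_configurations(self, rng):
        """Grid vs 1e6-sample MC within 0.5 percentage points (10 configs here;
        the full 50-config sweep runs in the acceptance suite)."""
        table = RadiiTable(scale=1.17)
        symbols = ["C", "N", "O", "H", "C"]
        radii_list = [table[s] for s in symbols]
        for k in range(10):
            coords = rng.normal(scale=1.8, size=(5, 3))
            got = buried_volume(coords, symbols, 0, sphere_r=3.5, radii=table,
                                grid=0.05)
            ref = mc_buried_volume(coords, radii_list, 0, 3.5, 10**6,
                                   seed=1000 + k)
            assert got == pytest.approx(ref, abs=0.5)

    def test_grid_convergence(self, rng):
        coords = rng.normal(scale=1.5, size=(4, 3))
        a = buried_volume(coords, ["C"] * 4, 0, grid=0.1)
        b = buried_volume(coords, ["C"] * 4, 0, grid=0.05)
        assert abs(a - b) < 0.2

    def test_bad_sphere_radius(self):
        with pytest.raises(ValueError):
            buried_volume(np.zeros((1, 3)), ["C"], 0, sphere_r=0.0)


class TestPyramidalization:
    def test_planar_nitrogen_is_zero(self):
        c = np.array([[0.0, 0, 0], [1, 0, 0], [-0.5, 0.866, 0], [-0.5, -0.866, 0]])
        assert pyramidalization(c, 0, [1, 2, 3]) == pytest.approx(0.0, abs=1e-9)

    def test_ideal_tetrahedral_angles(self):
        """Closed form: 360 - 3*arccos(-1/3) in degrees = 31.586."""
        t = np.array([
            [0.0, 0, 0], [1, 1, 1], [1, -1, -1], [-1, 1, -1],
        ]) / np.sqrt(3)
        got = pyramidalization(t, 0, [1, 2, 3])
        expected = 360.0 - 3 * math.degrees(math.acos(-1 / 3))
        assert got == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(31.586, abs=1e-3)

    def test_neighbor_order_irrelevant(self, rng):
        c = rng.normal(size=(4, 3))
        a = pyramidalization(c, 0, [1, 2, 3])
        b = pyramidalization(c, 0, [3, 1, 2])
        assert a == pytest.approx(b, abs=1e-12)

    def test_wrong_neighbor_count(self):
        with pytest.raises(ValueError):
            pyramidalization(np.zeros((3, 3)), 0, [1, 2])


class TestSasaVolume:
    def test_isolated_atom_closed_forms(self):
        sasa, vol = sasa_and_volume(np.zeros((1, 3)), ["C"])
        r = 1.70 + 1.4
        assert sasa == pytest.approx(4 * math.pi * r**2, rel=0.01)
        assert vol == pytest.approx(4 / 3 * math.pi * r**3, rel=0.005)

    def test_disjoint_atoms_are_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        sasa2, vol2 = sasa_and_volume(coords, ["C", "C"])
        sasa1, vol1 = sasa_and_volume(np.zeros((1, 3)), ["C"])
        assert sasa2 == pytest.approx(2 * sasa1, rel=1e-6)
        assert vol2 == pytest.approx(2 * vol1, rel=0.01)

    def test_buried_atom_has_no_sasa(self):
        # central atom enclosed by a much larger sphere
        table = RadiiTable({"C": 1.0, "Q": 9.0})
        sasa_pair, _ = sasa_and_volume(np.array([[0.0, 0, 0], [0.5, 0, 0]]),
                                       ["C", "Q"], radii=table)
        sasa_big, _ = sasa_and_volume(np.array([[0.5, 0, 0]]), ["Q"], radii=table)
        assert sasa_pair == pytest.approx(sasa_big, rel=1e-9)

    def test_negative_probe_rejected(self):
        with pytest.raises(ValueError):
            sasa_and_volume(np.zeros((1, 3)), ["C"], probe=-0.1)


class TestDipole:
    def test_two_point_charges(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert point_charge_dipole(coords, [-0.5, 0.5]) == pytest.approx(2.4016)

    def test_zero_charges(self):
        assert point_charge_dipole(np.ones((3, 3)), [0, 0, 0]) == 0.0

    def test_translation_invariance_when_neutral(self, rng):
        coords = rng.normal(size=(4, 3))
        q = np.array([0.3, -0.1, -0.4, 0.2])
        a = point_charge_dipole(coords, q)
        b = point_charge_dipole(coords + 7.3, q)
        assert a == pytest.approx(b, abs=1e-9)

    def test_net_charge_warns(self):
        with pytest.warns(UserWarning):
            point_charge_dipole(np.zeros((2, 3)), [1.0, 0.0])


class TestRigidMotionInvariance:
    def test_all_descriptors_invariant(self, rng):
        """20 random rotations+translations leave every descriptor unchanged."""
        coords = rng.normal(scale=1.5, size=(5, 3))
        symbols = ["N", "C", "C", "H", "O"]
        base_pyr = pyramidalization(coords, 0, [1, 2, 4])
        base_vbur = buried_volume(coords, symbols, 0, grid=0.1)
        base_sasa, base_vol = sasa_and_volume(coords, symbols)
        for _ in range(20):
            R, t = random_rigid_motion(rng)
            c2 = coords @ R.T + t
            assert pyramidalization(c2, 0, [1, 2, 4]) == pytest.approx(
                base_pyr, abs=1e-9)
            # sampled quantities: within sampling tolerance
            assert buried_volume(c2, symbols, 0, grid=0.1) == pytest.approx(
                base_vbur, abs=0.5)
            sasa, vol = sasa_and_volume(c2, symbols)
            assert sasa == pytest.approx(base_sasa, rel=0.01)
            assert vol == pytest.approx(base_vol, rel=0.01)
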