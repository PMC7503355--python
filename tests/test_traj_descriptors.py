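"""Tests for the SASA / interaction-energy / RMSF / t-test operations."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from md2qsar.traj_descriptors import (
    COULOMB_KE,
    compare_descriptors,
    compute_interaction_energy,
    compute_rmsf,
    compute_sasa,
    summarize_descriptors,
    sphere_points,
)

from conftest import toy_trajectory


def grid_sasa(coords, radii, probe, n_grid=200_000, seed=0):
    """Dense Monte-Carlo surface-integration oracle for small clusters."""
    rng = np.random.default_rng(seed)
    ext = radii + probe
    total = 0.0
    for i in range(len(coords)):
        pts = rng.normal(size=(n_grid, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + ext[i] * pts
        free = np.ones(n_grid, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
        total += 4.0 * math.pi * ext[i] ** 2 * free.mean()
    return total / 100.0


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        t = toy_trajectory([[0.0, 0.0, 0.0]], radii=[1.9])
        area = compute_sasa(t.coords[0], t.atoms, "protein", probe_radius=1.4)
        assert area == pytest.approx(4 * math.pi * 3.3 ** 2 / 100.0, rel=5e-3)

    def test_distant_atoms_add_their_isolated_areas(self):
        t = toy_trajectory([[0, 0, 0], [20, 0, 0]], radii=[1.9, 1.5])
        total = compute_sasa(t.coords[0], t.atoms, "protein")
        expected = (4 * math.pi * 3.3 ** 2 + 4 * math.pi * 2.9 ** 2) / 100.0
        assert total == pytest.approx(expected, rel=5e-3)

    def test_three_atom_cluster_matches_grid_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0], [1.2, 2.0, 0.5]])
        radii = np.array([1.9, 1.7, 1.5])
        t = toy_trajectory(coords, radii=radii)
        mine = compute_sasa(t.coords[0], t.atoms, "protein")
        oracle = grid_sasa(coords, radii, 1.4)
        assert mine == pytest.approx(oracle, rel=0.02)

    def test_group_area_in_context_of_whole_system(self):
        # a buried ligand atom must report less area than in isolation
        shell = sphere_points(30) * 3.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        t = toy_trajectory(coords, groups=["hPGS"] + ["protein"] * 30)
        buried = compute_sasa(t.coords[0], t.atoms, "hPGS")
        alone = 4 * math.pi * 3.3 ** 2 / 100.0
        assert buried < 0.5 * alone

    def test_rigid_motion_invariance(self):
        # translation moves the quadrature lattice with each atom -> exact;
        # rotation re-samples the occlusions -> equal to quadrature error
        rng = np.random.default_rng(1)
        coords = rng.uniform(-3, 3, (5, 3))
        t = toy_trajectory(coords)
        base = compute_sasa(t.coords[0], t.atoms, "protein")
        shifted = toy_trajectory(coords + np.array([5.0, -2.0, 11.0]))
        assert compute_sasa(shifted.coords[0], shifted.atoms, "protein") == \
            pytest.approx(base, rel=1e-12)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        rotated = toy_trajectory(coords @ rot.T)
        assert compute_sasa(rotated.coords[0], rotated.atoms, "protein") == \
            pytest.approx(base, rel=0.02)

    def test_invalid_inputs_rejected(self):
        t = toy_trajectory([[0, 0, 0]])
        with pytest.raises(ValueError):
            compute_sasa(t.coords[0], t.atoms, "hPGS")  # empty group
        with pytest.raises(ValueError):
            compute_sasa(t.coords[0], t.atoms, "protein", n_sphere_points=6)


class TestInteractionEnergy:
    def test_coulomb_closed_form_at_one_nm(self):
        t = toy_trajectory(
            [[0, 0, 0], [10.0, 0, 0]], charges=[1.0, 1.0],
            eps=[0.0, 0.0], groups=["protein", "hPGS"],
        )
        e = compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS")
        assert e == pytest.approx(COULOMB_KE, rel=1e-12)

    @pytest.mark.parametrize(
        "r_nm,expected", [(0.35, 0.0), (0.35 * 2 ** (1 / 6), -0.5)]
    )
    def test_lennard_jones_closed_forms(self, r_nm, expected):
        t = toy_trajectory(
            [[0, 0, 0], [r_nm * 10.0, 0, 0]], charges=[0.0, 0.0],
            eps=[0.5, 0.5], sigma=[0.35, 0.35], groups=["protein", "hPGS"],
        )
        e = compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS")
        assert e == pytest.approx(expected, abs=1e-10)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        n = 20
        coords = rng.uniform(0, 15, (n, 3))
        charges = rng.uniform(-0.8, 0.8, n)
        eps = rng.uniform(0.1, 1.0, n)
        sig = rng.uniform(0.25, 0.45, n)
        groups = ["protein"] * 12 + ["hPGS"] * 8
        t = toy_trajectory(coords, charges=charges, eps=eps, sigma=sig, groups=groups)
        mine = compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS")
        oracle = 0.0
        for i in range(12):
            for j in range(12, n):
                r = np.linalg.norm(coords[i] - coords[j]) / 10.0
                oracle += COULOMB_KE * charges[i] * charges[j] / r
                s = 0.5 * (sig[i] + sig[j])
                e = math.sqrt(eps[i] * eps[j])
                oracle += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert mine == pytest.approx(oracle, rel=1e-10)

    def test_symmetric_in_group_order_and_linear_in_charge(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 12, (8, 3))
        charges = rng.uniform(-1, 1, 8)
        groups = ["NADP"] * 4 + ["hPGS"] * 4
        t = toy_trajectory(coords, charges=charges, groups=groups)
        e_ab = compute_interaction_energy(t.coords[0], t.atoms, "NADP", "hPGS")
        e_ba = compute_interaction_energy(t.coords[0], t.atoms, "hPGS", "NADP")
        assert e_ab == pytest.approx(e_ba, rel=1e-12)
        t2 = toy_trajectory(
            coords, charges=np.where(np.arange(8) < 4, 3.0 * charges, charges),
            groups=groups,
        )
        e_scaled = compute_interaction_energy(t2.coords[0], t2.atoms, "NADP", "hPGS")
        assert e_scaled == pytest.approx(3.0 * e_ab, rel=1e-12)

    def test_cutoff_excludes_far_pairs(self):
        t = toy_trajectory(
            [[0, 0, 0], [3.0, 0, 0], [30.0, 0, 0]],
            charges=[1.0, 0.5, 0.5], eps=[0, 0, 0],
            groups=["protein", "hPGS", "hPGS"],
        )
        full = compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS")
        near = compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS", cutoff=10.0)
        assert near == pytest.approx(COULOMB_KE * 0.5 / 0.3, rel=1e-12)
        assert full > near

    def test_overlapping_groups_and_zero_distance_error(self):
        t = toy_trajectory([[0, 0, 0], [0.0, 0, 0]], groups=["protein", "hPGS"])
        with pytest.raises(ValueError):
            compute_interaction_energy(t.coords[0], t.atoms, "protein", "protein")
        with pytest.raises(ValueError):
            compute_interaction_energy(t.coords[0], t.atoms, "protein", "hPGS")


class TestRmsf:
    def test_static_trajectory_gives_zero(self):
        coords = np.tile(np.random.default_rng(0).uniform(0, 10, (4, 3)), (5, 1, 1))
        t = toy_trajectory(coords, names=["CA"] * 4)
        prof = compute_rmsf(t)
        assert np.allclose(prof["rmsf"], 0.0)

    def test_two_point_oscillation_equals_amplitude(self):
        # one atom alternating x = ±d about its mean, superposition off
        d = 0.7
        base = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]])
        frames = np.stack([base.copy() for _ in range(4)])
        frames[::2, 0, 0] = d
        frames[1::2, 0, 0] = -d
        t = toy_trajectory(frames, names=["CA"] * 4)
        prof = compute_rmsf(t, superpose=False)
        assert prof["rmsf"].iloc[0] == pytest.approx(d, rel=1e-12)
        assert np.allclose(prof["rmsf"].iloc[1:], 0.0)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        rng = np.random.default_rng(12)
        sigma = 0.4
        base = np.array([[0.0, 0, 0], [8, 0, 0], [0, 8, 0]])
        frames = base[None] + rng.normal(0, sigma, (10_000, 3, 3))
        t = toy_trajectory(frames, names=["CA"] * 3)
        prof = compute_rmsf(t, superpose=False)
        assert np.allclose(prof["rmsf"], sigma * math.sqrt(3), rtol=0.03)

    def test_rigid_body_motion_removed_by_superposition(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 10, (6, 3))
        frames = []
        for k in range(30):
            rot = Rotation.from_euler("z", 0.2 * k).as_matrix()
            frames.append(base @ rot.T + np.array([0.5 * k, -k, 2.0]))
        t = toy_trajectory(np.stack(frames), names=["CA"] * 6)
        prof = compute_rmsf(t, superpose=True)
        assert np.allclose(prof["rmsf"], 0.0, atol=1e-8)

    def test_empty_selection_errors(self):
        t = toy_trajectory(np.zeros((2, 3, 3)) + np.arange(3)[None, :, None] * 9)
        with pytest.raises(ValueError):
            compute_rmsf(t)  # no CA atoms present


class TestSummarize:
    def _complex(self, n_frames=2, shift=0.0):
        base = np.array(
            [[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0], [8.0, 8.0, 8.0]]
        )
        frames = np.stack([base.copy() for _ in range(n_frames)])
        frames[:, 1, 0] += shift * np.arange(n_frames)  # move the ligand only
        return toy_trajectory(
            frames,
            groups=["protein", "hPGS", "NADP", "protein"],
            charges=[0.3, -0.2, 0.1, -0.1],
            eps=[0.4, 0.4, 0.4, 0.4],
        )

    def test_identical_frames_have_zero_sd(self):
        row = summarize_descriptors(self._complex(3, 0.0), "X")
        assert row.sas_nadp_sd == row.sas_hpgs_sd == 0.0
        assert row.ie_p_hp_sd == row.ie_n_hp_sd == 0.0

    def test_two_frame_mean_sd_match_per_frame_evaluations(self):
        t = self._complex(2, 0.5)
        row = summarize_descriptors(t, "X")
        per_frame = [
            compute_interaction_energy(f, t.atoms, "protein", "hPGS")
            for f in t.coords
        ]
        assert row.ie_p_hp == pytest.approx(np.mean(per_frame), rel=1e-12)
        assert row.ie_p_hp_sd == pytest.approx(np.std(per_frame), rel=1e-12)

    def test_missing_group_errors(self):
        t = toy_trajectory(np.zeros((2, 2, 3)) + [[0, 0, 0], [5, 0, 0]],
                           groups=["protein", "hPGS"])
        with pytest.raises(ValueError):
            summarize_descriptors(t, "X")  # no NADP atoms


class TestCompare:
    def test_identical_constant_samples_sit_on_null_boundary(self):
        assert compare_descriptors([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_gross_separation_gives_vanishing_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        assert compare_descriptors(a, b, alternative="greater") < 1e-100

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        p = compare_descriptors(a, b, alternative="greater")
        pooled = np.concatenate([a, b])
        n_perm, hits = 20_000, 0
        obs = b.mean() - a.mean()
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if perm[12:].mean() - perm[:12].mean() >= obs:
                hits += 1
        p_perm = hits / n_perm
        assert p == pytest.approx(p_perm, abs=3 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_descriptors([1.0], [2.0, 3.0])
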