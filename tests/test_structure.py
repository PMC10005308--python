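"""Tests for structural/ordering analyses."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memprobe import structure, trajgen
from memprobe.exceptions import (
    AnalysisError,
    GeometryError,
    ParameterError,
    SelectionError,
)
from memprobe.structure import ChainSpec

from conftest import make_trajectory


# ------------------------------------------------------------ area per lipid
class TestAreaPerLipid:
    def test_simple_arithmetic(self):
        traj = make_trajectory(np.zeros((1, 1, 3)), box=(8.0, 8.0, 6.0))
        res = structure.compute_area_per_lipid(traj, 100)
        assert res.area_per_lipid.mean == pytest.approx(0.64)

    def test_fluctuating_box_brute_force(self):
        # oracle: frame-wise average computed directly from the drawn areas
        rng = np.random.default_rng(0)
        areas = rng.uniform(47.0, 49.0, size=200)
        sides = np.sqrt(areas)
        pos = np.zeros((200, 1, 3))
        traj = make_trajectory(pos, box=(1.0, 1.0, 1.0))
        traj.box[:, 0] = sides
        traj.box[:, 1] = sides
        res = structure.compute_area_per_lipid(traj, 100)
        assert res.area_per_lipid.mean == pytest.approx(
            np.mean(areas / 100.0), rel=1e-12
        )
        assert res.area_per_lipid.mean == pytest.approx(0.48, abs=0.005)

    def test_single_frame(self):
        traj = make_trajectory(np.zeros((1, 1, 3)), box=(6.928, 6.928, 6.0))
        res = structure.compute_area_per_lipid(traj, 100)
        assert res.area_per_lipid.mean == pytest.approx(0.48, abs=1e-3)

    def test_zero_lipids_rejected(self):
        traj = make_trajectory(np.zeros((1, 1, 3)))
        with pytest.raises(ParameterError):
            structure.compute_area_per_lipid(traj, 0)

    def test_translation_invariance(self):
        traj = make_trajectory(np.zeros((2, 1, 3)), box=(7.0, 7.0, 6.0))
        shifted = make_trajectory(np.ones((2, 1, 3)), box=(7.0, 7.0, 6.0))
        a = structure.compute_area_per_lipid(traj, 50).area_per_lipid.mean
        b = structure.compute_area_per_lipid(shifted, 50).area_per_lipid.mean
        assert a == b


# ----------------------------------------------------------------- thickness
class TestThickness:
    def _two_p_traj(self, z_up=2.0, z_lo=-2.0, shift=0.0):
        pos = np.array([[[1.0, 1.0, z_up + shift], [2.0, 2.0, z_lo + shift]]])
        return make_trajectory(
            pos, names=["P", "P"], leaflets=["upper", "lower"],
            mol_id=[0, 1],
        )

    def test_fixed_planes(self):
        res = structure.compute_thickness_dpp(self._two_p_traj())
        assert res.d_pp.mean == pytest.approx(4.0)
        assert res.d_pp.ci95 == 0.0

    def test_translation_invariance(self):
        a = structure.compute_thickness_dpp(self._two_p_traj()).d_pp.mean
        b = structure.compute_thickness_dpp(self._two_p_traj(shift=1.0)).d_pp.mean
        assert a == pytest.approx(b, abs=1e-12)

    def test_generator_ground_truth(self):
        spec = trajgen.SyntheticBilayerSpec(n_lipids_per_leaflet=16,
                                            d_pp_true=3.8)
        traj = trajgen.gen_bilayer_config(spec, 3, seed=0)
        res = structure.compute_thickness_dpp(traj)
        assert res.d_pp.mean == pytest.approx(3.8, abs=1e-6)

    def test_empty_leaflet_selector(self):
        pos = np.array([[[0.0, 0.0, 2.0]]])
        traj = make_trajectory(pos, names=["P"], leaflets=["upper"])
        with pytest.raises(SelectionError):
            structure.compute_thickness_dpp(traj)


# ---------------------------------------------------------------------- S_CD
class TestSCD:
    def test_parallel_gives_one(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        assert structure.scd_from_vectors(v) == pytest.approx(1.0)

    def test_perpendicular_gives_minus_half(self):
        v = np.tile([1.0, 0.0, 0.0], (100, 1))
        assert structure.scd_from_vectors(v) == pytest.approx(-0.5)

    def test_isotropic_gives_zero(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((100_000, 3))
        assert structure.scd_from_vectors(v) == pytest.approx(0.0, abs=0.01)

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            structure.scd_from_vectors(np.zeros((3, 3)))

    def test_profile_on_generator(self, small_bilayer):
        prof = structure.compute_scd_profile(
            small_bilayer, ChainSpec("lipid", "C1", "C6")
        )
        assert len(prof.carbon_index) == 4  # interior carbons only
        assert np.all(prof.s_cd >= -0.5) and np.all(prof.s_cd <= 1.0)

    def test_too_short_chain(self, small_bilayer):
        with pytest.raises(GeometryError):
            structure.compute_scd_profile(
                small_bilayer, ChainSpec("lipid", "C1", "C2")
            )


# ---------------------------------------------------------------------- tilt
class TestTiltDistribution:
    def test_aligned_chains(self):
        spec = trajgen.SyntheticBilayerSpec(
            n_lipids_per_leaflet=9, chain_length=4, tilt_mean=0.0
        )
        traj = trajgen.gen_bilayer_config(spec, 2, seed=0)
        dist = structure.compute_tilt_distribution(
            traj, ChainSpec("lipid", "C1", "C4")
        )
        assert dist.mean == pytest.approx(0.0, abs=1e-9)
        assert dist.variance == pytest.approx(0.0, abs=1e-12)

    def test_sd_recovery(self):
        spec = trajgen.SyntheticBilayerSpec(
            n_lipids_per_leaflet=100, chain_length=6, tilt_mean=30.0,
            tilt_sd_near=6.0, tilt_sd_mid=6.0, tilt_sd_far=6.0,
        )
        traj = trajgen.gen_bilayer_config(spec, 50, seed=3)
        dist = structure.compute_tilt_distribution(
            traj, ChainSpec("lipid", "C1", "C6")
        )
        assert np.sqrt(dist.variance) == pytest.approx(6.0, rel=0.10)

    def test_histogram_normalized(self, small_bilayer):
        dist = structure.compute_tilt_distribution(
            small_bilayer, ChainSpec("lipid", "C1", "C6")
        )
        integral = np.sum(dist.density * np.diff(dist.edges))
        assert integral == pytest.approx(1.0, abs=1e-9)


class TestProximityBinnedTilts:
    def test_far_only(self):
        # one probe 5 nm away from a single lipid: everything in far bin
        pos = np.array([[
            [0.0, 0.0, 1.0], [0.0, 0.0, 2.0],      # lipid chain C1, C2... P?
            [5.0, 0.0, 1.5], [5.0, 0.0, 2.0],      # probe
        ]])
        traj = make_trajectory(
            pos, box=(20.0, 20.0, 10.0),
            species=["lipid", "lipid", "probe", "probe"],
            names=["C2", "C1", "C1", "COO"],
            mol_id=[0, 0, 1, 1],
            leaflets=["upper"] * 4,
        )
        out = structure.compute_proximity_binned_tilts(
            traj, ChainSpec("lipid", "C1", "C2")
        )
        assert out["near"].n_samples == 0
        assert out["mid"].n_samples == 0
        assert out["far"].n_samples == 1

    def test_partition_completeness(self, small_bilayer):
        out = structure.compute_proximity_binned_tilts(
            small_bilayer, ChainSpec("lipid", "C1", "C6")
        )
        total = sum(d.n_samples for d in out.values())
        assert total == 2 * 64 * small_bilayer.n_frames

    def test_degenerate_edges(self, small_bilayer):
        out = structure.compute_proximity_binned_tilts(
            small_bilayer, ChainSpec("lipid", "C1", "C6"), r_edges=(0.7, 0.7)
        )
        assert out["mid"].n_samples == 0
        total = out["near"].n_samples + out["far"].n_samples
        assert total == 2 * 64 * small_bilayer.n_frames

    def test_no_probes(self):
        spec = trajgen.SyntheticBilayerSpec(n_lipids_per_leaflet=9,
                                            chain_length=4)
        traj = trajgen.gen_bilayer_config(spec, 1, seed=0)
        with pytest.raises(AnalysisError):
            structure.compute_proximity_binned_tilts(
                traj, ChainSpec("lipid", "C1", "C4")
            )

    def test_variance_ratio_recovery(self):
        spec = trajgen.SyntheticBilayerSpec(
            n_lipids_per_leaflet=100, chain_length=6, tilt_mean=30.0,
            tilt_sd_near=9.2, tilt_sd_mid=5.8, tilt_sd_far=5.8,
            probe_spec=trajgen.ProbeSpec(2, 1.9),
        )
        traj = trajgen.gen_bilayer_config(spec, 100, seed=8)
        out = structure.compute_proximity_binned_tilts(
            traj, ChainSpec("lipid", "C1", "C6")
        )
        ratio = out["near"].variance / out["far"].variance
        assert ratio == pytest.approx((9.2 / 5.8) ** 2, rel=0.15)
        assert out["near"].variance > out["far"].variance


class TestSdIncreasePercent:
    def test_published_values(self):
        assert structure.sd_increase_percent(33.5, 85.1) == 59
        assert structure.sd_increase_percent(37.3, 51.4) == 17

    def test_identity(self):
        assert structure.sd_increase_percent(12.3, 12.3) == 0

    def test_zero_far_rejected(self):
        with pytest.raises(ParameterError):
            structure.sd_increase_percent(0.0, 10.0)

    @given(
        var_far=st.floats(1.0, 100.0),
        a=st.floats(0.0, 100.0),
        b=st.floats(0.0, 100.0),
    )
    def test_monotone_in_var_near(self, var_far, a, b):
        lo, hi = sorted([a, b])
        assert structure.sd_increase_percent(
            var_far, lo
        ) <= structure.sd_increase_percent(var_far, hi)


# -------------------------------------------------------- transverse positions
class TestTransversePositions:
    def test_static_atom(self):
        # the bilayer COM is defined by the (heavy) lipid atoms; the probe
        # contributes negligible mass
        pos = np.array([[[0.0, 0.0, 0.0], [0.0, 0.0, 1.5]]])
        traj = make_trajectory(
            pos, species=["lipid", "probe"], names=["P", "COO"],
            masses=[1000.0, 1e-6],
            mol_id=[0, 1], leaflets=["upper", "upper"],
        )
        out = structure.compute_transverse_positions(
            traj, {"coo": ("probe", "COO")}
        )
        assert out["coo"].mean == pytest.approx(1.5, abs=1e-6)
        assert out["coo"].ci95 == 0.0

    def test_mirror_symmetry(self):
        spec = trajgen.SyntheticBilayerSpec(
            n_lipids_per_leaflet=16, tilt_mean=0.0, d_pp_true=4.0
        )
        traj = trajgen.gen_bilayer_config(spec, 1, seed=0)
        up = traj.select(name="P", leaflet="upper")
        lo = traj.select(name="P", leaflet="lower")
        z = traj.positions[0, :, 2]
        z_com = traj.bilayer_com()[0, 2]
        assert abs(np.abs(z[up] - z_com).mean()
                   - np.abs(z[lo] - z_com).mean()) < 1e-6

    def test_probe_depth_recovery(self, small_bilayer):
        out = structure.compute_transverse_positions(
            small_bilayer, {"coo": ("probe", "COO")}
        )
        assert out["coo"].mean == pytest.approx(1.9, abs=0.05)

    def test_empty_group(self, small_bilayer):
        with pytest.raises(SelectionError):
            structure.compute_transverse_positions(
                small_bilayer, {"x": ("nothing", "*")}
            )


# ------------------------------------------------------------- density profile
class TestDensityProfile:
    def test_uniform_slab(self):
        # stratified z fills the slab uniformly so the check isolates the
        # normalization and unit conversion, not sampling noise
        rng = np.random.default_rng(2)
        n, mass, lz = 200_000, 2.0, 2.0
        area = 25.0
        pos = np.zeros((1, n, 3))
        pos[0, :, 0] = rng.uniform(0, 5.0, n)
        pos[0, :, 1] = rng.uniform(0, 5.0, n)
        pos[0, :, 2] = (np.arange(n) + rng.uniform(size=n)) / n * lz - lz / 2
        traj = make_trajectory(
            pos, box=(5.0, 5.0, 4.0), masses=[mass] * n,
            mol_id=[0] * n, names=["X"] * n,
        )
        prof = structure.compute_density_profile(traj, bin_width=0.2)
        expected = n * mass / (area * lz) * 1.66053906660
        sel = np.abs(prof.z_centers) < lz / 2 - 0.2
        assert np.all(np.abs(prof.density["all"][sel] / expected - 1) < 0.01)

    def test_species_additivity(self, small_bilayer):
        prof = structure.compute_density_profile(small_bilayer)
        total = sum(
            v for k, v in prof.density.items() if k != "all"
        )
        np.testing.assert_allclose(total, prof.density["all"], rtol=1e-9)

    def test_mass_conservation(self, small_bilayer):
        prof = structure.compute_density_profile(small_bilayer)
        area = small_bilayer.box[0, 0] * small_bilayer.box[0, 1]
        for sp in ("lipid", "probe"):
            integral = prof.density[sp].sum() * prof.bin_width * area
            total = small_bilayer.topology.mass[
                small_bilayer.select(species=sp)
            ].sum() * 1.66053906660
            assert integral == pytest.approx(total, rel=0.005)

    def test_carboxylate_peak_location(self, small_bilayer):
        prof = structure.compute_density_profile(small_bilayer)
        coo_mass = small_bilayer.topology.mass[
            small_bilayer.select(species="probe", name="COO")
        ].sum()
        # restrict to upper half; the COO head bead dominates the probe peak
        upper = prof.z_centers > 0
        peak = prof.z_centers[upper][np.argmax(prof.density["probe"][upper])]
        assert abs(peak - 1.9) <= 2 * prof.bin_width + 1e-9
        assert coo_mass > 0

    def test_bad_bin_width(self, small_bilayer):
        with pytest.raises(ParameterError):
            structure.compute_density_profile(small_bilayer, bin_width=0.0)
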