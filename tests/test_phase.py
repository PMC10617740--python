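import numpy as np
import pytest

from idrslab.forcefield import build_system
from idrslab.io import IDRSequence
from idrslab.phase import (
    MM_PER_PER_NM3,
    PhaseAnalysisError,
    center_condensate,
    center_shift,
    chain_centers,
    delta_g_trans,
    density_profile,
    fit_coexistence,
)
from idrslab.simulate import Trajectory
from idrslab.synthetic import ProfileSpec, generate_tanh_profile


def central_occupancy(z, lz, shift):
    zc = z - shift
    zc -= lz * np.round(zc / lz)
    return int(np.sum(np.abs(zc) < lz / 6))


def brute_force_best_occupancy(z, lz, nbins=240):
    """Oracle: best central-third occupancy over all integer-bin shifts."""
    return max(
        central_occupancy(z, lz, k * lz / nbins - lz / 2) for k in range(nbins)
    )


class TestCenterCondensate:
    def test_point_mass_moved_to_origin(self):
        box = np.array([10.0, 10.0, 40.0])
        frame = np.tile([1.0, 2.0, 10.0], (50, 1))
        out = center_condensate(frame, box)
        assert np.allclose(out[:, 2], 0.0, atol=1e-9)
        assert np.allclose(out[:, :2], frame[:, :2])  # x, y untouched

    def test_uniform_distribution_returns_deterministic_zero_shift(self):
        box = np.array([10.0, 10.0, 40.0])
        z = np.linspace(-20, 20, 400, endpoint=False)
        assert center_shift(z, box[2]) == 0.0

    def test_wrapped_half_slabs_are_reunited(self, rng):
        """A slab split across the periodic boundary must be made whole."""
        lz = 40.0
        box = np.array([10.0, 10.0, lz])
        for _ in range(10):
            center = rng.uniform(-lz / 2, lz / 2)
            z = center + rng.normal(0, 2.0, size=300)
            z -= lz * np.round(z / lz)  # wrap; may split the cluster
            frame = np.column_stack([np.zeros(300), np.zeros(300), z])
            out = center_condensate(frame, box)
            # reunited: all beads near 0 with no wrap discontinuity
            assert np.std(out[:, 2]) < 3.0
            assert abs(np.mean(out[:, 2])) < 1.0
            # achieves (nearly) the brute-force maximal central occupancy
            best = brute_force_best_occupancy(z, lz)
            got = central_occupancy(z, lz, center_shift(z, lz))
            assert got >= best - max(2, 0.02 * len(z))


def _static_trajectory(system, z_positions, n_frames=4):
    """All chains collapsed to points at given z (one z per chain)."""
    frames = []
    L = system.chain_length
    for _ in range(n_frames):
        fr = np.zeros((system.n_beads, 3))
        for c, z in enumerate(z_positions):
            fr[c * L:(c + 1) * L, 2] = z
        frames.append(fr)
    times = np.arange(n_frames, dtype=float) + 1.0
    return Trajectory(times=times, frames=np.asarray(frames),
                      box=system.box.copy(), seed=0)


class TestDensityProfile:
    @pytest.fixture()
    def system(self, random_table):
        idr = IDRSequence(id="t", sequence="AGSA")
        return build_system(idr, copies=12, box=[10.0, 10.0, 40.0],
                            table=random_table)

    def test_single_bin_unit_conversion(self, system):
        """12 chains in one 1-nm bin -> n/(Lx*Ly*1) in mM."""
        traj = _static_trajectory(system, np.zeros(12))
        prof = density_profile(traj, system, equilibration_cut=0.5,
                               bin_width=1.0)
        want = 12 / (10.0 * 10.0 * 1.0) * MM_PER_PER_NM3
        assert prof.concentration.max() == pytest.approx(want)
        assert np.sum(prof.concentration > 0) == 1

    def test_mass_conservation(self, system, rng):
        z = rng.uniform(-20, 20, 12)
        traj = _static_trajectory(system, z)
        prof = density_profile(traj, system, equilibration_cut=0.5,
                               bin_width=1.0)
        assert prof.total_chains == pytest.approx(12, rel=1e-6)

    def test_bin_width_change_preserves_integral(self, system, rng):
        z = rng.uniform(-20, 20, 12)
        traj = _static_trajectory(system, z)
        p1 = density_profile(traj, system, equilibration_cut=0.5, bin_width=1.0)
        p2 = density_profile(traj, system, equilibration_cut=0.5, bin_width=2.0)
        assert len(p2.z_centers) == len(p1.z_centers) // 2
        assert p2.total_chains == pytest.approx(p1.total_chains, rel=1e-9)

    def test_ideal_gas_profile_is_flat(self, random_table, rng):
        """Uniformly scattered chains: max/min bin ratio stays small.

        Many chains per frame are needed because the per-frame centering
        step coherently aligns density fluctuations of sparse frames.
        """
        idr = IDRSequence(id="t", sequence="AGSA")
        system = build_system(idr, copies=200, box=[10.0, 10.0, 40.0],
                              table=random_table)
        L = system.chain_length
        frames = []
        for _ in range(100):  # 2e4 chain samples
            fr = np.zeros((system.n_beads, 3))
            z = rng.uniform(-20, 20, system.n_chains)
            for c in range(system.n_chains):
                fr[c * L:(c + 1) * L, 2] = z[c]
            frames.append(fr)
        traj = Trajectory(times=np.arange(100.0) + 1, frames=np.asarray(frames),
                          box=system.box.copy(), seed=0)
        prof = density_profile(traj, system, equilibration_cut=0.0,
                               bin_width=4.0)
        assert prof.concentration.max() / prof.concentration.min() < 1.5

    def test_no_frames_after_cut_is_an_error(self, system):
        traj = _static_trajectory(system, np.zeros(12))
        with pytest.raises(PhaseAnalysisError):
            density_profile(traj, system, equilibration_cut=100.0)

    def test_chain_centers_reconstruct_wrapped_chains(self, random_table):
        """A chain straddling the z boundary gets its true center back."""
        idr = IDRSequence(id="t", sequence="AGSA")
        system = build_system(idr, copies=1, box=[10.0, 10.0, 20.0],
                              table=random_table)
        z = np.array([9.7, 9.9, -9.9, -9.7])  # contiguous across the seam
        frame = np.zeros((4, 3))
        frame[:, 2] = z
        com_z = chain_centers(frame, system)[0, 2]
        com_z_expected = 9.8 + (
            (system.mass[2] + system.mass[3]) * 0.4 / system.mass.sum()
        )
        delta = com_z - com_z_expected
        delta -= 20.0 * np.round(delta / 20.0)
        assert abs(delta) < 0.2


class TestDeltaG:
    def test_equal_concentrations_give_zero(self):
        assert delta_g_trans(5.0, 5.0, 293.0) == 0.0

    def test_ratio_e_inverse_gives_minus_rt(self):
        got = delta_g_trans(np.exp(-1.0) * 7.0, 7.0, 293.0)
        assert got == pytest.approx(-2.436, abs=1e-3)

    def test_sign_and_antisymmetry(self):
        assert delta_g_trans(1.0, 10.0, 293.0) < 0
        assert delta_g_trans(1.0, 10.0, 293.0) == pytest.approx(
            -delta_g_trans(10.0, 1.0, 293.0)
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(PhaseAnalysisError):
            delta_g_trans(0.0, 1.0, 293.0)


class TestFitCoexistence:
    def test_noiseless_profile_recovered_exactly(self):
        spec = ProfileSpec(c_dense=40.0, c_dilute=0.8, z0=8.0, w=1.5,
                           lz=100.0, bins=100, noise=0.0)
        fit = fit_coexistence(generate_tanh_profile(spec), dilute_floor=False)
        assert fit.phase_separated
        assert fit.c_dense == pytest.approx(40.0, rel=1e-6)
        assert fit.c_dilute == pytest.approx(0.8, rel=1e-6)
        assert fit.z0 == pytest.approx(8.0, rel=1e-6)
        assert fit.w == pytest.approx(1.5, rel=1e-6)

    def test_flat_profile_flagged_no_phase_separation(self):
        spec = ProfileSpec(c_dense=5.0, c_dilute=5.0, z0=8.0, w=1.5,
                           lz=100.0, bins=60)
        fit = fit_coexistence(generate_tanh_profile(spec))
        assert not fit.phase_separated
        assert fit.delta_g_trans == 0.0
        assert fit.c_dense == pytest.approx(5.0, rel=1e-9)

    def test_mirror_symmetry_invariance(self):
        spec = ProfileSpec(c_dense=40.0, c_dilute=0.8, z0=8.0, w=1.5,
                           lz=100.0, bins=100, noise=0.03, seed=5)
        prof = generate_tanh_profile(spec)
        mirrored = type(prof)(
            z_centers=-prof.z_centers[::-1],
            concentration=prof.concentration[::-1],
            n_frames_averaged=prof.n_frames_averaged,
            bin_width=prof.bin_width, box=prof.box, n_chains=prof.n_chains,
        )
        f1 = fit_coexistence(prof, dilute_floor=False)
        f2 = fit_coexistence(mirrored, dilute_floor=False)
        assert f2.c_dense == pytest.approx(f1.c_dense, rel=1e-6)
        assert f2.c_dilute == pytest.approx(f1.c_dilute, rel=1e-6)

    def test_noisy_recovery_within_five_percent(self):
        """5% multiplicative noise, 50 bins: densities back within 5%."""
        spec0 = dict(c_dense=40.0, c_dilute=2.0, z0=8.0, w=1.5,
                     lz=50.0, bins=50, noise=0.05)
        cds, cls = [], []
        for seed in range(100):
            prof = generate_tanh_profile(ProfileSpec(**spec0, seed=seed))
            fit = fit_coexistence(prof, dilute_floor=False)
            assert fit.phase_separated
            cds.append(fit.c_dense)
            cls.append(fit.c_dilute)
        assert np.mean(cds) == pytest.approx(40.0, rel=0.05)
        assert np.mean(cls) == pytest.approx(2.0, rel=0.05)

    def test_dilute_floor_reported_as_bound(self):
        spec = ProfileSpec(c_dense=50.0, c_dilute=0.0, z0=6.0, w=1.0,
                           lz=60.0, lx=10.0, ly=10.0, bins=60)
        fit = fit_coexistence(generate_tanh_profile(spec))
        assert fit.phase_separated
        assert fit.dilute_is_bound
        assert fit.c_dilute > 0  # occupancy bound, not zero
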