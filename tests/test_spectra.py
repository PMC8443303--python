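"""Spectral estimators: dipole assembly, FT-DAC, prefactors, averaging."""

import math

import numpy as np
import pytest

from ringspec import md, spectra as sp, units



def _cosine_series(wn_cm1, n=16000, dt=0.5, axis=0):
    t = np.arange(n) * dt
    w = units.omega_from_wavenumber(wn_cm1)
    mu = np.zeros((n, 3))
    mu[:, axis] = np.cos(w * t)
    return sp.DipoleSeries(mu, dt)


class TestDipoleAssembly:
    def test_single_charged_atom(self):
        traj = md.Trajectory(
            positions=np.array([[[1.0, 0.0, 0.0]]]),
            charges=np.array([[1.0]]),
            times_fs=np.array([0.0]),
            dt_fs=0.5,
        )
        # a 1-frame series is below the estimator minimum but the
        # assembly itself is frame-wise
        mu = np.sum(traj.charges[..., None] * traj.positions, axis=-2)
        assert np.allclose(mu, [[1.0, 0.0, 0.0]])

    def test_two_frame_hand_sum(self):
        """Printed two-frame fixture summed by hand:
        frame 0: q=(0.5,-0.5) at (1,0,0),(0,1,0) -> mu=(0.5,-0.5,0)
        frame 1: q=(0.3,-0.3) at (2,0,0),(0,0,2) -> mu=(0.6,0,-0.6)."""
        traj = md.Trajectory(
            positions=np.array(
                [[[1.0, 0, 0], [0, 1.0, 0]], [[2.0, 0, 0], [0, 0, 2.0]]]
            ),
            charges=np.array([[0.5, -0.5], [0.3, -0.3]]),
            times_fs=np.array([0.0, 0.5]),
            dt_fs=0.5,
        )
        series = sp.dipole_from_trajectory(traj)
        assert np.allclose(series.values, [[0.5, -0.5, 0.0], [0.6, 0.0, -0.6]])

    def test_zero_charges_zero_series(self):
        traj = md.Trajectory(
            positions=np.random.default_rng(0).standard_normal((10, 3, 3)),
            charges=np.zeros((10, 3)),
            times_fs=np.arange(10.0),
            dt_fs=1.0,
        )
        assert np.all(sp.dipole_from_trajectory(traj).values == 0.0)

    def test_missing_charges_rejected(self):
        traj = md.Trajectory(
            positions=np.zeros((10, 2, 3)),
            charges=np.empty((10, 0)),
            times_fs=np.arange(10.0),
            dt_fs=1.0,
        )
        with pytest.raises(sp.SpectrumError, match="charge"):
            sp.dipole_from_trajectory(traj)


class TestBeadAverage:
    def test_identical_beads_equal_single(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((100, 3))
        from ringspec.ringpolymer import BeadTrajectory

        bt = BeadTrajectory(
            bead_dipoles=np.repeat(mu[:, None, :], 8, axis=1),
            centroid_positions=np.zeros((100, 1, 3)),
            centroid_charges=np.zeros((100, 1)),
            times_fs=np.arange(100.0),
            dt_fs=0.5,
        )
        assert np.allclose(sp.bead_average_dipole(bt).values, mu)

    def test_two_bead_arithmetic(self):
        from ringspec.ringpolymer import BeadTrajectory

        dip = np.zeros((4, 2, 3))
        dip[:, 0, 0] = 1.0  # bead 1: (1,0,0)
        dip[:, 1, 1] = 1.0  # bead 2: (0,1,0)
        bt = BeadTrajectory(
            bead_dipoles=dip,
            centroid_positions=np.zeros((4, 1, 3)),
            centroid_charges=np.zeros((4, 1)),
            times_fs=np.arange(4.0),
            dt_fs=0.5,
        )
        assert np.allclose(sp.bead_average_dipole(bt).values, [[0.5, 0.5, 0.0]] * 4)

    def test_ragged_bead_lists_rejected(self):
        mk = lambda n: md.Trajectory(
            positions=np.zeros((n, 1, 3)), charges=np.ones((n, 1)),
            times_fs=np.arange(float(n)), dt_fs=0.5,
        )
        with pytest.raises(sp.SpectrumError, match="ragged"):
            sp.bead_average_dipole([mk(10), mk(12)])


class TestFTDAC:
    @pytest.mark.parametrize("window", ["hann", "rect"])
    def test_cosine_peaks_at_its_frequency(self, window):
        """Analytic oracle: FT of a pure cosine concentrates at nu0
        within one resolution element."""
        series = _cosine_series(1000.0)
        spec = sp.ft_dac(series, window=window)
        res = spec.resolution_cm1
        assert abs(spec.peak_wavenumber(500, 1500) - 1000.0) <= res

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(7)
        series = sp.DipoleSeries(rng.standard_normal((16384, 3)), 0.5)
        spec = sp.ft_dac(series, window="hann")
        y = spec.intensity[1:]
        kernel = np.ones(101) / 101
        smooth = np.convolve(y, kernel, mode="valid")
        assert smooth.max() < 5.0 * np.median(smooth)

    def test_constant_series_gives_zero_spectrum(self):
        mu = np.ones((256, 3)) * 2.5
        spec = sp.ft_dac(sp.DipoleSeries(mu, 0.5), window="rect")
        assert np.abs(spec.intensity).max() < 1e-20

    def test_too_short_series_rejected(self):
        with pytest.raises(sp.SpectrumError, match="minimum"):
            sp.ft_dac(sp.DipoleSeries(np.ones((32, 3)), 0.5))

    def test_parseval_with_rectangular_window(self):
        """Sum of the raw power spectrum over the full FFT grid equals
        the dipole variance (lag-0 autocorrelation)."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((4096, 3))
        series = sp.DipoleSeries(x, 0.5)
        spec = sp.ft_dac(series, window="rect")
        var = ((x - x.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert abs(sp.spectral_power_sum(spec) - var) / var < 1e-8

    def test_resolution_matches_run_length(self):
        spec = sp.ft_dac(_cosine_series(1000.0, n=64000, dt=0.5))
        assert spec.resolution_cm1 == pytest.approx(
            1.0 / (64000 * 0.5 * units.C_CM_PER_FS)
        )
        assert spec.resolution_cm1 == pytest.approx(1.0424, abs=0.001)


class TestQuantumCorrection:
    @pytest.mark.parametrize("T", [100.0, 298.15])
    def test_identity_harmonic_equals_full_prefactor(self, T):
        """(1 - e^{-bhw}) Q_HC = bhw exactly, so the 'harmonic' mode is
        the closed-form collapsed prefactor."""
        nu = np.linspace(600.0, 3600.0, 3001)
        lhs = sp.quantum_correction_factor(nu, T, "none") * sp.harmonic_correction_QHC(
            nu, T
        )
        rhs = sp.quantum_correction_factor(nu, T, "harmonic")
        assert np.abs(lhs / rhs - 1.0).max() < 1e-12

    def test_qhc_tends_to_one_at_zero_frequency(self):
        nu = np.array([0.0, 1e-6, 1e-3])
        q = sp.harmonic_correction_QHC(nu, 298.15)
        # leading correction is bhw/2, so the deviation shrinks linearly
        assert q[0] == 1.0
        bhw = units.beta_hbar_omega(nu[1:], 298.15)
        assert np.abs(q[1:] - 1.0).max() < bhw.max()

    def test_qhc_against_high_precision_arithmetic(self):
        """beta hbar omega and Q_HC at 3000 cm^-1 / 298.15 K recomputed
        with 50-digit arithmetic from the defining constants."""
        import sympy

        h = sympy.Float("6.62607015e-34", 50)
        kB = sympy.Float("1.380649e-23", 50)
        c = sympy.Float("2.99792458e10", 50)  # cm/s
        T = sympy.Float("298.15", 50)
        nu = sympy.Integer(3000)
        bhw = h * c * nu / (kB * T)
        qhc = bhw / (1 - sympy.exp(-bhw))
        ours = sp.harmonic_correction_QHC(np.array([3000.0]), 298.15)[0]
        assert abs(ours / float(qhc) - 1.0) < 1e-12

    def test_corrected_intensity_nonnegative(self):
        spec = sp.ft_dac(_cosine_series(1000.0, n=2048))
        out = sp.apply_quantum_correction(spec, 298.15, "harmonic")
        assert np.all(out.intensity >= 0.0)
        assert out.provenance["correction"] == "Q_HC"

    def test_unknown_mode_rejected(self):
        spec = sp.ft_dac(_cosine_series(1000.0, n=2048))
        with pytest.raises(sp.SpectrumError):
            sp.apply_quantum_correction(spec, 298.15, "kubo")


class TestNormalization:
    def _spec(self, peaks):
        g = np.linspace(0.0, 4000.0, 4001)
        y = np.zeros_like(g)
        for pos, height in peaks:
            y += height * np.exp(-0.5 * ((g - pos) / 10.0) ** 2)
        return sp.Spectrum(g, y)

    def test_in_window_max_becomes_one(self):
        out = sp.normalize_spectrum(self._spec([(1000.0, 3.0), (2500.0, 7.0)]))
        m = (out.wavenumbers_cm1 >= 600) & (out.wavenumbers_cm1 <= 3600)
        assert out.intensity[m].max() == pytest.approx(1.0)

    def test_out_of_window_peak_may_exceed_one(self):
        out = sp.normalize_spectrum(self._spec([(100.0, 10.0), (2500.0, 2.0)]))
        assert out.intensity.max() > 1.0
        m = (out.wavenumbers_cm1 >= 600) & (out.wavenumbers_cm1 <= 3600)
        assert out.intensity[m].max() == pytest.approx(1.0)

    def test_grid_not_covering_window_rejected(self):
        g = np.linspace(1000.0, 2000.0, 100)
        with pytest.raises(sp.SpectrumError, match="cover"):
            sp.normalize_spectrum(sp.Spectrum(g, np.ones_like(g)))

    def test_all_zero_rejected(self):
        g = np.linspace(0.0, 4000.0, 100)
        with pytest.raises(sp.SpectrumError, match="zero"):
            sp.normalize_spectrum(sp.Spectrum(g, np.zeros_like(g)))


class TestReplicaAveraging:
    def _noise_specs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        g = np.linspace(0.0, 4000.0, 2001)
        return [
            sp.Spectrum(g, 1.0 + 0.3 * rng.standard_normal(len(g)) ** 2)
            for _ in range(n)
        ]

    def test_identical_replicas_zero_std(self):
        s = self._noise_specs(1)[0]
        out = sp.average_replicas([s, s, s], normalize=False)
        # zero up to round-off of the three-way mean
        assert np.abs(out.std).max() < 1e-12

    def test_two_replica_arithmetic(self):
        g = np.linspace(0.0, 4000.0, 11)
        a = sp.Spectrum(g, np.zeros_like(g))
        b = sp.Spectrum(g, np.full_like(g, 2.0))
        out = sp.average_replicas([a, b], normalize=False)
        assert np.allclose(out.intensity, 1.0)
        assert np.allclose(out.std, 1.0)  # population std of {0, 2}

    def test_std_scales_as_inverse_sqrt_replicas(self):
        """50 replicas of noise: the across-replica std of the mean
        tracks sigma/sqrt(50) within 20%."""
        specs = self._noise_specs(50, seed=5)
        out = sp.average_replicas(specs, normalize=False)
        stack = np.stack([s.intensity for s in specs])
        per_replica_sigma = stack.std(axis=0).mean()
        sem_expected = per_replica_sigma / math.sqrt(50)
        sem_measured = out.std.mean() / math.sqrt(50)
        # out.std *is* the population std; the SEM prediction follows
        assert abs(sem_measured / sem_expected - 1.0) < 0.2

    def test_mismatched_grids_rejected(self):
        g1 = np.linspace(0.0, 4000.0, 101)
        g2 = np.linspace(0.0, 4000.0, 102)
        with pytest.raises(sp.SpectrumError, match="grid"):
            sp.average_replicas(
                [sp.Spectrum(g1, np.ones_like(g1)), sp.Spectrum(g2, np.ones_like(g2))]
            )
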