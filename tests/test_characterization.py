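"""Localized-mode spectra, peak assignment and distance histograms."""

import math

import numpy as np
import pytest

from ringspec import md, units
from ringspec import characterization as ch
from ringspec import model as mdl
from ringspec import spectra as sp


def _diatomic_trajectory(wn=2000.0, production_ps=8.0, stretch=0.05):
    """NVE from a displaced bond with zero velocities: a pure stretch
    oscillation, free of rotational side bands."""
    model = mdl.build_diatomic(1.0, 16.0, wn)
    pos = model.reference_positions.copy()
    pos[1, 0] += stretch
    state = md.MDState(positions=pos, velocities=np.zeros((2, 3)))
    cfg = md.MDConfig(temperature_K=300.0, production_ps=production_ps, seed=0)
    return model, md.nve_production(model, state, cfg)


class TestInternalSeries:
    def test_static_distance(self):
        traj = md.Trajectory(
            positions=np.repeat(
                np.array([[[0.0, 0, 0], [0.96, 0, 0]]]), 5, axis=0
            ),
            charges=np.zeros((5, 2)),
            times_fs=np.arange(5.0),
            dt_fs=0.5,
        )
        spec = ch.InternalCoordinateSpec("distance", (0, 1), "O-H")
        assert np.allclose(ch.internal_series(traj, spec), 0.96)

    def test_dihedral_matches_independent_vector_algebra(self, rng):
        pos = rng.standard_normal((1, 4, 3)) * 2.0
        traj = md.Trajectory(
            positions=pos, charges=np.zeros((1, 4)),
            times_fs=np.array([0.0]), dt_fs=0.5,
        )
        spec = ch.InternalCoordinateSpec("dihedral", (0, 1, 2, 3))
        got = ch.internal_series(traj, spec)[0]
        p = pos[0]
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        ref = math.atan2(
            float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))),
            float(np.dot(n1, n2)),
        )
        assert abs(got - ref) < 1e-10

    def test_angle_of_right_angle_geometry(self):
        pos = np.array([[[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]]])
        traj = md.Trajectory(
            positions=pos, charges=np.zeros((1, 3)),
            times_fs=np.array([0.0]), dt_fs=0.5,
        )
        spec = ch.InternalCoordinateSpec("angle", (0, 1, 2))
        assert ch.internal_series(traj, spec)[0] == pytest.approx(math.pi / 2)

    def test_invalid_indices_rejected(self):
        traj = md.Trajectory(
            positions=np.zeros((2, 3, 3)), charges=np.zeros((2, 3)),
            times_fs=np.arange(2.0), dt_fs=0.5,
        )
        with pytest.raises(ValueError, match="out of range"):
            ch.internal_series(
                traj, ch.InternalCoordinateSpec("distance", (0, 7))
            )

    def test_spec_arity_validation(self):
        with pytest.raises(ValueError, match="3 atoms"):
            ch.InternalCoordinateSpec("angle", (0, 1))
        with pytest.raises(ValueError, match="unknown"):
            ch.InternalCoordinateSpec("improper", (0, 1, 2, 3))


class TestFTnuAC:
    def test_bond_length_series_peaks_at_stretch_frequency(self):
        """Core oracle: the FT-nu_N AC of a harmonic diatomic's bond
        length reproduces the stretch wavenumber within resolution,
        and coincides with the FT-DAC peak of the same trajectory."""
        model, traj = _diatomic_trajectory(wn=2000.0)
        spec = ch.InternalCoordinateSpec("distance", (0, 1), "A-B stretch")
        series = ch.internal_series(traj, spec)
        nuac = ch.ft_nuac(series, traj.dt_fs)
        res = nuac.resolution_cm1
        # velocity-Verlet carries an O((w dt)^2) frequency shift; the
        # estimator itself must land within one resolution element of
        # the integrator's effective frequency
        w = units.omega_from_wavenumber(2000.0)
        dt = 0.5
        w_eff = (2.0 / dt) * math.asin(w * dt / 2.0)
        nu_eff = units.wavenumber_from_omega(w_eff)
        assert abs(nuac.peak_wavenumber(1000, 3000) - nu_eff) <= res
        dac = sp.ft_dac(sp.dipole_from_trajectory(traj))
        assert abs(
            nuac.peak_wavenumber(1000, 3000) - dac.peak_wavenumber(1000, 3000)
        ) <= 2 * res

    def test_constant_series_yields_no_peaks(self):
        nuac = ch.ft_nuac(np.full(512, 1.23), 0.5)
        peaks = ch.find_spectral_peaks(nuac, band=(100.0, 3600.0))
        assert len(peaks) == 0

    def test_non_scalar_series_rejected(self):
        with pytest.raises(sp.SpectrumError, match="scalar"):
            ch.ft_nuac(np.zeros((100, 3)), 0.5)


class TestAssignment:
    def _two_mode_model(self):
        """Two independent diatomics in one model: stretches near 1000
        and 3000 cm^-1."""
        k1 = mdl._stretch_k(0.5, 1000.0)
        k2 = mdl._stretch_k(0.5, 3000.0)
        return mdl.MolecularModel(
            labels=["A", "B", "C", "D"],
            masses=[1.0, 1.0, 1.0, 1.0],
            terms=[
                mdl.HarmonicBond(0, 1, r0=1.0, k=k1),
                mdl.HarmonicBond(2, 3, r0=1.0, k=k2),
                mdl.SiteHarmonic(0, (5.0, 5.0, 5.0)),
                mdl.SiteHarmonic(2, (5.0, 5.0, 5.0), center=(4.0, 0.0, 0.0)),
            ],
            # flux != q/r0, otherwise the linear dipole derivative
            # cancels at equilibrium and only the overtone radiates
            charge_model=mdl.ChargeModel(
                reference=(0.3, -0.3, 0.3, -0.3),
                fluxes=((0, 1, 0.1, 1.0), (2, 3, 0.1, 1.0)),
            ),
            net_charge=0.0,
            reference_positions=np.array(
                [[0, 0, 0], [1.0, 0, 0], [4.0, 0, 0], [5.0, 0, 0]], dtype=float
            ),
        )

    def test_two_well_separated_modes_assigned_unambiguously(self):
        model = self._two_mode_model()
        pos = model.reference_positions.copy()
        pos[1, 0] += 0.05  # stretch both bonds, no rotation
        pos[3, 0] += 0.05
        state = md.MDState(positions=pos, velocities=np.zeros((4, 3)))
        cfg = md.MDConfig(temperature_K=300.0, production_ps=8.0, seed=4)
        traj = md.nve_production(model, state, cfg)
        dac = sp.ft_dac(sp.dipole_from_trajectory(traj))
        nuac = {
            "soft stretch": ch.ft_nuac(
                ch.internal_series(
                    traj, ch.InternalCoordinateSpec("distance", (0, 1))
                ),
                traj.dt_fs,
            ),
            "stiff stretch": ch.ft_nuac(
                ch.internal_series(
                    traj, ch.InternalCoordinateSpec("distance", (2, 3))
                ),
                traj.dt_fs,
            ),
        }
        table = ch.assign_peaks(dac, nuac, tolerance_cm1=50.0,
                                band=(600.0, 3600.0), prominence_frac=0.10)
        assigned = table.dropna(subset=["assignment"])
        got = {
            row["assignment"]
            for _, row in assigned.iterrows()
        }
        assert {"soft stretch", "stiff stretch"} <= got
        for _, row in assigned.iterrows():
            if row["wavenumber_cm1"] < 2000:
                assert row["assignment"] == "soft stretch"
            else:
                assert row["assignment"] == "stiff stretch"

    def test_zero_tolerance_assigns_only_exact_coincidences(self):
        g = np.linspace(0.0, 4000.0, 4001)
        y = np.exp(-0.5 * ((g - 1000.0) / 8.0) ** 2)
        dac = sp.Spectrum(g, y)
        same = sp.Spectrum(g, y.copy())
        shifted = sp.Spectrum(g, np.exp(-0.5 * ((g - 1005.0) / 8.0) ** 2))
        t_same = ch.assign_peaks(dac, {"x": same}, tolerance_cm1=0.0)
        assert t_same["assignment"].iloc[0] == "x"
        t_shift = ch.assign_peaks(dac, {"x": shifted}, tolerance_cm1=0.0)
        assert t_shift["assignment"].iloc[0] is None

    def test_single_mode_single_assignment(self):
        model, traj = _diatomic_trajectory(wn=1500.0, production_ps=4.0)
        dac = sp.ft_dac(sp.dipole_from_trajectory(traj))
        series = ch.internal_series(
            traj, ch.InternalCoordinateSpec("distance", (0, 1))
        )
        table = ch.assign_peaks(
            dac, {"stretch": ch.ft_nuac(series, traj.dt_fs)},
            band=(1000.0, 2000.0), prominence_frac=0.2,
        )
        assert len(table) >= 1
        assert (table["assignment"] == "stretch").all()


class TestHistograms:
    def test_static_geometry_single_occupied_bin(self):
        traj = md.Trajectory(
            positions=np.repeat(
                np.array([[[0.0, 0, 0], [2.8, 0, 0]]]), 100, axis=0
            ),
            charges=np.zeros((100, 2)),
            times_fs=np.arange(100.0),
            dt_fs=0.5,
        )
        (h,) = ch.distance_histograms(
            traj, [ch.InternalCoordinateSpec("distance", (0, 1), "pair")]
        )
        assert (h.density > 0).sum() == 1
        assert not h.bimodal

    def test_density_normalized(self, rng):
        n = 2000
        pos = np.zeros((n, 2, 3))
        pos[:, 1, 0] = 3.0 + 0.2 * rng.standard_normal(n)
        traj = md.Trajectory(
            positions=pos, charges=np.zeros((n, 2)),
            times_fs=np.arange(float(n)), dt_fs=0.5,
        )
        (h,) = ch.distance_histograms(
            traj, [ch.InternalCoordinateSpec("distance", (0, 1), "pair")]
        )
        assert abs(np.sum(h.density) * h.bin_width - 1.0) < 1e-12

    def test_mixture_flags_bimodal_with_mode_locations(self, rng):
        n = 4000
        r = np.where(
            rng.random(n) < 0.5,
            rng.normal(2.8, 0.05, n),
            rng.normal(4.5, 0.05, n),
        )
        pos = np.zeros((n, 2, 3))
        pos[:, 1, 0] = r
        traj = md.Trajectory(
            positions=pos, charges=np.zeros((n, 2)),
            times_fs=np.arange(float(n)), dt_fs=0.5,
        )
        (h,) = ch.distance_histograms(
            traj, [ch.InternalCoordinateSpec("distance", (0, 1), "mix")],
            bin_width=0.02,
        )
        assert h.bimodal
        assert len(h.modes) == 2
        assert abs(h.modes[0] - 2.8) < 0.05
        assert abs(h.modes[1] - 4.5) < 0.05

    def test_unimodal_not_flagged(self, rng):
        n = 4000
        pos = np.zeros((n, 2, 3))
        pos[:, 1, 0] = rng.normal(3.0, 0.1, n)
        traj = md.Trajectory(
            positions=pos, charges=np.zeros((n, 2)),
            times_fs=np.arange(float(n)), dt_fs=0.5,
        )
        (h,) = ch.distance_histograms(
            traj, [ch.InternalCoordinateSpec("distance", (0, 1), "uni")]
        )
        assert not h.bimodal

    def test_empty_trajectory_rejected(self):
        traj = md.Trajectory(
            positions=np.zeros((0, 2, 3)), charges=np.zeros((0, 2)),
            times_fs=np.zeros(0), dt_fs=0.5,
        )
        with pytest.raises(ValueError, match="empty"):
            ch.distance_histograms(
                traj, [ch.InternalCoordinateSpec("distance", (0, 1))]
            )
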