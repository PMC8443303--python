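"""Umbrella windows, WHAM reconstruction, basins and saddles."""

import numpy as np
import pytest

from ringspec import units, wham


@pytest.fixture(scope="module")
def sampled_two_well():
    """Biased Langevin samples of U = 2(1-cos t1) + (1-cos 2 t2) on a
    15-degree window grid (module-scoped: several tests reuse it)."""
    surf = wham.PeriodicSurface([(2.0, 1, 0, 0.0), (1.0, 0, 2, 0.0)])
    windows = wham.generate_windows(
        spacing_deg=15.0, bias="cosine", constants=(20.0, 20.0), length_ps=4.0
    )
    windows = wham.sample_surface_umbrella(surf, windows, 300.0, seed=21)
    return surf, windows


class TestWindows:
    def test_full_grid_counts(self):
        assert len(wham.generate_windows(5.0)) == 72 * 72
        assert len(wham.generate_windows(90.0)) == 16

    def test_protocol_bias_constants_accepted_verbatim(self):
        """The reference constants: cosine 75/65 kcal/mol at 100 K,
        150/125 at 298.15 K; harmonic 200 kJ/mol (degrees form)."""
        for consts in [(75.0, 65.0), (150.0, 125.0)]:
            w = wham.UmbrellaWindow((0.0, 0.0), "cosine", consts)
            # cosine form: E = k (1 - cos(theta - theta0)), theta in rad
            e = w.bias_energy(np.array([90.0, 0.0]))
            assert e == pytest.approx(consts[0] * 1.0)
        w = wham.UmbrellaWindow((0.0, 0.0), "harmonic", (200.0, 200.0))
        # harmonic form: E = 1/2 K (theta-theta0)^2, theta in degrees
        e = w.bias_energy(np.array([1.0, 0.0]))
        assert e == pytest.approx(0.5 * 200.0 * units.KJ_TO_KCAL)

    def test_bias_energy_is_periodic(self):
        w = wham.UmbrellaWindow((170.0, 0.0), "harmonic", (3.0, 3.0))
        # -175 deg is 15 deg from +170 across the seam
        e_seam = w.bias_energy(np.array([-175.0, 0.0]))
        e_near = w.bias_energy(np.array([185.0, 0.0]))
        assert e_seam == pytest.approx(e_near)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(wham.WHAMError):
            wham.generate_windows(-5.0)
        with pytest.raises(wham.WHAMError):
            wham.generate_windows(7.0)  # does not divide 360

    def test_negative_constants_rejected(self):
        with pytest.raises(wham.WHAMError):
            wham.UmbrellaWindow((0.0, 0.0), "cosine", (-1.0, 1.0))


class TestSampling:
    def test_stiff_spring_collapses_onto_center(self):
        surf = wham.PeriodicSurface([(1.0, 1, 0, 0.0)])
        windows = [
            wham.UmbrellaWindow((45.0, -60.0), "cosine", (5000.0, 5000.0),
                                length_ps=2.0)
        ]
        (w,) = wham.sample_surface_umbrella(surf, windows, 300.0, seed=2)
        assert np.abs(w.samples - np.array([45.0, -60.0])).std(axis=0).max() < 1.0
        assert np.abs(w.samples.mean(axis=0) - np.array([45.0, -60.0])).max() < 1.0

    def test_zero_bias_flat_potential_samples_uniformly(self):
        surf = wham.PeriodicSurface([])
        windows = [
            wham.UmbrellaWindow((0.0, 0.0), "cosine", (0.0, 0.0),
                                length_ps=200.0)
        ]
        (w,) = wham.sample_surface_umbrella(
            surf, windows, 300.0, seed=3, friction_fs=0.02,
            inertia_amuA2=0.25,
        )
        # coarse uniformity check on 8 bins per coordinate
        for c in range(2):
            h, _ = np.histogram(w.samples[:, c], bins=8, range=(-180, 180))
            expected = len(w.samples) / 8
            assert (h > 0.6 * expected).all() and (h < 1.4 * expected).all()


class TestWHAM:
    def test_single_unbiased_window_equals_direct_histogram(self):
        """WHAM with one zero-bias window is -kT ln(histogram) + const."""
        rng = np.random.default_rng(8)
        samples = np.column_stack(
            [rng.normal(0.0, 40.0, 20000), rng.normal(0.0, 40.0, 20000)]
        )
        w = wham.UmbrellaWindow((0.0, 0.0), "cosine", (0.0, 0.0), samples=samples)
        pmf = wham.wham_2d([w], 300.0, bin_width_deg=15.0)
        kT = units.KB_KCALMOL * 300.0
        h, _, _ = np.histogram2d(
            samples[:, 0], samples[:, 1],
            bins=[np.arange(-180, 181, 15.0)] * 2,
        )
        direct = -kT * np.log(np.where(h > 0, h, np.nan))
        direct -= np.nanmin(np.where(pmf.mask, direct, np.nan))
        assert np.allclose(
            pmf.free_energy[pmf.mask], direct[pmf.mask], atol=1e-9
        )

    def test_window_order_invariance(self, sampled_two_well):
        _, windows = sampled_two_well
        a = wham.wham_2d(windows, 300.0, bin_width_deg=15.0, tolerance=1e-12)
        b = wham.wham_2d(
            windows[::-1], 300.0, bin_width_deg=15.0, tolerance=1e-12
        )
        assert np.abs(a.free_energy[a.mask] - b.free_energy[b.mask]).max() < 1e-10

    def test_periodicity_shift_invariance(self, sampled_two_well):
        from dataclasses import replace

        _, windows = sampled_two_well
        a = wham.wham_2d(windows, 300.0, bin_width_deg=15.0)
        shifted = [replace(w, samples=w.samples + 360.0) for w in windows]
        b = wham.wham_2d(shifted, 300.0, bin_width_deg=15.0)
        assert np.abs(a.free_energy[a.mask] - b.free_energy[b.mask]).max() < 1e-12

    def test_reconstruction_matches_closed_form(self, sampled_two_well):
        surf, windows = sampled_two_well
        pmf = wham.wham_2d(windows, 300.0, bin_width_deg=15.0)
        T1, T2 = np.meshgrid(pmf.theta1_deg, pmf.theta2_deg, indexing="ij")
        U = surf.energy_deg(T1, T2)
        U = U - U[pmf.mask].min()
        err = np.abs(pmf.free_energy - U)[pmf.mask]
        assert err.max() < 0.3  # kcal/mol, a few standard errors
        assert np.sqrt((err**2).mean()) < 0.1

    def test_no_samples_rejected(self):
        w = wham.UmbrellaWindow((0.0, 0.0))
        with pytest.raises(wham.WHAMError, match="sample"):
            wham.wham_2d([w], 300.0)


class TestConvergence:
    def test_duplicated_halves_give_zero(self, sampled_two_well):
        from dataclasses import replace

        _, windows = sampled_two_well
        dup = [
            replace(w, samples=np.concatenate([w.samples, w.samples]))
            for w in windows
        ]
        max_diff, diff = wham.pmf_convergence(dup, 300.0, bin_width_deg=15.0)
        assert max_diff < 1e-9

    def test_adequate_sampling_converges_below_threshold(self, sampled_two_well):
        _, windows = sampled_two_well
        max_diff, _ = wham.pmf_convergence(windows, 300.0, bin_width_deg=15.0)
        assert max_diff < 0.5  # kcal/mol at desk sampling

    def test_undersampled_negative_control_flagged(self, sampled_two_well):
        """Truncating every window to a handful of samples must blow up
        the first/last-half diagnostic relative to the converged run."""
        from dataclasses import replace

        _, windows = sampled_two_well
        starved = [replace(w, samples=w.samples[:24]) for w in windows]
        bad, _ = wham.pmf_convergence(
            starved, 300.0, bin_width_deg=15.0, min_count=1
        )
        good, _ = wham.pmf_convergence(windows, 300.0, bin_width_deg=15.0)
        assert bad > 3 * good


class TestBasinsAndSaddles:
    def test_two_well_surface_barriers_match_closed_form(self, sampled_two_well):
        """U = 2(1-cos t1) + (1-cos 2 t2): two equal basins at t2 = 0 and
        180, separated by a 2 kcal/mol saddle at t2 = +-90."""
        _, windows = sampled_two_well
        pmf = wham.wham_2d(windows, 300.0, bin_width_deg=15.0)
        table = wham.basins_and_saddles(pmf)
        minima = table[table["kind"] == "minimum"]
        saddles = table[table["kind"] == "saddle"]
        assert len(minima) == 2
        assert minima["dG_kcalmol"].max() < 0.25
        assert len(saddles) == 1
        # the closed-form saddle is 2.0; the grid reports the energy of
        # the merging cell's center (1.93..2.0 across the cell) plus
        # sampling error
        assert saddles["dG_kcalmol"].iloc[0] == pytest.approx(2.0, abs=0.35)

    def test_saddle_symmetric_under_basin_swap(self, sampled_two_well):
        """The minimax definition gives TS(A->B) = TS(B->A); flipping the
        surface axes must not change the saddle height."""
        _, windows = sampled_two_well
        pmf = wham.wham_2d(windows, 300.0, bin_width_deg=15.0)
        t = wham.basins_and_saddles(pmf)
        s1 = t[t["kind"] == "saddle"]["dG_kcalmol"].iloc[0]
        flipped = wham.PMFSurface(
            theta1_deg=pmf.theta1_deg,
            theta2_deg=pmf.theta2_deg,
            free_energy=pmf.free_energy[::-1, ::-1].copy(),
            mask=pmf.mask[::-1, ::-1].copy(),
            temperature_K=pmf.temperature_K,
        )
        t2 = wham.basins_and_saddles(flipped)
        s2 = t2[t2["kind"] == "saddle"]["dG_kcalmol"].iloc[0]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_single_well_has_no_saddles(self):
        g = np.arange(-180.0, 180.0, 30.0)
        T1, T2 = np.meshgrid(g, g, indexing="ij")
        F = 2.0 * (1 - np.cos(np.deg2rad(T1))) + 2.0 * (1 - np.cos(np.deg2rad(T2)))
        pmf = wham.PMFSurface(g, g.copy(), F - F.min(),
                              np.ones_like(F, bool), 300.0)
        table = wham.basins_and_saddles(pmf)
        assert (table["kind"] == "minimum").sum() == 1
        assert (table["kind"] == "saddle").sum() == 0


class TestMolecularUmbrella:
    def test_toy_serine_windows_sample_near_centers(self, toy_serine):
        """Smoke-scale biased MD on the molecular model: strongly biased
        windows stay near their centers and WHAM runs through."""
        windows = wham.generate_windows(
            spacing_deg=90.0, bias="cosine", constants=(40.0, 40.0),
            length_ps=1.0,
        )
        out = wham.run_umbrella(
            toy_serine, windows, engine="classical", temperature_K=200.0,
            equilibration_ps=0.5, seed=13,
        )
        for w in out:
            d = np.abs(
                np.rad2deg(
                    np.deg2rad(w.samples - np.asarray(w.centers_deg) + 180.0)
                    % (2 * np.pi)
                )
            )
        pmf = wham.wham_2d(out, 200.0, bin_width_deg=90.0, min_count=5)
        assert pmf.mask.any()

    def test_trpmd_umbrella_biases_centroid(self, toy_serine):
        windows = [
            wham.UmbrellaWindow((-35.0, 55.0), "harmonic", (3.0, 3.0),
                                length_ps=0.3)
        ]
        out = wham.run_umbrella(
            toy_serine, windows, engine="trpmd", temperature_K=200.0,
            equilibration_ps=0.2, seed=14, n_beads=4,
        )
        (w,) = out
        d = np.abs(w.samples - np.array([-35.0, 55.0]))
        assert d.mean() < 45.0  # stays in the basin's neighborhood
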