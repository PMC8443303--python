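"""IR spectra from dipole autocorrelation functions (FT-DAC).

Pipeline, in the order a spectrum is produced:

1. ``dipole_from_trajectory`` — mu(t) = sum_i q_i(t) r_i(t) from a
   classical trajectory carrying per-atom charges; or
   ``bead_average_dipole`` — mu(t) = (1/n_beads) sum_j mu_j(t) from a
   bead-resolved TRPMD record.
2. ``ft_dac`` — the classical lineshape I_cl(omega): autocorrelation of
   the mean-removed dipole (dot product over x, y, z, FFT-based,
   unbiased overlap normalization), apodized (Hann by default) and
   cosine-transformed onto a wavenumber grid.
3. ``apply_quantum_correction`` — the absorption prefactor. The full
   coefficient is alpha(omega) ∝ omega (1 - e^{-beta hbar omega})
   Q(omega) I_cl(omega); with the harmonic correction
   Q_HC = beta hbar omega / (1 - e^{-beta hbar omega}) this collapses
   to omega * beta hbar omega * I_cl exactly. Classical spectra use
   mode="harmonic"; TRPMD spectra use mode="none" (no extra empirical
   correction), i.e. the bare omega (1 - e^{-beta hbar omega}) factor.
   The constant 4 pi^2/(3 V hbar c n(omega)) prefactor is absorbed by
   the normalization and never evaluated.
4. ``normalize_spectrum`` — maximal intensity in 600-3600 cm^-1 set
   to 1.0.
5. ``average_replicas`` — per-bin mean and population standard
   deviation across an ensemble (the shaded-band statistic), averaged
   first and normalized after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .md import Trajectory
from .ringpolymer import BeadTrajectory

__all__ = [
    "DipoleSeries",
    "Spectrum",
    "SpectrumError",
    "dipole_from_trajectory",
    "bead_average_dipole",
    "ft_dac",
    "quantum_correction_factor",
    "apply_quantum_correction",
    "normalize_spectrum",
    "average_replicas",
    "spectral_power_sum",
    "NORMALIZATION_BAND",
]

#: the normalization band (cm^-1): max intensity here is set to 1.0
NORMALIZATION_BAND = (600.0, 3600.0)

MIN_SERIES_LENGTH = 64


class SpectrumError(ValueError):
    """Invalid input to a spectral estimator."""


@dataclass
class DipoleSeries:
    """A dipole time series mu(t) in e*A at fixed timestep."""

    values: np.ndarray  # (n_frames, 3)
    dt_fs: float
    source: str = "classical"  # "classical" | "bead-averaged"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise SpectrumError("dipole series must have shape (n_frames, 3)")
        if len(self.values) < 2:
            raise SpectrumError("dipole series needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise SpectrumError("dipole series contains non-finite values")
        if self.dt_fs <= 0:
            raise SpectrumError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class Spectrum:
    """Intensity on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers_cm1: np.ndarray
    intensity: np.ndarray
    std: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers_cm1 = np.asarray(self.wavenumbers_cm1, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.wavenumbers_cm1.shape != self.intensity.shape:
            raise SpectrumError("grid and intensity shapes differ")
        if np.any(np.diff(self.wavenumbers_cm1) <= 0):
            raise SpectrumError("wavenumber grid must be strictly increasing")

    @property
    def resolution_cm1(self) -> float:
        """Physical resolution c^-1 (N dt)^-1 of the underlying series
        (bin spacing can be finer through zero padding)."""
        return self.provenance.get(
            "resolution_cm1", float(np.diff(self.wavenumbers_cm1).mean())
        )

    def band(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavenumbers in [lo, hi]."""
        m = (self.wavenumbers_cm1 >= lo) & (self.wavenumbers_cm1 <= hi)
        return Spectrum(
            self.wavenumbers_cm1[m],
            self.intensity[m],
            None if self.std is None else self.std[m],
            dict(self.provenance),
        )

    def peak_wavenumber(self, lo: float | None = None, hi: float | None = None) -> float:
        """Wavenumber of the maximum intensity bin (optionally in a band)."""
        s = self if lo is None else self.band(lo, hi)
        return float(s.wavenumbers_cm1[int(np.argmax(s.intensity))])


def dipole_from_trajectory(traj: Trajectory) -> DipoleSeries:
    """Assemble mu(t_k) = sum_i q_i(t_k) r_i(t_k) frame by frame."""
    if traj.charges is None or traj.charges.size == 0:
        raise SpectrumError(
            "trajectory carries no charge column; a dipole needs per-atom "
            "charges recorded at every frame"
        )
    mu = np.sum(traj.charges[..., None] * traj.positions, axis=-2)
    return DipoleSeries(mu, traj.dt_fs, source="classical")


def bead_average_dipole(beads) -> DipoleSeries:
    """Frame-wise mean of per-bead dipoles, mu = (1/n) sum_j mu_j.

    Accepts a `BeadTrajectory` (per-bead dipoles already assembled from
    per-bead charges and geometries) or a list of same-shape classical
    `Trajectory` objects, one per bead.
    """
    if isinstance(beads, BeadTrajectory):
        return DipoleSeries(
            beads.bead_dipoles.mean(axis=1), beads.dt_fs, source="bead-averaged"
        )
    trajs = list(beads)
    if not trajs:
        raise SpectrumError("no bead trajectories given")
    n0, dt0 = trajs[0].n_frames, trajs[0].dt_fs
    for t in trajs[1:]:
        if t.n_frames != n0 or t.dt_fs != dt0:
            raise SpectrumError(
                "ragged bead trajectories: all beads must share frame count "
                "and timestep"
            )
    mus = [dipole_from_trajectory(t).values for t in trajs]
    return DipoleSeries(np.mean(mus, axis=0), dt0, source="bead-averaged")


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Unbiased autocorrelation of a mean-removed (n, d) series,
    summed over the d components: c_k = <x(0).x(k dt)>."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    X = np.fft.rfft(x - x.mean(axis=0), n=nfft, axis=0)
    c = np.fft.irfft((X * X.conj()).real.sum(axis=1), n=nfft)[:n]
    return c / (n - np.arange(n))  # unbiased overlap normalization


def ft_dac(
    series: DipoleSeries,
    window: str = "hann",
    zero_pad: int = 4,
) -> Spectrum:
    """Classical FT-DAC lineshape I_cl on a wavenumber grid.

    The mean-removed dipole autocorrelation c_k (dot product over
    components, unbiased overlap weights) is apodized and
    cosine-transformed: I(omega) = Re sum_k c_k w_k e^{-i omega k dt},
    evaluated by FFT with ``zero_pad``-fold padding for fine bins. The
    nonnegative-frequency half is returned; the physical resolution
    (c (N dt))^-1 is recorded in the provenance.

    ``window``: "hann" (default; controls leakage of the truncated
    correlation function) or "rect" (bare periodogram; makes the
    Parseval identity exact).
    """
    if series.n_frames < MIN_SERIES_LENGTH:
        raise SpectrumError(
            f"series too short for a spectrum: {series.n_frames} frames "
            f"< minimum {MIN_SERIES_LENGTH}"
        )
    c = _autocorrelation(series.values)
    n = len(c)
    if window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * np.arange(n) / n))
    elif window == "rect":
        w = np.ones(n)
    else:
        raise SpectrumError(f"unknown window {window!r}")
    nfft = 1 << (max(2, zero_pad) * n - 1).bit_length()
    F = np.fft.rfft(c * w, n=nfft)
    intensity = F.real / nfft
    freqs = np.fft.rfftfreq(nfft, d=series.dt_fs)  # cycles/fs
    grid = freqs / units.C_CM_PER_FS  # cm^-1
    return Spectrum(
        grid,
        intensity,
        provenance={
            "estimator": "ft_dac",
            "window": window,
            "zero_pad": zero_pad,
            "nfft": nfft,
            "n_frames": n,
            "dt_fs": series.dt_fs,
            "source": series.source,
            "resolution_cm1": 1.0 / (n * series.dt_fs * units.C_CM_PER_FS),
            "correction": "none-applied",
        },
    )


def spectral_power_sum(spectrum: Spectrum) -> float:
    """Total power of a raw FT-DAC spectrum over the full FFT grid.

    With a rectangular window this equals the lag-0 autocorrelation
    (the dipole variance) exactly — the discrete Parseval identity.
    Negative-frequency bins are counted via Hermitian symmetry.
    """
    nfft = spectrum.provenance["nfft"]
    I = spectrum.intensity
    tot = I[0] + 2.0 * I[1:-1].sum()
    tot += I[-1] if nfft % 2 == 0 else 2.0 * I[-1]
    return float(tot)


def quantum_correction_factor(
    wavenumbers_cm1: np.ndarray, temperature_K: float, mode: str = "harmonic"
) -> np.ndarray:
    """The omega-dependent absorption prefactor applied to I_cl.

    mode="harmonic": omega * beta hbar omega — the full prefactor with
    the harmonic correction Q_HC folded in, using the identity
    (1 - e^{-beta hbar omega}) * Q_HC(omega) = beta hbar omega.
    mode="none": omega * (1 - e^{-beta hbar omega}) — the bare
    prefactor with Q = 1 (the TRPMD default).
    """
    nu = np.asarray(wavenumbers_cm1, float)
    if np.any(nu < 0):
        raise SpectrumError("negative wavenumbers are not physical here")
    w = 2.0 * math.pi * units.C_CM_PER_FS * nu  # rad/fs
    bhw = units.beta_kcalmol(temperature_K) * units.HBAR_KCALMOL_FS * w
    if mode == "harmonic":
        return w * bhw
    if mode == "none":
        return w * -np.expm1(-bhw)
    raise SpectrumError(f"unknown correction mode {mode!r}")


def harmonic_correction_QHC(
    wavenumbers_cm1: np.ndarray, temperature_K: float
) -> np.ndarray:
    """Q_HC = beta hbar omega / (1 - e^{-beta hbar omega}); -> 1 as
    omega -> 0."""
    nu = np.asarray(wavenumbers_cm1, float)
    w = 2.0 * math.pi * units.C_CM_PER_FS * nu
    bhw = units.beta_kcalmol(temperature_K) * units.HBAR_KCALMOL_FS * w
    out = np.ones_like(bhw)
    nz = bhw != 0
    out[nz] = bhw[nz] / (-np.expm1(-bhw[nz]))
    return out


def apply_quantum_correction(
    spectrum: Spectrum, temperature_K: float, mode: str = "harmonic"
) -> Spectrum:
    """Multiply a raw I_cl spectrum by the absorption prefactor.

    Clips tiny negative excursions of the windowed estimator to zero so
    the corrected intensity is nonnegative.
    """
    if temperature_K <= 0:
        raise SpectrumError("temperature must be positive")
    factor = quantum_correction_factor(spectrum.wavenumbers_cm1, temperature_K, mode)
    intensity = np.clip(spectrum.intensity, 0.0, None) * factor
    prov = dict(spectrum.provenance)
    prov["correction"] = "Q_HC" if mode == "harmonic" else "none"
    prov["temperature_K"] = temperature_K
    return Spectrum(
        spectrum.wavenumbers_cm1.copy(),
        intensity,
        None if spectrum.std is None else spectrum.std * factor,
        prov,
    )


def normalize_spectrum(
    spectrum: Spectrum, band: tuple[float, float] = NORMALIZATION_BAND
) -> Spectrum:
    """Set the maximal intensity in ``band`` (default 600-3600 cm^-1)
    to 1.0; out-of-band intensity may exceed 1 afterwards."""
    lo, hi = band
    g = spectrum.wavenumbers_cm1
    if g[0] > lo or g[-1] < hi:
        raise SpectrumError(
            f"grid [{g[0]:.1f}, {g[-1]:.1f}] cm^-1 does not cover the "
            f"normalization band [{lo}, {hi}]"
        )
    m = (g >= lo) & (g <= hi)
    peak = float(spectrum.intensity[m].max())
    if peak <= 0:
        raise SpectrumError("all-zero spectrum in the normalization band")
    prov = dict(spectrum.provenance)
    prov["normalized"] = True
    prov["normalization_band_cm1"] = [lo, hi]
    return Spectrum(
        g.copy(),
        spectrum.intensity / peak,
        None if spectrum.std is None else spectrum.std / peak,
        prov,
    )


def average_replicas(
    spectra: list[Spectrum],
    normalize: bool = True,
    band: tuple[float, float] = NORMALIZATION_BAND,
) -> Spectrum:
    """Per-bin mean and population standard deviation across replicas.

    Averaging precedes normalization (matching the shaded-band
    presentation); pass ``normalize=False`` to skip the final step.
    """
    if not spectra:
        raise SpectrumError("no replica spectra given")
    g0 = spectra[0].wavenumbers_cm1
    for s in spectra[1:]:
        if s.wavenumbers_cm1.shape != g0.shape or not np.allclose(
            s.wavenumbers_cm1, g0
        ):
            raise SpectrumError("replica spectra are on mismatched grids")
    stack = np.stack([s.intensity for s in spectra])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)  # population std
    prov = dict(spectra[0].provenance)
    prov["n_replicas"] = len(spectra)
    out = Spectrum(g0.copy(), mean, std, prov)
    return normalize_spectrum(out, band) if normalize else out
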