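"""Spectral peak assignment and structural histograms.

FT-DAC bands carry no mode labels. The localized-mode power spectrum
(FT-nu_N AC) recovers them: for each candidate internal coordinate
(a bond length for a stretch, an angle or dihedral for bends and
torsions) the scalar time series nu_N(t) is extracted from the
trajectory, and the Fourier transform of its autocorrelation places
that mode's frequencies. Peak positions are meaningful; intensities
are not (the coordinate is not a dipole), so assignment matches peak
locations only: each FT-DAC peak above a prominence threshold is
labeled by the internal coordinate with the nearest FT-nu_N AC peak
within a tolerance.

Interatomic distance histograms complement the assignment: a bond or
contact distributed in two populations (e.g. an H-bond donor-acceptor
distance sampling two conformers) flags conformational heterogeneity.
Bimodality is decided by a two- vs one-component Gaussian mixture BIC
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import geometry
from .md import Trajectory
from .ringpolymer import BeadTrajectory
from .spectra import DipoleSeries, Spectrum, SpectrumError, ft_dac

__all__ = [
    "InternalCoordinateSpec",
    "DistanceHistogram",
    "internal_series",
    "ft_nuac",
    "find_spectral_peaks",
    "assign_peaks",
    "distance_histograms",
]


@dataclass(frozen=True)
class InternalCoordinateSpec:
    """One internal coordinate: distance (2 atoms), angle (3) or
    dihedral (4), with a human label like "O-H stretch"."""

    kind: str
    atoms: tuple[int, ...]
    label: str = ""

    _REQUIRED = {"distance": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self):
        if self.kind not in self._REQUIRED:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        need = self._REQUIRED[self.kind]
        if len(self.atoms) != need:
            raise ValueError(
                f"{self.kind} coordinate needs {need} atoms, got {len(self.atoms)}"
            )


def _positions_of(traj, use: str) -> np.ndarray:
    """Frame-wise positions; bead-resolved records reduce to the
    centroid geometry by default (the RPMD physical observable), or to
    per-bead geometries with use="beads"."""
    if isinstance(traj, BeadTrajectory):
        if use == "centroid":
            return traj.centroid_positions
        if use == "beads":
            if traj.bead_positions is None:
                raise ValueError(
                    "bead-resolved positions were not stored in this trajectory"
                )
            return traj.bead_positions
        raise ValueError("use must be 'centroid' or 'beads'")
    return traj.positions


def internal_series(
    traj, spec: InternalCoordinateSpec, use: str = "centroid"
) -> np.ndarray:
    """Per-frame scalar value of the coordinate (A, or radians).

    Dihedral series are unwrapped on the circle so that a torsion
    drifting through +-180 deg stays continuous.
    """
    pos = _positions_of(traj, use)
    n = pos.shape[-2]
    if any(not (0 <= a < n) for a in spec.atoms):
        raise ValueError(f"coordinate atoms {spec.atoms} out of range for {n} atoms")
    idx = np.array([list(spec.atoms)])
    if spec.kind == "distance":
        return geometry.distances(pos, idx)[..., 0]
    if spec.kind == "angle":
        return geometry.angles(pos, idx)[..., 0]
    phi = geometry.dihedrals(pos, idx)[..., 0]
    return np.unwrap(phi, axis=0)


def ft_nuac(
    series: np.ndarray, dt_fs: float, window: str = "hann", zero_pad: int = 4
) -> Spectrum:
    """Power spectrum of a scalar internal-coordinate series.

    The same estimator as `ft_dac` applied to the mean-removed scalar
    autocovariance. Peak locations are the observable; intensities
    carry no absorption meaning.
    """
    x = np.asarray(series, float)
    if x.ndim != 1:
        raise SpectrumError("internal-coordinate series must be scalar")
    vec = np.zeros((len(x), 3))
    vec[:, 0] = x
    spec = ft_dac(DipoleSeries(vec, dt_fs, source="internal"), window, zero_pad)
    spec.provenance["estimator"] = "ft_nuac"
    return spec


def find_spectral_peaks(
    spectrum: Spectrum,
    band: tuple[float, float] = (600.0, 3600.0),
    prominence_frac: float = 0.05,
    smooth_bins: int = 0,
    min_intensity: float = 1e-20,
) -> pd.DataFrame:
    """Local maxima above ``prominence_frac`` of the in-band maximum.

    Returns a DataFrame with wavenumber_cm1, intensity and prominence,
    sorted by wavenumber; empty for a flat or all-zero band (anything
    below ``min_intensity``, which screens out the round-off spectrum
    of a constant series).
    """
    s = spectrum.band(*band)
    y = s.intensity.copy()
    if smooth_bins and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(y, kernel, mode="same")
    top = y.max(initial=0.0)
    if top <= min_intensity or not np.isfinite(top):
        return pd.DataFrame(columns=["wavenumber_cm1", "intensity", "prominence"])
    idx, props = find_peaks(y, prominence=prominence_frac * top)
    return pd.DataFrame(
        {
            "wavenumber_cm1": s.wavenumbers_cm1[idx],
            "intensity": y[idx],
            "prominence": props["prominences"],
        }
    )


def assign_peaks(
    full_spectrum: Spectrum,
    nuac_spectra: dict[str, Spectrum],
    tolerance_cm1: float = 30.0,
    band: tuple[float, float] = (600.0, 3600.0),
    prominence_frac: float = 0.05,
) -> pd.DataFrame:
    """Label FT-DAC peaks by the nearest localized-mode peak.

    For every FT-DAC peak above the prominence threshold, the
    FT-nu_N AC spectra are searched for their dominant peaks; the
    coordinate whose peak lies nearest within ``tolerance_cm1`` wins.
    Unassigned peaks keep ``assignment = None`` — an empty assignment
    is allowed, a missing peak is not invented.
    """
    peaks = find_spectral_peaks(full_spectrum, band, prominence_frac)
    coord_peaks: list[tuple[str, float]] = []
    for label, sp in nuac_spectra.items():
        cp = find_spectral_peaks(sp, band, prominence_frac)
        coord_peaks.extend((label, w) for w in cp["wavenumber_cm1"])
    rows = []
    for _, pk in peaks.iterrows():
        best_label, best_pos, best_off = None, np.nan, np.inf
        for label, w in coord_peaks:
            off = abs(w - pk["wavenumber_cm1"])
            if off < best_off:
                best_label, best_pos, best_off = label, w, off
        if best_label is not None and best_off <= tolerance_cm1:
            rows.append(
                (pk["wavenumber_cm1"], pk["intensity"], best_label, best_pos, best_off)
            )
        else:
            rows.append((pk["wavenumber_cm1"], pk["intensity"], None, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=[
            "wavenumber_cm1",
            "intensity",
            "assignment",
            "coordinate_peak_cm1",
            "offset_cm1",
        ],
    )


@dataclass
class DistanceHistogram:
    """Normalized density of an interatomic distance with a two-
    population (bimodality) flag."""

    bin_edges: np.ndarray  # (n_bins + 1,), A
    density: np.ndarray  # (n_bins,), integrates to 1
    label: str
    mean: float
    modes: tuple[float, ...]  # component means if bimodal, else the mode
    bimodal: bool

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


#: BIC margin (nats) the 2-component mixture must win by
_BIC_MARGIN = 10.0


def _bimodality(x: np.ndarray) -> tuple[bool, tuple[float, ...]]:
    """Two- vs one-component Gaussian mixture by BIC.

    The two-component model must beat the single Gaussian by a BIC
    margin and keep both weights above 10% and means separated by more
    than the pooled component width — guards against a heavy tail
    masquerading as a second population.
    """
    from sklearn.mixture import GaussianMixture

    X = x.reshape(-1, 1)
    if len(x) < 50 or np.std(x) < 1e-12:
        return False, (float(np.mean(x)),)
    g1 = GaussianMixture(1, random_state=0).fit(X)
    g2 = GaussianMixture(2, random_state=0, n_init=3).fit(X)
    if g2.bic(X) < g1.bic(X) - _BIC_MARGIN:
        w = g2.weights_
        mu = g2.means_.ravel()
        sig = np.sqrt(g2.covariances_.ravel())
        sep = abs(mu[0] - mu[1]) > np.hypot(sig[0], sig[1])
        if w.min() > 0.10 and sep:
            order = np.argsort(mu)
            return True, tuple(float(m) for m in mu[order])
    return False, (float(np.mean(x)),)


def distance_histograms(
    traj,
    pair_specs: list[InternalCoordinateSpec],
    bin_width: float = 0.01,
    use: str = "centroid",
) -> list[DistanceHistogram]:
    """Normalized histograms of interatomic distances with bimodality
    detection; density integrates to one."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pos = _positions_of(traj, use)
    if pos.shape[0] == 0:
        raise ValueError("empty trajectory")
    out = []
    for spec in pair_specs:
        if spec.kind != "distance":
            raise ValueError("distance histograms need distance coordinates")
        r = internal_series(traj, spec, use=use).ravel()
        lo = np.floor(r.min() / bin_width) * bin_width - bin_width
        hi = np.ceil(r.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        dens, edges = np.histogram(r, bins=edges, density=True)
        bimodal, modes = _bimodality(r)
        out.append(
            DistanceHistogram(
                bin_edges=edges,
                density=dens,
                label=spec.label or f"{spec.atoms}",
                mean=float(r.mean()),
                modes=modes,
                bimodal=bimodal,
            )
        )
    return out
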