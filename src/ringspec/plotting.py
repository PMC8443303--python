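"""Report figures: spectra with shaded replica bands, localized-mode
overlays, distance histograms and PMF contours."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectra import Spectrum
from .wham import PMFSurface

__all__ = ["plot_spectrum", "plot_comparison", "plot_histograms", "plot_pmf"]


def plot_spectrum(ax, spectrum: Spectrum, color="C0", label=None, band=None):
    g, y = spectrum.wavenumbers_cm1, spectrum.intensity
    if band is not None:
        m = (g >= band[0]) & (g <= band[1])
        g, y = g[m], y[m]
        s = spectrum.std[m] if spectrum.std is not None else None
    else:
        s = spectrum.std
    ax.plot(g, y, color=color, lw=1.0, label=label)
    if s is not None:
        ax.fill_between(g, np.clip(y - s, 0, None), y + s, color=color, alpha=0.25)
    ax.set_xlabel(r"wavenumber (cm$^{-1}$)")
    ax.set_ylabel("normalized intensity")


def plot_comparison(results, path, band=(600.0, 3600.0)):
    """Panels of classical (blue) vs TRPMD (red) spectra per
    temperature, shaded by the across-replica standard deviation."""
    temps = sorted(results)
    fig, axes = plt.subplots(
        len(temps), 1, figsize=(7.0, 3.0 * len(temps)), squeeze=False
    )
    for ax, T in zip(axes[:, 0], temps):
        plot_spectrum(ax, results[T]["classical"]["spectrum"], "C0",
                      f"classical {T:g} K", band)
        plot_spectrum(ax, results[T]["trpmd"]["spectrum"], "C3",
                      f"TRPMD {T:g} K", band)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_histograms(histograms, path):
    fig, axes = plt.subplots(
        1, len(histograms), figsize=(3.0 * len(histograms), 2.6), squeeze=False
    )
    for ax, h in zip(axes[0], histograms):
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        ax.fill_between(centers, h.density, step="mid", alpha=0.6)
        ax.set_title(f"{h.label}" + (" (bimodal)" if h.bimodal else ""), fontsize=9)
        ax.set_xlabel("distance (A)")
    axes[0, 0].set_ylabel("density (1/A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pmf(pmf: PMFSurface, path, vmax=10.0):
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    F = np.where(pmf.mask, pmf.free_energy, np.nan)
    m = ax.contourf(
        pmf.theta1_deg, pmf.theta2_deg, F.T, levels=np.linspace(0, vmax, 21),
        cmap="viridis", extend="max",
    )
    fig.colorbar(m, ax=ax, label="G (kcal/mol)")
    ax.set_xlabel(r"$\theta_1$ (deg)")
    ax.set_ylabel(r"$\theta_2$ (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
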