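"""End-to-end orchestration: model -> dynamics -> spectra -> analysis.

These functions wire the modules together the way the command-line
interface (and the test suite) consume them: resolve a preset, run the
engine, assemble dipoles, apply the correct absorption prefactor for
the engine (harmonic quantum correction for classical MD, none for
TRPMD), normalize, and characterize peaks with localized-mode spectra
and distance histograms.
"""

from __future__ import annotations

from pathlib import Path

from . import config as cfg
from . import io as rio
from . import md, model as mdl, ringpolymer as rpmd, spectra as sp
from .characterization import (
    InternalCoordinateSpec,
    assign_peaks,
    distance_histograms,
    ft_nuac,
    internal_series,
)

__all__ = [
    "load_model",
    "stretch_coordinates",
    "hbond_distances",
    "run_classical_spectrum",
    "run_trpmd_spectrum",
    "characterize_spectrum",
    "run_desk_pipeline",
]

STRETCH_BAND = (2600.0, 3600.0)


def load_model(source: str) -> mdl.MolecularModel:
    """Builtin name ("toy-serine", "harmonic", "morse") or a YAML path."""
    if source == "toy-serine":
        return mdl.build_toy_serine()
    if source == "harmonic":
        return mdl.build_harmonic_oscillator(1.0, 3000.0, 1.0)
    if source == "morse":
        return mdl.build_morse_oscillator(1.0, 3000.0)
    return mdl.MolecularModel.from_yaml(source)


def stretch_coordinates(model: mdl.MolecularModel) -> dict[str, InternalCoordinateSpec]:
    """The X-H stretch coordinates of a model, labeled by bond type.

    Selects every bond (harmonic or Morse) joining a heavy atom to a
    hydrogen-mass atom; labels follow the heavy atom element letter in
    the model's atom labels ("O-H stretch", "N-H stretch", ...).
    """
    out: dict[str, InternalCoordinateSpec] = {}
    for t in model.terms:
        if isinstance(t, (mdl.HarmonicBond, mdl.MorseBond)):
            mi, mj = model.masses[t.i], model.masses[t.j]
            if min(mi, mj) < 2.0 <= max(mi, mj):  # an X-H bond
                heavy, hyd = (t.i, t.j) if mi > mj else (t.j, t.i)
                el = model.labels[heavy][0]
                label = f"{el}-H stretch ({model.labels[heavy]}-{model.labels[hyd]})"
                out[label] = InternalCoordinateSpec(
                    "distance", (heavy, hyd), label
                )
    return out


def hbond_distances(model: mdl.MolecularModel) -> list[InternalCoordinateSpec]:
    """Distance coordinates probing the internal H-bond network of the
    serine analog: the hydroxyl bond itself, hydroxyl-carboxylate and
    carboxylate-amine contacts."""
    lab = {name: i for i, name in enumerate(model.labels)}
    pairs = [
        ("OG", "HG", "O-H bond"),
        ("HG", "O2", "HO-OCO"),
        ("O2", "HN2", "OCO-NH2"),
    ]
    out = []
    for a, b, label in pairs:
        if a in lab and b in lab:
            out.append(InternalCoordinateSpec("distance", (lab[a], lab[b]), label))
    return out


def run_classical_spectrum(
    model: mdl.MolecularModel,
    temperature_K: float,
    preset: str = "desk",
    seed: int = 0,
    n_replicas: int | None = None,
):
    """Classical protocol: Langevin equilibration, NVE production,
    FT-DAC with the harmonic quantum correction, replica averaging.

    Returns (trajectories, spectrum); the spectrum is normalized with
    per-bin std across replicas (zero std for a single replica).
    """
    p = cfg.PRESETS[preset]
    if n_replicas is None:
        n_replicas = p["classical"]["n_replicas"]
    trajs, specs = [], []
    for r in range(n_replicas):
        c = cfg.classical_config(temperature_K, preset, seed=seed + 1000 * r)
        state = md.initial_state(model, temperature_K, seed=c.seed)
        state = md.langevin_equilibrate(model, state, c)
        state = md.zero_com_momentum(model, state)
        traj = md.nve_production(model, state, c)
        trajs.append(traj)
        raw = sp.ft_dac(sp.dipole_from_trajectory(traj))
        specs.append(sp.apply_quantum_correction(raw, temperature_K, mode="harmonic"))
    return trajs, sp.average_replicas(specs)


def run_trpmd_spectrum(
    model: mdl.MolecularModel,
    temperature_K: float,
    preset: str = "desk",
    seed: int = 0,
    n_beads: int | None = None,
):
    """TRPMD protocol: thermostated equilibration, snapshot-seeded
    replica ensemble, bead-averaged dipoles, FT-DAC with no extra
    quantum correction (the bare omega(1 - e^{-beta hbar omega})
    prefactor), replica averaging.

    Returns (bead trajectories, spectrum).
    """
    protocol = cfg.trpmd_protocol(temperature_K, preset, seed=seed, n_beads=n_beads)
    ensemble = rpmd.run_trpmd_ensemble(model, protocol)
    specs = []
    for bt in ensemble:
        raw = sp.ft_dac(sp.bead_average_dipole(bt))
        specs.append(sp.apply_quantum_correction(raw, temperature_K, mode="none"))
    return ensemble, sp.average_replicas(specs)


def characterize_spectrum(
    traj,
    spectrum: sp.Spectrum,
    model: mdl.MolecularModel,
    band: tuple[float, float] = STRETCH_BAND,
    tolerance_cm1: float = 40.0,
    prominence_frac: float = 0.05,
):
    """Assign in-band FT-DAC peaks to stretch coordinates (FT-nu_N AC).

    ``traj`` may be classical or bead-resolved (centroid geometry is
    used). Returns (assignment table, {label: localized-mode spectrum}).
    """
    coords = stretch_coordinates(model)
    dt = traj.dt_fs
    nuac = {
        label: ft_nuac(internal_series(traj, spec), dt)
        for label, spec in coords.items()
    }
    table = assign_peaks(
        spectrum, nuac, tolerance_cm1=tolerance_cm1, band=band,
        prominence_frac=prominence_frac,
    )
    return table, nuac


def run_desk_pipeline(
    output_dir: str | Path | None = None,
    seed: int = 0,
    temperatures: tuple[float, ...] = (100.0, 298.15),
    preset: str = "desk",
    model: mdl.MolecularModel | None = None,
):
    """The full comparison at desk scale: classical vs TRPMD spectra at
    each temperature with peak assignment and distance histograms.

    Returns a nested dict
    results[T][engine] = {"spectrum", "assignment", "nuac", "histograms"}
    and, if ``output_dir`` is given, writes TSV/JSON artifacts there.
    """
    model = model or mdl.build_toy_serine()
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        model.to_yaml(out / "model.yaml")
    results: dict = {}
    for ti, T in enumerate(temperatures):
        results[T] = {}
        trajs, cspec = run_classical_spectrum(
            model, T, preset, seed=seed + 10 * ti
        )
        ensemble, qspec = run_trpmd_spectrum(
            model, T, preset, seed=seed + 10 * ti + 5
        )
        for engine, rep_traj, spec in (
            ("classical", trajs[0], cspec),
            ("trpmd", ensemble[0], qspec),
        ):
            table, nuac = characterize_spectrum(rep_traj, spec, model)
            hists = distance_histograms(rep_traj, hbond_distances(model))
            results[T][engine] = {
                "spectrum": spec,
                "assignment": table,
                "nuac": nuac,
                "histograms": hists,
            }
            if out is not None:
                tag = f"{engine}_{T:g}K"
                rio.write_spectrum(spec, out / f"spectrum_{tag}.tsv")
                rio.write_table(
                    table,
                    out / f"assignment_{tag}.tsv",
                    provenance={"temperature_K": T, "engine": engine, "seed": seed},
                )
                rio.write_histograms(hists, out / f"histograms_{tag}.tsv")
    return results
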