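# ringspec

IR spectra from classical and thermostated ring-polymer molecular
dynamics (TRPMD), with localized-mode peak assignment and 2D
umbrella-sampling free-energy surfaces.

## The problem

Gas-phase vibrational spectra of flexible molecules — the worked case
here is a deprotonated-serine analog with an internal hydrogen-bond
network — are routinely computed from molecular dynamics as the
Fourier transform of the dipole autocorrelation function (FT-DAC):

    I_cl(ω) = (1/2π) ∫ e^{-iωt} ⟨μ(0)·μ(t)⟩ dt,      μ = Σᵢ qᵢ rᵢ,

with per-atom charges qᵢ evaluated along the trajectory. Classical
nuclei miss nuclear quantum effects (zero-point energy, tunneling):
the usual patch is the harmonic quantum-correction factor

    Q_HC(ω) = βħω / (1 − e^{-βħω}),

applied to the absorption prefactor ω(1 − e^{-βħω})·Q_HC·I_cl ≡
ω·βħω·I_cl. The alternative is to put the quantum statistics into the
dynamics itself: thermostated ring-polymer MD (TRPMD) propagates
n_beads classical replicas joined by harmonic springs of frequency
ω_n = n/(βħ), thermostats the internal ring modes (PILE: γ_k = 2ω_k;
GLE matrices can be supplied), leaves the centroid Hamiltonian, and
assembles the dipole as the bead average μ = (1/n) Σⱼ μⱼ. Spectral
peaks are then identified by FT-ν_N AC — the power spectrum of each
candidate internal coordinate (bond length, angle, torsion) — and the
conformational landscape over two torsions is mapped by umbrella
sampling with WHAM reweighting.

This package implements that entire pipeline as a library plus CLI:
synthetic molecular models with geometry-dependent charges standing in
for an electronic-structure engine, BAOAB-Langevin/velocity-Verlet
classical dynamics, exact normal-mode ring-polymer propagation, the
spectral estimators, peak assignment, distance histograms, and
periodic 2D WHAM with basin/transition-state extraction.

## Worked example

A 3000 cm⁻¹ harmonic oscillator is the exactness oracle: RPMD is exact
for harmonic potentials, so classical MD and TRPMD must put the peak
in the same bin, while a Morse oscillator shows the anharmonic
red shift once the ring polymer samples zero-point geometries:

```python
from ringspec import (build_harmonic_oscillator, build_morse_oscillator,
                      MDConfig, TRPMDProtocol)
from ringspec import md, ringpolymer as rp, spectra as sp

morse = build_morse_oscillator(1.0, 3000.0, De=110.0)

cfg = MDConfig(temperature_K=298.15, equilibration_ps=4.0,
               production_ps=16.0, friction_fs=0.05, seed=5)
state = md.langevin_equilibrate(morse, md.initial_state(morse, 298.15, seed=5), cfg)
classical = sp.ft_dac(sp.dipole_from_trajectory(md.nve_production(morse, state, cfg)))

proto = TRPMDProtocol(temperature_K=298.15, equilibration_ps=2.0,
                      snapshot_stride=200, n_replicas=3,
                      production_ps=16.0, seed=6)   # 16 beads at 298.15 K
ensemble = rp.run_trpmd_ensemble(morse, proto)
trpmd = sp.average_replicas([sp.ft_dac(sp.bead_average_dipole(b)) for b in ensemble],
                            normalize=False)

print(f"classical peak: {classical.peak_wavenumber(2000, 3500):.1f} cm^-1")
print(f"TRPMD peak:     {trpmd.peak_wavenumber(2000, 3500):.1f} cm^-1")
```

Output:

```
classical peak: 3009.6 cm^-1
TRPMD peak:     2924.6 cm^-1
```

The classical peak sits at the bottom-of-well frequency; the TRPMD
peak is red-shifted by ~85 cm⁻¹ because the beads spread over the
softened outer wall of the Morse potential — the same physics that
red-shifts hydrogen-bonded O–H and N–H stretches when nuclear quantum
effects are switched on. (The identical run with
`build_harmonic_oscillator(1.0, 3000.0, 1.0)` prints the same peak
wavenumber, 3010.1 cm⁻¹, for both engines.)

The full desk-scale comparison on the built-in serine analog — both
engines at 100 K and 298.15 K, with peak assignment and distance
histograms — is one call (or `ringspec report`):

```python
from ringspec.pipeline import run_desk_pipeline
results = run_desk_pipeline("out/", seed=0)
print(results[298.15]["trpmd"]["assignment"])
```

which prints the assignment table for the 2600–3600 cm⁻¹ band, e.g.

```
 wavenumber_cm1  intensity           assignment  coordinate_peak_cm1  offset_cm1
    3297.162184   0.761446  O-H stretch (OG-HG)          3298.180141    1.017957
    3319.557234   0.894564  N-H stretch (N-HN1)          3318.539277    1.017957
    ...
```

## Command line

```
ringspec simulate-classical --model toy-serine --temperature 100 --preset desk --out run/
ringspec spectrum run/trajectory.extxyz --temperature 100 --correction harmonic --out spec.tsv
ringspec characterize run/trajectory.extxyz --spectrum spec.tsv --out run/
ringspec pmf --engine classical --temperature 298.15 --spacing 30 --out run/
ringspec report --out report/
```

Trajectories are extended XYZ with a per-atom charge column; spectra,
histograms, assignment tables and PMF grids are TSV with JSON
provenance sidecars; every run writes its resolved configuration.

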