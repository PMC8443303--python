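# Methods

This note records the models, estimators, numerical choices and known
limitations behind `ringspec`, in the order data flows through the
package.

## Units and constants

All internal computation uses Å, fs, amu, e and kcal/mol; dynamics is
integrated in the derived energy unit amu·Å²/fs² with the single
conversion factor collected in `ringspec.units` (CODATA-2018 /
exact-SI constants; ħ is derived from the exact Planck constant).
Spectra are reported in cm⁻¹ via ν̃ = ω/2πc, applied only at module
boundaries.

## Synthetic molecular models

The package replaces an electronic-structure force/charge engine with
classical models that reproduce the *structure* of its outputs:
energies, exact analytic forces, and geometry-dependent per-atom
charges at every geometry.

**Term types.** Harmonic and Morse bonds, harmonic angles, Fourier
torsions Σ k_n(1+cos(nφ−δ_n)), external site wells (harmonic and 1D
Morse), and a coupled two-torsion well
E = −A·exp[κ₁(cos(φ₁−c₁)−1) + κ₂(cos(φ₂−c₂)−1)] (a von-Mises product).
The coupled well exists because the target three-conformer pattern —
basins at (−35°, +55°), (+35°, −55°), (+35°, −170°) on the two
reaction-coordinate torsions — is not representable by separable
one-torsion potentials without creating spurious cross-product minima.
Dihedrals are signed IUPAC angles in (−180°, 180°] from the standard
atan2 construction (cross-checked against MDAnalysis), with
Blondel–Karplus analytic gradients; all torsion arithmetic lives on
the circle.

**Charges.** Fixed reference charges summing exactly to the net charge
plus antisymmetric bond-charge flux on the O–H and N–H analogs:
δq = j·(r−r₀) flows between the bonded atoms, conserving total charge
identically at every geometry. Pure fixed charges would give a nearly
vanishing dipole derivative for some stretches (and exactly zero when
j·r₀ happens to equal the H charge — an accidental cancellation worth
knowing about when building new models); the flux makes all
high-frequency stretch peaks visible, emulating geometry-dependent
population-analysis charges.

**The serine analog.** 13 atoms (carboxylate C+2O, Cα+Hα, N+2H,
Cβ+2H, hydroxyl O+H), net charge −1, reference geometry from an
MMFF94-optimized embedding frozen into the source. Stretch targets at
the global minimum: C–H analogs ≈ 2930, N–H ≈ 3320, O–H ≈ 3450 cm⁻¹
(the O–H bond is a Morse with D_e = 110 kcal/mol so its anharmonicity
is physical). Small Fourier torsions stiffen the otherwise-free
carboxylate and amine rotors, and one improper keeps the planar
carboxylate carbon rigid out-of-plane, so a basin minimum has exactly
3N−6 positive normal modes. Basin depths (0, 2.4, 7.0 kcal/mol by
default) are realized by solving a small linear system for the well
amplitudes (the wells overlap), refined by bounded least squares whose
starting guess is the only thing the build seed perturbs; a 5° grid
scan verifies every requested basin to within 1 kcal/mol at build
time and the construction fails loudly otherwise. The basin *pattern*
(locations, ordering, barrier scale of a few kcal/mol) is the design
target; no classical model can reproduce a tight-binding conformer
energetics quantitatively, and none is claimed.

**Limitations.** No nonbonded pair terms: the conformer landscape is
carried entirely by the coupled torsion wells, so stretch frequencies
do not shift with hydrogen-bond geometry as they would under a real
electronic structure. Charges are local (bond flux only), not
polarizable.

## Classical dynamics

Langevin equilibration uses BAOAB splitting with the exact
Ornstein–Uhlenbeck substep — the best configurational accuracy at a
given Δt. The friction γ = 0.01 fs⁻¹ by default (0.02–0.05 in the
faster desk presets); it is a sampling device, not part of the
emulated protocol, and is logged in every trajectory's metadata.
Initial velocities are Maxwell–Boltzmann; for free molecules the COM
momentum and angular momentum are removed at initialization (linear
molecules use the inertia pseudo-inverse). Production is
velocity-Verlet NVE at Δt = 0.5 fs with positions and charges
recorded every step; the symplectic integrator's total energy
oscillates at O((ωΔt)²) without secular drift, and the recorded
energy trace plus drift figure ship in the metadata.

Two deliberate choices about the dipole of a *net-charged* molecule:
μ = Σqᵢrᵢ contains (net charge)·R_com, so COM drift puts a secular
ramp in μ whose spectral tail, amplified by the ω-dependent absorption
prefactor, can bury every vibrational line. The total momentum is
therefore zeroed at the start of production (classical) and at each
replica's production start (TRPMD, a uniform shift that touches only
the centroid mode). Rotation is left free — rovibrational envelopes
are physical.

The velocity-Verlet effective frequency is ω_eff = (2/Δt)asin(ωΔt/2),
a +0.3% shift at ωΔt ≈ 0.28 (3000 cm⁻¹ at 0.5 fs). Where an oracle
demands peak positions at the ~1 cm⁻¹ level, the integrator runs at a
refined step (0.1 fs) while recording on the 0.5 fs grid; everywhere
a classical and a TRPMD spectrum are *compared*, both engines use the
same step and inherit the identical shift (for harmonic potentials
the ring-polymer centroid map reduces exactly to velocity Verlet).

## Thermostated ring-polymer MD

`n` beads at inverse temperature β are coupled by springs of frequency
ω_n = n/(βħ); the orthonormal real normal-mode transform diagonalizes
them at ω_k = 2ω_n sin(kπ/n). One step is the symmetric splitting
O(half)–B(half)–A(full)–B(half)–O(half), where A is the *exact*
free-ring-polymer phase-space rotation per mode — no spring-resonance
timestep artifacts at 0.5 fs with 32 beads — and O is the thermostat
on the normal modes. PILE is the default: white-noise friction
γ_k = ω_k/λ with λ = 1/2 on the internal modes; the centroid is
unthermostated in production (the defining TRPMD choice) and weakly
thermostated (γ₀ = 0.01 fs⁻¹) during equilibration so the full
quantum distribution converges. GLE thermostats are supported through
user-supplied drift/covariance matrices in a plain-text block format;
the matrices are checked for OU stability at load. The emulated
protocol used GLE thermostats whose matrices are not public; PILE is
this package's documented default, with the known trade-off that GLE
is more accurate for high-frequency band shapes and PILE for
low-frequency ones.

Protocol: equilibrate 40 ps (fully thermostated), then harvest
snapshots every 1000 steps as initial conditions for 50 independent
~32 ps production replicas — 32 beads at 100 K, 16 at 298.15 K (the
crossover is placed at 200 K). Per-bead charges are evaluated at
per-bead geometries every step and the bead-resolved dipoles μⱼ are
recorded; the Eq.-6-style bead average happens at analysis time.
Memory note: production records bead *dipoles*, centroid geometry and
centroid charges by default; full bead-resolved positions are an
opt-in for small systems.

Validation anchors: the transform round-trips to 1e−12 and its
frequencies match the dense spring matrix; the ring-polymer
Hamiltonian shows no secular drift without thermostat; PILE puts
every internal mode at kinetic temperature nT; the bead-site position
variance of a harmonic oscillator matches the exact finite-n formula
(1/βm)Σ_k 1/(ω_k²+ω²) at every bead count and approaches
(ħ/2mω)coth(βħω/2) monotonically (0.18% off at 32 beads for
βħω ≈ 4); one bead recovers kT/k and reproduces classical velocity
Verlet bitwise.

## Spectral estimators

The dipole autocorrelation (dot product over x, y, z, mean removed) is
computed by FFT with zero padding and unbiased overlap normalization,
apodized — Hann by default, because truncated-correlation leakage
matters when comparing band shapes; "rect" gives the bare periodogram
for which the discrete Parseval identity (power sum = lag-0
autocovariance) is exact — and cosine-transformed onto a cm⁻¹ grid.
The physical resolution (c·NΔt)⁻¹ ≈ 1.04 cm⁻¹ for 32 ps at 0.5 fs is
recorded in the provenance; zero padding only interpolates bins.

Absorption prefactor: classical spectra use "harmonic" mode,
ω·βħω·I_cl — algebraically identical to ω(1−e^{−βħω})Q_HC(ω)I_cl, an
identity the tests verify to 1e−12 — while TRPMD spectra apply no
extra empirical correction: "none" mode, the bare ω(1−e^{−βħω})
factor. The constant 4π²/3Vħc·n(ω) prefactor (n(ω)≈1) is never
evaluated; it cancels in the final normalization, which sets the
maximal intensity in 600–3600 cm⁻¹ to 1.0. Replica ensembles are
averaged first (per-bin mean and population standard deviation — the
shaded band) and normalized after; the opposite order is available by
flag.

## Peak characterization

FT-ν_N AC: the same estimator applied to the scalar autocovariance of
an internal coordinate (the vector notation of the source method
collapses to a scalar here). Peak positions are meaningful,
intensities are not. For bead-resolved trajectories internal
coordinates are evaluated on the centroid geometry by default (the
RPMD physical observable), per-bead as an option. Assignment: FT-DAC
local maxima above a prominence threshold (default 5% of the in-band
maximum, scipy `find_peaks`) are labeled by the internal coordinate
with the nearest localized-mode peak within a tolerance (default
40 cm⁻¹ in the pipeline); unassigned peaks are flagged, never
invented. A floor of 1e−20 on usable intensity screens out the
round-off spectrum of a constant series.

Distance histograms are density-normalized with a two-population
flag decided by a one- vs two-component Gaussian-mixture BIC
comparison (margin 10 nats, minority weight ≥ 10%, means separated by
more than the pooled component width) — chosen over the dip test,
which has no maintained implementation in the installed stack; the
guards suppress heavy-tail false positives.

## Umbrella sampling and WHAM

Windows tile the periodic torsion plane (5° spacing in the reference
protocol → 5184 windows of 100 ps; 15° and 10 ps at desk scale). Both
bias forms are implemented exactly as the emulated protocol printed
them: the cosine form k(1−cos(θ−θ₀)) with θ in radians and k in
kcal/mol (75/65 at 100 K, 150/125 at 298.15 K), and the harmonic form
½K(θ−θ₀)² with θ in *degrees* and the nominal K = 200 kJ/mol applied
literally as kJ/mol/deg². That unit convention is internally
inconsistent in the source protocol (200 kJ/mol/deg² is so stiff that
5°-spaced windows would barely overlap); it is preserved verbatim
because the formula is quoted that way, and the desk preset uses
3 kJ/mol/deg² for actual sampling. TRPMD umbrella biases act on the
centroid dihedral, with the restoring force spread equally over beads
— standard path-integral umbrella practice.

WHAM iterates the coupled equations for bin probabilities and window
free energies in log space (logsumexp) on the periodic 2D grid until
max|Δf_w| < 1e−7 kcal/mol. Bin width defaults to the window spacing;
bins with fewer than 10 total samples are masked, never extrapolated.
The bias is evaluated at bin centers — empirically the best-matched
convention (Boltzmann bin-averaging the bias *worsens* agreement
because samples concentrate where the bias is low within a bin), and
with the sampling used here the residual per-bin deviations from the
closed-form oracle are statistically indistinguishable from the
per-bin standard errors (rms ratio ≈ 1.05; coverage at 2·SE matches
the t-distribution of the SE estimator). Convergence is monitored by
WHAM on the first and last halves of every window; the duplicated-data
limit of that diagnostic is exactly zero.

Basins are unmasked bins below all 8 periodic neighbors. The
transition state between two basins is the minimax point — the lowest
free energy at which their sub-level sets merge — found by an
ascending-energy union-find flood, which is symmetric in the basin
pair by construction and agrees with the closed-form barrier of a
two-well test surface to within one grid cell's energy span. How the
emulated protocol located its transition states is unstated; the
minimax definition is this package's documented choice.

## Problem sizes

The `paper` preset resolves the full reference protocol (50 ps + 32 ps
classical, 40 ps + 50×32 ps TRPMD, 5°/100 ps umbrella grid) and is
config-complete but is not what the test suite runs. The `desk`
preset — 5 ps + 8 ps classical with 3 replicas, 2 ps + 4×8 ps TRPMD,
15°/10 ps umbrella windows sampled on the 2-DOF analytic surface —
was chosen as the smallest scale at which every qualitative claim
(peak assignment completeness, red-shift direction, WHAM accuracy at
the per-bin-standard-error level) is resolved with comfortable
statistical margin; the `smoke` preset exists for command-line smoke
runs. Synthetic-data defaults (temperatures 100.00/298.15 K, bead
counts, Δt = 0.5 fs, basin depths, stretch bands) are the study
conditions and are not tuning knobs.

## What passing tests do and do not show

The oracles are closed-form (harmonic/Morse oscillators, analytic
periodic surfaces, exact finite-n ring-polymer statistics), so the
tests validate the estimators and integrators, not the realism of the
force field. The serine analog demonstrates the *pipeline* — that
bead-averaged dipoles from flux charges produce assignable stretch
bands and that the two-torsion landscape is recoverable by WHAM — but
its numbers (basin depths, stretch positions, red-shift magnitudes)
are properties of the synthetic model, not predictions for serine.
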