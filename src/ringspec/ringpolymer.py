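"""Thermostated ring-polymer molecular dynamics (TRPMD).

A quantum particle at inverse temperature beta is represented by
``n_beads`` classical replicas joined into a ring by harmonic springs
of frequency ``omega_n = n_beads/(beta hbar)``. Propagation works in
the ring-polymer normal modes, where the free-ring-polymer part is an
exact phase-space rotation at the mode frequencies

    omega_k = 2 omega_n sin(k pi / n_beads),

so no spring-resonance timestep artifacts arise even with 32 beads at
dt = 0.5 fs. The internal modes are thermostated (PILE by default:
white-noise Langevin with gamma_k = 2 omega_k, i.e. lambda = 1/2;
generalized-Langevin (GLE) matrices may be supplied from a parameter
file). In production the centroid is not thermostated — that is the
defining choice of TRPMD, which damps the spurious resonance peaks
while leaving centroid dynamics, and hence spectra, Hamiltonian.

The ensemble protocol mirrors the reference recipe: thermostated
equilibration (default 40 ps, centroid included so the quantum
distribution converges), snapshots every 1000 steps seeding 50
independent ~32 ps production runs, 32 beads at 100 K / 16 beads at
298.15 K. Per-bead charges are evaluated at per-bead geometries each
step and the bead-averaged dipole mu = (1/n) sum_j mu_j is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .md import KB_INT, IntegrationError, Trajectory, _check_energy
from .model import MolecularModel

__all__ = [
    "RingPolymerState",
    "TRPMDProtocol",
    "PILEThermostat",
    "GLEParameters",
    "GLEThermostat",
    "BeadTrajectory",
    "normal_mode_matrix",
    "normal_mode_frequencies",
    "to_normal_modes",
    "from_normal_modes",
    "default_n_beads",
    "initial_ring_polymer_state",
    "trpmd_step",
    "integrate_trpmd",
    "run_trpmd_ensemble",
    "rp_bead_position_variance",
    "quantum_harmonic_variance",
]


# --------------------------------------------------------------------------
# normal modes of the free ring polymer
# --------------------------------------------------------------------------


def normal_mode_matrix(n_beads: int) -> np.ndarray:
    """Orthonormal real transform C with x_nm = C.T @ x_beads.

    Column 0 is the centroid (uniform) mode; columns k and n-k pair
    into cos/sin combinations at frequency omega_k. C is orthogonal,
    so the round trip is the identity to machine precision.
    """
    n = n_beads
    j = np.arange(n)[:, None]
    k = np.arange(n)[None, :]
    C = np.empty((n, n))
    C[:, 0] = math.sqrt(1.0 / n)
    for kk in range(1, (n + 1) // 2):
        C[:, kk] = math.sqrt(2.0 / n) * np.cos(2 * math.pi * j[:, 0] * kk / n)
    if n % 2 == 0:
        C[:, n // 2] = math.sqrt(1.0 / n) * (-1.0) ** j[:, 0]
    for kk in range(n // 2 + 1, n):
        C[:, kk] = math.sqrt(2.0 / n) * np.sin(2 * math.pi * j[:, 0] * kk / n)
    return C


def normal_mode_frequencies(n_beads: int, omega_n: float) -> np.ndarray:
    """omega_k (rad/fs) for each normal-mode column of the transform."""
    k = np.arange(n_beads)
    m = np.minimum(k, n_beads - k)
    return 2.0 * omega_n * np.sin(m * math.pi / n_beads)


def to_normal_modes(bead_array: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Transform a (n_beads, ...) bead-axis array into normal modes."""
    return np.tensordot(C.T, bead_array, axes=(1, 0))


def from_normal_modes(nm_array: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Inverse of `to_normal_modes` (C is orthogonal)."""
    return np.tensordot(C, nm_array, axes=(1, 0))


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------


@dataclass
class RingPolymerState:
    """Bead-resolved phase space plus the derived centroid view."""

    positions: np.ndarray  # (n_beads, n_atoms, 3), A
    velocities: np.ndarray  # (n_beads, n_atoms, 3), A/fs
    temperature_K: float
    time_fs: float = 0.0
    info: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def beta(self) -> float:
        """Inverse temperature, (kcal/mol)^-1."""
        return units.beta_kcalmol(self.temperature_K)

    @property
    def omega_n(self) -> float:
        """Ring-polymer spring frequency n/(beta hbar), rad/fs."""
        return self.n_beads / (self.beta * units.HBAR_KCALMOL_FS)

    @property
    def centroid_positions(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def centroid_velocities(self) -> np.ndarray:
        return self.velocities.mean(axis=0)

    def copy(self) -> "RingPolymerState":
        return RingPolymerState(
            self.positions.copy(),
            self.velocities.copy(),
            self.temperature_K,
            self.time_fs,
            dict(self.info),
        )


def default_n_beads(temperature_K: float) -> int:
    """Protocol bead counts: 32 beads at 100 K, 16 beads at 298.15 K.

    The crossover is placed at 200 K; colder ensembles need more
    imaginary-time slices for the same Trotter accuracy.
    """
    return 32 if temperature_K < 200.0 else 16


def initial_ring_polymer_state(
    model: MolecularModel,
    temperature_K: float,
    n_beads: int | None = None,
    seed: int = 0,
    positions: np.ndarray | None = None,
    spread: bool = True,
) -> RingPolymerState:
    """All beads at the (reference) geometry with free-RP thermal
    velocities; ``spread`` adds a small bead-position jitter so the
    internal modes do not start exactly at zero."""
    rng = np.random.default_rng(seed)
    nb = n_beads if n_beads is not None else default_n_beads(temperature_K)
    pos0 = (
        model.reference_positions if positions is None else np.asarray(positions)
    )
    pos = np.repeat(pos0[None].astype(float), nb, axis=0)
    if spread and nb > 1:
        pos += 0.02 * rng.standard_normal(pos.shape)
    # each normal mode carries kinetic energy at n*T; in bead space the
    # velocity marginals are Gaussian with variance n kT / m
    sig = np.sqrt(nb * KB_INT * temperature_K / model.masses)[None, :, None]
    vel = rng.standard_normal(pos.shape) * sig
    return RingPolymerState(pos, vel, temperature_K)


# --------------------------------------------------------------------------
# thermostats
# --------------------------------------------------------------------------


class PILEThermostat:
    """Path-integral Langevin equation thermostat.

    Internal mode k gets white-noise friction gamma_k = omega_k/lambda
    with lambda = 1/2 (i.e. gamma_k = 2 omega_k, critical damping of
    the free-RP mode); the centroid gets ``centroid_friction_fs``
    (0 in TRPMD production; > 0 gives fully canonical sampling for
    equilibration, "PILE-G style" global sampling is not needed here).
    """

    def __init__(self, lambda_: float = 0.5, centroid_friction_fs: float = 0.0):
        if lambda_ <= 0:
            raise ValueError("lambda must be positive")
        self.lambda_ = lambda_
        self.centroid_friction_fs = centroid_friction_fs

    def setup(self, n_beads, omega_k, masses, temperature_K, dt_fs):
        gamma = omega_k / self.lambda_
        gamma[0] = self.centroid_friction_fs
        self._c1 = np.exp(-gamma * (0.5 * dt_fs))  # half-step damping
        sig = np.sqrt(n_beads * KB_INT * temperature_K / masses)
        self._c2 = np.sqrt(1.0 - self._c1**2)[:, None, None] * sig[None, :, None]
        self._c1 = self._c1[:, None, None]

    def apply(self, vel_nm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self._c1 * vel_nm + self._c2 * rng.standard_normal(vel_nm.shape)


@dataclass
class GLEParameters:
    """Generalized-Langevin drift matrix A (fs^-1) and optional static
    covariance C (units of kT; defaults to the identity = canonical
    sampling). Loaded from a plain-text file of labeled matrix blocks:

        # units: A fs^-1
        A
        a11 a12 ...
        ...
        C        (optional)
        ...

    The (s+1)x(s+1) matrix A couples the physical momentum to s
    auxiliary momenta; A must be stable (all eigenvalue real parts
    positive) or loading fails.
    """

    A: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, float))
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("GLE drift matrix A must be square")
        if np.min(np.linalg.eigvals(self.A).real) <= 0:
            raise ValueError(
                "GLE drift matrix is not stable (an eigenvalue has "
                "non-positive real part); the OU process would diverge"
            )
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, float))
            if self.C.shape != self.A.shape:
                raise ValueError("C must match the shape of A")

    @property
    def n_aux(self) -> int:
        return self.A.shape[0] - 1

    @classmethod
    def from_file(cls, path) -> "GLEParameters":
        blocks: dict[str, list[list[float]]] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if line in ("A", "C"):
                    current = line
                    blocks[current] = []
                    continue
                if current is None:
                    raise ValueError(f"matrix data before block label: {line!r}")
                blocks[current].append([float(x) for x in line.split()])
        if "A" not in blocks:
            raise ValueError("GLE parameter file must contain an 'A' block")
        return cls(
            A=np.array(blocks["A"]),
            C=np.array(blocks["C"]) if "C" in blocks else None,
        )


class GLEThermostat:
    """Colored-noise thermostat from user-supplied GLE matrices.

    The same (s+1)-dimensional OU process acts on every internal mode
    (and optionally the centroid); auxiliary momenta are state carried
    between steps. The exact OU update over dt/2 is
    p <- T p + S xi, with T = expm(-A dt/2) and S S^T = C - T C T^T.
    """

    def __init__(self, params: GLEParameters, thermostat_centroid: bool = False):
        self.params = params
        self.thermostat_centroid = thermostat_centroid

    def setup(self, n_beads, omega_k, masses, temperature_K, dt_fs):
        from scipy.linalg import expm

        s = self.params.n_aux
        kT_n = n_beads * KB_INT * temperature_K
        Cmat = (
            np.eye(s + 1) if self.params.C is None else self.params.C
        ) * kT_n  # momentum-space covariance, mass-scaled later
        T = expm(-self.params.A * (0.5 * dt_fs))
        M = Cmat - T @ Cmat @ T.T
        # symmetrize and factor (Cholesky with jitter fallback)
        M = 0.5 * (M + M.T)
        try:
            S = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(M)
            S = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        self._T = T
        self._S = S
        self._masses = masses
        self._n_beads = n_beads
        self._aux = None
        self._centroid_slice = slice(None) if self.thermostat_centroid else slice(1, None)

    def apply(self, vel_nm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        nb, na, _ = vel_nm.shape
        s = self.params.n_aux
        sqm = np.sqrt(self._masses)[None, :, None]
        if self._aux is None:
            self._aux = np.zeros((nb, na, 3, s))
        sel = self._centroid_slice
        # stack scaled momentum with auxiliaries: shape (..., s+1)
        p = np.concatenate(
            [(vel_nm * sqm)[sel][..., None], self._aux[sel]], axis=-1
        )
        xi = rng.standard_normal(p.shape)
        p = p @ self._T.T + xi @ self._S.T
        out = vel_nm.copy()
        out[sel] = p[..., 0] / sqm  # sqm broadcasts over the bead axis
        self._aux[sel] = p[..., 1:]
        return out


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------


class _RPPropagator:
    """Precomputed machinery for one (model, state, dt) combination."""

    def __init__(self, model, n_beads, temperature_K, dt_fs, thermostat):
        self.model = model
        self.dt = dt_fs
        self.C = normal_mode_matrix(n_beads)
        beta = units.beta_kcalmol(temperature_K)
        omega_n = n_beads / (beta * units.HBAR_KCALMOL_FS)
        self.omega_k = normal_mode_frequencies(n_beads, omega_n)
        # exact free-RP evolution per mode over a full step
        c = np.cos(self.omega_k * dt_fs)
        s = np.sin(self.omega_k * dt_fs)
        self._evo_c = c[:, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            sw = np.where(self.omega_k > 0, s / np.where(self.omega_k > 0, self.omega_k, 1.0), dt_fs)
        self._evo_s_over_w = sw[:, None, None]
        self._evo_sw = (s * self.omega_k)[:, None, None]
        self.thermostat = thermostat
        if thermostat is not None:
            thermostat.setup(
                n_beads, self.omega_k.copy(), model.masses, temperature_K, dt_fs
            )
        self._f_to_a = units.KCAL_TO_INTERNAL / model.masses[None, :, None]

    def forces(self, pos, bias_force=None):
        e, f, q = self.model.evaluate(pos)
        if bias_force is not None:
            eb, fb = bias_force(pos)
            e = e + eb
            f = f + fb
        return e, f, q

    def step(self, pos, vel, f, rng, bias_force=None):
        """One OBABO step; returns (pos, vel, energy, forces, charges)."""
        if self.thermostat is not None:
            vel_nm = to_normal_modes(vel, self.C)
            vel_nm = self.thermostat.apply(vel_nm, rng)
            vel = from_normal_modes(vel_nm, self.C)
        vel = vel + 0.5 * self.dt * f * self._f_to_a
        pos_nm = to_normal_modes(pos, self.C)
        vel_nm = to_normal_modes(vel, self.C)
        new_pos = self._evo_c * pos_nm + self._evo_s_over_w * vel_nm
        new_vel = self._evo_c * vel_nm - self._evo_sw * pos_nm
        pos = from_normal_modes(new_pos, self.C)
        vel = from_normal_modes(new_vel, self.C)
        e, f, q = self.forces(pos, bias_force)
        vel = vel + 0.5 * self.dt * f * self._f_to_a
        if self.thermostat is not None:
            vel_nm = to_normal_modes(vel, self.C)
            vel_nm = self.thermostat.apply(vel_nm, rng)
            vel = from_normal_modes(vel_nm, self.C)
        return pos, vel, e, f, q

    def hamiltonian(self, pos, vel) -> float:
        """Ring-polymer Hamiltonian (kcal/mol): kinetic + springs + potential."""
        m = self.model.masses[None, :, None]
        ke = 0.5 * np.sum(m * vel**2) * units.INTERNAL_TO_KCAL
        e, _, _ = self.model.evaluate(pos)
        pot = float(np.sum(e))
        # spring energy via normal modes: 1/2 m omega_k^2 |x_k|^2
        pos_nm = to_normal_modes(pos, self.C)
        spring = 0.5 * np.sum(
            m * (self.omega_k[:, None, None] ** 2) * pos_nm**2
        ) * units.INTERNAL_TO_KCAL
        return ke + spring + pot


def trpmd_step(
    model: MolecularModel,
    state: RingPolymerState,
    dt_fs: float,
    thermostat,
    rng: np.random.Generator | None = None,
) -> RingPolymerState:
    """Advance one TRPMD step (convenience wrapper around the
    propagator; building a `_RPPropagator` once and looping is faster
    for long runs)."""
    rng = rng or np.random.default_rng(0)
    prop = _RPPropagator(model, state.n_beads, state.temperature_K, dt_fs, thermostat)
    _, f, _ = prop.forces(state.positions)
    pos, vel, e, f, q = prop.step(state.positions, state.velocities, f, rng)
    return RingPolymerState(pos, vel, state.temperature_K, state.time_fs + dt_fs)


@dataclass
class BeadTrajectory:
    """TRPMD production record.

    Carries the per-frame bead-resolved dipoles mu_j(t) (from per-bead
    charges at per-bead geometries), the centroid geometry and centroid
    charges for internal-coordinate analysis, and (optionally, for
    small runs) the full bead-resolved positions and charges.
    """

    bead_dipoles: np.ndarray  # (n_frames, n_beads, 3), e*A
    centroid_positions: np.ndarray  # (n_frames, n_atoms, 3)
    centroid_charges: np.ndarray  # (n_frames, n_atoms)
    times_fs: np.ndarray
    dt_fs: float
    bead_positions: np.ndarray | None = None
    bead_charges: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.bead_dipoles.shape[0]

    @property
    def n_beads(self) -> int:
        return self.bead_dipoles.shape[1]

    def centroid_trajectory(self) -> Trajectory:
        """View the centroid motion as a classical `Trajectory`."""
        return Trajectory(
            positions=self.centroid_positions,
            charges=self.centroid_charges,
            times_fs=self.times_fs,
            dt_fs=self.dt_fs,
            metadata={**self.metadata, "view": "centroid"},
        )


@dataclass
class TRPMDProtocol:
    """Ensemble protocol; defaults follow the reference recipe."""

    temperature_K: float
    n_beads: int | None = None  # None -> 32 below 200 K else 16
    timestep_fs: float = 0.5
    equilibration_ps: float = 40.0
    snapshot_stride: int = 1000
    n_replicas: int = 50
    production_ps: float = 32.0
    thermostat: str = "pile"  # "pile" | "gle"
    pile_lambda: float = 0.5
    centroid_friction_fs: float = 0.01  # equilibration only
    gle_params: GLEParameters | None = None
    #: zero the centroid center-of-mass velocity at each replica's
    #: production start (free molecules: keeps the net-charge dipole
    #: term from ramping; see md.zero_com_momentum)
    remove_com_momentum: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot stride must be >= 1")
        if self.thermostat not in ("pile", "gle"):
            raise ValueError("thermostat must be 'pile' or 'gle'")
        if self.thermostat == "gle" and self.gle_params is None:
            raise ValueError("gle thermostat requires gle_params")

    def resolve_n_beads(self) -> int:
        return (
            self.n_beads
            if self.n_beads is not None
            else default_n_beads(self.temperature_K)
        )

    def make_thermostat(self, production: bool):
        if self.thermostat == "gle":
            return GLEThermostat(
                self.gle_params, thermostat_centroid=not production
            )
        return PILEThermostat(
            lambda_=self.pile_lambda,
            centroid_friction_fs=0.0 if production else self.centroid_friction_fs,
        )


def integrate_trpmd(
    model: MolecularModel,
    state: RingPolymerState,
    n_steps: int,
    dt_fs: float,
    thermostat,
    seed: int = 0,
    record: bool = True,
    store_beads: bool = False,
    bias_force=None,
    record_stride: int = 1,
) -> tuple[RingPolymerState, BeadTrajectory | None]:
    """Run ``n_steps`` of TRPMD; optionally record a `BeadTrajectory`."""
    rng = np.random.default_rng(seed)
    prop = _RPPropagator(model, state.n_beads, state.temperature_K, dt_fs, thermostat)
    pos = state.positions.copy()
    vel = state.velocities.copy()
    _, f, q = prop.forces(pos, bias_force)

    n_rec = (n_steps // record_stride) if record else 0
    nb, na = state.n_beads, model.n_atoms
    if record:
        dips = np.empty((n_rec, nb, 3))
        cpos = np.empty((n_rec, na, 3))
        cq = np.empty((n_rec, na))
        times = np.empty(n_rec)
        bpos = np.empty((n_rec, nb, na, 3)) if store_beads else None
        bq = np.empty((n_rec, nb, na)) if store_beads else None
    k = 0
    for step in range(1, n_steps + 1):
        pos, vel, e, f, q = prop.step(pos, vel, f, rng, bias_force)
        _check_energy(float(np.sum(e)), step)
        if record and step % record_stride == 0:
            dips[k] = np.sum(q[..., None] * pos, axis=-2)
            cpos[k] = pos.mean(axis=0)
            cq[k] = q.mean(axis=0)
            times[k] = state.time_fs + step * dt_fs
            if store_beads:
                bpos[k] = pos
                bq[k] = q
            k += 1

    out_state = RingPolymerState(
        pos, vel, state.temperature_K, state.time_fs + n_steps * dt_fs
    )
    traj = None
    if record:
        traj = BeadTrajectory(
            bead_dipoles=dips,
            centroid_positions=cpos,
            centroid_charges=cq,
            times_fs=times,
            dt_fs=dt_fs * record_stride,
            bead_positions=bpos,
            bead_charges=bq,
            metadata={
                "ensemble": "TRPMD",
                "temperature_K": state.temperature_K,
                "n_beads": nb,
                "timestep_fs": dt_fs,
                "seed": seed,
                "model": model.metadata.get("kind", "unknown"),
            },
        )
    return out_state, traj


def run_trpmd_ensemble(
    model: MolecularModel,
    protocol: TRPMDProtocol,
    store_beads: bool = False,
) -> list[BeadTrajectory]:
    """Equilibrate, harvest snapshots, run independent production runs.

    Equilibration uses a fully thermostated PILE/GLE (centroid
    included) to converge the quantum distribution; the following
    ``n_replicas`` snapshots, sampled every ``snapshot_stride`` steps,
    seed independent production runs whose thermostats leave the
    centroid untouched (TRPMD). Per-replica seeds derive from the
    protocol seed. A replica that diverges is dropped with a log entry
    in its slot; the ensemble proceeds with the survivors.
    """
    nb = protocol.resolve_n_beads()
    dt = protocol.timestep_fs
    seedseq = np.random.SeedSequence(protocol.seed)
    eq_seed, *rep_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in seedseq.spawn(protocol.n_replicas + 1)
    ]

    state = initial_ring_polymer_state(
        model, protocol.temperature_K, n_beads=nb, seed=eq_seed
    )
    eq_thermo = protocol.make_thermostat(production=False)
    n_eq = int(round(protocol.equilibration_ps * 1000.0 / dt))
    state, _ = integrate_trpmd(
        model, state, n_eq, dt, eq_thermo, seed=eq_seed, record=False
    )

    snapshots = []
    for _ in range(protocol.n_replicas):
        state, _ = integrate_trpmd(
            model,
            state,
            protocol.snapshot_stride,
            dt,
            eq_thermo,
            seed=eq_seed,
            record=False,
        )
        snapshots.append(state.copy())

    n_prod = int(round(protocol.production_ps * 1000.0 / dt))
    ensemble: list[BeadTrajectory] = []
    failures: list[tuple[int, str]] = []
    from .md import _is_externally_bound

    for r, (snap, seed_r) in enumerate(zip(snapshots, rep_seeds)):
        if (
            protocol.remove_com_momentum
            and model.n_atoms > 1
            and not _is_externally_bound(model)
        ):
            # a uniform velocity shift touches only the centroid mode
            m = model.masses[None, :, None]
            vcom = (m * snap.velocities).sum(axis=(0, 1)) / (
                model.total_mass * snap.n_beads
            )
            snap.velocities = snap.velocities - vcom
        thermo = protocol.make_thermostat(production=True)
        try:
            _, traj = integrate_trpmd(
                model,
                snap,
                n_prod,
                dt,
                thermo,
                seed=seed_r,
                record=True,
                store_beads=store_beads,
            )
        except IntegrationError as err:
            failures.append((r, str(err)))
            continue
        traj.metadata["replica"] = r
        traj.metadata["protocol_seed"] = protocol.seed
        ensemble.append(traj)
    if not ensemble:
        raise IntegrationError(
            f"all {protocol.n_replicas} replicas diverged: {failures}"
        )
    if failures:
        for t in ensemble:
            t.metadata["failed_replicas"] = failures
    return ensemble


# --------------------------------------------------------------------------
# analytic references (harmonic oscillator)
# --------------------------------------------------------------------------


def rp_bead_position_variance(
    n_beads: int, temperature_K: float, mass_amu: float, wavenumber_cm1: float
) -> float:
    """Exact bead-site position variance (A^2 per Cartesian component)
    of an n-bead ring polymer in a harmonic well — the finite-n
    discretization of the quantum result, recovered as n -> infinity:

        <x^2>_n = (1/beta m) sum_k 1/(omega_k^2 + omega^2).
    """
    w = units.omega_from_wavenumber(wavenumber_cm1)
    beta = units.beta_kcalmol(temperature_K)
    omega_n = n_beads / (beta * units.HBAR_KCALMOL_FS)
    wk = 2.0 * omega_n * np.sin(np.arange(n_beads) * np.pi / n_beads)
    beta_int = units.beta_internal(temperature_K)
    return float(np.sum(1.0 / (beta_int * mass_amu * (wk**2 + w**2))))


def quantum_harmonic_variance(
    temperature_K: float, mass_amu: float, wavenumber_cm1: float
) -> float:
    """Exact quantum <x^2> = (hbar/2 m omega) coth(beta hbar omega/2), A^2."""
    w = units.omega_from_wavenumber(wavenumber_cm1)
    bhw = units.beta_hbar_omega(wavenumber_cm1, temperature_K)
    return units.HBAR_INTERNAL / (2.0 * mass_amu * w) / math.tanh(bhw / 2.0)
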