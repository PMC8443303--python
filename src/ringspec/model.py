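"""Synthetic molecular models: analytic test potentials and a "toy serine".

This module stands in for an electronic-structure force/charge engine.
It provides classical bonded force fields with geometry-dependent
per-atom charges (fixed reference charges plus bond-charge flux), from
which the dipole moment mu = sum_i q_i r_i is assembled exactly as it
would be from population-analysis charges in a tight-binding run.

Three builders matter in practice:

``build_harmonic_oscillator``
    a single atom in an isotropic 3D harmonic well — the exact oracle
    for spectral and ring-polymer tests (every Cartesian component is an
    independent copy of the requested mode);
``build_morse_oscillator``
    a single atom in a 1D Morse potential with stiff transverse
    confinement — the minimal anharmonic system showing a zero-point
    red shift;
``build_toy_serine``
    a 13-atom deprotonated-serine analog (net charge -1) with O-H,
    N-H and C-H stretches in the 2600-3600 cm^-1 band and a sculpted
    two-torsion conformer landscape with >= 3 basins.

Energies are in kcal/mol, lengths in A, charges in e (see `units`).
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import geometry, units

__all__ = [
    "ModelError",
    "EvaluationError",
    "HarmonicBond",
    "MorseBond",
    "HarmonicAngle",
    "TorsionFourier",
    "TorsionWell",
    "SiteHarmonic",
    "SiteMorse",
    "ChargeModel",
    "TorsionLandscapeSpec",
    "MolecularModel",
    "build_harmonic_oscillator",
    "build_morse_oscillator",
    "build_diatomic",
    "build_toy_serine",
    "normal_modes",
]

#: any interatomic distance below this (A) aborts evaluation — guards
#: against Morse dissociation/fusion artifacts in runaway trajectories
HARD_CORE_CUTOFF = 0.25


class ModelError(ValueError):
    """Invalid model construction input."""


class EvaluationError(RuntimeError):
    """Geometry rejected at evaluation time (e.g. hard-core overlap)."""


# --------------------------------------------------------------------------
# term types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicBond:
    """E = 1/2 k (r - r0)^2, k in kcal/mol/A^2, r0 in A."""

    i: int
    j: int
    r0: float
    k: float


@dataclass(frozen=True)
class MorseBond:
    """E = De (1 - exp(-a (r - r0)))^2; harmonic limit k = 2 De a^2."""

    i: int
    j: int
    r0: float
    De: float
    a: float


@dataclass(frozen=True)
class HarmonicAngle:
    """E = 1/2 k (theta - theta0)^2, k in kcal/mol/rad^2."""

    i: int
    j: int
    k_: int
    theta0: float
    k: float


@dataclass(frozen=True)
class TorsionFourier:
    """E = sum_n k_n (1 + cos(n phi - delta_n)) over the listed terms."""

    i: int
    j: int
    k_: int
    l: int
    terms: tuple[tuple[int, float, float], ...]  # (n, k_n, delta_n[rad])


@dataclass(frozen=True)
class TorsionWell:
    """Coupled two-torsion basin: a periodic (von Mises product) well.

    E = -A exp(kappa1 (cos(phi1 - c1) - 1) + kappa2 (cos(phi2 - c2) - 1))

    The well bottoms out at -A when both dihedrals sit at their centers
    and decays smoothly (and periodically) away from them. Sums of such
    wells sculpt an arbitrary basin pattern on the 2-torsion map —
    something separable Fourier torsions cannot do.
    """

    quad1: tuple[int, int, int, int]
    quad2: tuple[int, int, int, int]
    center1: float  # rad
    center2: float  # rad
    kappa1: float
    kappa2: float
    amplitude: float  # kcal/mol, > 0


@dataclass(frozen=True)
class SiteHarmonic:
    """External anisotropic spring: E = 1/2 sum_d k_d (x_d - c_d)^2."""

    atom: int
    kvec: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SiteMorse:
    """External 1D Morse along ``axis``: E = De (1 - exp(-a s))^2,
    s = (r - center) . axis."""

    atom: int
    axis: tuple[float, float, float]
    De: float
    a: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ChargeModel:
    """Reference charges plus antisymmetric bond-charge flux.

    For each flux entry ``(i, j, jc, r0)`` a charge ``jc * (r_ij - r0)``
    flows from atom i to atom j as the bond stretches, so the total
    charge is conserved identically at every geometry. Pure fixed
    charges give vanishing intensity modulation for symmetric stretches;
    the flux makes the high-frequency peaks visible, emulating the
    geometry dependence of population-analysis charges.
    """

    reference: tuple[float, ...]
    fluxes: tuple[tuple[int, int, float, float], ...] = ()


@dataclass(frozen=True)
class TorsionLandscapeSpec:
    """Target two-torsion landscape for the toy-serine builder.

    ``basins`` are (theta1_deg, theta2_deg, depth_kcal) with depth
    measured relative to the global minimum (the basin with depth 0).
    """

    quad1: tuple[int, int, int, int]
    quad2: tuple[int, int, int, int]
    basins: tuple[tuple[float, float, float], ...]
    kappa: float = 4.0


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------


class MolecularModel:
    """A bonded force field with a geometry-dependent charge model.

    Supplies energy (kcal/mol), forces (kcal/mol/A, exact negative
    gradient) and per-atom charges (e) at any geometry, batched over
    arbitrary leading axes of ``positions``.
    """

    def __init__(
        self,
        labels: Sequence[str],
        masses: Sequence[float],
        terms: Sequence[object],
        charge_model: ChargeModel,
        net_charge: float,
        reference_positions: np.ndarray,
        torsion_spec: TorsionLandscapeSpec | None = None,
        metadata: dict | None = None,
    ):
        self.labels = list(labels)
        self.masses = np.asarray(masses, dtype=float)
        if self.masses.ndim != 1 or len(self.labels) != self.masses.size:
            raise ModelError("labels and masses must have matching length")
        if np.any(self.masses <= 0):
            raise ModelError("all masses must be positive")
        self.terms = list(terms)
        self.charge_model = charge_model
        self.net_charge = float(net_charge)
        self.reference_positions = np.asarray(reference_positions, dtype=float)
        if self.reference_positions.shape != (self.n_atoms, 3):
            raise ModelError("reference_positions must be (n_atoms, 3)")
        self.torsion_spec = torsion_spec
        self.metadata = dict(metadata or {})
        self._validate()
        self._compile()

    # -- construction ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def _validate(self) -> None:
        n = self.n_atoms
        ref = np.asarray(self.charge_model.reference, dtype=float)
        if ref.size != n:
            raise ModelError("charge model must give one reference charge per atom")
        if abs(ref.sum() - self.net_charge) > 1e-10:
            raise ModelError(
                f"reference charges sum to {ref.sum():.6f}, "
                f"expected net charge {self.net_charge:.6f}"
            )

        def chk(*idx):
            for a in idx:
                if not (0 <= int(a) < n):
                    raise ModelError(f"term references invalid atom index {a}")

        for t in self.terms:
            if isinstance(t, (HarmonicBond, MorseBond)):
                chk(t.i, t.j)
            elif isinstance(t, HarmonicAngle):
                chk(t.i, t.j, t.k_)
            elif isinstance(t, TorsionFourier):
                chk(t.i, t.j, t.k_, t.l)
            elif isinstance(t, TorsionWell):
                chk(*t.quad1, *t.quad2)
            elif isinstance(t, (SiteHarmonic, SiteMorse)):
                chk(t.atom)
            else:
                raise ModelError(f"unknown term type {type(t).__name__}")
        for i, j, _, _ in self.charge_model.fluxes:
            chk(i, j)

    def _compile(self) -> None:
        """Gather per-type index/parameter arrays for vectorized evaluation."""
        hb = [t for t in self.terms if isinstance(t, HarmonicBond)]
        mb = [t for t in self.terms if isinstance(t, MorseBond)]
        an = [t for t in self.terms if isinstance(t, HarmonicAngle)]
        tf = [t for t in self.terms if isinstance(t, TorsionFourier)]
        tw = [t for t in self.terms if isinstance(t, TorsionWell)]
        sh = [t for t in self.terms if isinstance(t, SiteHarmonic)]
        sm = [t for t in self.terms if isinstance(t, SiteMorse)]

        self._hb_idx = np.array([[t.i, t.j] for t in hb], int).reshape(-1, 2)
        self._hb_r0 = np.array([t.r0 for t in hb])
        self._hb_k = np.array([t.k for t in hb])

        self._mb_idx = np.array([[t.i, t.j] for t in mb], int).reshape(-1, 2)
        self._mb_r0 = np.array([t.r0 for t in mb])
        self._mb_De = np.array([t.De for t in mb])
        self._mb_a = np.array([t.a for t in mb])

        self._an_idx = np.array([[t.i, t.j, t.k_] for t in an], int).reshape(-1, 3)
        self._an_t0 = np.array([t.theta0 for t in an])
        self._an_k = np.array([t.k for t in an])

        # Fourier torsions: flatten (torsion, harmonic) pairs
        quads, ns, ks, ds, owner = [], [], [], [], []
        for ti, t in enumerate(tf):
            quads.append([t.i, t.j, t.k_, t.l])
            for (n, kn, dn) in t.terms:
                ns.append(n)
                ks.append(kn)
                ds.append(dn)
                owner.append(ti)
        self._tf_quads = np.array(quads, int).reshape(-1, 4)
        self._tf_n = np.array(ns, float)
        self._tf_k = np.array(ks, float)
        self._tf_d = np.array(ds, float)
        self._tf_owner = np.array(owner, int)

        self._tw = tw
        if tw:
            self._tw_quads = np.array(
                [list(t.quad1) for t in tw] + [list(t.quad2) for t in tw], int
            )
            self._tw_c = np.array([t.center1 for t in tw] + [t.center2 for t in tw])
            self._tw_kap = np.array([t.kappa1 for t in tw] + [t.kappa2 for t in tw])
            self._tw_A = np.array([t.amplitude for t in tw])
        self._sh = sh
        if sh:
            self._sh_atom = np.array([t.atom for t in sh], int)
            self._sh_k = np.array([t.kvec for t in sh])
            self._sh_c = np.array([t.center for t in sh])
        self._sm = sm
        if sm:
            self._sm_atom = np.array([t.atom for t in sm], int)
            ax = np.array([t.axis for t in sm], float)
            self._sm_axis = ax / np.linalg.norm(ax, axis=1, keepdims=True)
            self._sm_De = np.array([t.De for t in sm])
            self._sm_a = np.array([t.a for t in sm])
            self._sm_c = np.array([t.center for t in sm])

        self._q_ref = np.asarray(self.charge_model.reference, float)
        fx = self.charge_model.fluxes
        self._fx_idx = np.array([[f[0], f[1]] for f in fx], int).reshape(-1, 2)
        self._fx_j = np.array([f[2] for f in fx])
        self._fx_r0 = np.array([f[3] for f in fx])

        pairs = [(i, j) for i in range(self.n_atoms) for j in range(i + 1, self.n_atoms)]
        self._all_pairs = np.array(pairs, int).reshape(-1, 2)
        # the hard-core guard targets Morse/bond fusion artifacts; models
        # with only external site terms (non-interacting particles) skip it
        self._has_pair_terms = bool(self._hb_idx.size or self._mb_idx.size)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    # -- evaluation --------------------------------------------------------

    def evaluate(self, positions: np.ndarray, check_core: bool = True):
        """Energy, forces and charges at ``positions``.

        Parameters
        ----------
        positions : array, shape (..., n_atoms, 3), in A.
        check_core : reject geometries with interatomic distances below
            the hard-core cutoff (0.25 A).

        Returns
        -------
        energy : (...,) kcal/mol; forces : (..., n_atoms, 3) kcal/mol/A;
        charges : (..., n_atoms) e.
        """
        pos = np.asarray(positions, dtype=float)
        if pos.shape[-2:] != (self.n_atoms, 3):
            raise ModelError(
                f"positions must end in ({self.n_atoms}, 3), got {pos.shape}"
            )
        if check_core and self._has_pair_terms and self.n_atoms > 1:
            r = geometry.distances(pos, self._all_pairs)
            rmin = float(r.min())
            if rmin < HARD_CORE_CUTOFF:
                raise EvaluationError(
                    f"hard-core overlap: minimum interatomic distance "
                    f"{rmin:.3f} A < {HARD_CORE_CUTOFF} A"
                )

        batch = pos.shape[:-2]
        energy = np.zeros(batch)
        forces = np.zeros_like(pos)

        def scatter(idx, grad):
            # accumulate -dE/dr contributions onto atoms; idx (T,), grad (...,T,3)
            np.add.at(forces, (..., idx, slice(None)), grad)

        if self._hb_idx.size:
            r, u = geometry.distance_gradients(pos, self._hb_idx)
            dr = r - self._hb_r0
            energy += np.sum(0.5 * self._hb_k * dr**2, axis=-1)
            dEdr = (self._hb_k * dr)[..., None]
            scatter(self._hb_idx[:, 0], dEdr * u)
            scatter(self._hb_idx[:, 1], -dEdr * u)

        if self._mb_idx.size:
            r, u = geometry.distance_gradients(pos, self._mb_idx)
            ex = np.exp(-self._mb_a * (r - self._mb_r0))
            energy += np.sum(self._mb_De * (1.0 - ex) ** 2, axis=-1)
            dEdr = (2.0 * self._mb_De * self._mb_a * (1.0 - ex) * ex)[..., None]
            scatter(self._mb_idx[:, 0], dEdr * u)
            scatter(self._mb_idx[:, 1], -dEdr * u)

        if self._an_idx.size:
            th, gi, gj, gk = geometry.angle_gradients(pos, self._an_idx)
            dth = th - self._an_t0
            energy += np.sum(0.5 * self._an_k * dth**2, axis=-1)
            dEdth = (self._an_k * dth)[..., None]
            scatter(self._an_idx[:, 0], -dEdth * gi)
            scatter(self._an_idx[:, 1], -dEdth * gj)
            scatter(self._an_idx[:, 2], -dEdth * gk)

        if self._tf_quads.size:
            phi, g1, g2, g3, g4 = geometry.dihedral_gradients(pos, self._tf_quads)
            ph = phi[..., self._tf_owner]
            arg = self._tf_n * ph - self._tf_d
            energy += np.sum(self._tf_k * (1.0 + np.cos(arg)), axis=-1)
            dEdphi_h = -self._tf_k * self._tf_n * np.sin(arg)
            dEdphi = np.zeros(phi.shape)
            np.add.at(dEdphi, (..., self._tf_owner), dEdphi_h)
            dEdphi = dEdphi[..., None]
            scatter(self._tf_quads[:, 0], -dEdphi * g1)
            scatter(self._tf_quads[:, 1], -dEdphi * g2)
            scatter(self._tf_quads[:, 2], -dEdphi * g3)
            scatter(self._tf_quads[:, 3], -dEdphi * g4)

        if self._tw:
            nw = len(self._tw)
            phi, g1, g2, g3, g4 = geometry.dihedral_gradients(pos, self._tw_quads)
            # first nw entries are quad1 of each well, next nw are quad2
            expo = self._tw_kap * (np.cos(phi - self._tw_c) - 1.0)
            well = -self._tw_A * np.exp(expo[..., :nw] + expo[..., nw:])
            energy += np.sum(well, axis=-1)
            # dE/dphi_m = well * d expo_m/dphi_m
            dexpo = -self._tw_kap * np.sin(phi - self._tw_c)
            dEdphi = (np.concatenate([well, well], axis=-1) * dexpo)[..., None]
            scatter(self._tw_quads[:, 0], -dEdphi * g1)
            scatter(self._tw_quads[:, 1], -dEdphi * g2)
            scatter(self._tw_quads[:, 2], -dEdphi * g3)
            scatter(self._tw_quads[:, 3], -dEdphi * g4)

        if self._sh:
            d = pos[..., self._sh_atom, :] - self._sh_c
            energy += np.sum(0.5 * self._sh_k * d**2, axis=(-1, -2))
            scatter(self._sh_atom, -self._sh_k * d)

        if self._sm:
            d = pos[..., self._sm_atom, :] - self._sm_c
            s = np.sum(d * self._sm_axis, axis=-1)
            ex = np.exp(-self._sm_a * s)
            energy += np.sum(self._sm_De * (1.0 - ex) ** 2, axis=-1)
            dEds = (2.0 * self._sm_De * self._sm_a * (1.0 - ex) * ex)[..., None]
            scatter(self._sm_atom, -dEds * self._sm_axis)

        if not np.all(np.isfinite(energy)):
            raise EvaluationError("non-finite energy encountered")
        return energy, forces, self.charges(pos)

    def charges(self, positions: np.ndarray) -> np.ndarray:
        """Per-atom charges (e) at ``positions``; sums to the net charge."""
        pos = np.asarray(positions, dtype=float)
        q = np.broadcast_to(self._q_ref, pos.shape[:-2] + (self.n_atoms,)).copy()
        if self._fx_idx.size:
            r = geometry.distances(pos, self._fx_idx)
            dq = self._fx_j * (r - self._fx_r0)
            np.add.at(q, (..., self._fx_idx[:, 1]), dq)
            np.add.at(q, (..., self._fx_idx[:, 0]), -dq)
        return q

    def dipole(self, positions: np.ndarray) -> np.ndarray:
        """mu = sum_i q_i r_i, in e*A, shape (..., 3)."""
        pos = np.asarray(positions, dtype=float)
        return np.sum(self.charges(pos)[..., None] * pos, axis=-2)

    # -- torsion landscape -------------------------------------------------

    def torsion_energy(self, theta1_deg, theta2_deg) -> np.ndarray:
        """Analytic torsion-term energy on the (theta1, theta2) map.

        Evaluates only the terms that depend exclusively on the two
        reaction-coordinate dihedrals (the coupled wells, plus Fourier
        torsions defined on those same quads), which is the sculpted
        part of the landscape. Used to verify the basin pattern.
        """
        if self.torsion_spec is None:
            raise ModelError("model has no torsion landscape spec")
        t1 = np.deg2rad(np.asarray(theta1_deg, float))
        t2 = np.deg2rad(np.asarray(theta2_deg, float))
        e = np.zeros(np.broadcast(t1, t2).shape)
        q1, q2 = tuple(self.torsion_spec.quad1), tuple(self.torsion_spec.quad2)
        for t in self.terms:
            if isinstance(t, TorsionWell):
                e += -t.amplitude * np.exp(
                    t.kappa1 * (np.cos(t1 - t.center1) - 1.0)
                    + t.kappa2 * (np.cos(t2 - t.center2) - 1.0)
                )
            elif isinstance(t, TorsionFourier):
                quad = (t.i, t.j, t.k_, t.l)
                ph = t1 if quad == q1 else t2 if quad == q2 else None
                if ph is not None:
                    for (n, kn, dn) in t.terms:
                        e = e + kn * (1.0 + np.cos(n * ph - dn))
        return e

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str | None:
        """Serialize to a human-readable YAML config (round-trips exactly)."""
        doc = {
            "labels": self.labels,
            "masses": self.masses.tolist(),
            "net_charge": self.net_charge,
            "reference_positions": self.reference_positions.tolist(),
            "charges": {
                "reference": list(self.charge_model.reference),
                "fluxes": [list(f) for f in self.charge_model.fluxes],
            },
            "terms": [
                {"type": type(t).__name__, **_term_fields(t)} for t in self.terms
            ],
            "metadata": self.metadata,
        }
        if self.torsion_spec is not None:
            doc["torsion_spec"] = {
                "quad1": list(self.torsion_spec.quad1),
                "quad2": list(self.torsion_spec.quad2),
                "basins": [list(b) for b in self.torsion_spec.basins],
                "kappa": self.torsion_spec.kappa,
            }
        text = yaml.safe_dump(_pyify(doc), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "MolecularModel":
        """Load a model from a YAML string, path or open file."""
        if isinstance(source, str) and "\n" not in source:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(source, io.IOBase):
            doc = yaml.safe_load(source)
        else:
            doc = yaml.safe_load(source)
        terms = [_term_from_dict(d) for d in doc["terms"]]
        cm = ChargeModel(
            reference=tuple(doc["charges"]["reference"]),
            fluxes=tuple(tuple(f) for f in doc["charges"]["fluxes"]),
        )
        spec = None
        if "torsion_spec" in doc:
            ts = doc["torsion_spec"]
            spec = TorsionLandscapeSpec(
                quad1=tuple(ts["quad1"]),
                quad2=tuple(ts["quad2"]),
                basins=tuple(tuple(b) for b in ts["basins"]),
                kappa=ts["kappa"],
            )
        return cls(
            labels=doc["labels"],
            masses=doc["masses"],
            terms=terms,
            charge_model=cm,
            net_charge=doc["net_charge"],
            reference_positions=np.array(doc["reference_positions"]),
            torsion_spec=spec,
            metadata=doc.get("metadata", {}),
        )


def _pyify(obj):
    """Recursively convert numpy scalars/containers to plain Python."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


_TERM_TYPES = {
    t.__name__: t
    for t in (
        HarmonicBond,
        MorseBond,
        HarmonicAngle,
        TorsionFourier,
        TorsionWell,
        SiteHarmonic,
        SiteMorse,
    )
}


def _term_fields(t) -> dict:
    d = dataclasses.asdict(t)
    return {
        k: (list(list(x) if isinstance(x, tuple) else x for x in v)
            if isinstance(v, tuple) else v)
        for k, v in d.items()
    }


def _term_from_dict(d: dict):
    d = dict(d)
    cls = _TERM_TYPES[d.pop("type")]
    kw = {}
    for f in dataclasses.fields(cls):
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kw[f.name] = v
    return cls(**kw)


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------


def _stretch_k(mu_amu: float, wavenumber_cm1: float) -> float:
    """Harmonic force constant (kcal/mol/A^2) giving the requested
    stretch wavenumber at reduced mass mu."""
    w = units.omega_from_wavenumber(wavenumber_cm1)
    return mu_amu * w * w * units.INTERNAL_TO_KCAL


def build_harmonic_oscillator(
    mass: float, wavenumber: float, charge: float, n_atoms: int = 1
) -> MolecularModel:
    """A particle of ``mass`` amu in an isotropic harmonic well.

    Each Cartesian component vibrates at exactly ``wavenumber`` cm^-1
    and the dipole is ``charge * r``, so the model is an exact oracle
    for spectral estimators and ring-polymer statistics. ``n_atoms`` > 1
    replicates the well into that many independent particles (handy for
    statistics; they do not interact).
    """
    if mass <= 0 or wavenumber <= 0:
        raise ModelError("mass and wavenumber must be positive")
    k = _stretch_k(mass, wavenumber)
    terms = [SiteHarmonic(atom=i, kvec=(k, k, k)) for i in range(n_atoms)]
    return MolecularModel(
        labels=["X"] * n_atoms,
        masses=[mass] * n_atoms,
        terms=terms,
        charge_model=ChargeModel(reference=(charge,) * n_atoms),
        net_charge=charge * n_atoms,
        reference_positions=np.zeros((n_atoms, 3)),
        metadata={"kind": "harmonic_oscillator", "wavenumber_cm1": wavenumber},
    )


def build_morse_oscillator(
    mass: float,
    wavenumber: float,
    De: float = 110.0,
    charge: float = 1.0,
    transverse_wavenumber: float = 5000.0,
) -> MolecularModel:
    """A particle in a 1D Morse potential along x (harmonic wavenumber
    ``wavenumber`` cm^-1, well depth ``De`` kcal/mol) with stiff
    harmonic confinement in y, z (kept far above the analysis band).

    The Morse level spacing decreases with energy, so zero-point-aware
    dynamics red-shifts the fundamental relative to classical dynamics
    at low temperature — the minimal model of the anharmonic red shift.
    """
    if mass <= 0 or wavenumber <= 0 or De <= 0:
        raise ModelError("mass, wavenumber and De must be positive")
    w = units.omega_from_wavenumber(wavenumber)
    a = w * math.sqrt(mass / (2.0 * De * units.KCAL_TO_INTERNAL))
    kt = _stretch_k(mass, transverse_wavenumber)
    terms = [
        SiteMorse(atom=0, axis=(1.0, 0.0, 0.0), De=De, a=a),
        SiteHarmonic(atom=0, kvec=(0.0, kt, kt)),
    ]
    return MolecularModel(
        labels=["X"],
        masses=[mass],
        terms=terms,
        charge_model=ChargeModel(reference=(charge,)),
        net_charge=charge,
        reference_positions=np.zeros((1, 3)),
        metadata={
            "kind": "morse_oscillator",
            "wavenumber_cm1": wavenumber,
            "De_kcalmol": De,
        },
    )


def build_diatomic(
    mass1: float,
    mass2: float,
    wavenumber: float,
    charge: float = 0.3,
    r0: float = 1.0,
    flux: float = 0.2,
) -> MolecularModel:
    """A harmonic diatomic with charges (+q, -q) and bond-charge flux.

    The stretch vibrates at ``wavenumber`` cm^-1 (reduced mass); used
    to exercise internal-coordinate series on a real bond.
    """
    mu = mass1 * mass2 / (mass1 + mass2)
    k = _stretch_k(mu, wavenumber)
    return MolecularModel(
        labels=["A", "B"],
        masses=[mass1, mass2],
        terms=[HarmonicBond(0, 1, r0=r0, k=k)],
        charge_model=ChargeModel(
            reference=(charge, -charge), fluxes=((0, 1, flux, r0),)
        ),
        net_charge=0.0,
        reference_positions=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        metadata={"kind": "diatomic", "wavenumber_cm1": wavenumber},
    )


# reference geometry of the 13-atom deprotonated-serine analog (A).
# atoms: O1 C' O2 CA N CB OG HA HN1 HN2 HB1 HB2 HG
_SERINE_LABELS = [
    "O1", "C", "O2", "CA", "N", "CB", "OG", "HA", "HN1", "HN2", "HB1", "HB2", "HG",
]
_SERINE_MASSES = [
    15.999, 12.011, 15.999, 12.011, 14.007, 12.011, 15.999,
    1.008, 1.008, 1.008, 1.008, 1.008, 1.008,
]
_SERINE_REF = np.array(
    [
        [2.2848, 0.5454, 0.0254],    # O1
        [1.0701, 0.8785, -0.1200],   # C'
        [0.5281, 2.0216, -0.0533],   # O2
        [0.0888, -0.3129, -0.4328],  # CA
        [0.7512, -1.6103, -0.0659],  # N
        [-1.2066, -0.0905, 0.3492],  # CB
        [-1.9430, 1.0265, -0.1568],  # OG
        [-0.1039, -0.3045, -1.5115], # HA
        [0.9758, -1.5254, 0.9296],   # HN1
        [1.6960, -1.4999, -0.4680],  # HN2
        [-1.8590, -0.9660, 0.2659],  # HB1
        [-1.0141, 0.0845, 1.4138],   # HB2
        [-1.2680, 1.7530, -0.1756],  # HG
    ]
)
# indices
_O1, _C, _O2, _CA, _N, _CB, _OG = 0, 1, 2, 3, 4, 5, 6
_HA, _HN1, _HN2, _HB1, _HB2, _HG = 7, 8, 9, 10, 11, 12

#: theta1 = CA-CB-OG-HG (hydroxyl torsion), theta2 = C'-CA-CB-OG (backbone)
SERINE_QUAD1 = (_CA, _CB, _OG, _HG)
SERINE_QUAD2 = (_C, _CA, _CB, _OG)

#: the three-conformer default landscape: (theta1_deg, theta2_deg, depth)
SERINE_DEFAULT_BASINS = ((-35.0, 55.0, 0.0), (35.0, -55.0, 2.4), (35.0, -170.0, 7.0))

# harmonic stretch wavenumber targets (cm^-1) at the global minimum
_STRETCH_TARGETS = {"OH": 3450.0, "NH": 3320.0, "CH": 2930.0}


def default_torsion_spec() -> TorsionLandscapeSpec:
    """The default 3-basin landscape of the serine analog."""
    return TorsionLandscapeSpec(
        quad1=SERINE_QUAD1, quad2=SERINE_QUAD2, basins=SERINE_DEFAULT_BASINS
    )


def build_toy_serine(
    spec: TorsionLandscapeSpec | None = None,
    seed: int = 0,
    depth_tolerance: float = 1.0,
) -> MolecularModel:
    """Build the 13-atom deprotonated-serine analog (net charge -1).

    The skeleton carries harmonic bonds/angles with equilibrium values
    taken from the reference geometry; the O-H analog is a Morse bond
    and the N-H / C-H analogs are harmonic stretches placed in the
    2600-3600 cm^-1 band. The two-torsion conformer landscape is
    sculpted by coupled periodic wells at the basins requested in
    ``spec``; the well amplitudes are solved by a small least-squares
    fit so the realized basin depths match the requested ones, and the
    result is verified on a 5 deg torsion grid. ``seed`` only perturbs
    the optimizer's starting guess; the construction is deterministic
    given (spec, seed).
    """
    spec = spec or default_torsion_spec()
    if len(spec.basins) < 1:
        raise ModelError("landscape spec must define at least one basin")
    flat = all(b[2] == 0.0 for b in spec.basins) and len(spec.basins) == 1

    masses = np.array(_SERINE_MASSES)
    pos = _SERINE_REF

    def mu(i, j):
        return masses[i] * masses[j] / (masses[i] + masses[j])

    bonds_heavy = [
        (_C, _O1, 840.0),
        (_C, _O2, 840.0),
        (_C, _CA, 320.0),
        (_CA, _N, 330.0),
        (_CA, _CB, 300.0),
        (_CB, _OG, 360.0),
    ]
    terms: list[object] = []
    for i, j, k in bonds_heavy:
        r0 = float(np.linalg.norm(pos[j] - pos[i]))
        terms.append(HarmonicBond(i, j, r0=r0, k=k))
    for i, j in ((_CA, _HA), (_CB, _HB1), (_CB, _HB2)):
        r0 = float(np.linalg.norm(pos[j] - pos[i]))
        terms.append(HarmonicBond(i, j, r0=r0, k=_stretch_k(mu(i, j), _STRETCH_TARGETS["CH"])))
    for i, j in ((_N, _HN1), (_N, _HN2)):
        r0 = float(np.linalg.norm(pos[j] - pos[i]))
        terms.append(HarmonicBond(i, j, r0=r0, k=_stretch_k(mu(i, j), _STRETCH_TARGETS["NH"])))
    # O-H analog: Morse with the harmonic-limit k matching the target
    r0_oh = float(np.linalg.norm(pos[_HG] - pos[_OG]))
    De_oh = 110.0
    k_oh = _stretch_k(mu(_OG, _HG), _STRETCH_TARGETS["OH"])
    a_oh = math.sqrt(k_oh / (2.0 * De_oh))
    terms.append(MorseBond(_OG, _HG, r0=r0_oh, De=De_oh, a=a_oh))

    bond_pairs = {(min(i, j), max(i, j)) for i, j, *_ in bonds_heavy}
    bond_pairs |= {
        (min(i, j), max(i, j))
        for i, j in (
            (_CA, _HA), (_CB, _HB1), (_CB, _HB2), (_N, _HN1), (_N, _HN2), (_OG, _HG),
        )
    }
    adjacency: dict[int, list[int]] = {}
    for i, j in bond_pairs:
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)
    for j, nbrs in adjacency.items():
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[bi]
                tri = np.array([[i, j, k]])
                th0 = float(geometry.angles(pos[None], tri)[0, 0])
                terms.append(HarmonicAngle(i, j, k, theta0=th0, k=45.0))

    # small Fourier torsions stiffen the carboxylate and amine rotors
    # (otherwise free: rotations about C'-CA and N-CA change no bond or
    # angle), keeping all 3N-6 vibrational wavenumbers above the
    # zero-mode cutoff without reshaping the two-torsion landscape
    # the improper (O1, CA, C, O2) keeps the planar carboxylate carbon
    # rigid out-of-plane (its three angles are second-order there)
    for quad, n, kt in (
        ((_O1, _C, _CA, _N), 2, 2.0),
        ((_HN1, _N, _CA, _CB), 3, 1.5),
        ((_O1, _CA, _C, _O2), 2, 10.0),
    ):
        phi_ref = float(geometry.dihedrals(pos[None], np.array([list(quad)]))[0, 0])
        delta = n * phi_ref - math.pi  # reference geometry sits at the minimum
        terms.append(TorsionFourier(*quad, terms=((n, kt, delta),)))

    # torsional landscape: coupled wells at the requested basins
    if flat:
        wells: list[TorsionWell] = []
    else:
        amps = _solve_well_amplitudes(spec, seed)
        wells = [
            TorsionWell(
                quad1=spec.quad1,
                quad2=spec.quad2,
                center1=math.radians(b[0]),
                center2=math.radians(b[1]),
                kappa1=spec.kappa,
                kappa2=spec.kappa,
                amplitude=float(a),
            )
            for b, a in zip(spec.basins, amps)
        ]
    terms.extend(wells)

    q = {
        _O1: -0.66, _C: 0.62, _O2: -0.66, _CA: -0.01, _N: -0.72, _CB: 0.05,
        _OG: -0.62, _HA: 0.09, _HN1: 0.30, _HN2: 0.30, _HB1: 0.09, _HB2: 0.09,
        _HG: 0.39,
    }
    ref_q = np.array([q[i] for i in range(13)])
    ref_q[_CA] += -1.0 - ref_q.sum()  # enforce exact net charge
    r0_nh1 = float(np.linalg.norm(pos[_HN1] - pos[_N]))
    r0_nh2 = float(np.linalg.norm(pos[_HN2] - pos[_N]))
    cm = ChargeModel(
        reference=tuple(ref_q),
        fluxes=(
            (_OG, _HG, 0.25, r0_oh),
            (_N, _HN1, 0.20, r0_nh1),
            (_N, _HN2, 0.20, r0_nh2),
        ),
    )

    model = MolecularModel(
        labels=_SERINE_LABELS,
        masses=_SERINE_MASSES,
        terms=terms,
        charge_model=cm,
        net_charge=-1.0,
        reference_positions=pos,
        torsion_spec=spec,
        metadata={"kind": "toy_serine", "seed": seed},
    )

    if not flat:
        ok, report = verify_landscape(model, tolerance=depth_tolerance)
        if not ok:
            raise ModelError(f"unreachable basin targets: {report}")
        model.metadata["landscape_check"] = report
    return model


def _solve_well_amplitudes(spec: TorsionLandscapeSpec, seed: int) -> np.ndarray:
    """Solve well amplitudes so realized basin depths match the spec.

    Wells overlap, so the energy at basin b is a linear mix
    E_b = -sum_c A_c M_bc with M the von-Mises overlap matrix; we solve
    the linear system for the target E_b = -(A0 - depth_b), then refine
    with a bounded least squares (seeded starting point) to keep
    amplitudes positive.
    """
    from scipy.optimize import least_squares

    basins = np.array([list(b) for b in spec.basins], float)
    nb = len(basins)
    t1 = np.radians(basins[:, 0])
    t2 = np.radians(basins[:, 1])
    depth = basins[:, 2]
    kap = spec.kappa
    M = np.exp(
        kap * (np.cos(t1[:, None] - t1[None, :]) - 1.0)
        + kap * (np.cos(t2[:, None] - t2[None, :]) - 1.0)
    )  # M[b, c] = well c evaluated at basin b (unit amplitude)
    A0 = depth.max() + 1.5
    target = A0 - depth  # desired well depth below zero at each basin

    rng = np.random.default_rng(seed)
    x0 = np.linalg.solve(M, target)
    x0 = np.clip(x0 + 1e-6 * rng.standard_normal(nb), 0.05, None)

    def resid(a):
        return M @ a - target

    sol = least_squares(resid, x0, bounds=(0.0, np.inf))
    if not sol.success or np.max(np.abs(sol.fun)) > 0.5:
        raise ModelError(
            f"well-amplitude fit failed (residual {np.max(np.abs(sol.fun)):.3f})"
        )
    return sol.x


def verify_landscape(
    model: MolecularModel, grid_deg: float = 5.0, tolerance: float = 1.0
):
    """Scan the torsion landscape on a grid; locate minima and depths.

    Returns ``(ok, report)`` where ``report`` lists located minima as
    (theta1_deg, theta2_deg, depth) sorted by depth, and ``ok`` is True
    when each requested basin has a located minimum within one grid
    step in angle and within ``tolerance`` kcal/mol in depth.
    """
    spec = model.torsion_spec
    grid = np.arange(-180.0, 180.0, grid_deg)
    T1, T2 = np.meshgrid(grid, grid, indexing="ij")
    E = model.torsion_energy(T1, T2)
    minima = []
    n = len(grid)
    for a in range(n):
        for b in range(n):
            e0 = E[a, b]
            nb = [
                E[(a + da) % n, (b + db) % n]
                for da in (-1, 0, 1)
                for db in (-1, 0, 1)
                if (da, db) != (0, 0)
            ]
            if all(e0 < x for x in nb):
                minima.append((grid[a], grid[b], e0))
    if not minima:
        return False, []
    e_min = min(m[2] for m in minima)
    report = sorted(
        [(float(a), float(b), float(e - e_min)) for a, b, e in minima],
        key=lambda m: m[2],
    )
    ok = True
    for (bt1, bt2, bd) in spec.basins:
        best = None
        for (a, b, d) in report:
            da = abs(geometry.wrap_angle(math.radians(a - bt1)))
            db = abs(geometry.wrap_angle(math.radians(b - bt2)))
            if da <= math.radians(2 * grid_deg) and db <= math.radians(2 * grid_deg):
                best = d
                break
        if best is None or abs(best - bd) > tolerance:
            ok = False
    return ok, report


# --------------------------------------------------------------------------
# normal-mode analysis
# --------------------------------------------------------------------------

#: modes with |wavenumber| below this (cm^-1) count as zero modes
ZERO_MODE_CUTOFF = 10.0


def normal_modes(
    model: MolecularModel,
    positions: np.ndarray,
    force_tolerance: float = 1e-3,
    h: float = 1e-4,
):
    """Mass-weighted normal-mode analysis at a stationary point.

    The Hessian is built by central finite differences of the analytic
    forces (step ``h`` A). Returns ``(wavenumbers, modes, n_zero)``:
    wavenumbers in cm^-1 sorted ascending with zero modes excluded
    (negative values flag imaginary frequencies), ``modes`` the
    corresponding mass-weighted eigenvectors as rows reshaped to
    (n_modes, n_atoms, 3), and ``n_zero`` the count of near-zero modes
    (6 for a nonlinear molecule, 0 for a particle bound in an external
    well).

    Raises
    ------
    ModelError
        if ``positions`` is not a stationary point (max |F| reported).
    """
    pos = np.asarray(positions, dtype=float)
    _, f0, _ = model.evaluate(pos)
    fmax = float(np.abs(f0).max())
    if fmax > force_tolerance:
        raise ModelError(
            f"normal modes need a stationary point: max |F| = {fmax:.3e} "
            f"kcal/mol/A exceeds {force_tolerance:.1e}"
        )
    n = model.n_atoms
    dof = 3 * n
    # batched displacement stencil: one evaluate() call for all 2*dof points
    disp = np.zeros((2 * dof, n, 3))
    for d in range(dof):
        disp[2 * d, d // 3, d % 3] = h
        disp[2 * d + 1, d // 3, d % 3] = -h
    _, fd, _ = model.evaluate(pos[None] + disp, check_core=False)
    fd = fd.reshape(2 * dof, dof)
    hess = (fd[1::2] - fd[0::2]) / (2.0 * h)  # -dF/dx = d2E/dx2
    hess = 0.5 * (hess + hess.T)
    minv = 1.0 / np.sqrt(np.repeat(model.masses, 3))
    hw = hess * minv[:, None] * minv[None, :] * units.KCAL_TO_INTERNAL
    evals, evecs = np.linalg.eigh(hw)
    omega = np.sign(evals) * np.sqrt(np.abs(evals))  # rad/fs, signed
    wn = np.array([units.wavenumber_from_omega(w) for w in omega])
    zero = np.abs(wn) < ZERO_MODE_CUTOFF
    n_zero = int(zero.sum())
    keep = ~zero
    order = np.argsort(wn[keep])
    modes = evecs.T[keep][order].reshape(-1, n, 3)
    return wn[keep][order], modes, n_zero
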