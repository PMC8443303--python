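"""Run configuration and protocol presets.

Two presets resolve every protocol parameter:

* ``paper`` — the emulated reference protocol: dt = 0.5 fs; classical
  50 ps Langevin equilibration + ~32 ps NVE production; TRPMD 40 ps
  equilibration, snapshots every 1000 steps seeding 50 replicas of
  ~32 ps, 32 beads at 100 K / 16 beads at 298.15 K; umbrella windows
  every 5 deg, 100 ps each, cosine biases of (75, 65) kcal/mol at
  100 K and (150, 125) kcal/mol at 298.15 K for the classical engine
  and the literal harmonic 200 kJ/mol (degrees convention) for TRPMD.
* ``desk`` — the same pipeline at laptop scale for development and
  testing: shorter runs, fewer replicas, 15 deg windows.

A `RunConfig` names the model, engine, temperature and preset; its
``resolve()`` output is a complete, serializable parameter dictionary
written next to every output for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .md import MDConfig
from .ringpolymer import TRPMDProtocol

__all__ = ["RunConfig", "PRESETS", "classical_config", "trpmd_protocol", "umbrella_params"]

PRESETS = {
    "paper": {
        "timestep_fs": 0.5,
        "classical": {
            "equilibration_ps": 50.0,
            "production_ps": 32.0,
            "n_replicas": 1,
            "friction_fs": 0.01,
        },
        "trpmd": {
            "equilibration_ps": 40.0,
            "snapshot_stride": 1000,
            "n_replicas": 50,
            "production_ps": 32.0,
        },
        "umbrella": {
            "spacing_deg": 5.0,
            "length_ps": 100.0,
            "classical_bias": "cosine",
            "classical_constants": {100.0: (75.0, 65.0), 298.15: (150.0, 125.0)},
            "trpmd_bias": "harmonic",
            "trpmd_constants": (200.0, 200.0),  # kJ/mol, degrees convention
        },
    },
    # sub-minute sizes for command-line smoke runs and quick checks
    "smoke": {
        "timestep_fs": 0.5,
        "classical": {
            "equilibration_ps": 0.2,
            "production_ps": 0.5,
            "n_replicas": 1,
            "friction_fs": 0.05,
        },
        "trpmd": {
            "equilibration_ps": 0.1,
            "snapshot_stride": 50,
            "n_replicas": 2,
            "production_ps": 0.5,
        },
        "umbrella": {
            "spacing_deg": 90.0,
            "length_ps": 0.5,
            "classical_bias": "cosine",
            "classical_constants": {100.0: (20.0, 20.0), 298.15: (20.0, 20.0)},
            "trpmd_bias": "harmonic",
            "trpmd_constants": (3.0, 3.0),
        },
    },
    "desk": {
        "timestep_fs": 0.5,
        "classical": {
            "equilibration_ps": 5.0,
            "production_ps": 8.0,
            "n_replicas": 3,
            "friction_fs": 0.02,
        },
        "trpmd": {
            "equilibration_ps": 2.0,
            "snapshot_stride": 400,
            "n_replicas": 4,
            "production_ps": 8.0,
        },
        "umbrella": {
            "spacing_deg": 15.0,
            "length_ps": 10.0,
            "classical_bias": "cosine",
            "classical_constants": {100.0: (20.0, 20.0), 298.15: (20.0, 20.0)},
            "trpmd_bias": "harmonic",
            "trpmd_constants": (3.0, 3.0),  # kJ/mol/deg^2, desk-scale stiffness
        },
    },
}


def classical_config(
    temperature_K: float, preset: str = "paper", seed: int = 0, **overrides
) -> MDConfig:
    """Resolve an `MDConfig` from a preset (+ explicit overrides)."""
    p = PRESETS[preset]
    kw = {
        "temperature_K": temperature_K,
        "timestep_fs": p["timestep_fs"],
        "equilibration_ps": p["classical"]["equilibration_ps"],
        "production_ps": p["classical"]["production_ps"],
        "friction_fs": p["classical"]["friction_fs"],
        "seed": seed,
    }
    kw.update(overrides)
    return MDConfig(**kw)


def trpmd_protocol(
    temperature_K: float, preset: str = "paper", seed: int = 0, **overrides
) -> TRPMDProtocol:
    """Resolve a `TRPMDProtocol` from a preset (+ explicit overrides).

    Bead counts resolve by temperature (32 below 200 K, 16 above)
    unless overridden.
    """
    p = PRESETS[preset]
    kw = {
        "temperature_K": temperature_K,
        "timestep_fs": p["timestep_fs"],
        "equilibration_ps": p["trpmd"]["equilibration_ps"],
        "snapshot_stride": p["trpmd"]["snapshot_stride"],
        "n_replicas": p["trpmd"]["n_replicas"],
        "production_ps": p["trpmd"]["production_ps"],
        "seed": seed,
    }
    kw.update(overrides)
    return TRPMDProtocol(**kw)


def umbrella_params(
    temperature_K: float, engine: str = "classical", preset: str = "paper"
) -> dict:
    """Window spacing, run length and bias form/constants for a preset."""
    u = PRESETS[preset]["umbrella"]
    if engine == "classical":
        consts = u["classical_constants"]
        key = min(consts, key=lambda t: abs(t - temperature_K))
        return {
            "spacing_deg": u["spacing_deg"],
            "length_ps": u["length_ps"],
            "bias": u["classical_bias"],
            "constants": consts[key],
        }
    return {
        "spacing_deg": u["spacing_deg"],
        "length_ps": u["length_ps"],
        "bias": u["trpmd_bias"],
        "constants": u["trpmd_constants"],
    }


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    model: str = "toy-serine"  # builtin name or path to a model YAML
    engine: str = "classical"  # "classical" | "trpmd"
    temperature_K: float = 298.15
    preset: str = "desk"
    output_dir: str = "ringspec-out"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.engine not in ("classical", "trpmd"):
            raise ValueError("engine must be 'classical' or 'trpmd'")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def resolve(self) -> dict:
        """The complete parameter set this config implies."""
        p = PRESETS[self.preset]
        out = {
            "model": self.model,
            "engine": self.engine,
            "temperature_K": self.temperature_K,
            "preset": self.preset,
            "seed": self.seed,
            "timestep_fs": p["timestep_fs"],
            "classical": dict(p["classical"]),
            "trpmd": dict(p["trpmd"]),
            "umbrella": umbrella_params(self.temperature_K, self.engine, self.preset),
        }
        from .ringpolymer import default_n_beads

        out["trpmd"]["n_beads"] = default_n_beads(self.temperature_K)
        for k, v in self.overrides.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k].update(v)
            else:
                out[k] = v
        return out
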