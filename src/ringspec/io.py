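"""File formats: extended XYZ with a charge column, TSV/JSON writers.

The trajectory carrier is extended XYZ: per frame an atom count line,
a comment line of key=value pairs including a ``Properties`` descriptor
(``species:S:1:pos:R:3:charge:R:1``), then one line per atom with
symbol, x, y, z and charge at %.10f. The dialect interoperates with
common atomistic toolchains; frames can be streamed without loading
the file into memory.

Spectra, histograms, assignment tables and PMF grids are written as
TSV with a JSON provenance sidecar sufficient to re-run the producing
step.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .md import Trajectory
from .spectra import Spectrum
from .wham import PMFSurface

__all__ = [
    "ExtXYZError",
    "write_extxyz",
    "iter_extxyz",
    "read_extxyz",
    "write_spectrum",
    "read_spectrum",
    "write_pmf",
    "write_table",
    "write_histograms",
]

_FMT = "%.10f"


class ExtXYZError(ValueError):
    """Malformed extended-XYZ content; message carries the line number."""


def _format_value(v):
    if isinstance(v, bool):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    s = str(v)
    return f'"{s}"' if (" " in s or "=" in s) else s


def _parse_value(s: str):
    if s.startswith('"') and s.endswith('"'):
        return s[1:-1]
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("T", "F"):
        return s == "T"
    return s


def _parse_comment(line: str) -> dict:
    out = {}
    token = ""
    in_quote = False
    tokens = []
    for ch in line.strip():
        if ch == '"':
            in_quote = not in_quote
            token += ch
        elif ch == " " and not in_quote:
            if token:
                tokens.append(token)
            token = ""
        else:
            token += ch
    if token:
        tokens.append(token)
    for t in tokens:
        if "=" in t:
            k, v = t.split("=", 1)
            out[k] = _parse_value(v)
    return out


def write_extxyz(traj: Trajectory, path, labels=None) -> None:
    """Write a trajectory as extended XYZ with a charge column.

    Positions and charges round-trip losslessly to %.10f. Scalar
    metadata entries are carried on the comment line of every frame.
    """
    labels = list(labels) if labels is not None else ["X"] * traj.n_atoms
    has_q = traj.charges is not None and traj.charges.size > 0
    props = "species:S:1:pos:R:3" + (":charge:R:1" if has_q else "")
    meta = {
        k: v
        for k, v in traj.metadata.items()
        if isinstance(v, (str, int, float, bool, np.integer, np.floating))
    }
    meta["dt_fs"] = traj.dt_fs
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            pairs = {"Properties": props, "time_fs": float(traj.times_fs[fi]), **meta}
            fh.write(" ".join(f"{k}={_format_value(v)}" for k, v in pairs.items()))
            fh.write("\n")
            for ai in range(traj.n_atoms):
                x, y, z = traj.positions[fi, ai]
                row = f"{labels[ai]} {_FMT % x} {_FMT % y} {_FMT % z}"
                if has_q:
                    row += f" {_FMT % traj.charges[fi, ai]}"
                fh.write(row + "\n")


def iter_extxyz(path) -> Iterator[dict]:
    """Stream frames from an extended-XYZ file one at a time.

    Yields dicts with ``labels``, ``positions`` (n, 3), ``charges``
    (n,) or None, and ``comment`` (the parsed key=value header).
    Memory use is bounded by a single frame.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            if not header.strip():
                continue
            try:
                n = int(header.strip())
            except ValueError as err:
                raise ExtXYZError(
                    f"line {lineno}: expected atom count, got {header.strip()!r}"
                ) from err
            comment = _parse_comment(fh.readline())
            lineno += 1
            props = str(comment.get("Properties", "species:S:1:pos:R:3"))
            has_q = "charge" in props
            labels = []
            pos = np.empty((n, 3))
            q = np.empty(n) if has_q else None
            for i in range(n):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                want = 5 if has_q else 4
                if len(parts) < want:
                    raise ExtXYZError(
                        f"line {lineno}: expected {want} columns, got "
                        f"{len(parts)}: {line.strip()!r}"
                    )
                labels.append(parts[0])
                try:
                    pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                    if has_q:
                        q[i] = float(parts[4])
                except ValueError as err:
                    raise ExtXYZError(
                        f"line {lineno}: non-numeric coordinate in "
                        f"{line.strip()!r}"
                    ) from err
            yield {
                "labels": labels,
                "positions": pos,
                "charges": q,
                "comment": comment,
            }


def read_extxyz(path) -> tuple[Trajectory, list[str]]:
    """Read a whole extended-XYZ trajectory; returns (trajectory, labels).

    For very long files prefer `iter_extxyz` which streams frames.
    A file without a charge column is readable; the resulting
    trajectory carries ``charges=None`` and any dipole assembly on it
    fails with the documented error.
    """
    frames = list(iter_extxyz(path))
    if not frames:
        raise ExtXYZError("empty trajectory file")
    labels = frames[0]["labels"]
    pos = np.stack([f["positions"] for f in frames])
    has_q = frames[0]["charges"] is not None
    q = np.stack([f["charges"] for f in frames]) if has_q else None
    times = np.array(
        [float(f["comment"].get("time_fs", i)) for i, f in enumerate(frames)]
    )
    c0 = frames[0]["comment"]
    dt = float(c0.get("dt_fs", times[1] - times[0] if len(times) > 1 else 1.0))
    meta = {
        k: v for k, v in c0.items() if k not in ("Properties", "time_fs", "dt_fs")
    }
    return (
        Trajectory(
            positions=pos,
            charges=q if has_q else np.empty((len(frames), 0)),
            times_fs=times,
            dt_fs=dt,
            metadata=meta,
        ),
        labels,
    )


# --------------------------------------------------------------------------
# tabular writers
# --------------------------------------------------------------------------


def _sidecar(path: Path, payload: dict) -> None:
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def write_spectrum(spectrum: Spectrum, path) -> None:
    """TSV (wavenumber_cm-1, intensity, std) plus a JSON provenance
    sidecar (window, correction mode, temperature, replica count...)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "wavenumber_cm-1": spectrum.wavenumbers_cm1,
            "intensity": spectrum.intensity,
            "std": (
                spectrum.std
                if spectrum.std is not None
                else np.zeros_like(spectrum.intensity)
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    _sidecar(path, spectrum.provenance)


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    prov = {}
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        with open(side) as fh:
            prov = json.load(fh)
    std = df["std"].to_numpy() if "std" in df else None
    return Spectrum(
        df["wavenumber_cm-1"].to_numpy(), df["intensity"].to_numpy(), std, prov
    )


def write_pmf(pmf: PMFSurface, path) -> None:
    """Gridded TSV (theta1_deg, theta2_deg, G_kcalmol, n_samples);
    masked bins carry empty G."""
    path = Path(path)
    rows = []
    for i, t1 in enumerate(pmf.theta1_deg):
        for j, t2 in enumerate(pmf.theta2_deg):
            rows.append(
                {
                    "theta1_deg": t1,
                    "theta2_deg": t2,
                    "G_kcalmol": pmf.free_energy[i, j] if pmf.mask[i, j] else np.nan,
                    "n_samples": (
                        int(pmf.counts[i, j]) if pmf.counts is not None else -1
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    _sidecar(path, {"temperature_K": pmf.temperature_K, **pmf.metadata})


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if provenance:
        _sidecar(path, provenance)


def write_histograms(histograms, path) -> None:
    """All histograms in one long-format TSV (label, bin_center, density)."""
    path = Path(path)
    rows = []
    for h in histograms:
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        for c, d in zip(centers, h.density):
            rows.append({"label": h.label, "distance_A": c, "density": d})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    _sidecar(
        path,
        {
            "histograms": [
                {
                    "label": h.label,
                    "mean_A": h.mean,
                    "modes_A": list(h.modes),
                    "bimodal": h.bimodal,
                    "bin_width_A": h.bin_width,
                }
                for h in histograms
            ]
        },
    )
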