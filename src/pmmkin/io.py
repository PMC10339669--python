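"""Readers and writers for the plain-text (and HDF5) data dialects.

Quantum centers travel as structured JSON/YAML documents; perturbation
frames, gap traces, spectra and rate tables as delimited text with
``#``-prefixed header lines carrying a column manifest and provenance
(package version, seed, configuration hash).  Frame streams may also be
stored as an HDF5 group for large runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .kinetics import RateEstimate, TransitionEnergyTrace
from .qc_pmm import (
    Atom,
    InputError,
    PerturbationFrame,
    QuantumCenter,
    UnperturbedState,
)
from .vibronic import Spectrum, VibronicModeSet

__all__ = [
    "config_hash",
    "save_quantum_center",
    "load_quantum_center",
    "write_frames",
    "read_frames",
    "write_gap_trace",
    "read_gap_trace",
    "write_spectrum",
    "read_spectrum",
    "write_rate_table",
]

PACKAGE_VERSION = "0.1.0"
_FLOAT_FMT = "%.10g"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping (provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(columns: Sequence[str], meta: Optional[dict] = None) -> str:
    lines = [f"# pmmkin {PACKAGE_VERSION}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("# columns: " + "\t".join(columns))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# quantum centers


def _qc_to_dict(qc: QuantumCenter) -> dict:
    return {
        "atoms": [
            {"element": a.element, "mass": a.mass, "position": a.position.tolist()}
            for a in qc.atoms
        ],
        "states": [
            {
                "label": s.label,
                "energy": s.energy,
                "atomic_charges": s.atomic_charges.tolist(),
                "diagonal_dipole": s.diagonal_dipole.tolist(),
                "vibronic_correction": s.vibronic_correction,
            }
            for s in qc.states
        ],
        "transition_dipoles": qc.transition_dipoles.tolist(),
        "mode_sets": {
            label: {
                "omegas": m.omegas.tolist(),
                "displacements": m.displacements.tolist(),
                "temperature": m.temperature,
            }
            for label, m in qc.mode_sets.items()
        },
    }


def _qc_from_dict(doc: dict) -> QuantumCenter:
    try:
        atoms = [Atom(a["element"], a["mass"], a["position"]) for a in doc["atoms"]]
        states = [
            UnperturbedState(
                label=s["label"],
                energy=s["energy"],
                atomic_charges=s["atomic_charges"],
                diagonal_dipole=s["diagonal_dipole"],
                vibronic_correction=s.get("vibronic_correction", 0.0),
            )
            for s in doc["states"]
        ]
        mode_sets = {
            label: VibronicModeSet(
                m["omegas"], m["displacements"], temperature=m["temperature"]
            )
            for label, m in doc.get("mode_sets", {}).items()
        }
    except KeyError as exc:
        raise InputError(f"quantum center document missing field {exc}")
    return QuantumCenter(
        atoms=atoms,
        states=states,
        transition_dipoles=np.asarray(doc["transition_dipoles"], float),
        mode_sets=mode_sets,
    )


def save_quantum_center(path, qc: QuantumCenter) -> None:
    """Write a QC as JSON or YAML, chosen by the file extension."""
    path = Path(path)
    doc = _qc_to_dict(qc)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def load_quantum_center(path) -> QuantumCenter:
    """Read and validate a QC document (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return _qc_from_dict(doc)


# ---------------------------------------------------------------------------
# perturbation frames: TSV (time, V_1..V_n, E_x, E_y, E_z, dV) or HDF5


def _frame_columns(n_atoms: int):
    return (
        ["time_fs"]
        + [f"V_{i+1}" for i in range(n_atoms)]
        + ["E_x", "E_y", "E_z", "dV"]
    )


def write_frames(path, frames: Sequence[PerturbationFrame], meta=None) -> None:
    path = Path(path)
    n_atoms = frames[0].site_potentials.size
    rows = np.array(
        [
            np.concatenate(([f.time], f.site_potentials, f.field, [f.offset]))
            for f in frames
        ]
    )
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as h5:
            grp = h5.create_group("frames")
            grp.create_dataset("table", data=rows)
            grp.attrs["columns"] = ",".join(_frame_columns(n_atoms))
        return
    header = _header_lines(_frame_columns(n_atoms), meta)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rows, fmt=_FLOAT_FMT, delimiter="\t")


def read_frames(path) -> list:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as h5:
            rows = np.asarray(h5["frames/table"])
    else:
        rows = np.loadtxt(path, ndmin=2)
    n_atoms = rows.shape[1] - 5
    if n_atoms < 1:
        raise InputError("frame table needs time, >=1 potential, field and dV columns")
    return [
        PerturbationFrame(
            time=r[0],
            site_potentials=r[1 : 1 + n_atoms],
            field=r[1 + n_atoms : 4 + n_atoms],
            offset=r[4 + n_atoms],
        )
        for r in rows
    ]


# ---------------------------------------------------------------------------
# gap traces and spectra


def write_gap_trace(path, trace: TransitionEnergyTrace, meta=None) -> None:
    header = _header_lines(["time_fs", "gap_kJmol", "velocity_kJmol_fs"], meta)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(
            fh,
            np.column_stack([trace.times, trace.gap, trace.velocity]),
            fmt=_FLOAT_FMT,
            delimiter="\t",
        )


def read_gap_trace(path) -> TransitionEnergyTrace:
    rows = np.loadtxt(path, ndmin=2)
    if rows.shape[1] == 2:
        return TransitionEnergyTrace.from_gap(rows[:, 0], rows[:, 1])
    return TransitionEnergyTrace(rows[:, 0], rows[:, 1], rows[:, 2])


def write_spectrum(path, spectrum: Spectrum, meta=None) -> None:
    meta = dict(meta or {})
    meta.setdefault("kind", spectrum.kind)
    meta.setdefault("normalization", spectrum.normalization)
    header = _header_lines(["energy_kJmol", "intensity"], meta)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(
            fh,
            np.column_stack([spectrum.grid, spectrum.intensity]),
            fmt=_FLOAT_FMT,
            delimiter="\t",
        )


def read_spectrum(path) -> Spectrum:
    kind, norm = "emission", "absolute"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
            if line.startswith("# normalization:"):
                norm = line.split(":", 1)[1].strip()
    rows = np.loadtxt(path, ndmin=2)
    return Spectrum(rows[:, 0], rows[:, 1], kind=kind, normalization=norm)


# ---------------------------------------------------------------------------
# kinetic results


def write_rate_table(path, rows: Sequence[tuple], meta=None) -> None:
    """Write (channel, RateEstimate) pairs as a delimited results table."""
    cols = ["channel", "method", "tau0_fs", "tau0_se_fs", "alpha_G", "alpha_G_se",
            "tau_fs"]
    header = _header_lines(cols, meta)

    def _fmt(x):
        return "nan" if x is None else (_FLOAT_FMT % x)

    with open(path, "w") as fh:
        fh.write(header)
        for channel, est in rows:
            fh.write(
                "\t".join(
                    [
                        channel,
                        est.method,
                        _fmt(est.tau0),
                        _fmt(est.tau0_se),
                        _fmt(est.alpha_g),
                        _fmt(est.alpha_g_se),
                        _fmt(est.tau),
                    ]
                )
                + "\n"
            )
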