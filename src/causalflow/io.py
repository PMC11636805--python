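"""Readers, writers, fixtures and run configuration.

File conventions
----------------
* Ensembles as delimited text: comment header lines ``# dt = ...`` and
  optionally ``# labels = ...``, then one row per unit whose first field is
  the unit id and remaining fields are samples; or as HDF5 with datasets
  ``values``, ``dt``, ``unit_ids`` and optional ``labels``.
* Directed matrices as delimited text with unit-id row/column headers,
  missing entries as empty cells, plus a JSON sidecar carrying method,
  parameters, seed and the significance mask path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    ArrayGeometry,
    BaselineMatrix,
    CFMatrix,
    EnsembleTimeSeries,
    ICMatrix,
    PerturbationSession,
    SimulatorParams,
    _DirectedMatrix,
)

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "write_matrix",
    "read_matrix",
    "write_geometry",
    "read_geometry",
    "write_session",
    "read_session",
    "make_fixture",
    "RunConfig",
    "file_checksum",
]

MATRIX_SIDECAR_SCHEMA = {
    "type": "object",
    "required": ["kind", "unit_ids", "meta"],
    "properties": {
        "kind": {"type": "string"},
        "method": {"type": "string"},
        "unit_ids": {"type": "array"},
        "meta": {"type": "object"},
        "sig_mask_path": {"type": "string"},
    },
}


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_ensemble(ts: EnsembleTimeSeries, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "delimited")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=ts.values)
            f.create_dataset("dt", data=ts.dt)
            f.create_dataset("unit_ids", data=np.array(ts.unit_ids, dtype="S"))
            if ts.subnetwork_labels is not None:
                f.create_dataset("labels", data=np.array(ts.subnetwork_labels, dtype="S"))
    else:
        with open(path, "w") as f:
            f.write(f"# dt = {ts.dt!r}\n")
            if ts.subnetwork_labels is not None:
                f.write("# labels = " + ",".join(ts.subnetwork_labels) + "\n")
            for uid, row in zip(ts.unit_ids, ts.values):
                f.write(uid + "," + ",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_ensemble(path: str | Path, fmt: str | None = None) -> EnsembleTimeSeries:
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "delimited")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("values", "dt", "unit_ids"):
                if key not in f:
                    raise ValueError(f"HDF5 ensemble missing dataset {key!r}")
            values = f["values"][...]
            dt = float(f["dt"][()])
            unit_ids = [u.decode() for u in f["unit_ids"][...]]
            labels = [u.decode() for u in f["labels"][...]] if "labels" in f else None
        return EnsembleTimeSeries(values, dt, unit_ids, labels)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty ensemble file {path}")
    dt = None
    labels = None
    unit_ids: list[str] = []
    rows: list[np.ndarray] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition("=")
            key = key.strip()
            if key == "dt":
                dt = float(val)
            elif key == "labels":
                labels = [s.strip() for s in val.split(",")]
            continue
        fields = line.split(",")
        unit_ids.append(fields[0])
        try:
            rows.append(np.array([float(v) for v in fields[1:]]))
        except ValueError as e:
            raise ValueError(f"unparseable sample in row {fields[0]!r}: {e}") from e
    if dt is None:
        raise ValueError("ensemble file missing '# dt = ...' header")
    if len(set(unit_ids)) != len(unit_ids):
        dupes = sorted({u for u in unit_ids if unit_ids.count(u) > 1})
        raise ValueError(f"duplicate unit ids: {dupes}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
    values = np.vstack(rows)
    if not np.all(np.isfinite(values)):
        raise ValueError("NaN cells rejected")
    return EnsembleTimeSeries(values, dt, unit_ids, labels)


_KIND = {"CFMatrix": CFMatrix, "ICMatrix": ICMatrix, "BaselineMatrix": BaselineMatrix}


def write_matrix(matrix: _DirectedMatrix, path: str | Path) -> Path:
    """Delimited matrix with unit-id headers + JSON sidecar + sig-mask file."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.unit_ids, columns=matrix.unit_ids)
    df.to_csv(path, na_rep="")
    mask_path = path.with_suffix(".sig.csv")
    pd.DataFrame(matrix.sig_mask.astype(int), index=matrix.unit_ids, columns=matrix.unit_ids).to_csv(
        mask_path
    )
    meta = {k: v for k, v in matrix.meta.items()}
    sidecar = {
        "kind": type(matrix).__name__,
        "method": getattr(matrix, "method", ""),
        "unit_ids": list(matrix.unit_ids),
        "meta": meta,
        "sig_mask_path": mask_path.name,
    }
    if isinstance(matrix, ICMatrix):
        sidecar["n_trials"] = matrix.n_trials
        sidecar["window"] = matrix.window
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_matrix(path: str | Path) -> _DirectedMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cls = _KIND[sidecar["kind"]]
    df = pd.read_csv(path, index_col=0)
    mask = pd.read_csv(path.parent / sidecar["sig_mask_path"], index_col=0).to_numpy().astype(bool)
    kwargs = dict(
        values=df.to_numpy(),
        unit_ids=[str(u) for u in df.index],
        sig_mask=mask,
        meta=sidecar.get("meta", {}),
    )
    if cls is BaselineMatrix:
        kwargs["method"] = sidecar.get("method", "")
    if cls is ICMatrix:
        kwargs["n_trials"] = sidecar.get("n_trials", {})
        kwargs["window"] = sidecar.get("window", 0.2)
    return cls(**kwargs)


def write_geometry(geom: ArrayGeometry, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"unit_id": geom.unit_ids, "x": geom.coordinates[:, 0], "y": geom.coordinates[:, 1]}
    )
    with open(path, "w") as f:
        f.write(f"# pitch = {geom.pitch!r}\n")
        df.to_csv(f, index=False)
    return path


def read_geometry(path: str | Path) -> ArrayGeometry:
    path = Path(path)
    pitch = 1.0
    with open(path) as f:
        first = f.readline()
        if first.startswith("#"):
            pitch = float(first.partition("=")[2])
            df = pd.read_csv(f)
        else:
            df = pd.read_csv(path)
    return ArrayGeometry(
        unit_ids=[str(u) for u in df["unit_id"]],
        coordinates=df[["x", "y"]].to_numpy(float),
        pitch=pitch,
    )


def write_session(session: PerturbationSession, path: str | Path, ensemble_path: str | None = None) -> Path:
    path = Path(path)
    rec = {
        "stimulated_unit": session.stimulated_unit,
        "trial_onsets": session.trial_onsets.tolist(),
        "pulse_strength": session.pulse_strength,
        "pulse_duration": session.pulse_duration,
        "window": session.window,
        "ensemble_path": ensemble_path,
    }
    path.write_text(json.dumps(rec, indent=1))
    return path


def read_session(path: str | Path, load_recording: bool = True) -> PerturbationSession:
    path = Path(path)
    rec = json.loads(path.read_text())
    sess = PerturbationSession(
        stimulated_unit=rec["stimulated_unit"],
        trial_onsets=np.array(rec["trial_onsets"]),
        pulse_strength=rec["pulse_strength"],
        pulse_duration=rec["pulse_duration"],
        window=rec["window"],
    )
    if load_recording and rec.get("ensemble_path"):
        sess.recording = read_ensemble(path.parent / rec["ensemble_path"])
    return sess


@dataclass
class RunConfig:
    """Serializable pipeline configuration; a saved config re-executes to
    identical outputs for deterministic stages."""

    seed: int = 0
    out_dir: str = "."
    simulator: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=dict)
    surrogates: dict = field(default_factory=dict)
    interventional: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path = ".") -> list[Path]:
    """Small deterministic datasets used by the tests and docs.

    ``toy-series``: one unit with values 1..5 (the documented embedding
    example). ``coupled-pair``: two units with known one-way coupling
    y(t) = 0.8 x(t-1) + noise. ``grid-session``: a short simulator run with
    geometry and one pulse-session record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    if kind == "toy-series":
        ts = EnsembleTimeSeries(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]), dt=1.0, unit_ids=["u1"])
        written.append(write_ensemble(ts, out_dir / "toy_series.csv"))
    elif kind == "coupled-pair":
        # unidirectionally coupled logistic maps: a dynamical driver whose
        # attractor the driven unit can cross-map
        T, g = 2000, 0.32
        x, y = rng.uniform(0.2, 0.8, 2)
        X, Y = np.empty(T), np.empty(T)
        for t in range(T + 200):
            x, y = x * (3.8 - 3.8 * x), y * (3.5 - 3.5 * y - g * x)
            if t >= 200:
                X[t - 200], Y[t - 200] = x, y
        ts = EnsembleTimeSeries(np.vstack([X, Y]), dt=1.0, unit_ids=["driver", "driven"])
        written.append(write_ensemble(ts, out_dir / "coupled_pair.csv"))
    elif kind == "grid-session":
        from . import simulator as sim

        params = SimulatorParams(n_y=5, duration=145.0, transient=5.0, seed=seed)
        base = sim.simulate_network(params)
        onsets = sim.make_trial_onsets(8, record_duration=140.0, seed=seed)
        session = PerturbationSession(stimulated_unit="x1", trial_onsets=onsets)
        rec = sim.run_perturbation_session(params, session)
        written.append(write_ensemble(base, out_dir / "grid_base.csv"))
        written.append(write_ensemble(rec, out_dir / "grid_perturbed.csv"))
        written.append(write_session(session, out_dir / "grid_session.json", "grid_perturbed.csv"))
        from .evaluation import default_geometry

        geom = default_geometry(base.unit_ids)
        written.append(write_geometry(geom, out_dir / "grid_geometry.csv"))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
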