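"""MOT/STO time-series tables (coordinates and external loads).

A MOT document is a tab-separated numeric table with a small key=value
header.  Rotational coordinates are stored in degrees when the header says
``inDegrees=yes`` and converted at this boundary; translations are metres
throughout.  The external-loads dialect requires, per load, a
``<body>_force_x/y/z``, ``<body>_cop_x/y/z``, ``<body>_torque_x/y/z`` column
triad set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import ExternalLoad
from ..kinematics import CoordinateTrajectory

_LOAD_SUFFIXES = tuple(f"{kind}_{ax}" for kind in ("force", "cop", "torque")
                       for ax in "xyz")


@dataclass
class MotDocument:
    name: str
    labels: list
    data: np.ndarray                    # rows x columns, includes time col 0
    in_degrees: bool = False

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match columns")
        if self.labels[0] != "time":
            raise ValueError("first column must be time")
        if np.any(np.diff(self.data[:, 0]) <= 0):
            raise ValueError("time column must be strictly increasing")

    @property
    def times(self):
        return self.data[:, 0]

    def column(self, label):
        try:
            return self.data[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no column {label!r}") from None


def write_mot(doc: MotDocument, path):
    lines = [doc.name, "version=1",
             f"nRows={doc.data.shape[0]}", f"nColumns={doc.data.shape[1]}",
             f"inDegrees={'yes' if doc.in_degrees else 'no'}", "endheader",
             "\t".join(doc.labels)]
    for row in doc.data:
        lines.append("\t".join(f"{v:.10g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mot(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {}
    i = 0
    name = ""
    for i, ln in enumerate(lines):
        if ln.strip().lower() == "endheader":
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            meta[k.strip().lower()] = v.strip()
        elif ln.strip():
            name = ln.strip()
    else:
        raise ValueError("malformed MOT header: no endheader")
    labels = lines[i + 1].split("\t")
    labels = [lb.strip() for lb in labels if lb.strip()]
    if "time" not in labels:
        raise ValueError("MOT file lacks a time column")
    rows = [ln.split("\t") for ln in lines[i + 2:] if ln.strip()]
    data = np.array([[float(c) for c in r] for r in rows])
    if data.size and data.shape[1] != len(labels):
        raise ValueError("MOT data column count does not match labels")
    if "nrows" in meta and int(meta["nrows"]) != data.shape[0]:
        raise ValueError("declared row count does not match data")
    in_deg = meta.get("indegrees", "no").lower() in ("yes", "true", "1")
    return MotDocument(name, labels, data, in_deg)


# ---------------------------------------------------------------------------
# coordinate trajectories
# ---------------------------------------------------------------------------

def coordinates_to_mot(traj: CoordinateTrajectory, model, name="coordinates",
                       in_degrees=True):
    kinds = {c.name: c.kind for c in model.coords}
    data = np.column_stack([traj.times, traj.q])
    if in_degrees:
        data = data.copy()
        for j, n in enumerate(traj.names, start=1):
            if kinds.get(n, "rotational") == "rotational":
                data[:, j] = np.degrees(data[:, j])
    return MotDocument(name, ["time"] + list(traj.names), data, in_degrees)


def mot_to_coordinates(doc: MotDocument, model):
    names = [lb for lb in doc.labels if lb != "time"]
    kinds = {c.name: c.kind for c in model.coords}
    q = np.column_stack([doc.column(n) for n in names])
    if doc.in_degrees:
        for j, n in enumerate(names):
            if kinds.get(n, "rotational") == "rotational":
                q[:, j] = np.radians(q[:, j])
    return CoordinateTrajectory(doc.times, names, q)


# ---------------------------------------------------------------------------
# external loads
# ---------------------------------------------------------------------------

def external_load_to_mot(load: ExternalLoad, name="external loads"):
    labels = ["time"] + [f"{load.body}_{s}" for s in _LOAD_SUFFIXES]
    data = np.column_stack([load.times, load.force, load.cop, load.free_moment])
    return MotDocument(name, labels, data, in_degrees=False)


def external_loads_from_mot(doc: MotDocument):
    """Parse every ``<body>_force/cop/torque`` column group in the table."""
    bodies = sorted({lb[:-len("_force_x")] for lb in doc.labels
                     if lb.endswith("_force_x")})
    if not bodies:
        raise ValueError("external-loads file has no <body>_force_x column")
    loads = []
    for body in bodies:
        missing = [f"{body}_{s}" for s in _LOAD_SUFFIXES
                   if f"{body}_{s}" not in doc.labels]
        if missing:
            raise ValueError(f"external-loads dialect error: missing columns"
                             f" {missing}")
        cols = {s: doc.column(f"{body}_{s}") for s in _LOAD_SUFFIXES}
        loads.append(ExternalLoad(
            body, doc.times,
            np.column_stack([cols[f"force_{a}"] for a in "xyz"]),
            np.column_stack([cols[f"cop_{a}"] for a in "xyz"]),
            np.column_stack([cols[f"torque_{a}"] for a in "xyz"])))
    return loads
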