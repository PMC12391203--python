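"""TRC marker-trajectory files (tab-separated text).

Values are stored in the unit the header declares (mm by convention) and
converted to metres on read.  Blank cells mark occluded markers and map to
the visibility mask.  TRC does not encode which lab axis is up, so a
``#up_axis=<X|Y|Z>`` comment line is written into the header block and
recovered on read (defaulting to Y-up); readers of the plain format simply
skip it.  Numbers are written with 10 significant digits, comfortably beyond
marker hardware precision, so a write-read round trip is lossless for
practical purposes.
"""

from __future__ import annotations

import numpy as np

from ..kinematics import MarkerTrajectorySet


def write_trc(trajset: MarkerTrajectorySet, path, units="mm"):
    scale = {"mm": 1000.0, "m": 1.0}[units]
    rate = trajset.rate
    n, m = trajset.positions.shape[:2]
    lines = []
    lines.append(f"PathFileType\t4\t(X/Y/Z)\t{path}")
    lines.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    lines.append(f"{rate:.6f}\t{rate:.6f}\t{n}\t{m}\t{units}\t{rate:.6f}\t1\t{n}")
    lines.append(f"#up_axis={trajset.up_axis.upper()}")
    head = ["Frame#", "Time"]
    for name in trajset.names:
        head += [name, "", ""]
    lines.append("\t".join(head))
    axes = ["", ""]
    for i in range(1, m + 1):
        axes += [f"X{i}", f"Y{i}", f"Z{i}"]
    lines.append("\t".join(axes))
    lines.append("")
    for f in range(n):
        row = [str(f + 1), f"{trajset.times[f]:.10g}"]
        for j in range(m):
            if trajset.mask[f, j]:
                row += [f"{v * scale:.10g}" for v in trajset.positions[f, j]]
            else:
                row += ["", "", ""]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trc(path):
    with open(path) as fh:
        raw = fh.read().splitlines()
    up_axis = "Y"
    lines = []
    for ln in raw:
        if ln.startswith("#"):
            if ln.startswith("#up_axis="):
                up_axis = ln.split("=", 1)[1].strip() or "Y"
            continue
        lines.append(ln)
    if len(lines) < 5:
        raise ValueError("malformed TRC header: too few lines")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip()
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed TRC header: {exc}") from exc
    if units not in ("mm", "m"):
        raise ValueError(f"unsupported TRC units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0

    head = lines[3].split("\t")
    if head[0] != "Frame#":
        raise ValueError("malformed TRC header: missing column labels")
    names = [t for t in head[2:] if t.strip()]
    if len(names) != n_markers:
        raise ValueError(f"header declares {n_markers} markers but labels"
                         f" {len(names)}")

    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != n_frames:
        raise ValueError(f"header declares {n_frames} frames but file has"
                         f" {len(data_rows)}")
    times = np.empty(n_frames)
    pos = np.full((n_frames, n_markers, 3), np.nan)
    for f, ln in enumerate(data_rows):
        cells = ln.split("\t")
        if len(cells) < 2 + 3 * n_markers:
            cells = cells + [""] * (2 + 3 * n_markers - len(cells))
        elif len(cells) > 2 + 3 * n_markers:
            raise ValueError(f"row {f + 1}: inconsistent column count")
        times[f] = float(cells[1])
        for j in range(n_markers):
            trip = cells[2 + 3 * j:5 + 3 * j]
            if all(c.strip() for c in trip):
                pos[f, j] = [float(c) for c in trip]
    mask = ~np.isnan(pos).any(axis=2)
    pos = pos * scale
    pos[~mask] = 0.0
    return MarkerTrajectorySet(times, names, pos, mask, up_axis)
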