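"""Evaluation metrics: marker-tracking RMSE, residual RMS and RMS ratios.

Tracking quality is summarized as the per-marker root-mean-square error
between measured and model (virtual) marker positions over the frames of a
trial, averaged within the five anatomical marker groups (head, arm, torso,
pelvis, leg).  Dynamic inconsistency is summarized as the RMS of each pelvis
residual channel, and models are compared channel-wise through the ratio of
their residual RMS values — a ratio below one means the test model is more
dynamically consistent than the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MARKER_GROUP_SIZES

GROUP_ORDER = ("head", "arm", "torso", "pelvis", "leg")


@dataclass
class TrackingReport:
    marker_names: list
    rmse: np.ndarray                    # per-marker RMSE, m
    groups: dict                        # marker name -> group
    frames_used: int

    def group_means(self):
        return group_mean_rmse(self)

    def to_frame(self):
        return pd.DataFrame({
            "marker": self.marker_names,
            "group": [self.groups[n] for n in self.marker_names],
            "rmse_m": self.rmse,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class ResidualSummary:
    """Six residual RMS values and, optionally, ratios to a reference."""

    force_rms: np.ndarray               # 3, N
    moment_rms: np.ndarray              # 3, N m
    force_labels: tuple = ("anterior_posterior", "superior_inferior",
                           "medial_lateral")
    moment_labels: tuple = ("tilt", "list", "rotation")
    ratios: dict = field(default_factory=dict)

    def to_frame(self):
        rows = []
        for lab, v in zip(self.force_labels, self.force_rms):
            rows.append({"channel": f"force_{lab}", "rms": v,
                         "ratio": self.ratios.get(f"force_{lab}", np.nan)})
        for lab, v in zip(self.moment_labels, self.moment_rms):
            rows.append({"channel": f"moment_{lab}", "rms": v,
                         "ratio": self.ratios.get(f"moment_{lab}", np.nan)})
        return pd.DataFrame(rows)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def marker_rmse(measured, virtual, mask=None, names=None, groups=None,
                window=None):
    """Per-marker RMSE between measured and virtual trajectories.

    ``measured``/``virtual`` are (frames, markers, 3); masked frames are
    excluded per marker.  ``window`` is an inclusive (first, last) frame
    index pair.  A marker with zero usable frames raises.
    """
    meas = getattr(measured, "positions", measured)
    if mask is None:
        mask = getattr(measured, "mask", None)
    if names is None:
        names = list(getattr(measured, "names", range(meas.shape[1])))
    meas = np.asarray(meas, float)
    virtual = np.asarray(virtual, float)
    if mask is None:
        mask = np.ones(meas.shape[:2], bool)
    if window is not None:
        first, last = window
        sl = slice(first, last + 1)
        meas, virtual, mask = meas[sl], virtual[sl], mask[sl]
    if meas.shape != virtual.shape:
        raise ValueError("measured and virtual shapes differ")
    sq = np.sum((meas - virtual) ** 2, axis=2)
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        bad = [str(names[i]) for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"no usable frames for markers: {bad}")
    rmse = np.sqrt(np.where(mask, sq, 0.0).sum(axis=0) / counts)
    if groups is None:
        groups = {str(n): "all" for n in names}
    return TrackingReport([str(n) for n in names], rmse, dict(groups),
                          frames_used=meas.shape[0])


def group_mean_rmse(report: TrackingReport, expected_sizes=None):
    """Unweighted mean RMSE per marker group.

    With the full 57-marker protocol the groups partition as
    head 4 / arm 14 / torso 5 / pelvis 4 / leg 30.
    """
    means = {}
    for i, name in enumerate(report.marker_names):
        g = report.groups.get(name)
        if g is None:
            raise ValueError(f"marker {name!r} missing a group")
        means.setdefault(g, []).append(report.rmse[i])
    if expected_sizes:
        for g, n in expected_sizes.items():
            if len(means.get(g, ())) != n:
                raise ValueError(f"group {g!r} has {len(means.get(g, ()))}"
                                 f" markers, expected {n}")
    return {g: float(np.mean(v)) for g, v in means.items()}


def residual_rms(series, window=None):
    """Channel-wise RMS of a residual series over the analysis window."""
    forces = np.asarray(series.forces, float)
    moments = np.asarray(series.moments, float)
    if window is not None:
        first, last = window
        forces = forces[first:last + 1]
        moments = moments[first:last + 1]
    if forces.shape[0] == 0:
        raise ValueError("empty analysis window")
    return ResidualSummary(np.sqrt((forces ** 2).mean(axis=0)),
                           np.sqrt((moments ** 2).mean(axis=0)))


def rms_ratio(test: ResidualSummary, reference: ResidualSummary):
    """Channel-wise test/reference RMS ratios (NaN where reference is zero)."""
    ratios = {}
    for labs, tv, rv in ((test.force_labels, test.force_rms, reference.force_rms),
                         (test.moment_labels, test.moment_rms, reference.moment_rms)):
        kind = "force" if labs is test.force_labels else "moment"
        for lab, t, r in zip(labs, tv, rv):
            ratios[f"{kind}_{lab}"] = float(t / r) if r > 0 else float("nan")
    return ratios


def foot_in_air_filter(trajset, foot_markers=("LD1M", "LD5M"),
                       threshold=0.110, window=None, strict=True):
    """True when the swing foot stays above ``threshold`` throughout.

    Checks that the vertical (declared up-axis) coordinates of the swing
    foot's first and fifth distal-metatarsal markers exceed the 110 mm
    threshold at every frame of the window.  The boundary is exclusive by
    default (exactly at the threshold does not count as in the air).
    """
    up = trajset.up_index
    first, last = (0, len(trajset.times) - 1) if window is None else window
    sl = slice(first, last + 1)
    for name in foot_markers:
        if name not in trajset.names:
            raise ValueError(f"marker {name!r} missing from trial")
        j = trajset.index(name)
        h = trajset.positions[sl, j, up]
        if not np.all(trajset.mask[sl, j]):
            raise ValueError(f"marker {name!r} occluded inside the window")
        ok = np.all(h > threshold) if strict else np.all(h >= threshold)
        if not ok:
            return False
    return True
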