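"""Inertial partitioning of the upper body and subject scaling.

The reference skeleton keeps the published totals (75 kg, 170 cm).  When the
lumped head+neck+torso+shoulder segment is split into individual bodies, the
segment masses come from an :class:`InertialPartitionTable`-style recipe of
mass fractions, com fractions and radii of gyration; the rounding residual is
closed into the thorax (the largest piece) so the totals are preserved
exactly.  Rigid composition (:func:`compose_segments`) is the inverse
operation and is what the baseline lumped-torso variants use, which makes the
composite mass, com and inertia of every variant identical by construction.

Segments handled here carry lab-frame com and inertia at the default pose;
the model builder localizes them into segment frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BodySegment


def compose_segments(segments, name="composite"):
    """Rigidly compose segments into one (parallel-axis theorem).

    Inputs and output use lab-frame com positions and inertia tensors about
    each com at the default pose.
    """
    segments = list(segments)
    M = sum(s.mass for s in segments)
    if M <= 0:
        raise ValueError("composite mass must be positive")
    com = sum(s.mass * np.asarray(s.com, float) for s in segments) / M
    inertia = np.zeros((3, 3))
    for s in segments:
        d = np.asarray(s.com, float) - com
        inertia += s.inertia + s.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
    return BodySegment(name, M, com, inertia)


def partition_upper_body(lumped_mass, table, lumped_reference=None,
                         closing="thorax", closing_tol=0.02, com_tol=0.05):
    """Split the lumped upper-body mass into individual segments.

    Parameters
    ----------
    lumped_mass : float
        Mass of the lumped upper-body segment being split (kg).  Ignored if
        ``lumped_reference`` is given (its mass is used instead).
    table : dict[str, PartitionEntry]
        Per-segment recipe; ``mass_fraction`` values must sum to one within
        ``closing_tol``.
    lumped_reference : BodySegment, optional
        The original lumped segment; when given, the composite com of the
        returned pieces is checked against its com within ``com_tol`` (m).
    closing : str
        Segment that absorbs the mass-closure residual.

    Returns
    -------
    list[BodySegment] with lab-frame com/inertia, masses summing exactly to
    the lumped mass.
    """
    if lumped_reference is not None:
        lumped_mass = lumped_reference.mass
    fr_sum = sum(e.mass_fraction for e in table.values())
    if abs(fr_sum - 1.0) > closing_tol:
        raise ValueError(
            f"partition mass fractions sum to {fr_sum:.4f}; deviation exceeds"
            f" the closing tolerance {closing_tol}")
    if closing not in table:
        raise ValueError(f"closing segment {closing!r} not in table")

    segs = []
    masses = {k: e.mass_fraction * lumped_mass for k, e in table.items()}
    masses[closing] += lumped_mass - sum(masses.values())   # exact closure
    for key, e in table.items():
        p = np.asarray(e.proximal, float)
        d = np.asarray(e.distal, float)
        length = np.linalg.norm(d - p)
        com = p + e.com_fraction * (d - p) + np.asarray(e.com_offset, float)
        m = masses[key]
        radii = np.asarray(e.gyration, float) * length
        segs.append(BodySegment(key, m, com, np.diag(m * radii ** 2)))

    if lumped_reference is not None:
        comp = compose_segments(segs)
        dev = np.linalg.norm(comp.com - np.asarray(lumped_reference.com, float))
        if dev > com_tol:
            raise ValueError(
                f"composite com deviates {dev * 1e3:.1f} mm from the lumped"
                f" reference (tolerance {com_tol * 1e3:.0f} mm)")
    return segs


# ---------------------------------------------------------------------------
# subject scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaleFactorSet:
    """Per-segment axis scale factors plus the subject mass.

    ``factors`` maps body name -> scalar or 3-vector; bodies not listed use
    1.  ``subject_mass`` rescales all masses uniformly, preserving the
    generic model's relative mass distribution.
    """

    factors: dict = field(default_factory=dict)
    subject_mass: float = None

    def factor(self, body):
        f = np.asarray(self.factors.get(body, 1.0), float)
        if f.ndim == 0:
            f = np.full(3, float(f))
        if np.any(f <= 0):
            raise ValueError(f"nonpositive scale factor for body {body!r}")
        return f


def scale_model(model, factors: ScaleFactorSet):
    """Return a scaled copy of ``model``.

    Geometry (joint locations, marker offsets, com positions) scales per-axis
    in each segment's own frame; masses scale by subject/generic mass ratio;
    inertia entries scale by the mass ratio times the two axis factors of
    their indices.
    """
    from .model import SkeletalModel, BodySegment as BS, JointDefinition, \
        MarkerDefinition, total_mass

    generic_mass = total_mass(model)
    mass_ratio = 1.0 if factors.subject_mass is None else \
        float(factors.subject_mass) / generic_mass

    bodies = {}
    for name, seg in model.bodies.items():
        f = factors.factor(name)
        inertia = seg.inertia * mass_ratio * np.outer(f, f)
        bodies[name] = BS(name, seg.mass * mass_ratio, seg.com * f, inertia)

    joints = []
    for j in model.joints:
        fp = factors.factor(j.parent) if j.parent != "ground" else np.ones(3)
        fc = factors.factor(j.child)
        coords = [type(c)(c.name, c.kind, c.default, c.range, c.locked,
                          c.constrained) for c in j.coords]
        joints.append(JointDefinition(j.name, j.parent, j.child, j.kind,
                                      j.location_in_parent * fp,
                                      j.location_in_child * fc,
                                      [a.copy() for a in j.axes], coords))
    markers = [MarkerDefinition(m.name, m.body,
                                m.offset * factors.factor(m.body),
                                m.group, m.weight) for m in model.markers]
    drivers = [type(c)(c.name, c.kind, c.default, c.range, c.locked,
                       c.constrained) for c in model.drivers]
    constraints = [type(c)(c.dependent, list(c.independents))
                   for c in model.constraints]
    return SkeletalModel(bodies, joints, constraints, markers, drivers,
                         model.variant, model.geometry)


def scale_factors_from_static(model, static_markers, pairs,
                              subject_mass=None):
    """Isotropic per-segment scale factors from a static calibration trial.

    ``pairs`` maps body name -> list of (marker_a, marker_b); each factor is
    the mean measured pair distance over the trial divided by the model pair
    distance at the default pose.
    """
    from .kinematics import forward_kinematics

    _, virtual = forward_kinematics(model, model.default_q())
    idx = {n: i for i, n in enumerate(static_markers.names)}
    factors = {}
    for body, plist in pairs.items():
        ratios = []
        for a, bm in plist:
            for name in (a, bm):
                if name not in idx:
                    raise ValueError(f"marker {name!r} missing from static trial")
            mi = model.marker_names.index(a)
            mj = model.marker_names.index(bm)
            model_d = np.linalg.norm(virtual[mi] - virtual[mj])
            if model_d < 1e-9:
                raise ValueError(f"model distance between {a} and {bm} is zero")
            pa = static_markers.positions[:, idx[a]]
            pb = static_markers.positions[:, idx[bm]]
            ok = static_markers.mask[:, idx[a]] & static_markers.mask[:, idx[bm]]
            if not np.any(ok):
                raise ValueError(f"no visible frames for pair {a}-{bm}")
            meas = np.linalg.norm(pa[ok] - pb[ok], axis=1).mean()
            ratios.append(meas / model_d)
        factors[body] = float(np.mean(ratios))
    return ScaleFactorSet(factors, subject_mass)
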