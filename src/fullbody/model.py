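"""Skeletal model core: rigid-body tree, joints, coordinates, couplings.

The central object is :class:`SkeletalModel`, a rooted kinematic tree of
rigid segments connected by joints of fixed kinds (free 6-DoF root, 3-DoF
ball/custom rotation, 2-DoF universal, pin, weld).  Generalized coordinates
may be *locked* (frozen at their default) or *constrained* (their value is a
linear combination of independent coordinates, e.g. the even split of axial
head rotation across the two cervical joints); neither counts as a degree of
freedom.

:func:`build_model` assembles any tested variant of the full-body model —
from the baseline lumped-torso configuration to the augmented model with a
two-joint cervical spine, sternoclavicular shoulder girdle and a two-joint
torso (29 bodies, 48 DoF) — from a :class:`~fullbody.geometry.GeometryConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryConfig, default_geometry

JOINT_DOF = {"free6": 6, "ball3": 3, "custom_rot3": 3,
             "universal2": 2, "pin1": 1, "weld0": 0}

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])

#: inherited segment name stems (pelvis + limbs), used for body bookkeeping
LOWER_BODY_STEMS = ("pelvis", "femur", "patella", "tibia", "fibula",
                    "talus", "calcn", "toes")
ARM_STEMS = ("humerus", "forearm", "hand")
UPPER_BODY_NEW = ("abdomen", "thorax", "torso", "head_neck", "neck", "head",
                  "clavicle_r", "clavicle_l", "scapula_r", "scapula_l")


@dataclass
class BodySegment:
    """Rigid segment: mass, com and inertia tensor about the com.

    Inside a :class:`SkeletalModel` the com and inertia are expressed in the
    segment frame (origin at the proximal joint centre, axes aligned with the
    lab frame at the default pose).
    """

    name: str
    mass: float
    com: np.ndarray
    inertia: np.ndarray

    def __post_init__(self):
        self.com = np.asarray(self.com, float)
        self.inertia = np.asarray(self.inertia, float)


@dataclass
class GeneralizedCoordinate:
    name: str
    kind: str = "rotational"            # rotational (rad) | translational (m)
    default: float = 0.0
    range: tuple = (-2.6, 2.6)
    locked: bool = False
    constrained: bool = False


@dataclass
class JointDefinition:
    """Joint connecting ``parent`` to ``child``.

    Coordinates are ordered translations-then-rotations; ``axes`` holds one
    unit vector per coordinate, expressed in the parent segment frame.
    Rotations compose intrinsically in the listed order.
    """

    name: str
    parent: str
    child: str
    kind: str
    location_in_parent: np.ndarray
    location_in_child: np.ndarray
    axes: list
    coords: list                        # list[GeneralizedCoordinate]

    def __post_init__(self):
        self.location_in_parent = np.asarray(self.location_in_parent, float)
        self.location_in_child = np.asarray(self.location_in_child, float)
        self.axes = [np.asarray(a, float) for a in self.axes]

    @property
    def coordinates(self):
        return [c.name for c in self.coords]

    @property
    def n_trans(self):
        return sum(1 for c in self.coords if c.kind == "translational")


@dataclass
class LinearCouplingConstraint:
    """dependent = sum(ratio_i * independent_i), enforced at all times."""

    dependent: str
    independents: list                  # list[(coordinate name, ratio)]


@dataclass
class MarkerDefinition:
    name: str
    body: str
    offset: np.ndarray
    group: str
    weight: float = 1.0

    def __post_init__(self):
        self.offset = np.asarray(self.offset, float)


@dataclass
class ModelVariantSpec:
    """Which neck / shoulder / torso representation to build.

    ``full_augmented`` is shorthand for the published augmented model
    (two-joint neck, sternoclavicular joints on, two-joint torso) and
    overrides the three individual fields.
    """

    neck: str = "none"                  # none | one_joint | two_joint
    shoulder_sc: bool = False
    torso: str = "L5S1"                 # L5S1 | Lumbar | L5S1_T12L1 | Lumbar_T12L1
    full_augmented: bool = False

    def resolved(self):
        if self.full_augmented:
            return ModelVariantSpec("two_joint", True, "L5S1_T12L1", False)
        if self.neck not in ("none", "one_joint", "two_joint"):
            raise ValueError(f"unknown neck variant {self.neck!r}")
        if self.torso not in ("L5S1", "Lumbar", "L5S1_T12L1", "Lumbar_T12L1"):
            raise ValueError(f"unknown torso variant {self.torso!r}")
        return ModelVariantSpec(self.neck, bool(self.shoulder_sc), self.torso)

    @classmethod
    def augmented(cls):
        return cls(full_augmented=True)

    @classmethod
    def baseline(cls):
        """The lumped-torso reference configuration."""
        return cls()

    def label(self):
        s = self.resolved()
        return f"neck={s.neck},sc={'on' if s.shoulder_sc else 'off'},torso={s.torso}"


class SkeletalModel:
    """Rooted kinematic tree with coupling constraints and markers."""

    def __init__(self, bodies, joints, constraints, markers, drivers,
                 variant=None, geometry=None):
        self.bodies = dict(bodies)            # name -> BodySegment
        self.joints = list(joints)            # tree order, root joint first
        self.constraints = list(constraints)
        self.markers = list(markers)
        self.drivers = list(drivers)          # model-level independent coords
        self.variant = variant
        self.geometry = geometry
        self._finalize()

    # -- structure ---------------------------------------------------------

    def _finalize(self):
        self.joint_of_child = {j.child: j for j in self.joints}
        self.children = {}
        for j in self.joints:
            self.children.setdefault(j.parent, []).append(j)
        # full coordinate ordering: joint coords in tree order, then drivers
        self.coords = [c for j in self.joints for c in j.coords] + list(self.drivers)
        self.coord_index = {c.name: i for i, c in enumerate(self.coords)}
        if len(self.coord_index) != len(self.coords):
            raise ValueError("duplicate coordinate names in model")
        self.independent = [c for c in self.coords
                            if not c.locked and not c.constrained]
        self.ind_index = {c.name: i for i, c in enumerate(self.independent)}
        self._coupling = None

    @property
    def coordinate_names(self):
        return [c.name for c in self.coords]

    @property
    def independent_names(self):
        return [c.name for c in self.independent]

    @property
    def marker_names(self):
        return [m.name for m in self.markers]

    def marker_groups(self):
        groups = {}
        for m in self.markers:
            groups.setdefault(m.group, []).append(m.name)
        return groups

    def default_q(self):
        """Defaults of the independent coordinates."""
        return np.array([c.default for c in self.independent])

    # -- coupling ----------------------------------------------------------

    def coupling(self):
        """(C, d) with q_full = C @ q_independent + d.

        Locked coordinates contribute constant rows (their defaults in d);
        constrained coordinates carry their linear ratios.
        """
        if self._coupling is None:
            n_full, n_ind = len(self.coords), len(self.independent)
            C = np.zeros((n_full, n_ind))
            d = np.zeros(n_full)
            dep = {c.dependent: c for c in self.constraints}
            for i, c in enumerate(self.coords):
                if c.locked:
                    d[i] = c.default
                elif c.constrained:
                    con = dep.get(c.name)
                    if con is None:
                        raise ValueError(
                            f"coordinate {c.name!r} marked constrained but has"
                            " no coupling constraint")
                    for name, ratio in con.independents:
                        if name not in self.ind_index:
                            raise ValueError(
                                f"constraint on {c.name!r} references"
                                f" non-independent coordinate {name!r}")
                        C[i, self.ind_index[name]] += ratio
                else:
                    C[i, self.ind_index[c.name]] = 1.0
            self._coupling = (C, d)
        return self._coupling

    def full_q(self, q_ind):
        C, d = self.coupling()
        q_ind = np.asarray(q_ind, float)
        return q_ind @ C.T + d if q_ind.ndim > 1 else C @ q_ind + d


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_coupling(model, q_independent):
    """Expand independent coordinates to the full coordinate vector."""
    return model.full_q(q_independent)


def count_dofs(model, names=None):
    """Number of unlocked, unconstrained coordinates (optionally a subset)."""
    if names is None:
        return len(model.independent)
    names = set(names)
    return sum(1 for c in model.independent if c.name in names)


def count_bodies(model, merge_welds=False):
    """Number of bodies in the tree (ground excluded).

    The published tally counts every rigid body, welded ones included;
    ``merge_welds=True`` instead collapses each weld-attached body into its
    parent and counts the clusters.
    """
    if not merge_welds:
        return len(model.bodies)
    return sum(1 for j in model.joints if j.kind != "weld0")


def total_mass(model):
    return float(sum(b.mass for b in model.bodies.values()))


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.violations


def validate_model(model):
    """Structural validation; violations are report entries, not exceptions."""
    rep = ValidationReport()
    v = rep.violations

    names = [b for b in model.bodies]
    if len(set(names)) != len(names):
        v.append("duplicate body names")
    free = [j for j in model.joints if j.kind == "free6"]
    if len(free) != 1:
        v.append(f"expected exactly one free6 joint, found {len(free)}")
    elif free[0].parent != "ground":
        v.append("free6 joint does not connect ground")

    seen = {"ground"}
    for j in model.joints:
        if j.parent not in seen:
            v.append(f"joint {j.name}: parent {j.parent!r} not yet in tree")
        if j.child in seen:
            v.append(f"joint {j.name}: child {j.child!r} already in tree (cycle)")
        seen.add(j.child)
        if len(j.coords) != JOINT_DOF[j.kind]:
            v.append(f"joint {j.name}: {len(j.coords)} coordinates for kind {j.kind}")
        for a in j.axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                v.append(f"joint {j.name}: non-unit axis")
    unreached = set(model.bodies) - seen
    if unreached:
        v.append(f"bodies not connected to tree: {sorted(unreached)}")

    for b in model.bodies.values():
        if b.mass < 0:
            v.append(f"body {b.name}: negative mass")
        if not np.allclose(b.inertia, b.inertia.T, atol=1e-12):
            v.append(f"body {b.name}: inertia not symmetric")
        else:
            w = np.linalg.eigvalsh(b.inertia)
            if w.min() < -1e-12:
                v.append(f"body {b.name}: inertia not positive semidefinite")
            elif w[2] > w[0] + w[1] + 1e-12:
                v.append(f"body {b.name}: principal moments violate triangle inequality")

    mnames = [m.name for m in model.markers]
    dup = {n for n in mnames if mnames.count(n) > 1}
    for n in sorted(dup):
        v.append(f"duplicate marker name {n!r}")
    for m in model.markers:
        if m.body not in model.bodies:
            v.append(f"marker {m.name}: unknown body {m.body!r}")
        if m.weight < 0:
            v.append(f"marker {m.name}: negative weight")

    ind = set(model.ind_index)
    all_names = set(model.coord_index)
    for con in model.constraints:
        if con.dependent not in all_names:
            v.append(f"constraint references missing coordinate {con.dependent!r}")
            continue
        if not model.coords[model.coord_index[con.dependent]].constrained:
            v.append(f"constraint dependent {con.dependent!r} not marked constrained")
        for name, _ in con.independents:
            if name == con.dependent:
                v.append(f"constraint on {con.dependent!r} is circular")
            elif name not in ind:
                v.append(f"constraint on {con.dependent!r} uses dependent/missing"
                         f" coordinate {name!r}")
    return rep


def summary(model):
    """Plain-text table of bodies, joints, coordinates and the DoF count."""
    lines = []
    label = model.variant.label() if model.variant else "custom"
    lines.append(f"model variant : {label}")
    lines.append(f"bodies        : {count_bodies(model)}")
    lines.append(f"degrees of freedom : {count_dofs(model)}")
    lines.append(f"total mass    : {total_mass(model):.3f} kg")
    lines.append(f"markers       : {len(model.markers)}")
    lines.append("")
    lines.append(f"{'body':<12} {'mass kg':>8}   joint            kind        coordinates")
    for j in model.joints:
        b = model.bodies[j.child]
        cn = ", ".join(c.name + ("*" if c.constrained else "^" if c.locked else "")
                       for c in j.coords) or "-"
        lines.append(f"{j.child:<12} {b.mass:8.3f}   {j.name:<16} {j.kind:<11} {cn}")
    if model.drivers:
        lines.append("")
        lines.append("driver coordinates: " + ", ".join(c.name for c in model.drivers))
    lines.append("")
    lines.append("(* constrained, ^ locked)")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, geo: GeometryConfig):
        self.geo = geo
        self.bodies = {}
        self.joints = []
        self.constraints = []
        self.drivers = []
        self.origins = {"ground": np.zeros(3)}

    def driver(self, name, kind="rotational", rng=None):
        rng = rng or self.geo.coordinate_range
        c = GeneralizedCoordinate(name, kind, 0.0, tuple(rng))
        self.drivers.append(c)
        return c

    def body(self, name, seg, parent, centre, kind, coord_defs,
             joint_name=None):
        """Attach ``seg`` (lab-frame com/inertia) at ``centre`` (lab frame).

        ``coord_defs`` is a list of (name, 'rot'|'trans', axis) in joint
        order; axes are lab-frame (= parent frame at default pose).
        """
        centre = np.asarray(centre, float)
        coords, axes = [], []
        for cname, ctype, axis in coord_defs:
            axis = np.asarray(axis, float)
            axis = axis / np.linalg.norm(axis)
            kind_c = "translational" if ctype == "trans" else "rotational"
            rng = (self.geo.translation_range if ctype == "trans"
                   else self.geo.coordinate_range)
            coords.append(GeneralizedCoordinate(cname, kind_c, 0.0, tuple(rng)))
            axes.append(axis)
        j = JointDefinition(joint_name or f"{parent}_{name}", parent, name,
                            kind, centre - self.origins[parent],
                            np.zeros(3), axes, coords)
        self.joints.append(j)
        self.origins[name] = centre
        self.bodies[name] = BodySegment(name, seg.mass, seg.com - centre,
                                        seg.inertia)
        return j

    def couple(self, dependent, independents):
        for j in self.joints:
            for c in j.coords:
                if c.name == dependent:
                    c.constrained = True
        self.constraints.append(LinearCouplingConstraint(dependent, list(independents)))

    def seg(self, stem, side=None):
        """Inherited segment with lab-frame com/inertia from the geometry."""
        geo = self.geo
        key = stem if side is None else f"{stem}_{side}"
        mass = geo.segment_mass(stem)
        return BodySegment(key, mass, np.asarray(geo.coms[key], float),
                           geo.segment_inertia(stem, mass))

    def finish(self, variant):
        return SkeletalModel(self.bodies, self.joints, self.constraints,
                             self._markers(), self.drivers, variant, self.geo)

    def _markers(self):
        markers = []
        for name, info in self.geo.markers.items():
            body = next((b for b in info["chain"] if b in self.bodies), None)
            if body is None:
                raise ValueError(f"no attachment body available for marker {name}"
                                 f" (chain {info['chain']})")
            pos = np.asarray(info["pos"], float)
            markers.append(MarkerDefinition(name, body, pos - self.origins[body],
                                            info["group"]))
        return markers


def _rot3_defs(prefix, suffix=""):
    """Extension(Z) / bending(X) / axial(Y) coordinate triple."""
    s = suffix
    return [(f"{prefix}_extension{s}", "rot", _EZ),
            (f"{prefix}_bending{s}", "rot", _EX),
            (f"{prefix}_rotation{s}", "rot", _EY)]


def build_model(spec: ModelVariantSpec, geometry: GeometryConfig = None):
    """Construct a validated skeletal model for the requested variant."""
    geo = geometry or default_geometry()
    spec = ModelVariantSpec() if spec is None else spec
    rspec = spec.resolved()
    b = _Builder(geo)

    # avoid a circular import at module load; anthropometry needs BodySegment
    from . import anthropometry as anth

    lumped_mass = geo.lumped_upper_fraction() * geo.total_mass
    parts = anth.partition_upper_body(lumped_mass, geo.partition)
    parts = {p.name: p for p in parts}

    # ---- pelvis on the ground free joint --------------------------------
    pelvis_c = geo.jc("pelvis")
    b.body("pelvis", b.seg("pelvis"), "ground", pelvis_c, "free6",
           [("pelvis_tx", "trans", _EX), ("pelvis_ty", "trans", _EY),
            ("pelvis_tz", "trans", _EZ),
            ("pelvis_tilt", "rot", _EZ), ("pelvis_list", "rot", _EX),
            ("pelvis_rotation", "rot", _EY)],
           joint_name="ground_pelvis")

    # ---- legs ------------------------------------------------------------
    for s in ("r", "l"):
        b.body(f"femur_{s}", b.seg("femur", s), "pelvis", geo.jc(f"hip_{s}"),
               "ball3", [(f"hip_flexion_{s}", "rot", _EZ),
                         (f"hip_adduction_{s}", "rot", _EX),
                         (f"hip_rotation_{s}", "rot", _EY)])
        b.body(f"patella_{s}", b.seg("patella", s), f"femur_{s}",
               geo.jc(f"patellofemoral_{s}"), "weld0", [])
        b.body(f"tibia_{s}", b.seg("tibia", s), f"femur_{s}",
               geo.jc(f"knee_{s}"), "pin1", [(f"knee_angle_{s}", "rot", _EZ)])
        b.body(f"fibula_{s}", b.seg("fibula", s), f"tibia_{s}",
               geo.jc(f"tibfib_{s}"), "weld0", [])
        b.body(f"talus_{s}", b.seg("talus", s), f"tibia_{s}",
               geo.jc(f"ankle_{s}"), "pin1", [(f"ankle_angle_{s}", "rot", _EZ)])
        b.body(f"calcn_{s}", b.seg("calcn", s), f"talus_{s}",
               geo.jc(f"subtalar_{s}"), "pin1",
               [(f"subtalar_angle_{s}", "rot", (0.78, 0.62, 0.0))])
        b.body(f"toes_{s}", b.seg("toes", s), f"calcn_{s}",
               geo.jc(f"mtp_{s}"), "pin1", [(f"mtp_angle_{s}", "rot", _EZ)])

    # ---- torso stack -----------------------------------------------------
    # Decide which split upper-body pieces get merged back into the topmost
    # torso body for this variant; merging preserves total mass and the
    # composite com/inertia exactly (rigid composition at the default pose).
    merge_into_top = []
    if rspec.neck == "none":
        merge_into_top += ["neck", "head"]
    if not rspec.shoulder_sc:
        merge_into_top += ["clavicle_r", "clavicle_l", "scapula_r", "scapula_l"]

    two_part_torso = rspec.torso in ("L5S1_T12L1", "Lumbar_T12L1")
    lumbar_chain = rspec.torso in ("Lumbar", "Lumbar_T12L1")

    top_pieces = [parts["thorax"]] + [parts[k] for k in merge_into_top]
    if not two_part_torso and not lumbar_chain:
        top_pieces.append(parts["abdomen"])

    top_name = "thorax" if two_part_torso else "torso"
    top_seg = anth.compose_segments(top_pieces, name=top_name)

    l5s1 = geo.jc("l5s1")
    t12l1 = geo.jc("t12l1")

    if not lumbar_chain:
        if two_part_torso:
            b.body("abdomen", parts["abdomen"], "pelvis", l5s1, "custom_rot3",
                   _rot3_defs("lumbar"), joint_name="l5s1")
            b.body("thorax", top_seg, "abdomen", t12l1, "custom_rot3",
                   _rot3_defs("thorax"), joint_name="t12l1")
            b.driver("torso_rotation")
            b.couple("lumbar_rotation", [("torso_rotation", 0.5)])
            b.couple("thorax_rotation", [("torso_rotation", 0.5)])
        else:
            b.body("torso", top_seg, "pelvis", l5s1, "custom_rot3",
                   _rot3_defs("lumbar"), joint_name="l5s1")
    else:
        # five lumbar vertebrae whose intervertebral rotations are coupled
        # to three total-lumbar coordinates with per-level ratios
        ratios = list(geo.lumbar_ratios)          # L1L2 .. L5S1, sum 1
        if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 5:
            raise ValueError("lumbar_ratios must be 5 values summing to 1")
        abdomen = parts["abdomen"]
        m_v = abdomen.mass / 5.0
        centres = [l5s1] + [geo.jc(f"lumbar{i}") for i in range(1, 5)] + [t12l1]
        if two_part_torso:
            ax_driver = None  # vertebral axial couples to torso_rotation below
        b.driver("lumbar_extension")
        b.driver("lumbar_bending")
        axial_name = "torso_rotation" if two_part_torso else "lumbar_rotation"
        b.driver(axial_name)
        axial_scale = 0.5 if two_part_torso else 1.0
        parent = "pelvis"
        for i in range(5):
            # vertebra 5 (bottom, at L5S1) .. vertebra 1 (top)
            level = 5 - i
            vname = f"lumbar{level}"
            mid = 0.5 * (np.asarray(centres[i]) + np.asarray(centres[i + 1]))
            com = mid + np.array([0.03, 0.0, 0.0])
            seg = BodySegment(vname, m_v, com,
                              np.diag(m_v * np.array([0.08, 0.05, 0.09]) ** 2))
            b.body(vname, seg, parent, centres[i], "custom_rot3",
                   _rot3_defs(f"ivj{level}"), joint_name=f"ivj{level}")
            r = ratios[4 - i]                      # L5S1 share is the last
            b.couple(f"ivj{level}_extension", [("lumbar_extension", r)])
            b.couple(f"ivj{level}_bending", [("lumbar_bending", r)])
            b.couple(f"ivj{level}_rotation", [(axial_name, r * axial_scale)])
            parent = vname
        if two_part_torso:
            b.body("thorax", top_seg, "lumbar1", t12l1, "custom_rot3",
                   [("thorax_extension", "rot", _EZ),
                    ("thorax_bending", "rot", _EX),
                    ("thorax_rotation", "rot", _EY)], joint_name="t12l1")
            b.couple("thorax_rotation", [("torso_rotation", 0.5)])
        else:
            b.body("torso", top_seg, "lumbar1", t12l1, "weld0", [],
                   joint_name="t12l1_weld")

    # ---- neck / head -----------------------------------------------------
    c7t1 = geo.jc("c7t1")
    c1 = geo.jc("c1skull")
    if rspec.neck == "one_joint":
        hn = anth.compose_segments([parts["neck"], parts["head"]],
                                   name="head_neck")
        b.body("head_neck", hn, top_name, c7t1, "custom_rot3",
               _rot3_defs("neck"), joint_name="c7t1")
    elif rspec.neck == "two_joint":
        b.body("neck", parts["neck"], top_name, c7t1, "custom_rot3",
               _rot3_defs("neck"), joint_name="c7t1")
        b.body("head", parts["head"], "neck", c1, "custom_rot3",
               _rot3_defs("skull"), joint_name="c1skull")
        b.driver("head_rotation")
        b.couple("neck_rotation", [("head_rotation", 0.5)])
        b.couple("skull_rotation", [("head_rotation", 0.5)])

    # ---- shoulder girdle and arms ---------------------------------------
    up = _EY
    for s in ("r", "l"):
        arm_parent = top_name
        if rspec.shoulder_sc:
            sc = geo.jc(f"sc_{s}")
            ac = geo.jc(f"ac_{s}")
            x = ac - sc
            x = x / np.linalg.norm(x)
            z = np.cross(x, up)
            z = z / np.linalg.norm(z)
            y = np.cross(z, x)
            b.body(f"clavicle_{s}", parts[f"clavicle_{s}"], top_name, sc,
                   "universal2", [(f"sc_protraction_{s}", "rot", y),
                                  (f"sc_elevation_{s}", "rot", z)],
                   joint_name=f"sc_{s}")
            b.body(f"scapula_{s}", parts[f"scapula_{s}"], f"clavicle_{s}", ac,
                   "weld0", [], joint_name=f"ac_{s}")
            arm_parent = f"scapula_{s}"
        b.body(f"humerus_{s}", b.seg("humerus", s), arm_parent,
               geo.jc(f"glenohumeral_{s}"), "ball3",
               [(f"arm_flex_{s}", "rot", _EZ), (f"arm_add_{s}", "rot", _EX),
                (f"arm_rot_{s}", "rot", _EY)])
        b.body(f"forearm_{s}", b.seg("forearm", s), f"humerus_{s}",
               geo.jc(f"elbow_{s}"), "pin1", [(f"elbow_flex_{s}", "rot", _EZ)])
        b.body(f"hand_{s}", b.seg("hand", s), f"forearm_{s}",
               geo.jc(f"wrist_{s}"), "custom_rot3",
               [(f"pro_sup_{s}", "rot", _EY), (f"wrist_flex_{s}", "rot", _EZ),
                (f"wrist_dev_{s}", "rot", _EX)])

    model = b.finish(spec)
    rep = validate_model(model)
    if not rep.ok:
        raise ValueError("built model failed validation:\n  "
                         + "\n  ".join(rep.violations))
    return model


def all_variant_specs():
    """All 2 x 3 x 4 neck/shoulder/torso combinations."""
    specs = []
    for neck in ("none", "one_joint", "two_joint"):
        for sc in (False, True):
            for torso in ("L5S1", "Lumbar", "L5S1_T12L1", "Lumbar_T12L1"):
                specs.append(ModelVariantSpec(neck, sc, torso))
    return specs
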