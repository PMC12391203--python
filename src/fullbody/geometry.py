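"""Reference-skeleton geometry configuration.

All joint centres and marker positions are expressed in the laboratory frame
at the neutral (default) pose of a 170 cm / 75 kg reference skeleton:
X anterior, Y up, Z to the subject's right, origin on the floor below the
pelvis.  Body frames are aligned with the lab frame at the default pose and
originate at each segment's proximal joint centre, so local offsets are
simple world-coordinate differences computed at build time.

Every number here is a replaceable configuration value derived from standard
anthropometric proportions, not a measured quantity; model tests depend only
on topology and on values declared here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

GRAVITY = 9.80665  # m/s^2, standard gravity
UP_AXIS = 1  # lab Y is up

#: marker groups and their sizes in the 57-marker protocol
MARKER_GROUP_SIZES = {"head": 4, "arm": 14, "torso": 5, "pelvis": 4, "leg": 30}


def _mirror(p):
    """Mirror a lab-frame point across the sagittal (XY) plane."""
    return (p[0], p[1], -p[2])


# ---------------------------------------------------------------------------
# joint centres (lab frame, default pose), right side; left is mirrored
# ---------------------------------------------------------------------------

_JOINT_CENTRES_AXIAL = {
    "pelvis": (0.0, 0.95, 0.0),
    "l5s1": (-0.05, 1.05, 0.0),
    "t12l1": (-0.05, 1.25, 0.0),
    "c7t1": (-0.03, 1.45, 0.0),
    "c1skull": (-0.02, 1.55, 0.0),
    "head_top": (-0.01, 1.70, 0.0),
}

_JOINT_CENTRES_RIGHT = {
    "hip": (-0.02, 0.90, 0.09),
    "patellofemoral": (0.05, 0.49, 0.09),
    "knee": (0.00, 0.47, 0.09),
    "tibfib": (-0.01, 0.44, 0.105),
    "ankle": (0.00, 0.08, 0.09),
    "subtalar": (0.01, 0.05, 0.09),
    "mtp": (0.14, 0.02, 0.09),
    "sc": (0.02, 1.40, 0.02),
    "ac": (0.00, 1.44, 0.17),
    "glenohumeral": (0.00, 1.40, 0.19),
    "elbow": (0.01, 1.10, 0.21),
    "wrist": (0.00, 0.83, 0.22),
    "hand_end": (0.00, 0.72, 0.22),
}

# lumbar vertebral joint centres L5S1 .. L1L2 stacked between l5s1 and t12l1
_N_LUMBAR = 5


# ---------------------------------------------------------------------------
# marker table: name -> (group, attachment preference chain, lab position)
# The chain lists candidate bodies in priority order; the model builder
# attaches each marker to the first body present in the variant.
# ---------------------------------------------------------------------------

def _marker_table():
    t = {}

    def add(name, group, chain, pos):
        t[name] = {"group": group, "chain": tuple(chain), "pos": tuple(pos)}

    head_chain = ["head", "head_neck", "thorax", "torso"]
    add("LFHD", "head", head_chain, (0.07, 1.67, -0.06))
    add("RFHD", "head", head_chain, (0.07, 1.67, 0.06))
    add("LBHD", "head", head_chain, (-0.09, 1.66, -0.06))
    add("RBHD", "head", head_chain, (-0.09, 1.66, 0.06))

    tchain = ["thorax", "torso"]
    add("C7", "torso", tchain, (-0.06, 1.46, 0.0))
    add("T10", "torso", tchain, (-0.10, 1.22, 0.0))
    add("RBAK", "torso", ["scapula_r"] + tchain, (-0.10, 1.35, 0.10))
    add("CLAV", "torso", tchain, (0.04, 1.42, 0.0))
    add("STRN", "torso", tchain, (0.08, 1.28, 0.0))

    add("LASI", "pelvis", ["pelvis"], (0.09, 0.97, -0.12))
    add("RASI", "pelvis", ["pelvis"], (0.09, 0.97, 0.12))
    add("LPSI", "pelvis", ["pelvis"], (-0.12, 0.98, -0.04))
    add("RPSI", "pelvis", ["pelvis"], (-0.12, 0.98, 0.04))

    arm_right = {
        "SHO": (["scapula_r"] + tchain, (0.00, 1.45, 0.18)),
        "UPA": (["humerus_r"], (0.00, 1.25, 0.22)),
        "ELB": (["humerus_r"], (0.00, 1.10, 0.24)),
        "FRM": (["forearm_r"], (-0.03, 0.97, 0.22)),
        # wrist markers ride on the hand so the wrist/pronation coordinates
        # stay observable with a single finger marker
        "WRA": (["hand_r"], (0.03, 0.84, 0.20)),
        "WRB": (["hand_r"], (-0.03, 0.83, 0.24)),
        "FIN": (["hand_r"], (0.01, 0.72, 0.22)),
    }
    for stem, (chain, pos) in arm_right.items():
        add("R" + stem, "arm", chain, pos)
        lchain = [c.replace("_r", "_l") for c in chain]
        add("L" + stem, "arm", lchain, _mirror(pos))

    leg_right = {
        "THI1": (["femur_r"], (0.02, 0.75, 0.14)),
        "THI2": (["femur_r"], (0.02, 0.65, 0.14)),
        "THIA": (["femur_r"], (0.06, 0.70, 0.09)),
        "KNE": (["tibia_r"], (0.00, 0.47, 0.14)),
        "MKNE": (["tibia_r"], (0.00, 0.47, 0.04)),
        "TTUB": (["tibia_r"], (0.04, 0.43, 0.09)),
        "HFIB": (["fibula_r", "tibia_r"], (-0.01, 0.44, 0.13)),
        "SHN": (["tibia_r"], (0.03, 0.28, 0.09)),
        "TIB": (["fibula_r", "tibia_r"], (0.01, 0.26, 0.13)),
        "ANK": (["tibia_r"], (0.00, 0.08, 0.13)),
        "MMA": (["tibia_r"], (0.00, 0.08, 0.05)),
        "MPCT": (["calcn_r"], (-0.05, 0.03, 0.06)),
        "LPCT": (["calcn_r"], (-0.05, 0.03, 0.12)),
        "D1M": (["toes_r"], (0.16, 0.03, 0.05)),
        "D5M": (["toes_r"], (0.14, 0.03, 0.13)),
    }
    for stem, (chain, pos) in leg_right.items():
        add("R" + stem, "leg", chain, pos)
        lchain = [c.replace("_r", "_l") for c in chain]
        add("L" + stem, "leg", lchain, _mirror(pos))
    return t


# ---------------------------------------------------------------------------
# inertial defaults
# ---------------------------------------------------------------------------

# mass fractions of total body mass for the inherited (lower body + arm)
# segments; the remainder is the lumped upper body that the partition table
# splits.  Values follow standard adjusted male segment-mass proportions.
_INHERITED_MASS_FRACTIONS = {
    "pelvis": 0.1117,
    "femur": 0.1411,
    "patella": 0.0005,
    "tibia": 0.0358,
    "fibula": 0.0075,
    "talus": 0.0010,
    "calcn": 0.0107,
    "toes": 0.0020,
    "humerus": 0.0271,
    "forearm": 0.0162,
    "hand": 0.0061,
}

# centre-of-mass positions (lab frame, default pose), right side
_COM_RIGHT = {
    "pelvis": (-0.04, 0.95, 0.0),
    "femur": (0.00, 0.70, 0.09),
    "patella": (0.05, 0.49, 0.09),
    "tibia": (0.00, 0.30, 0.09),
    "fibula": (-0.01, 0.26, 0.105),
    "talus": (0.01, 0.065, 0.09),
    "calcn": (0.02, 0.03, 0.09),
    "toes": (0.17, 0.02, 0.09),
    "humerus": (0.00, 1.25, 0.20),
    "forearm": (0.00, 0.97, 0.215),
    "hand": (0.01, 0.78, 0.22),
}

# radii of gyration (m) about the segment com, lab axes at default pose
_GYRATION = {
    "pelvis": (0.10, 0.10, 0.11),
    "femur": (0.14, 0.06, 0.14),
    "patella": (0.02, 0.02, 0.02),
    "tibia": (0.12, 0.04, 0.12),
    "fibula": (0.12, 0.02, 0.12),
    "talus": (0.02, 0.02, 0.02),
    "calcn": (0.05, 0.04, 0.05),
    "toes": (0.03, 0.02, 0.03),
    "humerus": (0.11, 0.05, 0.11),
    "forearm": (0.10, 0.04, 0.10),
    "hand": (0.06, 0.03, 0.06),
}


@dataclass
class PartitionEntry:
    """Inertial recipe for one split upper-body segment.

    ``mass_fraction`` is the fraction of the *lumped upper-body* mass;
    ``proximal``/``distal`` span the segment in the lab frame at the default
    pose; ``com_fraction`` locates the com along that span; ``gyration`` are
    radii of gyration as fractions of the span length, lab axes.
    """

    mass_fraction: float
    proximal: tuple
    distal: tuple
    com_fraction: float
    gyration: tuple
    com_offset: tuple = (0.0, 0.0, 0.0)  # lateral/AP shim off the span axis


def default_partition_table():
    """Upper-body inertial partition for the 170 cm reference skeleton.

    Fractions are of the lumped head+neck+torso+shoulder-girdle mass and sum
    to one; the closing residual policy lives in :mod:`fullbody.anthropometry`.
    """
    jc = _JOINT_CENTRES_AXIAL
    sc_r = _JOINT_CENTRES_RIGHT["sc"]
    ac_r = _JOINT_CENTRES_RIGHT["ac"]
    gh_r = _JOINT_CENTRES_RIGHT["glenohumeral"]
    return {
        "abdomen": PartitionEntry(0.260, jc["l5s1"], jc["t12l1"], 0.50,
                                  (0.48, 0.44, 0.52), (0.03, 0.0, 0.0)),
        "thorax": PartitionEntry(0.460, jc["t12l1"], jc["c7t1"], 0.52,
                                 (0.62, 0.58, 0.66), (0.04, 0.0, 0.0)),
        "neck": PartitionEntry(0.045, jc["c7t1"], jc["c1skull"], 0.50,
                               (0.48, 0.40, 0.48), (0.01, 0.0, 0.0)),
        "head": PartitionEntry(0.135, jc["c1skull"], jc["head_top"], 0.45,
                               (0.52, 0.56, 0.52), (0.01, 0.0, 0.0)),
        "clavicle_r": PartitionEntry(0.015, sc_r, ac_r, 0.50,
                                     (0.45, 0.45, 0.15)),
        "clavicle_l": PartitionEntry(0.015, _mirror(sc_r), _mirror(ac_r), 0.50,
                                     (0.45, 0.45, 0.15)),
        "scapula_r": PartitionEntry(0.035, ac_r, (gh_r[0] - 0.06, gh_r[1] - 0.04, gh_r[2] - 0.04),
                                    0.50, (0.60, 0.60, 0.45)),
        "scapula_l": PartitionEntry(0.035, _mirror(ac_r),
                                    (gh_r[0] - 0.06, gh_r[1] - 0.04, -(gh_r[2] - 0.04)),
                                    0.50, (0.60, 0.60, 0.45)),
    }


# default per-level shares of total lumbar rotation, L1L2 .. L5S1, summing
# to 1 (decreasing cranio-caudally, the sub-45-degree-flexion pattern)
DEFAULT_LUMBAR_RATIOS = (0.25, 0.23, 0.20, 0.17, 0.15)


@dataclass
class GeometryConfig:
    """Versioned geometry/variant configuration for model construction."""

    total_mass: float = 75.0  # kg
    height: float = 1.70      # m
    joint_centres: dict = field(default_factory=dict)
    markers: dict = field(default_factory=_marker_table)
    inherited_mass_fractions: dict = field(
        default_factory=lambda: dict(_INHERITED_MASS_FRACTIONS))
    coms: dict = field(default_factory=dict)
    gyration: dict = field(default_factory=lambda: dict(_GYRATION))
    partition: dict = field(default_factory=default_partition_table)
    lumbar_ratios: tuple = DEFAULT_LUMBAR_RATIOS
    coordinate_range: tuple = (-2.6, 2.6)       # rad, rotational default
    translation_range: tuple = (-10.0, 10.0)    # m
    version: str = "reference-170cm-1"

    def __post_init__(self):
        if not self.joint_centres:
            jc = dict(_JOINT_CENTRES_AXIAL)
            for name, p in _JOINT_CENTRES_RIGHT.items():
                jc[name + "_r"] = p
                jc[name + "_l"] = _mirror(p)
            # interpolated lumbar vertebral joint centres (L5S1 level is the
            # existing l5s1 centre; four more stacked towards t12l1)
            lo = np.asarray(jc["l5s1"], float)
            hi = np.asarray(jc["t12l1"], float)
            for i in range(1, _N_LUMBAR):
                f = i / _N_LUMBAR
                jc[f"lumbar{i}"] = tuple(lo + f * (hi - lo))
            self.joint_centres = jc
        if not self.coms:
            coms = {"pelvis": _COM_RIGHT["pelvis"]}
            for name, p in _COM_RIGHT.items():
                if name == "pelvis":
                    continue
                coms[name + "_r"] = p
                coms[name + "_l"] = _mirror(p)
            self.coms = coms

    # -- accessors ---------------------------------------------------------

    def jc(self, name):
        """Joint centre as an ndarray (lab frame, default pose)."""
        try:
            return np.asarray(self.joint_centres[name], float)
        except KeyError:
            raise KeyError(f"geometry config has no joint centre {name!r}") from None

    def segment_mass(self, stem):
        return self.inherited_mass_fractions[stem] * self.total_mass

    def segment_inertia(self, stem, mass):
        r = np.asarray(self.gyration[stem], float)
        return np.diag(mass * r ** 2)

    def lumped_upper_fraction(self):
        inherited = (self.inherited_mass_fractions["pelvis"]
                     + 2 * sum(self.inherited_mass_fractions[k]
                               for k in ("femur", "patella", "tibia", "fibula",
                                         "talus", "calcn", "toes"))
                     + 2 * sum(self.inherited_mass_fractions[k]
                               for k in ("humerus", "forearm", "hand")))
        return 1.0 - inherited

    # -- (de)serialization -------------------------------------------------

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["partition"] = {k: dataclasses.asdict(v) for k, v in self.partition.items()}
        return _pylist(d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        part = {k: PartitionEntry(**{kk: _tup(vv) for kk, vv in v.items()})
                for k, v in d.pop("partition", {}).items()}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "partition":
                continue
            if f.name in d:
                kwargs[f.name] = _tup(d[f.name])
        cfg = cls(**kwargs)
        if part:
            cfg.partition = part
        return cfg

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _pylist(x):
    """Recursively convert tuples/arrays to lists for clean YAML."""
    if isinstance(x, dict):
        return {k: _pylist(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_pylist(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _tup(x):
    if isinstance(x, list):
        return tuple(_tup(v) for v in x)
    if isinstance(x, dict):
        return {k: _tup(v) for k, v in x.items()}
    return x


def default_geometry():
    """The shipped 170 cm / 75 kg reference geometry."""
    return GeometryConfig()
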