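"""Synthetic motion-capture trials with known ground truth.

Real cutting-style trials from instrumented athletes are not distributable,
so this module manufactures them: smooth coordinate trajectories built from
windowed sinusoid/smoothstep primitives per movement archetype, marker
trajectories by forward kinematics plus isotropic Gaussian noise, and a
ground-reaction load that is *dynamically consistent by construction* — the
whole-body Newton-Euler wrench of the generating model attributed to the
stance foot at a heel-to-toe centre-of-pressure trace.

The default amplitudes reproduce the study conditions the archetypes
emulate: the upper-body degrees of freedom move through 9.6-22.5 degrees,
lumbar flexion through 22.5 degrees, and the swing (left) foot is lifted so
its distal-metatarsal markers stay above the 110 mm ground-clearance
threshold throughout the stance window.  These trials are stylized
primitives, not biomechanical gait models; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ExternalLoad, differentiate, spatial_states, _gravity_vector
from .geometry import GRAVITY
from .kinematics import CoordinateTrajectory, MarkerTrajectorySet, fk_state
from .model import ModelVariantSpec, build_model

ARCHETYPES = ("agility_turn", "vcut", "cone_cut", "quick_stop",
              "side_shuffle", "static")

DEG = np.pi / 180.0

# Range-of-motion targets (degrees, max minus min) for the oscillatory
# coordinates; coordinates absent from a variant are simply skipped.
DEFAULT_AMPLITUDES = {
    # torso
    "lumbar_extension": 22.5, "lumbar_bending": 18.0, "lumbar_rotation": 15.0,
    "torso_rotation": 15.0, "thorax_extension": 12.0, "thorax_bending": 10.0,
    # neck / head
    "neck_extension": 15.0, "neck_bending": 9.6, "neck_rotation": 20.0,
    "head_rotation": 20.0, "skull_extension": 10.0, "skull_bending": 9.6,
    # shoulder girdle
    "sc_protraction_r": 12.0, "sc_elevation_r": 10.0,
    "sc_protraction_l": 12.0, "sc_elevation_l": 10.0,
    # arms
    "arm_flex_r": 45.0, "arm_add_r": 18.0, "arm_rot_r": 20.0,
    "elbow_flex_r": 40.0, "pro_sup_r": 25.0,
    "wrist_flex_r": 15.0, "wrist_dev_r": 10.0,
    "arm_flex_l": 45.0, "arm_add_l": 18.0, "arm_rot_l": 20.0,
    "elbow_flex_l": 40.0, "pro_sup_l": 25.0,
    "wrist_flex_l": 15.0, "wrist_dev_l": 10.0,
    # pelvis orientation and stance leg
    "pelvis_tilt": 8.0, "pelvis_list": 8.0,
    "hip_flexion_r": 20.0, "hip_adduction_r": 8.0, "hip_rotation_r": 8.0,
    "knee_angle_r": 18.0, "ankle_angle_r": 12.0,
    "hip_adduction_l": 8.0, "hip_rotation_l": 8.0, "ankle_angle_l": 10.0,
    # swing leg oscillation on top of the lift offsets below
    "hip_flexion_l": 10.0, "knee_angle_l": 12.0,
}

# Constant offsets (degrees) ramped in over the first 20% of the trial;
# the swing-leg values hold the left foot clear of the ground.
SWING_LIFT_OFFSETS = {"hip_flexion_l": 30.0, "knee_angle_l": 60.0}

# pelvis yaw change (degrees) and translation (m) per archetype
ARCHETYPE_PATH = {
    "agility_turn": {"yaw": 140.0, "tx": 1.0, "tz": 0.0},
    "vcut": {"yaw": 90.0, "tx": 1.2, "tz": -0.5},
    "cone_cut": {"yaw": -90.0, "tx": 1.2, "tz": 0.5},
    "quick_stop": {"yaw": 0.0, "tx": 1.0, "tz": 0.0},
    "side_shuffle": {"yaw": 0.0, "tx": 0.0, "tz": 0.8},
    "static": {"yaw": 0.0, "tx": 0.0, "tz": 0.0},
}


def _smoothstep(u):
    """C2 quintic smoothstep on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (6.0 * u ** 2 - 15.0 * u + 10.0)


@dataclass
class SyntheticTrialConfig:
    archetype: str = "vcut"
    duration: float = 1.2               # s
    rate: float = 240.0                 # Hz
    amplitudes: dict = field(default_factory=dict)   # RoM overrides, deg
    marker_noise_sd: float = 2.0        # mm, isotropic per axis
    seed: int = 0
    variant: ModelVariantSpec = field(default_factory=ModelVariantSpec.augmented)

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown movement archetype {self.archetype!r}")
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")

    @property
    def events(self):
        """(foot strike, foot off) of the right pivot foot, seconds."""
        return (0.30 * self.duration, 0.75 * self.duration)


@dataclass
class SyntheticTrial:
    truth: CoordinateTrajectory
    markers: MarkerTrajectorySet
    loads: ExternalLoad
    events: tuple
    config: SyntheticTrialConfig


def generate_motion(model, config: SyntheticTrialConfig):
    """Smooth ground-truth coordinate trajectories for one trial.

    Oscillatory coordinates follow whole-number-of-cycle sinusoids whose
    peak-to-peak amplitude equals the commanded range of motion; the pelvis
    follows the archetype's smoothstep path; swing-leg offsets are ramped in
    over the first fifth of the trial.
    """
    cfg = config
    n = int(round(cfg.duration * cfg.rate)) + 1
    t = np.arange(n) / cfg.rate
    T = cfg.duration
    rng = np.random.default_rng(cfg.seed)
    names = model.independent_names
    q = np.tile(model.default_q(), (n, 1))
    ranges = {c.name: c.range for c in model.independent}

    if cfg.archetype != "static":
        amps = dict(DEFAULT_AMPLITUDES)
        amps.update(cfg.amplitudes)
        ramp = _smoothstep(t / (0.2 * T))
        path = ARCHETYPE_PATH[cfg.archetype]

        for i, name in enumerate(names):
            rom = amps.get(name)
            off = SWING_LIFT_OFFSETS.get(name, 0.0) * DEG
            if rom is None and off == 0.0:
                continue
            amp = 0.5 * (rom or 0.0) * DEG
            lo, hi = ranges[name]
            if not (lo <= -amp + min(0.0, off) and amp + max(0.0, off) <= hi):
                raise ValueError(f"amplitude for {name} exceeds its range")
            cycles = int(rng.integers(1, 3))
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
            q[:, i] = q[:, i] + off * ramp + amp * np.sin(
                2.0 * np.pi * cycles * t / T + phase)

        progress = _smoothstep(t / T)
        turn = _smoothstep((t - 0.25 * T) / (0.5 * T))
        for cname, val in (("pelvis_tx", path["tx"] * progress),
                           ("pelvis_tz", path["tz"] * turn),
                           ("pelvis_rotation", path["yaw"] * DEG * turn),
                           ("pelvis_ty", 0.02 * np.sin(2 * np.pi * t / T))):
            if cname in names:
                q[:, names.index(cname)] += val
    return CoordinateTrajectory(t, names, q)


def synthesize_markers(model, truth, noise_sd=0.0, seed=0, dropout=None,
                       up_axis="Y"):
    """Forward-kinematics marker trajectories with optional noise/occlusion.

    ``noise_sd`` is the per-axis Gaussian standard deviation in metres;
    ``dropout`` maps marker name -> (first_frame, last_frame) occluded range
    (inclusive).
    """
    n = len(truth.times)
    names = model.marker_names
    pos = np.empty((n, len(names), 3))
    for f in range(n):
        pos[f] = fk_state(model, truth.q[f]).markers
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_sd, pos.shape)
    mask = np.ones((n, len(names)), bool)
    for name, (f0, f1) in (dropout or {}).items():
        mask[f0:f1 + 1, names.index(name)] = False
    return MarkerTrajectorySet(truth.times, list(names), pos, mask, up_axis)


def synthesize_consistent_grf(model, truth, stance_body="calcn_r",
                              cop_rule="heel_toe", events=None,
                              gravity=GRAVITY, window=None):
    """Ground-reaction load that exactly balances the generating motion.

    At every frame the whole-body Newton-Euler wrench (force = sum m_i a_i -
    M g; moment balance about the centre of pressure fixes the free moment)
    is attributed to the stance body.  The cop traces heel to toe on the
    floor during stance and holds at the nearest end outside it.  The load
    covers the whole trial so the zero-phase filter in the inverse-dynamics
    pipeline sees no discontinuity; restrict with ``window`` if required.
    Only single support is modelled — pass one stance body.
    """
    if not isinstance(stance_body, str):
        raise ValueError("double support is unsupported: pass one stance body")
    if stance_body not in model.bodies:
        raise ValueError(f"unknown stance body {stance_body!r}")
    qd, qdd = differentiate(truth)
    C, dvec = model.coupling()
    gvec = _gravity_vector(gravity)
    n = len(truth.times)
    force = np.empty((n, 3))
    cop = np.empty((n, 3))
    moment = np.empty((n, 3))
    strike, off = events if events is not None else (truth.times[0], truth.times[-1])
    side = stance_body.rsplit("_", 1)[-1]
    heel_body, toe_body = f"calcn_{side}", f"toes_{side}"
    for f in range(n):
        states, _, _ = spatial_states(model, C @ truth.q[f] + dvec,
                                      C @ qd[f], C @ qdd[f])
        if cop_rule == "heel_toe" and heel_body in states and toe_body in states:
            s = np.clip((truth.times[f] - strike) / max(off - strike, 1e-9), 0, 1)
            pt = (1 - s) * states[heel_body].p + s * states[toe_body].p
        else:
            pt = states[stance_body].p
        pt = pt.copy()
        pt[1] = 0.0                     # cop lies on the floor
        F = np.zeros(3)
        M = np.zeros(3)
        for name, body in model.bodies.items():
            st = states[name]
            Iw = st.R @ body.inertia @ st.R.T
            fb = body.mass * (st.acom - gvec)
            F += fb
            M += np.cross(st.xcom - pt, fb) + Iw @ st.al + np.cross(st.w, Iw @ st.w)
        force[f], cop[f], moment[f] = F, pt, M
    if window is not None:
        first, last = window
        keep = np.zeros(n, bool)
        keep[first:last + 1] = True
        force[~keep] = 0.0
        moment[~keep] = 0.0
    return ExternalLoad(stance_body, truth.times, force, cop, moment)


def make_trial(config: SyntheticTrialConfig, model=None):
    """Generate one complete trial (truth, markers, consistent loads)."""
    model = model if model is not None else build_model(config.variant)
    truth = generate_motion(model, config)
    markers = synthesize_markers(model, truth,
                                 noise_sd=config.marker_noise_sd * 1e-3,
                                 seed=config.seed + 1)
    loads = synthesize_consistent_grf(model, truth, events=config.events)
    return SyntheticTrial(truth, markers, loads, config.events, config)


def make_fixture_suite(seed=0):
    """Deterministic small trial suite for tests and documentation.

    One static, one vcut-like and one cone-cut-like trial for each of the
    baseline and augmented generating variants.
    """
    suite = {}
    for vname, variant in (("baseline", ModelVariantSpec.baseline()),
                           ("augmented", ModelVariantSpec.augmented())):
        model = build_model(variant)
        for arch, dur, noise in (("static", 0.5, 0.0),
                                 ("vcut", 1.2, 2.0),
                                 ("cone_cut", 1.2, 2.0)):
            cfg = SyntheticTrialConfig(archetype=arch, duration=dur,
                                       marker_noise_sd=noise, seed=seed,
                                       variant=variant)
            suite[f"{arch}_{vname}"] = make_trial(cfg, model)
    return suite
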