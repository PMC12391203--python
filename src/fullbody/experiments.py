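"""Canned model-comparison experiments on synthetic trials.

Three experiment families mirror the evaluation protocol:

* **segment tests** isolate one modelling choice (neck, shoulder girdle or
  torso articulation).  Markers on the *base* segment are weighted 10 and
  markers on the *tested* segment 1 during inverse kinematics, so the base
  is tracked equally well across candidate models and any difference in the
  tested group's RMSE is attributable to the joint model under test.
* **full-body comparison** tracks the same trial with the baseline and the
  augmented model using uniform weight 1 for all markers and reports the
  five marker-group RMSEs.
* **inverse-dynamics comparison** runs the complete IK + ID pipeline for
  both full-body models against loads that are dynamically consistent with
  the articulated ground truth, and reports pelvis residual RMS values and
  the augmented/baseline RMS ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import select_stance_window, solve_ik_trajectory
from .dynamics import run_inverse_dynamics
from .metrics import group_mean_rmse, marker_rmse, residual_rms, rms_ratio
from .model import ModelVariantSpec, build_model
from .synthetic import SyntheticTrialConfig, make_trial

#: base/tested segment pairs and the candidate variants per segment test
SEGMENT_TESTS = {
    "neck": {
        "base_group": "torso", "tested_group": "head",
        "truth": ModelVariantSpec("two_joint", False, "L5S1"),
        "candidates": {
            "one_joint": ModelVariantSpec("one_joint", False, "L5S1"),
            "two_joint": ModelVariantSpec("two_joint", False, "L5S1"),
        },
    },
    "shoulder": {
        "base_group": "torso", "tested_group": "arm",
        "truth": ModelVariantSpec("none", True, "L5S1"),
        "candidates": {
            "no_sc": ModelVariantSpec("none", False, "L5S1"),
            "sc": ModelVariantSpec("none", True, "L5S1"),
        },
    },
    "torso": {
        "base_group": "pelvis", "tested_group": "torso",
        "truth": ModelVariantSpec("none", False, "L5S1_T12L1"),
        "candidates": {
            "L5S1": ModelVariantSpec("none", False, "L5S1"),
            "Lumbar": ModelVariantSpec("none", False, "Lumbar"),
            "L5S1_T12L1": ModelVariantSpec("none", False, "L5S1_T12L1"),
            "Lumbar_T12L1": ModelVariantSpec("none", False, "Lumbar_T12L1"),
        },
    },
}


def _track_group_rmse(model, markers, weights):
    ik = solve_ik_trajectory(model, markers, weights=weights)
    groups = {m.name: m.group for m in model.markers}
    rep = marker_rmse(markers, ik.virtual, names=markers.names, groups=groups)
    return group_mean_rmse(rep), ik


@dataclass
class SegmentTestResult:
    kind: str
    tested_group: str
    base_group: str
    group_rmse: dict                    # candidate -> {group: rmse m}

    def tested_rmse(self):
        return {k: v[self.tested_group] for k, v in self.group_rmse.items()}


def segment_test(kind, seed=0, archetype="vcut", duration=0.6, rate=120.0,
                 noise_mm=1.0):
    """Tracking comparison for one segment's candidate joint models.

    The trial is generated with the most articulated candidate; IK weights
    follow the base-10 / tested-1 protocol.
    """
    try:
        setup = SEGMENT_TESTS[kind]
    except KeyError:
        raise ValueError(f"unknown segment test {kind!r}") from None
    cfg = SyntheticTrialConfig(archetype=archetype, duration=duration,
                               rate=rate, marker_noise_sd=noise_mm,
                               seed=seed, variant=setup["truth"])
    trial = make_trial(cfg)
    weights = {setup["base_group"]: 10.0, setup["tested_group"]: 1.0}
    out = {}
    for name, spec in setup["candidates"].items():
        model = build_model(spec)
        out[name], _ = _track_group_rmse(model, trial.markers, weights)
    return SegmentTestResult(kind, setup["tested_group"], setup["base_group"], out)


def compare_fullbody(seed=0, archetype="vcut", duration=1.0, rate=120.0,
                     noise_mm=2.0):
    """Uniform-weight tracking comparison: baseline vs augmented model.

    Returns {model: {group: rmse m}}; the trial is generated with the
    augmented model (articulated upper-body motion).
    """
    cfg = SyntheticTrialConfig(archetype=archetype, duration=duration,
                               rate=rate, marker_noise_sd=noise_mm, seed=seed,
                               variant=ModelVariantSpec.augmented())
    trial = make_trial(cfg)
    out = {}
    for name, spec in (("baseline", ModelVariantSpec.baseline()),
                       ("augmented", ModelVariantSpec.augmented())):
        out[name], _ = _track_group_rmse(build_model(spec), trial.markers,
                                         weights=None)
    return out


@dataclass
class IdComparisonResult:
    summaries: dict                     # model -> ResidualSummary
    ratios: dict                        # channel -> augmented/baseline ratio
    window: tuple


def compare_id(seed=0, archetype="vcut", duration=1.2, rate=240.0,
               cutoff=20.0, noise_mm=0.0):
    """Full IK + ID pipeline comparison of dynamic inconsistency.

    The trial (kinematics and single-support ground reaction) is generated
    with the augmented model; both models are tracked with uniform weights
    and fed the identical loads; residual RMS is taken over the stance
    window (stance plus 10% before foot strike).  Noiseless markers isolate
    the modelling error, which is what the RMS ratio measures.
    """
    cfg = SyntheticTrialConfig(archetype=archetype, duration=duration,
                               rate=rate, marker_noise_sd=noise_mm, seed=seed,
                               variant=ModelVariantSpec.augmented())
    trial = make_trial(cfg)
    win = select_stance_window(trial.events, trial.truth.times)
    summaries = {}
    for name, spec in (("baseline", ModelVariantSpec.baseline()),
                       ("augmented", ModelVariantSpec.augmented())):
        model = build_model(spec)
        ik = solve_ik_trajectory(model, trial.markers)
        _, residuals = run_inverse_dynamics(model, ik.trajectory,
                                            [trial.loads], cutoff=cutoff)
        summaries[name] = residual_rms(residuals, window=win)
    ratios = rms_ratio(summaries["augmented"], summaries["baseline"])
    return IdComparisonResult(summaries, ratios, win)
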