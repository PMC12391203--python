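"""Model construction, DoF/body accounting, coupling, validation."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fullbody as fb
from fullbody.model import JOINT_DOF, LinearCouplingConstraint


class TestStructuralCounts:
    def test_augmented_counts(self, augmented):
        assert fb.count_dofs(augmented) == 48
        assert fb.count_bodies(augmented) == 29
        assert fb.total_mass(augmented) == pytest.approx(75.0, abs=1e-9)

    def test_baseline_counts(self, baseline):
        # hand count: 6 pelvis + 2x7 legs + 3 lumbosacral + 2x7 arms = 37
        assert fb.count_dofs(baseline) == 37
        assert fb.count_bodies(baseline) == 22
        assert fb.total_mass(baseline) == pytest.approx(75.0, abs=1e-9)
        # single joint between sacrum and L5, no other upper-body joints
        names = {j.name for j in baseline.joints}
        assert "l5s1" in names
        assert not any(n in names for n in ("t12l1", "c7t1", "sc_r"))

    def test_inherited_body_partition(self, augmented):
        """Pelvis + limbs contribute 21 bodies; the upper-body split adds 8."""
        from fullbody.model import LOWER_BODY_STEMS, ARM_STEMS
        inherited = [b for b in augmented.bodies
                     if b.split("_")[0] in LOWER_BODY_STEMS + ARM_STEMS]
        assert len(inherited) == 21
        new = set(augmented.bodies) - set(inherited)
        assert new == {"abdomen", "thorax", "neck", "head",
                       "clavicle_r", "clavicle_l", "scapula_r", "scapula_l"}

    def test_lower_and_upper_limb_dofs(self, augmented):
        lower = [c for c in augmented.independent_names
                 if c.startswith(("pelvis_", "hip_", "knee_", "ankle_",
                                  "subtalar_", "mtp_"))]
        arms = [c for c in augmented.independent_names
                if c.startswith(("arm_", "elbow_", "pro_sup", "wrist_"))]
        assert len(lower) == 20
        assert len(arms) == 14

    def test_merge_welds_collapses_welded_bodies(self, augmented):
        n_welds = sum(1 for j in augmented.joints if j.kind == "weld0")
        assert n_welds == 6  # 2 patellae, 2 fibulae, 2 scapulae
        assert fb.count_bodies(augmented, merge_welds=True) == 29 - n_welds

    def test_marker_protocol(self, augmented):
        assert len(augmented.markers) == 57
        groups = augmented.marker_groups()
        assert {g: len(v) for g, v in groups.items()} == {
            "head": 4, "arm": 14, "torso": 5, "pelvis": 4, "leg": 30}


class TestVariants:
    def test_dof_accounting_all_variants(self, all_variants):
        """count_dofs = sum of joint DoFs + drivers - locked - constrained."""
        for label, m in all_variants.items():
            expected = (sum(JOINT_DOF[j.kind] for j in m.joints)
                        + len(m.drivers)
                        - sum(1 for c in m.coords if c.locked)
                        - sum(1 for c in m.coords if c.constrained))
            assert fb.count_dofs(m) == expected, label

    def test_mass_conserved_across_variants(self, all_variants):
        masses = [fb.total_mass(m) for m in all_variants.values()]
        assert np.ptp(masses) < 1e-12 * 75.0

    def test_sternoclavicular_adds_four_dofs(self, all_variants):
        for neck in ("none", "one_joint", "two_joint"):
            for torso in ("L5S1", "Lumbar", "L5S1_T12L1", "Lumbar_T12L1"):
                off = all_variants[f"neck={neck},sc=off,torso={torso}"]
                on = all_variants[f"neck={neck},sc=on,torso={torso}"]
                assert fb.count_dofs(on) - fb.count_dofs(off) == 4

    def test_two_joint_neck_adds_two_dofs_over_one_joint(self, all_variants):
        """Axial rotation is a shared coupled coordinate, so the second
        cervical joint contributes only its flexion and bending."""
        for sc in ("off", "on"):
            one = all_variants[f"neck=one_joint,sc={sc},torso=L5S1"]
            two = all_variants[f"neck=two_joint,sc={sc},torso=L5S1"]
            assert fb.count_dofs(two) - fb.count_dofs(one) == 2

    def test_lumbar_coupling_removes_all_added_dofs(self, all_variants):
        l5s1 = all_variants["neck=none,sc=off,torso=L5S1"]
        lumbar = all_variants["neck=none,sc=off,torso=Lumbar"]
        assert fb.count_dofs(lumbar) == fb.count_dofs(l5s1)
        assert fb.count_bodies(lumbar) == fb.count_bodies(l5s1) + 5

    def test_full_augmented_overrides_fields(self):
        spec = fb.ModelVariantSpec("none", False, "L5S1", full_augmented=True)
        r = spec.resolved()
        assert (r.neck, r.shoulder_sc, r.torso) == ("two_joint", True, "L5S1_T12L1")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="neck"):
            fb.build_model(fb.ModelVariantSpec(neck="three_joint"))
        with pytest.raises(ValueError, match="torso"):
            fb.build_model(fb.ModelVariantSpec(torso="bogus"))


class TestCoupling:
    def test_even_axial_split_neck(self, augmented):
        """20 degrees of head axial rotation puts 10 at each cervical joint."""
        q = augmented.default_q()
        i = augmented.ind_index["head_rotation"]
        q[i] = np.radians(20.0)
        full = fb.apply_coupling(augmented, q)
        names = augmented.coordinate_names
        assert full[names.index("neck_rotation")] == pytest.approx(np.radians(10))
        assert full[names.index("skull_rotation")] == pytest.approx(np.radians(10))

    def test_even_axial_split_torso(self, augmented):
        q = augmented.default_q()
        q[augmented.ind_index["torso_rotation"]] = np.radians(14.0)
        full = fb.apply_coupling(augmented, q)
        names = augmented.coordinate_names
        assert full[names.index("lumbar_rotation")] == pytest.approx(np.radians(7))
        assert full[names.index("thorax_rotation")] == pytest.approx(np.radians(7))

    def test_lumbar_ratios_sum_to_commanded_total(self, all_variants):
        m = all_variants["neck=none,sc=off,torso=Lumbar"]
        q = m.default_q()
        q[m.ind_index["lumbar_extension"]] = 0.4
        full = fb.apply_coupling(m, q)
        names = m.coordinate_names
        parts = [full[names.index(f"ivj{k}_extension")] for k in range(1, 6)]
        assert sum(parts) == pytest.approx(0.4, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_coupling_exact_for_random_q(self, all_variants, seed):
        rng = np.random.default_rng(seed)
        for m in (all_variants["neck=two_joint,sc=on,torso=L5S1_T12L1"],
                  all_variants["neck=none,sc=off,torso=Lumbar_T12L1"]):
            q = rng.uniform(-1, 1, len(m.independent))
            full = fb.apply_coupling(m, q)
            idx = {c.name: i for i, c in enumerate(m.coords)}
            for con in m.constraints:
                expect = sum(r * q[m.ind_index[n]] for n, r in con.independents)
                assert full[idx[con.dependent]] == pytest.approx(expect, abs=1e-15)


class TestValidation:
    def test_valid_models_pass(self, all_variants):
        for m in all_variants.values():
            assert fb.validate_model(m).ok

    def test_duplicate_marker_flagged(self, baseline):
        m = fb.build_model(fb.ModelVariantSpec.baseline())
        m.markers[1].name = m.markers[0].name
        rep = fb.validate_model(m)
        assert any("duplicate marker" in v for v in rep.violations)

    def test_circular_constraint_flagged(self, baseline):
        m = fb.build_model(fb.ModelVariantSpec.baseline())
        m.constraints.append(
            LinearCouplingConstraint("lumbar_extension",
                                     [("lumbar_extension", 1.0)]))
        rep = fb.validate_model(m)
        assert any("circular" in v for v in rep.violations)

    def test_bad_inertia_flagged(self):
        m = fb.build_model(fb.ModelVariantSpec.baseline())
        m.bodies["torso"].inertia = np.diag([10.0, 1.0, 1.0])  # 10 > 1 + 1
        rep = fb.validate_model(m)
        assert any("triangle" in v for v in rep.violations)


class TestSummaryAndConfig:
    def test_summary_golden(self, augmented):
        golden = (Path(__file__).parent / "data" /
                  "summary_augmented.txt").read_text()
        assert fb.summary(augmented) + "\n" == golden

    def test_geometry_yaml_round_trip(self, tmp_path, geometry):
        path = tmp_path / "geometry.yaml"
        geometry.to_yaml(path)
        loaded = fb.GeometryConfig.from_yaml(path)
        m = fb.build_model(fb.ModelVariantSpec.augmented(), loaded)
        assert fb.count_dofs(m) == 48
        assert fb.total_mass(m) == pytest.approx(75.0, abs=1e-9)
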