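"""Conformational classifiers: threshold behaviour, decision rules,
config validation and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinoforge.classifiers import (ClassifierConfig, FeatureVector,
                                   classify_alphac, classify_aloop,
                                   classify_dfg, classify_ploop,
                                   classify_structure, compute_features,
                                   default_config)
from kinoforge.errors import ConfigError


def make_fv(config, **overrides):
    """Feature vector sitting mid-class for stretched/in/open, overridable."""
    base = dict(
        psi_gmotif_m1=135.0, psi_gmotif_p1=135.0, xi_gmotif_p1_p2=120.0,
        d_phi_hrd_p4=24.0, xi_dfg_m1_d=-90.0, xi_dfg_f_g=90.0,
        d_hrd_m4_dfg_p3=24.5, d_lys_glu=3.0, chi_glu=-60.0,
        dfg_pseudodihedral=90.0)
    base.update(overrides)
    return FeatureVector(**base)


class TestAlphaC:
    @pytest.mark.parametrize("d,chi,expected", [
        (3.5, 150.0, "in"),      # published rule: d <= 4 -> in
        (4.0, 150.0, "in"),      # boundary inclusive
        (9.0, 150.0, "out"),     # d >= 8.5 -> out
        (8.5, 150.0, "out"),     # boundary inclusive
        (6.0, 90.0, "inter"),    # intermediate band, chi <= 100
        (6.0, 100.0, "inter"),   # chi boundary inclusive
        (6.0, 120.0, "in"),      # intermediate band, chi > 100
    ])
    def test_salt_bridge_rule(self, config, d, chi, expected):
        fv = make_fv(config, d_lys_glu=d, chi_glu=chi)
        assert classify_alphac(fv, config).value == expected

    def test_monotone_step_function_of_distance(self, config):
        """At fixed chi <= 100 the class steps in -> inter -> out with
        exactly two change points, at 4.0 and 8.5 A."""
        labels = [classify_alphac(make_fv(config, d_lys_glu=d, chi_glu=50.0),
                                  config).value
                  for d in np.arange(0.5, 12.0, 0.01)]
        changes = [(a, b) for a, b in zip(labels, labels[1:]) if a != b]
        assert changes == [("in", "inter"), ("inter", "out")]

    def test_unavailable_distance_unassigned(self, config):
        fv = make_fv(config, d_lys_glu=None)
        fv.unavailable["d_lys_glu"] = "missing NZ"
        label = classify_alphac(fv, config)
        assert label.value == "unassigned" and "missing NZ" in label.reason

    def test_chi_needed_in_band(self, config):
        fv = make_fv(config, d_lys_glu=6.0, chi_glu=None)
        label = classify_alphac(fv, config)
        assert label.value == "unassigned" and "chi needed" in label.reason


class TestPloop:
    def test_all_four_conditions(self, config):
        box = config.ploop_classes["collapsed"]
        fv = make_fv(config,
                     psi_gmotif_m1=box["psi_gmotif_m1"].midpoint(),
                     psi_gmotif_p1=box["psi_gmotif_p1"].midpoint(),
                     xi_gmotif_p1_p2=box["xi_gmotif_p1_p2"].midpoint(),
                     d_phi_hrd_p4=box["d_phi_hrd_p4"].midpoint())
        assert classify_ploop(fv, config).value == "collapsed"

    def test_three_of_four_suffices(self, config):
        # stretched on 3 features, one in neither class's interval
        fv = make_fv(config, d_phi_hrd_p4=17.0)  # between the class intervals
        assert classify_ploop(fv, config).value == "stretched"

    def test_two_of_four_unassigned(self, config):
        collapsed = config.ploop_classes["collapsed"]
        fv = make_fv(config,
                     psi_gmotif_m1=collapsed["psi_gmotif_m1"].midpoint(),
                     xi_gmotif_p1_p2=collapsed["xi_gmotif_p1_p2"].midpoint(),
                     d_phi_hrd_p4=17.0)
        label = classify_ploop(fv, config)
        assert label.value == "unassigned"

    def test_minimum_satisfied_conditions_is_three(self, config):
        """Sweep the number of stretched-satisfying features: assignment
        first appears at exactly min_conditions = 3."""
        stretched = config.ploop_classes["stretched"]
        neutral = {"psi_gmotif_m1": 45.0, "psi_gmotif_p1": 45.0,
                   "xi_gmotif_p1_p2": 30.0, "d_phi_hrd_p4": 17.0}
        names = list(neutral)
        outcomes = {}
        for k in range(5):
            values = dict(neutral)
            for name in names[:k]:
                values[name] = stretched[name].midpoint()
            fv = make_fv(config, **values)
            outcomes[k] = classify_ploop(fv, config).value
        assert outcomes == {0: "unassigned", 1: "unassigned", 2: "unassigned",
                            3: "stretched", 4: "stretched"}

    def test_tie_is_ambiguous(self, config):
        """Equal qualifying counts for both classes yield unassigned."""
        cfg_doc = config.to_dict()
        # make the two classes identical: every vector ties
        cfg_doc["ploop"]["classes"]["stretched"] = \
            dict(cfg_doc["ploop"]["classes"]["collapsed"])
        tied = ClassifierConfig.from_dict(cfg_doc)
        box = tied.ploop_classes["collapsed"]
        fv = make_fv(tied,
                     psi_gmotif_m1=box["psi_gmotif_m1"].midpoint(),
                     psi_gmotif_p1=box["psi_gmotif_p1"].midpoint(),
                     xi_gmotif_p1_p2=box["xi_gmotif_p1_p2"].midpoint(),
                     d_phi_hrd_p4=box["d_phi_hrd_p4"].midpoint())
        label = classify_ploop(fv, tied)
        assert label.value == "unassigned" and "ambiguous" in label.reason

    def test_two_missing_features_unassigned(self, config):
        fv = make_fv(config, psi_gmotif_m1=None, xi_gmotif_p1_p2=None)
        assert classify_ploop(fv, config).value == "unassigned"


class TestAloop:
    @pytest.mark.parametrize("name", ["closed_type2", "open_dfg_out",
                                      "closed_a_under_p"])
    def test_midpoint_of_each_box(self, config, name):
        box = config.aloop_classes[name]
        fv = make_fv(config,
                     xi_dfg_m1_d=box["xi_dfg_m1_d"].midpoint(),
                     xi_dfg_f_g=box["xi_dfg_f_g"].midpoint(),
                     d_hrd_m4_dfg_p3=box["d_hrd_m4_dfg_p3"].midpoint())
        assert classify_aloop(fv, config).value == name

    def test_outside_all_boxes_unassigned(self, config):
        fv = make_fv(config, d_hrd_m4_dfg_p3=18.0)  # inter-box gap
        assert classify_aloop(fv, config).value == "unassigned"

    def test_missing_feature_unassigned_with_reason(self, config):
        fv = make_fv(config, xi_dfg_f_g=None)
        label = classify_aloop(fv, config)
        assert label.value == "unassigned" and "xi_dfg_f_g" in label.reason


class TestDfg:
    def test_in_out_and_gap(self, config):
        assert classify_dfg(make_fv(config, dfg_pseudodihedral=90.0),
                            config).value == "out"
        assert classify_dfg(make_fv(config, dfg_pseudodihedral=-90.0),
                            config).value == "in"
        gap = 0.5 * (config.dfg_in.hi + config.dfg_out.lo)
        assert classify_dfg(make_fv(config, dfg_pseudodihedral=gap),
                            config).value == "unassigned"


class TestConfigValidation:
    def test_overlapping_aloop_boxes_rejected(self, config):
        doc = config.to_dict()
        doc["aloop"]["classes"]["closed_type2"] = \
            dict(doc["aloop"]["classes"]["open_dfg_out"])
        with pytest.raises(ConfigError, match="overlap"):
            ClassifierConfig.from_dict(doc)

    def test_alphac_ordering_enforced(self, config):
        doc = config.to_dict()
        doc["alphac"]["d_in_max"] = 9.0
        with pytest.raises(ConfigError):
            ClassifierConfig.from_dict(doc)

    def test_min_conditions_range(self, config):
        doc = config.to_dict()
        doc["ploop"]["min_conditions"] = 5
        with pytest.raises(ConfigError):
            ClassifierConfig.from_dict(doc)

    def test_yaml_round_trip(self, config, tmp_path):
        import yaml
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(config.to_dict()))
        again = ClassifierConfig.from_yaml(path)
        assert again.to_dict() == config.to_dict()


class TestCompositeClassification:
    def test_composite_reports_all_elements(self, default_scaffold, config):
        label = classify_structure(default_scaffold, config)
        assert label.as_dict() == {"dfg": "in", "aloop": "open_dfg_out",
                                   "ploop": "stretched", "alphac": "in"}
        assert label.alphac.evidence["d_lys_glu"] == pytest.approx(3.0,
                                                                   abs=1e-6)

    def test_missing_glu_sidechain_flags_feature(self, config):
        from kinoforge.synthetic_fixtures import ScaffoldParams, make_scaffold
        domain = make_scaffold(ScaffoldParams(
            seed=3, min_clearance=0.0,
            omit_atoms=((91, "OE1"), (91, "OE2"), (91, "CD"), (91, "CG"))),
            config)
        fv = compute_features(domain, config)
        assert fv.d_lys_glu is None and "d_lys_glu" in fv.unavailable

    def test_invariant_under_rigid_motion(self, default_scaffold, config):
        rot = Rotation.from_euler("xyz", [33, -48, 121], degrees=True)
        moved = default_scaffold.transformed(rot.as_matrix(),
                                             np.array([10.0, -4.0, 7.0]))
        before = compute_features(default_scaffold, config)
        after = compute_features(moved, config)
        for name, value in before.as_dict().items():
            assert after.get(name) == pytest.approx(value, abs=1e-6)
        assert classify_structure(moved, config).as_dict() == \
            classify_structure(default_scaffold, config).as_dict()

    def test_grid_labels_recovered(self, labeled_grid, config):
        """Generated label equals classifier output for every grid member."""
        for member in labeled_grid:
            got = classify_structure(member.domain, config).as_dict()
            assert got == member.label.as_dict(), member.tag
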