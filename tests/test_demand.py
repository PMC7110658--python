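"""Synthetic demand generator: load model, curvature, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

import spinerel as sr
from spinerel.calibrate import calibrate_demand_scale, system_beta_at_scale
from spinerel.errors import (
    CalibrationBracketError,
    InvalidDistributionError,
    MissingEntryError,
)
from spinerel.materials import LoadMode, TissueKind

G = 9.81


class TestTopology:
    def test_default_topology_counts(self, topology):
        assert len(topology.sections) == 24  # 7 cervical + 12 thoracic + 5 lumbar
        assert topology.labels[0] == "C1"
        assert topology.labels[-1] == "L5"
        discs = [s.disc for s in topology.sections if s.disc is not None]
        assert len(discs) == 23  # every vertebra but the last has a disc below

    def test_support_block_extends_series_count(self):
        assert sr.default_topology().n == 24
        assert sr.default_topology(include_support=True).n == 25

    def test_topology_round_trip(self, topology, tmp_path):
        path = tmp_path / "topo.csv"
        sr.write_topology(topology, path)
        assert sr.read_topology(path).sections == topology.sections


class TestAxialLoad:
    def test_head_only_load_below_c2(self, topology):
        forces = sr.cumulative_axial_load(topology, sr.LoadCase(body_mass=0.0))
        assert forces["C1"] == 0.0
        for label in topology.labels[1:]:
            assert forces[label] == pytest.approx(5.0 * G)  # 49.05 N

    def test_bottom_section_carries_head_plus_full_trunk_share(self, topology):
        forces = sr.cumulative_axial_load(
            topology, sr.LoadCase(70.0, trunk_fraction=0.55, head_mass=5.0)
        )
        assert forces["L5"] == pytest.approx((5.0 + 0.55 * 70.0) * G)  # 426.74 N

    @pytest.mark.parametrize("mass", [0.0, 30.0, 55.5, 80.0])
    def test_force_monotone_cranial_to_caudal(self, topology, mass):
        forces = sr.cumulative_axial_load(topology, sr.LoadCase(mass))
        seq = [forces[lab] for lab in topology.labels]
        assert all(b >= a for a, b in zip(seq, seq[1:]))

    def test_non_cumulative_switch_gives_flat_trunk_share(self, topology):
        forces = sr.cumulative_axial_load(
            topology, sr.LoadCase(70.0), cumulative=False
        )
        below_head = [forces[lab] for lab in topology.labels[1:]]
        assert np.allclose(below_head, below_head[0])

    def test_load_case_bounds_enforced(self):
        with pytest.raises(InvalidDistributionError):
            sr.LoadCase(70.0, trunk_fraction=0.7)
        with pytest.raises(InvalidDistributionError):
            sr.LoadCase(70.0, head_mass=6.0)


class TestNominalStress:
    def test_force_over_area_in_mpa(self, areas):
        # N / mm^2 is MPa directly
        a = areas.area("L5", TissueKind.CORTICAL)
        assert sr.nominal_stress(426.74, "L5", TissueKind.CORTICAL, areas) == pytest.approx(
            426.74 / a
        )

    def test_doubling_area_halves_stress(self):
        t1 = sr.AreaTable({("X", TissueKind.CORTICAL): 600.0})
        t2 = sr.AreaTable({("X", TissueKind.CORTICAL): 1200.0})
        s1 = sr.nominal_stress(426.74, "X", TissueKind.CORTICAL, t1)
        s2 = sr.nominal_stress(426.74, "X", TissueKind.CORTICAL, t2)
        assert s1 == pytest.approx(0.711, abs=5e-4)
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_force_zero_stress(self, areas):
        assert sr.nominal_stress(0.0, "T5", TissueKind.ANNULUS, areas) == 0.0

    def test_missing_area_entry_raises(self, areas):
        with pytest.raises(MissingEntryError):
            sr.nominal_stress(10.0, "L5", TissueKind.ANNULUS, areas)  # L5 has no disc


class TestCurvature:
    def test_normal_profile_is_identity(self, topology, normal_demands):
        out = sr.apply_curvature(normal_demands, sr.CurvatureProfile.normal(), topology)
        assert out == list(normal_demands)

    def test_kappa_two_doubles_at_inflection_and_decays_out(self, topology, normal_demands):
        prof = sr.CurvatureProfile.scoliosis(("T7",), amplification=2.0, decay_width=3)
        out = sr.apply_curvature(normal_demands, prof, topology)
        for before, after in zip(normal_demands, out):
            dist = abs(topology.index(before.section) - topology.index("T7"))
            if dist == 0:
                assert after.mean == pytest.approx(2.0 * before.mean)
            elif dist >= 3:
                assert after.mean == before.mean

    def test_amplification_preserves_cov(self, topology, areas):
        demands = sr.generate_demand_table(
            topology, sr.LoadCase(70.0), sr.CurvatureProfile.scoliosis(),
            cov=0.1, seed=3, areas=areas,
        )
        for d in demands:
            assert d.std == pytest.approx(0.1 * d.mean)

    def test_governing_demand_sits_near_an_inflection(self, topology, areas):
        prof = sr.CurvatureProfile.scoliosis()
        demands = sr.generate_demand_table(
            topology, sr.LoadCase(70.0), prof, seed=7, areas=areas,
        )
        infl = [topology.index(lab) for lab in prof.inflection_sections]
        for tissue in TissueKind:
            for mode in LoadMode:
                rows = [d for d in demands if d.tissue is tissue and d.mode is mode]
                top = max(rows, key=lambda d: d.mean)
                dist = min(abs(topology.index(top.section) - i) for i in infl)
                assert dist < prof.decay_width

    def test_unknown_inflection_label_raises(self, topology, normal_demands):
        prof = sr.CurvatureProfile.scoliosis(("T99",))
        with pytest.raises(MissingEntryError):
            sr.apply_curvature(normal_demands, prof, topology)

    def test_profile_invariants(self):
        with pytest.raises(InvalidDistributionError):
            sr.CurvatureProfile("normal", ("T7",), 2.0)  # normal with inflections
        with pytest.raises(InvalidDistributionError):
            sr.CurvatureProfile("scoliosis", ("T7",), 1.0)  # kappa not > 1
        with pytest.raises(InvalidDistributionError):
            sr.CurvatureProfile("scoliosis", (), 2.0)  # no inflection


class TestGenerateTable:
    def test_one_row_per_section_tissue_mode(self, normal_demands):
        # 24 sections x 2 vertebral tissues x 2 modes + 23 discs x 2 x 2
        assert len(normal_demands) == 24 * 4 + 23 * 4
        keys = {(d.section, d.tissue, d.mode) for d in normal_demands}
        assert len(keys) == len(normal_demands)

    def test_zero_cov_gives_zero_std(self, topology, areas):
        demands = sr.generate_demand_table(
            topology, sr.LoadCase(60.0), sr.CurvatureProfile.normal(),
            cov=0.0, seed=2, areas=areas,
        )
        assert all(d.std == 0.0 for d in demands)

    def test_bit_identical_under_same_seed(self, topology, areas):
        kw = dict(cov=0.1, seed=123, areas=areas)
        a = sr.generate_demand_table(
            topology, sr.LoadCase(50.0), sr.CurvatureProfile.normal(), **kw
        )
        b = sr.generate_demand_table(
            topology, sr.LoadCase(50.0), sr.CurvatureProfile.normal(), **kw
        )
        assert a == b

    def test_demand_monotone_in_body_mass(self, topology, areas):
        light = sr.generate_demand_table(
            topology, sr.LoadCase(40.0), sr.CurvatureProfile.normal(), seed=5, areas=areas
        )
        heavy = sr.generate_demand_table(
            topology, sr.LoadCase(75.0), sr.CurvatureProfile.normal(), seed=5, areas=areas
        )
        for lo, hi in zip(light, heavy):
            assert hi.mean >= lo.mean

    def test_scoliosis_dominates_normal_everywhere(self, normal_demands, scoliosis_demands, topology):
        prof = sr.CurvatureProfile.scoliosis()
        infl = [topology.index(lab) for lab in prof.inflection_sections]
        strictly_greater = 0
        for n, s in zip(normal_demands, scoliosis_demands):
            assert (n.section, n.tissue, n.mode) == (s.section, s.tissue, s.mode)
            assert s.mean >= n.mean
            if min(abs(topology.index(n.section) - i) for i in infl) == 0:
                assert s.mean > n.mean
                strictly_greater += 1
        assert strictly_greater > 0

    def test_demand_table_round_trip(self, normal_demands, tmp_path):
        path = tmp_path / "demand.csv"
        sr.write_demand_table(normal_demands, path)
        assert sr.read_demand_table(path) == list(normal_demands)


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestCalibration:
    def test_fixed_point_returns_unit_scale(self, topology, resistances, normal_demands):
        beta0 = system_beta_at_scale(1.0, topology, resistances, normal_demands)
        s = calibrate_demand_scale(topology, resistances, normal_demands, beta0)
        assert s == pytest.approx(1.0, abs=5e-3)

    @pytest.mark.parametrize("target", [3.75, 3.96, 4.10])
    def test_recomputed_beta_hits_target(self, topology, resistances, normal_demands, target):
        s = calibrate_demand_scale(topology, resistances, normal_demands, target)
        assert system_beta_at_scale(s, topology, resistances, normal_demands) == pytest.approx(
            target, abs=1e-3
        )

    def test_scale_strictly_decreasing_in_target(self, topology, resistances, normal_demands):
        scales = [
            calibrate_demand_scale(topology, resistances, normal_demands, t)
            for t in (3.75, 3.96, 4.10)
        ]
        assert scales[0] > scales[1] > scales[2]

    def test_unreachable_target_raises_bracket_error(self, topology, resistances, normal_demands):
        with pytest.raises(CalibrationBracketError):
            calibrate_demand_scale(topology, resistances, normal_demands, 1e6)

    def test_scale_demands_requires_positive_scale(self, normal_demands):
        with pytest.raises(InvalidDistributionError):
            sr.scale_demands(normal_demands, 0.0)
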