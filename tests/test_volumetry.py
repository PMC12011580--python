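"""Organ volumetry and the IREOV statistic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import orbitometry as om
from orbitometry.volumetry import DataQualityWarning, VolumetryError
from .conftest import make_measurement


def _tiny_labelmap(globe_voxels=1000, spacing=(0.5, 0.5, 0.5)):
    schema = om.default_schema()
    data = np.zeros((20, 20, 20), dtype=np.int16)
    flat = data.reshape(-1)
    flat[:globe_voxels] = schema.label(om.GLOBE)
    return om.LabelMap(flat.reshape(20, 20, 20), spacing, (0.0, 0.0, 0.0), schema)


class TestOrganVolume:
    def test_count_times_voxel_volume(self):
        lm = _tiny_labelmap(1000, (0.5, 0.5, 0.5))
        assert om.organ_volume(lm, om.GLOBE) == pytest.approx(125.0)

    def test_empty_mask_is_zero(self):
        lm = _tiny_labelmap(0)
        assert om.organ_volume(lm, om.GLOBE) == 0.0

    def test_rasterized_sphere_matches_analytic(self):
        h = 0.4
        n = 70
        mask = om.ball_mask((n, n, n), (h, h, h), (14.0, 14.0, 14.0), 12.0)
        vol = mask.data.sum() * h ** 3
        true = 4.0 / 3.0 * math.pi * 12.0 ** 3
        assert true == pytest.approx(7238.23, abs=0.01)
        assert abs(vol - true) / true < 0.02

    def test_equals_brute_force_voxel_loop(self, quiet_phantom):
        _, pre, _, _ = quiet_phantom
        sub = pre.data[90:130, 30:70, 40:80]  # window containing muscle tissue
        label = pre.schema.label(om.MEDIAL_RECTUS)
        count = 0
        for v in sub.ravel():
            if v == label:
                count += 1
        lm = om.LabelMap(np.ascontiguousarray(sub), pre.spacing, pre.origin,
                         pre.schema)
        assert om.organ_volume(lm, om.MEDIAL_RECTUS) == count * pre.voxel_volume


class TestMeasureOrbit:
    def test_phantom_volumes_match_voxel_counts(self, default_phantom):
        _, pre, _, _ = default_phantom
        m = om.measure_orbit(pre, orbit_id="p", timepoint="pre")
        for role in om.RECTUS_ROLES:
            n = np.count_nonzero(pre.data == pre.schema.label(role))
            assert m.organ_volumes[role] == n * pre.voxel_volume

    def test_no_muscles_means_zero_organ_volume(self):
        lm = _tiny_labelmap(500)
        m = om.measure_orbit(lm)
        assert all(m.organ_volumes[r] == 0.0 for r in om.RECTUS_ROLES)

    def test_organ_set_does_not_change_orbital_volume(self, default_phantom):
        _, pre, _, _ = default_phantom
        m4 = om.measure_orbit(pre)
        m5 = om.measure_orbit(pre, (*om.RECTUS_ROLES, om.GLOBE))
        assert m5.orbital_volume == m4.orbital_volume
        assert set(m5.organ_set) - set(m4.organ_set) == {om.GLOBE}


class TestEffectiveVolume:
    def test_subtraction(self):
        m = make_measurement(v_orb=27000.0, rectus=(1500.0,) * 4)
        assert om.effective_orbital_volume(m) == pytest.approx(21000.0)

    def test_empty_organ_set_equals_orbital_volume(self):
        m = make_measurement(v_orb=27000.0, organ_set=())
        assert om.effective_orbital_volume(m) == 27000.0

    def test_negative_effective_volume_warns(self):
        m = make_measurement(v_orb=5000.0, rectus=(1500.0,) * 4)
        with pytest.warns(DataQualityWarning):
            assert om.effective_orbital_volume(m) == pytest.approx(-1000.0)


class TestIreov:
    def test_hand_computed_example(self):
        pre = make_measurement(v_orb=27000.0, rectus=(1500.0,) * 4)
        post = make_measurement(timepoint="post", v_orb=31050.0,
                                rectus=(1567.5,) * 4)
        res = om.ireov(pre, post)
        # (24780 - 21000) / 27000
        assert res.ireov == pytest.approx(0.14, abs=1e-12)

    def test_identical_measurements_give_exact_zero(self):
        pre = make_measurement()
        post = make_measurement(timepoint="post")
        assert om.ireov(pre, post).ireov == 0.0

    def test_negative_ireov_admissible(self):
        pre = make_measurement(v_orb=27000.0, rectus=(1500.0,) * 4)
        post = make_measurement(timepoint="post", v_orb=27000.0,
                                rectus=(1750.0,) * 4)
        res = om.ireov(pre, post)
        assert res.ireov == pytest.approx(-1000.0 / 27000.0, abs=1e-12)

    @pytest.mark.parametrize("kwargs,match", [
        (dict(orbit_id="other"), "orbit mismatch"),
        (dict(organ_set=(om.MEDIAL_RECTUS,)), "organ sets"),
        (dict(timepoint="pre"), "must be"),
    ])
    def test_contract_violations_raise(self, kwargs, match):
        pre = make_measurement()
        post = make_measurement(timepoint="post")
        bad = make_measurement(**{"timepoint": "post", **kwargs})
        with pytest.raises(VolumetryError, match=match):
            om.ireov(pre, bad)

    @given(k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, k):
        pre = make_measurement(v_orb=27000.0, rectus=(1400.0, 1500.0, 1600.0, 1700.0))
        post = make_measurement(timepoint="post", v_orb=30000.0,
                                rectus=(1500.0, 1600.0, 1700.0, 1800.0))
        scaled = om.ireov(
            make_measurement(v_orb=27000.0 * k,
                             rectus=tuple(v * k for v in (1400.0, 1500.0, 1600.0, 1700.0))),
            make_measurement(timepoint="post", v_orb=30000.0 * k,
                             rectus=tuple(v * k for v in (1500.0, 1600.0, 1700.0, 1800.0))),
        )
        assert scaled.ireov == pytest.approx(om.ireov(pre, post).ireov, abs=1e-9)

    @given(v=st.floats(1.0, 20000.0))
    def test_constant_volume_organ_cancels(self, v):
        base_pre = make_measurement(v_orb=27000.0)
        base_post = make_measurement(timepoint="post", v_orb=30000.0,
                                     rectus=(1600.0,) * 4)
        with_globe = om.ireov(
            make_measurement(v_orb=27000.0, extra={om.GLOBE: v},
                             organ_set=(*om.RECTUS_ROLES, om.GLOBE)),
            make_measurement(timepoint="post", v_orb=30000.0, rectus=(1600.0,) * 4,
                             extra={om.GLOBE: v},
                             organ_set=(*om.RECTUS_ROLES, om.GLOBE)),
        )
        assert with_globe.ireov == pytest.approx(
            om.ireov(base_pre, base_post).ireov, abs=1e-12)


class TestMuscleChangeTable:
    @staticmethod
    def _result(oid, ireov_value, delta):
        return om.IreovResult(orbit_id=oid, orbital_volume_pre=27000.0,
                              organ_volume_pre=6000.0, orbital_volume_post=30000.0,
                              organ_volume_post=6000.0, ireov=ireov_value,
                              muscle_delta=dict(zip(om.RECTUS_ROLES, delta)))

    def test_varying_muscle_dominates_correlation(self):
        # only the medial rectus delta varies, anti-correlated with IREOV
        results = [self._result(f"o{i}", 0.20 - 0.002 * dv,
                                (float(dv), 10.0, 10.0, 10.0))
                   for i, dv in enumerate((5, 20, 40, 60, 80))]
        table = om.muscle_change_table(results)
        rho = table["spearman_rho_vs_ireov"]
        assert rho[om.MEDIAL_RECTUS] == pytest.approx(-1.0)
        assert rho.drop(om.MEDIAL_RECTUS).isna().all()

    def test_all_zero_deltas_report_nan(self):
        results = [self._result(f"o{i}", 0.1 + 0.01 * i, (0.0,) * 4)
                   for i in range(4)]
        table = om.muscle_change_table(results)
        assert table["spearman_rho_vs_ireov"].isna().all()

    def test_identical_delta_vectors_get_identical_correlations(self):
        results = [self._result(f"o{i}", 0.1 + 0.03 * i,
                                (float(i * 7), float(i * 7), 3.0, 4.0))
                   for i in range(5)]
        table = om.muscle_change_table(results)
        assert table.loc[om.MEDIAL_RECTUS, "spearman_rho_vs_ireov"] == \
            table.loc[om.LATERAL_RECTUS, "spearman_rho_vs_ireov"]

    def test_needs_three_results(self):
        results = [self._result("a", 0.1, (1.0,) * 4),
                   self._result("b", 0.2, (2.0,) * 4)]
        with pytest.raises(VolumetryError):
            om.muscle_change_table(results)
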