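"""DVH curves, Vx / MLD metrics, and their consistency properties."""

import numpy as np
import pytest

from vqlung.dosimetry import (
    DVHCurve,
    MetricRecord,
    activity_weighted_metrics,
    compute_metrics,
    cumulative_dvh,
    mean_dose,
    vx,
)
from vqlung.grid import BinaryMask, ImageGrid
from vqlung.segmentation import segment_functional


def dose_grid(values, spacing=(2.0, 2.0, 2.0)):
    return ImageGrid(np.asarray(values, dtype=float), spacing=spacing)


def full_mask(shape, spacing=(2.0, 2.0, 2.0)):
    return BinaryMask(np.ones(shape, dtype=bool), spacing=spacing)


class TestCumulativeDvh:
    def test_uniform_dose_is_step_function(self):
        mask = full_mask((5, 5, 4))
        curve = cumulative_dvh(dose_grid(np.full(mask.shape, 10.0)), mask, 0.1)
        for edge, value in zip(curve.bin_edges, curve.volume_pct):
            assert value == (100.0 if edge <= 10.0 else 0.0)

    def test_zero_dose(self):
        mask = full_mask((3, 3, 3))
        curve = cumulative_dvh(dose_grid(np.zeros(mask.shape)), mask, 0.1)
        assert curve.volume_pct[0] == 100.0
        assert curve.value_at(0.05) == 0.0
        assert curve.value_at(50.0) == 0.0

    def test_matches_brute_force_voxel_count(self, random_volumes):
        dose, mask = random_volumes
        curve = cumulative_dvh(dose, mask, 0.5)
        in_mask = [dose.values[idx] for idx in np.ndindex(*mask.shape) if mask.values[idx]]
        for edge, value in zip(curve.bin_edges, curve.volume_pct):
            count = sum(1 for d in in_mask if d >= edge)
            assert value == 100.0 * count / len(in_mask)

    def test_curve_invariants(self, random_volumes):
        dose, mask = random_volumes
        curve = cumulative_dvh(dose, mask, 0.25)
        assert curve.bin_edges[0] == 0.0
        assert curve.volume_pct[0] == 100.0
        assert np.all(np.diff(curve.volume_pct) <= 0)
        assert curve.bin_edges[-1] >= dose.values[mask.values].max()

    def test_empty_mask_rejected(self):
        empty = BinaryMask(np.zeros((3, 3, 3), dtype=bool), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="empty"):
            cumulative_dvh(dose_grid(np.ones((3, 3, 3))), empty)

    def test_bad_bin_width_rejected(self, random_volumes):
        dose, mask = random_volumes
        with pytest.raises(ValueError, match="bin_width"):
            cumulative_dvh(dose, mask, 0.0)

    def test_curve_type_validates_monotonicity(self):
        with pytest.raises(ValueError, match="non-increasing"):
            DVHCurve(np.array([0.0, 1.0, 2.0]), np.array([100.0, 50.0, 60.0]))


class TestMeanDose:
    def test_uniform(self):
        mask = full_mask((4, 4, 4))
        assert mean_dose(dose_grid(np.full(mask.shape, 7.3)), mask) == pytest.approx(7.3)

    def test_half_zero_half_forty(self):
        mask = full_mask((4, 4, 4))
        vals = np.zeros(mask.shape)
        vals.reshape(-1)[:32] = 40.0
        assert mean_dose(dose_grid(vals), mask) == pytest.approx(20.0)

    def test_matches_sum_count_loop(self, random_volumes):
        dose, mask = random_volumes
        total = count = 0.0
        for idx in np.ndindex(*mask.shape):
            if mask.values[idx]:
                total += dose.values[idx]
                count += 1
        assert mean_dose(dose, mask) == pytest.approx(total / count, rel=1e-12)


class TestVx:
    def test_zero_cut_is_total_volume(self, random_volumes):
        dose, mask = random_volumes
        assert vx(dose, mask, 0.0) == 100.0

    def test_quarter_above_cut(self):
        mask = full_mask((4, 4, 4))
        vals = np.full(mask.shape, 5.0)
        vals.reshape(-1)[:16] = 30.0  # exactly 25% of 64 voxels
        assert vx(dose_grid(vals), mask, 20.0) == pytest.approx(25.0)

    def test_above_max_dose_is_zero(self, random_volumes):
        dose, mask = random_volumes
        assert vx(dose, mask, dose.values.max() + 1.0) == 0.0

    def test_boundary_inclusive_vs_strict(self):
        mask = full_mask((2, 2, 2))
        vals = np.full(mask.shape, 20.0)
        assert vx(dose_grid(vals), mask, 20.0, inclusive=True) == 100.0
        assert vx(dose_grid(vals), mask, 20.0, inclusive=False) == 0.0

    def test_consistent_with_dvh_at_every_edge(self, random_volumes):
        dose, mask = random_volumes
        curve = cumulative_dvh(dose, mask, 0.7)
        for edge, value in zip(curve.bin_edges, curve.volume_pct):
            assert vx(dose, mask, float(edge)) == value


class TestScalingAndIntegral:
    @pytest.mark.parametrize("c", [0.5, 2.0, 11.0])
    def test_dose_scaling(self, random_volumes, c):
        dose, mask = random_volumes
        scaled = ImageGrid(dose.values * c, spacing=dose.spacing, origin=dose.origin)
        assert vx(scaled, mask, c * 15.0) == vx(dose, mask, 15.0)
        assert mean_dose(scaled, mask) == pytest.approx(c * mean_dose(dose, mask))

    def test_mld_equals_dvh_integral_and_refines(self, random_volumes):
        dose, mask = random_volumes
        mld = mean_dose(dose, mask)
        gaps = []
        for bw in (1.0, 0.5, 0.25, 0.125):
            curve = cumulative_dvh(dose, mask, bw)
            integral = np.trapezoid(curve.volume_pct / 100.0, curve.bin_edges)
            gaps.append(abs(integral - mld))
            assert gaps[-1] <= bw  # within one bin of trapezoid error
        assert gaps[-1] <= gaps[0] + 1e-12


class TestComputeMetrics:
    def _funcs(self, lung, q_act, v_act):
        q = segment_functional(q_act, lung, 0.30, "perfusion")
        v = segment_functional(v_act, lung, 0.30, "ventilation")
        return q, v

    def test_uniform_activity_degeneracy(self, rng):
        lung = full_mask((6, 6, 6))
        dose = dose_grid(rng.uniform(0, 40, lung.shape))
        act = dose_grid(np.full(lung.shape, 9.0))
        q, v = self._funcs(lung, act, act)
        rec = compute_metrics(dose, lung, q, v)
        assert rec.Q_V20 == rec.V_V20 == rec.V20
        assert rec.Q_MLD == rec.V_MLD == rec.MLD

    def test_concentration_property(self):
        # all high-dose voxels inside a smaller functional region
        lung = full_mask((4, 4, 4))
        dose_vals = np.full(lung.shape, 5.0)
        dose_vals.reshape(-1)[:8] = 30.0
        act = np.full(lung.shape, 0.1)
        act.reshape(-1)[:16] = 1.0  # functional region = first 16 voxels ⊃ high dose
        q, v = self._funcs(lung, dose_grid(act), dose_grid(act))
        rec = compute_metrics(dose_grid(dose_vals), lung, q, v)
        assert rec.Q_V20 >= rec.V20

    def test_empty_functional_mask_names_modality(self, rng):
        lung = full_mask((4, 4, 4))
        dose = dose_grid(rng.uniform(0, 40, lung.shape))
        act = dose_grid(np.full(lung.shape, 2.0))
        q, v = self._funcs(lung, act, act)
        hollow = BinaryMask(np.zeros(lung.shape, dtype=bool), spacing=lung.spacing)
        from dataclasses import replace

        with pytest.raises(ValueError, match="ventilation"):
            compute_metrics(dose, lung, q, replace(v, mask=hollow))

    def test_record_bounds_validated(self):
        with pytest.raises(ValueError, match="V20"):
            MetricRecord(V20=120.0, MLD=5, Q_V20=10, Q_MLD=5, V_V20=10, V_MLD=5)
        with pytest.raises(ValueError, match="MLD"):
            MetricRecord(V20=10.0, MLD=-1, Q_V20=10, Q_MLD=5, V_V20=10, V_MLD=5)


class TestActivityWeighted:
    def test_uniform_activity_reduces_to_unweighted(self, rng):
        lung = full_mask((5, 5, 5))
        dose = dose_grid(rng.uniform(0, 40, lung.shape))
        act = dose_grid(np.full(lung.shape, 3.0))
        out = activity_weighted_metrics(dose, act, lung, x=20.0)
        assert out["fMLD"] == pytest.approx(mean_dose(dose, lung), rel=1e-12)
        assert out["fVx"] == pytest.approx(vx(dose, lung, 20.0), rel=1e-12)

    def test_concentrated_activity_reaches_100(self):
        lung = full_mask((3, 3, 3))
        dose_vals = np.full(lung.shape, 5.0)
        dose_vals.reshape(-1)[:5] = 25.0
        act = np.zeros(lung.shape)
        act.reshape(-1)[:5] = 1.0
        out = activity_weighted_metrics(dose_grid(dose_vals), dose_grid(act), lung, x=20.0)
        assert out["fVx"] == 100.0

    def test_matches_weighted_sum_loop(self, rng):
        lung = BinaryMask(rng.random((6, 6, 6)) < 0.8, spacing=(2, 2, 2))
        dose = ImageGrid(rng.uniform(0, 40, lung.shape), spacing=(2, 2, 2))
        act = ImageGrid(rng.uniform(0, 5, lung.shape), spacing=(2, 2, 2))
        out = activity_weighted_metrics(dose, act, lung, x=20.0)
        num = den = hit = 0.0
        for idx in np.ndindex(*lung.shape):
            if lung.values[idx]:
                a, d = act.values[idx], dose.values[idx]
                num += a * d
                den += a
                if d >= 20.0:
                    hit += a
        assert out["fMLD"] == pytest.approx(num / den, rel=1e-12)
        assert out["fVx"] == pytest.approx(100.0 * hit / den, rel=1e-12)

    def test_zero_total_activity_rejected(self):
        lung = full_mask((3, 3, 3))
        with pytest.raises(ValueError, match="zero"):
            activity_weighted_metrics(
                dose_grid(np.ones(lung.shape)), dose_grid(np.zeros(lung.shape)), lung
            )
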