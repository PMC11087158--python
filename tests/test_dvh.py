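import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oardose.core_grid import GridHeader, StructureMask
from oardose.dvh import (
    DoseDelta,
    MetricKind,
    MetricUnavailableError,
    dose_delta,
    dose_metric,
    dvh_curve,
)
from conftest import make_dose, make_mask
from oracles import brute_dose_metric

ALL_METRICS = [MetricKind.D1, MetricKind.D5, MetricKind.D50, MetricKind.DMAX]


def grid_with_doses(doses):
    """Pack a 1-D dose list into a (1, 1, n) grid with a full mask."""
    doses = np.asarray(doses, dtype=float).reshape(1, 1, -1)
    return make_dose(doses), make_mask(np.ones(doses.shape, bool))


class TestDoseMetric:
    @pytest.mark.parametrize("metric", ALL_METRICS)
    def test_uniform_field(self, metric):
        d, m = grid_with_doses([5000.0] * 64)
        assert dose_metric(d, m, metric) == 5000.0

    def test_staircase_d50(self):
        # 100 equal-volume voxels at 100..10000: hottest 50 are 5100..10000
        d, m = grid_with_doses(np.arange(100, 10001, 100))
        assert dose_metric(d, m, MetricKind.D50) == 5100.0

    def test_staircase_d1_and_dmax(self):
        d, m = grid_with_doses(np.arange(100, 10001, 100))
        assert dose_metric(d, m, MetricKind.D1) == 10000.0
        assert dose_metric(d, m, MetricKind.DMAX) == 10000.0

    def test_absent_mask_never_scores_zero(self, header):
        d = make_dose(np.ones(header.shape))
        absent = StructureMask.absent(header)
        with pytest.raises(MetricUnavailableError):
            dose_metric(d, absent, MetricKind.D1)

    @pytest.mark.parametrize("metric", ["D1%", "D5%", "D50%", "Dmax"])
    def test_matches_brute_force_oracle(self, metric, rng):
        for _ in range(50):
            n = int(rng.integers(1, 500))
            doses = rng.uniform(0, 7000, n)
            d, m = grid_with_doses(doses)
            assert dose_metric(d, m, MetricKind(metric)) == brute_dose_metric(doses, metric)

    def test_ordering_property(self, rng):
        for _ in range(50):
            doses = rng.uniform(0, 7000, int(rng.integers(2, 400)))
            d, m = grid_with_doses(doses)
            d1 = dose_metric(d, m, MetricKind.D1)
            d5 = dose_metric(d, m, MetricKind.D5)
            d50 = dose_metric(d, m, MetricKind.D50)
            dmax = dose_metric(d, m, MetricKind.DMAX)
            assert dmax >= d1 >= d5 >= d50

    def test_scale_equivariance(self, rng):
        doses = rng.uniform(0, 7000, 200)
        for k in (0.5, 2.0, 13.7):
            for metric in ALL_METRICS:
                d, m = grid_with_doses(doses)
                dk, _ = grid_with_doses(k * doses)
                assert dose_metric(dk, m, metric) == pytest.approx(
                    k * dose_metric(d, m, metric)
                )

    def test_permutation_invariance(self, rng):
        doses = rng.uniform(0, 7000, 333)
        for metric in ALL_METRICS:
            d1, m = grid_with_doses(doses)
            d2, _ = grid_with_doses(rng.permutation(doses))
            assert dose_metric(d1, m, metric) == dose_metric(d2, m, metric)

    @settings(max_examples=50, deadline=None)
    @given(
        doses=st.lists(st.floats(0, 10000, allow_nan=False), min_size=1, max_size=200),
        metric=st.sampled_from(["D1%", "D5%", "D50%", "Dmax"]),
    )
    def test_hypothesis_oracle_equivalence(self, doses, metric):
        d, m = grid_with_doses(doses)
        assert dose_metric(d, m, MetricKind(metric)) == brute_dose_metric(doses, metric)


class TestDvhCurve:
    def test_monotone_and_starts_at_one(self, rng):
        d, m = grid_with_doses(rng.uniform(100, 6000, 500))
        curve = dvh_curve(d, m)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)


class TestDoseDelta:
    def test_identity(self, rng):
        doses = rng.uniform(100, 6000, 64)
        d, m = grid_with_doses(doses)
        dd = dose_delta(d, m, m, MetricKind.D1)
        assert dd.delta_cGy == 0.0
        assert dd.percent == 0.0
        assert dd.status == "ok"

    def test_definitional_arithmetic(self):
        # gold D1% = 5000, auto D1% = 5500 -> +500 cGy, +10%
        vals = np.array([[[5000.0, 5500.0]]])
        d = make_dose(vals)
        gold = make_mask([[[True, False]]])
        auto = make_mask([[[False, True]]])
        dd = dose_delta(d, gold, auto, MetricKind.D1)
        assert dd.delta_cGy == pytest.approx(500.0)
        assert dd.percent == pytest.approx(10.0)
        assert dd.abs_percent == pytest.approx(10.0)

    def test_failed_auto_recorded(self, header):
        d = make_dose(np.full(header.shape, 1000.0))
        gold = StructureMask(np.ones(header.shape, bool), header)
        auto = StructureMask.absent(header, status="failed")
        dd = dose_delta(d, gold, auto, MetricKind.D5)
        assert not dd.available
        assert dd.status == "failed"
        assert dd.gold_cGy == 1000.0
        assert dd.auto_cGy is None

    def test_eroded_away_status_preserved(self, header):
        d = make_dose(np.full(header.shape, 1000.0))
        gold = StructureMask(np.ones(header.shape, bool), header)
        auto = StructureMask.absent(header, status="eroded-away")
        dd = dose_delta(d, gold, auto, MetricKind.D5)
        assert dd.status == "eroded-away"

    def test_zero_gold_dose_percent_undefined(self):
        vals = np.array([[[0.0, 500.0]]])
        d = make_dose(vals)
        gold = make_mask([[[True, False]]])
        auto = make_mask([[[False, True]]])
        dd = dose_delta(d, gold, auto, MetricKind.DMAX)
        assert dd.percent is None
        assert dd.status == "undefined-percent"
        assert dd.delta_cGy == pytest.approx(500.0)  # absolute delta still reported

    def test_prescription_normalization(self):
        vals = np.array([[[5000.0, 5500.0]]])
        d = make_dose(vals)
        gold = make_mask([[[True, False]]])
        auto = make_mask([[[False, True]]])
        dd = dose_delta(
            d, gold, auto, MetricKind.D1,
            normalization="prescription", prescription_cGy=6000.0,
        )
        assert dd.percent == pytest.approx(100.0 * 500.0 / 6000.0)

    def test_percent_scale_invariance(self, rng):
        doses = rng.uniform(100, 6000, 64).reshape(4, 4, 4)
        d = make_dose(doses)
        occ = np.zeros((4, 4, 4), bool)
        occ[:2] = True
        gold = make_mask(occ)
        auto = make_mask(~occ)
        d2 = make_dose(3.0 * doses)
        p1 = dose_delta(d, gold, auto, MetricKind.D5).percent
        p2 = dose_delta(d2, gold, auto, MetricKind.D5).percent
        assert p1 == pytest.approx(p2)
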