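import numpy as np
import pytest

from oardose.core_grid import GridHeader, ProtocolSpec
from oardose.dvh import MetricKind, dose_metric
from oardose.geometry import dsc
from oardose.synthetic import (
    PROTOCOL_A,
    PROTOCOL_B,
    ErrorProfile,
    PerturbationSpec,
    PhantomSpec,
    Sphere,
    default_phantom,
    generate_dose,
    generate_structures,
    perturb,
    simulate_cohort,
)
from oracles import brute_dose_metric


def small_phantom(oars=None, noise_sd=0.0, R=12.0, w=2.0, b=0.05):
    grid = GridHeader((33, 33, 33), (2.0, 2.0, 2.0))
    return PhantomSpec(
        grid=grid,
        ptv_center_mm=(32.0, 32.0, 32.0),
        ptv_radius_mm=R,
        gradient_width_mm=w,
        background_fraction=b,
        oars=oars or {"oar": Sphere((32.0, 32.0, 52.0), 5.0)},
        noise_sd=noise_sd,
    )


class TestGenerateDose:
    def test_saturates_to_prescription_at_center(self):
        ph = small_phantom(R=14.0, w=2.0)  # R/w = 7
        d = generate_dose(ph, PROTOCOL_A)
        center_idx = (16, 16, 16)
        assert d.values[center_idx] == pytest.approx(6000.0, rel=1e-3)

    def test_half_dose_at_gradient(self):
        ph = small_phantom(R=12.0, w=2.0, b=0.05)
        d = generate_dose(ph, PROTOCOL_A)
        # voxel at exactly d = R from the centre along an axis
        val = d.values[16, 16, 16 + 6]  # 12 mm away at 2 mm spacing
        assert val == pytest.approx(6000.0 * (0.05 + 0.95 / 2.0), rel=1e-9)

    def test_deterministic_under_seed(self):
        ph = small_phantom(noise_sd=0.02)
        a = generate_dose(ph, PROTOCOL_A, seed=7)
        b = generate_dose(ph, PROTOCOL_A, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_monotone_in_distance_without_noise(self):
        ph = small_phantom()
        d = generate_dose(ph, PROTOCOL_B)
        # along a ray from the centre, dose never increases
        ray = d.values[16, 16, 16:]
        assert np.all(np.diff(ray) <= 1e-9)

    def test_background_fraction(self):
        ph = small_phantom(R=6.0, w=1.0, b=0.10)
        d = generate_dose(ph, PROTOCOL_A)
        corner = d.values[0, 0, 0]
        assert corner == pytest.approx(600.0, rel=1e-2)


class TestGenerateStructures:
    def test_sphere_voxel_count(self):
        grid = GridHeader((21, 21, 21), (1.0, 1.0, 1.0))
        ph = PhantomSpec(
            grid=grid, ptv_center_mm=(10, 10, 10), ptv_radius_mm=5.0,
            gradient_width_mm=1.0, background_fraction=0.05,
            oars={"s": Sphere((10.0, 10.0, 10.0), 5.0)},
        )
        masks = generate_structures(ph)
        expected = 4.0 / 3.0 * np.pi * 125.0
        assert masks["s"].voxel_count() == pytest.approx(expected, rel=0.10)

    def test_disjoint_primitives_do_not_overlap(self):
        grid = GridHeader((21, 21, 21), (1.0, 1.0, 1.0))
        ph = PhantomSpec(
            grid=grid, ptv_center_mm=(10, 10, 10), ptv_radius_mm=3.0,
            gradient_width_mm=1.0, background_fraction=0.05,
            oars={
                "a": Sphere((5.0, 5.0, 5.0), 3.0),
                "b": Sphere((15.0, 15.0, 15.0), 3.0),
            },
        )
        masks = generate_structures(ph)
        assert not (masks["a"].values & masks["b"].values).any()

    def test_default_roster_has_13_structures(self):
        masks = generate_structures(default_phantom())
        assert len(masks) == 13
        assert all(m.present for m in masks.values())

    def test_primitive_outside_grid_rejected(self):
        grid = GridHeader((11, 11, 11), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            PhantomSpec(
                grid=grid, ptv_center_mm=(5, 5, 5), ptv_radius_mm=3.0,
                gradient_width_mm=1.0, background_fraction=0.05,
                oars={"out": Sphere((10.0, 10.0, 10.0), 5.0)},
            )


class TestPerturb:
    @pytest.fixture
    def gold(self):
        return generate_structures(small_phantom())["oar"]

    @pytest.mark.parametrize("kind", ["dilate", "erode", "truncate"])
    def test_magnitude_zero_is_identity(self, gold, kind):
        out = perturb(gold, PerturbationSpec(kind, magnitude=0.0))
        np.testing.assert_array_equal(out.values, gold.values)

    def test_translate_zero_is_identity(self, gold):
        out = perturb(gold, PerturbationSpec("translate", vector_mm=(0.0, 0.0, 0.0)))
        np.testing.assert_array_equal(out.values, gold.values)

    def test_dilate_grows_erode_shrinks(self, gold):
        big = perturb(gold, PerturbationSpec("dilate", magnitude=2.0))
        small = perturb(gold, PerturbationSpec("erode", magnitude=2.0))
        assert big.voxel_count() > gold.voxel_count() > small.voxel_count()
        assert (gold.values | big.values == big.values).all()

    def test_erode_away_flagged(self, gold):
        out = perturb(gold, PerturbationSpec("erode", magnitude=50.0))
        assert not out.present
        assert out.status == "eroded-away"

    def test_mislocate_disjoint_count_preserved(self, gold):
        out = perturb(gold, PerturbationSpec("mislocate", seed=3))
        assert out.voxel_count() == gold.voxel_count()
        assert dsc(gold, out) == 0.0

    def test_fail_produces_absent(self, gold):
        out = perturb(gold, PerturbationSpec("fail"))
        assert not out.present
        assert out.status == "failed"

    def test_truncate_removes_occupied_slices(self, gold):
        n_slices = len(np.unique(np.argwhere(gold.values)[:, 0]))
        out = perturb(gold, PerturbationSpec("truncate", magnitude=2.0, axis=0))
        assert len(np.unique(np.argwhere(out.values)[:, 0])) == n_slices - 2

    def test_translate_on_uniform_dose_leaves_d1_unchanged(self):
        # structure far from the gradient: a 1-voxel shift cannot change D1%
        ph = small_phantom(oars={"far": Sphere((10.0, 10.0, 10.0), 5.0)}, R=6.0, w=1.0)
        dose = generate_dose(ph, PROTOCOL_A)
        gold = generate_structures(ph)["far"]
        auto = perturb(gold, PerturbationSpec("translate", vector_mm=(2.0, 0.0, 0.0)))
        d1_gold = brute_dose_metric(dose.values[gold.values], "D1%")
        d1_auto = brute_dose_metric(dose.values[auto.values], "D1%")
        assert d1_auto == pytest.approx(d1_gold, abs=1e-6)
        assert dose_metric(dose, auto, MetricKind.D1) == pytest.approx(d1_gold, abs=1e-6)


class TestSimulateCohort:
    def profiles(self):
        return {
            "m1": ErrorProfile({"none": 1.0, "translate": 1.0, "fail": 0.5}),
            "m2": ErrorProfile({"none": 2.0, "dilate": 1.0}),
        }

    def test_deterministic(self):
        ph = small_phantom(noise_sd=0.01)
        c1 = simulate_cohort(4, ph, self.profiles(), seed=11)
        c2 = simulate_cohort(4, ph, self.profiles(), seed=11)
        for a, b in zip(c1.cases, c2.cases):
            np.testing.assert_array_equal(a.dose.values, b.dose.values)
            for organ in a.gold:
                np.testing.assert_array_equal(a.gold[organ].values, b.gold[organ].values)
            for model in a.auto:
                for organ in a.auto[model]:
                    np.testing.assert_array_equal(
                        a.auto[model][organ].values, b.auto[model][organ].values
                    )

    def test_always_fail_profile(self):
        ph = small_phantom()
        profiles = {"m": ErrorProfile({"fail": 1.0})}
        cohort = simulate_cohort(5, ph, profiles, seed=0)
        for case in cohort.cases:
            assert not case.auto["m"]["oar"].present

    def test_no_perturbation_identity(self):
        ph = small_phantom()
        profiles = {"m": ErrorProfile({"none": 1.0})}
        cohort = simulate_cohort(3, ph, profiles, seed=0)
        for case in cohort.cases:
            assert dsc(case.gold["oar"], case.auto["m"]["oar"]) == 1.0

    def test_failure_rate_matches_profile(self):
        ph = small_phantom()
        p_fail = 0.3
        profiles = {"m": ErrorProfile({"none": 0.7, "fail": 0.3})}
        cohort = simulate_cohort(120, ph, profiles, seed=5)
        n_failed = sum(not c.auto["m"]["oar"].present for c in cohort.cases)
        rate = n_failed / 120
        se = np.sqrt(p_fail * (1 - p_fail) / 120)
        assert abs(rate - p_fail) < 3.5 * se

    def test_protocol_split(self):
        ph = small_phantom()
        cohort = simulate_cohort(10, ph, {"m": ErrorProfile({"none": 1.0})},
                                 seed=1, protocol_a_fraction=0.6)
        labels = [c.protocol.name for c in cohort.cases]
        assert labels.count("A") == 6 and labels.count("B") == 4

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(2, small_phantom(), {}, seed=0)


class TestGradientOverlapProperty:
    """Geometric errors only move dose metrics where they cross the gradient."""

    def test_both_arms(self):
        R, w = 12.0, 2.0
        grid = GridHeader((41, 41, 61), (2.0, 2.0, 2.0))
        ph = PhantomSpec(
            grid=grid, ptv_center_mm=(40.0, 40.0, 30.0),
            ptv_radius_mm=R, gradient_width_mm=w, background_fraction=0.05,
            oars={
                # centre 34 mm past the gradient edge (> 5 w beyond R)
                "far": Sphere((40.0, 40.0, 96.0), 6.0),
                # straddles d = R
                "near": Sphere((40.0, 40.0, 42.0), 6.0),
            },
        )
        dose = generate_dose(ph, PROTOCOL_A)
        gold = generate_structures(ph)
        shift = PerturbationSpec("translate", vector_mm=(0.0, 0.0, 6.0))
        presc = PROTOCOL_A.prescription_cGy

        far_auto = perturb(gold["far"], shift)
        delta_far = abs(
            dose_metric(dose, far_auto, MetricKind.D1)
            - dose_metric(dose, gold["far"], MetricKind.D1)
        )
        assert dsc(gold["far"], far_auto) < 0.8
        assert delta_far < 0.01 * presc

        near_auto = perturb(gold["near"], shift)
        delta_near = abs(
            dose_metric(dose, near_auto, MetricKind.D1)
            - dose_metric(dose, gold["near"], MetricKind.D1)
        )
        assert delta_near > 0.05 * presc
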