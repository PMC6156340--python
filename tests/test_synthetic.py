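import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divmap import (
    PlantedZone,
    SyntheticSlideConfig,
    generate_slide,
    match_zones_to_truth,
    recovery_metrics,
    shape_factor,
)
from divmap.tessellation import ZoneMap
from shapely.geometry import box


def small_config(**kw):
    defaults = dict(width=2000.0, height=2000.0, n_cancer=500,
                    n_lymphocyte=100, n_stromal=100,
                    spatial_clustering="uniform", rng_seed=0)
    defaults.update(kw)
    return SyntheticSlideConfig(**defaults)


class TestGenerator:
    def test_class_counts_exact(self):
        table, _ = generate_slide(small_config())
        counts = table.class_counts()
        assert counts["cancer"] == 500
        assert counts["lymphocyte"] == 100
        assert counts["stromal"] == 100

    def test_reproducible_from_seed(self):
        t1, _ = generate_slide(small_config(rng_seed=9))
        t2, _ = generate_slide(small_config(rng_seed=9))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        t3, _ = generate_slide(small_config(rng_seed=10))
        assert not t3.data.equals(t1.data)

    def test_shape_factor_at_least_one_by_construction(self):
        table, _ = generate_slide(small_config(rng_seed=3))
        s = shape_factor(table.data.nucleus_perimeter, table.data.nucleus_area)
        assert np.all(s > 1.0)

    def test_planted_variance_inflates_in_circle_sd(self):
        cfg = small_config(planted_zones=[PlantedZone(1000, 1000, 400, 3.0)],
                           n_cancer=4000, rng_seed=4)
        table, truth = generate_slide(cfg)
        s = shape_factor(table.data.nucleus_perimeter, table.data.nucleus_area)
        cancer = (table.data.cell_class == "cancer").to_numpy()
        inside = truth.per_cell_in_planted & cancer
        outside = ~truth.per_cell_in_planted & cancer
        assert np.std(s[inside]) > 2 * np.std(s[outside])

    def test_unit_multiplier_is_a_true_null(self):
        cfg = small_config(planted_zones=[PlantedZone(1000, 1000, 400, 1.0)],
                           n_cancer=4000, rng_seed=5)
        table, truth = generate_slide(cfg)
        s = shape_factor(table.data.nucleus_perimeter, table.data.nucleus_area)
        cancer = (table.data.cell_class == "cancer").to_numpy()
        ks = stats.ks_2samp(s[truth.per_cell_in_planted & cancer],
                            s[~truth.per_cell_in_planted & cancer])
        assert ks.pvalue > 0.01

    def test_full_depletion_empties_circles_of_lymphocytes(self):
        cfg = small_config(
            planted_zones=[PlantedZone(1000, 1000, 400, 3.0,
                                       lymphocyte_depletion=1.0)],
            n_lymphocyte=500, rng_seed=6)
        table, truth = generate_slide(cfg)
        lymph = (table.data.cell_class == "lymphocyte").to_numpy()
        assert not np.any(truth.per_cell_in_planted & lymph)
        assert lymph.sum() == 500  # depletion displaces, never deletes

    def test_ground_truth_membership_consistent_with_geometry(self):
        cfg = small_config(planted_zones=[PlantedZone(500, 500, 200, 2.0)],
                           rng_seed=7)
        table, truth = generate_slide(cfg)
        xy = table.coords
        manual = (xy[:, 0] - 500) ** 2 + (xy[:, 1] - 500) ** 2 <= 200**2
        assert np.array_equal(manual, truth.per_cell_in_planted)

    def test_zone_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            small_config(planted_zones=[PlantedZone(1990, 1000, 100, 2.0)])

    @pytest.mark.parametrize("kw", [
        dict(variance_multiplier=0.5), dict(lymphocyte_depletion=1.5),
        dict(radius=-1.0)])
    def test_invalid_zone_parameters_rejected(self, kw):
        base = dict(x=100.0, y=100.0, radius=50.0)
        base.update(kw)
        with pytest.raises(ValueError):
            PlantedZone(**base)

    def test_thomas_process_is_clustered(self):
        uni, _ = generate_slide(small_config(rng_seed=8, n_cancer=3000))
        tho, _ = generate_slide(small_config(
            rng_seed=8, n_cancer=3000, spatial_clustering="thomas",
            parent_intensity=5e-6, cluster_sd=100.0))
        # clustered pattern: much smaller mean nearest-neighbor distance
        from scipy.spatial import cKDTree
        def mean_nn(t):
            xy = t.subset("cancer")[["x", "y"]].to_numpy()
            d, _ = cKDTree(xy).query(xy, k=2)
            return d[:, 1].mean()
        assert mean_nn(tho) < 0.8 * mean_nn(uni)


def manual_zone_map(points, assignment, slide_id="synthetic"):
    return ZoneMap(
        seed_cell_ids=list(range(int(assignment.max()) + 1)),
        seed_coords=np.zeros((int(assignment.max()) + 1, 2)),
        regions=[box(0, 0, 1, 1)] * (int(assignment.max()) + 1),
        assignment=np.asarray(assignment),
        tissue_polygon=box(0, 0, 1, 1),
        slide_id=slide_id,
    )


class TestMatching:
    def setup_method(self):
        self.cfg = small_config(
            planted_zones=[PlantedZone(500, 500, 300, 3.0)], rng_seed=11)
        self.table, self.truth = generate_slide(self.cfg)

    def test_threshold_splits_partial_overlap(self):
        # zone 0: 3 of 10 cancer cells inside the circle
        xy = self.table.coords
        cancer_idx = np.flatnonzero(
            (self.table.data.cell_class == "cancer").to_numpy())
        inside = self.truth.per_cell_in_planted
        chosen = np.concatenate([
            cancer_idx[inside[cancer_idx]][:3],
            cancer_idx[~inside[cancer_idx]][:7]])
        assignment = np.full(len(self.table), 1)
        assignment[chosen] = 0
        zm = manual_zone_map(xy, assignment)
        assert not match_zones_to_truth(zm, self.table, self.truth, 0.5)[0]
        assert match_zones_to_truth(zm, self.table, self.truth, 0.25)[0]

    def test_zone_with_no_circle_cells_is_false(self):
        assignment = np.zeros(len(self.table), dtype=int)
        outside_rows = np.flatnonzero(~self.truth.per_cell_in_planted)
        assignment[outside_rows] = 1  # zone 1 entirely outside
        zm = manual_zone_map(self.table.coords, assignment)
        labels = match_zones_to_truth(zm, self.table, self.truth, 0.5)
        assert not labels[1]
        assert labels[0]  # zone 0 holds exactly the in-circle cells

    def test_slide_identity_mismatch_raises(self):
        zm = manual_zone_map(self.table.coords,
                             np.zeros(len(self.table), dtype=int),
                             slide_id="other")
        with pytest.raises(ValueError, match="other"):
            match_zones_to_truth(zm, self.table, self.truth)


class TestRecoveryMetrics:
    def test_hand_confusion_matrix(self):
        pred = [True] * 8 + [False] * 2 + [True] * 1 + [False] * 89
        tru = [True] * 10 + [False] * 90
        m = recovery_metrics(pred, tru)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(8 / 9)
        assert m["specificity"] == pytest.approx(89 / 90)

    def test_perfect_prediction(self):
        m = recovery_metrics([True, False, True], [True, False, True])
        assert m["sensitivity"] == 1 and m["specificity"] == 1

    def test_all_negative_prediction_zero_sensitivity(self):
        m = recovery_metrics([False] * 4, [True, True, False, False])
        assert m["sensitivity"] == 0

    def test_undefined_ratios_are_none_not_zero(self):
        m = recovery_metrics([False, False], [False, False])
        assert m["sensitivity"] is None
        assert m["precision"] is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            recovery_metrics([True], [True, False])
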