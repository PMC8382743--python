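import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memic import (
    CellTable,
    ChamberMeta,
    FlatProfileError,
    OpeningSpec,
    assign_distance,
    binned_fraction,
    half_max_position,
    moving_profile,
    normalize_channel,
)
from conftest import make_table


class TestAssignDistance:
    def test_left_edge_identity(self):
        t = make_table([350.0], [0.0])
        assert t.df.distance_um.iloc[0] == 350.0

    def test_right_edge_orientation(self):
        t = make_table([350.0], [0.0], assign=False)
        t = assign_distance(t, OpeningSpec("right", 500.0))
        assert t.df.distance_um.iloc[0] == 150.0

    def test_top_and_bottom_edges_use_y(self):
        df = pd.DataFrame(
            {"cell_id": [1], "x_um": [10.0], "y_um": [40.0], "area_um2": [1.0]}
        )
        t = CellTable(df, ChamberMeta())
        assert assign_distance(t, OpeningSpec("top", 0.0)).df.distance_um.iloc[0] == 40.0
        assert assign_distance(t, OpeningSpec("bottom", 100.0)).df.distance_um.iloc[0] == 60.0

    def test_reservoir_side_clamped_and_flagged(self):
        t = make_table([-20.0], [0.0])
        assert t.df.distance_um.iloc[0] == 0.0
        assert bool(t.df.outside_chamber.iloc[0])

    def test_missing_opening_raises(self):
        t = make_table([10.0], [0.0], assign=False)
        with pytest.raises(ValueError, match="OpeningSpec"):
            assign_distance(t, None)


class TestNormalizeChannel:
    @staticmethod
    def table_with_channels(gfp, hoechst):
        df = pd.DataFrame(
            {
                "cell_id": np.arange(1, len(gfp) + 1),
                "x_um": 0.0,
                "y_um": 0.0,
                "area_um2": 1.0,
                "gfp_mean": gfp,
                "hoechst_mean": hoechst,
            }
        )
        return CellTable(df, ChamberMeta())

    def test_identity_ratio(self):
        t = self.table_with_channels([5.0, 7.0], [5.0, 7.0])
        out, dropped = normalize_channel(t, "gfp", "hoechst")
        assert dropped == 0
        assert np.all(out.df["gfp_over_hoechst"] == 1.0)

    def test_linearity(self):
        t1 = self.table_with_channels([4.0, 6.0], [2.0, 3.0])
        t2 = self.table_with_channels([8.0, 12.0], [2.0, 3.0])
        r1, _ = normalize_channel(t1, "gfp", "hoechst")
        r2, _ = normalize_channel(t2, "gfp", "hoechst")
        np.testing.assert_allclose(
            r2.df["gfp_over_hoechst"], 2 * r1.df["gfp_over_hoechst"]
        )

    def test_zero_denominator_cells_excluded_and_counted(self):
        t = self.table_with_channels([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])
        out, dropped = normalize_channel(t, "gfp", "hoechst")
        assert dropped == 1 and len(out) == 2

    def test_all_zero_denominator_hard_error(self):
        t = self.table_with_channels([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            normalize_channel(t, "gfp", "hoechst")

    def test_ratio_profile_recovers_reporter_shape(self, noisy_scene):
        """GFP/Hoechst ratio tracks the generator's linear reporter up to a
        constant factor (Hoechst is uniform)."""
        from memic import detect_nuclei, measure_cells

        labels = detect_nuclei(noisy_scene.images["hoechst"])
        t = measure_cells(labels, list(noisy_scene.images.values()))
        t = assign_distance(t, OpeningSpec())
        t, _ = normalize_channel(t, "gfp", "hoechst")
        d = t.df.distance_um.to_numpy()
        ratio = t.df.gfp_over_hoechst.to_numpy()
        true = 200 + 1.5 * d
        scale = np.median(ratio / true)
        assert np.corrcoef(ratio, true)[0, 1] > 0.95
        rel_err = np.abs(ratio / (true * scale) - 1)
        assert np.quantile(rel_err, 0.9) < 0.25  # per-cell shot noise remains


class TestMovingProfile:
    def test_constant_value_zero_iqr(self):
        t = make_table(np.linspace(0, 500, 300), np.full(300, 7.0))
        prof = moving_profile(t, "v", window_width=100, step=25, min_cells=5)
        pop = prof.populated
        assert pop.any()
        assert np.all(prof.median[pop] == 7.0)
        assert np.all(prof.q75[pop] - prof.q25[pop] == 0.0)

    def test_identity_map_median_tracks_center(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 2000, 5000)
        t = make_table(d, d)
        prof = moving_profile(t, "v", window_width=100, step=25, min_cells=20)
        pop = prof.populated & (prof.centers > 50) & (prof.centers < 1950)
        assert np.all(np.abs(prof.median[pop] - prof.centers[pop]) < 25)

    def test_sparse_window_flagged_absent(self):
        t = make_table([0.0, 1.0, 2.0, 500.0], [1.0, 1.0, 1.0, 9.0])
        prof = moving_profile(t, "v", window_width=50, step=25, min_cells=3)
        i = np.argmin(np.abs(prof.centers - 500))
        assert prof.counts[i] == 1 and np.isnan(prof.median[i])

    def test_empty_table_empty_profile(self):
        t = make_table([], [])
        prof = moving_profile(t, "v")
        assert len(prof.centers) == 0

    def test_matches_exhaustive_window_recomputation(self):
        """Searchsorted implementation equals per-window brute force."""
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 3000, 10_000)
        v = rng.normal(size=10_000) * (1 + d / 1000)
        t = make_table(d, v)
        w, step, mc = 100.0, 25.0, 20
        prof = moving_profile(t, "v", w, step, mc)
        for i, c in enumerate(prof.centers):
            sel = (d >= c - w / 2) & (d < c + w / 2)
            assert prof.counts[i] == sel.sum()
            if sel.sum() >= mc:
                np.testing.assert_allclose(prof.median[i], np.median(v[sel]), rtol=1e-12)
                np.testing.assert_allclose(prof.q25[i], np.percentile(v[sel], 25), rtol=1e-12)
            else:
                assert np.isnan(prof.median[i])

    def test_quartiles_bracket_median(self, noisy_scene):
        from memic import detect_nuclei, measure_cells

        labels = detect_nuclei(noisy_scene.images["hoechst"])
        t = assign_distance(
            measure_cells(labels, [noisy_scene.images["gfp"]]), OpeningSpec()
        )
        prof = moving_profile(t, "gfp_mean", min_cells=5)
        pop = prof.populated
        assert np.all(prof.q25[pop] <= prof.median[pop])
        assert np.all(prof.median[pop] <= prof.q75[pop])

    @given(shift_steps=st.integers(min_value=0, max_value=40))
    @settings(deadline=None, max_examples=20)
    def test_shift_equivariance_on_step_multiples(self, shift_steps):
        """Translating distances by a multiple of the window step shifts every
        profile statistic by exactly that amount (the grid is 0-anchored)."""
        rng = np.random.default_rng(17)
        d = rng.uniform(0, 800, 2000)
        v = rng.normal(size=2000)
        delta = shift_steps * 25.0
        p0 = moving_profile(make_table(d, v), "v", 100, 25, 10)
        p1 = moving_profile(make_table(d + delta, v), "v", 100, 25, 10)
        k = int(shift_steps)
        np.testing.assert_allclose(p1.centers[k : k + len(p0.centers)] - delta, p0.centers)
        np.testing.assert_array_equal(p1.median[k : k + len(p0.median)], p0.median)

    def test_monotone_input_gives_monotone_profile(self):
        d = np.linspace(0, 1000, 4000)
        t = make_table(d, np.sqrt(d))
        prof = moving_profile(t, "v", 100, 25, 10)
        med = prof.median[prof.populated]
        assert np.all(np.diff(med) >= 0)


class TestBinnedFraction:
    def test_all_positive_saturates_at_one(self):
        t = make_table(np.linspace(0, 900, 50), np.full(50, 10.0))
        prof = binned_fraction([t], "v", threshold=5.0, bin_width=250)
        pop = prof.counts[0] > 0
        assert np.all(prof.fractions[0][pop] == 1.0)

    def test_counting_seven_of_twenty(self):
        vals = np.r_[np.full(7, 10.0), np.full(13, 0.0)]
        t = make_table(np.linspace(0, 100, 20), vals)
        prof = binned_fraction([t], "v", threshold=5.0, bin_width=250)
        assert prof.fractions[0][0] == pytest.approx(0.35)

    def test_bins_are_half_open_zero_anchored(self):
        # a cell exactly at 250 belongs to [250, 500), not [0, 250)
        t = make_table([100.0, 250.0], [10.0, 0.0])
        prof = binned_fraction([t], "v", threshold=5.0, bin_width=250)
        assert prof.counts[0][0] == 1 and prof.counts[0][1] == 1
        assert prof.fractions[0][0] == 1.0 and prof.fractions[0][1] == 0.0

    def test_step_positivity_recovered_within_binomial_error(self):
        """Known positivity probability p(x): step from 0.8 to 0.1 at 1 mm."""
        rng = np.random.default_rng(23)
        n = 4000
        d = rng.uniform(0, 2000, n)
        p = np.where(d < 1000, 0.8, 0.1)
        v = (rng.uniform(size=n) < p).astype(float)
        t = make_table(d, v)
        prof = binned_fraction([t], "v", threshold=0.5, bin_width=250)
        for b in range(prof.fractions.shape[1]):
            n_b = prof.counts[0][b]
            if n_b == 0:
                continue
            expect = 0.8 if prof.bin_centers[b] < 1000 else 0.1
            se = np.sqrt(expect * (1 - expect) / n_b)
            assert abs(prof.fractions[0][b] - expect) < 4 * se


class TestHalfMaxPosition:
    def test_exact_grid_point_crossing(self):
        x = np.array([100.0, 200, 300, 400, 500])
        v = np.array([0.0, 0, 50, 100, 100])
        assert half_max_position((x, v)) == 300.0

    def test_linear_interpolation_between_centers(self):
        # threshold = min + 0.5*(max - min) = 40, reached exactly at 200 µm
        x = np.array([100.0, 200, 300])
        v = np.array([0.0, 40, 80])
        assert half_max_position((x, v)) == 200.0

    def test_interpolated_off_grid_crossing(self):
        x = np.array([100.0, 200, 300])
        v = np.array([0.0, 30, 80])  # threshold 40 crossed at 220
        assert half_max_position((x, v)) == pytest.approx(220.0)

    def test_logistic_midpoint_recovered(self):
        x0 = 730.0
        x = np.arange(0, 1500, 10.0)
        v = 1 / (1 + np.exp(-(x - x0) / 80))
        assert abs(half_max_position((x, v)) - x0) < 10

    def test_flat_profile_raises(self):
        x = np.array([0.0, 100, 200])
        with pytest.raises(FlatProfileError):
            half_max_position((x, np.full(3, 5.0)))

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError, match="3"):
            half_max_position((np.array([0.0, 100]), np.array([0.0, 1.0])))

    @given(
        k=st.floats(min_value=0.01, max_value=100),
        delta=st.floats(min_value=0, max_value=1e4),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance_and_shift_equivariance(self, k, delta):
        x = np.arange(0, 1000, 25.0)
        v = 1 / (1 + np.exp(-(x - 400) / 60))
        base = half_max_position((x, v))
        assert half_max_position((x, k * v)) == pytest.approx(base)
        assert half_max_position((x + delta, v)) == pytest.approx(base + delta)
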