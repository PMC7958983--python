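"""Rank normalization, the hue/lightness transform, PCA and polar binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ipvcooc import (
    PolarGridSpec,
    ResponseMatrix,
    bin_radial,
    hsl_transform,
    pca_project,
    radial_coords,
    radial_points,
    rank_normalize,
)


def frame(**cols):
    return pd.DataFrame(cols)


class TestRankNormalize:
    def test_distinct_scores_give_rank_over_n(self):
        r = rank_normalize(frame(PV=[10.0, 20.0, 30.0, 40.0]))
        assert r["PV"].tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_ties_receive_average_rank(self):
        r = rank_normalize(frame(PV=[5.0, 5.0, 9.0]))
        assert r["PV"].tolist() == pytest.approx([0.5, 0.5, 1.0])

    def test_single_survivor_maps_to_one(self):
        assert rank_normalize(frame(PV=[3.0]))["PV"].tolist() == [1.0]

    @given(st.lists(st.floats(-50, 50).map(lambda x: round(x, 3)),
                    min_size=2, max_size=40, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        base = frame(PV=xs)
        transformed = frame(PV=[np.exp(x / 25) + 3 * x for x in xs])
        pd.testing.assert_frame_equal(rank_normalize(base), rank_normalize(transformed))

    def test_uniform_marginal_up_to_ties(self):
        rng = np.random.default_rng(8)
        r = rank_normalize(frame(PV=rng.normal(size=500)))["PV"]
        from scipy import stats

        assert stats.kstest(r, "uniform").statistic < 0.05


class TestHslTransform:
    def test_pure_pv_ray(self):
        out = hsl_transform([1.0], [0.0], [0.0])
        assert out.loc[0, "intensity"] == 0.5
        assert out.loc[0, "h_prime"] == 0.0
        assert out.loc[0, "angle"] == 0.0
        assert not out.loc[0, "achromatic"]

    def test_equal_channels_are_achromatic(self):
        out = hsl_transform([0.5], [0.5], [0.5])
        assert out.loc[0, "intensity"] == 0.5
        assert out.loc[0, "achromatic"]
        assert np.isnan(out.loc[0, "angle"])

    def test_pure_pa_branch(self):
        out = hsl_transform([0.0], [1.0], [0.0])
        assert out.loc[0, "h_prime"] == 2.0
        assert out.loc[0, "angle"] == pytest.approx(2 * np.pi / 6)

    def test_pure_type_rays_are_constant_and_distinct(self):
        """Rank triples (c,0,0), (0,c,0), (0,0,c) map to three fixed angles."""
        angles = set()
        for channel in range(3):
            per_c = []
            for c in (0.2, 0.5, 0.9, 1.0):
                r = [0.0, 0.0, 0.0]
                r[channel] = c
                out = hsl_transform([r[0]], [r[1]], [r[2]])
                assert out.loc[0, "intensity"] == pytest.approx(c / 2)
                per_c.append(out.loc[0, "angle"])
            assert len(set(np.round(per_c, 12))) == 1
            angles.add(round(per_c[0], 12))
        assert len(angles) == 3

    def test_max_tie_uses_pv_precedence_and_branches_agree(self):
        """r_PV = r_PA > r_SV: both admissible branches give the same hue."""
        out = hsl_transform([0.8], [0.8], [0.2])
        pv_branch = ((0.8 - 0.2) / 0.6) % 6
        pa_branch = (0.2 - 0.8) / 0.6 + 2
        assert pv_branch == pytest.approx(pa_branch)  # boundary consistency
        assert out.loc[0, "h_prime"] == pytest.approx(pv_branch)

    def test_pv_branch_uses_nonnegative_mod(self):
        # r_PA < r_SV makes the raw hue negative; mod 6 wraps it into [0, 6)
        out = hsl_transform([1.0], [0.0], [0.5])
        assert 0 <= out.loc[0, "h_prime"] < 6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rank scores"):
            hsl_transform([1.2], [0.0], [0.0])

    def test_standard_hue_scale_doubles_angles(self):
        narrow = hsl_transform([0.0], [1.0], [0.0], hue_scale="narrow")
        standard = hsl_transform([0.0], [1.0], [0.0], hue_scale="standard")
        assert standard.loc[0, "angle"] == pytest.approx(2 * narrow.loc[0, "angle"])

    @given(st.integers(0, 2**32 - 1))
    def test_radius_identity_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(size=(200, 3))
        out = hsl_transform(r[:, 0], r[:, 1], r[:, 2])
        x, y = radial_coords(out["intensity"].to_numpy(), out["angle"].to_numpy())
        sel = ~out["achromatic"].to_numpy()
        np.testing.assert_allclose(
            np.hypot(x[sel], y[sel]), out["intensity"].to_numpy()[sel], atol=1e-12
        )


class TestRadialCoords:
    def test_cardinal_points(self):
        x, y = radial_coords([0.5, 1.0], [0.0, np.pi / 2])
        assert (x[0], y[0]) == (0.5, 0.0)
        assert x[1] == pytest.approx(0.0, abs=1e-12)
        assert y[1] == pytest.approx(1.0)

    def test_achromatic_placed_on_zero_ray(self):
        x, y = radial_coords([0.7], [np.nan])
        assert (x[0], y[0]) == (0.7, 0.0)


class TestPcaProject:
    def test_rank_one_matrix_explains_everything_on_pc1(self):
        base = np.outer([0, 1, 1, 2], [1, 0, 2]).astype(int)
        rm = ResponseMatrix([f"s{i}" for i in range(4)], ["A", "B", "C"], base)
        _, _, evr = pca_project(rm)
        assert evr[0] == pytest.approx(1.0)

    def test_two_block_design_separates_on_components(self):
        rng = np.random.default_rng(1)
        block = np.zeros((40, 4), dtype=int)
        block[:20, :2] = rng.integers(2, 5, size=(20, 2))
        block[20:, 2:] = rng.integers(2, 5, size=(20, 2))
        rm = ResponseMatrix([f"s{i}" for i in range(40)], list("ABCD"), block)
        scores, _, _ = pca_project(rm)
        a = scores.iloc[:20]["PC1"].mean()
        b = scores.iloc[20:]["PC1"].mean()
        assert abs(a - b) > 1.0

    def test_duplicated_rows_project_identically(self, small_cohort):
        rm = small_cohort.responses
        dup = ResponseMatrix(
            [f"{s}b" for s in rm.survivor_ids] + rm.survivor_ids,
            rm.item_ids,
            np.vstack([rm.values, rm.values]),
        )
        scores, _, _ = pca_project(dup)
        n = rm.n_survivors
        np.testing.assert_allclose(scores.iloc[:n].to_numpy(), scores.iloc[n:].to_numpy())

    def test_sign_convention_fixes_largest_loading_positive(self, small_cohort):
        _, loadings, _ = pca_project(small_cohort.responses)
        for pc in ("PC1", "PC2"):
            assert loadings[pc].iloc[np.argmax(np.abs(loadings[pc].to_numpy()))] > 0


class TestBinRadial:
    def _points(self, intensity, angle):
        return pd.DataFrame(
            {
                "intensity": intensity,
                "angle": angle,
                "achromatic": [np.isnan(a) for a in angle],
            }
        )

    def test_single_survivor_bin(self):
        pts = self._points([0.3], [0.1])
        grid = bin_radial(pts, [2.0])
        row = grid.table[grid.table["count"] > 0]
        assert len(row) == 1
        assert row.iloc[0]["mean_outcome"] == 2.0

    def test_two_survivors_one_bin_average(self):
        pts = self._points([0.31, 0.32], [0.1, 0.1])
        grid = bin_radial(pts, [1.0, 3.0])
        row = grid.table[grid.table["count"] > 0]
        assert row.iloc[0]["count"] == 2
        assert row.iloc[0]["mean_outcome"] == 2.0

    def test_mismatched_lengths_raise(self):
        pts = self._points([0.3], [0.1])
        with pytest.raises(ValueError, match="outcome length"):
            bin_radial(pts, [1.0, 2.0])

    def test_achromatic_excluded_and_counts_conserved(self):
        pts = self._points([0.3, 0.5, 0.9], [0.1, np.nan, 2.0])
        grid = bin_radial(pts)
        assert grid.n_achromatic == 1
        assert grid.table["count"].sum() == 2

    def test_uniform_angles_fill_bins_uniformly(self):
        rng = np.random.default_rng(12)
        n = 5000
        spec = PolarGridSpec(n_angle=12, n_radius=5)
        pts = self._points(rng.uniform(0, 1, n), rng.uniform(0, spec.angle_max, n))
        grid = bin_radial(pts, grid=spec)
        counts = grid.table["count"].to_numpy()
        p = 1 / len(counts)
        tol = 3.29 * np.sqrt(p * (1 - p) * n)  # multinomial 99.9% per-bin band
        assert np.all(np.abs(counts - n * p) < tol)


def test_radial_points_end_to_end(small_cohort, catalog):
    from ipvcooc import compute_type_scores, filter_survivors

    scores = compute_type_scores(filter_survivors(small_cohort.responses), catalog)
    pts = radial_points(scores)
    sel = ~pts["achromatic"]
    np.testing.assert_allclose(
        np.hypot(pts.loc[sel, "x"], pts.loc[sel, "y"]), pts.loc[sel, "intensity"],
        atol=1e-12,
    )
    assert pts["intensity"].between(0, 1).all()
    assert pts.loc[sel, "angle"].between(0, np.pi).all()
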