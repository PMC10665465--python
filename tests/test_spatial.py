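"""Spatially corrected correlation, RMA, latitudinal fits, null model,
and rank comparisons."""

import numpy as np
import pandas as pd
import pytest

from angiodiv import (
    latitude_fit,
    modified_ttest,
    rank_compare,
    richness_null,
    rma_fit,
)
from angiodiv.spatial import f_ratio_from_r, great_circle_distances


def scatter_coords(rng, n=60):
    return rng.uniform(-60, 70, n), rng.uniform(-180, 180, n)


class TestModifiedTTest:
    def test_published_f_ratios(self):
        assert round(f_ratio_from_r(-0.352), 3) == 0.141
        assert round(f_ratio_from_r(0.386), 3) == 0.175

    def test_ess_at_most_n_and_df_definition(self, rng):
        lat, lon = scatter_coords(rng)
        res = modified_ttest(rng.normal(size=60), rng.normal(size=60), lat, lon)
        assert 1.0 <= res.ess <= res.n
        assert res.df == pytest.approx(res.ess - 2)
        assert res.f_ratio == pytest.approx(f_ratio_from_r(res.r))

    def test_iid_fields_keep_most_of_the_sample(self, rng):
        ratios = []
        for _ in range(30):
            lat, lon = scatter_coords(rng)
            res = modified_ttest(rng.normal(size=60), rng.normal(size=60),
                                 lat, lon)
            ratios.append(res.ess / res.n)
        assert np.mean(ratios) > 0.85

    def test_affine_invariance_of_f_ratio(self, rng):
        lat, lon = scatter_coords(rng)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        a = modified_ttest(x, y, lat, lon)
        b = modified_ttest(3.0 * x - 7.0, -2.0 * y + 11.0, lat, lon)
        assert b.f_ratio == pytest.approx(a.f_ratio, rel=1e-9)
        assert b.ess == pytest.approx(a.ess, rel=1e-9)

    def test_perfect_correlation_capped_and_flagged(self, rng):
        lat, lon = scatter_coords(rng)
        x = rng.normal(size=60)
        res = modified_ttest(x, x + 5.0, lat, lon)
        assert res.degenerate
        assert np.isfinite(res.f_ratio)
        assert np.isnan(res.p)

    def test_zero_variance_errors(self, rng):
        lat, lon = scatter_coords(rng)
        with pytest.raises(ValueError):
            modified_ttest(np.ones(60), rng.normal(size=60), lat, lon)

    def test_haversine_known_distances(self):
        d = great_circle_distances(np.array([0.0, 0.0]), np.array([0.0, 90.0]))
        assert d[0, 1] == pytest.approx(np.pi / 2 * 6371.0, rel=1e-6)


class TestRma:
    def test_exact_line_and_sign_symmetry(self):
        up = rma_fit([0, 1, 2], [0, 2, 4])
        assert (up.slope, up.intercept) == (pytest.approx(2.0), pytest.approx(0.0))
        down = rma_fit([0, 1, 2], [4, 2, 0])
        assert (down.slope, down.intercept) == (pytest.approx(-2.0), pytest.approx(4.0))

    def test_hand_computed_noisy_fit(self):
        fit = rma_fit([1, 2, 3, 4], [2, 3, 5, 6])
        assert fit.slope == pytest.approx(np.sqrt(2), abs=1e-5)
        assert fit.intercept == pytest.approx(0.46447, abs=1e-5)

    def test_slope_is_geometric_mean_of_ols_slopes(self, rng):
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40) * 0.5
        fit = rma_fit(x, y)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        # geometric mean of the y-on-x slope and the inverted x-on-y slope
        assert abs(fit.slope) == pytest.approx(np.sqrt(abs(b_yx / b_xy)), rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            rma_fit([1, 1, 1], [1, 2, 3])


class TestLatitudeFit:
    def test_exact_parabola(self):
        fit = latitude_fit([90, 100, 90], [-10, 0, 10], kind="quadratic")
        assert fit.r2 == pytest.approx(1.0)
        # vertex at the equator: linear term zero
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.quad < 0

    def test_constant_values(self, rng):
        lats = rng.uniform(-60, 60, 20)
        fit = latitude_fit(np.full(20, 5.0), lats, kind="quadratic")
        assert fit.r2 == pytest.approx(0.0)
        lw = latitude_fit(np.full(20, 5.0), lats, kind="lowess")
        assert np.allclose(lw.fitted, 5.0)

    def test_lowess_reproduces_a_line(self, rng):
        lats = np.sort(rng.uniform(-60, 60, 30))
        vals = 2.0 * lats + 1.0
        for span in (0.3, 0.5, 1.0):
            lw = latitude_fit(vals, lats, kind="lowess", span=span)
            assert np.allclose(lw.fitted, 2.0 * lw.x + 1.0, atol=1e-6)

    def test_bad_span_errors(self, rng):
        with pytest.raises(ValueError):
            latitude_fit(rng.normal(size=10), rng.uniform(-60, 60, 10),
                         kind="lowess", span=0.0)


def tiny_profiles():
    return pd.DataFrame({
        "genus": ["g1", "g2", "g3"],
        "stem_age": [10.0, 20.0, 30.0],
        "lambda_tip": [0.12, 0.22, 0.32],
        "netdiv_tip": [0.1, 0.2, 0.3],
    }).set_index("genus")


class TestRichnessNull:
    def test_single_draw_units_enumerate_pool(self):
        """Two richness-1 units: a unit's null mean rate is uniform on the
        pool, so the grand mean over replicates approaches the pool mean."""
        inc = pd.DataFrame({"genus": ["g1", "g2"], "unit": ["u1", "u2"]})
        ens = richness_null(inc, tiny_profiles(),
                            lambda d: d["mean_netdiv"][0], n_reps=3000, seed=5)
        values = np.unique(np.round(ens.replicates, 10))
        assert set(values) <= {0.1, 0.2, 0.3}
        assert ens.replicates.mean() == pytest.approx(0.2, abs=3 * 0.0816 / np.sqrt(3000))

    def test_richness_preserved_in_every_replicate(self):
        inc = pd.DataFrame({"genus": ["g1", "g2", "g3", "g1"],
                            "unit": ["u1", "u1", "u1", "u2"]})
        ens = richness_null(inc, tiny_profiles(), lambda d: 0.0,
                            n_reps=50, seed=1, keep_draws=True)
        for rep in ens.draws:
            assert [len(set(u)) for u in rep] == [3, 1]
            assert [len(u) for u in rep] == [3, 1]

    def test_same_seed_identical_ensemble(self):
        inc = pd.DataFrame({"genus": ["g1", "g2"], "unit": ["u1", "u2"]})
        a = richness_null(inc, tiny_profiles(), lambda d: d["mean_age"][1],
                          n_reps=99, seed=7)
        b = richness_null(inc, tiny_profiles(), lambda d: d["mean_age"][1],
                          n_reps=99, seed=7)
        assert np.array_equal(a.replicates, b.replicates)
        assert a.p_empirical == b.p_empirical

    def test_unit_richer_than_pool_errors(self):
        inc = pd.DataFrame({"genus": [f"x{i}" for i in range(4)],
                            "unit": ["u1"] * 4})
        with pytest.raises(ValueError):
            richness_null(inc, tiny_profiles(), lambda d: 0.0, n_reps=9, seed=0)


class TestRankCompare:
    def test_exact_one_tailed_enumeration(self):
        table = rank_compare({"a": [1, 2, 3], "b": [4, 5, 6]},
                             alternative="less")
        assert table.loc[0, "U"] == 0
        assert table.loc[0, "p"] == pytest.approx(1 / 20)

    def test_identical_groups_two_sided_p_one(self):
        table = rank_compare({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_three_groups_pairwise_holm(self, rng):
        groups = {k: rng.normal(loc, size=12) for k, loc in
                  [("x", 0.0), ("y", 0.5), ("z", 2.0)]}
        table = rank_compare(groups, pairwise=True)
        assert len(table) == 3
        assert (table["p_holm"] >= table["p"] - 1e-15).all()

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_compare({"a": [1.0], "b": []})
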