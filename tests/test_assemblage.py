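"""QC of occurrence records, assemblage summaries, quartiles and belts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiodiv import (
    GeoUnit,
    OccurrenceRecord,
    annotate_profiles,
    assemblage_summary,
    assign_belts,
    belt_genus_union,
    qc_filter,
    quartile_partition,
    resolve_overlap,
    unit_quartile_proportions,
)
from angiodiv.assemblage import BELT_BOUNDS


def unit(uid="u1", lat=0.0, region="Other", fractions=None):
    return GeoUnit(id=uid, centroid_lat=lat, centroid_lon=10.0, area=300_000,
                   region_group=region, belt_fractions=fractions or {})


def occ(genus="g1", uid="u1", sources=1, introduced=False,
        granularity="rangemap", overlap=1.0):
    return OccurrenceRecord(genus=genus, unit=uid, source_count=sources,
                            introduced=introduced, granularity=granularity,
                            overlap=overlap)


class TestResolveOverlap:
    @pytest.mark.parametrize("granularity,overlap,accepted", [
        ("locality", 0.85, True),
        ("locality", 0.80, True),
        ("locality", 0.75, False),
        ("gridcell", 0.51, True),
        ("gridcell", 0.50, False),   # strictly larger than half
        ("coordinate", 1.0, True),
        ("coordinate", 0.99, False),
        ("rangemap", 0.10, True),
    ])
    def test_acceptance_rules(self, granularity, overlap, accepted):
        assert resolve_overlap(occ(granularity=granularity, overlap=overlap)) is accepted

    def test_unknown_granularity_errors(self):
        rec = occ()
        object.__setattr__(rec, "granularity", "satellite")
        with pytest.raises(ValueError):
            resolve_overlap(rec)


class TestQcFilter:
    UNITS = {
        "eu": unit("eu", region="Europe"),
        "au": unit("au", region="Australia"),
        "ot": unit("ot", region="Other"),
    }

    def test_regional_source_thresholds(self):
        records = [occ("g1", "eu", sources=3), occ("g2", "eu", sources=2),
                   occ("g3", "au", sources=2), occ("g4", "au", sources=1),
                   occ("g5", "ot", sources=1)]
        inc = qc_filter(records, self.UNITS)
        assert set(inc["genus"]) == {"g1", "g3", "g5"}

    def test_introduced_records_dropped(self):
        inc = qc_filter([occ("g1", "ot", introduced=True)], self.UNITS)
        assert inc.empty

    def test_unknown_unit_errors(self):
        with pytest.raises(ValueError, match="nowhere"):
            qc_filter([occ("g1", "nowhere")], self.UNITS)

    def test_best_corroboration_across_records(self):
        records = [occ("g1", "eu", sources=1), occ("g1", "eu", sources=3)]
        assert len(qc_filter(records, self.UNITS)) == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(1, 4)),
                    min_size=1, max_size=30))
    def test_raising_threshold_is_monotone(self, items):
        records = [occ(f"g{g}", "ot", sources=s) for g, s in items]
        lo = qc_filter(records, self.UNITS, thresholds={"Other": 1})
        hi = qc_filter(records, self.UNITS, thresholds={"Other": 3})
        lo_set = set(map(tuple, lo.to_numpy()))
        hi_set = set(map(tuple, hi.to_numpy()))
        assert hi_set <= lo_set


def profile_frame(ages, lams=None, rs=None):
    genera = [f"g{i}" for i in range(len(ages))]
    lams = lams if lams is not None else [0.1] * len(ages)
    rs = rs if rs is not None else [l - 0.02 for l in lams]
    return pd.DataFrame({"genus": genera, "stem_age": ages,
                         "lambda_tip": lams, "netdiv_tip": rs}).set_index("genus")


class TestAssemblageSummary:
    def test_unweighted_means(self):
        profiles = profile_frame([10.0, 30.0], rs=[0.02, 0.08])
        inc = pd.DataFrame({"genus": ["g0", "g1"], "unit": ["u1", "u1"]})
        table = assemblage_summary(inc, profiles)
        assert table.loc["u1", "richness"] == 2
        assert table.loc["u1", "mean_age"] == pytest.approx(20.0)
        assert table.loc["u1", "mean_netdiv"] == pytest.approx(0.05)

    def test_single_genus_unit_and_empty_unit(self):
        profiles = profile_frame([10.0, 30.0])
        inc = pd.DataFrame({"genus": ["g1"], "unit": ["u1"]})
        units = {"u1": unit("u1"), "u2": unit("u2")}
        table = assemblage_summary(inc, profiles, units=units)
        assert table.loc["u1", "mean_age"] == pytest.approx(30.0)
        assert table.loc["u2", "richness"] == 0
        assert np.isnan(table.loc["u2", "mean_age"])

    def test_means_bounded_by_incident_metrics(self, small_dataset, rng):
        profiles = small_dataset.profiles
        genera = profiles.index.to_numpy()
        inc = pd.DataFrame({
            "genus": np.concatenate([rng.choice(genera, 12, replace=False)
                                     for _ in range(5)]),
            "unit": np.repeat([f"u{i}" for i in range(5)], 12)})
        table = assemblage_summary(inc, profiles)
        for u, row in table.iterrows():
            sub = profiles.loc[inc.loc[inc["unit"] == u, "genus"]]
            assert sub["stem_age"].min() - 1e-12 <= row["mean_age"] <= sub["stem_age"].max() + 1e-12

    def test_missing_profile_named(self):
        inc = pd.DataFrame({"genus": ["mystery"], "unit": ["u1"]})
        with pytest.raises(ValueError, match="mystery"):
            assemblage_summary(inc, profile_frame([1.0]))


class TestQuartiles:
    def test_octet_splits_into_pairs(self):
        profiles = profile_frame(list(range(1, 9)))
        labels = quartile_partition(profiles, "age")
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_unit_proportions_count_extremes(self):
        profiles = profile_frame(list(range(1, 9)))
        labels = quartile_partition(profiles, "age")
        inc = pd.DataFrame({"genus": ["g0", "g7"], "unit": ["u1", "u1"]})
        props = unit_quartile_proportions(inc, labels)
        assert props.loc["u1"].tolist() == [0.5, 0.0, 0.0, 0.5]

    def test_proportions_sum_to_one_and_counts_to_richness(self, small_dataset, rng):
        profiles = small_dataset.profiles
        labels = quartile_partition(profiles, "age")  # stem ages are all distinct
        genera = profiles.index.to_numpy()
        inc = pd.DataFrame({
            "genus": np.concatenate([rng.choice(genera, 15, replace=False)
                                     for _ in range(4)]),
            "unit": np.repeat([f"u{i}" for i in range(4)], 15)})
        props = unit_quartile_proportions(inc, labels)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_degenerate_values_error(self):
        with pytest.raises(ValueError):
            quartile_partition(profile_frame([1.0, 1.0, 1.0, 1.0, 2.0]), "age")


class TestBelts:
    def test_majority_assignment_and_strict_boundary(self):
        units = {
            "a": unit("a", fractions={"N25-N35": 0.6, "N35-N45": 0.4}),
            "b": unit("b", fractions={"N25-N35": 0.5, "N35-N45": 0.5}),
        }
        assignment = assign_belts(units)
        assert assignment["a"] == "N25-N35"
        assert assignment["b"] is None

    def test_belt_union_pools_genera(self):
        units = {
            "a": unit("a", fractions={"S5-N5": 0.9}),
            "b": unit("b", fractions={"S5-N5": 0.8}),
        }
        inc = pd.DataFrame({"genus": ["g1", "g2", "g2", "g3"],
                            "unit": ["a", "a", "b", "b"]})
        union = belt_genus_union(inc, assign_belts(units))
        assert union["S5-N5"] == {"g1", "g2", "g3"}

    def test_thirteen_belts_cover_s55_to_n75(self):
        los = sorted(lo for lo, hi in BELT_BOUNDS.values())
        assert len(BELT_BOUNDS) == 13
        assert los[0] == -55 and max(hi for lo, hi in BELT_BOUNDS.values()) == 75


class TestAnnotate:
    def test_growth_form_thresholds_leave_a_gap(self):
        profiles = profile_frame([1.0, 2.0, 3.0, 4.0])
        woody = pd.Series([0.7, 0.3, 0.5, 0.61], index=profiles.index)
        out = annotate_profiles(profiles, woody_fraction=woody)
        assert out["growth_form"].tolist() == [
            "woody", "herbaceous", "unclassified", "woody"]

    def test_cam_c4_any_species_rule(self):
        profiles = profile_frame([1.0, 2.0])
        cam = pd.Series([True, False], index=profiles.index)
        out = annotate_profiles(profiles, cam_any_species=cam)
        assert out["cam"].tolist() == [True, False]
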