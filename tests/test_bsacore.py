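"""The association statistic: SNP-index, filters, windows, null envelopes, regions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkseg import bsacore
from bulkseg.bsacore import NullModel, WindowSpec

from conftest import (
    exact_null_delta_distribution,
    exact_quantile,
    make_track,
    quantile_identifiable,
)


class TestSnpIndex:
    @pytest.mark.parametrize(
        "donor,total,expected",
        [(7, 10, 0.7), (0, 10, 0.0), (10, 10, 1.0)],
    )
    def test_values(self, donor, total, expected):
        # 0 = same as the recurrent parent, 1 = fully donor
        assert bsacore.snp_index(donor, total) == pytest.approx(expected)

    def test_zero_total_is_missing_not_zero(self):
        assert math.isnan(bsacore.snp_index(0, 0))
        assert math.isnan(bsacore.snp_index(0, float("nan")))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            bsacore.snp_index(11, 10)

    @pytest.mark.parametrize(
        "i1,i2,expected", [(0.9, 0.2, 0.7), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0)]
    )
    def test_delta(self, i1, i2, expected):
        assert bsacore.delta_snp_index(i1, i2) == pytest.approx(expected)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_delta_bounds(self, i1, i2):
        d = bsacore.delta_snp_index(i1, i2)
        assert -1.0 <= d <= 1.0
        assert d == i1 - i2


FIVE_LOCUS_TOY = [
    ("A10", 100, 0.9, 0.1, 10, 10),  # pass
    ("A10", 200, 0.3, 0.2, 10, 10),  # index < 0.5 in both pools
    ("A10", 300, 0.9, 0.1, 4, 10),  # depth < 5 in one pool
    ("A10", 400, 0.8, np.nan, 12, np.nan),  # missing in HC2
    ("A10", 500, 0.6, 0.4, 6, 7),  # pass
]


class TestFilterSites:
    def test_five_locus_fixture(self):
        out = bsacore.filter_sites(make_track(FIVE_LOCUS_TOY))
        assert list(out["filter_status"]) == [
            "pass",
            "low_index_both",
            "low_depth",
            "missing_in_pool",
            "pass",
        ]
        assert len(bsacore.pass_sites(out)) == 2

    def test_empty_track(self):
        out = bsacore.filter_sites(make_track([]))
        assert out.empty

    def test_all_pass_when_one_index_high_and_depth_ok(self):
        rows = [("A10", i * 100, 0.8, 0.1, 9, 9) for i in range(1, 20)]
        out = bsacore.filter_sites(make_track(rows))
        assert (out["filter_status"] == "pass").all()

    def test_either_index_rule_is_stricter(self):
        track = make_track(FIVE_LOCUS_TOY)
        either = bsacore.filter_sites(track, index_rule="either")
        # site 5 (0.6, 0.4) now fails: HC2 index below 0.5
        assert list(either["filter_status"])[4] == "low_index_both"

    def test_filtering_never_raises_on_weird_data(self):
        rows = [("A10", 1, np.nan, np.nan, np.nan, np.nan), ("A10", 2, 1.0, 0.0, 0, 0)]
        out = bsacore.filter_sites(make_track(rows))
        assert len(out) == 2


class TestWindowScan:
    def test_window_mean_of_member_deltas(self):
        rows = [("A10", 100_000, 0.7, 0.5, 30, 30), ("A10", 200_000, 0.9, 0.5, 30, 30)]
        spec = WindowSpec(1_000_000, 1_000_000, min_sites_per_window=1)
        w = bsacore.window_scan(make_track(rows), spec, {"A10": 1_000_000})
        assert len(w) == 1
        assert w.loc[0, "mean_delta"] == pytest.approx(0.3)
        assert w.loc[0, "n_sites"] == 2

    def test_single_site_window_equals_the_site(self):
        rows = [("A10", 500_000, 0.85, 0.15, 28, 31)]
        spec = WindowSpec(1_000_000, 1_000_000, min_sites_per_window=1)
        w = bsacore.window_scan(make_track(rows), spec, {"A10": 1_000_000})
        assert w.loc[0, "mean_index_HC1"] == pytest.approx(0.85)
        assert w.loc[0, "mean_delta"] == pytest.approx(0.7)

    def test_underpopulated_window_flagged_missing(self):
        rows = [("A10", 500_000, 0.85, 0.15, 28, 31)]
        spec = WindowSpec(1_000_000, 1_000_000, min_sites_per_window=10)
        w = bsacore.window_scan(make_track(rows), spec, {"A10": 1_000_000})
        assert np.isnan(w.loc[0, "mean_delta"]) and w.loc[0, "n_sites"] == 1

    def test_window_tiling_and_mean_bounds(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 5_000_001), 400, replace=False))
        i1 = rng.uniform(0.5, 1.0, 400)
        i2 = rng.uniform(0.0, 0.5, 400)
        rows = [("A10", int(p), a, b, 30, 30) for p, a, b in zip(pos, i1, i2)]
        spec = WindowSpec(1_000_000, 100_000, 5)
        w = bsacore.window_scan(make_track(rows), spec, {"A10": 5_000_000})
        assert (w["start"].to_numpy()[1:] - w["start"].to_numpy()[:-1] == 100_000).all()
        deltas = np.array(i1) - np.array(i2)
        scored = w[w["mean_delta"].notna()]
        assert (scored["mean_delta"] >= deltas.min() - 1e-12).all()
        assert (scored["mean_delta"] <= deltas.max() + 1e-12).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(100, 200)
        with pytest.raises(ValueError):
            WindowSpec(0, 0)


class TestNullThresholds:
    def test_envelope_nesting_99_contains_95(self):
        null = NullModel(seed=5)
        lo95, hi95 = bsacore.null_thresholds(30, 30, null, 95)
        lo99, hi99 = bsacore.null_thresholds(30, 30, null, 99)
        assert lo99 <= lo95 <= hi95 <= hi99

    def test_tiny_confidence_collapses_to_median_near_zero(self):
        null = NullModel(seed=5)
        lo, hi = bsacore.null_thresholds(30, 30, null, 1e-6)
        assert abs(lo) < 0.1 and abs(hi) < 0.1 and lo <= hi

    def test_matches_enumeration_oracle_at_small_depth(self):
        # exhaustive enumeration of read-count outcomes over the exact
        # finite-bulk frequency distribution, vs the Monte-Carlo sampler
        null = NullModel(seed=11)
        for d1, d2 in [(5, 5), (6, 4), (6, 6)]:
            xs, cdf = exact_null_delta_distribution(d1, d2, null.n_high, null.n_low)
            for conf in (95.0, 99.0):
                alpha = 1 - conf / 100
                lo, hi = bsacore.null_thresholds(d1, d2, null, conf)
                for p, got in ((alpha / 2, lo), (1 - alpha / 2, hi)):
                    if quantile_identifiable(xs, cdf, p, null.n_reps):
                        assert got == pytest.approx(
                            exact_quantile(xs, cdf, p), abs=0.02
                        )

    def test_confidence_domain(self):
        null = NullModel(seed=1)
        for bad in (0, 100, -5, 101):
            with pytest.raises(ValueError):
                bsacore.null_thresholds(10, 10, null, bad)

    def test_attach_thresholds_per_depth_pair(self):
        rows = [("A10", 1 + i * 100_000, 0.8, 0.2, 30, 30) for i in range(30)]
        w = bsacore.window_scan(
            make_track(rows), WindowSpec(1_000_000, 1_000_000, 1), {"A10": 3_000_000}
        )
        out = bsacore.attach_null_thresholds(w, NullModel(seed=2))
        scored = out[out["mean_delta"].notna()]
        assert (scored["ci99_high"] >= scored["ci95_high"]).all()
        assert (scored["ci99_low"] <= scored["ci95_low"]).all()
        assert set(out.columns) >= {"ci95_low", "ci95_high", "ci99_low", "ci99_high", "significant_99"}

    def test_label_permutation_envelope_is_symmetric_under_null(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(0, 0.2, 500).clip(-1, 1)
        rows = [
            ("A10", 1 + i * 1000, 0.5 + d / 2, 0.5 - d / 2, 30, 30)
            for i, d in enumerate(delta)
        ]
        null = NullModel(seed=3, method="label_permutation", n_reps=20_000)
        lo, hi = bsacore.permutation_null_envelope(make_track(rows), null, 95)
        assert lo < 0 < hi
        assert abs(abs(lo) - abs(hi)) < 0.1


def windows_frame(entries):
    df = pd.DataFrame(
        entries,
        columns=["chrom", "start", "end", "mean_delta", "ci99_high"],
    )
    df["n_sites"] = 20
    df["ci99_low"] = -df["ci99_high"]
    return df


class TestCallRegions:
    SPEC = WindowSpec(1_000_000, 100_000, 10)

    def test_no_significant_windows_gives_empty_list(self):
        w = windows_frame([("A10", 1, 1_000_000, 0.1, 0.4)])
        assert bsacore.call_regions(w, self.SPEC) == []

    def test_three_overlapping_windows_merge_to_one_region(self):
        w = windows_frame(
            [
                ("A10", 1, 1_000_000, 0.6, 0.4),
                ("A10", 100_001, 1_100_000, 0.7, 0.4),
                ("A10", 200_001, 1_200_000, 0.6, 0.4),
            ]
        )
        regions = bsacore.call_regions(w, self.SPEC)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1, 1_200_000)
        assert r.window_indices == [0, 1, 2]
        assert r.peak_delta == pytest.approx(0.7)

    def test_distant_windows_stay_separate(self):
        w = windows_frame(
            [
                ("A10", 1, 1_000_000, 0.6, 0.4),
                ("A10", 5_000_001, 6_000_000, 0.6, 0.4),
            ]
        )
        regions = bsacore.call_regions(w, self.SPEC)
        assert len(regions) == 2

    def test_span_of_the_a10_candidate_interval(self):
        w = windows_frame([("A10", 20_600_000, 22_200_000, 0.6, 0.4)])
        (r,) = bsacore.call_regions(w, self.SPEC)
        assert r.span_bp == 1_600_000  # the 1.6 Mb interval, end - start

    def test_positive_tail_only_by_default(self):
        w = windows_frame([("A10", 1, 1_000_000, -0.9, 0.4)])
        assert bsacore.call_regions(w, self.SPEC) == []
        assert len(bsacore.call_regions(w, self.SPEC, tail="both")) == 1

    def test_member_sites_collected_from_track(self):
        w = windows_frame([("A10", 1, 1_000_000, 0.6, 0.4)])
        track = bsacore.filter_sites(
            make_track(
                [
                    ("A10", 500, 0.9, 0.1, 30, 30),
                    ("A10", 900_000, 0.8, 0.2, 30, 30),
                    ("A10", 2_000_000, 0.8, 0.2, 30, 30),
                ]
            )
        )
        (r,) = bsacore.call_regions(w, self.SPEC, track=track)
        assert list(r.member_sites) == [500, 900_000]
        assert r.n_sites == 2


class TestAntisymmetry:
    def test_parent_swap_negates_delta_and_swaps_tails(self):
        rows = [("A10", 1 + i * 100_000, 0.9, 0.2, 30, 30) for i in range(30)]
        track = make_track(rows)
        flipped = track.copy()
        flipped["index_HC1"] = 1 - track["index_HC1"]
        flipped["index_HC2"] = 1 - track["index_HC2"]
        flipped["delta"] = flipped["index_HC1"] - flipped["index_HC2"]
        spec = WindowSpec(1_000_000, 1_000_000, 1)
        null = NullModel(seed=7)
        w_a = bsacore.attach_null_thresholds(
            bsacore.window_scan(track, spec, {"A10": 3_000_000}), null
        )
        w_b = bsacore.attach_null_thresholds(
            bsacore.window_scan(flipped, spec, {"A10": 3_000_000}), null
        )
        np.testing.assert_allclose(w_b["mean_delta"], -w_a["mean_delta"])
        pos = bsacore.call_regions(w_a, spec, tail="positive")
        neg = bsacore.call_regions(w_b, spec, tail="negative")
        assert [(r.start, r.end) for r in pos] == [(r.start, r.end) for r in neg]
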