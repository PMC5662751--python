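"""Sfpq->Ago2 dependency statistics: merge, distance classes, Fisher tests,
shuffle Z-score test, recruitment correlation and geometry summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from conftest import (
    brute_jaccard,
    fisher_exact_enum,
    random_peakset,
    ranksum_exact_p,
)
from scipy import stats

from clipdep import synth
from clipdep.clip import (
    ShuffleTest,
    categorize_by_distance,
    category_enrichment_test,
    dependent_peak_merge,
    find_host_utrs,
    fraction_independent_close,
    peak_geometry_summary,
    recruitment_spatial_correlation,
    utr_length_comparison,
)
from clipdep.intervals import GenomicInterval, PeakSet, TranscriptAnnotation


def _utr_annotation(utrs):
    """Annotation with one 3'UTR per transcript: utrs = [(id, start, end)]."""
    return [
        TranscriptAnnotation(
            tid, "chr1", "+", {"UTR3": [GenomicInterval("chr1", s, e, "+")]}
        )
        for tid, s, e in utrs
    ]


class TestDependentPeakMerge:
    def test_identical_filters_return_everything(self):
        rng = np.random.default_rng(2)
        a = random_peakset(rng, 30, "a")
        assert len(dependent_peak_merge(a, a, a)) == len(a)

    def test_empty_filters_return_empty(self):
        rng = np.random.default_rng(2)
        a = random_peakset(rng, 10, "a")
        empty = PeakSet([], label="e")
        assert len(dependent_peak_merge(a, empty, empty)) == 0

    def test_and_or_semantics_match_brute_force(self):
        rng = np.random.default_rng(19)
        a = random_peakset(rng, 100, "a")
        f1 = random_peakset(rng, 60, "f1")
        f2 = random_peakset(rng, 60, "f2")

        def support(iv, fs):
            return any(brute_jaccard(iv, f) >= 0.10 for f in fs)

        want_and = {iv.name for iv in a if support(iv, f1) and support(iv, f2)}
        want_or = {iv.name for iv in a if support(iv, f1) or support(iv, f2)}
        got_and = {iv.name for iv in dependent_peak_merge(a, f1, f2)}
        got_or = {iv.name for iv in dependent_peak_merge(a, f1, f2, mode="or")}
        assert got_and == want_and
        assert got_or == want_or


class TestCategorizeByDistance:
    def test_boundary_distances(self, toy_annotation):
        sfpq = PeakSet([GenomicInterval("chr1", 3000, 3100, "+", name="s")])
        queries = PeakSet(
            [
                GenomicInterval("chr1", 2501, 2551, "+", name="d499"),
                GenomicInterval("chr1", 2450, 2500, "+", name="d500"),
                GenomicInterval("chr1", 10100, 10150, "+", name="d7000"),
            ]
        )
        calls = {
            c.ago2_peak.name: c
            for c in categorize_by_distance(queries, sfpq, toy_annotation)
        }
        assert calls["d499"].distance == 449  # 3000 - 2551
        assert calls["d499"].distance_category.value == "close"
        assert calls["d500"].distance == 500
        assert calls["d500"].distance_category.value == "far"
        assert calls["d7000"].distance == 7000
        assert calls["d7000"].distance_category.value == "very_far"

    def test_empty_reference_all_very_far(self, toy_annotation):
        rng = np.random.default_rng(3)
        q = random_peakset(rng, 20, "q", chroms=("chr1",))
        calls = categorize_by_distance(q, PeakSet([], "sfpq"), toy_annotation)
        assert all(c.distance_category.value == "very_far" for c in calls)
        assert all(math.isinf(c.distance) for c in calls)

    def test_partition(self, toy_annotation):
        rng = np.random.default_rng(5)
        q = random_peakset(rng, 50, "q", chroms=("chr1",))
        s = random_peakset(rng, 20, "s", chroms=("chr1",))
        calls = categorize_by_distance(q, s, toy_annotation)
        assert len(calls) == len(q)
        assert all(
            c.distance_category.value in {"close", "far", "very_far"}
            for c in calls
        )


class TestFisherEnrichment:
    def test_scipy_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            table = [[a, b], [c, d]]
            p_scipy = stats.fisher_exact(table, alternative="two-sided").pvalue
            assert p_scipy == pytest.approx(fisher_exact_enum(table), abs=1e-9)

    def test_forced_table_value(self):
        assert fisher_exact_enum([[10, 0], [0, 10]]) == pytest.approx(
            1.082e-5, rel=1e-3
        )
        p = stats.fisher_exact([[10, 0], [0, 10]]).pvalue
        assert p == pytest.approx(1.082e-5, rel=1e-3)

    def test_identical_proportions_give_p_one_and_row_swap_symmetry(self):
        from clipdep.intervals import categorize_distance
        from clipdep.clip import DependencyCall

        def call(i, dist, cat):
            return DependencyCall(
                GenomicInterval("chr1", 1000 + i * 100, 1050 + i * 100,
                                "+", name=f"p{i}"),
                "s", dist, categorize_distance(dist), cat,
            )

        calls = [
            call(0, 100, "UTR3"), call(1, 100, "CDS"),       # close: 1/2 in
            call(2, 1000, "UTR3"), call(3, 1000, "CDS"),     # far:   1/2 in
            call(4, 9000, "UTR3"), call(5, 9000, "intron"),  # vfar:  1/2 in
        ]
        res = category_enrichment_test(calls)
        assert res["p_close_vs_far"] == pytest.approx(1.0)
        assert res["p_close_vs_very_far"] == pytest.approx(1.0)
        # two-sided Fisher p is invariant to swapping the two rows
        t = [[7, 3], [2, 8]]
        assert stats.fisher_exact(t).pvalue == pytest.approx(
            stats.fisher_exact(t[::-1]).pvalue
        )

    def test_empty_class_is_an_error(self, toy_annotation):
        sfpq = PeakSet([GenomicInterval("chr1", 3000, 3100, "+", name="s")])
        only_close = PeakSet(
            [GenomicInterval("chr1", 2900, 2950, "+", name="c")]
        )
        calls = categorize_by_distance(only_close, sfpq, toy_annotation)
        with pytest.raises(ValueError, match="far"):
            category_enrichment_test(calls)


class TestFractionIndependentClose:
    def test_extremes_and_recount(self, toy_annotation):
        sfpq = PeakSet([GenomicInterval("chr1", 3000, 3100, "+", name="s")])
        rng = np.random.default_rng(7)
        q = random_peakset(rng, 60, "q", chroms=("chr1",), span=11_000)
        calls = categorize_by_distance(q, sfpq, toy_annotation)
        pct = fraction_independent_close(calls)
        manual = 100 * sum(
            1
            for c in calls
            if c.genomic_category == "UTR3"
            and c.distance_category.value == "close"
        ) / len(calls)
        assert pct == pytest.approx(manual)
        all_close = [c for c in calls
                     if c.genomic_category == "UTR3"
                     and c.distance_category.value == "close"]
        if all_close:
            assert fraction_independent_close(all_close) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            fraction_independent_close([])


class TestShuffleTest:
    def _setup(self, seed=0, n_utrs=30, utr_len=3000, n_sfpq_per_utr=5):
        """UTRs with Sfpq peaks and Ago2 peaks planted 0-200 nt away."""
        rng = np.random.default_rng(seed)
        utrs, sfpq, ago2 = [], [], []
        for i in range(n_utrs):
            u0 = 10_000 + i * 50_000
            utrs.append((f"tx{i}", u0, u0 + utr_len))
            anchors = []
            for j in range(n_sfpq_per_utr):
                s = int(rng.integers(u0, u0 + utr_len - 60))
                anchors.append((s, s + 60))
                sfpq.append(
                    GenomicInterval("chr1", s, s + 60, "+", name=f"s{i}_{j}")
                )
            s, e = anchors[int(rng.integers(0, len(anchors)))]
            gap = int(rng.integers(0, 200))
            start = min(e + gap, u0 + utr_len - 50)
            ago2.append(
                GenomicInterval("chr1", start, start + 50, "+", name=f"a{i}")
            )
        return (
            PeakSet(ago2, "reduced"),
            PeakSet(sfpq, "sfpq"),
            _utr_annotation(utrs),
        )

    def test_planted_signal_recovered(self):
        zs = []
        for seed in range(6):
            reduced, sfpq, ann = self._setup(seed=seed)
            res = ShuffleTest(
                reduced, sfpq, ann, n_shuffles=300, seed=seed
            ).fit()
            zs.append([b.z for b in res.bins])
        z = np.median(np.array(zs), axis=0)
        assert z[0] >= 1.96  # bin [0, 250)
        assert abs(z[2]) < 1.96 and abs(z[3]) < 1.96  # bins beyond 500

    def test_no_signal_stays_null(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            utrs, sfpq, ago2 = [], [], []
            for i in range(25):
                u0 = 10_000 + i * 50_000
                utrs.append((f"tx{i}", u0, u0 + 3000))
                s = int(rng.integers(u0, u0 + 2940))
                sfpq.append(
                    GenomicInterval("chr1", s, s + 60, "+", name=f"s{i}")
                )
                a = int(rng.integers(u0, u0 + 2950))
                ago2.append(
                    GenomicInterval("chr1", a, a + 50, "+", name=f"a{i}")
                )
            res = ShuffleTest(
                PeakSet(ago2, "r"), PeakSet(sfpq, "s"), _utr_annotation(utrs),
                n_shuffles=300, seed=seed,
            ).fit()
            if any(abs(b.z) >= 3 for b in res.bins if not math.isnan(b.z)):
                flagged += 1
        assert flagged <= 2  # >= 80% of runs fully inside |Z| < 3

    def test_deterministic_and_order_invariant(self):
        reduced, sfpq, ann = self._setup(seed=3)
        r1 = ShuffleTest(reduced, sfpq, ann, n_shuffles=100, seed=9).fit()
        r2 = ShuffleTest(reduced, sfpq, ann, n_shuffles=100, seed=9).fit()
        assert r1.to_dataframe().equals(r2.to_dataframe())
        shuffled_input = PeakSet(list(reduced)[::-1], "reduced")
        r3 = ShuffleTest(shuffled_input, sfpq, ann, n_shuffles=100, seed=9).fit()
        assert r1.to_dataframe().equals(r3.to_dataframe())

    def test_zero_shuffles_rejected(self):
        reduced, sfpq, ann = self._setup()
        with pytest.raises(ValueError, match="n_shuffles"):
            ShuffleTest(reduced, sfpq, ann, n_shuffles=0)

    def test_peak_exceeding_host_utr_reported(self):
        ann = _utr_annotation([("tx0", 1000, 1100)])
        big = PeakSet([GenomicInterval("chr1", 990, 1190, "+", name="big")])
        sfpq = PeakSet([GenomicInterval("chr1", 1000, 1040, "+", name="s")])
        with pytest.raises(ValueError, match="big"):
            ShuffleTest(big, sfpq, ann, n_shuffles=10).fit()

    def test_unhosted_peak_reported(self):
        ann = _utr_annotation([("tx0", 1000, 2000)])
        lost = PeakSet([GenomicInterval("chr1", 5000, 5050, "+", name="lost")])
        sfpq = PeakSet([GenomicInterval("chr1", 1000, 1040, "+", name="s")])
        with pytest.raises(ValueError, match="lost"):
            find_host_utrs(lost, ann)

    def test_null_counts_bounded_by_peak_number(self):
        reduced, sfpq, ann = self._setup(seed=1, n_utrs=10)
        res = ShuffleTest(reduced, sfpq, ann, n_shuffles=50, seed=1).fit()
        df = res.to_dataframe()
        assert (df["null_mean"].sum()) <= len(reduced) + 1e-9
        assert (df["observed"].sum()) <= len(reduced)


class TestRecruitment:
    def test_identical_sets_concentrate_in_first_bin(self):
        utrs = [(f"tx{i}", 10_000 + 50_000 * i, 14_000 + 50_000 * i)
                for i in range(10)]
        ann = _utr_annotation(utrs)
        ivs = [
            GenomicInterval("chr1", u0 + 1000, u0 + 1050, "+", name=f"p{i}")
            for i, (_t, u0, _u1) in enumerate(utrs)
        ]
        peaks = PeakSet(ivs, "r")
        recruited = PeakSet(
            [GenomicInterval(iv.chrom, iv.start, iv.end, "+", name=f"q{i}")
             for i, iv in enumerate(ivs)],
            "n",
        )
        df = recruitment_spatial_correlation(
            peaks, recruited, ann, n_perm=200, seed=0
        )
        assert df["pct_recruited"].sum() == pytest.approx(100.0, abs=1e-9)
        first = df.iloc[0]
        assert first["pct_recruited"] == pytest.approx(100.0)
        assert first["flag"] == "above"

    def test_uniform_recruitment_rarely_flagged(self):
        flagged_runs = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            utrs, reduced, recruited = [], [], []
            for i in range(20):
                u0 = 10_000 + i * 50_000
                utrs.append((f"tx{i}", u0, u0 + 4000))
                s = int(rng.integers(u0, u0 + 3950))
                reduced.append(
                    GenomicInterval("chr1", s, s + 50, "+", name=f"r{i}")
                )
                a = int(rng.integers(u0, u0 + 3950))
                recruited.append(
                    GenomicInterval("chr1", a, a + 50, "+", name=f"n{i}")
                )
            df = recruitment_spatial_correlation(
                PeakSet(reduced, "r"), PeakSet(recruited, "n"),
                _utr_annotation(utrs), n_perm=300, seed=seed,
            )
            # only bins with observable mass matter
            if (df["flag"] != "within").any():
                flagged_runs += 1
        assert flagged_runs <= 5

    def test_disjoint_utrs_rejected(self):
        ann = _utr_annotation([("tx0", 10_000, 12_000), ("tx1", 50_000, 52_000)])
        reduced = PeakSet(
            [GenomicInterval("chr1", 10_500, 10_550, "+", name="r")], "r"
        )
        recruited = PeakSet(
            [GenomicInterval("chr1", 50_500, 50_550, "+", name="n")], "n"
        )
        with pytest.raises(ValueError, match="shared"):
            recruitment_spatial_correlation(reduced, recruited, ann)


class TestGeometryAndUtrLengths:
    def test_single_peak_category_has_missing_neighbor_stats(self, toy_annotation):
        peaks = PeakSet([GenomicInterval("chr1", 2600, 2700, "+", name="p")])
        df = peak_geometry_summary(peaks, toy_annotation).set_index("category")
        assert df.loc["UTR3", "length_median"] == 100
        assert math.isnan(df.loc["UTR3", "neighbor_median"])

    def test_abutting_peaks_have_zero_neighbor_distance(self, toy_annotation):
        peaks = PeakSet(
            [
                GenomicInterval("chr1", 2600, 2700, "+", name="p1"),
                GenomicInterval("chr1", 2700, 2800, "+", name="p2"),
            ]
        )
        df = peak_geometry_summary(peaks, toy_annotation).set_index("category")
        assert df.loc["UTR3", "neighbor_median"] == 0

    def test_medians_match_direct_recomputation(self, toy_annotation):
        rng = np.random.default_rng(11)
        peaks = random_peakset(rng, 40, "p", chroms=("chr1",), span=11_000)
        df = peak_geometry_summary(peaks, toy_annotation)
        from clipdep.intervals import assign_genomic_category

        for _, row in df.iterrows():
            lengths = [
                iv.length
                for iv in peaks
                if assign_genomic_category(iv, toy_annotation) == row["category"]
            ]
            assert row["length_median"] == pytest.approx(np.median(lengths))
            assert row["n"] == len(lengths)

    def test_utr_length_comparison(self):
        rng = np.random.default_rng(13)
        base = rng.lognormal(7.5, 0.5, 200)
        res = utr_length_comparison(base, base + 10_000, base + 20_000)
        assert res["p_occupied_vs_all"] < 1e-10
        assert res["p_dependency_vs_occupied"] < 1e-10
        same = utr_length_comparison(base, base, base)
        assert 0.4 < same["p_occupied_vs_all"] < 0.6
        with pytest.raises(ValueError, match="too small"):
            utr_length_comparison(base, [1.0], base)

    def test_ranksum_matches_exact_enumeration_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            p_scipy = stats.mannwhitneyu(
                x, y, alternative="greater", method="exact"
            ).pvalue
            assert p_scipy == pytest.approx(
                ranksum_exact_p(x, y, "greater"), abs=1e-9
            )


class TestPlantedPipelineRecovery:
    def test_direct_set_recovered_with_low_false_positives(self):
        from clipdep.intervals import filter_by_score

        recoveries, fprs = [], []
        for seed in range(1, 6):
            cfg = synth.SynthConfig(seed=seed)
            txome = synth.make_transcriptome(cfg)
            peaks = synth.make_peaks(cfg, txome)
            ago2 = filter_by_score(peaks.ago2_all, 7.0)
            merged = dependent_peak_merge(
                ago2, peaks.ago2_filter1, peaks.ago2_filter2
            )
            calls = categorize_by_distance(
                ago2, peaks.sfpq, txome.annotation,
                reduced_names={iv.name for iv in merged},
            )
            direct = {
                c.ago2_peak.name
                for c in calls
                if c.reduced_on_knockdown
                and c.distance_category.value == "close"
            }
            truth = set(
                peaks.truth.loc[peaks.truth["planted"] == "direct", "name"]
            )
            recoveries.append(len(direct & truth) / len(truth))
            fprs.append(len(direct - truth) / max(len(direct), 1))
        assert np.median(recoveries) >= 0.9
        assert np.median(fprs) <= 0.1
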