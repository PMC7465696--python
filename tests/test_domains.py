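"""Domain/complex calling: segmentation, intersection, classes, census."""

import math

import numpy as np
import pytest

from hetchrom import (
    CallerParams,
    DomainCall,
    GenomeDef,
    IntervalSet,
    call_domains,
    enriched_intervals,
    summarize,
)
from hetchrom.domains import size_class
from hetchrom.synthetic import make_bundle

from conftest import make_track

GENOME = GenomeDef((("chrT", 1_000_000),))
W = 5000


def track_with_runs(runs, fill=1.0, mark="m", genome=GENOME, value=8.0):
    """Track at `fill` with bp intervals set to `value` (bin-aligned)."""
    n = genome.n_bins("chrT", W)
    v = np.full(n, fill)
    for s, e in runs:
        v[s // W : e // W] = value
    return make_track(genome, W, mark, chrT=v)


class TestEnrichedIntervals:
    def test_constant_below_threshold_empty(self):
        t = make_track(GENOME, W, fill=1.0)
        assert len(enriched_intervals(t, 2.0)) == 0

    def test_single_planted_run_recovered(self):
        t = track_with_runs([(100_000, 150_000)])
        out = enriched_intervals(t, 2.0)
        assert [(s, e) for _, s, e, _ in out] == [(100_000, 150_000)]

    def test_merge_gap_boundary(self):
        # two runs separated by exactly merge_gap merge; one bin more splits
        gap = 2 * W
        t1 = track_with_runs([(0, 50_000), (50_000 + gap, 100_000)])
        out1 = enriched_intervals(t1, 2.0, merge_gap=gap)
        assert len(out1) == 1
        t2 = track_with_runs([(0, 50_000), (50_000 + gap + W, 100_000)])
        out2 = enriched_intervals(t2, 2.0, merge_gap=gap)
        assert len(out2) == 2

    def test_default_merge_gap_is_one_bin(self):
        t = track_with_runs([(0, 50_000), (55_000, 100_000)])
        assert len(enriched_intervals(t, 2.0)) == 1

    def test_min_size_filter(self):
        t = track_with_runs([(0, W), (100_000, 200_000)])
        out = enriched_intervals(t, 2.0, min_size=50_000)
        assert [(s, e) for _, s, e, _ in out] == [(100_000, 200_000)]

    def test_raising_tau_never_adds_bp(self):
        rng = np.random.default_rng(0)
        t = make_track(GENOME, W, chrT=rng.lognormal(0.5, 1.0, 200))
        total = [
            enriched_intervals(t, tau, merge_gap=0).total_bp()
            for tau in (1.0, 2.0, 4.0, 8.0)
        ]
        assert total == sorted(total, reverse=True)

    def test_raising_merge_gap_never_adds_calls(self):
        rng = np.random.default_rng(1)
        t = make_track(GENOME, W, chrT=rng.lognormal(0.5, 1.0, 200))
        n = [
            len(enriched_intervals(t, 2.0, merge_gap=g))
            for g in (0, W, 3 * W, 10 * W)
        ]
        assert n == sorted(n, reverse=True)


class TestSizeClass:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (100_000, "domain"),
            (99_999, "complex"),
            (10_000, "complex"),
            (9_999, None),
            (1_000_000, "large_domain"),
            (999_999, "domain"),
        ],
    )
    def test_half_open_boundaries(self, length, expected):
        assert size_class(length) == expected


class TestCallDomains:
    def test_planted_recovery_one_per_class(self):
        b = make_bundle(
            noise_cv=0.0, coloc=1.0, seed=13,
            counts={"large_domain": 1, "domain": 1, "complex": 1},
        )
        hp1 = [b.tracks["HP1a"], b.tracks["HP1g"]]
        calls = call_domains(hp1, b.tracks["H3K9me3"], CallerParams(),
                             b.het_mask, "exclude_mask")
        got = sorted((c.chrom, c.start, c.end, c.size_class) for c in calls)
        want = sorted((c, s, e, lab) for c, s, e, lab in b.truth)
        assert got == want

    def test_hp1_only_interval_not_called(self):
        hp1 = track_with_runs([(100_000, 200_000)], mark="HP1a")
        k9 = make_track(GENOME, W, "H3K9me3", fill=1.0)
        k9.values["chrT"][0] = 8.0  # some K9 signal elsewhere
        assert call_domains([hp1], k9, CallerParams()) == []

    def test_intersection_semantics(self):
        hp1 = track_with_runs([(100_000, 300_000)], mark="HP1a")
        k9 = track_with_runs([(200_000, 400_000)], mark="H3K9me3")
        calls = call_domains([hp1], k9, CallerParams())
        assert [(c.start, c.end) for c in calls] == [(200_000, 300_000)]
        assert calls[0].size_class == "domain"

    def test_exactly_100kb_is_domain(self):
        hp1 = track_with_runs([(0, 100_000)], mark="HP1a")
        k9 = track_with_runs([(0, 100_000)], mark="H3K9me3")
        (call,) = call_domains([hp1], k9, CallerParams())
        assert call.size_class == "domain" and call.length == 100_000

    def test_union_vs_intersection_of_isoforms(self):
        a = track_with_runs([(100_000, 200_000)], mark="HP1a")
        g = track_with_runs([(400_000, 500_000)], mark="HP1g")
        k9 = track_with_runs([(0, 1_000_000)], mark="H3K9me3")
        union_calls = call_domains([a, g], k9, CallerParams())
        assert len(union_calls) == 2
        inter = CallerParams(hp1_combine="intersection")
        assert call_domains([a, g], k9, inter) == []

    def test_marks_present_and_means(self):
        a = track_with_runs([(100_000, 200_000)], mark="HP1a")
        g = make_track(GENOME, W, "HP1g", fill=1.0)
        k9 = track_with_runs([(100_000, 200_000)], mark="H3K9me3")
        (call,) = call_domains([a, g], k9, CallerParams())
        assert call.marks_present == ("HP1a", "H3K9me3")
        assert call.mean_enrichment["HP1a"] == 8.0
        assert call.mean_enrichment["HP1g"] == 1.0

    def test_mask_overlap_policies(self):
        hp1 = track_with_runs([(100_000, 200_000)], mark="HP1a")
        k9 = track_with_runs([(100_000, 200_000)], mark="H3K9me3")
        mask_60 = IntervalSet.from_records([("chrT", 100_000, 160_000)])
        mask_40 = IntervalSet.from_records([("chrT", 100_000, 140_000)])
        p = CallerParams()  # half policy
        assert call_domains([hp1], k9, p, mask_60, "exclude_mask") == []
        assert len(call_domains([hp1], k9, p, mask_40, "exclude_mask")) == 1
        p_any = CallerParams(mask_policy="any")
        assert call_domains([hp1], k9, p_any, mask_40, "exclude_mask") == []

    def test_no_hp1_rejected(self):
        k9 = make_track(GENOME, W, "H3K9me3", fill=1.0)
        with pytest.raises(ValueError, match="at least one HP1"):
            call_domains([], k9)

    def test_exclude_counts_never_exceed_whole(self):
        for seed in range(3):
            b = make_bundle(noise_cv=0.4, coloc=0.7, seed=seed)
            hp1 = [b.tracks["HP1a"], b.tracks["HP1b"]]
            whole = call_domains(hp1, b.tracks["H3K9me3"], CallerParams(),
                                 b.het_mask, "whole_genome")
            excl = call_domains(hp1, b.tracks["H3K9me3"], CallerParams(),
                                b.het_mask, "exclude_mask")
            s = summarize({"whole_genome": whole, "exclude_mask": excl})
            assert (
                s.counts["exclude_mask"] <= s.counts["whole_genome"]
            ).all()


def _call(length, cls, start=0):
    return DomainCall("chrT", start, start + length, cls, ("HP1a",), {})


class TestSummarize:
    def test_counts_per_class_per_mode(self):
        calls = [
            _call(50_000, "complex"),
            _call(500_000, "domain", 10**6),
            _call(2_000_000, "large_domain", 4 * 10**6),
        ]
        s = summarize({"whole_genome": calls, "exclude_mask": calls})
        assert (s.counts.loc[:, "whole_genome"] == 1).all()
        assert (s.counts["exclude_mask"] <= s.counts["whole_genome"]).all()

    def test_fraction_10_30kb(self):
        calls = [
            _call(12_000, "complex"),
            _call(25_000, "complex", 10**6),
            _call(80_000, "complex", 2 * 10**6),
        ]
        s = summarize({"exclude_mask": calls})
        assert s.fraction_10_30kb == pytest.approx(2 / 3)
        assert s.fraction_defined

    def test_empty_fraction_flagged_undefined(self):
        s = summarize({"whole_genome": []})
        assert (s.counts == 0).all().all()
        assert math.isnan(s.fraction_10_30kb) and not s.fraction_defined
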