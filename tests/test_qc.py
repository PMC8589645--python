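"""Call-level QC: filters, merging to fixpoint, artefact flagging."""

import pytest
from hypothesis import given, strategies as st

from cnvburden.intervals import CnvCall, GenomicInterval, RegionSet
from cnvburden.qc import (
    QcConfig,
    apply_exclusion_list,
    filter_calls,
    flag_artifacts,
    merge_adjacent,
    run_qc,
)

iv = GenomicInterval
CFG = QcConfig()


def call(start, end, cn=1, probes=12, sample="s1", chrom="chr1"):
    return CnvCall(sample, iv(chrom, start, end), cn, probes)


class TestFilter:
    @pytest.mark.parametrize(
        "length, probes, kept",
        [
            (150_000, 12, True),
            (150_000, 9, False),
            (100_000, 10, True),    # thresholds inclusive
            (99_999, 10, False),
        ],
    )
    def test_thresholds(self, length, probes, kept):
        c = call(0, length, probes=probes)
        out, report = filter_calls([c], CFG)
        assert (len(out) == 1) is kept
        assert report.stages["filter"]["in"] == 1

    def test_empty_input(self):
        out, _ = filter_calls([], CFG)
        assert out == []


class TestMerge:
    def test_small_gap_merges(self):
        a, b = call(100_000, 250_000), call(260_000, 300_000)
        merged, _ = merge_adjacent([a, b], CFG)  # gap 10k / span 200k = 0.05
        (m,) = merged
        assert (m.interval.start, m.interval.end) == (100_000, 300_000)
        assert m.n_probes == a.n_probes + b.n_probes

    def test_large_gap_does_not_merge(self):
        a, b = call(0, 100_000), call(200_000, 250_000)  # 100k / 250k = 0.4
        merged, _ = merge_adjacent([a, b], CFG)
        assert len(merged) == 2

    def test_different_states_never_merge(self):
        a, b = call(100_000, 250_000, cn=1), call(260_000, 300_000, cn=3)
        merged, _ = merge_adjacent([a, b], CFG)
        assert len(merged) == 2

    def test_different_samples_never_merge(self):
        a = call(100_000, 250_000, sample="s1")
        b = call(260_000, 300_000, sample="s2")
        merged, _ = merge_adjacent([a, b], CFG)
        assert len(merged) == 2

    def test_overlapping_same_state_merge_with_warning(self):
        a, b = call(0, 150_000), call(100_000, 250_000)
        merged, report = merge_adjacent([a, b], CFG)
        assert len(merged) == 1
        assert any("overlapping" in w for w in report.warnings)

    def test_cascade_to_fixpoint(self):
        # each adjacent pair merges; the chain collapses to one span
        calls = [call(i * 110_000, i * 110_000 + 100_000) for i in range(4)]
        merged, _ = merge_adjacent(calls, CFG)
        assert len(merged) == 1
        assert merged[0].interval == iv("chr1", 0, 430_000)

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20),
                      st.sampled_from([1, 3])),
            min_size=1, max_size=8,
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_and_order_independent(self, spec, rnd):
        calls = [call(s * 100_000, (s + l) * 100_000, cn=cn)
                 for s, l, cn in spec]
        once, _ = merge_adjacent(calls, CFG)
        twice, _ = merge_adjacent(once, CFG)
        assert once == twice
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        reordered, _ = merge_adjacent(shuffled, CFG)
        assert reordered == once

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20)),
            min_size=1, max_size=8,
        )
    )
    def test_merging_never_loses_covered_bases(self, spec):
        calls = [call(s * 100_000, (s + l) * 100_000) for s, l in spec]
        merged, _ = merge_adjacent(calls, CFG)

        def union_len(cs):
            segs = sorted((c.interval.start, c.interval.end) for c in cs)
            total, cur_e = 0, -1
            cur_s = None
            for s, e in segs:
                if s > cur_e:
                    if cur_s is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            return total + (cur_e - cur_s if cur_s is not None else 0)

        assert union_len(merged) >= union_len(calls)


class TestArtifacts:
    hla = RegionSet("hla_ig", [(iv("chr6", 1_000_000, 2_000_000), {})])
    telo = RegionSet("telo_cent", [(iv("chr1", 0, 10_000), {})])

    def test_majority_hla_overlap_flagged(self):
        c = call(900_000, 1_900_000, chrom="chr6")  # 90% covered
        clean, flagged, _ = flag_artifacts([c], self.hla, self.telo, CFG)
        assert flagged and not clean

    def test_near_telomere_flagged(self):
        c = call(410_000, 600_000)  # 400 kb from the telomere region edge
        clean, flagged, _ = flag_artifacts([c], self.hla, self.telo, CFG)
        assert flagged and not clean

    def test_below_both_rules_clean(self):
        # 49% covered by HLA and 600 kb from the telomere
        c = call(1_510_000, 2_510_000, chrom="chr6")
        clean, flagged, _ = flag_artifacts(
            [c], self.hla,
            RegionSet("telo", [(iv("chr6", 3_110_000, 3_200_000), {})]), CFG)
        assert clean and not flagged

    def test_partition(self):
        calls = [call(i * 3_000_000, i * 3_000_000 + 200_000)
                 for i in range(1, 4)]
        clean, flagged, _ = flag_artifacts(calls, self.hla, self.telo, CFG)
        assert sorted(clean + flagged, key=lambda c: c.interval.start) == calls


class TestExclusionList:
    def test_empty_list_is_identity(self):
        calls = [call(0, 200_000)]
        out, _ = apply_exclusion_list(calls, [])
        assert out == calls

    def test_matching_key_removed(self):
        calls = [call(0, 200_000), call(500_000, 700_000)]
        out, _ = apply_exclusion_list(calls, [("s1", "chr1", 0, 200_000)])
        assert out == calls[1:]

    def test_unmatched_key_warns(self):
        calls = [call(0, 200_000)]
        out, report = apply_exclusion_list(calls, [("sX", "chr9", 1, 2)])
        assert out == calls
        assert report.warnings


def test_full_qc_leaves_only_calls_satisfying_every_predicate(null_bundle):
    cfg = QcConfig()
    kept, report = run_qc(
        null_bundle.calls, cfg,
        hla_ig=null_bundle.regions["hla_ig"],
        telo_cent=null_bundle.regions["telo_cent"],
    )
    from cnvburden.intervals import covered_fraction, min_distance_to_set
    for c in kept:
        assert c.n_probes >= cfg.min_probes
        assert c.length >= cfg.min_length
        assert covered_fraction(c.interval, null_bundle.regions["hla_ig"]) \
            < cfg.artefact_overlap_fraction
        assert min_distance_to_set(c.interval,
                                   null_bundle.regions["telo_cent"]) \
            > cfg.proximity_bp
    for stage, counts in report.stages.items():
        assert counts["in"] == counts["kept"] + counts["removed"]
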