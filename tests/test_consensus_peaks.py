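import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chromtriad.consensus_peaks import (
    CountMatrix,
    FragmentSet,
    aggregate_replicates,
    classify_differential,
    count_fragments_in_peaks,
    fragment_size_qc,
    normalize,
    peak_id,
    union_peak_lists,
)
from chromtriad.genomic_core import GenomicInterval, Peak
from oracles import aggregate_bruteforce, union_bruteforce


def pk(start, end, chrom="chr1", **kw):
    return Peak(interval=GenomicInterval(chrom, start, end), **kw)


def random_replicate_peaks(rng, n_reps=2, max_peaks=8, span=500, max_len=80):
    reps = {}
    for r in range(n_reps):
        peaks = []
        for _ in range(rng.integers(1, max_peaks + 1)):
            s = int(rng.integers(0, span))
            l = int(rng.integers(1, max_len))
            peaks.append(pk(s, s + l))
        reps[f"rep{r + 1}"] = peaks
    return reps


class TestAggregateReplicates:
    def test_half_overlap_meets_threshold(self):
        result = aggregate_replicates(
            {"r1": [pk(100, 200)], "r2": [pk(150, 250)]}, min_overlap=0.5
        )
        (p,) = result.peaks
        assert (p.start, p.end, p.support) == (100, 250, 2)

    def test_below_threshold_discards_both(self):
        result = aggregate_replicates(
            {"r1": [pk(100, 200)], "r2": [pk(195, 300)]}, min_overlap=0.5
        )
        assert result.peaks == []

    def test_single_replicate_cluster_discarded(self):
        result = aggregate_replicates(
            {"r1": [pk(0, 100), pk(500, 600)], "r2": [pk(50, 150)]},
            min_overlap=0.5,
        )
        (p,) = result.peaks
        assert (p.start, p.end) == (0, 150)

    def test_fewer_than_two_replicates_is_error(self):
        with pytest.raises(ValueError, match="consensus undefined"):
            aggregate_replicates({"r1": [pk(0, 10)]})

    def test_invariant_to_replicate_label_order(self):
        rng = np.random.default_rng(5)
        reps = random_replicate_peaks(rng, n_reps=3)
        fwd = aggregate_replicates(reps, 0.5)
        rev = aggregate_replicates(dict(reversed(list(reps.items()))), 0.5)
        assert [(p.start, p.end, p.support) for p in fwd.peaks] == [
            (p.start, p.end, p.support) for p in rev.peaks
        ]

    def test_consensus_peaks_never_overlap_and_carry_support(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            reps = random_replicate_peaks(rng, n_reps=3)
            res = aggregate_replicates(reps, 0.5)
            for a, b in zip(res.peaks, res.peaks[1:]):
                assert a.end <= b.start or a.chrom != b.chrom
            assert all(p.support >= 2 for p in res.peaks)

    def test_matches_bruteforce_clustering_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            reps = random_replicate_peaks(rng)
            got = aggregate_replicates(reps, 0.5)
            expected = aggregate_bruteforce(reps, 0.5)
            assert [
                (p.chrom, p.start, p.end, frozenset(p.replicate_id.split(",")))
                for p in got.peaks
            ] == expected


class TestUnionPeakLists:
    def _consensus(self, sample, spans):
        peaks = [pk(s, e, sample_id=sample, support=2) for s, e in spans]
        from chromtriad.consensus_peaks import ConsensusPeakSet

        return ConsensusPeakSet(sample_id=sample, peaks=peaks, provenance=[])

    def test_overlapping_sets_merge_to_hull(self):
        master = union_peak_lists(
            [self._consensus("WT", [(100, 200)]), self._consensus("KO", [(150, 250)])]
        )
        (p,) = master
        assert (p.start, p.end, p.support) == (100, 250, 2)
        assert set(p.sample_id.split(",")) == {"WT", "KO"}

    def test_union_with_empty_set(self):
        master = union_peak_lists(
            [self._consensus("WT", [(100, 200)]), self._consensus("KO", [])]
        )
        assert [(p.start, p.end) for p in master] == [(100, 200)]

    def test_chained_overlaps_match_per_base_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            sets = []
            for s in range(3):
                spans = []
                for _ in range(rng.integers(0, 6)):
                    a = int(rng.integers(0, 400))
                    spans.append((a, a + int(rng.integers(1, 100))))
                # consensus sets must be internally non-overlapping
                merged = []
                for a, b in sorted(spans):
                    if merged and a < merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                    else:
                        merged.append((a, b))
                sets.append(self._consensus(f"s{s}", merged))
            got = union_peak_lists(sets)
            expected = union_bruteforce(
                [[p.interval for p in s.peaks] for s in sets]
            )
            assert [(p.chrom, p.start, p.end) for p in got] == expected


class TestFragmentCounting:
    def test_midpoint_rule_assigns_edge_spanning_fragment_once(self):
        frags = FragmentSet("s", [GenomicInterval("chr1", 140, 260)])  # mid 200
        master = [pk(100, 201, support=2), pk(300, 400, support=2)]
        cm = count_fragments_in_peaks({"s": frags}, master)
        assert cm.counts.loc[peak_id(master[0]), "s"] == 1
        assert cm.counts.loc[peak_id(master[1]), "s"] == 0

    def test_fragment_outside_all_peaks_uncounted(self):
        frags = FragmentSet("s", [GenomicInterval("chr1", 900, 950)])
        cm = count_fragments_in_peaks({"s": frags}, [pk(0, 100)])
        assert cm.counts.to_numpy().sum() == 0

    def test_count_conservation(self, rng):
        frags = FragmentSet(
            "s",
            [
                GenomicInterval("chr1", int(s), int(s) + 50)
                for s in rng.integers(0, 2000, 100)
            ],
        )
        master = [pk(0, 500), pk(700, 1200)]
        cm = count_fragments_in_peaks({"s": frags}, master)
        assert cm.counts.to_numpy().sum() <= 100
        mids = [f.midpoint for f in frags.fragments]
        expected = sum(
            1 for m in mids if 0 <= m < 500 or 700 <= m < 1200
        )
        assert cm.counts.to_numpy().sum() == expected

    def test_overlapping_master_peaks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            count_fragments_in_peaks(
                {"s": FragmentSet("s", [])}, [pk(0, 100), pk(50, 150)]
            )


class TestNormalize:
    def test_single_feature_tpm_forced_to_million(self):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [17]}, index=["f1"]),
            feature_lengths=pd.Series([100.0], index=["f1"]),
        )
        out = normalize(cm, "TPM")
        assert out.counts.loc["f1", "s1"] == pytest.approx(1e6)

    def test_tpm_ratio_reflects_length(self):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [10, 10]}, index=["a", "b"]),
            feature_lengths=pd.Series([100.0, 200.0], index=["a", "b"]),
        )
        out = normalize(cm, "TPM")
        a, b = out.counts["s1"]
        assert a / b == pytest.approx(2.0)
        assert a + b == pytest.approx(1e6)

    def test_cpm_arithmetic(self):
        cm = CountMatrix(counts=pd.DataFrame({"s1": [1, 3]}, index=["a", "b"]))
        out = normalize(cm, "CPM")
        assert list(out.counts["s1"]) == [250000.0, 750000.0]

    def test_zero_column_and_missing_lengths_are_errors(self):
        cm = CountMatrix(counts=pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="zero column"):
            normalize(cm, "CPM")
        cm2 = CountMatrix(counts=pd.DataFrame({"s1": [1, 2]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="feature_lengths"):
            normalize(cm2, "TPM")

    def test_double_normalization_rejected(self):
        cm = CountMatrix(counts=pd.DataFrame({"s1": [1, 3]}, index=["a", "b"]))
        out = normalize(cm, "CPM")
        with pytest.raises(ValueError, match="already normalized"):
            normalize(out, "CPM")


def _normed(values_by_sample, features):
    cm = CountMatrix(
        counts=pd.DataFrame(values_by_sample, index=features, dtype=float),
        norm_state="CPM",
    )
    return cm


class TestClassifyDifferential:
    def test_equal_means_are_same(self):
        cm = _normed({"a1": [10.0], "b1": [10.0]}, ["f"])
        (r,) = classify_differential(cm, ["a1"], ["b1"], lfc_cutoff=0.4)
        assert (r.log2fc, r.cls) == (0.0, "same")

    def test_pseudocount_arithmetic(self):
        cm = _normed({"a1": [10.0], "b1": [43.0]}, ["f"])
        (r,) = classify_differential(cm, ["a1"], ["b1"], lfc_cutoff=2.0)
        assert r.log2fc == pytest.approx(2.0)  # log2(44/11)
        assert r.cls == "up"

    def test_boundary_is_inclusive(self):
        # engineered so log2FC == cutoff exactly
        cm = _normed({"a1": [3.0], "b1": [7.0]}, ["f"])  # log2(8/4) = 1
        (r,) = classify_differential(cm, ["a1"], ["b1"], lfc_cutoff=1.0)
        assert r.cls == "up"
        cm2 = _normed({"a1": [7.0], "b1": [3.0]}, ["f"])
        (r2,) = classify_differential(cm2, ["a1"], ["b1"], lfc_cutoff=1.0)
        assert r2.cls == "down"

    def test_group_overlap_rejected(self):
        cm = _normed({"a1": [1.0], "b1": [2.0]}, ["f"])
        with pytest.raises(ValueError, match="overlap"):
            classify_differential(cm, ["a1"], ["a1"], lfc_cutoff=0.4)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_partition_and_cutoff_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.lognormal(3, 1.5, (n, 4))
        cm = CountMatrix(
            counts=pd.DataFrame(
                vals, index=[f"f{i}" for i in range(n)],
                columns=["a1", "a2", "b1", "b2"],
            ),
            norm_state="CPM",
        )
        prev_same: set[str] = set()
        for cutoff in (0.2, 0.4, 0.8, 1.6):
            res = classify_differential(cm, ["a1", "a2"], ["b1", "b2"], cutoff)
            assert len(res) == n  # partition: one class per feature
            same = {r.feature_id for r in res if r.cls == "same"}
            assert prev_same <= same  # raising cutoff only moves toward same
            prev_same = same

    def test_fdr_gate_moves_noisy_features_to_same(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(4, 0.1, (20, 2))
        vals = np.hstack([base, base * 4])  # strong consistent shift
        noisy = np.array([[5.0, 500.0, 400.0, 4.0]])
        cm = CountMatrix(
            counts=pd.DataFrame(
                np.vstack([vals, noisy]),
                index=[f"f{i}" for i in range(21)],
                columns=["a1", "a2", "b1", "b2"],
            ),
            norm_state="CPM",
        )
        res = classify_differential(
            cm, ["a1", "a2"], ["b1", "b2"], 1.0, use_fdr=True, q_max=0.05
        )
        by_id = {r.feature_id: r for r in res}
        assert by_id["f20"].cls == "same"  # inconsistent across replicates
        assert sum(r.cls == "up" for r in res) >= 15


class TestFragmentSizeQC:
    def _frags(self, sizes):
        return FragmentSet(
            "s", [GenomicInterval("chr1", 1000, 1000 + int(s)) for s in sizes]
        )

    def test_all_short_library(self):
        qc = fragment_size_qc(self._frags([50] * 150))
        assert qc.fraction_below_100bp == 1.0
        assert qc.periodicity_flag is False

    def test_bimodal_library_detects_mononucleosome_peak(self, rng):
        sizes = np.concatenate(
            [
                np.clip(rng.normal(60, 10, 600), 20, 99),
                np.clip(rng.normal(200, 15, 400), 150, 280),
            ]
        )
        qc = fragment_size_qc(self._frags(sizes))
        assert qc.fraction_below_100bp == pytest.approx(0.6, abs=0.02)
        assert abs(qc.modal_size - 200) <= 15
        assert qc.periodicity_flag is True

    def test_uniform_large_fragments_no_flag(self, rng):
        sizes = rng.integers(300, 400, 200)
        qc = fragment_size_qc(self._frags(sizes))
        assert qc.periodicity_flag is False

    def test_too_few_fragments_is_error(self):
        with pytest.raises(ValueError, match=">=100"):
            fragment_size_qc(self._frags([100] * 99))
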