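"""Replicate-consensus peak aggregation, counting, normalization and
tri-class differential calling.

The workflow mirrors a standard multi-replicate ATAC/ChIP analysis:

1. per-sample replicate peak calls are aggregated into consensus peaks
   (transitive clustering at a minimum overlap fraction; clusters supported
   by a single replicate are discarded);
2. per-sample consensus sets are unioned into a master peak list;
3. fragments are counted under master peaks (midpoint assignment, so each
   fragment is counted at most once);
4. counts are normalized (CPM or TPM) and each feature is classified as
   up / down / same from the log2 fold change between two sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genomic_core import (
    GenomicInterval,
    GenomeDef,
    Peak,
    merge_cluster,
    overlap_fraction,
)

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_SAME = "same"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ConsensusPeakSet:
    """Non-overlapping peaks each supported by >=2 replicates of one sample."""

    sample_id: str
    peaks: list[Peak]
    provenance: list[str]

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.support < 2:
                raise ValueError(
                    f"consensus peak {p.chrom}:{p.start}-{p.end} has support "
                    f"{p.support} < 2"
                )
        by_chrom: dict[str, list[Peak]] = {}
        for p in sorted(self.peaks, key=lambda p: (p.chrom, p.start)):
            by_chrom.setdefault(p.chrom, []).append(p)
        for plist in by_chrom.values():
            for a, b in zip(plist, plist[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"consensus peaks overlap: {a.chrom}:{a.start}-{a.end} "
                        f"and {b.chrom}:{b.start}-{b.end}"
                    )


@dataclass
class FragmentSet:
    """Paired-end fragment spans of one sample."""

    sample_id: str
    fragments: list[GenomicInterval]

    def sizes(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=int)

    def validate(self, genome: GenomeDef) -> None:
        for f in self.fragments:
            genome.check(f)


@dataclass
class CountMatrix:
    """Features x samples count table with explicit normalization state.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample.  ``feature_lengths`` (bp) is required only for TPM.
    """

    counts: pd.DataFrame
    norm_state: str = "raw"  # raw | CPM | TPM
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_state not in ("raw", "CPM", "TPM"):
            raise ValueError(f"unknown norm_state {self.norm_state!r}")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        norm_state: str = "raw",
        feature_lengths: pd.Series | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        df.index.name = "feature_id"
        return cls(counts=df, norm_state=norm_state, feature_lengths=feature_lengths)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature differential call between two groups (B vs A)."""

    feature_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float | None
    q_value: float | None
    cls: str  # up | down | same

    def __post_init__(self) -> None:
        if self.cls not in (CLASS_UP, CLASS_DOWN, CLASS_SAME):
            raise ValueError(f"unknown class {self.cls!r}")


def differential_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "class": [r.cls for r in results],
        }
    )


# ---------------------------------------------------------------------------
# replicate aggregation and union
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_by_overlap(
    peaks: Sequence[Peak], min_overlap: float
) -> list[list[Peak]]:
    """Transitive clusters of peaks whose pairwise overlap fraction meets
    ``min_overlap``.  A clusters with B and B with C merges all three even if
    A and C themselves fall short (interval-merge semantics)."""
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    uf = _UnionFind(len(peaks))
    active: list[int] = []
    prev_chrom: str | None = None
    for idx in order:
        p = peaks[idx]
        if p.chrom != prev_chrom:
            active = []
            prev_chrom = p.chrom
        active = [j for j in active if peaks[j].end > p.start]
        for j in active:
            if overlap_fraction(p.interval, peaks[j].interval) >= min_overlap:
                uf.union(idx, j)
        active.append(idx)
    clusters: dict[int, list[Peak]] = {}
    for i, p in enumerate(peaks):
        clusters.setdefault(uf.find(i), []).append(p)
    return list(clusters.values())


def _merge_touching(peaks: list[Peak]) -> list[Peak]:
    """Any-overlap (>=1 bp) merge enforcing a pairwise non-overlapping set.

    sample_id strings are combined (comma-joined unique), support is the
    size of the union of contributing replicate labels when available,
    otherwise the max of the inputs.
    """
    merged: list[Peak] = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == p.chrom and p.start < merged[-1].end:
            q = merged[-1]
            labels = sorted(
                set(filter(None, q.sample_id.split(",") + p.sample_id.split(",")))
            )
            reps = sorted(
                set(filter(None, q.replicate_id.split(",") + p.replicate_id.split(",")))
            )
            merged[-1] = Peak(
                interval=GenomicInterval(q.chrom, q.start, max(q.end, p.end)),
                score=max(q.score, p.score),
                sample_id=",".join(labels),
                replicate_id=",".join(reps),
                support=len(reps) if reps else max(q.support, p.support),
            )
        else:
            merged.append(p)
    return merged


def aggregate_replicates(
    replicate_peaks: Mapping[str, Sequence[Peak]],
    min_overlap: float = 0.5,
    sample_id: str = "",
) -> ConsensusPeakSet:
    """Aggregate per-replicate peak calls into a consensus set.

    Peaks across replicates are transitively clustered wherever the overlap
    fraction (relative to the shorter peak) meets ``min_overlap``; each
    cluster is collapsed to its convex hull.  Clusters contributed by a
    single replicate are removed; ``support`` records the number of distinct
    replicates in the cluster.
    """
    if len(replicate_peaks) < 2:
        raise ValueError(
            "consensus undefined: need >=2 replicates, got "
            f"{len(replicate_peaks)}"
        )
    if not (0 < min_overlap <= 1):
        raise ValueError(f"min_overlap must be in (0, 1], got {min_overlap}")

    tagged: list[Peak] = []
    for rep_id, peaks in replicate_peaks.items():
        for p in peaks:
            tagged.append(replace(p, replicate_id=rep_id))

    consensus: list[Peak] = []
    for cluster in _cluster_by_overlap(tagged, min_overlap):
        reps = {p.replicate_id for p in cluster}
        if len(reps) < 2:
            continue
        hull = merge_cluster([p.interval for p in cluster])
        consensus.append(
            Peak(
                interval=hull,
                score=max(p.score for p in cluster),
                sample_id=sample_id,
                replicate_id=",".join(sorted(reps)),
                support=len(reps),
            )
        )
    # hulls of distinct threshold-clusters may still touch; enforce the
    # non-overlap invariant of the consensus set
    consensus = _merge_touching(consensus)
    return ConsensusPeakSet(
        sample_id=sample_id,
        peaks=sorted(consensus, key=lambda p: (p.chrom, p.start)),
        provenance=sorted(replicate_peaks),
    )


def union_peak_lists(sets: Sequence[ConsensusPeakSet]) -> list[Peak]:
    """Master peak list: any-overlap merge across per-sample consensus sets.

    Each master peak's ``sample_id`` records the contributing samples
    (comma-joined) and ``support`` the number of distinct samples.
    """
    if not sets:
        raise ValueError("union of zero peak sets is undefined")
    pool: list[Peak] = []
    for s in sets:
        for p in s.peaks:
            pool.append(
                Peak(
                    interval=p.interval,
                    score=p.score,
                    sample_id=s.sample_id,
                    replicate_id=s.sample_id,  # reused as contributor label
                    support=1,
                )
            )
    master = _merge_touching(pool)
    return [
        Peak(
            interval=p.interval,
            score=p.score,
            sample_id=p.sample_id,
            replicate_id="",
            support=len(set(filter(None, p.sample_id.split(",")))),
        )
        for p in master
    ]


# ---------------------------------------------------------------------------
# fragment counting
# ---------------------------------------------------------------------------

def _check_non_overlapping(master: Sequence[Peak]) -> None:
    by_chrom: dict[str, list[Peak]] = {}
    for p in sorted(master, key=lambda p: (p.chrom, p.start)):
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        for a, b in zip(plist, plist[1:]):
            if b.start < a.end:
                raise ValueError(
                    "master peaks overlap: "
                    f"{a.chrom}:{a.start}-{a.end} / {b.chrom}:{b.start}-{b.end}"
                )


def peak_id(p: Peak) -> str:
    return f"{p.chrom}:{p.start}-{p.end}"


def count_fragments_in_peaks(
    frags: Mapping[str, FragmentSet] | Sequence[FragmentSet],
    master: Sequence[Peak],
) -> CountMatrix:
    """Count fragments under master peaks by the midpoint rule.

    A fragment is assigned to the unique peak containing its midpoint; a
    fragment overlapping a peak edge is therefore counted at most once, and
    total assigned counts never exceed the number of fragments.
    """
    _check_non_overlapping(master)
    if isinstance(frags, Mapping):
        frag_sets = list(frags.values())
    else:
        frag_sets = list(frags)

    order = sorted(range(len(master)), key=lambda i: (master[i].chrom, master[i].start))
    by_chrom_starts: dict[str, np.ndarray] = {}
    by_chrom_ends: dict[str, np.ndarray] = {}
    by_chrom_idx: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in master}:
        idx = np.array([i for i in order if master[i].chrom == chrom], dtype=int)
        by_chrom_starts[chrom] = np.array([master[i].start for i in idx])
        by_chrom_ends[chrom] = np.array([master[i].end for i in idx])
        by_chrom_idx[chrom] = idx

    feature_ids = [peak_id(p) for p in master]
    data = np.zeros((len(master), len(frag_sets)), dtype=int)
    for j, fs in enumerate(frag_sets):
        mids_by_chrom: dict[str, list[int]] = {}
        for f in fs.fragments:
            mids_by_chrom.setdefault(f.chrom, []).append(f.midpoint)
        for chrom, mids in mids_by_chrom.items():
            if chrom not in by_chrom_starts:
                continue
            mids_arr = np.array(mids)
            starts = by_chrom_starts[chrom]
            ends = by_chrom_ends[chrom]
            pos = np.searchsorted(starts, mids_arr, side="right") - 1
            ok = (pos >= 0) & (mids_arr < ends[np.clip(pos, 0, None)])
            hit = by_chrom_idx[chrom][pos[ok]]
            np.add.at(data[:, j], hit, 1)

    counts = pd.DataFrame(
        data, index=pd.Index(feature_ids, name="feature_id"),
        columns=[fs.sample_id for fs in frag_sets],
    )
    lengths = pd.Series(
        [p.interval.length for p in master], index=counts.index, dtype=float
    )
    return CountMatrix(counts=counts, norm_state="raw", feature_lengths=lengths)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(cm: CountMatrix, method: str) -> CountMatrix:
    """Library-size normalization.

    CPM: ``counts / column_sum * 1e6``.
    TPM: ``(counts / length) / sum_k(counts_k / length_k) * 1e6`` — every
    sample column sums to exactly one million.
    """
    if cm.norm_state != "raw":
        raise ValueError(f"matrix already normalized ({cm.norm_state})")
    x = cm.counts.to_numpy(dtype=float)
    colsums = x.sum(axis=0)
    if (colsums == 0).any():
        bad = [cm.sample_ids[i] for i in np.flatnonzero(colsums == 0)]
        raise ValueError(f"zero column sum for sample(s) {bad}; cannot normalize")
    if method == "CPM":
        out = x / colsums * 1e6
    elif method == "TPM":
        if cm.feature_lengths is None or cm.feature_lengths.isna().any():
            raise ValueError("TPM requires feature_lengths for every feature")
        rate = x / cm.feature_lengths.to_numpy(dtype=float)[:, None]
        denom = rate.sum(axis=0)
        if (denom == 0).any():
            raise ValueError("zero length-normalized column sum")
        out = rate / denom * 1e6
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return CountMatrix(
        counts=pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns),
        norm_state=method,
        feature_lengths=cm.feature_lengths,
    )


# ---------------------------------------------------------------------------
# tri-class differential calling
# ---------------------------------------------------------------------------

def classify_differential(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_cutoff: float,
    use_fdr: bool = False,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DifferentialResult]:
    """Classify every feature as up / down / same (B relative to A).

    log2FC = log2((mean_b + c) / (mean_a + c)) on normalized values with
    pseudocount ``c``.  The cutoff boundary is inclusive: |log2FC| equal to
    the cutoff is called up/down.  With ``use_fdr`` a Welch t-test on
    log2(normalized + 1) values with Benjamini-Hochberg adjustment gates the
    up/down calls at ``q <= q_max``; this requires >=2 samples per group.
    """
    if cm.norm_state == "raw":
        raise ValueError("classify_differential expects a normalized matrix")
    if lfc_cutoff <= 0:
        raise ValueError(f"lfc_cutoff must be > 0, got {lfc_cutoff}")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    missing = (set(group_a) | set(group_b)) - set(cm.sample_ids)
    if missing:
        raise ValueError(f"unknown sample(s) {sorted(missing)}")
    if use_fdr and (len(group_a) < 2 or len(group_b) < 2):
        raise ValueError("FDR testing requires >=2 samples per group")

    a = cm.counts[list(group_a)].to_numpy(dtype=float)
    b = cm.counts[list(group_b)].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    p_values = np.full(len(lfc), np.nan)
    q_values = np.full(len(lfc), np.nan)
    if use_fdr:
        la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
        p_values = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
        q_values = multipletests(p_values, method="fdr_bh")[1]

    results: list[DifferentialResult] = []
    for i, fid in enumerate(cm.feature_ids):
        significant = (not use_fdr) or (q_values[i] <= q_max)
        if lfc[i] >= lfc_cutoff and significant:
            cls = CLASS_UP
        elif lfc[i] <= -lfc_cutoff and significant:
            cls = CLASS_DOWN
        else:
            cls = CLASS_SAME
        results.append(
            DifferentialResult(
                feature_id=fid,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=float(lfc[i]),
                p_value=float(p_values[i]) if use_fdr else None,
                q_value=float(q_values[i]) if use_fdr else None,
                cls=cls,
            )
        )
    return results


# ---------------------------------------------------------------------------
# fragment-size QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSizeQC:
    fraction_below_100bp: float
    modal_size: float
    periodicity_flag: bool
    histogram: tuple[tuple[float, int], ...]  # (bin center, count)


def fragment_size_qc(frags: FragmentSet, bin_width: int = 10) -> FragmentSizeQC:
    """Fragment-size distribution QC for a tagmentation library.

    A healthy library shows a high proportion of sub-100 bp fragments
    (open chromatin) plus a mono-nucleosome component near 200 bp.  The
    ``periodicity_flag`` is true when the 10 bp histogram has a local
    maximum with center in [160, 260] bp; ``modal_size`` is the center of
    the highest bin at >=120 bp (the mono-nucleosome search window).
    """
    sizes = frags.sizes()
    if sizes.size < 100:
        raise ValueError(f"need >=100 fragments for QC, got {sizes.size}")
    max_size = int(sizes.max())
    edges = np.arange(0, max_size + 2 * bin_width, bin_width)
    hist, _ = np.histogram(sizes, bins=edges)
    centers = edges[:-1] + bin_width / 2.0

    frac_short = float((sizes < 100).mean())

    window = centers >= 120
    if window.any() and hist[window].max() > 0:
        modal = float(centers[window][np.argmax(hist[window])])
    else:
        modal = float(centers[np.argmax(hist)])

    padded = np.concatenate([[0], hist, [0]])
    flag = False
    for i in range(len(hist)):
        if not (160 <= centers[i] <= 260) or hist[i] == 0:
            continue
        left, right = padded[i], padded[i + 2]
        if hist[i] >= left and hist[i] >= right and (hist[i] > left or hist[i] > right):
            flag = True
            break

    return FragmentSizeQC(
        fraction_below_100bp=frac_short,
        modal_size=modal,
        periodicity_flag=flag,
        histogram=tuple((float(c), int(h)) for c, h in zip(centers, hist)),
    )
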