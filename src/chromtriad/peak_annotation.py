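"""Peak-to-feature and peak-to-gene annotation.

Every base of the genome is labeled with exactly one feature class under a
fixed precedence (TSS window > 5'UTR > exon > intron > intergenic), so the
class sizes tile the genome and peak proportions can be normalized by the
genomic share of each class.  Peaks are assigned to genes by nearest TSS
within a radius, falling back to the gene whose span contains the peak
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomeDef, GenomicInterval, Peak

# painting order: low to high precedence; code = position in this list
FEATURE_CLASSES = ("intergenic", "intron", "exon", "5UTR", "TSS")
_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}


@dataclass
class FeatureClassMap:
    """Per-chromosome per-base feature-class labels plus class sizes (bp)."""

    labels: dict[str, np.ndarray]  # uint8 arrays, codes into FEATURE_CLASSES
    class_sizes: dict[str, int]
    tss_halfwidth: int

    @property
    def genome_size(self) -> int:
        return sum(self.class_sizes.values())

    def class_of(self, chrom: str, pos: int) -> str:
        arr = self.labels[chrom]
        if not (0 <= pos < arr.size):
            raise ValueError(f"position {chrom}:{pos} outside genome")
        return FEATURE_CLASSES[arr[pos]]


def build_feature_map(
    annotation: Sequence[GeneModel],
    genome: GenomeDef,
    tss_halfwidth: int = 500,
) -> FeatureClassMap:
    """Label every base with its highest-precedence overlapping feature.

    Precedence (high to low): TSS window (+-``tss_halfwidth``), 5'UTR, exon,
    intron (gene span minus exons), intergenic.  TSS windows are clipped to
    chromosome bounds; a gene extending past its chromosome is an error.
    """
    labels = {
        chrom: np.zeros(size, dtype=np.uint8)
        for chrom, size in genome.chrom_sizes.items()
    }
    for g in annotation:
        genome.check(g.gene_span)
        arr = labels[g.chrom]
        span = g.gene_span
        # introns: paint whole span, exons overwrite below
        arr[span.start : span.end] = np.maximum(
            arr[span.start : span.end], _CODE["intron"]
        )
    for g in annotation:
        arr = labels[g.chrom]
        for ex in g.exons:
            arr[ex.start : ex.end] = np.maximum(
                arr[ex.start : ex.end], _CODE["exon"]
            )
    for g in annotation:
        if g.utr5 is not None:
            arr = labels[g.chrom]
            arr[g.utr5.start : g.utr5.end] = np.maximum(
                arr[g.utr5.start : g.utr5.end], _CODE["5UTR"]
            )
    for g in annotation:
        arr = labels[g.chrom]
        lo = max(0, g.tss - tss_halfwidth)
        hi = min(arr.size, g.tss + tss_halfwidth)
        arr[lo:hi] = _CODE["TSS"]

    class_sizes = {name: 0 for name in FEATURE_CLASSES}
    for arr in labels.values():
        counts = np.bincount(arr, minlength=len(FEATURE_CLASSES))
        for i, name in enumerate(FEATURE_CLASSES):
            class_sizes[name] += int(counts[i])
    return FeatureClassMap(
        labels=labels, class_sizes=class_sizes, tss_halfwidth=tss_halfwidth
    )


def classify_midpoint(
    mid: int,
    chrom: str,
    annotation: Sequence[GeneModel],
    tss_halfwidth: int = 500,
) -> str:
    """Feature class of a single position by the same precedence rule,
    without materializing a per-base map (used when no map is at hand)."""
    best = _CODE["intergenic"]
    for g in annotation:
        if g.chrom != chrom:
            continue
        if -tss_halfwidth <= mid - g.tss < tss_halfwidth:
            return "TSS"
        if g.utr5 is not None and g.utr5.contains(mid):
            best = max(best, _CODE["5UTR"])
        elif any(ex.contains(mid) for ex in g.exons):
            best = max(best, _CODE["exon"])
        elif g.gene_span.contains(mid):
            best = max(best, _CODE["intron"])
    return FEATURE_CLASSES[best]


def region_proportion_enrichment(
    peaks: Sequence[Peak], fmap: FeatureClassMap
) -> pd.Series:
    """Peak proportion per feature class normalized by the class's genomic share.

    For class c: ``(n_peaks_c / n_peaks) / (size_c / genome_size)``; a value
    of 1 means the class holds exactly its genome-proportional share of peak
    midpoints.  The size-weighted mean of the values is therefore 1 whenever
    every class is populated according to its share.
    """
    if not peaks:
        raise ValueError("need >=1 peak")
    n_total = len(peaks)
    n_per_class = {name: 0 for name in FEATURE_CLASSES}
    for p in peaks:
        n_per_class[fmap.class_of(p.chrom, p.midpoint)] += 1
    genome_size = fmap.genome_size
    values = {}
    for name in FEATURE_CLASSES:
        share = fmap.class_sizes[name] / genome_size
        if share == 0:
            values[name] = np.nan if n_per_class[name] == 0 else np.inf
        else:
            values[name] = (n_per_class[name] / n_total) / share
    return pd.Series(values, name="normalized_proportion")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: str | None
    feature_class: str
    distance_to_tss: int | None  # signed, strand-aware (+ = downstream)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    annotation: Sequence[GeneModel],
    max_tss_distance: int = 5000,
    fmap: FeatureClassMap | None = None,
    tss_halfwidth: int = 500,
) -> list[PeakGeneAssignment]:
    """Assign each peak to at most one gene.

    Rule: the gene with the nearest TSS within ``max_tss_distance`` of the
    peak midpoint wins; ties break to the lexicographically smaller gene_id;
    otherwise a gene whose span contains the midpoint (again smallest id);
    otherwise unassigned.  The signed TSS distance is strand-aware
    (positive = downstream of the TSS).
    """
    if max_tss_distance <= 0:
        raise ValueError("max_tss_distance must be > 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[PeakGeneAssignment] = []
    for p in peaks:
        mid = p.midpoint
        genes = by_chrom.get(p.chrom, [])
        best: GeneModel | None = None
        best_key: tuple[int, str] | None = None
        for g in genes:
            d = abs(mid - g.tss)
            if d <= max_tss_distance:
                key = (d, g.gene_id)
                if best_key is None or key < best_key:
                    best, best_key = g, key
        if best is None:
            containing = sorted(
                (g for g in genes if g.gene_span.contains(mid)),
                key=lambda g: g.gene_id,
            )
            best = containing[0] if containing else None

        if fmap is not None:
            fclass = fmap.class_of(p.chrom, mid)
        else:
            fclass = classify_midpoint(mid, p.chrom, annotation, tss_halfwidth)

        if best is None:
            out.append(
                PeakGeneAssignment(
                    peak_id=f"{p.chrom}:{p.start}-{p.end}",
                    gene_id=None,
                    feature_class=fclass,
                    distance_to_tss=None,
                )
            )
        else:
            signed = mid - best.tss if best.strand != "-" else best.tss - mid
            out.append(
                PeakGeneAssignment(
                    peak_id=f"{p.chrom}:{p.start}-{p.end}",
                    gene_id=best.gene_id,
                    feature_class=fclass,
                    distance_to_tss=int(signed),
                )
            )
    return out


def assignments_to_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in assignments],
            "gene_id": [a.gene_id if a.gene_id is not None else "" for a in assignments],
            "feature_class": [a.feature_class for a in assignments],
            "distance_to_tss": [
                a.distance_to_tss if a.distance_to_tss is not None else ""
                for a in assignments
            ],
        }
    )


def gene_level_atac_classes(
    assignments: Sequence[PeakGeneAssignment],
    peak_classes: Mapping[str, str],
    peak_lfc: Mapping[str, float],
) -> dict[str, str]:
    """Gene-level accessibility class: class of the gene's largest-|log2FC|
    assigned peak (deterministic tie-break on peak id)."""
    best: dict[str, tuple[float, str, str]] = {}
    for a in assignments:
        if a.gene_id is None or a.peak_id not in peak_classes:
            continue
        lfc = abs(peak_lfc[a.peak_id])
        key = (-lfc, a.peak_id)
        if a.gene_id not in best or key < (best[a.gene_id][0], best[a.gene_id][1]):
            best[a.gene_id] = (-lfc, a.peak_id, peak_classes[a.peak_id])
    return {gene: cls for gene, (_, _, cls) in best.items()}
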