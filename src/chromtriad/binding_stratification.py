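"""Stratify differential accessibility peaks by binding-site overlap and
build paired coverage matrices over fixed-width regions around peak centers.

Differential ATAC peaks are split into six cells —
{bound, unbound} x {up, down, same} — where "bound" means >=1 bp overlap
with a consensus binding (ChIP) peak.  Regions of +-``flank`` bp around
each peak center feed binned fragment-coverage matrices; WT and KO matrices
are computed over the same region list so rows pair one-to-one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .consensus_peaks import FragmentSet
from .genomic_core import GenomeDef, GenomicInterval, Peak, overlap_length

logger = logging.getLogger(__name__)

STRATA = (
    ("bound", "up"),
    ("bound", "down"),
    ("bound", "same"),
    ("unbound", "up"),
    ("unbound", "down"),
    ("unbound", "same"),
)


@dataclass
class StratifiedPeaks:
    """Six disjoint peak lists partitioning the classified input set."""

    cells: dict[tuple[str, str], list[Peak]]

    def counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.cells.items()}

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.cells.values())


def stratify_by_binding(
    atac_diff: Sequence[tuple[Peak, str]],
    chip_peaks: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> StratifiedPeaks:
    """Partition classified ATAC peaks by overlap with binding-site peaks.

    An ATAC peak is "bound" iff it shares at least ``min_overlap_bp`` bases
    with any ChIP peak; the differential class label is carried through.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    chip_by_chrom: dict[str, list[Peak]] = {}
    for c in sorted(chip_peaks, key=lambda p: (p.chrom, p.start)):
        chip_by_chrom.setdefault(c.chrom, []).append(c)
    starts = {
        chrom: np.array([c.start for c in lst])
        for chrom, lst in chip_by_chrom.items()
    }
    ends = {
        chrom: np.array([c.end for c in lst]) for chrom, lst in chip_by_chrom.items()
    }

    cells: dict[tuple[str, str], list[Peak]] = {k: [] for k in STRATA}
    for peak, cls in atac_diff:
        if cls not in ("up", "down", "same"):
            raise ValueError(f"unknown class {cls!r}")
        bound = False
        lst = chip_by_chrom.get(peak.chrom)
        if lst:
            s, e = starts[peak.chrom], ends[peak.chrom]
            # candidate chip peaks overlapping [start, end)
            lo = int(np.searchsorted(e, peak.start, side="right"))
            hi = int(np.searchsorted(s, peak.end, side="left"))
            for c in lst[lo:hi]:
                if overlap_length(peak.interval, c.interval) >= min_overlap_bp:
                    bound = True
                    break
        cells[("bound" if bound else "unbound", cls)].append(peak)
    return StratifiedPeaks(cells=cells)


def make_regions(
    peaks: Sequence[Peak],
    flank: int = 1500,
    genome: GenomeDef | None = None,
) -> list[GenomicInterval]:
    """Fixed-width regions ``[center - flank, center + flank)`` around peak
    centers (center = floor midpoint).  Regions that would extend past a
    chromosome end are dropped (not clipped) so all rows stay commensurate;
    the number dropped is logged."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    regions: list[GenomicInterval] = []
    dropped = 0
    for p in peaks:
        center = p.midpoint
        start, end = center - flank, center + flank
        if start < 0:
            dropped += 1
            continue
        if genome is not None:
            size = genome.chrom_sizes.get(p.chrom)
            if size is None or end > size:
                dropped += 1
                continue
        regions.append(GenomicInterval(p.chrom, start, end))
    if dropped:
        logger.warning("make_regions: dropped %d regions past chromosome ends", dropped)
    return regions


@dataclass
class RegionMatrix:
    """Regions x bins fragment-coverage matrix for one sample/condition."""

    regions: list[GenomicInterval]
    bin_size: int
    values: np.ndarray  # shape (n_regions, n_bins)
    label: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.regions):
            raise ValueError("values rows must match number of regions")


def coverage_matrix(
    frags: FragmentSet,
    regions: Sequence[GenomicInterval],
    bin_size: int = 50,
    norm: str = "raw",
    label: str = "",
) -> RegionMatrix:
    """Binned fragment-midpoint coverage over fixed-width regions.

    ``value[r, b]`` counts fragments whose midpoint falls in bin ``b`` of
    region ``r``; with ``norm='per-million'`` counts are scaled by
    1e6 / total fragments in the sample.
    """
    if not regions:
        return RegionMatrix(regions=[], bin_size=bin_size,
                            values=np.zeros((0, 0)), label=label)
    widths = {r.length for r in regions}
    if len(widths) != 1:
        raise ValueError("regions must share one width")
    width = widths.pop()
    if width % bin_size != 0:
        raise ValueError(f"bin size {bin_size} does not divide region width {width}")
    n_bins = width // bin_size

    mids_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for f in frags.fragments:
        tmp.setdefault(f.chrom, []).append(f.midpoint)
    for chrom, mids in tmp.items():
        mids_by_chrom[chrom] = np.sort(np.array(mids))

    values = np.zeros((len(regions), n_bins), dtype=float)
    for i, r in enumerate(regions):
        mids = mids_by_chrom.get(r.chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, r.start, side="left")
        hi = np.searchsorted(mids, r.end, side="left")
        if hi > lo:
            bins = (mids[lo:hi] - r.start) // bin_size
            values[i] += np.bincount(bins, minlength=n_bins)

    if norm == "per-million":
        total = len(frags.fragments)
        if total > 0:
            values *= 1e6 / total
    elif norm != "raw":
        raise ValueError(f"unknown norm {norm!r}")
    return RegionMatrix(regions=list(regions), bin_size=bin_size,
                        values=values, label=label or frags.sample_id)


def paired_coverage_matrices(
    frags_a: FragmentSet,
    frags_b: FragmentSet,
    regions: Sequence[GenomicInterval],
    bin_size: int = 50,
    norm: str = "per-million",
    labels: tuple[str, str] = ("WT", "KO"),
) -> tuple[RegionMatrix, RegionMatrix]:
    """Two coverage matrices over the *same* region list, row-paired."""
    ma = coverage_matrix(frags_a, regions, bin_size, norm, labels[0])
    mb = coverage_matrix(frags_b, regions, bin_size, norm, labels[1])
    return ma, mb


def profile(rm: RegionMatrix) -> np.ndarray:
    """Average signal per bin across regions (the meta-peak profile)."""
    if rm.values.shape[0] == 0:
        raise ValueError("profile of an empty region matrix is undefined")
    return rm.values.mean(axis=0)
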