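"""Coupled ChIP/ATAC/RNA simulation with a planted direct-target taxonomy.

The generator emulates the design of a two-genotype (WT vs knockout)
regulatory study: duplicate ChIP replicates (antibody vs IgG), duplicate
ATAC samples per genotype with paired-end fragment-size structure
(sub-100 bp open-chromatin component plus a mono-nucleosome component near
200 bp), and negative-binomial RNA counts.  Each gene carries a planted
label — bound or not, RNA class, accessibility class — whose combination
implies a mechanism category, so end-to-end recovery can be scored exactly.

Genes are placed on a regular slot grid (one gene per slot, with generous
intergenic margins); every gene gets an accessible promoter site whose KO
fragment intensity scales by ``2**(+-lfc_atac)`` when an accessibility
change is planted, and bound genes get a promoter-proximal ChIP peak in
every replicate with bounded jitter, so true peaks always satisfy the 50%
replicate-overlap rule while replicate-private decoy peaks never do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus_peaks import CountMatrix, FragmentSet
from .enrichment import GeneSetCollection
from .genomic_core import GeneModel, GenomeDef, GenomicInterval, Peak
from .target_integration import MECHANISM_MAP, MECHANISMS

_GENE_MARGIN = 2000  # bp kept clear on each side of a gene within its slot


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic tri-omic experiment.

    Effect sizes (``lfc_atac`` 1.5, ``lfc_rna`` 2.0) sit comfortably above
    the classification cutoffs (0.4 / 0.7 / 1.0) so recovery tests isolate
    pipeline correctness from statistical power; ``hard_mode`` rescales
    them to 1.1x the corresponding cutoff to exercise boundary behavior.
    """

    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 1000
    n_replicates: int = 2

    # planted taxonomy sizes
    n_per_category: int = 20           # per mechanism category (x4)
    n_bound_unresolved_per_direction: int = 5   # bound, RNA +-, ATAC same
    n_unbound_de_per_direction: int = 10        # unbound, RNA +-
    n_bound_atac_only_per_direction: int = 5    # bound, RNA same, ATAC +-
    n_unbound_atac_only_per_direction: int = 5  # unbound, RNA same, ATAC +-
    n_bound_quiet: int = 80                     # bound, RNA same, ATAC same

    # planted effects and noise
    lfc_atac: float = 1.5
    lfc_rna: float = 2.0
    nb_dispersion: float = 0.05    # RNA count dispersion (NB alpha)
    atac_dispersion: float = 0.01  # replicate-level ATAC peak-count dispersion

    # library scale and peak geometry
    reads_per_sample: int = 150_000
    rna_mean_log: float = float(np.log(200.0))
    rna_sigma_log: float = 0.6
    peak_width_mean: int = 400
    peak_width_sd: int = 60
    atac_site_width_mean: int = 500
    atac_site_width_sd: int = 80
    replicate_jitter: int = 40
    singleton_rate: float = 0.2
    short_fragment_fraction: float = 0.55
    background_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.singleton_rate <= 1):
            raise ValueError("singleton_rate must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates")
        if self.replicate_jitter * 2 >= self.peak_width_mean - 2 * self.peak_width_sd:
            raise ValueError(
                "replicate_jitter too large: planted replicate peaks would "
                "not be guaranteed to satisfy the 50% overlap rule"
            )

    def hard_mode(self, atac_cutoff: float = 0.4, rna_cutoff: float = 0.7
                  ) -> "SimulationConfig":
        """Copy with effects at 1.1x the classification cutoffs."""
        return dataclasses.replace(
            self, lfc_atac=1.1 * atac_cutoff, lfc_rna=1.1 * rna_cutoff
        )


@dataclass
class SimulationTruth:
    """Planted per-gene taxonomy (and the implied mechanism category)."""

    genes: pd.DataFrame  # gene_id, bound, rna_class, atac_class, mechanism

    def __post_init__(self) -> None:
        required = {"gene_id", "bound", "rna_class", "atac_class", "mechanism"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")

    @property
    def bound_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["bound"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t")
        df["bound"] = df["bound"].astype(bool)
        return cls(genes=df)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per component
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def _slot_layout(cfg: SimulationConfig) -> tuple[int, int]:
    slots_per_chrom = -(-cfg.n_genes // cfg.n_chroms)  # ceil
    slot_width = cfg.chrom_length // max(slots_per_chrom, 1)
    return slots_per_chrom, slot_width


def _gene_slot(cfg: SimulationConfig, idx: int) -> tuple[str, int]:
    slots_per_chrom, slot_width = _slot_layout(cfg)
    chrom = f"chr{idx % cfg.n_chroms + 1}"
    slot_start = (idx // cfg.n_chroms) * slot_width
    return chrom, slot_start


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeDef, list[GeneModel]]:
    """Place non-overlapping genes (one per slot) on the synthetic genome."""
    rng = rng or _rng(cfg, 0)
    genome = GenomeDef(
        chrom_sizes={f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    )
    if cfg.n_genes == 0:
        return genome, []
    _, slot_width = _slot_layout(cfg)
    max_len = 6000
    if slot_width < max_len + 2 * _GENE_MARGIN:
        raise ValueError(
            f"infeasible packing: slot width {slot_width} bp cannot hold a "
            f"{max_len} bp gene with {_GENE_MARGIN} bp margins"
        )
    genes: list[GeneModel] = []
    for idx in range(cfg.n_genes):
        chrom, slot_start = _gene_slot(cfg, idx)
        length = int(rng.integers(2000, max_len + 1))
        offset = int(rng.integers(_GENE_MARGIN, slot_width - length - _GENE_MARGIN + 1))
        start = slot_start + offset
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        exons = (
            GenomicInterval(chrom, start, start + length // 5, strand),
            GenomicInterval(
                chrom, start + 2 * length // 5, start + 3 * length // 5, strand
            ),
            GenomicInterval(chrom, start + 4 * length // 5, end, strand),
        )
        if strand == "+":
            tss = start
            utr5 = GenomicInterval(chrom, start, start + 800, strand)
        else:
            tss = end - 1
            utr5 = GenomicInterval(chrom, end - 800, end, strand)
        genes.append(
            GeneModel(
                gene_id=f"g{idx:04d}", chrom=chrom, strand=strand, tss=tss,
                gene_span=GenomicInterval(chrom, start, end, strand),
                exons=exons, utr5=utr5,
            )
        )
    return genome, genes


# ---------------------------------------------------------------------------
# planted taxonomy
# ---------------------------------------------------------------------------

def make_truth(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Assign every gene a planted (bound, rna_class, atac_class) label."""
    rng = rng or _rng(cfg, 1)
    blocks: list[tuple[bool, str, str, int]] = [
        (True, "up", "up", cfg.n_per_category),
        (True, "up", "down", cfg.n_per_category),
        (True, "down", "up", cfg.n_per_category),
        (True, "down", "down", cfg.n_per_category),
        (True, "up", "same", cfg.n_bound_unresolved_per_direction),
        (True, "down", "same", cfg.n_bound_unresolved_per_direction),
        (False, "up", "same", cfg.n_unbound_de_per_direction),
        (False, "down", "same", cfg.n_unbound_de_per_direction),
        (True, "same", "up", cfg.n_bound_atac_only_per_direction),
        (True, "same", "down", cfg.n_bound_atac_only_per_direction),
        (False, "same", "up", cfg.n_unbound_atac_only_per_direction),
        (False, "same", "down", cfg.n_unbound_atac_only_per_direction),
        (True, "same", "same", cfg.n_bound_quiet),
    ]
    n_special = sum(n for *_, n in blocks)
    if n_special > len(genes):
        raise ValueError(
            f"taxonomy needs {n_special} genes but only {len(genes)} simulated"
        )
    order = rng.permutation(len(genes))
    rows = []
    cursor = 0
    labels: dict[int, tuple[bool, str, str]] = {}
    for bound, rna_cls, atac_cls, n in blocks:
        for i in order[cursor : cursor + n]:
            labels[int(i)] = (bound, rna_cls, atac_cls)
        cursor += n
    for idx, g in enumerate(genes):
        bound, rna_cls, atac_cls = labels.get(idx, (False, "same", "same"))
        mech = MECHANISM_MAP.get((rna_cls, atac_cls), "unresolved") if bound else "unresolved"
        if not (bound and rna_cls != "same" and atac_cls in ("up", "down")):
            mech = "unresolved"
        rows.append(
            {
                "gene_id": g.gene_id, "bound": bound,
                "rna_class": rna_cls, "atac_class": atac_cls, "mechanism": mech,
            }
        )
    return SimulationTruth(genes=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fragment helpers
# ---------------------------------------------------------------------------

def _fragment_sizes(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Bimodal tagmentation size mixture: sub-100 bp + mono-nucleosome."""
    short = rng.random(n) < cfg.short_fragment_fraction
    sizes = np.empty(n, dtype=int)
    sizes[short] = np.clip(
        rng.normal(60, 18, short.sum()).round().astype(int), 20, 99
    )
    sizes[~short] = np.clip(
        rng.normal(200, 25, (~short).sum()).round().astype(int), 120, 350
    )
    return sizes


def _fragments_from_midpoints(
    chrom: str,
    mids: np.ndarray,
    sizes: np.ndarray,
    chrom_len: int,
) -> list[GenomicInterval]:
    starts = mids - sizes // 2
    starts = np.clip(starts, 0, None)
    ends = starts + sizes
    over = ends > chrom_len
    starts[over] = chrom_len - sizes[over]
    ends = starts + sizes
    return [
        GenomicInterval(chrom, int(s), int(e))
        for s, e in zip(starts, ends)
        if e > s
    ]


def _nb_counts(
    lam: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts via a Poisson-Gamma mixture."""
    lam = np.asarray(lam, dtype=float)
    if dispersion <= 0:
        return rng.poisson(lam)
    shape = 1.0 / dispersion
    rate = rng.gamma(shape, lam * dispersion)
    return rng.poisson(rate)


def _background_fragments(
    cfg: SimulationConfig,
    genome: GenomeDef,
    n: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    chroms = sorted(genome.chrom_sizes)
    lens = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    picks = rng.choice(len(chroms), size=n, p=probs)
    out: list[GenomicInterval] = []
    for ci in range(len(chroms)):
        m = int((picks == ci).sum())
        if m == 0:
            continue
        clen = int(lens[ci])
        mids = rng.integers(0, clen, m)
        sizes = _fragment_sizes(cfg, m, rng)
        out.extend(_fragments_from_midpoints(chroms[ci], mids, sizes, clen))
    return out


# ---------------------------------------------------------------------------
# ChIP simulation
# ---------------------------------------------------------------------------

def simulate_chip(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    genes: Sequence[GeneModel],
    genome: GenomeDef,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[Peak]], dict[str, FragmentSet]]:
    """Per-replicate antibody peak calls plus antibody/IgG fragment sets.

    Every bound gene receives a promoter-proximal peak in *all* replicates
    (center jitter <= ``replicate_jitter``, width fixed per gene, so the
    replicate pair always clears the 50% overlap rule).  Decoy peaks are
    injected into exactly one replicate each at ``singleton_rate`` x the
    number of true peaks; decoys live in intergenic slot margins partitioned
    by replicate, so no decoy ever overlaps a peak of another replicate.
    """
    rng = rng or _rng(cfg, 2)
    gene_by_id = {g.gene_id: g for g in genes}
    idx_by_id = {g.gene_id: i for i, g in enumerate(genes)}
    bound_ids = sorted(truth.bound_genes)

    widths = {
        gid: int(np.clip(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd),
                         200, None))
        for gid in bound_ids
    }
    replicate_peaks: dict[str, list[Peak]] = {}
    for rep in range(cfg.n_replicates):
        rep_id = f"chip_rep{rep + 1}"
        peaks: list[Peak] = []
        for gid in bound_ids:
            g = gene_by_id[gid]
            w = widths[gid]
            shift = int(rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
            center = g.tss + shift
            clen = genome.chrom_sizes[g.chrom]
            start = int(np.clip(center - w // 2, 0, clen - w))
            peaks.append(
                Peak(
                    interval=GenomicInterval(g.chrom, start, start + w),
                    score=float(rng.uniform(5, 50)),
                    sample_id=gid,
                    replicate_id=rep_id,
                )
            )
        # replicate-private decoys in slot margins assigned to this replicate
        n_decoys = int(round(cfg.singleton_rate * len(bound_ids)))
        candidates = [
            idx_by_id[gid] for gid in gene_by_id
            if idx_by_id[gid] % cfg.n_replicates == rep
        ]
        chosen = rng.choice(candidates, size=min(n_decoys, len(candidates)),
                            replace=False)
        for j in chosen:
            chrom, slot_start = _gene_slot(cfg, int(j))
            w = int(np.clip(rng.normal(300, 30), 150, 600))
            center = slot_start + 600
            start = max(0, center - w // 2)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + w),
                    score=float(rng.uniform(2, 10)),
                    sample_id=f"decoy_{rep_id}_{int(j)}",
                    replicate_id=rep_id,
                )
            )
        replicate_peaks[rep_id] = sorted(peaks, key=lambda p: (p.chrom, p.start))

    # fragments: antibody enriched at bound promoters, IgG pure background
    n_chip_reads = max(cfg.reads_per_sample // 3, 1000)
    n_signal = int(n_chip_reads * 0.8)
    per_site = np.full(len(bound_ids), n_signal / max(len(bound_ids), 1))
    counts = _nb_counts(per_site, cfg.atac_dispersion, rng)
    ab_frags: list[GenomicInterval] = []
    for gid, n_i in zip(bound_ids, counts):
        g = gene_by_id[gid]
        w = widths[gid]
        clen = genome.chrom_sizes[g.chrom]
        mids = np.clip(
            rng.normal(g.tss, w / 5, int(n_i)).round().astype(int),
            max(0, g.tss - w // 2), min(clen - 1, g.tss + w // 2),
        )
        sizes = np.clip(rng.normal(250, 50, int(n_i)).round().astype(int), 50, 600)
        ab_frags.extend(_fragments_from_midpoints(g.chrom, mids, sizes, clen))
    ab_frags.extend(
        _background_fragments(cfg, genome, n_chip_reads - n_signal, rng)
    )
    igg_frags = _background_fragments(cfg, genome, n_chip_reads, rng)
    fragment_sets = {
        "antibody": FragmentSet(sample_id="antibody", fragments=ab_frags),
        "IgG": FragmentSet(sample_id="IgG", fragments=igg_frags),
    }
    return replicate_peaks, fragment_sets


# ---------------------------------------------------------------------------
# ATAC simulation
# ---------------------------------------------------------------------------

@dataclass
class AtacSites:
    """Per-gene accessible site with genotype-specific expected intensity."""

    table: pd.DataFrame  # gene_id, chrom, center, width, wt_mult, ko_mult, ...


def _effect_multipliers(cls: str, lfc: float) -> tuple[float, float]:
    """Geometric-mean-centered (WT, KO) intensity multipliers.

    Planted effects are split symmetrically around the baseline
    (WT x 2^(-lfc/2), KO x 2^(+lfc/2) for "up"), which leaves the planted
    log2FC at exactly +-lfc while keeping the total planted signal mass
    identical between genotypes, so library-size normalization introduces
    no directional bias at unchanged features.
    """
    if cls == "up":
        return 2.0 ** (-lfc / 2), 2.0 ** (lfc / 2)
    if cls == "down":
        return 2.0 ** (lfc / 2), 2.0 ** (-lfc / 2)
    return 1.0, 1.0


def _atac_sites(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> AtacSites:
    cls = dict(zip(truth.genes["gene_id"], truth.genes["atac_class"]))
    rows = []
    for g in genes:
        width = int(np.clip(rng.normal(cfg.atac_site_width_mean,
                                       cfg.atac_site_width_sd), 250, None))
        rel = float(rng.lognormal(0.0, 0.4))
        wt_mult, ko_mult = _effect_multipliers(cls.get(g.gene_id, "same"),
                                               cfg.lfc_atac)
        rows.append(
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "center": g.tss,
                "width": width, "rel_intensity": rel,
                "wt_mult": wt_mult, "ko_mult": ko_mult,
            }
        )
    return AtacSites(table=pd.DataFrame(rows))


def simulate_atac(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    genes: Sequence[GeneModel],
    genome: GenomeDef,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, FragmentSet], dict[str, dict[str, list[Peak]]], AtacSites]:
    """WT/KO fragment sets (one per replicate) plus per-replicate peak calls.

    Fragment intensity at a planted gene's promoter site scales by
    ``2**(+-lfc_atac)`` in the KO at fixed sequencing depth; counts carry
    Poisson-Gamma (negative-binomial) replicate noise; fragment sizes follow
    the bimodal tagmentation mixture.
    """
    rng = rng or _rng(cfg, 3)
    sites = _atac_sites(cfg, truth, genes, rng)
    tbl = sites.table
    n_signal = int(cfg.reads_per_sample * (1.0 - cfg.background_fraction))
    rel = tbl["rel_intensity"].to_numpy()
    wt_rel = rel * tbl["wt_mult"].to_numpy()
    ko_rel = rel * tbl["ko_mult"].to_numpy()
    lam = {
        "WT": wt_rel / wt_rel.sum() * n_signal,
        "KO": ko_rel / ko_rel.sum() * n_signal,
    }

    fragment_sets: dict[str, FragmentSet] = {}
    peak_calls: dict[str, dict[str, list[Peak]]] = {"WT": {}, "KO": {}}
    centers = tbl["center"].to_numpy()
    widths = tbl["width"].to_numpy()
    chroms = tbl["chrom"].to_numpy()
    for genotype in ("WT", "KO"):
        for rep in range(cfg.n_replicates):
            sample = f"{genotype}_rep{rep + 1}"
            counts = _nb_counts(lam[genotype], cfg.atac_dispersion, rng)
            frags: list[GenomicInterval] = []
            for i in range(len(tbl)):
                n_i = int(counts[i])
                if n_i == 0:
                    continue
                clen = genome.chrom_sizes[chroms[i]]
                half = int(widths[i]) // 2
                mids = np.clip(
                    rng.normal(centers[i], widths[i] / 5, n_i).round().astype(int),
                    max(0, centers[i] - half),
                    min(clen - 1, centers[i] + half),
                )
                sizes = _fragment_sizes(cfg, n_i, rng)
                frags.extend(
                    _fragments_from_midpoints(chroms[i], mids, sizes, clen)
                )
            frags.extend(
                _background_fragments(
                    cfg, genome, cfg.reads_per_sample - n_signal, rng
                )
            )
            fragment_sets[sample] = FragmentSet(sample_id=sample, fragments=frags)

            # per-replicate peak calls (emulating an upstream peak caller)
            peaks = []
            for i in range(len(tbl)):
                w = int(widths[i])
                shift = int(
                    rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1)
                )
                clen = genome.chrom_sizes[chroms[i]]
                start = int(np.clip(centers[i] + shift - w // 2, 0, clen - w))
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chroms[i], start, start + w),
                        score=float(lam[genotype][i]),
                        sample_id=str(tbl["gene_id"].iloc[i]),
                        replicate_id=f"{sample}",
                    )
                )
            peak_calls[genotype][sample] = sorted(
                peaks, key=lambda p: (p.chrom, p.start)
            )
    return fragment_sets, peak_calls, sites


# ---------------------------------------------------------------------------
# RNA simulation
# ---------------------------------------------------------------------------

def simulate_rna(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Gene-level negative-binomial counts for WT/KO replicates.

    Baseline means are log-normal; planted genes scale the KO mean by
    ``2**(+-lfc_rna)``.  Deterministic for a fixed config seed.
    """
    rng = rng or _rng(cfg, 4)
    cls = dict(zip(truth.genes["gene_id"], truth.genes["rna_class"]))
    mu = rng.lognormal(cfg.rna_mean_log, cfg.rna_sigma_log, len(genes))
    mults = np.array(
        [_effect_multipliers(cls.get(g.gene_id, "same"), cfg.lfc_rna)
         for g in genes]
    )
    wt_mu, ko_mu = mu * mults[:, 0], mu * mults[:, 1]
    samples = [f"WT_rep{r + 1}" for r in range(cfg.n_replicates)] + [
        f"KO_rep{r + 1}" for r in range(cfg.n_replicates)
    ]
    data = {}
    for s in samples:
        lam = ko_mu if s.startswith("KO") else wt_mu
        data[s] = _nb_counts(lam, cfg.nb_dispersion, rng)
    counts = pd.DataFrame(
        data, index=pd.Index([g.gene_id for g in genes], name="feature_id")
    )
    lengths = pd.Series(
        [float(g.exonic_length) for g in genes], index=counts.index
    )
    return CountMatrix(counts=counts, norm_state="raw", feature_lengths=lengths)


# ---------------------------------------------------------------------------
# gene-set fixtures
# ---------------------------------------------------------------------------

def make_gene_set_fixtures(
    truth: SimulationTruth,
    n_random_sets: int = 5,
    random_set_size: int = 30,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Hallmark-style synthetic gene sets: the planted classes plus random
    decoy sets, over the simulated gene universe."""
    rng = rng or np.random.default_rng(0)
    df = truth.genes
    universe = frozenset(df["gene_id"])
    sets: dict[str, frozenset[str]] = {}
    planted = {
        "PLANTED_RNA_UP": df.loc[df["rna_class"] == "up", "gene_id"],
        "PLANTED_RNA_DOWN": df.loc[df["rna_class"] == "down", "gene_id"],
        "PLANTED_BOUND": df.loc[df["bound"], "gene_id"],
        "PLANTED_DIRECT_TARGETS": df.loc[
            df["bound"] & df["rna_class"].isin(["up", "down"]), "gene_id"
        ],
    }
    for name, series in planted.items():
        if len(series):
            sets[name] = frozenset(series)
    all_genes = sorted(universe)
    for i in range(n_random_sets):
        members = rng.choice(all_genes, size=min(random_set_size, len(all_genes)),
                             replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=universe)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    per_category: pd.DataFrame  # category, planted, predicted, recovered,
    #                             recall, precision
    confusion: pd.DataFrame     # truth mechanism x predicted mechanism

    def to_dict(self) -> dict:
        per_cat = {}
        for _, row in self.per_category.iterrows():
            per_cat[row["category"]] = {
                "planted": int(row["planted"]),
                "predicted": int(row["predicted"]),
                "recovered": int(row["recovered"]),
                "recall": None if pd.isna(row["recall"]) else float(row["recall"]),
                "precision": None
                if pd.isna(row["precision"])
                else float(row["precision"]),
            }
        return {
            "per_category": per_cat,
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.confusion.iterrows()
            },
        }


def score_recovery(
    predicted: pd.DataFrame, truth: SimulationTruth
) -> RecoveryReport:
    """Per-mechanism precision/recall of a predicted direct-target table
    against the planted taxonomy, plus the full confusion table."""
    t = truth.genes.set_index("gene_id")
    p = predicted.set_index("gene_id")
    if set(t.index) != set(p.index):
        raise ValueError("gene namespaces of prediction and truth differ")
    p = p.reindex(t.index)
    rows = []
    for cat in MECHANISMS:
        planted = t["mechanism"] == cat
        called = p["mechanism"] == cat
        recovered = int((planted & called).sum())
        n_planted, n_called = int(planted.sum()), int(called.sum())
        rows.append(
            {
                "category": cat,
                "planted": n_planted,
                "predicted": n_called,
                "recovered": recovered,
                "recall": recovered / n_planted if n_planted else np.nan,
                "precision": recovered / n_called if n_called else np.nan,
            }
        )
    confusion = pd.crosstab(t["mechanism"], p["mechanism"])
    return RecoveryReport(per_category=pd.DataFrame(rows), confusion=confusion)
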