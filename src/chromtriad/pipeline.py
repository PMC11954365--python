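"""Configuration and the one-command end-to-end run.

Order of stages (simulation mode): simulate -> ChIP consensus -> ATAC
consensus/union/counting -> differential accessibility -> annotation ->
binding stratification + coverage profiles -> RNA differential ->
direct-target calling + mechanism taxonomy -> gene-set enrichment ->
recovery scoring.  Every cutoff the analysis uses is configuration, never
a constant in code, because different questions use different fold-change
cutoffs (accessibility 0.4; headline expression 1.0; integration 0.7).

All stage outputs are plain TSV/BED/JSON written with fixed float
formatting, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import binding_stratification as strat
from . import consensus_peaks as cp
from . import enrichment as enr
from . import peak_annotation as ann
from . import synthetic_data as sim
from . import target_integration as ti
from .genomic_core import (
    GenomicInterval,
    Peak,
    file_sha256,
    write_bed,
    write_bed12_genes,
    write_chrom_sizes,
)

logger = logging.getLogger("chromtriad")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed after earlier stages succeeded."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Cutoffs:
    atac_lfc: float = 0.4
    rna_lfc: float = 1.0              # headline expression list
    rna_integration_lfc: float = 0.7  # direct-target integration
    q_max: float = 0.05
    use_fdr: bool = False

    def validate(self) -> None:
        for name in ("atac_lfc", "rna_lfc", "rna_integration_lfc", "q_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"cutoffs.{name} must be > 0")


@dataclass
class OverlapConfig:
    consensus_min: float = 0.5  # replicate aggregation overlap fraction
    binding_min_bp: int = 1     # ATAC x ChIP overlap in bases

    def validate(self) -> None:
        if not (0 < self.consensus_min <= 1):
            raise ConfigError("overlap.consensus_min must be in (0, 1]")
        if self.binding_min_bp < 1:
            raise ConfigError("overlap.binding_min_bp must be >= 1")


@dataclass
class RegionConfig:
    flank: int = 1500
    bin: int = 50

    def validate(self) -> None:
        if self.flank <= 0 or self.bin <= 0:
            raise ConfigError("regions.flank and regions.bin must be > 0")
        if (2 * self.flank) % self.bin != 0:
            raise ConfigError(
                f"regions.bin ({self.bin}) must divide the region width "
                f"({2 * self.flank})"
            )


@dataclass
class AnnotationConfig:
    tss_halfwidth: int = 500
    max_tss_distance: int = 5000

    def validate(self) -> None:
        if self.tss_halfwidth <= 0 or self.max_tss_distance <= 0:
            raise ConfigError("annotation windows must be > 0")


@dataclass
class EnrichmentConfig:
    n_perm: int = 500
    weight_p: float = 1.0
    top_k: int = 10

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ConfigError("enrichment.n_perm must be >= 100")
        if self.top_k < 1:
            raise ConfigError("enrichment.top_k must be >= 1")


@dataclass
class PipelineConfig:
    seed: int = 7
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    write_fragments: bool = False

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.validate()

    def validate(self) -> None:
        for section in (self.cutoffs, self.overlap, self.regions,
                        self.annotation, self.enrichment):
            section.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        sections = {
            "simulation": sim.SimulationConfig,
            "cutoffs": Cutoffs,
            "overlap": OverlapConfig,
            "regions": RegionConfig,
            "annotation": AnnotationConfig,
            "enrichment": EnrichmentConfig,
        }
        scalar_keys = {"seed", "write_fragments"}
        unknown = set(raw) - set(sections) - scalar_keys
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            k: raw[k] for k in scalar_keys if k in raw
        }
        for name, klass in sections.items():
            if name not in raw:
                continue
            sub = raw[name]
            if not isinstance(sub, Mapping):
                raise ConfigError(f"config section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(
                    f"unknown key(s) in config section {name!r}: {sorted(bad)}"
                )
            try:
                kwargs[name] = klass(**sub)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid {name} config: {exc}") from exc
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must contain a YAML mapping")
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    truth: sim.SimulationTruth
    chip_consensus: cp.ConsensusPeakSet
    master_peaks: list[Peak]
    atac_results: list[cp.DifferentialResult]
    rna_results_headline: list[cp.DifferentialResult]
    rna_results_integration: list[cp.DifferentialResult]
    region_enrichment: pd.Series
    stratified: strat.StratifiedPeaks
    profiles: dict[str, dict[str, np.ndarray]]  # cell -> {WT, KO} -> profile
    bound_genes: set[str]
    gene_atac_classes: dict[str, str]
    target_table: pd.DataFrame
    enrichment_results: list[enr.EnrichmentResult]
    ora_results: list[enr.EnrichmentResult]
    recovery: sim.RecoveryReport
    fragment_qc: cp.FragmentSizeQC


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the full tri-omic integration on simulated data.

    Writes every intermediate table plus a manifest of the parameters used
    and sha256 hashes of the outputs; reruns with the same config are
    byte-identical.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.simulation
    stage = "simulate"
    try:
        genome, genes = sim.simulate_genome(scfg)
        truth = sim.make_truth(scfg, genes)
        chip_reps, chip_frags = sim.simulate_chip(scfg, truth, genes, genome)
        atac_frags, atac_calls, _sites = sim.simulate_atac(
            scfg, truth, genes, genome
        )
        rna_raw = sim.simulate_rna(scfg, truth, genes)
        collection = sim.make_gene_set_fixtures(
            truth, rng=np.random.default_rng([scfg.seed, 5])
        )

        write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
        write_bed12_genes(genes, outdir / "genes.bed12")
        truth.to_tsv(outdir / "truth.tsv")
        for rep_id, peaks in chip_reps.items():
            write_bed(peaks, outdir / f"{rep_id}.peaks.bed")
        for genotype, reps in atac_calls.items():
            for rep_id, peaks in reps.items():
                write_bed(peaks, outdir / f"atac_{rep_id}.peaks.bed")
        rna_raw.to_tsv(outdir / "rna_counts.tsv")
        enr.write_gmt(collection, outdir / "gene_sets.gmt")
        if cfg.write_fragments:
            for name, fs in {**atac_frags, **chip_frags}.items():
                write_bed(
                    [Peak(interval=f) for f in fs.fragments],
                    outdir / f"fragments_{name}.bed",
                )

        stage = "chip_consensus"
        chip_consensus = cp.aggregate_replicates(
            chip_reps, min_overlap=cfg.overlap.consensus_min, sample_id="chip"
        )
        write_bed(chip_consensus.peaks, outdir / "chip_consensus.bed",
                  with_support=True)

        stage = "atac_consensus"
        atac_consensus = {
            genotype: cp.aggregate_replicates(
                reps, min_overlap=cfg.overlap.consensus_min, sample_id=genotype
            )
            for genotype, reps in atac_calls.items()
        }
        master = cp.union_peak_lists(list(atac_consensus.values()))
        write_bed(master, outdir / "atac_master_peaks.bed", with_support=True)

        stage = "atac_counting"
        atac_cm = cp.count_fragments_in_peaks(atac_frags, master)
        atac_cm.to_tsv(outdir / "atac_counts.tsv")
        atac_cpm = cp.normalize(atac_cm, "CPM")
        wt_samples = [s for s in atac_cm.sample_ids if s.startswith("WT")]
        ko_samples = [s for s in atac_cm.sample_ids if s.startswith("KO")]
        atac_results = cp.classify_differential(
            atac_cpm, wt_samples, ko_samples, lfc_cutoff=cfg.cutoffs.atac_lfc
        )
        _write_tsv(cp.differential_to_frame(atac_results),
                   outdir / "atac_differential.tsv")
        qc = cp.fragment_size_qc(atac_frags[wt_samples[0]])

        stage = "annotation"
        fmap = ann.build_feature_map(
            genes, genome, tss_halfwidth=cfg.annotation.tss_halfwidth
        )
        enrich_by_class = ann.region_proportion_enrichment(master, fmap)
        enrich_by_class.rename_axis("feature_class").reset_index().pipe(
            _write_tsv, outdir / "region_enrichment.tsv"
        )
        assignments = ann.assign_peaks_to_genes(
            master, genes, max_tss_distance=cfg.annotation.max_tss_distance,
            fmap=fmap,
        )
        _write_tsv(ann.assignments_to_frame(assignments),
                   outdir / "peak_annotation.tsv")
        peak_classes = {r.feature_id: r.cls for r in atac_results}
        peak_lfc = {r.feature_id: r.log2fc for r in atac_results}
        gene_atac = ann.gene_level_atac_classes(assignments, peak_classes, peak_lfc)

        stage = "stratification"
        class_by_peak = [(p, peak_classes[cp.peak_id(p)]) for p in master]
        stratified = strat.stratify_by_binding(
            class_by_peak, chip_consensus.peaks,
            min_overlap_bp=cfg.overlap.binding_min_bp,
        )
        counts_rows = [
            {"binding": b, "class": c, "n_peaks": n}
            for (b, c), n in stratified.counts().items()
        ]
        _write_tsv(pd.DataFrame(counts_rows), outdir / "stratification_counts.tsv")
        for (b, c), peaks in stratified.cells.items():
            write_bed(peaks, outdir / f"atac_{b}_{c}.bed")

        wt_pool = cp.FragmentSet(
            sample_id="WT",
            fragments=[f for s in wt_samples for f in atac_frags[s].fragments],
        )
        ko_pool = cp.FragmentSet(
            sample_id="KO",
            fragments=[f for s in ko_samples for f in atac_frags[s].fragments],
        )
        profiles: dict[str, dict[str, np.ndarray]] = {}
        profile_cols: dict[str, np.ndarray] = {}
        for (b, c) in (("bound", "up"), ("bound", "down"),
                       ("unbound", "up"), ("unbound", "down")):
            peaks = stratified.cells[(b, c)]
            if not peaks:
                continue
            regions = strat.make_regions(peaks, flank=cfg.regions.flank,
                                         genome=genome)
            if not regions:
                continue
            m_wt, m_ko = strat.paired_coverage_matrices(
                wt_pool, ko_pool, regions, bin_size=cfg.regions.bin
            )
            cell = f"{b}_{c}"
            profiles[cell] = {"WT": strat.profile(m_wt), "KO": strat.profile(m_ko)}
            profile_cols[f"{cell}_WT"] = profiles[cell]["WT"]
            profile_cols[f"{cell}_KO"] = profiles[cell]["KO"]
        if profile_cols:
            n_bins = 2 * cfg.regions.flank // cfg.regions.bin
            offsets = np.arange(n_bins) * cfg.regions.bin - cfg.regions.flank
            prof_df = pd.DataFrame({"bin_start_offset": offsets, **profile_cols})
            _write_tsv(prof_df, outdir / "profiles.tsv")

        stage = "rna_differential"
        rna_tpm = cp.normalize(rna_raw, "TPM")
        rna_wt = [s for s in rna_tpm.sample_ids if s.startswith("WT")]
        rna_ko = [s for s in rna_tpm.sample_ids if s.startswith("KO")]
        rna_headline = cp.classify_differential(
            rna_tpm, rna_wt, rna_ko, lfc_cutoff=cfg.cutoffs.rna_lfc,
            use_fdr=cfg.cutoffs.use_fdr, q_max=cfg.cutoffs.q_max,
        )
        rna_integration = cp.classify_differential(
            rna_tpm, rna_wt, rna_ko, lfc_cutoff=cfg.cutoffs.rna_integration_lfc,
            use_fdr=cfg.cutoffs.use_fdr, q_max=cfg.cutoffs.q_max,
        )
        _write_tsv(cp.differential_to_frame(rna_headline),
                   outdir / "rna_differential_headline.tsv")
        _write_tsv(cp.differential_to_frame(rna_integration),
                   outdir / "rna_differential_integration.tsv")

        stage = "target_integration"
        chip_assign = ann.assign_peaks_to_genes(
            chip_consensus.peaks, genes,
            max_tss_distance=cfg.annotation.max_tss_distance, fmap=fmap,
        )
        bound_genes = {a.gene_id for a in chip_assign if a.gene_id is not None}
        table = ti.call_direct_targets(bound_genes, rna_integration)
        table = ti.classify_mechanism(table, gene_atac)
        _write_tsv(table, outdir / "direct_targets.tsv")

        stage = "enrichment"
        ranked = sorted(
            ((r.feature_id, r.log2fc) for r in rna_integration),
            key=lambda t: -t[1],
        )
        pre_results = enr.preranked_collection(
            ranked, collection, weight_p=cfg.enrichment.weight_p,
            n_perm=cfg.enrichment.n_perm, seed=scfg.seed,
        )
        top = enr.top_k(pre_results, k=cfg.enrichment.top_k)
        _write_tsv(
            pd.DataFrame(
                {
                    "set_name": [r.set_name for r in top],
                    "es": [r.es for r in top],
                    "nes": [r.nes for r in top],
                    "p_value": [r.p_value for r in top],
                    "q_value": [r.q_value for r in top],
                }
            ),
            outdir / "enrichment_preranked.tsv",
        )
        universe = [r.feature_id for r in rna_integration]
        up_targets = set(
            table.loc[
                table["bound"] & (table["rna_class"] == "up"), "gene_id"
            ]
        )
        ora_results = []
        if up_targets:
            for name in sorted(collection.sets):
                ora_results.append(
                    enr.hypergeometric_ora(
                        up_targets, collection.sets[name], universe, set_name=name
                    )
                )
        _write_tsv(
            pd.DataFrame(
                {
                    "set_name": [r.set_name for r in ora_results],
                    "overlap": [r.overlap for r in ora_results],
                    "odds_ratio": [r.odds_ratio for r in ora_results],
                    "p_value": [r.p_value for r in ora_results],
                }
            ),
            outdir / "enrichment_ora.tsv",
        )

        stage = "recovery"
        recovery = sim.score_recovery(table, truth)
        with (outdir / "recovery.json").open("w") as fh:
            json.dump(recovery.to_dict(), fh, indent=2, sort_keys=True)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "parameters": cfg.to_dict(),
        "outputs": {},
    }
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["outputs"][f.name] = file_sha256(f)
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=cfg,
        outdir=outdir,
        truth=truth,
        chip_consensus=chip_consensus,
        master_peaks=master,
        atac_results=atac_results,
        rna_results_headline=rna_headline,
        rna_results_integration=rna_integration,
        region_enrichment=enrich_by_class,
        stratified=stratified,
        profiles=profiles,
        bound_genes=bound_genes,
        gene_atac_classes=gene_atac,
        target_table=table,
        enrichment_results=pre_results,
        ora_results=ora_results,
        recovery=recovery,
        fragment_qc=qc,
    )
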