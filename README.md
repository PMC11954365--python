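# chromtriad

Tri-omic (ChIP-seq / ATAC-seq / RNA-seq) integration for identifying genes
whose expression is controlled by a chromatin remodeler's **direct binding**.

## The problem

Knocking out an ATP-dependent chromatin remodeler changes the expression of
thousands of genes, but only some of those changes are direct consequences of
the factor acting at the locus. A standard desk-scale strategy to separate
direct from indirect effects combines three assays on wild-type (WT) versus
knockout (KO) cells:

* **ChIP-seq** (antibody vs IgG, duplicate replicates) — where the factor binds;
* **ATAC-seq** (duplicate samples per genotype) — where chromatin accessibility
  changes when the factor is lost;
* **RNA-seq** (replicated counts per genotype) — which genes change expression.

`chromtriad` implements that analysis chain, starting from called peaks,
fragment intervals and count matrices (peak calling and alignment are
upstream, out of scope):

1. **Replicate-consensus aggregation** — peaks from different replicates are
   transitively clustered wherever their overlap is ≥ 50% of the shorter
   peak, clusters are collapsed to their hull, and clusters supported by a
   single replicate are removed.
2. **Master peak list** — the union (any-overlap merge) of all per-sample
   consensus sets.
3. **Counting and normalization** — fragments are assigned to the unique
   master peak containing their midpoint; counts are normalized as CPM, or
   TPM for gene-level expression (`TPM_ij = (c_ij/ℓ_i) / Σ_k (c_kj/ℓ_k) × 10⁶`).
4. **Tri-class differential calling** — each feature is classified
   `up` / `down` / `same` from
   `log2FC = log2((mean_KO + 1)/(mean_WT + 1))` with an inclusive cutoff
   (accessibility 0.4; headline expression 1.0; integration 0.7; all
   configurable, with an optional Welch-t + Benjamini–Hochberg FDR gate).
5. **Annotation** — every base is labeled TSS > 5′UTR > exon > intron >
   intergenic; peak proportions per class are normalized by the class's
   genomic share; peaks map to the gene with the nearest TSS within 5 kb
   (midpoint-containment fallback).
6. **Binding stratification** — differential ATAC peaks are split
   {bound, unbound} × {up, down, same} by ≥ 1 bp overlap with consensus
   ChIP peaks, and paired WT/KO coverage matrices are built over ± 1.5 kb
   regions around peak centers (50 bp bins).
7. **Direct-target taxonomy** — a gene is a direct target iff it is bound
   and differentially expressed; adding the gene-level accessibility class
   (the gene's largest-|log2FC| assigned peak) yields four mechanism
   categories:

   | RNA (KO vs WT) | ATAC (KO vs WT) | mechanism (WT role of the factor) |
   |---|---|---|
   | up   | up   | `repressed_via_closing` |
   | up   | down | `repressed_via_opening` |
   | down | up   | `activated_via_closing` |
   | down | down | `activated_via_opening` |

8. **Gene-set statistics** — hypergeometric over-representation and a
   preranked weighted-KS enrichment score (ES/NES) with a gene-label
   permutation null.

A coupled synthetic-data generator (`chromtriad.synthetic_data`) emulates
the full study design with a **planted** per-gene taxonomy, so the entire
chain is testable end to end with exact recovery scoring — no downloads
required.

## Worked example

```bash
chromtriad run --seed 7 --out runs/demo
```

runs the simulated study at its default design (1000 genes on 2 × 5 Mb
chromosomes; 20 genes planted per mechanism category; accessibility effect
1.5 log2, expression effect 2.0 log2; two replicates per assay and
genotype) and prints the recovery of the planted taxonomy:

```
             category  planted  predicted  recovered  recall  precision
repressed_via_closing       20         20         20     1.0   1.000000
repressed_via_opening       20         21         20     1.0   0.952381
activated_via_closing       20         21         20     1.0   0.952381
activated_via_opening       20         21         20     1.0   0.952381
```

Every planted gene is recovered in its correct category; the handful of
extra predictions are null genes whose replicate noise crossed both the
expression and accessibility cutoffs. The run directory contains, among
others:

* `atac_differential.tsv` — 1000 master peaks classified 70 up / 66 down /
  864 same (KO vs WT, cutoff 0.4);
* `direct_targets.tsv` — per gene: bound flag, RNA class, ATAC class,
  mechanism; 180 bound genes, 48 up-regulated and 47 down-regulated direct
  targets at the 0.7 integration cutoff:

  ```
  gene_id  bound  rna_class  atac_class  mechanism
  g0012    True   up         up          repressed_via_closing
  g0017    True   down       down        activated_via_opening
  ```
* `profiles.tsv` — paired WT/KO mean coverage around bound differential
  peaks (the KO signal exceeds WT at the center of bound-up regions);
* `region_enrichment.tsv` — promoter-proximal peaks give a TSS-class
  normalized proportion of 10.0 (all simulated peaks sit at TSSs, which
  cover 10% of this genome) and ~0 elsewhere;
* `recovery.json`, `manifest.json` — recovery report and a manifest of all
  parameters and output hashes (reruns are byte-identical).

The fragment-size QC of the simulated ATAC libraries reports 55% of
fragments below 100 bp with a modal size of ~205 bp and a detected
mono-nucleosome periodicity peak — the signature of a healthy
tagmentation library.

Subcommands (`chromtriad consensus / diff / annotate / stratify /
integrate / enrich / simulate`) expose each stage on plain BED/TSV/GMT
files; see `chromtriad --help`.

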