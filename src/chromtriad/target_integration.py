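"""Gene-level tri-omic integration.

A *direct target* is a gene that is both bound (consensus binding peak
assigned to it) and differentially expressed.  Adding the gene-level
accessibility class yields a four-way mechanism taxonomy describing how the
remodeler controls the gene in wild-type cells (classes are read from the
knockout contrast, so e.g. RNA up + ATAC up in the knockout means the
factor normally represses the gene by keeping its locus closed):

==========  ===========  ==========================
rna_class   atac_class   mechanism
==========  ===========  ==========================
up          up           repressed_via_closing
up          down         repressed_via_opening
down        up           activated_via_closing
down        down         activated_via_opening
==========  ===========  ==========================

Any other combination (not bound, RNA same, or no classified accessibility
peak at the gene) is ``unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus_peaks import DifferentialResult

MECHANISMS = (
    "repressed_via_closing",
    "repressed_via_opening",
    "activated_via_closing",
    "activated_via_opening",
)

MECHANISM_MAP: dict[tuple[str, str], str] = {
    ("up", "up"): "repressed_via_closing",
    ("up", "down"): "repressed_via_opening",
    ("down", "up"): "activated_via_closing",
    ("down", "down"): "activated_via_opening",
}

TABLE_COLUMNS = ["gene_id", "bound", "rna_class", "atac_class", "mechanism"]


def call_direct_targets(
    bound_genes: Iterable[str],
    rna: Sequence[DifferentialResult],
) -> pd.DataFrame:
    """Build the direct-target table over the whole RNA universe.

    A gene is a direct target iff it is bound and its RNA class is up or
    down.  The returned frame covers every gene in the RNA results, with
    ``atac_class`` initialized to ``none`` and ``mechanism`` to
    ``unresolved`` (filled by :func:`classify_mechanism`).
    """
    if not rna:
        raise ValueError("empty RNA universe")
    bound = set(bound_genes)
    rows = []
    for r in rna:
        rows.append(
            {
                "gene_id": r.feature_id,
                "bound": r.feature_id in bound,
                "rna_class": r.cls,
                "atac_class": "none",
                "mechanism": "unresolved",
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values("gene_id", ignore_index=True)


def is_direct_target(df: pd.DataFrame) -> pd.Series:
    return df["bound"] & df["rna_class"].isin(["up", "down"])


def classify_mechanism(
    targets: pd.DataFrame,
    atac_gene_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Fill ``atac_class`` and ``mechanism`` on a direct-target table.

    Genes without a classified accessibility peak keep ``atac_class none``;
    mechanism is assigned only for bound, RNA-differential genes with an
    up/down accessibility class, per the module-level mapping.
    """
    df = targets.copy()
    df["atac_class"] = [
        atac_gene_classes.get(g, "none") for g in df["gene_id"]
    ]
    mech = []
    for _, row in df.iterrows():
        if row["bound"] and (row["rna_class"], row["atac_class"]) in MECHANISM_MAP:
            mech.append(MECHANISM_MAP[(row["rna_class"], row["atac_class"])])
        else:
            mech.append("unresolved")
    df["mechanism"] = mech
    return df


def mechanism_counts(df: pd.DataFrame) -> dict[str, int]:
    counts = {m: int((df["mechanism"] == m).sum()) for m in MECHANISMS}
    counts["unresolved_targets"] = int(
        (is_direct_target(df) & (df["mechanism"] == "unresolved")).sum()
    )
    return counts


@dataclass(frozen=True)
class OverlapSummary:
    """Shared/specific decomposition of two gene sets (e.g. two cell types)."""

    n_a: int
    n_b: int
    shared: int
    specific_a: int
    specific_b: int
    shared_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.shared + self.specific_a == self.n_a
        assert self.shared + self.specific_b == self.n_b


def cross_celltype_overlap(a: Iterable[str], b: Iterable[str]) -> OverlapSummary:
    """Exact intersection/difference sizes for two gene sets sharing one
    namespace."""
    sa, sb = set(a), set(b)
    shared = sa & sb
    return OverlapSummary(
        n_a=len(sa),
        n_b=len(sb),
        shared=len(shared),
        specific_a=len(sa - sb),
        specific_b=len(sb - sa),
        shared_genes=tuple(sorted(shared)),
    )
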