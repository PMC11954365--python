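"""Gene-set statistics: hypergeometric over-representation and a preranked
weighted Kolmogorov-Smirnov enrichment score with a gene-label permutation
null.

The preranked statistic walks the ranked gene list accumulating
``|score|^p / sum_hits |score|^p`` at set members and ``-1/(N - Nh)`` at
non-members; the enrichment score (ES) is the running-sum extremum of
largest magnitude.  Significance comes from re-scoring random same-size
gene sets: ``p = (1 + #{|null ES| >= |ES|}) / (1 + n_perm)`` (two-sided by
magnitude, exactly uniform under the null by exchangeability), and
``NES = ES / mean |null ES of the same sign|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# gene-set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets, optionally restricted to an explicit universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if self.universe is not None and not genes <= self.universe:
                extra = sorted(genes - self.universe)[:5]
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {extra}"
                )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 GMT columns")
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(
    collection: GeneSetCollection, path: str | Path, description: str = "na"
) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    p_value: float
    q_value: float | None = None
    es: float | None = None
    nes: float | None = None
    odds_ratio: float | None = None
    overlap: int | None = None
    leading_edge: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p out of range: {self.p_value}")
        if self.es is not None and abs(self.es) > 1 + 1e-12:
            raise ValueError(f"|ES| must be <= 1, got {self.es}")


# ---------------------------------------------------------------------------
# over-representation (hypergeometric tail)
# ---------------------------------------------------------------------------

def hypergeometric_ora(
    query: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of query / gene-set overlap.

    ``p = P(X >= k)`` where X is the overlap of a random query of the same
    size; the odds ratio comes from the 2x2 table with a Haldane 0.5
    correction when any cell is zero.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    s = set(gene_set) & uni
    if set(query) - uni or set(gene_set) - uni:
        raise ValueError("query and gene set must be subsets of the universe")
    m, n_set, n_query = len(uni), len(s), len(q)
    k = len(q & s)
    p = float(sps.hypergeom.sf(k - 1, m, n_set, n_query))
    a, b = k, n_query - k
    c, d = n_set - k, m - n_set - n_query + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        set_name=set_name, p_value=min(1.0, p), odds_ratio=float(odds), overlap=k
    )


# ---------------------------------------------------------------------------
# preranked weighted-KS enrichment
# ---------------------------------------------------------------------------

def _prepare_ranking(
    ranked: Sequence[tuple[str, float]]
) -> tuple[list[str], np.ndarray]:
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in ranking")
    scores = np.array([s for _, s in ranked], dtype=float)
    order = np.argsort(-scores, kind="stable")
    return [genes[i] for i in order], scores[order]


def _running_sum(
    hits: np.ndarray, scores: np.ndarray, weight_p: float
) -> np.ndarray:
    n = hits.size
    nh = int(hits.sum())
    w = np.abs(scores) ** weight_p
    denom = w[hits].sum()
    inc = np.zeros(n)
    if denom > 0:
        inc[hits] = w[hits] / denom
    else:  # all hit scores zero: fall back to equal weights
        inc[hits] = 1.0 / nh
    if nh < n:
        inc[~hits] = -1.0 / (n - nh)
    return np.cumsum(inc)


def preranked_es(
    ranked: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running sum for one gene set.

    ``ranked`` is (gene, score) pairs; they are ordered by descending score
    internally (stable for ties).  ES is the running-sum value of largest
    magnitude (first such position on ties).
    """
    genes, scores = _prepare_ranking(ranked)
    members = set(gene_set)
    hits = np.array([g in members for g in genes])
    if not hits.any():
        raise ValueError("gene set shares no genes with the ranking")
    running = _running_sum(hits, scores, weight_p)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    scores: np.ndarray, nh: int, weight_p: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized ES for ``n_perm`` random same-size gene sets."""
    n = scores.size
    w = np.abs(scores) ** weight_p
    # random hit indicator matrix: choose nh positions per row
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, nh - 1, axis=1)[:, :nh]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    hit_w = np.where(hits, w[None, :], 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    inc = np.where(denom > 0, hit_w / np.where(denom == 0, 1, denom), 0.0)
    if denom.min() == 0:
        inc[denom[:, 0] == 0] = np.where(
            hits[denom[:, 0] == 0], 1.0 / nh, 0.0
        )
    if nh < n:
        inc = inc - np.where(hits, 0.0, 1.0 / (n - nh))
    running = np.cumsum(inc, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pos]


def preranked_significance(
    ranked: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    set_name: str = "",
) -> EnrichmentResult:
    """Permutation significance for the preranked enrichment score.

    The null re-scores ``n_perm`` uniformly random gene sets of the same
    size (gene-label permutation).  Reproducible for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes, scores = _prepare_ranking(ranked)
    members = set(gene_set)
    hits = np.array([g in members for g in genes])
    if not hits.any():
        raise ValueError("gene set shares no genes with the ranking")
    running = _running_sum(hits, scores, weight_p)
    pos = int(np.argmax(np.abs(running)))
    es = float(running[pos])
    if es >= 0:
        leading = tuple(g for g, h in zip(genes[: pos + 1], hits[: pos + 1]) if h)
    else:
        leading = tuple(g for g, h in zip(genes[pos + 1 :], hits[pos + 1 :]) if h)

    null = _null_es(scores, int(hits.sum()), weight_p, n_perm, rng)
    p = float((1 + np.sum(np.abs(null) >= abs(es))) / (1 + n_perm))
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = float(es / denom) if denom > 0 else float("nan")
    return EnrichmentResult(
        set_name=set_name, p_value=p, es=es, nes=nes, leading_edge=leading
    )


def preranked_collection(
    ranked: Sequence[tuple[str, float]],
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every set in a collection; q-values by Benjamini-Hochberg on
    the permutation p-values (simpler than ES-pooling FDR, and testable)."""
    rng = np.random.default_rng(seed)
    results = []
    for name in sorted(collection.sets):
        try:
            res = preranked_significance(
                ranked, collection.sets[name], weight_p, n_perm, rng, set_name=name
            )
        except ValueError:
            continue  # set disjoint from ranking
        results.append(res)
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def top_k(results: Sequence[EnrichmentResult], k: int = 10) -> list[EnrichmentResult]:
    """The k most enriched sets: smallest p, ties by |NES| (or odds ratio)
    descending, then name ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def sort_key(r: EnrichmentResult) -> tuple:
        strength = r.nes if r.nes is not None else r.odds_ratio
        strength = abs(strength) if strength is not None else 0.0
        return (r.p_value, -strength, r.set_name)

    return sorted(results, key=sort_key)[:k]
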