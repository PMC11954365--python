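"""Independent brute-force oracles used by unit and acceptance tests.

Everything here works on explicit per-base sets and graph traversal so it
shares no code path with the package's sweep/union-find implementations.
"""

from __future__ import annotations

from chromtriad.genomic_core import GenomicInterval, Peak


def bases(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, b) for b in range(iv.start, iv.end)}


def overlap_fraction_bruteforce(a: GenomicInterval, b: GenomicInterval) -> float:
    shared = bases(a) & bases(b)
    if not shared:
        return 0.0
    return len(shared) / min(len(bases(a)), len(bases(b)))


def _components(n: int, edges: set[tuple[int, int]]) -> list[list[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        comps.append(sorted(comp))
    return comps


def aggregate_bruteforce(
    replicate_peaks: dict[str, list[Peak]], min_overlap: float
) -> list[tuple[str, int, int, frozenset[str]]]:
    """Consensus aggregation by explicit graph clustering on per-base sets.

    Returns (chrom, start, end, replicate set) tuples sorted by position,
    after (1) transitive clustering at the overlap threshold, (2) hulls,
    (3) dropping single-replicate clusters, (4) merging any hulls that
    still share a base.
    """
    items: list[tuple[str, GenomicInterval]] = []
    for rep, peaks in replicate_peaks.items():
        for p in peaks:
            items.append((rep, p.interval))
    edges = set()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if overlap_fraction_bruteforce(items[i][1], items[j][1]) >= min_overlap:
                edges.add((i, j))
    hulls: list[tuple[str, int, int, frozenset[str]]] = []
    for comp in _components(len(items), edges):
        reps = frozenset(items[k][0] for k in comp)
        if len(reps) < 2:
            continue
        ivs = [items[k][1] for k in comp]
        hulls.append(
            (ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs), reps)
        )
    # merge hulls sharing >=1 base
    edges2 = set()
    for i in range(len(hulls)):
        for j in range(i + 1, len(hulls)):
            a = bases(GenomicInterval(hulls[i][0], hulls[i][1], hulls[i][2]))
            b = bases(GenomicInterval(hulls[j][0], hulls[j][1], hulls[j][2]))
            if a & b:
                edges2.add((i, j))
    merged = []
    for comp in _components(len(hulls), edges2):
        chrom = hulls[comp[0]][0]
        start = min(hulls[k][1] for k in comp)
        end = max(hulls[k][2] for k in comp)
        reps = frozenset().union(*(hulls[k][3] for k in comp))
        merged.append((chrom, start, end, reps))
    return sorted(merged)


def union_bruteforce(
    peak_lists: list[list[GenomicInterval]],
) -> list[tuple[str, int, int]]:
    """Any-overlap union across lists via per-base component analysis.

    Abutting (non-overlapping) intervals stay separate: components require
    at least one shared base.
    """
    items = [iv for lst in peak_lists for iv in lst]
    edges = set()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if bases(items[i]) & bases(items[j]):
                edges.add((i, j))
    out = []
    for comp in _components(len(items), edges):
        ivs = [items[k] for k in comp]
        out.append(
            (ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs))
        )
    return sorted(out)


def running_sum_bruteforce(
    ranked: list[tuple[str, float]], gene_set: set[str], weight_p: float
) -> tuple[float, list[float]]:
    """Step-by-step preranked enrichment running sum (plain python floats)."""
    ordered = sorted(ranked, key=lambda t: -t[1])
    hits = [g in gene_set for g, _ in ordered]
    n = len(ordered)
    nh = sum(hits)
    weights = [abs(s) ** weight_p for _, s in ordered]
    denom = sum(w for w, h in zip(weights, hits) if h)
    running = []
    total = 0.0
    for (g, s), h, w in zip(ordered, hits, weights):
        if h:
            total += (w / denom) if denom > 0 else 1.0 / nh
        else:
            total -= 1.0 / (n - nh)
        running.append(total)
    best = max(range(n), key=lambda i: (abs(running[i]), -i))
    return running[best], running
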