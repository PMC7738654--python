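"""Over-representation analysis of gene lists against gene-set collections.

Given a query list (e.g. the upregulated genes) and a universe (the detected
genes — enrichment background must be the set that could have been called),
each gene set is scored with the one-sided upper-tail hypergeometric
probability of the observed overlap,

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the universe size, K the set size within the universe, n the query
size and k the overlap.  Up- and down-regulated lists are always analysed
separately.  A co-annotation gene network is also provided: two query genes
are linked when they share at least ``w`` gene sets, which yields a
pathway-style interaction sketch without external database retrieval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: TERM <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with an analysis universe.

    Sets that become empty after intersection are dropped with a warning.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        trimmed = {}
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            if inter:
                trimmed[name] = inter
            else:
                warnings.warn(f"gene set {name!r} empty after universe intersection", stacklevel=2)
        self.sets = trimmed

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str]) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), universe=set(universe))


def ora(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation rows, sorted by ascending p then term.

    Columns: term, K (set size in universe), n (query size), k (overlap),
    p, neg_log10_p, genes (comma-joined overlap).
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    query_set = set(query)
    outside = query_set - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2
        )
    query_set &= universe
    if not query_set:
        warnings.warn("query empty after universe intersection", stacklevel=2)
    n, N = len(query_set), len(universe)
    records = []
    for term, genes in collection.sets.items():
        overlap = sorted(query_set & genes)
        k, K = len(overlap), len(genes)
        # upper tail P(X >= k); sf(k-1) is exact, and P(X >= 0) = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            {
                "term": term,
                "K": K,
                "n": n,
                "k": k,
                "p": p,
                "neg_log10_p": -math.log10(p) if p > 0 else float("inf"),
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame.from_records(
        records, columns=["term", "K", "n", "k", "p", "neg_log10_p", "genes"]
    )
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def shared_term_network(
    query: Iterable[str], collection: GeneSetCollection, min_shared: int = 1
) -> pd.DataFrame:
    """Undirected co-annotation edges among query genes.

    Edge (g1, g2) exists when the pair co-occurs in >= ``min_shared`` sets;
    weight is the co-occurrence count.  Columns: gene1, gene2, weight, with
    gene1 < gene2 and rows sorted.
    """
    query_set = set(query) & collection.universe
    weights: dict[tuple[str, str], int] = {}
    for genes in collection.sets.values():
        members = sorted(query_set & genes)
        for g1, g2 in combinations(members, 2):
            weights[(g1, g2)] = weights.get((g1, g2), 0) + 1
    records = [
        {"gene1": g1, "gene2": g2, "weight": w}
        for (g1, g2), w in sorted(weights.items())
        if w >= min_shared
    ]
    return pd.DataFrame.from_records(records, columns=["gene1", "gene2", "weight"])


def synthetic_collection(
    universe: Iterable[str],
    enriched_genes: Iterable[str],
    rng,
    n_sets: int = 20,
    set_size: int = 25,
    n_enriched_sets: int = 4,
    enriched_overlap: float = 0.6,
) -> GeneSetCollection:
    """Synthetic gene-set collection over simulated gene names.

    Builds ``n_sets`` random sets from the universe, the first
    ``n_enriched_sets`` of which draw ``enriched_overlap`` of their members
    from ``enriched_genes`` — giving downstream enrichment something real to
    find on simulated data, where no curated annotation exists.
    """
    universe = sorted(set(universe))
    enriched = sorted(set(enriched_genes) & set(universe))
    rest = sorted(set(universe) - set(enriched))
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        if i < n_enriched_sets and enriched:
            n_hit = min(int(round(enriched_overlap * set_size)), len(enriched))
            hits = list(rng.choice(enriched, size=n_hit, replace=False))
            fill = list(rng.choice(rest, size=set_size - n_hit, replace=False))
            sets[f"SYNTH_ENRICHED_{i + 1:02d}"] = set(hits) | set(fill)
        else:
            members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
            sets[f"SYNTH_RANDOM_{i + 1:02d}"] = set(members)
    return GeneSetCollection(sets=sets, universe=set(universe))
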