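"""MCScanX-style classification of family genes into duplication classes
(singleton / dispersed / proximal / tandem / WGD-segmental) and the
per-species percentage summaries.

Classification follows the documented MCScanX precedence: a gene with no
family homolog is a singleton; a gene inside a collinear block pair is
WGD/segmental; a rank-adjacent homolog makes it tandem; a homolog within
the proximity window makes it proximal; anything else is dispersed.
Defaults mirror MCScanX (top 5 hits per query, blocks of >= 5 pairs,
proximity window 10 genes), all exposed in the signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import ScoreMatrix
from .seqio import GeneModel

__all__ = [
    "DUP_CLASSES",
    "CollinearBlock",
    "build_hit_graph",
    "detect_collinear_blocks",
    "classify_duplications",
    "summarize_dup_table",
    "species_summary_table",
]

DUP_CLASSES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass(frozen=True)
class CollinearBlock:
    """An ordered run of homologous gene pairs on two chromosome segments."""

    chrom_a: str
    chrom_b: str
    pairs: tuple[tuple[str, str], ...]  # gene id pairs, ordered along chrom_a

    @property
    def size(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


def build_hit_graph(
    scores: ScoreMatrix,
    evalue_max: float = 1e-5,
    top_n: int = 5,
) -> dict[frozenset[str], float]:
    """Homolog pair set from all-vs-all scores.

    Keeps, per query, at most ``top_n`` non-self subjects at
    E <= ``evalue_max``, then symmetrizes (a pair is kept if either
    direction kept it).  Returns pair -> best E-value.
    """
    graph: dict[frozenset[str], float] = {}
    for query in scores.ids:
        for subject, evalue in scores.hits(query, evalue_max)[:top_n]:
            key = frozenset((query, subject))
            if key not in graph or evalue < graph[key]:
                graph[key] = evalue
    return graph


def _chain_pairs(
    pairs: list[tuple[int, int, str, str]], min_block_size: int, max_gap: int
) -> list[list[tuple[str, str]]]:
    """Longest-increasing-chain DP over (rank_a, rank_b) pairs.

    Successive pairs in a chain must advance by 1..max_gap on both
    segments.  Returns maximal non-overlapping chains, longest first.
    """
    pairs = sorted(pairs)
    n = len(pairs)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ra_i, rb_i = pairs[i][0], pairs[i][1]
        for j in range(i):
            ra_j, rb_j = pairs[j][0], pairs[j][1]
            if 0 < ra_i - ra_j <= max_gap and 0 < rb_i - rb_j <= max_gap:
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
    used = [False] * n
    chains: list[list[tuple[str, str]]] = []
    for i in sorted(range(n), key=lambda i: -best_len[i]):
        if used[i] or best_len[i] < min_block_size:
            continue
        chain_idx = []
        k = i
        while k != -1:
            chain_idx.append(k)
            k = prev[k]
        if any(used[k] for k in chain_idx):
            continue
        for k in chain_idx:
            used[k] = True
        chain_idx.reverse()
        chains.append([(pairs[k][2], pairs[k][3]) for k in chain_idx])
    return chains


def detect_collinear_blocks(
    hit_graph: Mapping[frozenset[str], float],
    genes: Mapping[str, GeneModel],
    min_block_size: int = 5,
    max_gap: int = 25,
    gene_of_protein: Mapping[str, str] | None = None,
) -> list[CollinearBlock]:
    """Collinear blocks: chains of homologous gene pairs whose ranks
    advance monotonically on both segments with gaps <= ``max_gap``.

    Antiparallel chains (one segment reversed) are allowed.  Hit-graph
    node ids are translated through ``gene_of_protein`` when given.
    """
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for pair in hit_graph:
        a, b = sorted(pair)
        if gene_of_protein is not None:
            a, b = gene_of_protein.get(a, a), gene_of_protein.get(b, b)
        if a == b or a not in genes or b not in genes:
            continue
        ga, gb = genes[a], genes[b]
        if (gb.chrom, gb.rank) < (ga.chrom, ga.rank):
            ga, gb = gb, ga
            a, b = b, a
        by_chrom_pair.setdefault((ga.chrom, gb.chrom), []).append(
            (ga.rank, gb.rank, a, b)
        )
    blocks: list[CollinearBlock] = []
    for (ca, cb), pairs in sorted(by_chrom_pair.items()):
        found = _chain_pairs(list(pairs), min_block_size, max_gap)
        # antiparallel: negate the second segment's ranks
        flipped = [(ra, -rb, a, b) for ra, rb, a, b in pairs]
        found_anti = _chain_pairs(flipped, min_block_size, max_gap)
        seen = {tuple(ch) for ch in found}
        for ch in found_anti:
            if tuple(ch) not in seen:
                found.append(ch)
        for chain in found:
            blocks.append(CollinearBlock(ca, cb, tuple(chain)))
    blocks.sort(key=lambda b: (-b.size, b.chrom_a, b.chrom_b, b.pairs))
    return blocks


def classify_duplications(
    family: Iterable[str],
    hit_graph: Mapping[frozenset[str], float],
    genes: Mapping[str, GeneModel],
    blocks: Sequence[CollinearBlock] = (),
    proximal_window: int = 10,
    gene_of_protein: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign each family gene exactly one duplication class.

    Priority: singleton -> WGD/segmental -> tandem -> proximal ->
    dispersed.  Tandem requires a same-chromosome rank difference of
    exactly 1 to a family homolog; proximal a difference of at most
    ``proximal_window``.  A family gene absent from ``genes`` is an
    error.
    """
    family = sorted(set(family))
    for g in family:
        if g not in genes:
            raise KeyError(f"family gene {g!r} missing from the gene ranks")
    fam_set = set(family)
    neighbors: dict[str, set[str]] = {g: set() for g in family}
    for pair in hit_graph:
        a, b = sorted(pair)
        if gene_of_protein is not None:
            a, b = gene_of_protein.get(a, a), gene_of_protein.get(b, b)
        if a == b:
            continue
        if a in fam_set and b in fam_set:
            neighbors[a].add(b)
            neighbors[b].add(a)
    block_genes: set[str] = set()
    for blk in blocks:
        block_genes |= blk.genes()

    classes: dict[str, str] = {}
    for g in family:
        homs = neighbors[g]
        if not homs:
            classes[g] = "singleton"
            continue
        if g in block_genes:
            classes[g] = "wgd_segmental"
            continue
        gm = genes[g]
        dists = [
            abs(genes[h].rank - gm.rank)
            for h in homs
            if genes[h].chrom == gm.chrom
        ]
        if any(d == 1 for d in dists):
            classes[g] = "tandem"
        elif any(d <= proximal_window for d in dists):
            classes[g] = "proximal"
        else:
            classes[g] = "dispersed"
    return classes


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0." + "0" * ndigits),
                                          rounding=ROUND_HALF_UP))


def summarize_dup_table(
    classes: Mapping[str, str] | Mapping[str, int],
) -> dict[str, float]:
    """Per-class counts, total, and percent dispersed (1 decimal,
    half-up).

    Accepts either gene -> class assignments or already-tallied
    class -> count mappings (e.g. published per-species tables).
    """
    if not classes:
        raise ValueError("no classified genes")
    values = list(classes.values())
    if all(isinstance(v, (int, float)) for v in values):
        counts = {c: int(classes.get(c, 0)) for c in DUP_CLASSES}  # type: ignore[arg-type]
        unknown = set(classes) - set(DUP_CLASSES)
        if unknown:
            raise ValueError(f"unknown duplication class(es): {sorted(unknown)}")
    else:
        counts = {c: 0 for c in DUP_CLASSES}
        for g, c in classes.items():
            if c not in counts:
                raise ValueError(f"gene {g!r}: unknown class {c!r}")
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified genes")
    summary: dict[str, float] = dict(counts)
    summary["total"] = total
    summary["percent_dispersed"] = _round_half_up(
        100.0 * counts["dispersed"] / total
    )
    return summary


def species_summary_table(
    per_species: Mapping[str, Mapping[str, str] | Mapping[str, int]],
) -> pd.DataFrame:
    """Classes x species count table with total and percent-dispersed rows."""
    data = {}
    for species, classes in per_species.items():
        s = summarize_dup_table(classes)
        data[species] = [s[c] for c in DUP_CLASSES] + [
            s["total"], s["percent_dispersed"]
        ]
    index = list(DUP_CLASSES) + ["total", "percent_dispersed"]
    return pd.DataFrame(data, index=index)
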