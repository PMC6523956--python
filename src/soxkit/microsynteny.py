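"""Anchor/flank-window microsynteny detection.

Two family genes are declared a syntenic block — evidence of a shared
large-scale duplication origin — when at least ``min_pairs`` (default 2)
conserved gene pairs lie within ``k`` (default 20) genes upstream and
downstream of the two anchors.  A conserved pair is a flanker in one
window whose best non-self hit across the *whole* proteome (not just
the windows) falls in the other window at E below the cutoff; each
flanker participates in at most one pair (greedy matching by ascending
E-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .homology import ScoreMatrix
from .seqio import GeneModel

__all__ = [
    "SyntenyBlock",
    "flank_window",
    "best_hit_map",
    "conserved_pairs",
    "detect_blocks",
    "blocks_table",
]


@dataclass(frozen=True)
class SyntenyBlock:
    anchor_a: str
    anchor_b: str
    conserved_pairs: tuple[tuple[str, str, float], ...]  # (flanker_a, flanker_b, E)

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_pairs)


def flank_window(
    anchor: str, genes: Mapping[str, GeneModel], k: int = 20
) -> list[str]:
    """The up-to-2k genes flanking an anchor on its chromosome.

    Returns the k preceding and k following ranks (anchor excluded),
    truncated at chromosome ends, in rank order.
    """
    if anchor not in genes:
        raise KeyError(f"unknown anchor gene {anchor!r}")
    gm = genes[anchor]
    chrom_genes = sorted(
        (g for g in genes.values() if g.chrom == gm.chrom),
        key=lambda g: g.rank,
    )
    lo, hi = gm.rank - k, gm.rank + k
    return [
        g.gene_id for g in chrom_genes
        if lo <= g.rank <= hi and g.gene_id != anchor
    ]


def best_hit_map(
    scores: ScoreMatrix,
    gene_of_protein: Mapping[str, str] | None = None,
) -> dict[str, tuple[str, float]]:
    """Genome-wide best non-self hit (gene id -> (gene id, E-value))."""
    out: dict[str, tuple[str, float]] = {}
    for pid in scores.ids:
        hit = scores.best_nonself_hit(pid)
        if hit is None:
            continue
        subj, evalue = hit
        g = gene_of_protein.get(pid, pid) if gene_of_protein else pid
        s = gene_of_protein.get(subj, subj) if gene_of_protein else subj
        if g != s:
            out[g] = (s, evalue)
    return out


def conserved_pairs(
    window_a: Sequence[str],
    window_b: Sequence[str],
    best_hits: Mapping[str, tuple[str, float]],
    evalue_max: float = 1e-5,
) -> list[tuple[str, str, float]]:
    """Conserved gene pairs between two flank windows.

    A pair (x in window_a, y in window_b) qualifies when y is x's best
    non-self hit (or vice versa) at E < ``evalue_max``.  Genes shared by
    overlapping windows, and each gene generally, are used in at most
    one pair; candidates are committed greedily by ascending E-value.
    """
    set_a, set_b = set(window_a), set(window_b)
    candidates: list[tuple[float, str, str]] = []
    for x in window_a:
        hit = best_hits.get(x)
        if hit and hit[0] in set_b and hit[1] < evalue_max and hit[0] != x:
            candidates.append((hit[1], x, hit[0]))
    for y in window_b:
        hit = best_hits.get(y)
        if hit and hit[0] in set_a and hit[1] < evalue_max and hit[0] != y:
            candidates.append((hit[1], hit[0], y))
    candidates.sort()
    used: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    for evalue, x, y in candidates:
        if x in used or y in used or x == y:
            continue
        used.update((x, y))
        pairs.append((x, y, evalue))
    return pairs


def detect_blocks(
    family: Sequence[str],
    genes: Mapping[str, GeneModel],
    scores: ScoreMatrix,
    k: int = 20,
    evalue_max: float = 1e-5,
    min_pairs: int = 2,
    gene_of_protein: Mapping[str, str] | None = None,
) -> tuple[list[SyntenyBlock], list[str]]:
    """Test every unordered family gene pair for microsynteny.

    Returns the detected blocks plus the family genes present in none
    of them ("not present in any microsynteny").
    """
    best_hits = best_hit_map(scores, gene_of_protein)
    blocks: list[SyntenyBlock] = []
    for a, b in combinations(sorted(set(family)), 2):
        win_a = [g for g in flank_window(a, genes, k) if g != b]
        win_b = [g for g in flank_window(b, genes, k) if g != a]
        pairs = conserved_pairs(win_a, win_b, best_hits, evalue_max)
        if len(pairs) >= min_pairs:
            blocks.append(SyntenyBlock(a, b, tuple(pairs)))
    in_block = {g for blk in blocks for g in (blk.anchor_a, blk.anchor_b)}
    lonely = [g for g in sorted(set(family)) if g not in in_block]
    return blocks, lonely


def blocks_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """TSV-ready block report (one row per conserved flanker pair)."""
    rows = []
    for blk in blocks:
        for fa, fb, ev in blk.conserved_pairs:
            rows.append(
                {
                    "anchor_a": blk.anchor_a,
                    "anchor_b": blk.anchor_b,
                    "n_conserved": blk.n_conserved,
                    "flanker_a": fa,
                    "flanker_b": fb,
                    "evalue": ev,
                }
            )
    return pd.DataFrame(
        rows, columns=["anchor_a", "anchor_b", "n_conserved",
                       "flanker_a", "flanker_b", "evalue"],
    )
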