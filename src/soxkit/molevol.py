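"""Codon-aware alignment and Nei--Gojobori (NG86) Ka/Ks with
Jukes--Cantor correction, plus the sliding-window selection scan.

The NG86 estimator counts, per codon, the fraction of the three possible
changes at each position that are synonymous (stop-codon changes count
as nonsynonymous), giving synonymous (S) and nonsynonymous (N) site
totals with N + S = 3 x n_codons exactly.  Observed differences between
codons are resolved by averaging over all minimal substitution pathways,
excluding pathways that pass through a stop codon (re-weighting the
remaining ones equally).  Proportions are corrected for multiple hits
with the Jukes--Cantor formula d = -(3/4) ln(1 - 4p/3); a proportion
at or beyond the 3/4 saturation point leaves the rate undefined (NaN
sentinel, never an exception), as does Ks = 0 for the ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import CdsRecord

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonAlignment",
    "KaKsResult",
    "WindowPoint",
    "codon_align",
    "ng86",
    "ng86_pair",
    "jukes_cantor",
    "sliding_window",
    "selection_call",
    "pairwise_kaks_table",
]

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_NT = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns for two coding sequences."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def slice(self, start_codon: int, end_codon: int) -> "CodonAlignment":
        return CodonAlignment(
            self.gene_a, self.gene_b,
            self.codons_a[start_codon:end_codon],
            self.codons_b[start_codon:end_codon],
        )


@dataclass(frozen=True)
class KaKsResult:
    gene_a: str
    gene_b: str
    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    n_diffs: float  # nonsynonymous differences Nd
    s_diffs: float  # synonymous differences Sd
    pn: float
    ps: float
    ka: float  # NaN when the correction diverges
    ks: float
    ratio: float  # NaN when Ks == 0 or either rate is undefined


@dataclass(frozen=True)
class WindowPoint:
    start_bp: int  # 1-based inclusive on the ungapped codon alignment
    end_bp: int
    ka: float
    ks: float
    ka_ks: float


# ---------------------------------------------------------------------------
# Per-codon site fractions and pathway-averaged difference counts


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of a sense codon: per position, the fraction of
    its 3 single-nucleotide changes that preserve the amino acid
    (changes to stop codons are nonsynonymous)."""
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all minimal
    substitution pathways that avoid stop-codon intermediates.

    If every pathway passes through a stop (possible only for 2- or
    3-fold differences), all pathways are used as a fallback so the
    counts remain defined.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # fall back to every pathway, stops included
        for order in itertools.permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if a not in STOP_CODONS and b not in STOP_CODONS and _AA[a] == _AA[b]:
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def jukes_cantor(p: float) -> float:
    """Jukes--Cantor multiple-hit correction; NaN at/beyond saturation."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Codon alignment by back-translation threading


def codon_align(
    aligned_prot_a: str,
    aligned_prot_b: str,
    cds_a: CdsRecord,
    cds_b: CdsRecord,
    trim_stop: bool = True,
) -> CodonAlignment:
    """Thread CDS codons through a protein alignment.

    Each aligned protein column expands to the source codons; columns
    gapped in either row are masked out, as are columns containing an
    ambiguous codon.  A codon that does not translate to its aligned
    residue is an error naming the first offending codon.
    """
    if len(aligned_prot_a) != len(aligned_prot_b):
        raise ValueError("aligned protein rows differ in length")

    def codons_of(cds: CdsRecord) -> list[str]:
        seq = cds.sequence
        if trim_stop and len(seq) >= 3 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        if len(seq) % 3:
            raise ValueError(f"CDS {cds.gene_id}: length not divisible by 3")
        return [seq[i:i + 3] for i in range(0, len(seq), 3)]

    cod_a, cod_b = codons_of(cds_a), codons_of(cds_b)
    ia = ib = 0
    cols_a: list[str] = []
    cols_b: list[str] = []
    for col, (ra, rb) in enumerate(zip(aligned_prot_a, aligned_prot_b)):
        ca = cb = None
        if ra != "-":
            if ia >= len(cod_a):
                raise ValueError(f"CDS {cds_a.gene_id}: shorter than its protein alignment")
            ca = cod_a[ia]
            if ca in SENSE_CODONS and _AA[ca] != ra.upper() and ra.upper() != "X":
                raise ValueError(
                    f"CDS {cds_a.gene_id}: codon {ia + 1} ({ca}) does not "
                    f"translate to aligned residue {ra!r}"
                )
            ia += 1
        if rb != "-":
            if ib >= len(cod_b):
                raise ValueError(f"CDS {cds_b.gene_id}: shorter than its protein alignment")
            cb = cod_b[ib]
            if cb in SENSE_CODONS and _AA[cb] != rb.upper() and rb.upper() != "X":
                raise ValueError(
                    f"CDS {cds_b.gene_id}: codon {ib + 1} ({cb}) does not "
                    f"translate to aligned residue {rb!r}"
                )
            ib += 1
        if ca is None or cb is None:
            continue  # gap column: masked
        if ca not in SENSE_CODONS or cb not in SENSE_CODONS:
            continue  # ambiguous or stop codon: masked
        cols_a.append(ca)
        cols_b.append(cb)
    return CodonAlignment(cds_a.gene_id, cds_b.gene_id,
                          tuple(cols_a), tuple(cols_b))


# ---------------------------------------------------------------------------
# NG86


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei--Gojobori Ka/Ks for a gap-free codon alignment."""
    if alignment.n_codons < 1:
        raise ValueError("empty codon alignment")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        s_c = (_syn_sites(ca) + _syn_sites(cb)) / 2.0  # averaged between seqs
        s_sites += s_c
        n_sites += 3.0 - s_c
        sd, nd = _pair_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ka, ks = jukes_cantor(pn), jukes_cantor(ps)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(alignment.gene_a, alignment.gene_b,
                      n_sites, s_sites, n_diffs, s_diffs, pn, ps, ka, ks, ratio)


def ng86_pair(cds_a: CdsRecord, cds_b: CdsRecord) -> KaKsResult:
    """NG86 for two equal-length, codon-homologous coding sequences."""
    aligned_a = "".join(
        _AA.get(cds_a.sequence[i:i + 3], "X")
        for i in range(0, len(cds_a.sequence) - len(cds_a.sequence) % 3, 3)
    )
    aligned_b = "".join(
        _AA.get(cds_b.sequence[i:i + 3], "X")
        for i in range(0, len(cds_b.sequence) - len(cds_b.sequence) % 3, 3)
    )
    return ng86(codon_align(aligned_a, aligned_b, cds_a, cds_b, trim_stop=False))


# ---------------------------------------------------------------------------
# Sliding windows


def sliding_window(
    alignment: CodonAlignment, window_bp: int = 150, step_bp: int = 9
) -> list[WindowPoint]:
    """Ka/Ks in sliding windows over the ungapped codon alignment.

    Windows start at offsets 0, step, 2*step, ... while a full window
    fits, so the count is floor((L - window)/step) + 1 for alignment
    length L in bp.  Codons only partially covered by a window are
    excluded from its estimate.  Returns an empty list when L < window.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    L = 3 * alignment.n_codons
    out: list[WindowPoint] = []
    off = 0
    while off + window_bp <= L:
        first_codon = (off + 2) // 3  # first codon fully inside
        last_codon = (off + window_bp) // 3  # exclusive
        sub = alignment.slice(first_codon, last_codon)
        if sub.n_codons >= 1:
            res = ng86(sub)
            out.append(WindowPoint(off + 1, off + window_bp,
                                   res.ka, res.ks, res.ratio))
        off += step_bp
    return out


# ---------------------------------------------------------------------------
# Pair tables


def selection_call(ratio: float, neutral_band: tuple[float, float] = (0.9, 1.1)) -> str:
    """Classify a Ka/Ks ratio: purifying (<1), neutral (~1) or positive (>1).

    A band around 1 (default 0.9--1.1) absorbs estimation noise in the
    neutral call; an undefined ratio yields "undefined".
    """
    if math.isnan(ratio):
        return "undefined"
    lo, hi = neutral_band
    if ratio < lo:
        return "purifying"
    if ratio > hi:
        return "positive"
    return "neutral"


def pairwise_kaks_table(
    pairs: Iterable[tuple[str, str]],
    cds_by_gene: Mapping[str, CdsRecord],
    protein_alignments: Mapping[tuple[str, str], tuple[str, str]] | None = None,
    neutral_band: tuple[float, float] = (0.9, 1.1),
) -> pd.DataFrame:
    """One NG86 row per gene pair, with a selection call.

    ``protein_alignments`` maps a pair to its two aligned (gapped)
    protein rows; without it the CDSs must be codon-homologous as given.
    """
    rows = []
    for a, b in pairs:
        for g in (a, b):
            if g not in cds_by_gene:
                raise ValueError(f"missing CDS for gene {g}")
        if protein_alignments and (a, b) in protein_alignments:
            pa, pb = protein_alignments[(a, b)]
            res = ng86(codon_align(pa, pb, cds_by_gene[a], cds_by_gene[b]))
        else:
            res = ng86_pair(cds_by_gene[a], cds_by_gene[b])
        rows.append(
            {
                "gene_a": a, "gene_b": b,
                "n_sites": round(res.n_sites, 2), "s_sites": round(res.s_sites, 2),
                "n_diffs": round(res.n_diffs, 2), "s_diffs": round(res.s_diffs, 2),
                "ka": round(res.ka, 4) if not math.isnan(res.ka) else math.nan,
                "ks": round(res.ks, 4) if not math.isnan(res.ks) else math.nan,
                "ka_ks": round(res.ratio, 4) if not math.isnan(res.ratio) else math.nan,
                "call": selection_call(res.ratio, neutral_band),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_sites", "s_sites", "n_diffs",
                       "s_diffs", "ka", "ks", "ka_ks", "call"],
    )
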