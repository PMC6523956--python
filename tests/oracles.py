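"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive dynamic
programming, pathway enumeration, grid scans) and stay independent of
the code paths they check.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def local_affine_score(a: str, b: str, gap_open: int = 11,
                       gap_extend: int = 1) -> float:
    """Brute-force Gotoh local alignment score.

    A gap of length L costs gap_open + L * gap_extend (BLAST
    existence/extension convention).
    """
    first = gap_open + gap_extend
    neg = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_pathways(c1: str, c2: str) -> tuple[float, float, int]:
    """Exhaustive pathway enumeration between two sense codons.

    Returns (Sd, Nd, hamming distance), averaging synonymous /
    nonsynonymous step counts over every minimal substitution pathway
    that avoids stop-codon intermediates (all pathways if every one is
    blocked).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0, 0
    all_paths, open_paths = [], []
    for order in itertools.permutations(diff):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            open_paths.append(steps)
    paths = open_paths or all_paths
    sd = nd = 0.0
    for steps in paths:
        for x, y in steps:
            if x not in _STOPS and y not in _STOPS and _aa(x) == _aa(y):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths), len(diff)


def grid_scan_pi(charge_fn, step: float = 0.001) -> float:
    """Exhaustive pH grid scan: the pH (0..14) minimising |net charge|."""
    best_ph, best_q = 0.0, abs(charge_fn(0.0))
    ph = 0.0
    while ph <= 14.0:
        q = abs(charge_fn(ph))
        if q < best_q:
            best_ph, best_q = ph, q
        ph += step
    return best_ph
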