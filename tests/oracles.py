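"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: a plain-Python
affine-gap Smith-Waterman dynamic program, a brute-force enumerator of
all local alignment paths (for validating the DP itself at tiny
lengths), and an exact hypergeometric tail by combinatorial enumeration
with rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(x: str, y: str) -> int:
    if x == "X" or y == "X":
        return 0
    return int(_B62[x, y])


def sw_affine_score(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1, score=blosum62) -> int:
    """Affine-gap local alignment score, three-state DP in plain Python.

    A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    neg = float("-inf")
    la, lb = len(a), len(b)
    h = [[0] * (lb + 1) for _ in range(la + 1)]   # best ending in match/any
    e = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (up)
    f = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (left)
    best = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e[i][j] = max(h[i - 1][j] - gap_open - gap_extend,
                          e[i - 1][j] - gap_extend)
            f[i][j] = max(h[i][j - 1] - gap_open - gap_extend,
                          f[i][j - 1] - gap_extend)
            diag = h[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            h[i][j] = max(0, diag, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return best


def sw_enumerate_score(a: str, b: str, gap_open: int = 11,
                       gap_extend: int = 1, score=blosum62) -> int:
    """Best local score by exhaustive DFS over all alignment paths.

    Exponential; only usable for very short sequences.  An optimal local
    alignment never starts or ends with a gap, so paths start at a
    residue pair.
    """
    best = 0

    def rec(i: int, j: int, acc: int, state: str) -> None:
        nonlocal best
        if acc > best:
            best = acc
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]), "M")
        if i < len(a):
            cost = gap_extend if state == "D" else gap_open + gap_extend
            rec(i + 1, j, acc - cost, "D")
        if j < len(b):
            cost = gap_extend if state == "I" else gap_open + gap_extend
            rec(i, j + 1, acc - cost, "I")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0 + 1, j0 + 1, score(a[i0], b[j0]), "M")
    return best


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    num = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            num += comb(K, x) * comb(N - K, n - x)
    return Fraction(num, total)
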