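"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: a plain three-state
Gotoh dynamic program for affine-gap global alignment scores, and an
all-substrings motif scanner.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def gotoh_global_score(a: str, b: str, gap_open: float = 10.0,
                       gap_extend: float = 1.0) -> float:
    """Optimal affine-gap global alignment score, BLOSUM62.

    A gap run of length L costs gap_open + (L - 1) * gap_extend,
    matching the package's alignment convention.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def all_substring_matches(text: str, motif: str) -> list[int]:
    """Every start where text[i : i + len(motif)] equals motif, X excluded."""
    out = []
    for i in range(len(text)):
        window = text[i : i + len(motif)]
        if len(window) == len(motif) and window == motif and "X" not in window:
            out.append(i)
    return out
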