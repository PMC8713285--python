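"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: plain-Python recursive
enumeration for local alignment, and an all-pairs scan for peak matching.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _sub(a: str, b: str) -> float:
    alph = _B62.alphabet
    a = a if a in alph else "X"
    b = b if b in alph else "X"
    return float(_B62[a, b])


def _global_score(q: str, s: str, i: int, j: int, last: str,
                  go: float, ge: float) -> float:
    """Best global alignment score of q[i:] vs s[j:] by exhaustive
    recursion (no memoisation)."""
    if i == len(q) and j == len(s):
        return 0.0
    options = []
    if i < len(q) and j < len(s):
        options.append(
            _sub(q[i], s[j]) + _global_score(q, s, i + 1, j + 1, "D", go, ge)
        )
    if i < len(q):
        cost = ge if last == "U" else go + ge
        options.append(-cost + _global_score(q, s, i + 1, j, "U", go, ge))
    if j < len(s):
        cost = ge if last == "L" else go + ge
        options.append(-cost + _global_score(q, s, i, j + 1, "L", go, ge))
    return max(options)


def brute_force_local_score(
    query: str, subject: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal local alignment score by enumerating all substring pairs.

    Terminal gaps always lower the score, so enumerating gap-free-ended
    global alignments of all non-empty substring pairs covers every
    optimal local alignment.
    """
    best = 0.0
    for a in range(len(query)):
        for b in range(a + 1, len(query) + 1):
            for c in range(len(subject)):
                for d in range(c + 1, len(subject) + 1):
                    score = _global_score(
                        query[a:b], subject[c:d], 0, 0, "", gap_open, gap_extend
                    )
                    if score > best:
                        best = score
    return best


def brute_force_peak_matches(
    theoreticals: list[tuple[str, int, float]],
    peaks: list[float],
    tol: float,
    mode: str = "da",
) -> set[tuple[str, int]]:
    """All (peptide, charge) with any peak within tolerance: O(n*m) scan."""
    out = set()
    for name, z, t in theoreticals:
        for p in peaks:
            ok = abs(t - p) <= tol if mode == "da" else abs(t - p) / t * 1e6 <= tol
            if ok:
                out.add((name, z))
    return out
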