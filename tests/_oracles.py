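"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (quadratic DP, exhaustive
enumeration) and shares no code with the package's own algorithms.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def smith_waterman(a: str, b: str, match: float = 1.0, mismatch: float = -2.0,
                   gap: float = -2.5):
    """Pure-Python local alignment with linear gaps.

    Returns (score, identities, columns, q_start, q_end, s_start, s_end)
    of the best-scoring local alignment, or None when the best score is
    not positive.  Traceback prefers diagonal, then up (gap in b), then
    left, matching one deterministic optimum.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            v = max(0.0, diag, up, left)
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return None
    # traceback
    i, j = bi, bj
    identities = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        v = H[i][j]
        diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if abs(v - diag) < 1e-9:
            identities += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif abs(v - (H[i - 1][j] + gap)) < 1e-9:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, identities, columns, i, bi, j, bj


def best_chain_weight(pairs: list[tuple[int, int, int]]) -> int:
    """Max total weight over subsets strictly increasing in both ordinals,
    by exhaustive enumeration (inputs of ~10 items)."""
    n = len(pairs)
    best = 0
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            seq = [pairs[i] for i in combo]
            seq.sort()
            ok = all(
                seq[i][0] < seq[i + 1][0] and seq[i][1] < seq[i + 1][1]
                for i in range(len(seq) - 1)
            )
            if ok:
                best = max(best, sum(p[2] for p in seq))
    return best


def n50_brute(lengths: list[int]) -> int:
    """Smallest L among the lengths with sum(l for l >= L) >= total/2."""
    total = sum(lengths)
    candidates = [
        L for L in sorted(set(lengths))
        if sum(l for l in lengths if l >= L) >= total / 2
    ]
    return max(candidates)


def weighted_jaccard_brute(cov_a: dict[str, int], cov_b: dict[str, int]) -> float:
    fams = sorted(set(cov_a) | set(cov_b))
    if not fams:
        return 1.0
    num = sum(min(cov_a.get(f, 0), cov_b.get(f, 0)) for f in fams)
    den = sum(max(cov_a.get(f, 0), cov_b.get(f, 0)) for f in fams)
    return num / den if den else 1.0
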