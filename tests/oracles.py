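"""Independent reference implementations used only to check the package.

These deliberately use the slowest, most transparent formulation of each
quantity (exhaustive enumeration, quadratic DP, pair counting) so they
share no code path with the implementation under test.
"""

from itertools import combinations


def lcs_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming LCS length."""
    m = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i, ca in enumerate(a, 1):
        for j, cb in enumerate(b, 1):
            m[i][j] = m[i - 1][j - 1] + 1 if ca == cb else max(
                m[i - 1][j], m[i][j - 1])
    return m[len(a)][len(b)]


def lcs_exhaustive(a: str, b: str) -> int:
    """LCS by enumerating every subsequence of the shorter string (<= 12 nt)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    assert len(short) <= 12, "exhaustive oracle limited to short strings"

    def is_subsequence(sub: str, s: str) -> bool:
        it = iter(s)
        return all(ch in it for ch in sub)

    best = 0
    n = len(short)
    for k in range(n, best, -1):
        for idx in combinations(range(n), k):
            if is_subsequence("".join(short[i] for i in idx), long_):
                return k
    return 0


def mann_whitney_u(x, y) -> float:
    """U statistic for the first sample by brute-force pair counting
    (wins count 1, ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def per_base_mean_score(intervals, start: int, end: int) -> float:
    """Average conservation over [start, end) by walking every base."""
    total = 0.0
    for pos in range(start, end):
        for (s, e, score) in intervals:
            if s <= pos < e:
                total += score
                break
    return total / (end - start)
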