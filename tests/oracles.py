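"""Independent brute-force oracles used by the test suite.

Each oracle is a direct transcription of the operation's definition in
plain Python, kept deliberately separate from the (vectorized) package
implementations it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def align_scan(seq: str, genome: dict[str, str], max_mm: int, report_all: bool):
    """All-positions Hamming scan on both strands.

    Returns sorted (chrom, start, strand, mismatches) tuples; when
    ``report_all`` is false only the best (minimum-mismatch) stratum.
    """
    hits = []
    rc = revcomp(seq)
    for chrom in sorted(genome):
        g = genome[chrom]
        for pos in range(len(g) - len(seq) + 1):
            window = g[pos : pos + len(seq)]
            for strand, probe in (("+", seq), ("-", rc)):
                mm = hamming(window, probe)
                if mm <= max_mm:
                    hits.append((chrom, pos, strand, mm))
    if not report_all and hits:
        best = min(h[3] for h in hits)
        hits = [h for h in hits if h[3] == best]
    return sorted(hits)


def duplex_scan(srna: str, target: str, max_mm: int) -> list[tuple[int, int]]:
    """Sliding-window duplex search: mismatches of each target window
    against the reverse complement of the sRNA (G:U counted as mismatch)."""
    L = len(srna)
    rc = revcomp(srna)
    out = []
    for i in range(len(target) - L + 1):
        mm = hamming(target[i : i + L], rc)
        if mm <= max_mm:
            out.append((i, mm))
    return out


PAIRABLE = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def hairpin_max_pairs(window: str, min_loop: int, max_bulge: int) -> int:
    """Maximum nested pairs of any single-stem hairpin in the window.

    Plain memoized recursion over closed structures: the outermost pair
    (i, j) either closes a terminal loop of >= min_loop unpaired bases or
    stacks onto an inner pair (i', j'), spending (i'-i-1) + (j-j'-1) of the
    total bulge budget.
    """

    @lru_cache(maxsize=None)
    def closed(i: int, j: int, budget: int) -> float:
        if (window[i], window[j]) not in PAIRABLE:
            return -math.inf
        best = -math.inf
        if j - i - 1 >= min_loop:
            best = 0.0
        for i2 in range(i + 1, min(i + budget + 2, j)):
            cost_i = i2 - i - 1
            for j2 in range(j - 1, max(i2, j - (budget - cost_i) - 2), -1):
                cost = cost_i + (j - j2 - 1)
                if cost > budget or j2 <= i2:
                    continue
                best = max(best, closed(i2, j2, budget - cost))
        return 1 + best if best > -math.inf else -math.inf

    best = 0
    n = len(window)
    for i in range(n):
        for j in range(i + 1, n):
            v = closed(i, j, max_bulge)
            if v > best:
                best = int(v)
    return best


def welch_formula(a, b) -> tuple[float, float]:
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def hypergeom_upper_tail(overlap: int, n_universe: int, n_category: int, n_draws: int) -> float:
    """P(X >= overlap) by exact summation with integer combinatorics."""
    total = math.comb(n_universe, n_draws)
    acc = 0
    for k in range(overlap, min(n_category, n_draws) + 1):
        acc += math.comb(n_category, k) * math.comb(n_universe - n_category, n_draws - k)
    return acc / total


def pearson_formula(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
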