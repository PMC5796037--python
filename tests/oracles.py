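"""Independent brute-force / exact-arithmetic oracles used by the tests.

Everything here is deliberately written from the definitions, not from
the package's algorithms: exhaustive enumeration for the dynamic
programs, rational arithmetic for the combinatorics, and plain pattern
matching for the seed scanner.
"""

from fractions import Fraction
from math import comb

from mirmint.target_predict import (
    LOOP_EXT,
    LOOP_OPEN,
    PAIRABLE,
    RNA_COMPLEMENT,
    STACK_ENERGIES,
)


# ---------------------------------------------------------------------------
# seed sites: direct pattern matching
# ---------------------------------------------------------------------------

def naive_seed_sites(mirna_seq: str, utr: str):
    """All seed sites by direct pattern comparison, one per 6mer core,
    reported at the highest class; returns {(start, end, class), ...}."""
    seed7 = mirna_seq[1:8]
    seed6 = mirna_seq[1:7]
    rc = lambda s: "".join(RNA_COMPLEMENT[b] for b in reversed(s))
    pat8 = rc(seed7) + "A"
    pat7m8 = rc(seed7)
    pat7a1 = rc(seed6) + "A"
    pat6 = rc(seed6)

    best: dict[int, tuple[int, int, str]] = {}  # core position -> site

    def consider(core_pos, start, end, cls, rank):
        prev = best.get(core_pos)
        if prev is None or rank > prev[3]:
            best[core_pos] = (start, end, cls, rank)

    n = len(utr)
    for i in range(n):
        if utr[i:i + 8] == pat8:
            consider(i + 1, i, i + 8, "8mer", 4)
        if utr[i:i + 7] == pat7m8:
            consider(i + 1, i, i + 7, "7mer-m8", 3)
        if utr[i:i + 7] == pat7a1:
            consider(i, i, i + 7, "7mer-A1", 2)
        if utr[i:i + 6] == pat6:
            consider(i, i, i + 6, "6mer", 1)
    return {(s, e, c) for s, e, c, _ in best.values()}


# ---------------------------------------------------------------------------
# duplex MFE: enumerate every monotone pairing
# ---------------------------------------------------------------------------

def _matchings(u, v, i0, j0):
    """Yield all monotone sets of pairable (i, j) columns starting at
    or after (i0, j0)."""
    yield []
    for i in range(i0, len(u)):
        for j in range(j0, len(v)):
            if u[i] + v[j] in PAIRABLE:
                for rest in _matchings(u, v, i + 1, j + 1):
                    yield [(i, j)] + rest


def enumerate_duplex_mfe(mirna_seq: str, window: str):
    """Minimum energy over every explicit antiparallel pairing.

    Energy of a pairing = sum of stack energies for adjacent columns plus
    LOOP_OPEN + LOOP_EXT*k for each internal stretch of k > 0 unpaired
    nucleotides; None when no pairable column exists.
    """
    u, v = mirna_seq, window[::-1]
    best = None
    for matching in _matchings(u, v, 0, 0):
        if not matching:
            continue
        energy = 0.0
        for (pi, pj), (i, j) in zip(matching, matching[1:]):
            gap = (i - pi - 1) + (j - pj - 1)
            if gap == 0:
                energy += STACK_ENERGIES[(u[pi] + v[pj], u[i] + v[j])]
            else:
                energy += LOOP_OPEN + LOOP_EXT * gap
        if best is None or energy < best:
            best = energy
    return best


# ---------------------------------------------------------------------------
# maximum base pairing: enumerate every nested structure
# ---------------------------------------------------------------------------

def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum pairs over an explicit enumeration of nested structures."""
    from functools import lru_cache

    n = len(seq)

    def structures(i, j):
        """Yield pair counts of all nested structures on seq[i..j]."""
        if j - i < min_loop + 1:
            yield 0
            return
        # position i unpaired
        yield from structures(i + 1, j)
        # position i paired with k
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in PAIRABLE:
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        yield 1 + inner + outer

    # memoised max (the enumeration explodes above ~14 nt otherwise)
    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < min_loop + 1:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in PAIRABLE:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    if n <= 10:
        return max(structures(0, n - 1)) if n else 0
    return best(0, n - 1)


# ---------------------------------------------------------------------------
# hypergeometric tail: exact rational arithmetic
# ---------------------------------------------------------------------------

def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


# ---------------------------------------------------------------------------
# Pearson r from the definition, in compensated arithmetic
# ---------------------------------------------------------------------------

def definition_pearson_r(x, y) -> float:
    import math

    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    cov = math.fsum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = math.fsum((a - mx) ** 2 for a in x)
    vy = math.fsum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


# ---------------------------------------------------------------------------
# Student t two-sided p via the regularized incomplete beta
# ---------------------------------------------------------------------------

def exact_t_twosided_p(t: float, df: float) -> float:
    """P(|T_df| >= |t|) = I_{df/(df+t^2)}(df/2, 1/2), via mpmath."""
    import mpmath

    x = df / (df + t * t)
    return float(mpmath.betainc(df / 2.0, 0.5, 0, x, regularized=True))
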