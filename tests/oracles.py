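"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-base membership sets, explicit
outcome enumeration, exact rational arithmetic — and shares no code with
the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from peako.intervals import GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# per-base interval algebra
# ---------------------------------------------------------------------------


def covered_bases(intervals) -> set[tuple[str, int]]:
    bases: set[tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases


def brute_subtract_all(a: PeakSet, b: PeakSet) -> list[GenomicInterval]:
    b_bases = covered_bases(b)
    return [iv for iv in a if not (covered_bases([iv]) & b_bases)]


def brute_intersect_keep_a(a: PeakSet, b: PeakSet) -> list[GenomicInterval]:
    out = []
    for iv_a in a:
        bases_a = covered_bases([iv_a])
        for iv_b in b:
            if bases_a & covered_bases([iv_b]):
                out.append(iv_a)
    return out


def brute_merge(p: PeakSet) -> list[tuple[str, int, int]]:
    """Maximal runs of covered bases per chromosome."""
    by_chrom: dict[str, set[int]] = {}
    for chrom, pos in covered_bases(p):
        by_chrom.setdefault(chrom, set()).add(pos)
    out = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run_start = prev = positions[0]
        for pos in positions[1:]:
            if pos != prev + 1:
                out.append((chrom, run_start, prev + 1))
                run_start = pos
            prev = pos
        out.append((chrom, run_start, prev + 1))
    return out


def brute_peako_r(a_wt: PeakSet, a_ko: PeakSet, b: PeakSet) -> tuple[int, int, float]:
    """r computed entirely through the per-base oracles."""
    a_unique = []
    seen = set()
    for iv in a_wt:
        if iv.key not in seen:
            seen.add(iv.key)
            a_unique.append(iv)
    survivors = brute_subtract_all(PeakSet(a_unique), a_ko)
    supported = brute_intersect_keep_a(PeakSet(survivors), b)
    merged = brute_merge(PeakSet(supported))
    den = len(a_unique)
    num = len(merged)
    return num, den, (num / den if den else 0.0)


# ---------------------------------------------------------------------------
# exact statistics
# ---------------------------------------------------------------------------


def exact_binomial_upper_tail(k: int, n: int, w: int, total: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, w/total), exact rational arithmetic."""
    p = Fraction(w, total)
    return sum(
        (comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)),
        Fraction(0),
    )


def exact_fisher_greater(k_pos: int, n_pos: int, k_neg: int, n_neg: int) -> Fraction:
    """One-sided (greater) Fisher p for [[k_pos, n_pos-k_pos],
    [k_neg, n_neg-k_neg]]: hypergeometric tail with fixed margins, exact."""
    K = k_pos + k_neg  # in-window total
    N = n_pos + n_neg
    denom = comb(N, n_pos)
    tail = Fraction(0)
    for x in range(k_pos, min(K, n_pos) + 1):
        if K - x > n_neg:
            continue
        tail += Fraction(comb(K, x) * comb(N - K, n_pos - x), denom)
    return tail


# ---------------------------------------------------------------------------
# naive PWM scanning
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_best_match(bases: str, lodds, min_score: float = 0.0):
    """Exhaustive two-strand scan with python loops.

    Returns (offset, strand, score) of the best eligible window under the
    tie rules (highest score, then smallest |center displacement|, then
    + strand, then leftmost), or None.
    """
    L, m = len(bases), len(lodds)
    if L < m:
        return None
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    candidates = []
    for offset in range(L - m + 1):
        window = bases[offset : offset + m]
        if "N" in window:
            continue
        fwd = sum(lodds[j][idx[window[j]]] for j in range(m))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = sum(lodds[j][idx[rc[j]]] for j in range(m))
        disp = abs(offset - (L - m) / 2.0)
        if fwd >= min_score:
            candidates.append((-fwd, disp, 0, offset))
        if rev >= min_score:
            candidates.append((-rev, disp, 1, offset))
    if not candidates:
        return None
    neg_score, _, strand_code, offset = min(candidates)
    return offset, "+" if strand_code == 0 else "-", -neg_score


# ---------------------------------------------------------------------------
# random peak-set generation (shared by property tests and acceptance)
# ---------------------------------------------------------------------------


def random_peakset(
    rng,
    max_intervals: int = 30,
    max_coord: int = 1000,
    n_chroms: int = 3,
    min_len: int = 1,
    max_len: int = 60,
) -> PeakSet:
    n = int(rng.integers(0, max_intervals + 1))
    out = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, max(1, max_coord - length)))
        out.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(out)


def random_triple(rng):
    """A random (A_WT, A_KO, B) triple; every third draw is adversarial,
    with B intervals long enough to span several A_WT peaks."""
    if rng.integers(0, 3) == 0:
        a = random_peakset(rng, max_intervals=20, min_len=5, max_len=30)
        ko = random_peakset(rng, max_intervals=5, min_len=5, max_len=30)
        b = random_peakset(rng, max_intervals=6, min_len=200, max_len=900)
    else:
        a = random_peakset(rng)
        ko = random_peakset(rng)
        b = random_peakset(rng)
    return a, ko, b
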