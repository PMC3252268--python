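"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literally as possible — explicit loops,
per-window recounting, exhaustive enumeration — and deliberately shares no
code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def _norm(seq: str) -> str:
    return seq.upper().replace("T", "U")


def brute_pentamers(seq: str) -> list[int]:
    s = _norm(seq)
    return [i for i in range(len(s) - 4) if s[i : i + 5] == "AUUUA"]


def brute_blocks(seq: str, word: int = 20, start_au: float = 0.80, end_au: float = 0.55) -> list[tuple[int, int]]:
    """Open/extend/close rule applied literally, one window at a time.

    Returns merged maximal [start, end) intervals via a position-coverage set.
    """
    s = _norm(seq)
    covered: set[int] = set()
    in_block = False
    block_positions: set[int] = set()
    for i in range(len(s) - word + 1):
        window = s[i : i + word]
        frac = (window.count("A") + window.count("U")) / word
        if not in_block:
            if frac >= start_au:
                in_block = True
                block_positions = set(range(i, i + word))
        else:
            if frac >= end_au:
                block_positions |= set(range(i, i + word))
            else:
                covered |= block_positions
                in_block = False
    if in_block:
        covered |= block_positions
    # maximal runs of covered positions
    blocks = []
    for pos in sorted(covered):
        if blocks and pos == blocks[-1][1]:
            blocks[-1][1] = pos + 1
        else:
            blocks.append([pos, pos + 1])
    return [tuple(b) for b in blocks]


def brute_total(
    seq: str,
    pentamer_value: float = 1.0,
    overlap: float = 1.5,
    g03: float = 0.75,
    g46: float = 0.4,
    g79: float = 0.2,
    block_bonus: float = 0.3,
    word: int = 20,
    start_au: float = 0.80,
    end_au: float = 0.55,
) -> float:
    hits = brute_pentamers(seq)
    basal = pentamer_value * len(hits)
    proximity = 0.0
    for prev, nxt in zip(hits, hits[1:]):
        gap = nxt - (prev + 5)
        if gap < 0:
            proximity += overlap
        elif gap <= 3:
            proximity += g03
        elif gap <= 6:
            proximity += g46
        elif gap <= 9:
            proximity += g79
    blocks = brute_blocks(seq, word, start_au, end_au)
    n_in_block = sum(
        1 for h in hits if any(b0 <= h and h + 5 <= b1 for b0, b1 in blocks)
    )
    return basal + proximity + block_bonus * n_in_block


def random_sequences(rng: np.random.Generator, n: int, min_len: int = 20, max_len: int = 500):
    """Random sequences of varying AU fraction for equivalence testing."""
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        au = rng.uniform(0.3, 0.9)
        p = [au / 2, au / 2, (1 - au) / 2, (1 - au) / 2]
        out.append("".join(rng.choice(list("AUGC"), size=length, p=p)))
    return out


def pair_count_auc(pos, neg) -> float:
    """AUC by exhaustive pair counting; ties count one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c

    def p_of(k: int) -> float:
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(r1 + r2, c1)
        )

    p_obs = p_of(a)
    return sum(p for k in range(c1 + 1) if (p := p_of(k)) <= p_obs * (1 + 1e-9))


def rank_pearson(x, y) -> float:
    """Spearman as Pearson of average-rank vectors, computed from scratch."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def enumerate_tables(max_n: int):
    """All 2x2 tables [[a,b],[c,d]] with positive margins and a+b+c+d <= max_n."""
    for n in range(2, max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    if (a + b) and (c + d) and (a + c) and (b + d):
                        yield a, b, c, d
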