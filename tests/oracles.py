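"""Independent reference implementations used only to check the package.

These deliberately re-derive results from first principles (exhaustive
enumeration, naive recounting) rather than sharing code with the library.
"""

from __future__ import annotations

import itertools
from math import inf


def naive_min_dg(mseq: str, useq: str, model) -> float:
    """Minimum duplex free energy by direct evaluation of the energy definition.

    ``E[i][j]`` = best energy of a duplex whose 3'-most (in UTR) pair is
    (utr i, miRNA j), obtained by scanning *every* possible predecessor pair;
    loop penalties and stacks are taken straight from the model's public
    functions.  O(N²L²) -- tractable for the small instances it is used on.
    """
    N, L = len(useq), len(mseq)
    E: dict[tuple[int, int], float] = {}
    best = inf
    for i in range(N):
        for j in reversed(range(L)):
            if not model.pairable(useq[i], mseq[j]):
                continue
            e = model.init_dG
            for (i2, j2), e2 in E.items():
                if i2 >= i or j2 <= j:
                    continue
                gap_u, gap_m = i - i2 - 1, j2 - j - 1
                if gap_u == 0 and gap_m == 0:
                    cost = model.stack(useq[i2], mseq[j2], useq[i], mseq[j])
                else:
                    cost = model.loop_dG(gap_u, gap_m)
                e = min(e, e2 + cost)
            E[(i, j)] = e
            best = min(best, e)
    return best


def enumerate_min_dg(mseq: str, useq: str, model) -> float:
    """Minimum free energy by brute-force enumeration of every legal pairing.

    Recursively builds all antiparallel, non-crossing pair sets and scores
    each one; exponential, so only for very small instances.
    """
    N, L = len(useq), len(mseq)
    pairable = [
        (i, j) for i in range(N) for j in range(L) if model.pairable(useq[i], mseq[j])
    ]

    best = [inf]

    def score(chain: list[tuple[int, int]]) -> float:
        e = model.init_dG
        for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
            gap_u, gap_m = i2 - i1 - 1, j1 - j2 - 1
            if gap_u == 0 and gap_m == 0:
                e += model.stack(useq[i1], mseq[j1], useq[i2], mseq[j2])
            else:
                e += model.loop_dG(gap_u, gap_m)
        return e

    def extend(chain: list[tuple[int, int]]) -> None:
        if chain:
            best[0] = min(best[0], score(chain))
        last = chain[-1] if chain else None
        for i, j in pairable:
            if last is None or (i > last[0] and j < last[1]):
                chain.append((i, j))
                extend(chain)
                chain.pop()

    extend([])
    return best[0]


def recount_features(pairs, site_start, site_end, mirna_len, seed_start):
    """Naive recount of the four binding features from a raw pair list."""
    utr_paired = {u for u, _, _ in pairs}
    mir_paired = {m for _, m, _ in pairs}
    mm_mrna = len([p for p in range(site_start, site_end + 1) if p not in utr_paired])
    mm_mirna = len([p for p in range(1, mirna_len + 1) if p not in mir_paired])
    gu_whole = len([1 for _, _, c in pairs if c == "GU"])
    gu_seed = len(
        [1 for _, m, c in pairs if c == "GU" and seed_start <= m <= seed_start + 6]
    )
    return mm_mrna, mm_mirna, gu_whole, gu_seed


def coverage_by_counting(values, threshold):
    """Fraction of values ≤ threshold, counted one by one."""
    kept = 0
    for v in values:
        if v <= threshold:
            kept += 1
    return kept / len(values)


def enumerate_alignments(a: str, b: str, max_len: int):
    """Yield all global alignments of a and b of length ≤ max_len as string pairs."""

    def rec(i, j, ta, tb, length):
        if length > max_len:
            return
        if i == len(a) and j == len(b):
            yield ta, tb
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ta + a[i], tb + b[j], length + 1)
        if i < len(a):
            yield from rec(i + 1, j, ta + a[i], tb + "-", length + 1)
        if j < len(b):
            yield from rec(i, j + 1, ta + "-", tb + b[j], length + 1)

    yield from rec(0, 0, "", "", 0)


def score_alignment(ta: str, tb: str, match=1.9, mismatch=0.0, gap_open=22.50, gap_ext=0.83):
    """ClustalX-style affine score with free terminal gaps."""
    score = 0.0
    n = len(ta)
    for strand in (ta, tb):
        for is_gap, run in itertools.groupby(range(n), key=lambda k: strand[k] == "-"):
            run = list(run)
            if is_gap and run[0] != 0 and run[-1] != n - 1:
                score -= gap_open + gap_ext * len(run)
    for x, y in zip(ta, tb):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
    return score


def best_alignment_identities(a: str, b: str, max_len: int):
    """Identity values of all optimal affine-gap alignments (free end gaps)."""
    best_score = -inf
    idents: set[float] = set()
    for ta, tb in enumerate_alignments(a, b, max_len):
        s = score_alignment(ta, tb)
        ident = 100.0 * sum(1 for x, y in zip(ta, tb) if x == y and x != "-") / len(ta)
        if s > best_score + 1e-9:
            best_score = s
            idents = {ident}
        elif abs(s - best_score) <= 1e-9:
            idents.add(ident)
    return best_score, idents
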