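"""Independent brute-force reference implementations used for validation.

Each function here recomputes a pipeline quantity by exhaustive enumeration
or first-principles arithmetic, sharing at most the parameter tables (never
the algorithms) with the production code paths it cross-checks:

* :func:`brute_force_mfe` enumerates every nested secondary structure of a
  short sequence and scores it by direct loop decomposition.
* :func:`fisher_exact_enum` enumerates the full hypergeometric distribution
  of a 2x2 table with exact big-integer binomials.
* :func:`categorize_profile` re-derives the degradome category of a cleavage
  site from the raw position counts.
* :func:`best_target_score` rescans every window of a transcript with the
  complementarity penalty scheme.

These are exponential- or linear-scan implementations intended for tiny
inputs only.
"""

from __future__ import annotations

import math
from statistics import median

from . import fold_params as P
from ._seq import to_rna


# ---------------------------------------------------------------------------
# RNA folding by exhaustive enumeration
# ---------------------------------------------------------------------------

def _pairable(a: str, b: str) -> bool:
    return P.PAIR_CODE[P.BASE_CODE[a], P.BASE_CODE[b]] >= 0


def enumerate_structures(seq: str):
    """Yield every nested structure (as a sorted tuple of 0-based pairs)."""
    rna = to_rna(seq)
    n = len(rna)

    memo: dict[tuple[int, int], list[tuple]] = {}

    def rec(i: int, j: int) -> list[tuple]:
        if i >= j:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))
        for k in range(i + P.MIN_HAIRPIN + 1, j + 1):
            if _pairable(rna[i], rna[k]):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(left + right + ((i, k),))
        memo[key] = out
        return out

    yield from rec(0, n - 1)


def structure_energy(seq: str, pairs) -> int:
    """Energy (0.01 kcal/mol) of a given structure by loop decomposition.

    Walks each loop closed by a pair and charges it as a hairpin, stack,
    bulge, internal loop, or multiloop under the shared parameter tables.
    The exterior loop is free. Structures containing an interior loop larger
    than the DP's MAXLOOP bound are rejected (returns a huge energy) so the
    enumeration explores exactly the DP's structure space.
    """
    rna = to_rna(seq)
    partner = {i: j for i, j in pairs}
    partner.update({j: i for i, j in pairs})
    total = 0
    for i, j in pairs:
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += P.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 + n2 > P.MAXLOOP:
                return 1 << 40
            pc_out = P.PAIR_CODE[P.BASE_CODE[rna[i]], P.BASE_CODE[rna[j]]]
            pc_in = P.PAIR_CODE[P.BASE_CODE[rna[k]], P.BASE_CODE[rna[l]]]
            if n1 == 0 and n2 == 0:
                total += int(P.STACK[pc_out, pc_in])
            elif n1 == 0 or n2 == 0:
                total += P.bulge_energy(n1 + n2)
            else:
                total += P.internal_energy(n1, n2)
        else:
            total += P.ML_CLOSE + P.ML_BRANCH * (len(children) + 1) + P.ML_UNPAIRED * unpaired
    return total


def brute_force_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE in kcal/mol (feasible up to ~20 nt)."""
    best = 0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best / 100.0


# ---------------------------------------------------------------------------
# Fisher's exact test by full hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_exact_enum(a: int, total1: int, b: int, total2: int) -> float:
    """Two-sided Fisher p for [[a, total1-a], [b, total2-b]] from scratch.

    Enumerates every table with the observed margins using exact big-integer
    binomial coefficients and sums the probabilities of tables no more likely
    than the observed one (with the conventional 1+1e-7 tie guard).
    """
    if min(a, b) < 0 or a > total1 or b > total2:
        raise ValueError("counts must be within their totals")
    n = total1 + total2
    r = a + b
    denom = math.comb(n, r)
    lo, hi = max(0, r - total2), min(r, total1)
    probs = {
        k: math.comb(total1, k) * math.comb(total2, r - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p = sum(pk for pk in probs.values() if pk <= p_obs * (1 + 1e-7))
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Degradome category from first principles
# ---------------------------------------------------------------------------

def categorize_profile(counts: dict[int, int], position: int) -> int:
    """Re-derive the evidence category of a cleavage position.

    counts maps transcript positions to degradome 5'-end read counts;
    position must have a nonzero count. Category 4: a single raw read at the
    site; 0: the site is the unique maximum; 1: the site ties the maximum;
    2: above the median of occupied positions; 3: otherwise.
    """
    occupied = sorted(c for c in counts.values() if c > 0)
    c = counts[position]
    if c < 1:
        raise ValueError("no degradome read at the candidate position")
    if c == 1:
        return 4
    biggest = occupied[-1]
    if c == biggest:
        return 0 if occupied.count(biggest) == 1 else 1
    return 2 if c > median(occupied) else 3


# ---------------------------------------------------------------------------
# miRNA-target complementarity score by window rescan
# ---------------------------------------------------------------------------

def best_target_score(mirna: str, transcript: str) -> float:
    """Minimal complementarity penalty of a miRNA over every transcript window.

    Recomputes the penalty per window directly: 0 per Watson-Crick match,
    0.5 per G:U wobble, 1 per mismatch, doubled at miRNA positions 2-13.
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    m = to_rna(mirna)
    t = to_rna(transcript)
    L = len(m)
    best = math.inf
    for s in range(0, len(t) - L + 1):
        window = t[s : s + L]
        score = 0.0
        for idx in range(L):  # miRNA position idx+1 pairs window base L-1-idx
            mb, tb = m[idx], window[L - 1 - idx]
            if comp.get(mb) == tb:
                pen = 0.0
            elif (mb, tb) in (("G", "U"), ("U", "G")):
                pen = 0.5
            else:
                pen = 1.0
            if 2 <= idx + 1 <= 13:
                pen *= 2
            score += pen
        best = min(best, score)
    return best
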