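"""Minimum-free-energy RNA secondary structure prediction and hairpin statistics.

The folder is a Zuker-style dynamic program over the energy model defined in
:mod:`stemloop.fold_params`. Energies are integer centi-kcal/mol throughout,
so optima are exact and reproducible; the reported MFE is the integer optimum
divided by 100. Co-optimal structures are resolved by a fixed traceback
preference (helix extension, then smallest interior loop, then multiloop,
then hairpin closure), which makes the returned dot-bracket deterministic and
biased toward structures with more paired bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import fold_params as P
from ._seq import gc_fraction, to_rna  # noqa: F401  (gc_fraction re-exported)

INF = np.int64(1) << 40

_HP, _BG, _IL = P.loop_tables()
_PAIR = P.PAIR_CODE
_STACK = P.STACK


@dataclass(frozen=True)
class FoldResult:
    """Optimal structure of one sequence: dot-bracket, MFE, and pair table."""

    sequence: str  # RNA alphabet
    structure: str  # dot-bracket, same length
    mfe: float  # kcal/mol, <= 0
    pairs: tuple  # partner index per position, -1 if unpaired (0-based)

    def __post_init__(self):
        assert len(self.structure) == len(self.sequence)


@njit(cache=True)
def _fill(s, pair, stack, hp, bg, il, minhp, maxloop, ml_close, ml_branch, ml_unpaired, inf):
    n = s.shape[0]
    V = np.full((n, n), inf, dtype=np.int64)
    WM = np.full((n, n), inf, dtype=np.int64)
    W = np.zeros(n + 1, dtype=np.int64)
    asym_per, asym_max = 50, 300

    for span in range(minhp + 1, n):
        for i in range(0, n - span):
            j = i + span
            pc = pair[s[i], s[j]]
            if pc >= 0:
                best = hp[j - i - 1]
                # stacked pair / bulge / internal loop closing (k,l)
                max_n1 = j - i - 2 - minhp - 1
                if max_n1 > maxloop:
                    max_n1 = maxloop
                for n1 in range(0, max_n1 + 1):
                    k = i + 1 + n1
                    lim2 = maxloop - n1
                    top = j - 1 - (k + minhp + 1)
                    if top < lim2:
                        lim2 = top
                    for n2 in range(0, lim2 + 1):
                        l = j - 1 - n2
                        pc2 = pair[s[k], s[l]]
                        if pc2 < 0 or V[k, l] >= inf:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = stack[pc, pc2]
                        elif n1 == 0 or n2 == 0:
                            e = bg[n1 + n2]
                        else:
                            a = asym_per * (n1 - n2 if n1 > n2 else n2 - n1)
                            if a > asym_max:
                                a = asym_max
                            e = il[n1 + n2] + a
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k] < inf and WM[k + 1, j - 1] < inf:
                        cand = ml_close + ml_branch + WM[i + 1, k] + WM[k + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM
            best = inf
            if pc >= 0 and V[i, j] < inf:
                best = V[i, j] + ml_branch
            if WM[i + 1, j] < inf:
                cand = WM[i + 1, j] + ml_unpaired
                if cand < best:
                    best = cand
            if WM[i, j - 1] < inf:
                cand = WM[i, j - 1] + ml_unpaired
                if cand < best:
                    best = cand
            for k in range(i + 1, j):
                if WM[i, k] < inf and WM[k + 1, j] < inf:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best

    for j in range(0, n):
        best = W[j]  # prefix W index offset by one: W[j] covers 0..j-1
        for i in range(0, j):
            if V[i, j] < inf:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return V, WM, W


def _traceback(s, V, WM, W):
    n = s.shape[0]
    partner = np.full(n, -1, dtype=np.int64)

    def can_pair(i, j):
        return _PAIR[s[i], s[j]] >= 0 and j - i - 1 >= P.MIN_HAIRPIN

    def trace_V(i, j):
        partner[i], partner[j] = j, i
        e = V[i, j]
        pc = _PAIR[s[i], s[j]]
        # helix extension / interior loops, smallest loop first
        max_n1 = min(P.MAXLOOP, j - i - 2 - P.MIN_HAIRPIN - 1)
        for n1 in range(0, max_n1 + 1):
            k = i + 1 + n1
            lim2 = min(P.MAXLOOP - n1, j - 1 - (k + P.MIN_HAIRPIN + 1))
            for n2 in range(0, lim2 + 1):
                l = j - 1 - n2
                pc2 = _PAIR[s[k], s[l]]
                if pc2 < 0 or V[k, l] >= INF:
                    continue
                if n1 == 0 and n2 == 0:
                    le = _STACK[pc, pc2]
                elif n1 == 0 or n2 == 0:
                    le = _BG[n1 + n2]
                else:
                    le = _IL[n1 + n2] + min(P.ASYM_MAX, P.ASYM_PER_NT * abs(n1 - n2))
                if le + V[k, l] == e:
                    trace_V(k, l)
                    return
        for k in range(i + 2, j - 1):
            if (
                WM[i + 1, k] < INF
                and WM[k + 1, j - 1] < INF
                and P.ML_CLOSE + P.ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1] == e
            ):
                trace_WM(i + 1, k)
                trace_WM(k + 1, j - 1)
                return
        assert e == _HP[j - i - 1], "traceback failed to reproduce V"

    def trace_WM(i, j):
        e = WM[i, j]
        if can_pair(i, j) and V[i, j] < INF and V[i, j] + P.ML_BRANCH == e:
            trace_V(i, j)
            return
        for k in range(i + 1, j):
            if WM[i, k] < INF and WM[k + 1, j] < INF and WM[i, k] + WM[k + 1, j] == e:
                trace_WM(i, k)
                trace_WM(k + 1, j)
                return
        if WM[i + 1, j] < INF and WM[i + 1, j] + P.ML_UNPAIRED == e:
            trace_WM(i + 1, j)
            return
        assert WM[i, j - 1] < INF and WM[i, j - 1] + P.ML_UNPAIRED == e
        trace_WM(i, j - 1)

    j = n - 1
    while j >= 0:
        if W[j + 1] == W[j]:
            j -= 1
            continue
        done = False
        for i in range(0, j):
            if can_pair(i, j) and V[i, j] < INF and W[i] + V[i, j] == W[j + 1]:
                trace_V(i, j)
                j = i - 1
                done = True
                break
        assert done, "exterior traceback failed"
    return partner


def fold(sequence: str) -> FoldResult:
    """Predict the MFE structure of an RNA (or DNA-alphabet) sequence.

    Returns the optimal dot-bracket under the built-in nearest-neighbor
    model; an unpairable sequence folds to all dots with MFE 0. Deterministic
    for a given input.
    """
    rna = to_rna(sequence)
    if not rna:
        raise ValueError("cannot fold an empty sequence")
    if len(rna) > P.MAX_SEQ:
        raise ValueError(f"sequence longer than {P.MAX_SEQ} nt")
    s = P.encode(rna)
    n = len(s)
    if n <= P.MIN_HAIRPIN + 1:
        return FoldResult(rna, "." * n, 0.0, tuple([-1] * n))
    V, WM, W = _fill(
        s, _PAIR, _STACK, _HP, _BG, _IL,
        P.MIN_HAIRPIN, P.MAXLOOP, P.ML_CLOSE, P.ML_BRANCH, P.ML_UNPAIRED, INF,
    )
    mfe_int = int(W[n])
    if mfe_int >= 0:
        return FoldResult(rna, "." * n, 0.0, tuple([-1] * n))
    partner = _traceback(s, V, WM, W)
    db = "".join(
        "(" if p > i else ")" if p >= 0 else "." for i, p in enumerate(partner)
    )
    return FoldResult(rna, db, mfe_int / 100.0, tuple(int(p) for p in partner))


@dataclass(frozen=True)
class HairpinSpan:
    """A maximal stem-loop: 5' stem, terminal loop, 3' stem (1-based inclusive)."""

    stem5: tuple  # (start, end)
    loop: tuple
    stem3: tuple
    n_pairs: int

    @property
    def start(self) -> int:
        return self.stem5[0]

    @property
    def end(self) -> int:
        return self.stem3[1]


def find_hairpins(fr: FoldResult) -> list[HairpinSpan]:
    """Extract maximal stem-loops from a fold.

    Each innermost helix closing a terminal loop is extended outward through
    nested pairs (crossing bulges and internal loops) until it reaches a
    multiloop or the exterior loop. Multibranch structures therefore yield
    one span per branch.
    """
    partner = fr.pairs
    n = len(partner)
    spans: list[HairpinSpan] = []
    for i in range(n):
        j = partner[i]
        if j <= i:
            continue
        # innermost pair: nothing paired strictly inside
        if any(partner[k] >= 0 for k in range(i + 1, j)):
            continue
        inner_i, inner_j = i, j
        a, b = i, j
        n_pairs = 1
        while True:
            p = a - 1
            while p >= 0 and partner[p] < 0:
                p -= 1
            if p < 0 or partner[p] <= b:
                break
            q = partner[p]
            if any(partner[k] >= 0 for k in range(b + 1, q)):
                break
            a, b = p, q
            n_pairs += 1
        spans.append(
            HairpinSpan(
                stem5=(a + 1, inner_i + 1),
                loop=(inner_i + 2, inner_j),
                stem3=(inner_j + 1, b + 1),
                n_pairs=n_pairs,
            )
        )
    return spans


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: |MFE| per 100 nt over GC percent.

    MFEI = (|mfe| / length * 100) / (gc * 100); high values (around 0.7-1.5)
    are characteristic of miRNA precursors versus other RNA classes.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc <= 1:
        raise ValueError("MFEI is undefined for GC fraction 0")
    return (abs(mfe) / length * 100.0) / (gc * 100.0)
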