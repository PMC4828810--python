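"""Nearest-neighbor energy parameters for the built-in RNA folding model.

The model is a compact Turner-style loop decomposition: Watson-Crick and G:U
wobble pairs, stacking energies per adjacent pair of helical base pairs,
length-dependent hairpin/bulge/internal-loop penalties with logarithmic
extrapolation, a linear multiloop score, and a zero-energy exterior loop.
There are no dangling-end or terminal-AU terms. All energies are integers in
units of 0.01 kcal/mol so that the dynamic program, the traceback, and the
brute-force enumeration oracle compare energies exactly.

Absolute energies are therefore model-specific; thresholds expressed in
kcal/mol (for example the -18 kcal/mol precursor gate) are configuration
values tied to this model rather than universal constants.
"""

from __future__ import annotations

import math

import numpy as np

# Base encoding: A=0, C=1, G=2, U/T=3.
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# Pair codes: CG=0, GC=1, GU=2, UG=3, AU=4, UA=5; -1 = not pairable.
PAIR_CODE = -np.ones((4, 4), dtype=np.int64)
PAIR_CODE[1, 2] = 0  # C-G
PAIR_CODE[2, 1] = 1  # G-C
PAIR_CODE[2, 3] = 2  # G-U
PAIR_CODE[3, 2] = 3  # U-G
PAIR_CODE[0, 3] = 4  # A-U
PAIR_CODE[3, 0] = 5  # U-A

# Stacking energies (0.01 kcal/mol): STACK[outer_pair][inner_pair] for the
# helix element 5'-i,i+1 / j-1,j-3' with (i,j) the outer pair.
STACK = np.array(
    [
        # inner:  CG    GC    GU    UG    AU    UA
        [-330, -240, -210, -140, -210, -210],  # outer CG
        [-340, -330, -250, -150, -220, -240],  # outer GC
        [-250, -210, -140, -50, -130, -140],  # outer GU
        [-150, -140, -60, -50, -100, -60],  # outer UG
        [-220, -210, -140, -100, -110, -90],  # outer AU
        [-240, -210, -130, -60, -130, -90],  # outer UA
    ],
    dtype=np.int64,
)

MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop
MAXLOOP = 30  # largest bulge/internal loop handled by the DP

# Multiloop linear model: closing penalty + per-branch + per-unpaired base.
ML_CLOSE = 340
ML_BRANCH = 40
ML_UNPAIRED = 10

MAX_SEQ = 2000  # longest sequence the precomputed loop tables cover

_HAIRPIN_SMALL = {3: 540, 4: 560, 5: 570, 6: 580, 7: 590, 8: 600, 9: 610}
_BULGE_SMALL = {1: 380, 2: 280, 3: 320, 4: 360, 5: 400, 6: 440}
_INTERNAL_SMALL = {2: 150, 3: 160, 4: 170, 5: 200, 6: 220}

ASYM_PER_NT = 50  # internal-loop asymmetry penalty per nt, capped below
ASYM_MAX = 300


def hairpin_energy(n: int) -> int:
    """Penalty for a hairpin loop of n unpaired bases (n >= MIN_HAIRPIN)."""
    if n < MIN_HAIRPIN:
        raise ValueError(f"hairpin loop of {n} < {MIN_HAIRPIN} bases")
    if n <= 9:
        return _HAIRPIN_SMALL[n]
    return 610 + int(round(108.0 * math.log(n / 9.0)))


def bulge_energy(n: int) -> int:
    """Penalty for a bulge loop of n unpaired bases on one strand."""
    if n < 1:
        raise ValueError("bulge of size 0 is a stack")
    if n <= 6:
        return _BULGE_SMALL[n]
    return 440 + int(round(108.0 * math.log(n / 6.0)))


def internal_energy(n1: int, n2: int) -> int:
    """Penalty for an internal loop with n1/n2 unpaired bases per strand."""
    if n1 < 1 or n2 < 1:
        raise ValueError("internal loop needs unpaired bases on both strands")
    n = n1 + n2
    base = _INTERNAL_SMALL[n] if n <= 6 else 220 + int(round(108.0 * math.log(n / 6.0)))
    return base + min(ASYM_MAX, ASYM_PER_NT * abs(n1 - n2))


def loop_tables(max_len: int = MAX_SEQ):
    """Precomputed (hairpin, bulge, internal-base) arrays for the DP kernel.

    internal[n] is the size-dependent part for total loop size n; the
    asymmetry term is added inside the kernel.
    """
    hp = np.zeros(max_len + 1, dtype=np.int64)
    bg = np.zeros(max_len + 1, dtype=np.int64)
    il = np.zeros(2 * MAXLOOP + 1, dtype=np.int64)
    for n in range(MIN_HAIRPIN, max_len + 1):
        hp[n] = hairpin_energy(n)
    for n in range(1, max_len + 1):
        bg[n] = bulge_energy(n)
    for n in range(2, 2 * MAXLOOP + 1):
        il[n] = internal_energy(1, n - 1) - min(ASYM_MAX, ASYM_PER_NT * abs(n - 2))
    return hp, bg, il


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as the int array the DP kernel consumes."""
    try:
        return np.array([BASE_CODE[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from exc
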