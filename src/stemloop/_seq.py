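"""Small sequence helpers shared across the pipeline.

All pipeline-internal sequences are DNA-alphabet uppercase strings (A/C/G/T);
report surfaces convert mature miRNAs to the RNA alphabet (A/C/G/U) to match
miRBase conventions.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA (or RNA) string."""
    if "U" in seq:
        return seq.translate(_RNA_COMP)[::-1]
    return seq.translate(_DNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length; raises on empty input."""
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
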