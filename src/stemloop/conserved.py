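"""Conserved miRNA assignment against a reference mature set.

Unique sRNAs (pre-filtered to 20-24 nt and TPM >= 5 in at least one library)
are compared to a miRBase-style mature FASTA by ungapped, equal-length
comparison allowing up to two mismatches; assigned reads are grouped into
miRNA families and summarised, including the positional nucleotide bias.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from ._seq import to_dna
from .preprocess import UniqueRead

FAMILY_RE = re.compile(r"(miR)\s*?(\d+)", re.IGNORECASE)


@dataclass
class ConservedAssignment:
    unique_read: UniqueRead
    ref_id: str
    family: str
    mismatches: int


def candidate_gate(
    unique_reads: list[UniqueRead],
    tpm_min: float = 5.0,
    min_len: int = 20,
    max_len: int = 24,
) -> list[UniqueRead]:
    """Inclusion gate for miRNA identification: 20-24 nt and TPM >= 5 somewhere."""
    return [
        u
        for u in unique_reads
        if min_len <= len(u) <= max_len and max(u.tpm.values()) >= tpm_min
    ]


def family_name(ref_id: str) -> str:
    """Family token: 'miR' + digits, suffixes stripped (aof-miR166d-1 -> miR166)."""
    m = FAMILY_RE.search(ref_id)
    if not m:
        return ref_id
    return f"miR{m.group(2)}"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


def match_known(
    unique_reads: list[UniqueRead],
    mature_db,
    max_mismatch: int = 2,
) -> tuple[list[ConservedAssignment], list[UniqueRead]]:
    """Assign each read to the closest equal-length reference mature.

    Comparison is ungapped and end-to-end; a read is assigned to the entry
    with the fewest mismatches (<= max_mismatch), ties broken by the
    lexicographically smallest reference id. Returns (assignments,
    unassigned reads) -- the latter flow to novel identification.
    """
    db = [(rec.id, to_dna(str(rec.seq))) for rec in mature_db]
    if not db:
        raise ValueError("mature_db must be non-empty")
    by_len: dict[int, list[tuple[str, str]]] = {}
    for rid, seq in sorted(db):
        by_len.setdefault(len(seq), []).append((rid, seq))
    assigned, unassigned = [], []
    for u in unique_reads:
        best: tuple[int, str] | None = None
        for rid, seq in by_len.get(len(u.sequence), []):
            d = hamming(u.sequence, seq)
            if d <= max_mismatch and (best is None or d < best[0]):
                best = (d, rid)
        if best is None:
            unassigned.append(u)
        else:
            assigned.append(
                ConservedAssignment(u, best[1], family_name(best[1]), best[0])
            )
    return assigned, unassigned


def family_summary(assignments: list[ConservedAssignment]) -> pd.DataFrame:
    """(family, member count) table sorted by count descending, then name."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.family] = counts.get(a.family, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["family", "members"],
    )
    return df


def nucleotide_bias(sequences: list[str]) -> pd.DataFrame:
    """Position x base frequency matrix (RNA alphabet, positions 1..max length).

    Each position's frequencies sum to 1 over the sequences long enough to
    cover it. In conserved plant miRNA sets, position 1 is dominated by U.
    """
    if not sequences:
        raise ValueError("nucleotide_bias of empty input")
    seqs = [s.upper().replace("T", "U") for s in sequences]
    max_len = max(len(s) for s in seqs)
    rows = []
    for pos in range(max_len):
        bases = [s[pos] for s in seqs if len(s) > pos]
        n = len(bases)
        rows.append({"position": pos + 1, **{b: bases.count(b) / n for b in "ACGU"}})
    return pd.DataFrame(rows).fillna(0.0)
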