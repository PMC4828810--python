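"""Raw-read preprocessing: adapter trimming, filtering, collapsing, accounting.

Converts each library's raw reads into collapsed unique small RNAs with
per-library counts and TPM (tags per million, normalised by each library's
final clean read total), and produces the per-stage read accounting and the
unique-read length distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp

MIN_LEN = 15
MAX_LEN = 45


@dataclass
class LibraryAccounting:
    """Per-library read counts after each preprocessing stage."""

    library: str
    raw_reads: int = 0
    after_trim: int = 0  # adapter found, quality OK
    clean_reads: int = 0  # within the 15-45 nt length window
    final_clean: int = 0  # after ncRNA contaminant removal
    unique_reads: int = 0

    def validate(self) -> None:
        seq = [self.raw_reads, self.after_trim, self.clean_reads, self.final_clean]
        if any(a < b for a, b in zip(seq, seq[1:])) or self.unique_reads > self.final_clean:
            raise ValueError(f"non-monotone accounting for library {self.library}")
        if min(seq + [self.unique_reads]) < 0:
            raise ValueError("negative count in accounting")


@dataclass
class UniqueRead:
    """A collapsed distinct sRNA with per-library raw counts and TPM."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(
    read: str, adapter: str, min_overlap: int = 6, max_mismatch: int = 1
) -> str | None:
    """Insert preceding the left-most adapter occurrence, or None if absent.

    The adapter may be truncated at the read's 3' end, as long as at least
    `min_overlap` bases overlap with at most `max_mismatch` mismatches.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    if not read:
        return None
    read, adapter = read.upper(), adapter.upper()
    for p in range(0, len(read) - min_overlap + 1):
        ov = min(len(adapter), len(read) - p)
        mism = sum(1 for a, b in zip(read[p : p + ov], adapter[:ov]) if a != b)
        if mism <= max_mismatch:
            return read[:p]
    return None


def quality_ok(quals: list[int] | None, seq: str, min_mean_phred: int = 20) -> bool:
    """FASTQ quality gate: no N and mean Phred >= threshold; FASTA always passes."""
    if "N" in seq.upper():
        return False
    if quals is None:
        return True
    return sum(quals) / len(quals) >= min_mean_phred if quals else False


def filter_length(reads, min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> list[str]:
    """Keep reads with length in [min_len, max_len], preserving order."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def filter_ncrna(reads, ncrna_set) -> tuple[list[str], int]:
    """Drop reads that are exact substrings of any ncRNA record, either strand.

    Returns (retained reads, removed count). ncrna_set is a collection of
    Bio SeqRecords (or plain strings).
    """
    seqs = [str(getattr(r, "seq", r)).upper() for r in ncrna_set]
    if not seqs:
        raise ValueError("ncRNA set must be non-empty")
    haystack = "#".join(seqs + [revcomp(s) for s in seqs])
    kept = [r for r in reads if r not in haystack]
    return kept, len(reads) - len(kept)


def preprocess_library(
    raw_reads,
    adapter: str | None,
    ncrna_set,
    library: str,
    qualities=None,
    min_overlap: int = 6,
    max_mismatch: int = 1,
    pre_trimmed: bool = False,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[str], LibraryAccounting]:
    """Run one library through trim -> quality -> length -> ncRNA filters.

    In "raw" mode (default) a read without any adapter occurrence is
    rejected; with pre_trimmed=True reads lacking the adapter are kept as-is.
    """
    acc = LibraryAccounting(library=library, raw_reads=len(raw_reads))
    trimmed: list[str] = []
    for i, read in enumerate(raw_reads):
        q = qualities[i] if qualities is not None else None
        if not quality_ok(q, read):
            continue
        if adapter is None:
            trimmed.append(read.upper())
            continue
        insert = trim_adapter(read, adapter, min_overlap, max_mismatch)
        if insert is None:
            if pre_trimmed:
                trimmed.append(read.upper())
            continue
        elif insert:
            trimmed.append(insert)
    acc.after_trim = len(trimmed)
    clean = filter_length(trimmed, min_len, max_len)
    acc.clean_reads = len(clean)
    final, _removed = filter_ncrna(clean, ncrna_set)
    acc.final_clean = len(final)
    acc.unique_reads = len(set(final))
    acc.validate()
    return final, acc


def collapse(reads_per_library: dict[str, list[str]]) -> list[UniqueRead]:
    """Collapse clean reads into unique sRNAs with per-library counts and TPM.

    TPM denominators are each library's final clean totals, so per-library
    TPMs sum to 1e6 over the unique-read set.
    """
    counters = {lib: Counter(reads) for lib, reads in reads_per_library.items()}
    totals = {lib: sum(c.values()) for lib, c in counters.items()}
    all_seqs = sorted(set().union(*[set(c) for c in counters.values()]))
    out = []
    for seq in all_seqs:
        counts = {lib: counters[lib][seq] for lib in counters}
        tpm = {
            lib: (counts[lib] / totals[lib] * 1e6 if totals[lib] else 0.0)
            for lib in counters
        }
        out.append(UniqueRead(sequence=seq, counts=counts, tpm=tpm))
    return out


def length_distribution(unique_reads: list[UniqueRead]) -> pd.DataFrame:
    """Unique-read counts and fractions per length (15-45 nt), per library.

    Counts distinct sequences (not read abundance), mirroring the standard
    unique-sRNA length profile where 24-nt then 21-nt classes dominate.
    """
    if not unique_reads:
        raise ValueError("length_distribution of empty input")
    libs = sorted(unique_reads[0].counts)
    rows = []
    for ln in range(MIN_LEN, MAX_LEN + 1):
        row: dict = {"length": ln}
        for lib in libs:
            row[f"count_{lib}"] = sum(
                1 for u in unique_reads if len(u) == ln and u.counts[lib] > 0
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for lib in libs:
        total = df[f"count_{lib}"].sum()
        df[f"fraction_{lib}"] = df[f"count_{lib}"] / total if total else 0.0
    return df


def accounting_table(accounts: list[LibraryAccounting]) -> pd.DataFrame:
    """Accounting rows in sequencing-statistics style, one column per library."""
    rows = {
        "Raw reads": [a.raw_reads for a in accounts],
        "Adaptor/quality/<15 nt removed": [a.raw_reads - a.clean_reads for a in accounts],
        "Clean reads": [a.clean_reads for a in accounts],
        "ncRNA removed": [a.clean_reads - a.final_clean for a in accounts],
        "Final clean reads": [a.final_clean for a in accounts],
        "Unique reads": [a.unique_reads for a in accounts],
    }
    return pd.DataFrame(rows, index=[a.library for a in accounts]).T
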