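"""FASTA/FASTQ readers and plain-text writers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import UniqueRead


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def read_reads(path) -> tuple[list[str], list[list[int]] | None]:
    """Read sequences (and Phred qualities for FASTQ) from FASTA or FASTQ."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads, quals = [], []
    for rec in SeqIO.parse(str(path), fmt):
        reads.append(str(rec.seq).upper())
        if fmt == "fastq":
            quals.append(rec.letter_annotations["phred_quality"])
    return reads, (quals if fmt == "fastq" else None)


def write_fasta(records, path) -> None:
    """Write (id, seq) pairs or SeqRecords as FASTA."""
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_reads_fasta(reads: list[str], path, prefix: str = "read") -> None:
    write_fasta([(f"{prefix}{i + 1}", r) for i, r in enumerate(reads)], path)


def write_unique_reads(unique_reads: list[UniqueRead], tsv_path, fasta_path=None) -> None:
    """Collapsed unique sRNAs as TSV and optional 'id_countF_countM' FASTA."""
    libs = sorted(unique_reads[0].counts) if unique_reads else ["F", "M"]
    with open(tsv_path, "w") as fh:
        cols = ["sequence"] + [f"count_{l}" for l in libs] + [f"tpm_{l}" for l in libs]
        fh.write("\t".join(cols) + "\n")
        for u in unique_reads:
            row = [u.sequence]
            row += [str(u.counts[l]) for l in libs]
            row += [f"{u.tpm[l]:.4f}" for l in libs]
            fh.write("\t".join(row) + "\n")
    if fasta_path:
        write_fasta(
            [
                ("u{}_{}".format(i + 1, "_".join(str(u.counts[l]) for l in libs)), u.sequence)
                for i, u in enumerate(unique_reads)
            ],
            fasta_path,
        )


def read_unique_reads(tsv_path) -> list[UniqueRead]:
    out = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libs = [c[len("count_"):] for c in header if c.startswith("count_")]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rec = dict(zip(header, parts))
            out.append(
                UniqueRead(
                    sequence=rec["sequence"],
                    counts={l: int(rec[f"count_{l}"]) for l in libs},
                    tpm={l: float(rec[f"tpm_{l}"]) for l in libs},
                )
            )
    return out


def write_truth_table(truth, path) -> None:
    """Generator ground truth as TSV (one row per planted miRNA locus)."""
    cols = [
        "mirna_id", "sequence", "unigene", "start", "end", "strand", "arm",
        "count_F", "count_M", "de_direction",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in truth.mirnas:
            c = truth.counts.get(m.mirna_id, {"F": 0, "M": 0})
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        m.mirna_id, m.mature, m.unigene, m.start, m.end, m.strand,
                        m.arm, c["F"], c["M"], truth.de_flags.get(m.mirna_id) or "ns",
                    ]
                )
                + "\n"
            )
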