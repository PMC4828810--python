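"""Novel miRNA calling from transcript-mapped small RNAs.

Reads that pass the candidate gate but match no reference mature are mapped
perfectly to the unigene reference on both strands; a 200-nt flanking window
around each locus is extracted and folded; candidates must place the mature
entirely within one arm of a stem-loop, pair with a recoverable star sequence
(2-nt 3' overhangs, limited duplex mismatches and bulges), and clear the
precursor MFE gate. The reported precursor is trimmed to the minimal
hairpin-containing subsequence, and loci of the same mature are merged when
their windows largely overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from ._seq import gc_fraction, revcomp, to_rna
from .preprocess import UniqueRead
from .structure import FoldResult, find_hairpins, fold, mfei


@dataclass
class Thresholds:
    """Tunable criteria for precursor acceptance."""

    flank: int = 200  # nt of transcript context on each side of the mature
    mfe_max: float = -18.0  # kcal/mol gate on the trimmed precursor
    mfei_window: tuple = (0.7, 1.5)
    mfei_gate: bool = False  # MFEI window is advisory by default
    max_duplex_mismatch: int = 4  # unpaired mature bases in the duplex region
    max_asymmetric_bulge: int = 2
    min_len: int = 20
    max_len: int = 24
    tpm_min: float = 5.0


@dataclass
class Locus:
    unigene: str
    start: int  # 1-based inclusive, + axis
    end: int
    strand: str


@dataclass
class PrecursorCandidate:
    mature: str  # DNA
    locus: Locus  # mature locus
    unigene: str
    start: int  # trimmed precursor span, 1-based inclusive on the + axis
    end: int
    strand: str
    precursor: str  # sense-strand precursor sequence (DNA)
    fold_result: FoldResult | None
    mfe: float
    gc: float  # GC fraction of the trimmed precursor
    mfei_value: float
    mature_offset: int  # 0-based offset of the mature within the precursor
    arm: str  # 5p | 3p | ""
    star: str | None
    verdicts: dict = field(default_factory=dict)
    fail_reason: str = ""

    @property
    def passed(self) -> bool:
        return all(self.verdicts.get(k, False) for k in ("hairpin", "arm", "duplex", "star", "mfe", "mfei"))


@dataclass
class NovelMiRNA:
    mirna_id: str
    mature: str  # DNA
    counts: dict
    tpm: dict
    precursors: list[PrecursorCandidate]


def map_perfect(sread: str, transcripts: dict[str, str]) -> list[Locus]:
    """All exact occurrences of a read on both strands of the reference.

    Minus-strand hits (the reverse complement occurs in the transcript) are
    reported in +-axis coordinates, 1-based inclusive.
    """
    loci = []
    rc = revcomp(sread)
    for uid in sorted(transcripts):
        t = transcripts[uid]
        for query, strand in ((sread, "+"), (rc, "-")):
            p = t.find(query)
            while p != -1:
                loci.append(Locus(uid, p + 1, p + len(query), strand))
                p = t.find(query, p + 1)
    return loci


def extract_precursor(
    locus: Locus, transcripts: dict[str, str], flank: int = 200
) -> tuple[str, int, int]:
    """Window of `flank` nt around the locus: (sequence, wstart, wend).

    Coordinates are 1-based inclusive on the + axis; for minus-strand loci
    the returned sequence is the reverse complement of the window so the
    mature is always a literal substring.
    """
    t = transcripts[locus.unigene]
    wstart = max(1, locus.start - flank)
    wend = min(len(t), locus.end + flank)
    seq = t[wstart - 1 : wend]
    if locus.strand == "-":
        seq = revcomp(seq)
    return seq, wstart, wend


def _duplex_stats(partner: tuple, m_off: int, L: int) -> tuple[int, int, list[int], list[int]]:
    """Mismatches, max asymmetric bulge, paired mature indices, partners.

    The duplex region excludes the mature's 2-nt 3' overhang (indices
    0..L-3). Only pairs on the majority side (the star arm) count as duplex
    pairs; unpaired bases, self-pairs, and stray pairs to the other side all
    count as mismatches.
    """
    pairs = []
    for i in range(L - 2):
        q = partner[m_off + i]
        if q >= 0:
            pairs.append((i, q))
    left = [(i, q) for i, q in pairs if q < m_off]
    right = [(i, q) for i, q in pairs if q > m_off + L - 1]
    side = left if len(left) >= len(right) else right
    if side:
        # along an ungapped duplex, partner + index is constant; pairs far
        # off that register belong to stray helices, not the miRNA* duplex
        register = sorted(q + i for i, q in side)[len(side) // 2]
        side = [(i, q) for i, q in side if abs(q + i - register) <= 6]
    idx = [i for i, _ in side]
    part = [q for _, q in side]
    mismatches = (L - 2) - len(side)
    bulge = 0
    for (i1, q1), (i2, q2) in zip(zip(idx, part), zip(idx[1:], part[1:])):
        gap_m = i2 - i1 - 1
        gap_s = q1 - q2 - 1
        bulge = max(bulge, abs(gap_m - gap_s))
    return mismatches, bulge, idx, part


def find_star(window: str, fr: FoldResult, mature_offset: int, mature_len: int) -> str | None:
    """Recover the star sequence pairing the mature with 2-nt 3' overhangs.

    Uses the duplex geometry (partner + index is constant along an ungapped
    duplex) anchored at the median to tolerate scattered mismatches; absent
    when fewer than mature_len - 4 duplex bases are paired or the span falls
    outside the window.
    """
    L = mature_len
    mismatches, _, idx, part = _duplex_stats(fr.pairs, mature_offset, L)
    if len(idx) < L - 4:
        return None
    c = int(median(q + i for i, q in zip(idx, part)))
    lo, hi = c - (L - 3), c + 2
    if lo < 0 or hi >= len(window):
        return None
    if not (hi < mature_offset or lo > mature_offset + L - 1):
        return None  # degenerate: star span overlaps the mature
    return window[lo : hi + 1]


def evaluate_candidate(
    mature: str,
    window: str,
    locus: Locus,
    wstart: int,
    wend: int,
    thresholds: Thresholds | None = None,
) -> PrecursorCandidate:
    """Fold a precursor window and apply the acceptance criteria.

    Criteria: the mature lies entirely within one arm of a stem-loop; the
    mature/star duplex has at most `max_duplex_mismatch` unpaired mature
    bases and no asymmetric bulge larger than `max_asymmetric_bulge`; a star
    with 2-nt 3' overhangs exists on the opposite arm; the trimmed precursor
    MFE is at most `mfe_max`; and (advisory by default) its MFEI falls in
    `mfei_window`. The reported precursor is the minimal hairpin span.
    """
    th = thresholds or Thresholds()
    L = len(mature)
    m_off = window.find(mature)
    cand = PrecursorCandidate(
        mature=mature, locus=locus, unigene=locus.unigene,
        start=wstart, end=wend, strand=locus.strand, precursor=window,
        fold_result=None, mfe=0.0, gc=0.0, mfei_value=0.0,
        mature_offset=m_off, arm="", star=None,
    )
    if m_off < 0:
        cand.fail_reason = "mature not in window"
        cand.verdicts = {k: False for k in ("hairpin", "arm", "duplex", "star", "mfe", "mfei")}
        return cand
    if len(window) < 2 * L + 8:
        cand.fail_reason = "window too short for a duplex"
        cand.verdicts = {k: False for k in ("hairpin", "arm", "duplex", "star", "mfe", "mfei")}
        return cand

    fr = fold(window)
    cand.fold_result = fr
    spans = find_hairpins(fr)
    mismatches, bulge, idx, part = _duplex_stats(fr.pairs, m_off, L)

    # The stem-loop is located by the mature's paired duplex extent; the
    # unpaired 2-nt 3' overhang may poke past the outermost pair (3p arm) or
    # into the terminal loop (5p arm) without penalty.
    hp = None
    if idx:
        p_lo, p_hi = m_off + idx[0] + 1, m_off + idx[-1] + 1  # 1-based
        hp = next((h for h in spans if h.start <= p_lo and p_hi <= h.end), None)
    cand.verdicts["hairpin"] = hp is not None

    # Arm containment: duplex pairs all point at the opposite arm (strays
    # already counted as mismatches, but >2 or any self-pair fails), and the
    # paired extent stays on its side of the terminal loop.
    arm_ok = False
    if hp is not None and idx:
        partners = [fr.pairs[m_off + i] for i in range(L)]
        self_paired = any(m_off <= p <= m_off + L - 1 for p in partners if p >= 0)
        strays = sum(
            1 for i in range(L - 2)
            if fr.pairs[m_off + i] >= 0 and i not in idx
        )
        if not self_paired and strays <= 2:
            if all(q > m_off + L - 1 for q in part):
                if p_lo >= hp.stem5[0] and p_hi <= hp.loop[1]:
                    cand.arm, arm_ok = "5p", True
            elif all(q < m_off for q in part):
                if p_lo >= hp.loop[0] and p_hi <= hp.stem3[1]:
                    cand.arm, arm_ok = "3p", True
    cand.verdicts["arm"] = arm_ok

    cand.verdicts["duplex"] = (
        mismatches <= th.max_duplex_mismatch and bulge <= th.max_asymmetric_bulge
    )
    cand.star = find_star(window, fr, m_off, L)
    cand.verdicts["star"] = cand.star is not None

    if hp is not None:
        t_lo = min(hp.start, m_off + 1)
        t_hi = max(hp.end, m_off + L)
        trimmed = window[t_lo - 1 : t_hi]
        tfr = fold(trimmed)
        cand.mfe = tfr.mfe
        cand.gc = gc_fraction(trimmed)
        cand.mfei_value = mfei(tfr.mfe, len(trimmed), cand.gc) if cand.gc > 0 else 0.0
        cand.precursor = trimmed
        cand.mature_offset = m_off - (t_lo - 1)
        # map the trimmed span back to +-axis unigene coordinates
        if locus.strand == "+":
            cand.start = wstart + t_lo - 1
            cand.end = wstart + t_hi - 1
        else:
            cand.start = wend - t_hi + 1
            cand.end = wend - t_lo + 1
    cand.verdicts["mfe"] = hp is not None and cand.mfe <= th.mfe_max
    lo, hi = th.mfei_window
    in_window = hp is not None and lo <= cand.mfei_value <= hi
    cand.verdicts["mfei"] = in_window if th.mfei_gate else True
    if not cand.passed and not cand.fail_reason:
        cand.fail_reason = ",".join(k for k, v in cand.verdicts.items() if not v)
    return cand


def call_candidates(
    unique_reads: list[UniqueRead],
    transcripts: dict[str, str],
    thresholds: Thresholds | None = None,
) -> list[PrecursorCandidate]:
    """Map each unassigned read and evaluate every locus window."""
    th = thresholds or Thresholds()
    out = []
    for u in unique_reads:
        for locus in map_perfect(u.sequence, transcripts):
            window, wstart, wend = extract_precursor(locus, transcripts, th.flank)
            out.append(evaluate_candidate(u.sequence, window, locus, wstart, wend, th))
    return out


def _merge_loci(cands: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse same-mature candidates whose precursor spans overlap >= 50%."""
    kept: list[PrecursorCandidate] = []
    for c in sorted(cands, key=lambda c: (c.unigene, c.strand, c.start, c.end)):
        dup = False
        for k in kept:
            if k.unigene != c.unigene or k.strand != c.strand:
                continue
            ov = min(k.end, c.end) - max(k.start, c.start) + 1
            if ov > 0 and ov >= 0.5 * min(k.end - k.start + 1, c.end - c.start + 1):
                dup = True
                break
        if not dup:
            kept.append(c)
    return kept


def assemble_novel_set(
    candidates: list[PrecursorCandidate],
    unique_reads: list[UniqueRead],
    conserved_sequences: set[str] | None = None,
    prefix: str = "miRn",
) -> list[NovelMiRNA]:
    """Aggregate passing candidates into one novel miRNA per mature sequence.

    Matures already assigned to a reference miRNA are excluded; ids are
    assigned in lexicographic order of the mature sequence.
    """
    conserved_sequences = conserved_sequences or set()
    reads = {u.sequence: u for u in unique_reads}
    by_mature: dict[str, list[PrecursorCandidate]] = {}
    for c in candidates:
        if c.passed and c.mature not in conserved_sequences:
            by_mature.setdefault(c.mature, []).append(c)
    out = []
    for i, mature in enumerate(sorted(by_mature), start=1):
        u = reads.get(mature)
        out.append(
            NovelMiRNA(
                mirna_id=f"{prefix}{i:02d}",
                mature=mature,
                counts=dict(u.counts) if u else {},
                tpm=dict(u.tpm) if u else {},
                precursors=_merge_loci(by_mature[mature]),
            )
        )
    return out


def novel_table(novel_set: list[NovelMiRNA]) -> pd.DataFrame:
    """Locus-level novel miRNA report (one row per precursor locus)."""
    rows = []
    for nm in novel_set:
        for c in nm.precursors:
            rows.append(
                {
                    "miRNA-name": nm.mirna_id,
                    "Sequence": to_rna(nm.mature),
                    "Length": len(nm.mature),
                    "GC%": f"{gc_fraction(nm.mature) * 100:.1f}",
                    "TPM female": f"{nm.tpm.get('F', 0.0):.2f}",
                    "TPM male": f"{nm.tpm.get('M', 0.0):.2f}",
                    "Folding energy": f"{c.mfe:.2f}",
                    "MFEI": f"{c.mfei_value:.2f}",
                    "Unigene": c.unigene,
                    "Start": c.start,
                    "End": c.end,
                    "Strand": c.strand,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "miRNA-name", "Sequence", "Length", "GC%", "TPM female", "TPM male",
            "Folding energy", "MFEI", "Unigene", "Start", "End", "Strand",
        ],
    )


def novel_summary(table: pd.DataFrame) -> dict:
    """Corpus statistics of a locus-level novel-miRNA table.

    Star entries (names ending in '*') are excluded from the miRNA census.
    Returns the number of distinct novel miRNAs, the percent at each mature
    length, per-miRNA locus counts, and the number of miRNAs per unigene.
    """
    df = table[~table["miRNA-name"].astype(str).str.endswith("*")]
    names = df["miRNA-name"].unique()
    lengths = df.drop_duplicates("miRNA-name")["Length"].astype(int)
    loci_per = df.groupby("miRNA-name").size()
    mirnas_per_unigene = df.groupby("Unigene")["miRNA-name"].nunique()
    return {
        "n_mirnas": len(names),
        "length_pct": {
            int(ln): round(100.0 * (lengths == ln).sum() / len(lengths), 1)
            for ln in sorted(lengths.unique())
        },
        "loci_per_mirna": loci_per.to_dict(),
        "n_multi_locus": int((loci_per > 1).sum()),
        "mirnas_per_unigene": mirnas_per_unigene.to_dict(),
    }
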