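"""Degradome (PARE) analysis: mapping, target alignment, cleavage categories.

Degradome reads mark the uncapped 5' ends of mRNA decay fragments; a
miRNA-guided cleavage leaves a dominant 5' end opposite the 10th miRNA
nucleotide. This module builds per-transcript 5'-end profiles from perfectly
mapped sense-strand reads, scans transcripts for complementarity to each
miRNA with the plant-target penalty scheme (0 per match, 0.5 per G:U wobble,
1 per mismatch, doubled over miRNA positions 2-13, cutoff 7.0), detects
cleavage signatures at the expected position, and classifies hits into the
t-plot evidence categories 0-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from ._seq import to_dna

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class DegradomeProfile:
    transcript: str
    counts: dict[int, int] = field(default_factory=dict)  # 1-based position -> reads

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_count(self) -> int:
        return max(self.counts.values(), default=0)


@dataclass
class TargetAlignment:
    mirna_id: str
    mirna: str  # DNA
    transcript: str
    site_start: int  # 1-based inclusive on the transcript
    site_end: int
    score: float
    pairing: str  # one symbol per miRNA position: '|' match, 'o' wobble, 'x' mismatch


@dataclass
class DegradomeHit:
    alignment: TargetAlignment
    cleavage_pos: int  # 1-based transcript coordinate
    reads: int
    category: int = -1


def map_degradome(
    reads: list[str], transcripts: dict[str, str], min_len: int = 20, max_len: int = 21
) -> dict[str, DegradomeProfile]:
    """Per-transcript 5'-end profiles from perfect sense-strand matches.

    Multi-mapping reads increment every matched position; antisense matches
    are ignored (mRNA decay is sense-strand).
    """
    profiles = {uid: DegradomeProfile(uid) for uid in transcripts}
    for read in reads:
        r = to_dna(read)
        if not min_len <= len(r) <= max_len:
            continue
        for uid in sorted(transcripts):
            t = transcripts[uid]
            p = t.find(r)
            while p != -1:
                profiles[uid].counts[p + 1] = profiles[uid].counts.get(p + 1, 0) + 1
                p = t.find(r, p + 1)
    return {uid: pr for uid, pr in profiles.items() if pr.counts}


def _position_penalty(mirna_base: str, target_base: str, pos_1based: int) -> float:
    if _COMP[mirna_base] == target_base:
        pen = 0.0
    elif (mirna_base, target_base) in _WOBBLE:
        pen = 0.5
    else:
        pen = 1.0
    return pen * 2 if 2 <= pos_1based <= 13 else pen


def target_align(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    max_score: float = 7.0,
) -> list[TargetAlignment]:
    """Ungapped complementarity scan of a miRNA along a transcript.

    The miRNA is slid in reverse-complement frame; miRNA position i (1-based
    from the 5' end) faces transcript base site_start + L - i. Sites with a
    total penalty <= max_score are retained.
    """
    m = to_dna(mirna)
    L = len(m)
    if not 20 <= L <= 24:
        raise ValueError("miRNA length must be 20-24 nt")
    t = to_dna(transcript)
    out = []
    for s in range(0, len(t) - L + 1):
        score = 0.0
        pairing = []
        for i in range(1, L + 1):
            pen = _position_penalty(m[i - 1], t[s + L - i], i)
            score += pen
            pairing.append("|" if pen == 0 else "o" if pen in (0.5, 1.0) and (m[i - 1], t[s + L - i]) in _WOBBLE else "x")
            if score > max_score:
                break
        if score <= max_score:
            out.append(
                TargetAlignment(
                    mirna_id=mirna_id,
                    mirna=m,
                    transcript=transcript_id,
                    site_start=s + 1,
                    site_end=s + L,
                    score=score,
                    pairing="".join(pairing),
                )
            )
    return out


def detect_cleavage(
    alignment: TargetAlignment,
    profile: DegradomeProfile,
    offset_window: tuple = (10,),
) -> DegradomeHit | None:
    """Hit iff degradome 5' ends fall opposite miRNA nucleotide 10.

    The transcript position facing miRNA position k is site_start + L - k;
    the default window is the strict position 10, configurable to (9, 10, 11).
    Returns the hit at the best-covered window position, or None.
    """
    L = len(alignment.mirna)
    best: DegradomeHit | None = None
    for k in offset_window:
        pos = alignment.site_start + L - k
        reads = profile.counts.get(pos, 0)
        if reads > 0 and (best is None or reads > best.reads):
            best = DegradomeHit(alignment=alignment, cleavage_pos=pos, reads=reads)
    return best


def categorize(hit: DegradomeHit, profile: DegradomeProfile) -> int:
    """T-plot evidence category of a cleavage site.

    With c the count at the cleavage position, M the transcript maximum and
    m the median over occupied positions: 4 iff c == 1; 0 iff c == M attained
    at exactly one position; 1 iff c == M shared; 2 iff c > m; else 3.
    """
    c = profile.counts.get(hit.cleavage_pos, 0)
    if c < 1:
        raise ValueError("cleavage position has no degradome reads")
    if c == 1:
        return 4
    occupied = [v for v in profile.counts.values() if v > 0]
    M = max(occupied)
    if c == M:
        return 0 if occupied.count(M) == 1 else 1
    return 2 if c > median(occupied) else 3


def call_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    max_score: float = 7.0,
    offset_window: tuple = (10,),
) -> list[DegradomeHit]:
    """Full degradome target calling over profiled transcripts."""
    hits = []
    for mid in sorted(mirnas):
        for uid in sorted(profiles):
            for aln in target_align(mid, mirnas[mid], uid, transcripts[uid], max_score):
                hit = detect_cleavage(aln, profiles[uid], offset_window)
                if hit is not None:
                    hit.category = categorize(hit, profiles[uid])
                    hits.append(hit)
    return hits


def tplot_table(profile: DegradomeProfile, hits: list[DegradomeHit]) -> pd.DataFrame:
    """Per-position (position, count, is_cleavage_site) table for t-plots."""
    flagged = {h.cleavage_pos for h in hits if h.alignment.transcript == profile.transcript}
    rows = [
        {"position": pos, "count": cnt, "is_cleavage_site": pos in flagged}
        for pos, cnt in sorted(profile.counts.items())
    ]
    return pd.DataFrame(rows, columns=["position", "count", "is_cleavage_site"])


def hits_table(hits: list[DegradomeHit]) -> pd.DataFrame:
    """Hit-level degradome report."""
    rows = [
        {
            "miRNA": h.alignment.mirna_id,
            "Transcript": h.alignment.transcript,
            "Site start": h.alignment.site_start,
            "Site end": h.alignment.site_end,
            "Align score": h.alignment.score,
            "Cleavage pos": h.cleavage_pos,
            "Reads": h.reads,
            "Category": h.category,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["miRNA", "Transcript", "Site start", "Site end",
                 "Align score", "Cleavage pos", "Reads", "Category"],
    )
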