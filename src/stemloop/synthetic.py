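"""Ground-truth synthetic data for the full miRNA-discovery pipeline.

Emulates a two-library (female/male) plant small-RNA experiment over a
de-novo transcript ("unigene") reference: stem-loop miRNA precursors planted
on either strand and either arm, multi-locus matures, conserved miRNAs drawn
from a reference mature set, structured-ncRNA contaminants, a 3' sequencing
adapter, library-biased read counts for differential expression, and a
degradome library whose 5' ends mark miRNA-guided cleavage positions on
planted target sites plus uniform background decay.

All randomness flows through explicit integer seeds; identical seeds give
byte-identical outputs. Reads are emitted in the DNA alphabet (sequencers
report T); mature miRNAs are converted to RNA only on report surfaces.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp, to_dna

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "T", "T": "G"}  # G:U in DNA alphabet


class PlacementError(ValueError):
    """Raised when a precursor or target site does not fit its unigene."""


@dataclass
class PlantedMiRNA:
    mirna_id: str
    mature: str  # DNA alphabet
    arm: str  # 5p | 3p
    strand: str  # + | -
    unigene: str
    start: int  # 1-based inclusive mature locus on the + axis
    end: int
    star: str  # DNA, 5'->3' on the precursor sense strand
    conserved_ref: str | None = None  # reference mature id if conserved


@dataclass
class CleavageTruth:
    mirna_id: str
    unigene: str
    position: int  # 1-based cleavage position (degradome 5' end)


@dataclass
class TruthTable:
    """Everything the generator planted, for downstream recovery checks."""

    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # id -> {F, M}
    de_flags: dict[str, str | None] = field(default_factory=dict)
    cleavage: list[CleavageTruth] = field(default_factory=list)
    decoys: list[tuple[str, str, int]] = field(default_factory=list)  # (unigene, seq, start)

    def validate(self, transcripts: dict[str, str]) -> None:
        for m in self.mirnas:
            if m.conserved_ref is not None and m.unigene == "-":
                continue  # conserved matures are planted as reads, not loci
            L = len(transcripts[m.unigene])
            if not (1 <= m.start <= m.end <= L):
                raise ValueError(f"{m.mirna_id} locus outside {m.unigene}")
        for mid, c in self.counts.items():
            if min(c.values()) < 0 or max(c.values()) == 0:
                raise ValueError(f"bad expected counts for {mid}")
        for cl in self.cleavage:
            if not 1 <= cl.position <= len(transcripts[cl.unigene]):
                raise ValueError(f"cleavage position outside {cl.unigene}")

    def matures(self) -> dict[str, str]:
        return {m.mirna_id: m.mature for m in self.mirnas}


def _rand_seq(rng: random.Random, n: int, gc: float) -> str:
    out = []
    for _ in range(n):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return "".join(out)


def generate_transcriptome(
    n_unigenes: int,
    length_range: tuple[int, int] = (300, 2000),
    gc_fraction: float = 0.42,
    seed: int = 0,
) -> list[SeqRecord]:
    """Random unigene reference with ids UN00001.. and controlled GC."""
    lo, hi = length_range
    if n_unigenes < 1:
        raise ValueError("n_unigenes must be >= 1")
    if not (300 <= lo <= hi <= 5000):
        raise ValueError("length_range must lie within [300, 5000]")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = random.Random(seed)
    records = []
    for i in range(n_unigenes):
        n = rng.randint(lo, hi)
        records.append(
            SeqRecord(Seq(_rand_seq(rng, n, gc_fraction)), id=f"UN{i + 1:05d}", description="")
        )
    return records


def _build_precursor(mature: str, stem_mismatches: int, rng: random.Random) -> tuple[str, str, int]:
    """Return (core sequence, star, mature offset in core) for a 5p-arm layout.

    The star is the reverse complement of the mature minus its 2-nt 3'
    overhang, with `stem_mismatches` non-pairing substitutions injected at
    interior duplex positions, plus a 2-nt unpaired 3' overhang of its own;
    mature and star are joined by an 8-12 nt loop.
    """
    L = len(mature)
    star_core = list(revcomp(mature[: L - 2]))
    interior = list(range(2, L - 6))
    rng.shuffle(interior)
    # keep injected mismatches >= 4 nt apart so the fold opens separate 1x1
    # internal loops instead of one wide loop that drops duplex coverage
    chosen: list[int] = []
    for p in interior:
        if len(chosen) == stem_mismatches:
            break
        if all(abs(p - q) >= 4 for q in chosen):
            chosen.append(p)
    for p in chosen:
        paired = mature[L - 3 - p]
        banned = {_COMP[paired], _WOBBLE.get(paired, "")}
        star_core[p] = rng.choice([b for b in "ACGT" if b not in banned and b != star_core[p]])
    overhang = "".join(rng.choice("AC") for _ in range(2))
    star = "".join(star_core) + overhang
    loop = _rand_seq(rng, rng.randint(8, 12), 0.2)
    core = mature + loop + star
    return core, star, 0


def plant_precursor(
    unigene: SeqRecord,
    mature: str,
    arm: str = "5p",
    strand: str = "+",
    position: int | None = None,
    stem_mismatches: int = 1,
    seed: int = 0,
    mirna_id: str = "planted",
) -> tuple[SeqRecord, PlantedMiRNA]:
    """Overwrite a unigene segment with a stem-loop precursor for `mature`.

    position is the 1-based start of the precursor core on the + axis; if
    None a random feasible position is chosen. Returns the modified record
    and the truth entry (mature locus coordinates on the + axis).
    """
    from .novel import Locus, evaluate_candidate, extract_precursor

    mat = to_dna(mature)
    if not 20 <= len(mat) <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if arm not in ("5p", "3p") or strand not in ("+", "-"):
        raise ValueError("arm must be 5p/3p and strand +/-")
    rng = random.Random(seed)
    L = len(mat)
    seq = str(unigene.seq)
    n = len(seq)

    # The construction is validated against the default-threshold evaluator
    # (the contract: a planted window folds into a qualifying stem-loop even
    # inside its random flanking context) and re-rolled on the rare fold
    # where flank interactions disrupt the duplex.
    last = None
    for _attempt in range(25):
        core5p, star, _ = _build_precursor(mat, stem_mismatches, rng)
        Ls = len(star)
        loop_len = len(core5p) - L - Ls
        core = core5p if arm == "5p" else star + core5p[L : L + loop_len] + mat
        mat_off = 0 if arm == "5p" else Ls + loop_len
        pos = position
        if pos is None:
            if n < len(core) + 2:
                raise PlacementError("unigene too short for a precursor")
            pos = rng.randint(1, n - len(core) + 1)
        p0 = pos - 1
        if p0 < 0 or p0 + len(core) > n:
            raise PlacementError(f"precursor window does not fit at {pos}")
        insert = core if strand == "+" else revcomp(core)
        new_seq = seq[:p0] + insert + seq[p0 + len(core):]
        if strand == "+":
            start = pos + mat_off
        else:
            start = pos + (len(core) - mat_off - L)
        truth = PlantedMiRNA(
            mirna_id=mirna_id,
            mature=mat,
            arm=arm,
            strand=strand,
            unigene=unigene.id,
            start=start,
            end=start + L - 1,
            star=star,
        )
        rec = SeqRecord(Seq(new_seq), id=unigene.id, description=unigene.description)
        last = (rec, truth)
        locus = Locus(unigene.id, start, start + L - 1, strand)
        window, ws, we = extract_precursor(locus, {unigene.id: new_seq})
        if evaluate_candidate(mat, window, locus, ws, we).passed:
            return rec, truth
    return last  # best effort after repeated flank interference


def plant_decoy(unigene: SeqRecord, seq: str, position: int) -> tuple[SeqRecord, tuple[str, str, int]]:
    """Embed a bare sequence (no stem-loop context) so it maps but fails calling."""
    s = str(unigene.seq)
    p0 = position - 1
    if p0 < 0 or p0 + len(seq) > len(s):
        raise PlacementError("decoy does not fit")
    rec = SeqRecord(Seq(s[:p0] + to_dna(seq) + s[p0 + len(seq):]), id=unigene.id, description="")
    return rec, (unigene.id, to_dna(seq), position)


def plant_target_site(
    unigene: SeqRecord, mirna_id: str, mature: str, position: int
) -> tuple[SeqRecord, CleavageTruth]:
    """Write a perfectly complementary target site; cleavage opposite base 10.

    The site is the reverse complement of the mature at `position` (1-based);
    the expected degradome 5' end is position + L - 10.
    """
    mat = to_dna(mature)
    site = revcomp(mat)
    s = str(unigene.seq)
    p0 = position - 1
    if p0 < 0 or p0 + len(site) > len(s):
        raise PlacementError("target site does not fit")
    rec = SeqRecord(Seq(s[:p0] + site + s[p0 + len(site):]), id=unigene.id, description="")
    return rec, CleavageTruth(mirna_id, unigene.id, position + len(mat) - 10)


def make_ncrna_set(n_records: int = 8, length_range=(80, 300), seed: int = 0) -> list[SeqRecord]:
    """Synthetic structured-ncRNA contaminant set (rRNA/tRNA/sn(o)RNA stand-ins)."""
    rng = random.Random(seed)
    kinds = ["rRNA", "tRNA", "snRNA", "snoRNA"]
    recs = []
    for i in range(n_records):
        n = rng.randint(*length_range)
        recs.append(
            SeqRecord(
                Seq(_rand_seq(rng, n, 0.5)),
                id=f"{kinds[i % len(kinds)]}_{i + 1:02d}",
                description="synthetic contaminant",
            )
        )
    return recs


def simulate_srna_libraries(
    truth: TruthTable,
    adapter: str,
    ncrna_set: list[SeqRecord],
    contaminant_fraction: float = 0.4,
    noise_reads: int = 300,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Raw adapter-containing reads for the two libraries (keys F and M).

    Every planted id appears exactly its expected-count times per library as
    insert+adapter; contaminants are exact substrings of the ncRNA set sized
    so they make up ~`contaminant_fraction` of each library; noise reads are
    random 15-45 nt inserts. Emitted read count per library is exactly
    planted + contaminants + noise.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be >= 10 nt")
    if not 0 <= contaminant_fraction < 1:
        raise ValueError("contaminant_fraction must be in [0, 1)")
    adapter = to_dna(adapter)
    rng = random.Random(seed)
    seqs = {m.mirna_id: m.mature for m in truth.mirnas}
    seqs.update({f"decoy:{u}:{s}": s for (u, s, _pos) in truth.decoys})
    libs: dict[str, list[str]] = {}
    for lib in ("F", "M"):
        reads: list[str] = []
        planted = 0
        for mid, c in truth.counts.items():
            insert = seqs.get(mid)
            if insert is None:
                raise KeyError(f"no sequence for planted id {mid}")
            reads.extend([insert + adapter] * c[lib])
            planted += c[lib]
        signal = planted + noise_reads
        n_cont = int(round(contaminant_fraction * signal / (1.0 - contaminant_fraction)))
        for _ in range(n_cont):
            rec = rng.choice(ncrna_set)
            s = str(rec.seq)
            ln = rng.randint(16, min(30, len(s)))
            start = rng.randint(0, len(s) - ln)
            reads.append(s[start : start + ln] + adapter)
        for _ in range(noise_reads):
            reads.append(_rand_seq(rng, rng.randint(15, 45), 0.45) + adapter)
        rng.shuffle(reads)
        libs[lib] = reads
    return libs


def simulate_degradome(
    truth: TruthTable,
    transcripts: dict[str, str],
    reads_per_site: int = 12,
    background_reads: int = 100,
    read_length: int = 20,
    seed: int = 0,
) -> list[str]:
    """Degradome reads: 5' ends at every planted cleavage position + background."""
    if reads_per_site < 1:
        raise ValueError("reads_per_site must be >= 1")
    if not 20 <= read_length <= 21:
        raise ValueError("degradome read length must be 20-21 nt")
    rng = random.Random(seed)
    reads: list[str] = []
    for cl in truth.cleavage:
        t = transcripts[cl.unigene]
        p0 = cl.position - 1
        if p0 + read_length > len(t):
            warnings.warn(f"cleavage site {cl.unigene}:{cl.position} too close to 3' end; skipped")
            continue
        reads.extend([t[p0 : p0 + read_length]] * reads_per_site)
    ids = sorted(transcripts)
    for _ in range(background_reads):
        uid = rng.choice(ids)
        t = transcripts[uid]
        start = rng.randint(0, len(t) - read_length)
        reads.append(t[start : start + read_length])
    rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------------
# One-call dataset used by the end-to-end tests and the demo
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    transcripts: list[SeqRecord]
    truth: TruthTable
    mature_db: list[SeqRecord]
    ncrna_set: list[SeqRecord]
    adapter: str
    libraries: dict[str, list[str]]
    degradome: list[str]


_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA 3' adapter


def _random_mature(rng: random.Random, existing: set[str]) -> str:
    """Random mature: 21 nt most common, 5'-U biased, GC within 0.45-0.65.

    The GC band keeps planted precursor duplexes comfortably below the
    default -18 kcal/mol stability gate, as the generator contract requires.
    """
    while True:
        n = rng.choice([20, 21, 21, 21, 22, 24])  # 21 nt most common
        first = "T" if rng.random() < 0.8 else rng.choice("ACG")
        s = first + _rand_seq(rng, n - 1, 0.55)
        gc = (s.count("G") + s.count("C")) / n
        if s not in existing and 0.45 <= gc <= 0.65:
            existing.add(s)
            return s


def synthetic_dataset(
    n_novel: int = 20,
    n_conserved: int = 6,
    n_de: int = 4,
    n_cleavage: int = 5,
    n_decoys: int = 4,
    n_unigenes: int = 40,
    contaminant_fraction: float = 0.4,
    noise_reads: int = 300,
    seed: int = 0,
) -> SyntheticDataset:
    """Build a complete two-library study with known ground truth.

    Plants `n_novel` novel miRNAs (one on the minus strand, one on the 3'
    arm, one at two loci), `n_conserved` copies of reference matures, marks
    the first `n_de` novel miRNAs as differentially expressed (alternating
    female/male direction, one male-specific), plants `n_cleavage` perfect
    target sites for the first novel miRNAs, and embeds `n_decoys` bare
    (hairpin-free) mapped sequences as negative controls.
    """
    rng = random.Random(seed)
    need = n_novel + 1 + n_decoys + n_cleavage
    if n_unigenes < need:
        raise ValueError(f"need at least {need} unigenes")
    records = generate_transcriptome(n_unigenes, (600, 1200), 0.42, seed=rng.randrange(2**31))
    truth = TruthTable()
    existing: set[str] = set()

    # --- novel miRNAs -------------------------------------------------------
    for i in range(n_novel):
        mid = f"novel{i + 1:02d}"
        mature = _random_mature(rng, existing)
        arm = "3p" if i % 5 == 1 else "5p"
        strand = "-" if i % 7 == 3 else "+"
        rec, entry = plant_precursor(
            records[i], mature, arm=arm, strand=strand,
            stem_mismatches=rng.randint(0, 1), seed=rng.randrange(2**31), mirna_id=mid,
        )
        records[i] = rec
        truth.mirnas.append(entry)
        if i == 0:  # multi-locus case: same mature at a second unigene
            rec2, entry2 = plant_precursor(
                records[n_novel], mature, arm="5p", strand="+",
                stem_mismatches=1, seed=rng.randrange(2**31), mirna_id=mid,
            )
            records[n_novel] = rec2
            truth.mirnas.append(entry2)

    # --- conserved miRNAs ---------------------------------------------------
    families = ["miR166", "miR396", "miR168", "miR159", "miR160", "miR156", "miR172"]
    mature_db: list[SeqRecord] = []
    for i in range(n_conserved):
        fam = families[i % len(families)]
        mid = f"cons{i + 1:02d}"
        mature = _random_mature(rng, existing)
        ref_id = f"aof-{fam}{chr(ord('a') + i)}"
        mature_db.append(SeqRecord(Seq(mature.replace("T", "U")), id=ref_id, description=""))
        truth.mirnas.append(
            PlantedMiRNA(mid, mature, "5p", "+", "-", 0, 0, "", conserved_ref=ref_id)
        )
    # a couple of extra db entries nothing maps to
    for j in range(3):
        extra = _random_mature(rng, existing)
        mature_db.append(
            SeqRecord(Seq(extra.replace("T", "U")), id=f"osa-miR99{j}", description="")
        )

    # --- expected counts and DE flags --------------------------------------
    novel_ids = [f"novel{i + 1:02d}" for i in range(n_novel)]
    cons_ids = [f"cons{i + 1:02d}" for i in range(n_conserved)]
    for k, mid in enumerate(novel_ids + cons_ids):
        base = rng.randint(20, 60)
        jit = rng.randint(-2, 2)
        truth.counts[mid] = {"F": base, "M": max(1, base + jit)}
        truth.de_flags[mid] = None
    for k in range(n_de):
        mid = novel_ids[k]
        hi, lo = rng.randint(60, 90), rng.randint(5, 10)
        if k == n_de - 1:  # one library-specific miRNA (male only)
            truth.counts[mid] = {"F": 0, "M": hi}
            truth.de_flags[mid] = "up_male"
        elif k % 2 == 0:
            truth.counts[mid] = {"F": hi, "M": lo}
            truth.de_flags[mid] = "up_female"
        else:
            truth.counts[mid] = {"F": lo, "M": hi}
            truth.de_flags[mid] = "up_male"

    # --- decoys -------------------------------------------------------------
    for d in range(n_decoys):
        seq = _random_mature(rng, existing)
        uid = n_novel + 1 + d
        pos = rng.randint(50, len(records[uid].seq) - 50 - len(seq))
        records[uid], entry = plant_decoy(records[uid], seq, pos)
        truth.decoys.append(entry)
        did = f"decoy:{entry[0]}:{entry[1]}"
        truth.counts[did] = {"F": rng.randint(10, 25), "M": rng.randint(10, 25)}
        truth.de_flags[did] = None

    # --- degradome target sites --------------------------------------------
    by_id: dict[str, str] = {}
    for m in truth.mirnas:
        by_id.setdefault(m.mirna_id, m.mature)
    for c in range(n_cleavage):
        mid = novel_ids[c % n_novel]
        uid = n_novel + 1 + n_decoys + c
        pos = rng.randint(100, len(records[uid].seq) - 100)
        records[uid], cl = plant_target_site(records[uid], mid, by_id[mid], pos)
        truth.cleavage.append(cl)

    ncrna = make_ncrna_set(seed=rng.randrange(2**31))
    transcripts = {r.id: str(r.seq) for r in records}
    truth.validate(transcripts)
    libraries = simulate_srna_libraries(
        truth, _ADAPTER, ncrna,
        contaminant_fraction=contaminant_fraction,
        noise_reads=noise_reads,
        seed=rng.randrange(2**31),
    )
    degradome = simulate_degradome(
        truth, transcripts, reads_per_site=12, background_reads=100,
        read_length=20, seed=rng.randrange(2**31),
    )
    return SyntheticDataset(
        transcripts=records,
        truth=truth,
        mature_db=mature_db,
        ncrna_set=ncrna,
        adapter=_ADAPTER,
        libraries=libraries,
        degradome=degradome,
    )
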