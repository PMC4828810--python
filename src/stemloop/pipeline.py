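"""End-to-end orchestration: preprocess -> conserved -> novel -> DE -> degradome.

All stage outputs are plain-text TSV/FASTA for diff-ability; identical inputs
and configuration produce byte-identical report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conserved as cons
from . import degradome as deg
from . import diffexpr as dx
from . import novel as nv
from . import preprocess as pp
from .io import read_fasta, read_reads
from .novel import Thresholds

log = logging.getLogger("stemloop")


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full run."""

    library_f: str = ""
    library_m: str = ""
    transcriptome: str = ""
    mature_db: str = ""
    ncrna_db: str = ""
    degradome: str | None = None
    adapter: str | None = None
    output_dir: str = "stemloop_out"
    seed: int = 0
    pre_trimmed: bool = False
    min_len: int = 15
    max_len: int = 45
    tpm_min: float = 5.0
    cand_min_len: int = 20
    cand_max_len: int = 24
    max_mismatch: int = 2
    flank: int = 200
    mfe_max: float = -18.0
    mfei_min: float = 0.7
    mfei_max: float = 1.5
    mfei_gate: bool = False
    fc_threshold: float = 2.0
    alpha: float = 0.05
    de_test: str = "fisher"
    p_adjust_method: str = "bh"
    degradome_max_score: float = 7.0
    cleavage_window: tuple = (10,)
    novel_prefix: str = "miRn"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cleavage_window" in raw:
            raw["cleavage_window"] = tuple(raw["cleavage_window"])
        return cls(**raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            flank=self.flank,
            mfe_max=self.mfe_max,
            mfei_window=(self.mfei_min, self.mfei_max),
            mfei_gate=self.mfei_gate,
            min_len=self.cand_min_len,
            max_len=self.cand_max_len,
            tpm_min=self.tpm_min,
        )


@dataclass
class PipelineResult:
    accounting: list = field(default_factory=list)
    unique_reads: list = field(default_factory=list)
    assignments: list = field(default_factory=list)
    novel_set: list = field(default_factory=list)
    de_results: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    profiles: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    libraries: dict[str, list[str]] | None = None,
    transcripts: dict[str, str] | None = None,
    mature_db=None,
    ncrna_set=None,
    degradome_reads: list[str] | None = None,
    qualities: dict | None = None,
) -> PipelineResult:
    """Execute every stage; in-memory inputs override the configured paths."""
    if libraries is None:
        for p in (config.library_f, config.library_m, config.transcriptome,
                  config.mature_db, config.ncrna_db):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        reads_f, quals_f = read_reads(config.library_f)
        reads_m, quals_m = read_reads(config.library_m)
        libraries = {"F": reads_f, "M": reads_m}
        qualities = {"F": quals_f, "M": quals_m}
    if transcripts is None:
        transcripts = {r.id: str(r.seq).upper() for r in read_fasta(config.transcriptome)}
    if mature_db is None:
        mature_db = read_fasta(config.mature_db)
    if ncrna_set is None:
        ncrna_set = read_fasta(config.ncrna_db)
    if degradome_reads is None and config.degradome and Path(config.degradome).exists():
        degradome_reads, _ = read_reads(config.degradome)

    res = PipelineResult()
    clean: dict[str, list[str]] = {}
    for lib in ("F", "M"):
        quals = (qualities or {}).get(lib)
        final, acc = pp.preprocess_library(
            libraries[lib], config.adapter, ncrna_set, lib,
            qualities=quals, pre_trimmed=config.pre_trimmed,
            min_len=config.min_len, max_len=config.max_len,
        )
        clean[lib] = final
        res.accounting.append(acc)
        log.info("preprocess %s: %d raw -> %d final clean (%d removed)",
                 lib, acc.raw_reads, acc.final_clean, acc.raw_reads - acc.final_clean)
    res.unique_reads = pp.collapse(clean)
    res.totals = {lib: len(clean[lib]) for lib in clean}
    log.info("collapse: %d unique reads", len(res.unique_reads))

    gated = cons.candidate_gate(
        res.unique_reads, tpm_min=config.tpm_min,
        min_len=config.cand_min_len, max_len=config.cand_max_len,
    )
    res.assignments, unassigned = cons.match_known(gated, mature_db, config.max_mismatch)
    log.info("conserved: %d of %d gated reads assigned, %d unassigned",
             len(res.assignments), len(gated), len(unassigned))

    th = config.thresholds()
    candidates = nv.call_candidates(unassigned, transcripts, th)
    conserved_seqs = {a.unique_read.sequence for a in res.assignments}
    res.novel_set = nv.assemble_novel_set(
        candidates, res.unique_reads, conserved_seqs, prefix=config.novel_prefix
    )
    log.info("novel: %d candidate loci evaluated, %d novel miRNAs called",
             len(candidates), len(res.novel_set))

    counts: dict[str, tuple[int, int]] = {}
    seqs: dict[str, str] = {}
    by_ref: dict[str, dict[str, int]] = {}
    for a in res.assignments:
        agg = by_ref.setdefault(a.ref_id, {"F": 0, "M": 0})
        for lib in agg:
            agg[lib] += a.unique_read.counts.get(lib, 0)
        seqs.setdefault(a.ref_id, a.unique_read.sequence)
    for rid, agg in by_ref.items():
        counts[rid] = (agg["F"], agg["M"])
    for nm in res.novel_set:
        counts[nm.mirna_id] = (nm.counts.get("F", 0), nm.counts.get("M", 0))
        seqs[nm.mirna_id] = nm.mature
    res.de_results = dx.differential_expression(
        counts, res.totals["F"], res.totals["M"], sequences=seqs,
        fc_threshold=config.fc_threshold, alpha=config.alpha,
        test=config.de_test, p_adjust_method=config.p_adjust_method,
    )
    n_de = sum(1 for r in res.de_results if r.de_call != "ns")
    log.info("differential expression: %d of %d miRNAs called DE",
             n_de, len(res.de_results))

    if degradome_reads:
        res.profiles = deg.map_degradome(degradome_reads, transcripts)
        mirnas = {mid: seqs[mid] for mid in counts}
        res.hits = deg.call_targets(
            mirnas, transcripts, res.profiles,
            max_score=config.degradome_max_score,
            offset_window=config.cleavage_window,
        )
        log.info("degradome: %d profiled transcripts, %d hits",
                 len(res.profiles), len(res.hits))
    else:
        log.info("degradome: no reads supplied, stage skipped")
    return res


def render_reports(result: PipelineResult, outdir, families: dict | None = None) -> list[Path]:
    """Write the report TSVs and a plain-text summary; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df, name):
        p = outdir / name
        df.to_csv(p, sep="\t", index=name == "accounting.tsv")
        written.append(p)

    save(pp.accounting_table(result.accounting), "accounting.tsv")
    if result.unique_reads:
        save(pp.length_distribution(result.unique_reads), "length_distribution.tsv")

    import pandas as pd

    cons_rows = [
        {
            "sequence": a.unique_read.sequence.replace("T", "U"),
            "ref_id": a.ref_id,
            "family": a.family,
            "mismatches": a.mismatches,
            "tpm_F": f"{a.unique_read.tpm.get('F', 0.0):.2f}",
            "tpm_M": f"{a.unique_read.tpm.get('M', 0.0):.2f}",
        }
        for a in sorted(result.assignments, key=lambda a: a.ref_id)
    ]
    save(pd.DataFrame(cons_rows, columns=["sequence", "ref_id", "family",
                                          "mismatches", "tpm_F", "tpm_M"]), "conserved.tsv")
    save(cons.family_summary(result.assignments), "families.tsv")
    save(nv.novel_table(result.novel_set), "novel.tsv")
    fam = families or {a.ref_id: a.family for a in result.assignments}
    save(dx.de_table(result.de_results, fam), "de.tsv")
    save(deg.hits_table(result.hits), "degradome_hits.tsv")
    for uid in sorted(result.profiles):
        save(deg.tplot_table(result.profiles[uid], result.hits), f"tplot_{uid}.tsv")

    n_de_f = sum(1 for r in result.de_results if r.de_call == "up_female")
    n_de_m = sum(1 for r in result.de_results if r.de_call == "up_male")
    summary = outdir / "summary.txt"
    with open(summary, "w") as fh:
        for a in result.accounting:
            fh.write(f"library {a.library}: final clean reads {a.final_clean}, "
                     f"unique reads {a.unique_reads}\n")
        fh.write(f"unique sRNAs: {len(result.unique_reads)}\n")
        fh.write(f"conserved assignments: {len(result.assignments)}\n")
        fh.write(f"novel miRNAs: {len(result.novel_set)}\n")
        fh.write(f"differentially expressed: {n_de_f} up in female, {n_de_m} up in male\n")
        fh.write(f"degradome hits: {len(result.hits)}\n")
    written.append(summary)
    return written
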