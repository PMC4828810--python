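"""Generator contracts: determinism, ground-truth invariants, read accounting."""

import warnings

import pytest

from stemloop.novel import Locus, Thresholds, evaluate_candidate, extract_precursor
from stemloop.preprocess import filter_ncrna
from stemloop.synthetic import (
    PlacementError,
    generate_transcriptome,
    make_ncrna_set,
    plant_precursor,
    plant_target_site,
    simulate_degradome,
    simulate_srna_libraries,
    synthetic_dataset,
)
from stemloop._seq import revcomp


class TestTranscriptome:
    def test_forced_single_record(self):
        recs = generate_transcriptome(1, (500, 500), 0.5, seed=7)
        assert len(recs) == 1 and len(recs[0].seq) == 500
        assert recs[0].id == "UN00001"

    def test_determinism(self):
        a = generate_transcriptome(5, (300, 800), 0.4, seed=3)
        b = generate_transcriptome(5, (300, 800), 0.4, seed=3)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_pooled_gc_within_three_points(self):
        recs = generate_transcriptome(50, (300, 2000), 0.42, seed=1)
        pool = "".join(str(r.seq) for r in recs)
        gc = (pool.count("G") + pool.count("C")) / len(pool)
        assert 0.39 <= gc <= 0.45

    @pytest.mark.parametrize("kwargs", [
        {"n_unigenes": 0},
        {"length_range": (100, 200)},
        {"gc_fraction": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        args = {"n_unigenes": 3, "length_range": (300, 500), "gc_fraction": 0.5}
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_transcriptome(**args, seed=0)


class TestPlantPrecursor:
    def setup_method(self):
        self.unigene = generate_transcriptome(1, (800, 800), 0.42, seed=5)[0]
        self.mature = "TGGAGCTCCCTTCACTCCCTC"  # 21 nt, GC 0.57

    def test_plus_strand_mature_maps_exactly(self):
        rec, truth = plant_precursor(self.unigene, self.mature, "5p", "+", seed=2)
        assert str(rec.seq)[truth.start - 1 : truth.end] == self.mature
        assert truth.strand == "+" and truth.arm == "5p"

    def test_minus_strand_mature_maps_to_reverse_complement(self):
        rec, truth = plant_precursor(self.unigene, self.mature, "5p", "-", seed=2)
        segment = str(rec.seq)[truth.start - 1 : truth.end]
        assert revcomp(segment) == self.mature

    @pytest.mark.parametrize("arm,strand", [("5p", "+"), ("3p", "+"), ("5p", "-"), ("3p", "-")])
    def test_planted_precursor_passes_default_evaluator(self, arm, strand):
        rec, truth = plant_precursor(self.unigene, self.mature, arm, strand, seed=9)
        transcripts = {rec.id: str(rec.seq)}
        locus = Locus(truth.unigene, truth.start, truth.end, truth.strand)
        window, ws, we = extract_precursor(locus, transcripts, 200)
        cand = evaluate_candidate(self.mature, window, locus, ws, we, Thresholds())
        assert cand.passed, cand.verdicts
        assert cand.arm == arm

    def test_window_that_does_not_fit_raises(self):
        with pytest.raises(PlacementError):
            plant_precursor(self.unigene, self.mature, "5p", "+", position=790, seed=0)


class TestLibraries:
    def test_planted_counts_reproduced_exactly(self, dataset):
        adapter = dataset.adapter
        for m in dataset.truth.mirnas:
            exp = dataset.truth.counts[m.mirna_id]
            for lib in ("F", "M"):
                n = sum(1 for r in dataset.libraries[lib] if r == m.mature + adapter)
                assert n == exp[lib], m.mirna_id

    def test_read_conservation(self, dataset):
        truth = dataset.truth
        noise = 300
        for lib in ("F", "M"):
            planted = sum(c[lib] for c in truth.counts.values())
            signal = planted + noise
            n_cont = int(round(0.4 * signal / 0.6))
            assert len(dataset.libraries[lib]) == planted + noise + n_cont

    def test_zero_contaminants_means_ncrna_filter_removes_nothing(self, dataset):
        libs = simulate_srna_libraries(
            dataset.truth, dataset.adapter, dataset.ncrna_set,
            contaminant_fraction=0.0, noise_reads=50, seed=4,
        )
        inserts = [r[: -len(dataset.adapter)] for r in libs["F"]]
        _kept, removed = filter_ncrna(inserts, dataset.ncrna_set)
        assert removed == 0

    def test_contaminants_are_exact_ncrna_substrings(self, dataset):
        adapter = dataset.adapter
        ncrna = [str(r.seq) for r in dataset.ncrna_set]
        hay = "#".join(ncrna)
        planted = {m.mature for m in dataset.truth.mirnas}
        planted |= {s for (_u, s, _p) in dataset.truth.decoys}
        n_cont = 0
        for r in dataset.libraries["F"]:
            insert = r[: -len(adapter)]
            if insert in planted:
                continue
            if insert in hay:
                n_cont += 1
        assert n_cont > 0

    def test_invalid_parameters(self, dataset):
        with pytest.raises(ValueError):
            simulate_srna_libraries(dataset.truth, "ACGT", dataset.ncrna_set, seed=0)
        with pytest.raises(ValueError):
            simulate_srna_libraries(
                dataset.truth, dataset.adapter, dataset.ncrna_set,
                contaminant_fraction=1.0, seed=0,
            )


class TestDegradome:
    def test_each_site_gets_reads_per_site_reads(self, dataset, transcripts):
        reads = simulate_degradome(dataset.truth, transcripts, reads_per_site=7,
                                   background_reads=0, seed=3)
        assert len(reads) == 7 * len(dataset.truth.cleavage)
        for cl in dataset.truth.cleavage:
            t = transcripts[cl.unigene]
            expected = t[cl.position - 1 : cl.position - 1 + 20]
            assert sum(1 for r in reads if r == expected) >= 7

    def test_background_only_contains_no_planted_site_reads(self, dataset, transcripts):
        truth = dataset.truth
        reads = simulate_degradome(truth, transcripts, reads_per_site=1,
                                   background_reads=0, seed=1)
        bg = simulate_degradome(truth, transcripts, reads_per_site=1,
                                background_reads=200, seed=1)
        site_reads = set(reads)
        n_sites = sum(1 for r in bg if r in site_reads)
        assert n_sites >= len(truth.cleavage)  # sites present when requested
        truth_empty = type(truth)(mirnas=truth.mirnas, counts=truth.counts,
                                  de_flags=truth.de_flags, cleavage=[])
        only_bg = simulate_degradome(truth_empty, transcripts, reads_per_site=1,
                                     background_reads=100, seed=1)
        assert len(only_bg) == 100

    def test_site_past_transcript_end_is_skipped_with_warning(self, dataset, transcripts):
        from stemloop.synthetic import CleavageTruth, TruthTable

        uid = sorted(transcripts)[0]
        truth = TruthTable(cleavage=[CleavageTruth("x", uid, len(transcripts[uid]) - 3)])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            reads = simulate_degradome(truth, transcripts, reads_per_site=5,
                                       background_reads=0, seed=0)
        assert reads == []
        assert any("skipped" in str(x.message) for x in w)

    def test_determinism(self, dataset, transcripts):
        a = simulate_degradome(dataset.truth, transcripts, seed=11)
        b = simulate_degradome(dataset.truth, transcripts, seed=11)
        assert a == b


class TestDatasetTruth:
    def test_truth_invariants_hold(self, dataset, transcripts):
        dataset.truth.validate(transcripts)

    def test_every_cleavage_position_marks_position_ten(self, dataset, transcripts):
        by_id = {}
        for m in dataset.truth.mirnas:
            by_id.setdefault(m.mirna_id, m.mature)
        for cl in dataset.truth.cleavage:
            mat = by_id[cl.mirna_id]
            t = transcripts[cl.unigene]
            site_start = cl.position - (len(mat) - 10)
            site = t[site_start - 1 : site_start - 1 + len(mat)]
            assert site == revcomp(mat)

    def test_dataset_determinism(self):
        a = synthetic_dataset(n_novel=4, n_conserved=2, n_de=2, n_cleavage=2,
                              n_unigenes=11, seed=5)
        b = synthetic_dataset(n_novel=4, n_conserved=2, n_de=2, n_cleavage=2,
                              n_unigenes=11, seed=5)
        assert a.libraries == b.libraries
        assert a.degradome == b.degradome
        assert [str(r.seq) for r in a.transcripts] == [str(r.seq) for r in b.transcripts]


def test_ncrna_set_ids_name_contaminant_classes():
    recs = make_ncrna_set(n_records=4, seed=0)
    kinds = {r.id.split("_")[0] for r in recs}
    assert kinds == {"rRNA", "tRNA", "snRNA", "snoRNA"}
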