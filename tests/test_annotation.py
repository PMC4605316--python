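"""Origin-class annotation, summaries, TAR overlap and consensus profiles."""

import numpy as np
import pandas as pd
import pytest

from rsrna import annotate
from rsrna.datamodel import (
    AlignmentHit,
    ConsensusProfile,
    GeneModel,
    GenomicInterval,
    RepeatElement,
)


def _gene(start, end, strand="+", biotype="protein_coding", exons=None, gene_id="g"):
    iv = GenomicInterval("chr1", start, end, strand)
    return GeneModel(gene_id, iv, exons or [iv], biotype)


def _hit(seq_len, start, strand="+"):
    seq = "A" * seq_len
    return AlignmentHit(seq, GenomicInterval("chr1", start, start + seq_len, strand), 0)


class TestClassifyLoci:
    def test_intron_hit(self):
        gene = _gene(0, 300, exons=[GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
        calls = annotate.classify_loci([_hit(20, 120)], [gene], [])
        assert calls[0].primary_class == "intron"

    def test_repeat_inside_intron_takes_priority(self):
        gene = _gene(0, 300, exons=[GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
        alu = RepeatElement(GenomicInterval("chr1", 110, 180), "Alu", 0, 280)
        calls = annotate.classify_loci([_hit(20, 120)], [gene], [alu])
        assert calls[0].primary_class == "repeat"
        assert calls[0].repeat_families == frozenset({"Alu"})

    def test_exon_requires_sense_strand(self):
        gene = _gene(0, 100, strand="+")
        sense = annotate.classify_loci([_hit(20, 10, "+")], [gene], [])
        anti = annotate.classify_loci([_hit(20, 10, "-")], [gene], [])
        assert sense[0].primary_class == "exon"
        assert anti[0].primary_class == "intergenic"

    def test_ncrna_exon_class(self):
        nc = _gene(0, 100, biotype="lincRNA")
        calls = annotate.classify_loci([_hit(20, 10)], [nc], [])
        assert calls[0].primary_class == "ncRNA"

    def test_priority_across_loci(self):
        gene = _gene(0, 100)
        hits = [_hit(20, 10, "+"), _hit(20, 500, "+")]
        calls = annotate.classify_loci(hits, [gene], [])
        assert calls[0].primary_class == "exon"
        assert calls[0].class_set == frozenset({"exon", "intergenic"})

    def test_hit_beyond_genome_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            annotate.classify_loci([_hit(20, 90)], [], [], genome_lengths={"chr1": 100})

    def test_planted_origin_classes_recovered(self, bundle_noiseless, records_by_seq_noiseless):
        for p in bundle_noiseless.truth.planted:
            rec = records_by_seq_noiseless[p.seq]
            assert rec.annotation is not None
            assert rec.annotation.primary_class == p.expected_primary_class


class TestSummarize:
    def test_published_style_percentages(self):
        out = annotate.summarize_annotation({"repeat": 5078, "intron": 5324}, 11234)
        by = out.set_index("class")["percent"]
        assert by["repeat"] == 45.20
        assert by["intron"] == 47.39

    def test_single_class_is_hundred(self):
        out = annotate.summarize_annotation({"intron": 7}, 7)
        assert out.loc[0, "percent"] == 100.00

    def test_all_classes_mode_can_double_count(self):
        calls = annotate.classify_loci(
            [_hit(20, 10, "+"), _hit(20, 500, "+")], [_gene(0, 100)], []
        )
        primary = annotate.summarize_annotation(calls, 1, mode="primary")
        both = annotate.summarize_annotation(calls, 1, mode="all_classes")
        assert primary["count"].sum() == 1
        assert both["count"].sum() == 2

    def test_total_must_be_positive(self):
        with pytest.raises(ValueError):
            annotate.summarize_annotation({"exon": 1}, 0)


class TestTarOverlap:
    def _call(self, start, cls="intron", srna_id="x"):
        iv = GenomicInterval("chr1", start, start + 20)
        return annotate.AnnotationCall(srna_id, [(iv, cls)], cls, frozenset({cls}))

    def test_overlap_and_abutting(self):
        tar = [GenomicInterval("chr1", 100, 200)]
        inside = self._call(150, srna_id="in")
        abutting = self._call(200, srna_id="ab")   # half-open: zero overlap
        flags, _frac = annotate.tar_overlap([inside, abutting], tar)
        assert flags["in"] is True
        assert flags["ab"] is False

    def test_exonic_srnas_excluded_from_denominator(self):
        tar = [GenomicInterval("chr1", 100, 200)]
        exonic = annotate.AnnotationCall(
            "e", [(GenomicInterval("chr1", 150, 170), "exon")], "exon", frozenset({"exon"})
        )
        nc = self._call(150)
        _flags, frac = annotate.tar_overlap([exonic, nc], tar, restrict_to_noncoding=True)
        assert frac == 1.0                    # only the non-coding sRNA counts

    def test_planted_tar_fraction_exact(self, bundle_noiseless, result_noiseless):
        truth = bundle_noiseless.truth
        calls = {c.srna_id: c for c in result_noiseless.annotation_calls}
        by_seq = {r.sequence: r for r in result_noiseless.records}
        flags = [calls[by_seq[p.seq].srna_id].tar_overlap for p in truth.planted]
        assert sum(flags) / len(flags) == pytest.approx(truth.config.tar_fraction)


class TestConsensusProfile:
    def _repeat(self, start, length, offset, orientation):
        return RepeatElement(
            GenomicInterval("chr1", start, start + length), "Alu", offset, 280, orientation
        )

    def test_plus_orientation_offset_arithmetic(self):
        copy = self._repeat(1000, 100, 30, "+")
        hit = _hit(20, 1010)
        profile = annotate.consensus_profile([hit], [copy], {hit.seq: 2.5}, "Alu")
        assert profile.weights[40] == pytest.approx(2.5)
        assert profile.weights.sum() == pytest.approx(2.5)

    def test_minus_orientation_reflects_through_copy(self):
        copy = self._repeat(1000, 100, 30, "-")
        hit = _hit(20, 1010)                  # rel = 10 -> 30 + (100 - 1 - 10)
        profile = annotate.consensus_profile([hit], [copy], {hit.seq: 1.0}, "Alu")
        assert profile.weights[30 + 89] == pytest.approx(1.0)

    def test_out_of_range_weight_counted_as_dropped(self):
        copy = self._repeat(1000, 100, 180, "+")
        hit = _hit(20, 1000 + 99)             # maps past consensus length? 180+99=279 ok
        far = self._repeat(1000, 100, 260, "+")
        hit2 = _hit(20, 1000 + 50)            # 260 + 50 = 310 >= 280 -> dropped
        profile = annotate.consensus_profile([hit2], [far], {hit2.seq: 3.0}, "Alu")
        assert profile.dropped_weight == pytest.approx(3.0)
        assert profile.weights.sum() == 0

    def test_weight_conservation(self):
        rng = np.random.default_rng(9)
        copies = [self._repeat(1000 + 300 * i, 100, int(rng.integers(0, 150)), "+") for i in range(4)]
        hits, weights = [], {}
        for i in range(12):
            c = copies[i % 4]
            seq = "".join(rng.choice(list("ACGT"), 20))
            h = AlignmentHit(
                seq, GenomicInterval("chr1", c.interval.start + 5 + i, c.interval.start + 25 + i), 0
            )
            hits.append(h)
            weights[h.seq] = float(rng.uniform(0.5, 5))
        profile = annotate.consensus_profile(hits, copies, weights, "Alu")
        total_in = sum(weights[h.seq] for h in hits)
        assert profile.weights.sum() + profile.dropped_weight == pytest.approx(total_in)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            annotate.consensus_profile([], [self._repeat(0, 50, 0, "+")], {}, "LINE9")

    def test_normalized_sums_to_one(self):
        copy = self._repeat(1000, 100, 0, "+")
        hit = _hit(20, 1010)
        profile = annotate.consensus_profile([hit], [copy], {hit.seq: 4.0}, "Alu", normalize=True)
        assert profile.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestProfileGroupTest:
    def _profiles(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = np.abs(rng.normal(1, 0.1, 50))
        out = {}
        for i in range(4):
            w = base + rng.normal(0, 0.01, 50)
            out[f"t{i}"] = ConsensusProfile("Alu", w / w.sum(), "sum-to-1")
        for i in range(4):
            w = base.copy()
            w[10] += shift
            w = w + rng.normal(0, 0.01, 50)
            out[f"n{i}"] = ConsensusProfile("Alu", w / w.sum(), "sum-to-1")
        return out

    def test_identical_profiles_not_significant(self):
        w = np.full(20, 0.05)
        profiles = {s: ConsensusProfile("Alu", w.copy(), "sum-to-1") for s in ("a", "b", "c", "d")}
        table, summary = annotate.profile_group_test(profiles, ["a", "b"], ["c", "d"])
        assert (table["t"] == 0).all()
        assert (table["p"] == 1).all()
        assert summary["positions_p_lt_0.05"] == 0

    def test_shifted_position_dominates(self):
        profiles = self._profiles(shift=1.0, seed=3)
        table, _ = annotate.profile_group_test(profiles, [f"t{i}" for i in range(4)], [f"n{i}" for i in range(4)])
        assert int(table.sort_values("p").iloc[0]["position"]) == 10

    def test_label_permutation_within_group_invariant(self):
        profiles = self._profiles(shift=0.5, seed=5)
        a = annotate.profile_group_test(profiles, ["t0", "t1", "t2", "t3"], ["n0", "n1", "n2", "n3"])[0]
        b = annotate.profile_group_test(profiles, ["t3", "t1", "t0", "t2"], ["n2", "n0", "n3", "n1"])[0]
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_samples_rejected(self):
        profiles = self._profiles()
        with pytest.raises(ValueError):
            annotate.profile_group_test(profiles, ["t0"], ["n0", "n1"])
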