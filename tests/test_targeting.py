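"""Seed/duplex target predictors, consensus, and interaction evidence."""

import numpy as np
import pytest

import oracles
from rsrna import targeting
from rsrna.datamodel import (
    AlignmentHit,
    ClashChimera,
    GeneModel,
    GenomicInterval,
    revcomp,
)

SRNA = "TGAGGTAGTAGGTTGTATAGT"        # 21 nt, starts with T (U in RNA)


def _gene(utr_seq: str, gene_id: str = "g1", strand: str = "+", offset: int = 0) -> GeneModel:
    """Single-exon gene: 10 nt 5'UTR + 20 nt CDS + the given 3'UTR."""
    head = "CCCCCCCCCC" + "ATG" + "GGCCGGCCGGCCGGCC" + "A"
    transcript = head + utr_seq
    n = len(transcript)
    if strand == "+":
        iv = GenomicInterval("chrT", offset, offset + n, "+")
        five = [GenomicInterval("chrT", offset, offset + 10, "+")]
        cds = [GenomicInterval("chrT", offset + 10, offset + 30, "+")]
        three = [GenomicInterval("chrT", offset + 30, offset + n, "+")]
    else:
        iv = GenomicInterval("chrT", offset, offset + n, "-")
        five = [GenomicInterval("chrT", offset + n - 10, offset + n, "-")]
        cds = [GenomicInterval("chrT", offset + n - 30, offset + n - 10, "-")]
        three = [GenomicInterval("chrT", offset, offset + n - 30, "-")]
    gene = GeneModel(gene_id, iv, [iv], "protein_coding", five, cds, three)
    gene.spliced_seq = transcript
    return gene


def seed_site_8mer(srna: str) -> str:
    """Canonical 8mer site: positions 2-8 complement plus the A anchor."""
    return revcomp(srna[1:8]) + "A"


class TestSeedScanner:
    def test_8mer_requires_m8_match_and_a_anchor(self):
        target = "CCCCC" + seed_site_8mer(SRNA) + "CCCCC"
        [(s, e, cls)] = targeting.scan_seed_matches(SRNA, target)
        assert cls == "8mer" and (e - s) == 8

    def test_7mer_m8_without_anchor(self):
        target = "CCCCC" + revcomp(SRNA[1:8]) + "CCCCC"
        [(s, e, cls)] = targeting.scan_seed_matches(SRNA, target)
        assert cls == "7mer-m8" and (e - s) == 7

    def test_7mer_a1_without_m8(self):
        bad_m8 = "T" if revcomp(SRNA[7]) != "T" else "G"
        core = revcomp(SRNA[1:7])
        target = "CCCC" + bad_m8 + core + "A" + "CCCC"
        hits = [h for h in targeting.scan_seed_matches(SRNA, target)]
        assert [cls for _s, _e, cls in hits] == ["7mer-A1"]

    def test_bare_6mer_classified_none(self):
        bad_m8 = "T" if revcomp(SRNA[7]) != "T" else "G"
        target = "CCCC" + bad_m8 + revcomp(SRNA[1:7]) + "C" + "CCCC"
        assert [cls for _s, _e, cls in targeting.scan_seed_matches(SRNA, target)] == ["none"]

    def test_short_srna_rejected(self):
        with pytest.raises(ValueError):
            targeting.scan_seed_matches("ACGTACG", "ACGTACGTACGT")


def test_seed_sites_found_iff_seed_complement_present():
    rng = np.random.default_rng(3)
    found_with, found_without = 0, 0
    for i in range(40):
        utr = "".join(rng.choice(list("ACGT"), 120))
        gene = _gene(utr)
        sites = targeting.predict_seed_sites("x", SRNA, [gene])
        has_7mer = any(
            cls in ("8mer", "7mer-m8", "7mer-A1")
            for _s, _e, cls in oracles_scan_seed(SRNA, utr)
        )
        assert bool(sites) == has_7mer
        found_with += bool(sites)
    utr = "CC" + seed_site_8mer(SRNA) + "CC"
    assert targeting.predict_seed_sites("x", SRNA, [_gene(utr)])[0].seed_class == "8mer"


def oracles_scan_seed(srna, target):
    """String-search oracle for seed classes, independent of the scanner."""
    core = oracles.revcomp(srna[1:7])
    out = []
    for pos in range(len(target) - 5):
        if target[pos : pos + 6] != core:
            continue
        m8 = pos >= 1 and target[pos - 1] == oracles.revcomp(srna[7])
        a1 = pos + 6 < len(target) and target[pos + 6] == "A"
        cls = {(True, True): "8mer", (True, False): "7mer-m8",
               (False, True): "7mer-A1", (False, False): "none"}[(m8, a1)]
        out.append((pos, pos + 6, cls))
    return out


class TestDuplexScanner:
    def test_perfect_complement_is_zero_mismatch(self):
        target = "GG" + revcomp(SRNA) + "GG"
        assert (2, 0) in targeting.scan_duplex_windows(SRNA, target, 2)

    def test_three_substitutions_excluded(self):
        window = list(revcomp(SRNA))
        for pos in (3, 9, 15):
            window[pos] = "A" if window[pos] != "A" else "C"
        target = "GG" + "".join(window) + "GG"
        hits = targeting.scan_duplex_windows(SRNA, target, 2)
        assert all(start != 2 for start, _mm in hits)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            srna = "".join(rng.choice(list("ACGT"), int(rng.integers(17, 25))))
            target = "".join(rng.choice(list("ACGT"), 150))
            if rng.random() < 0.5:       # plant a near-complement window
                pos = int(rng.integers(0, 150 - len(srna)))
                site = list(revcomp(srna))
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(site)))
                    site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
                target = target[:pos] + "".join(site) + target[pos + len(srna):]
            got = targeting.scan_duplex_windows(srna, target, 2)
            assert got == oracles.duplex_scan(srna, target, 2)

    def test_wobble_allowance_forgives_gu_pairs(self):
        srna = "G" + "ACGTACGTACGTACGTA"
        window = list(revcomp(srna))
        window[-1] = "T"                  # opposite the sRNA's 5' G: a G:U pair
        target = "".join(window)
        assert targeting.scan_duplex_windows(srna, target, 0) == []
        assert targeting.scan_duplex_windows(srna, target, 0, wobble_allowance=1) == [(0, 0)]

    def test_mismatch_budget_monotone(self):
        rng = np.random.default_rng(23)
        srna = "".join(rng.choice(list("ACGT"), 20))
        target = "".join(rng.choice(list("ACGT"), 300))
        prev = set()
        for k in (0, 1, 2, 3):
            now = {s for s, _m in targeting.scan_duplex_windows(srna, target, k)}
            assert prev <= now
            prev = now


def test_duplex_sites_reflect_under_reverse_complement():
    """Reverse-complementing both sRNA and target leaves the site set
    invariant up to coordinate reflection."""
    rng = np.random.default_rng(29)
    srna = "".join(rng.choice(list("ACGT"), 19))
    target = "".join(rng.choice(list("ACGT"), 100)) + revcomp(srna) + "ACGT"
    fwd = targeting.scan_duplex_windows(srna, target, 2)
    rev = targeting.scan_duplex_windows(revcomp(srna), revcomp(target), 2)
    reflected = sorted((len(target) - (s + len(srna)), mm) for s, mm in fwd)
    assert sorted(rev) == reflected


class TestConsensus:
    def _sites(self):
        utr = "CC" + revcomp(SRNA) + "CCCC"
        gene = _gene(utr)
        seed = targeting.predict_seed_sites("x", SRNA, [gene])
        duplex = targeting.predict_duplex_sites("x", SRNA, [gene])
        return seed, duplex, gene

    def test_overlapping_sites_from_both_predictors_retained(self):
        seed, duplex, gene = self._sites()
        merged = targeting.consensus_sites(seed, duplex, {gene.gene_id: gene})
        assert len(merged) >= 1
        assert all(s.seed_predictor and s.duplex_predictor for s in merged)

    def test_seed_only_pairs_dropped(self):
        seed, _duplex, gene = self._sites()
        assert targeting.consensus_sites(seed, [], {gene.gene_id: gene}) == []

    def test_consensus_is_subset_of_both_pair_sets(self, result_noiseless):
        sites = result_noiseless.sites
        assert sites
        for s in sites:
            assert s.seed_predictor and s.duplex_predictor


def _site_for(gene, srna_id="x"):
    sites = targeting.predict_duplex_sites(srna_id, SRNA, [gene])
    assert sites
    return sites[0]


class TestInteractionEvidence:
    def _setup(self):
        utr = "CC" + revcomp(SRNA) + "CCCC"
        gene = _gene(utr, offset=1000)
        site = _site_for(gene)
        return gene, site

    def test_clip_requires_peak_and_read(self):
        _gene_, site = self._setup()
        piece = site.genomic[0]
        peaks = {"AGO2": [piece.expanded(5)]}
        targeting.clip_support([site], peaks, {"AGO2": [SRNA]}, {"x": SRNA})
        assert site.ago == {"AGO1": False, "AGO2": True, "AGO3": False, "AGO4": False}
        # same peak but the sRNA absent from the read set -> no support
        site2 = self._setup()[1]
        targeting.clip_support([site2], peaks, {"AGO2": []}, {"x": SRNA})
        assert not site2.ago["AGO2"]

    def test_unknown_ago_label_rejected(self):
        _g, site = self._setup()
        with pytest.raises(ValueError, match="AGO"):
            targeting.clip_support([site], {"AGO9": []}, {}, {"x": SRNA})

    def test_clash_overlap_and_slop(self):
        _g, site = self._setup()
        piece = site.genomic[0]
        near = ClashChimera("c1", SRNA, piece.expanded(5))
        far = ClashChimera(
            "c2", SRNA, GenomicInterval(piece.chrom, piece.start + 1000, piece.end + 1000)
        )
        targeting.clash_support([site], [near], {"x": SRNA})
        assert site.clash
        site2 = self._setup()[1]
        targeting.clash_support([site2], [far], {"x": SRNA})
        assert not site2.clash

    def test_clash_slop_monotone(self):
        _g, site = self._setup()
        piece = site.genomic[0]
        chim = ClashChimera(
            "c", SRNA, GenomicInterval(piece.chrom, piece.end + 30, piece.end + 50)
        )
        flags = []
        for slop in (0, 25, 60):
            s = self._setup()[1]
            targeting.clash_support([s], [chim], {"x": SRNA}, clash_slop_nt=slop)
            flags.append(s.clash)
        assert flags == sorted(flags)     # expanding slop never unsets the flag

    def test_antisense_requires_opposite_strand_overlap(self):
        gene, site = self._setup()
        piece = site.genomic[0]
        anti = AlignmentHit(SRNA, GenomicInterval(piece.chrom, piece.start, piece.end, "-"), 0)
        sense = AlignmentHit(SRNA, GenomicInterval(piece.chrom, piece.start, piece.end, "+"), 0)
        targeting.detect_antisense_origin([site], {"x": [anti]}, {gene.gene_id: gene})
        assert site.antisense
        site2 = self._setup()[1]
        targeting.detect_antisense_origin([site2], {"x": [sense]}, {gene.gene_id: gene})
        assert not site2.antisense

    def test_planted_interactions_recovered_exactly(self, bundle_noiseless, records_by_seq_noiseless):
        truth = bundle_noiseless.truth
        for p in truth.planted:
            rec = records_by_seq_noiseless[p.seq]
            if p.interaction_mode in ("both", "clip_only"):
                assert any(rec.ago[a] for a in p.ago_proteins)
            if p.interaction_mode in ("both", "clash_only"):
                assert rec.clash
        for d in truth.decoys:
            if d.failure_mode == "no_interaction":
                rec = records_by_seq_noiseless[d.seq]
                assert not rec.any_interaction()
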