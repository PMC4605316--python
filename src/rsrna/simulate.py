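"""Deterministic synthetic data generator with a ground-truth ledger.

Emulates the statistical structure the discovery cascade assumes: a small
genome carrying protein-coding genes (with introns and 3'UTRs), ncRNA
genes, mutated repeat copies of per-family consensus sequences, and
intergenic stem-loop (hairpin) loci; planted rsRNAs drawn from each origin
class with complementary target sites written into 3'UTRs; decoy reads
engineered to fail exactly one filter each; negative-binomial sequencing
counts with planted fold changes; AGO CLIP peaks/reads and CLASH chimeras
covering the planted interactions; wild-type/knockdown read sets encoding
biogenesis dependence; and expression matrices with planted
anti-correlation between rsRNAs and their targets.

Everything is a pure function of (config, seed): identical inputs give
byte-identical outputs. Every generated read, peak and chimera is
attributable to exactly one truth entity or to the background class.

Deliberately not modeled: sequencing errors, adapters, PCR duplicates,
realistic chromosome structure.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .biogenesis import detect_hairpin
from .config import PipelineConfig
from .datamodel import (
    CountMatrix,
    ClashChimera,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SampleMeta,
    revcomp,
)

ORIGIN_CLASSES = ("intron", "repeat", "ncRNA", "hairpin")
FAILURE_MODES = ("low_abundance", "single_condition", "known_miRNA", "no_interaction")
BIOGENESIS_LABELS = ("drosha_dgcr8_dependent", "dicer_only", "independent")
HAIRPIN_LOOP = "CTGTCC"              # holds the apical TGT; ends cannot pair inward
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """The configured genome is too short for the requested features."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort: 4 experimental conditions with
    tumor and normal states, 5 samples per state, negative-binomial sRNA
    counts (mean 50, dispersion 0.1, i.e. biological CV ~ 30%), 4-fold
    planted differential expression and planted anti-correlation of
    r ~ -0.8. Setting ``nb_dispersion`` to None switches to noiseless
    (deterministic) counts.
    """

    genome_length: int = 60_000
    chrom: str = "chr1"
    n_genes: int = 24
    n_ncrna: int = 6
    repeat_copies: dict = field(default_factory=lambda: {"Alu": 12, "L1": 6})
    consensus_lengths: dict = field(default_factory=lambda: {"Alu": 280, "L1": 500})
    repeat_divergence: float = 0.08
    n_hairpin_loci: int = 6
    n_planted: dict = field(
        default_factory=lambda: {"intron": 5, "repeat": 5, "ncRNA": 4, "hairpin": 6}
    )
    n_decoys: dict = field(
        default_factory=lambda: {
            "low_abundance": 5,
            "single_condition": 5,
            "known_miRNA": 5,
            "no_interaction": 5,
        }
    )
    n_known_mirnas: int = 20
    n_conditions: int = 4
    samples_per_group: int = 5
    nb_mean: float = 50.0
    nb_dispersion: Optional[float] = 0.1        # biological CV ~ 30% at these means
    fold_change: float = 4.0
    anticorr_r: float = -0.8
    # Background emulates the bulk of a real sRNA library: a shared pool of
    # condition-restricted sequences that dominates library size (so RPM
    # fold changes track count fold changes despite composition shifts)
    # plus rare one-copy reads.
    n_background_shared: int = 600
    background_shared_mean: float = 30.0
    background_unique_per_sample: int = 50
    tar_fraction: float = 0.7
    min_len: int = 17
    max_len: int = 28
    rng_seed: int = 1

    def validate(self) -> "GeneratorConfig":
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (or None for noiseless)")
        if not (-1.0 < self.anticorr_r < 0.0):
            raise ValueError("anticorr_r must lie in (-1, 0)")
        if not (self.min_len <= self.max_len):
            raise ValueError("min_len must not exceed max_len")
        for name, table in (("n_planted", self.n_planted), ("n_decoys", self.n_decoys)):
            for key, value in table.items():
                if value < 0:
                    raise ValueError(f"{name}[{key}] must be >= 0")
        return self


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class PlantedSite:
    gene_id: str
    tstart: int
    tend: int
    mismatches: int
    genomic: list[GenomicInterval]


@dataclass
class PlantedRsRNA:
    srna_id: str
    seq: str
    origin_class: str
    locus: GenomicInterval
    biogenesis_label: str
    has_motifs: bool
    sites: list[PlantedSite]
    de_direction: str                  # up_in_tumor | up_in_normal
    home_conditions: tuple[str, str]
    interaction_mode: str              # both | clip_only | clash_only
    ago_proteins: tuple[str, ...]
    tar_covered: bool
    expected_primary_class: str
    expected_class_set: frozenset
    hairpin_index: Optional[int] = None


@dataclass
class Decoy:
    decoy_id: str
    seq: str
    failure_mode: str
    sites: list[PlantedSite] = field(default_factory=list)
    home_conditions: tuple[str, ...] = ()


@dataclass
class HairpinLocus:
    precursor: GenomicInterval
    arm5: GenomicInterval
    loop: GenomicInterval
    with_motifs: bool


@dataclass
class Reference:
    genome: dict                       # chrom -> bytearray (mutable until finalized)
    genes: list[GeneModel]
    repeats: list[RepeatElement]
    hairpins: list[HairpinLocus]
    known_mirnas: list[tuple[str, str]]
    consensus: dict
    tar_intervals: list[GenomicInterval] = field(default_factory=list)
    config: Optional[GeneratorConfig] = None

    def genome_str(self) -> dict[str, str]:
        return {c: bytes(b).decode() for c, b in self.genome.items()}

    def attach_sequences(self) -> None:
        rio.attach_spliced_sequences(self.genes, self.genome_str())


@dataclass
class SyntheticTruth:
    reference: Reference
    planted: list[PlantedRsRNA]
    decoys: list[Decoy]
    config: GeneratorConfig


@dataclass
class Bundle:
    truth: SyntheticTruth
    samples: list[SampleMeta]
    read_sets: dict                    # sample_id -> list of read sequences
    count_matrix: CountMatrix          # expected counts (pre-collapse oracle)
    ago_peaks: dict                    # AGO -> list[GenomicInterval]
    ago_reads: dict                    # AGO -> Counter
    chimeras: list[ClashChimera]
    perturbations: dict                # set name -> Counter
    expression: dict                   # layer -> DataFrame (genes x samples)


def _rng(config: GeneratorConfig, stage: int, seed: Optional[int] = None):
    base = config.rng_seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base) % (2**31), stage]))


def _random_seq(rng, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(config: GeneratorConfig) -> Reference:
    """Build the genome scaffold: genes, ncRNAs, repeat copies, hairpins.

    Features are laid out left to right with random intergenic gaps; repeat
    copies are mutated copies of a stored per-family consensus with
    recorded (consensus_offset, orientation); each hairpin locus embeds a
    perfect-complement 30-pair stem around a fixed apical loop, guarded by
    4 nt non-pairable pads, with the three Drosha motifs written at their
    configured offsets when requested.
    """
    config.validate()
    rng = _rng(config, 0)
    chrom = config.chrom
    genome = bytearray(_random_seq(rng, config.genome_length).encode())
    cursor = 200
    cfg_pipe = PipelineConfig()

    def advance(n: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += n
        cursor += int(rng.integers(30, 80))      # intergenic gap
        if cursor > config.genome_length - 200:
            need = cursor + 200
            raise SizingError(
                f"genome_length={config.genome_length} too short; needs >= {need}"
            )
        return start

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        strand = "-" if i % 5 == 4 else "+"
        utr5, cds_a, cds_b, cds_c, utr3 = 60, 90, 90, 60, 250
        i1, i2 = 120, 150
        total = utr5 + cds_a + i1 + cds_b + i2 + cds_c + utr3
        g0 = advance(total)
        if strand == "+":
            # left to right: [5'UTR + CDS] intron [CDS] intron [CDS + 3'UTR]
            e1 = GenomicInterval(chrom, g0, g0 + utr5 + cds_a, strand)
            e2 = GenomicInterval(chrom, e1.end + i1, e1.end + i1 + cds_b, strand)
            e3 = GenomicInterval(chrom, e2.end + i2, e2.end + i2 + cds_c + utr3, strand)
            five = [GenomicInterval(chrom, e1.start, e1.start + utr5, strand)]
            cds = [
                GenomicInterval(chrom, e1.start + utr5, e1.end, strand),
                e2,
                GenomicInterval(chrom, e3.start, e3.start + cds_c, strand),
            ]
            three = [GenomicInterval(chrom, e3.start + cds_c, e3.end, strand)]
        else:
            # transcript runs right to left: 3'UTR at the left edge
            e1 = GenomicInterval(chrom, g0, g0 + utr3 + cds_c, strand)
            e2 = GenomicInterval(chrom, e1.end + i2, e1.end + i2 + cds_b, strand)
            e3 = GenomicInterval(chrom, e2.end + i1, e2.end + i1 + cds_a + utr5, strand)
            three = [GenomicInterval(chrom, e1.start, e1.start + utr3, strand)]
            cds = [
                GenomicInterval(chrom, e1.start + utr3, e1.end, strand),
                e2,
                GenomicInterval(chrom, e3.start, e3.start + cds_a, strand),
            ]
            five = [GenomicInterval(chrom, e3.start + cds_a, e3.end, strand)]
        genes.append(
            GeneModel(
                gene_id=f"gene{i:03d}",
                interval=GenomicInterval(chrom, g0, e3.end, strand),
                exons=[e1, e2, e3],
                biotype="protein_coding",
                five_utr=five,
                cds=cds,
                three_utr=three,
            )
        )
    for i in range(config.n_ncrna):
        length = 200
        g0 = advance(length)
        iv = GenomicInterval(chrom, g0, g0 + length, "+")
        genes.append(
            GeneModel(
                gene_id=f"ncrna{i:03d}",
                interval=iv,
                exons=[iv],
                biotype="lincRNA",
            )
        )

    consensus = {
        fam: _random_seq(rng, length) for fam, length in config.consensus_lengths.items()
    }
    repeats: list[RepeatElement] = []
    for fam in sorted(config.repeat_copies):
        n_copies = config.repeat_copies[fam]
        cons = consensus[fam]
        for j in range(n_copies):
            clen = len(cons)
            copy_len = int(rng.integers(max(60, clen // 3), clen + 1))
            offset = int(rng.integers(0, clen - copy_len + 1))
            orientation = "+" if rng.random() < 0.7 else "-"
            frag = cons[offset : offset + copy_len]
            if orientation == "-":
                frag = revcomp(frag)
            arr = bytearray(frag.encode())
            n_mut = rng.binomial(copy_len, config.repeat_divergence)
            for pos in rng.choice(copy_len, size=min(n_mut, copy_len), replace=False):
                cur = arr[pos]
                choices = [b for b in b"ACGT" if b != cur]
                arr[pos] = choices[int(rng.integers(0, 3))]
            g0 = advance(copy_len)
            genome[g0 : g0 + copy_len] = arr
            # consensus_offset is the lowest consensus coordinate the copy
            # covers, for both orientations; '-' copies reflect through the
            # copy (annotate.map_to_consensus implements the same rule)
            repeats.append(
                RepeatElement(
                    GenomicInterval(chrom, g0, g0 + copy_len, "+"),
                    fam,
                    offset,
                    clen,
                    orientation,
                )
            )

    hairpins: list[HairpinLocus] = []
    arm_len = 30
    pad = cfg_pipe.max_bulge_nt + 2               # outreaches any bulged extension
    for h in range(config.n_hairpin_loci):
        arm = _random_seq(rng, arm_len)
        stem = arm + HAIRPIN_LOOP + revcomp(arm)
        g0 = advance(len(stem) + 80)
        ps = g0 + 40
        pe = ps + len(stem)
        genome[ps:pe] = stem.encode()
        genome[ps - pad : ps] = b"A" * pad        # A-pads: stem cannot extend outward
        genome[pe : pe + pad] = b"A" * pad
        with_motifs = True
        # basal U(-14) / G(-13), CNNC starting 17 nt downstream of the 3' end
        genome[ps - 14 : ps - 12] = b"TG"
        genome[pe + 16] = ord("C")
        genome[pe + 17 : pe + 19] = _random_seq(rng, 2).encode()
        genome[pe + 19] = ord("C")
        hairpins.append(
            HairpinLocus(
                precursor=GenomicInterval(chrom, ps, pe, "+"),
                arm5=GenomicInterval(chrom, ps, ps + arm_len, "+"),
                loop=GenomicInterval(chrom, ps + arm_len, ps + arm_len + len(HAIRPIN_LOOP), "+"),
                with_motifs=with_motifs,
            )
        )
        window = bytes(genome[ps - 60 : pe + 60]).decode()
        found = detect_hairpin(window, cfg_pipe.min_stem_pairs, cfg_pipe.min_loop_nt,
                               cfg_pipe.max_bulge_nt)
        assert found is not None and found.n_pairs >= arm_len

    known = [(f"mir-{k:03d}", _random_seq(rng, 22)) for k in range(config.n_known_mirnas)]
    return Reference(
        genome={chrom: genome},
        genes=genes,
        repeats=repeats,
        hairpins=hairpins,
        known_mirnas=known,
        consensus=consensus,
        config=config,
    )


# ---------------------------------------------------------------------------
# planting


def _conditions(config: GeneratorConfig) -> list[str]:
    return [f"cond{c + 1}" for c in range(config.n_conditions)]


def plant_rsrnas(reference: Reference, config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticTruth:
    """Plant rsRNAs of each origin class plus decoys, write their target
    sites into 3'UTRs, and finalize the truth ledger and TAR intervals."""
    rng = _rng(config, 1, seed)
    chrom = config.chrom
    genome = reference.genome[chrom]
    conds = _conditions(config)
    known_seqs = {seq for _id, seq in reference.known_mirnas}
    used_seqs = set(known_seqs)
    coding = [g for g in reference.genes if g.biotype == "protein_coding"]
    ncrna = [g for g in reference.genes if g.biotype != "protein_coding"]
    utr_cursor: dict[str, int] = {}

    def draw_length() -> int:
        return int(rng.integers(config.min_len, config.max_len + 1))

    def substring(iv: GenomicInterval, length: int, sense: str) -> tuple[str, GenomicInterval]:
        if len(iv) < length:
            raise SizingError(f"feature {iv} shorter than requested sRNA length {length}")
        off = int(rng.integers(0, len(iv) - length + 1))
        g0 = iv.start + off
        raw = bytes(genome[g0 : g0 + length]).decode()
        seq = raw if sense == "+" else revcomp(raw)
        return seq, GenomicInterval(chrom, g0, g0 + length, sense)

    def pick_origin(origin: str, index: int) -> tuple[str, GenomicInterval, Optional[int]]:
        for _attempt in range(40):
            if origin == "intron":
                gene = coding[int(rng.integers(0, len(coding)))]
                intron = gene.introns()[int(rng.integers(0, 2))]
                seq, locus = substring(intron, draw_length(), gene.strand)
            elif origin == "repeat":
                rep = reference.repeats[int(rng.integers(0, len(reference.repeats)))]
                seq, locus = substring(rep.interval, draw_length(), "+")
            elif origin == "ncRNA":
                gene = ncrna[int(rng.integers(0, len(ncrna)))]
                seq, locus = substring(gene.exons[0], draw_length(), gene.strand)
            elif origin == "hairpin":
                hp = reference.hairpins[index % len(reference.hairpins)]
                length = min(draw_length(), len(hp.arm5))
                seq, locus = substring(hp.arm5, length, "+")
            else:                      # pragma: no cover
                raise ValueError(origin)
            if seq not in used_seqs and "N" not in seq:
                used_seqs.add(seq)
                hp_index = index % len(reference.hairpins) if origin == "hairpin" else None
                return seq, locus, hp_index
        raise SizingError(f"could not draw a fresh {origin} sRNA after 40 attempts")

    def write_site(seq: str, gene: GeneModel, n_mut: int) -> PlantedSite:
        """Write a near-perfect complementary site (8mer seed kept intact)
        into the gene's 3'UTR and return its transcript coordinates."""
        L = len(seq)
        site = bytearray(revcomp(seq).encode())
        mismatches = 0
        if seq[0] != "T":              # force the A anchor opposite position 1
            site[L - 1] = ord("A")
            mismatches += 1
        mut_positions = [2, 5, 8]      # pair sRNA positions >= 10: seed untouched
        for pos in mut_positions[: max(0, n_mut - mismatches)]:
            if pos >= L - 9:
                continue
            cur = site[pos]
            site[pos] = next(b for b in b"ACGT" if b != cur and b != ord("N"))
            mismatches += 1
        spans = gene.region_transcript_intervals("3UTR")
        t_lo, t_hi = spans[0]
        cursor = utr_cursor.get(gene.gene_id, t_lo + 5)
        if cursor + L + 5 > t_hi:
            raise SizingError(f"3'UTR of {gene.gene_id} exhausted for planted sites")
        tstart, tend = cursor, cursor + L
        utr_cursor[gene.gene_id] = tend + 12
        pieces = gene.transcript_to_genomic(tstart, tend)
        assert len(pieces) == 1
        piece = pieces[0]
        payload = bytes(site) if gene.strand == "+" else revcomp(bytes(site).decode()).encode()
        genome[piece.start : piece.end] = payload
        return PlantedSite(gene.gene_id, tstart, tend, mismatches, [piece])

    planted: list[PlantedRsRNA] = []
    index = 0
    ago_cycle = [("AGO1", "AGO2"), ("AGO2",), ("AGO3", "AGO4"),
                 ("AGO1", "AGO2", "AGO3", "AGO4")]
    mode_cycle = ["both", "clip_only", "clash_only"]
    for origin in ORIGIN_CLASSES:
        for k in range(config.n_planted.get(origin, 0)):
            seq, locus, hp_index = pick_origin(origin, k)
            gene = coding[index % len(coding)]
            site = write_site(seq, gene, n_mut=index % 3)
            if origin == "hairpin":
                label = "drosha_dgcr8_dependent"
            else:
                label = "dicer_only" if index % 2 == 0 else "independent"
            home = (conds[index % len(conds)], conds[(index + 1) % len(conds)])
            expected_primary = origin if origin != "hairpin" else "intergenic"
            expected_set = frozenset({expected_primary, "intergenic"})
            planted.append(
                PlantedRsRNA(
                    srna_id=f"rsRNA-{index + 1:04d}",
                    seq=seq,
                    origin_class=origin,
                    locus=locus,
                    biogenesis_label=label,
                    has_motifs=(origin == "hairpin"),
                    sites=[site],
                    de_direction="up_in_normal" if index % 5 == 4 else "up_in_tumor",
                    home_conditions=home,
                    interaction_mode=mode_cycle[index % 3],
                    ago_proteins=ago_cycle[index % 4],
                    tar_covered=False,
                    expected_primary_class=expected_primary,
                    expected_class_set=expected_set,
                    hairpin_index=hp_index,
                )
            )
            index += 1

    decoys: list[Decoy] = []
    d_index = 0
    intergenic_pool = GenomicInterval(chrom, 0, config.genome_length, "+")
    known_list = sorted(known_seqs)
    for mode in FAILURE_MODES:
        for k in range(config.n_decoys.get(mode, 0)):
            if mode == "known_miRNA":
                seq = known_list[k % len(known_list)]
                sites = []
            else:
                for _attempt in range(40):
                    seq, _locus = substring(intergenic_pool, draw_length(), "+")
                    if seq not in used_seqs:
                        used_seqs.add(seq)
                        break
                else:
                    raise SizingError("could not draw a fresh decoy sequence")
                sites = []
                if mode == "no_interaction":
                    gene = coding[(index + d_index) % len(coding)]
                    sites = [write_site(seq, gene, n_mut=d_index % 3)]
            home = (conds[d_index % len(conds)], conds[(d_index + 1) % len(conds)])
            if mode == "single_condition":
                home = (conds[d_index % len(conds)],)
            decoys.append(Decoy(f"decoy-{mode}-{k}", seq, mode, sites, home))
            d_index += 1

    # TAR intervals cover an exact fraction of planted origin loci.
    n_covered = int(round(config.tar_fraction * len(planted)))
    tar = []
    for p in planted[:n_covered]:
        p.tar_covered = True
        tar.append(p.locus.expanded(20, config.genome_length))
    reference.tar_intervals = [GenomicInterval(t.chrom, t.start, t.end, "+") for t in tar]
    reference.attach_sequences()
    return SyntheticTruth(reference, planted, decoys, config)


# ---------------------------------------------------------------------------
# sequencing simulation


def make_samples(config: GeneratorConfig, assay: str = "sRNA-seq") -> list[SampleMeta]:
    samples = []
    for cond in _conditions(config):
        for state in ("tumor", "normal"):
            for r in range(config.samples_per_group):
                samples.append(SampleMeta(f"{cond}_{state}_{r + 1}", cond, state, assay))
    return samples


def _nb_draw(rng, mean: float, dispersion: Optional[float]) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(round(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def expected_mean(entity, sample: SampleMeta, config: GeneratorConfig) -> float:
    """Planted per-sample mean count for an rsRNA or decoy."""
    m = config.nb_mean
    if isinstance(entity, PlantedRsRNA) or entity.failure_mode in ("known_miRNA", "no_interaction"):
        home = entity.home_conditions
        if sample.condition_id not in home:
            return 0.0
        de = sample.condition_id == home[0]
        direction = getattr(entity, "de_direction", "up_in_tumor")
        if de and isinstance(entity, PlantedRsRNA) or (
            de and getattr(entity, "failure_mode", "") == "no_interaction"
        ):
            if direction == "up_in_tumor":
                return m * config.fold_change if sample.state == "tumor" else m
            return m if sample.state == "tumor" else m * config.fold_change
        return m
    return 0.0


def simulate_sequencing(
    truth: SyntheticTruth, config: GeneratorConfig, seed: Optional[int] = None
) -> tuple[dict, CountMatrix, list[SampleMeta]]:
    """Per-sample read sets plus the expected count matrix.

    Planted rsRNAs draw negative-binomial counts around their per-condition
    means (fold change applied in the first home condition); decoy counts
    are deterministic by construction so that each decoy fails exactly its
    designed filter; background reads are random genomic substrings at one
    copy each.
    """
    rng = _rng(config, 2, seed)
    samples = make_samples(config)
    genome = truth.reference.genome[config.chrom]
    counts: dict[str, dict[str, int]] = {}

    def add(seq: str, sample_id: str, n: int) -> None:
        if n > 0:
            counts.setdefault(seq, {})[sample_id] = counts.setdefault(seq, {}).get(sample_id, 0) + n

    for entity in truth.planted + [d for d in truth.decoys if d.failure_mode in ("known_miRNA", "no_interaction")]:
        for s in samples:
            add(entity.seq, s.sample_id, _nb_draw(rng, expected_mean(entity, s, config), config.nb_dispersion))

    by_cond: dict[str, list[SampleMeta]] = {}
    for s in samples:
        by_cond.setdefault(s.condition_id, []).append(s)
    for d in truth.decoys:
        if d.failure_mode == "low_abundance":
            # one read in two samples of each of two conditions: recurrent but rare
            for cond in d.home_conditions[:2] or list(by_cond)[:2]:
                for s in by_cond[cond][:2]:
                    add(d.seq, s.sample_id, 1)
        elif d.failure_mode == "single_condition":
            cond = d.home_conditions[0]
            for s in by_cond[cond][:4]:
                add(d.seq, s.sample_id, 3)

    # shared background pool: each sequence expressed in one condition only
    # (recurrence filter removes it) at depths that dominate the library
    conds = _conditions(config)
    planted_seqs = {p.seq for p in truth.planted} | {d.seq for d in truth.decoys}
    for b in range(config.n_background_shared):
        length = int(rng.integers(config.min_len, config.max_len + 1))
        g0 = int(rng.integers(0, config.genome_length - length))
        seq = bytes(genome[g0 : g0 + length]).decode()
        if seq in planted_seqs:
            continue
        cond = conds[b % len(conds)]
        for s in samples:
            if s.condition_id == cond:
                add(seq, s.sample_id, _nb_draw(rng, config.background_shared_mean, config.nb_dispersion))
    # rare one-copy reads
    for s in samples:
        for _ in range(config.background_unique_per_sample):
            length = int(rng.integers(config.min_len, config.max_len + 1))
            g0 = int(rng.integers(0, config.genome_length - length))
            seq = bytes(genome[g0 : g0 + length]).decode()
            if seq not in planted_seqs:
                add(seq, s.sample_id, 1)

    all_seqs = sorted(counts)
    ids = [s.sample_id for s in samples]
    mat = pd.DataFrame(
        {sid: [counts[seq].get(sid, 0) for seq in all_seqs] for sid in ids},
        index=pd.Index(all_seqs, name="sequence"),
        dtype=np.int64,
    )
    cm = CountMatrix(mat, samples)
    read_sets = {
        sid: [seq for seq in all_seqs for _ in range(counts[seq].get(sid, 0))] for sid in ids
    }
    return read_sets, cm, samples


# ---------------------------------------------------------------------------
# interaction, perturbation and expression layers


def simulate_interaction_data(
    truth: SyntheticTruth, config: GeneratorConfig, seed: Optional[int] = None
) -> tuple[dict, dict, list[ClashChimera]]:
    """AGO1-4 peak sets and read sets plus CLASH chimera records covering
    every planted interaction; ``no_interaction`` decoys receive neither."""
    peaks: dict[str, list[GenomicInterval]] = {p: [] for p in ("AGO1", "AGO2", "AGO3", "AGO4")}
    reads: dict[str, Counter] = {p: Counter() for p in peaks}
    chimeras: list[ClashChimera] = []
    chim_idx = 0
    for p in truth.planted:
        for site in p.sites:
            piece = site.genomic[0]
            if p.interaction_mode in ("both", "clip_only"):
                for protein in p.ago_proteins:
                    peaks[protein].append(piece.expanded(10))
                    reads[protein][p.seq] += 5
            if p.interaction_mode in ("both", "clash_only"):
                frag = piece.expanded(10)
                chimeras.append(
                    ClashChimera(f"chimera{chim_idx:05d}", p.seq, frag, site.gene_id)
                )
                chim_idx += 1
    return peaks, reads, chimeras


_PRESENT = 8          # copies in a set where an sRNA is present


def simulate_perturbations(
    truth: SyntheticTruth, config: GeneratorConfig, seed: Optional[int] = None
) -> dict[str, Counter]:
    """WT/KD read sets for Dicer, DGCR8 and Drosha plus Dicer/TRBP/DGCR8
    CLIP sets implementing each planted biogenesis label exactly."""
    presence = {
        "drosha_dgcr8_dependent": {
            "dicer_wt": True, "dicer_kd": False, "dicer_clip": True, "trbp_clip": True,
            "dgcr8_wt": True, "dgcr8_kd": False, "dgcr8_clip": True,
            "drosha_wt": True, "drosha_kd": False,
        },
        "dicer_only": {
            "dicer_wt": True, "dicer_kd": False, "dicer_clip": True, "trbp_clip": True,
            "dgcr8_wt": True, "dgcr8_kd": True, "dgcr8_clip": True,
            "drosha_wt": True, "drosha_kd": True,
        },
        "independent": {
            "dicer_wt": True, "dicer_kd": True, "dicer_clip": True, "trbp_clip": True,
            "dgcr8_wt": True, "dgcr8_kd": True, "dgcr8_clip": True,
            "drosha_wt": True, "drosha_kd": True,
        },
    }
    sets: dict[str, Counter] = {
        name: Counter() for name in presence["independent"]
    }
    for p in truth.planted:
        table = presence[p.biogenesis_label]
        for name, present in table.items():
            if present:
                sets[name][p.seq] += _PRESENT
    return sets


def _anticorr_noise_sd(x: np.ndarray, r: float) -> float:
    return float(np.std(x) * np.sqrt(1.0 / (r * r) - 1.0))


def simulate_expression(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    srna_rpm: pd.DataFrame,
    seed: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Gene-level RNA-seq RPKM, microarray and protein matrices.

    Each planted (rsRNA, target) pair generates the target's abundance as a
    decreasing affine function of the rsRNA's RPM plus Gaussian noise
    calibrated so the realized Pearson r matches ``anticorr_r`` in
    expectation; all other genes are independent of rsRNA levels. Protein
    abundance is available for a subset of target genes only.
    """
    rng = _rng(config, 4, seed)
    samples = list(srna_rpm.columns)
    genes = [g.gene_id for g in truth.reference.genes if g.biotype == "protein_coding"]
    base = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=0.5, size=(len(genes), len(samples))),
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    micro = pd.DataFrame(
        rng.lognormal(mean=5.0, sigma=0.4, size=(len(genes), len(samples))),
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    r = config.anticorr_r
    protein_genes = []
    for i, p in enumerate(truth.planted):
        x = srna_rpm.loc[p.seq].to_numpy(dtype=float) if p.seq in srna_rpm.index else None
        if x is None or np.std(x) == 0:
            continue
        gene_id = p.sites[0].gene_id
        for layer, frame, scale in (("rnaseq", base, 1.0), ("microarray", micro, 4.0)):
            sd = _anticorr_noise_sd(x, r)
            noise = rng.normal(0.0, sd, size=len(x))
            y = (x.max() - x) * scale + noise * scale
            frame.loc[gene_id] = np.maximum(y - y.min() + 1.0, 0.0)
        if i % 2 == 0:
            protein_genes.append(gene_id)
    protein = pd.DataFrame(
        rng.lognormal(mean=1.0, sigma=0.3, size=(len(protein_genes), len(samples))),
        index=pd.Index(protein_genes, name="gene_id"),
        columns=samples,
    )
    for p in truth.planted:
        gene_id = p.sites[0].gene_id
        if gene_id not in protein.index or p.seq not in srna_rpm.index:
            continue
        x = srna_rpm.loc[p.seq].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        sd = _anticorr_noise_sd(x, r)
        y = (x.max() - x) + rng.normal(0.0, sd, size=len(x))
        protein.loc[gene_id] = np.maximum(y - y.min() + 0.5, 0.0)
    return {"rnaseq": base, "microarray": micro, "protein": protein}


def simulate_anticorr_pairs(
    n_samples: int = 30,
    n_pairs: int = 200,
    r_target: float = -0.8,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, list, list]:
    """Stand-alone calibration cohort for the anti-correlation screen.

    Returns (srna_rpm, expression, planted_pairs, null_pairs): ``n_pairs``
    planted pairs with affine-plus-noise targets calibrated to ``r_target``
    and the same number of independent null pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 99]))
    cols = [f"s{i}" for i in range(n_samples)]
    srna_ids = [f"x{i}" for i in range(n_pairs)]
    rpm = pd.DataFrame(
        rng.lognormal(mean=4.0, sigma=0.8, size=(n_pairs, n_samples)),
        index=pd.Index(srna_ids, name="srna_id"),
        columns=cols,
    )
    expr = {}
    planted_pairs = []
    null_pairs = []
    for i, sid in enumerate(srna_ids):
        x = rpm.loc[sid].to_numpy()
        sd = _anticorr_noise_sd(x, r_target)
        y = (x.max() - x) + rng.normal(0.0, sd, size=n_samples)
        expr[f"target{i}"] = np.maximum(y - y.min() + 1.0, 0.0)
        expr[f"null{i}"] = rng.lognormal(mean=3.0, sigma=0.5, size=n_samples)
        planted_pairs.append((sid, f"target{i}"))
        null_pairs.append((sid, f"null{i}"))
    expression = pd.DataFrame(expr, index=cols).T
    expression.index.name = "gene_id"
    return rpm, expression, planted_pairs, null_pairs


# ---------------------------------------------------------------------------
# full bundle


def generate_bundle(config: Optional[GeneratorConfig] = None) -> Bundle:
    """Generate every input the pipeline consumes, in memory."""
    config = (config or GeneratorConfig()).validate()
    reference = generate_reference(config)
    truth = plant_rsrnas(reference, config)
    read_sets, cm, samples = simulate_sequencing(truth, config)
    peaks, ago_reads, chimeras = simulate_interaction_data(truth, config)
    perturbations = simulate_perturbations(truth, config)
    lib = cm.counts.sum(axis=0).astype(float).replace(0, np.nan)
    rpm = (cm.counts * 1e6).div(lib, axis=1).fillna(0.0)
    expression = simulate_expression(truth, config, rpm)
    return Bundle(
        truth=truth,
        samples=samples,
        read_sets=read_sets,
        count_matrix=CountMatrix(cm.counts, samples, rpm),
        ago_peaks=peaks,
        ago_reads=ago_reads,
        chimeras=chimeras,
        perturbations=perturbations,
        expression=expression,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Serialize a bundle to the on-disk layout the CLI consumes."""
    out = Path(outdir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "perturb").mkdir(exist_ok=True)
    ref = bundle.truth.reference
    rio.write_sequences(out / "genome.fa", sorted(ref.genome_str().items()))
    rio.write_gff3(out / "models.gff3", ref.genes, ref.repeats)
    rio.write_sequences(out / "known_mirnas.fa", ref.known_mirnas)
    rio.write_bed(out / "tar.bed", [(iv, f"tar{i}") for i, iv in enumerate(ref.tar_intervals)])
    rio.write_samples(out / "samples.tsv", bundle.samples)
    for sid, reads in bundle.read_sets.items():
        rio.write_sequences(
            out / "reads" / f"{sid}.fa", [(f"{sid}.{i}", seq) for i, seq in enumerate(reads)]
        )
    for protein, peaks in bundle.ago_peaks.items():
        rio.write_bed(out / f"peaks_{protein}.bed", [(iv, f"{protein}.{i}") for i, iv in enumerate(peaks)])
        counter = bundle.ago_reads[protein]
        recs = []
        i = 0
        for seq in sorted(counter):
            for _ in range(counter[seq]):
                recs.append((f"{protein}.r{i}", seq))
                i += 1
        rio.write_sequences(out / f"clipreads_{protein}.fa", recs)
    rio.write_chimeras(out / "chimeras.tsv", bundle.chimeras)
    for name, counter in bundle.perturbations.items():
        recs = []
        i = 0
        for seq in sorted(counter):
            for _ in range(counter[seq]):
                recs.append((f"{name}.r{i}", seq))
                i += 1
        rio.write_sequences(out / "perturb" / f"{name}.fa", recs)
    for layer, frame in bundle.expression.items():
        rio.write_expression(out / f"expr_{layer}.tsv", frame)
    rio.write_count_matrix(
        bundle.count_matrix, out / "counts.tsv", out / "samples.tsv", out / "rpm.tsv"
    )
    _write_truth(bundle.truth, out)


def _write_truth(truth: SyntheticTruth, out: Path) -> None:
    rows = []
    for p in truth.planted:
        rows.append(
            {
                "entity_id": p.srna_id,
                "kind": "planted",
                "sequence": p.seq,
                "origin_class": p.origin_class,
                "locus": f"{p.locus.chrom}:{p.locus.start}-{p.locus.end}({p.locus.strand})",
                "biogenesis_label": p.biogenesis_label,
                "has_motifs": p.has_motifs,
                "target_genes": ",".join(s.gene_id for s in p.sites),
                "de_direction": p.de_direction,
                "home_conditions": ",".join(p.home_conditions),
                "interaction_mode": p.interaction_mode,
                "ago_proteins": ",".join(p.ago_proteins),
                "tar_covered": p.tar_covered,
                "expected_primary_class": p.expected_primary_class,
            }
        )
    for d in truth.decoys:
        rows.append(
            {
                "entity_id": d.decoy_id,
                "kind": "decoy",
                "sequence": d.seq,
                "origin_class": d.failure_mode,
                "locus": "",
                "biogenesis_label": "",
                "has_motifs": False,
                "target_genes": ",".join(s.gene_id for s in d.sites),
                "de_direction": "",
                "home_conditions": ",".join(d.home_conditions),
                "interaction_mode": "",
                "ago_proteins": "",
                "tar_covered": False,
                "expected_primary_class": "",
            }
        )
    rio.write_table(out / "truth.tsv", pd.DataFrame(rows))
    manifest = {
        "generator_config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(truth.config).items()
        },
        "n_planted": len(truth.planted),
        "n_decoys": len(truth.decoys),
    }
    rio.write_json(out / "truth.json", manifest)
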