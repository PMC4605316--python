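"""Core domain types shared across the pipeline.

Coordinate convention: 0-based half-open everywhere, strand in {+,-}.
Sequence convention: DNA alphabet internally (U is normalized to T on
ingest); writers can restore the RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_STATES = ("tumor", "normal")
VALID_ASSAYS = ("sRNA-seq", "RNA-seq", "microarray", "protein", "qPCR")


def revcomp(seq: str) -> str:
    """Reverse complement in the internal DNA alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U to T (internal comparison alphabet)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At-least-one-nucleotide overlap, strand-agnostic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, slop: int, chrom_length: Optional[int] = None) -> "GenomicInterval":
        start = max(0, self.start - slop)
        end = self.end + slop
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class GeneModel:
    """One gene with a single representative transcript.

    ``exons`` are genomic intervals sorted by genomic start; UTR/CDS
    sub-intervals partition the exons for protein-coding genes. Transcript
    coordinates run 5'->3' along the mature (spliced) transcript, so for a
    minus-strand gene transcript position 0 sits at the rightmost exon base.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "protein_coding"
    five_utr: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)
    spliced_seq: Optional[str] = None

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def transcript_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    # ---- transcript <-> genome mapping -------------------------------------

    def _exon_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to a transcript position (None if intronic)."""
        offset = 0
        for ex in self._exon_order():
            if ex.start <= pos < ex.end:
                if self.strand == "+":
                    return offset + (pos - ex.start)
                return offset + (ex.end - 1 - pos)
            offset += len(ex)
        return None

    def transcript_to_genomic(self, tstart: int, tend: int) -> list[GenomicInterval]:
        """Project a transcript interval through the exon structure.

        Returns one genomic interval per exon touched (sites spanning splice
        junctions project to multiple intervals).
        """
        if not (0 <= tstart < tend <= self.transcript_length):
            raise ValueError(
                f"{self.gene_id}: transcript interval ({tstart},{tend}) out of "
                f"range 0..{self.transcript_length}"
            )
        pieces = []
        offset = 0
        for ex in self._exon_order():
            lo = max(tstart, offset)
            hi = min(tend, offset + len(ex))
            if lo < hi:
                if self.strand == "+":
                    g0 = ex.start + (lo - offset)
                    g1 = ex.start + (hi - offset)
                else:
                    g1 = ex.end - (lo - offset)
                    g0 = ex.end - (hi - offset)
                pieces.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            offset += len(ex)
        return pieces

    def region_transcript_intervals(self, region: str) -> list[tuple[int, int]]:
        """Transcript-coordinate spans of 5UTR / CDS / 3UTR sub-annotations."""
        genomic = {"5UTR": self.five_utr, "CDS": self.cds, "3UTR": self.three_utr}
        try:
            parts = genomic[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r}") from None
        spans = []
        for iv in parts:
            t0 = self.genomic_to_transcript(iv.start if self.strand == "+" else iv.end - 1)
            t1 = self.genomic_to_transcript(iv.end - 1 if self.strand == "+" else iv.start)
            if t0 is None or t1 is None:
                raise ValueError(f"{self.gene_id}: {region} interval not exonic")
            spans.append((t0, t1 + 1))
        spans.sort()
        return spans

    def region_sequence(self, region: str) -> list[tuple[int, str]]:
        """(transcript start, sequence) for each span of the region."""
        if self.spliced_seq is None:
            raise ValueError(f"{self.gene_id}: spliced sequence not attached")
        return [(t0, self.spliced_seq[t0:t1]) for t0, t1 in self.region_transcript_intervals(region)]


@dataclass(frozen=True)
class RepeatElement:
    """A genomic repeat copy with its alignment to the family consensus.

    ``consensus_offset`` is the lowest consensus coordinate the copy covers;
    ``orientation`` says whether the copy runs along (+) or against (-) the
    consensus. A genomic position at offset ``rel`` from the copy start maps
    to consensus position ``consensus_offset + rel`` for a '+' copy and to
    ``consensus_offset + (copy_length - 1 - rel)`` for a '-' copy (see
    annotate.map_to_consensus).
    """

    interval: GenomicInterval
    family: str
    consensus_offset: int
    consensus_length: int
    orientation: str = "+"

    def __post_init__(self):
        if not (0 <= self.consensus_offset < self.consensus_length):
            raise ValueError(
                f"consensus_offset {self.consensus_offset} outside consensus "
                f"of length {self.consensus_length}"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition_id: str
    state: str
    assay: str = "sRNA-seq"

    def __post_init__(self):
        if self.state not in VALID_STATES:
            raise ValueError(f"invalid state {self.state!r}")
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"invalid assay {self.assay!r}")


class CountMatrix:
    """Unique sRNA sequences x samples: raw counts plus an optional RPM layer."""

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        rpm: Optional[pd.DataFrame] = None,
    ):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(counts.columns) != ids:
            raise ValueError("count matrix columns must match sample metadata order")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.samples = samples
        self.rpm = rpm

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        return next(s for s in self.samples if s.sample_id == sample_id)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition_id, None)
        return list(seen)

    def condition_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.condition_id, []).append(s.sample_id)
        return out

    def subset(self, sequences: Iterable[str]) -> "CountMatrix":
        seqs = [s for s in self.counts.index if s in set(sequences)]
        rpm = self.rpm.loc[seqs] if self.rpm is not None else None
        return CountMatrix(self.counts.loc[seqs], self.samples, rpm)

    def __len__(self) -> int:
        return len(self.counts.index)


@dataclass(frozen=True)
class AlignmentHit:
    """One Hamming-distance genomic match of a short read."""

    seq: str
    interval: GenomicInterval
    mismatches: int
    all_hits: bool = False

    def __post_init__(self):
        if len(self.interval) != len(self.seq):
            raise ValueError("hit interval length must equal read length")


@dataclass
class TargetSite:
    """One predicted sRNA:gene binding site with its evidence flags."""

    srna_id: str
    gene_id: str
    region: str
    tstart: int
    tend: int
    genomic: list[GenomicInterval]
    duplex_mismatches: Optional[int] = None
    seed_class: str = "none"           # 8mer | 7mer-m8 | 7mer-A1 | none
    seed_predictor: bool = False
    duplex_predictor: bool = False
    ago: dict[str, bool] = field(default_factory=dict)
    clash: bool = False
    antisense: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.srna_id, self.gene_id)

    def any_ago(self) -> bool:
        return any(self.ago.values())


@dataclass(frozen=True)
class ClashChimera:
    """One ligated sRNA:target hybrid read."""

    read_id: str
    srna_segment: str
    fragment: GenomicInterval
    gene_id: Optional[str] = None

    def __post_init__(self):
        if not self.srna_segment:
            raise ValueError("empty sRNA segment in chimera")


@dataclass
class HairpinStructure:
    """Single-stem hairpin in window coordinates.

    ``precursor`` spans the outermost pair; the 5' and 3' arms flank the
    terminal ``loop``; ``pairs`` lists (i, j) paired window positions
    (Watson-Crick or G:U), nested along one stem.
    """

    precursor: tuple[int, int]
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    loop: tuple[int, int]
    pairs: list[tuple[int, int]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def dot_bracket(self, window_length: int) -> str:
        chars = ["."] * window_length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass
class BiogenesisProfile:
    """Processing-dependence calls and hairpin/motif context for one sRNA.

    Tri-state flags use True/False/None, None meaning indeterminate.
    """

    srna_id: str
    dicer_clip: Optional[bool] = None
    dicer_dependent: Optional[str] = None     # dependent | independent | indeterminate
    trbp_clip: Optional[bool] = None
    dgcr8_dependent: Optional[str] = None
    drosha_dependent: Optional[str] = None
    hairpin_found: bool = False
    in_stem: bool = False
    cnnc: Optional[bool] = None
    basal_u: Optional[bool] = None
    basal_g: Optional[bool] = None
    basal_ug: Optional[bool] = None
    apical_ugu: Optional[bool] = None

    @property
    def all_three_motifs(self) -> Optional[bool]:
        flags = (self.cnnc, self.basal_ug, self.apical_ugu)
        if any(f is None for f in flags):
            return None
        return all(flags)


@dataclass
class AnnotationCall:
    """Genomic origin classes of one sRNA across all its aligned loci."""

    srna_id: str
    locus_classes: list[tuple[GenomicInterval, str]]
    primary_class: str
    class_set: frozenset[str]
    repeat_families: frozenset[str] = frozenset()
    tar_overlap: Optional[bool] = None


@dataclass
class ConsensusProfile:
    """Weight of sRNA 5' starts along a repeat family consensus."""

    family: str
    weights: np.ndarray
    normalization: str = "raw"        # raw | sum-to-1
    group: str = ""
    dropped_weight: float = 0.0

    def normalized(self) -> "ConsensusProfile":
        total = float(self.weights.sum())
        weights = self.weights / total if total > 0 else self.weights.copy()
        return ConsensusProfile(self.family, weights, "sum-to-1", self.group, self.dropped_weight)


@dataclass
class RsRNARecord:
    """Final integrated record for one candidate sequence."""

    srna_id: str
    sequence: str
    known_mirna: bool = False
    abundance_ok: Optional[bool] = None
    recurrence_ok: Optional[bool] = None
    n_conditions_present: int = 0
    consensus_targets: int = 0
    ago: dict[str, bool] = field(default_factory=dict)
    clash: bool = False
    antisense: bool = False
    de_flag: Optional[bool] = None
    de_conditions_up_tumor: int = 0
    de_conditions_up_normal: int = 0
    biogenesis: Optional[BiogenesisProfile] = None
    anticorr_hits: dict[str, int] = field(default_factory=dict)
    annotation: Optional[AnnotationCall] = None
    status: str = "unprocessed"

    def any_interaction(self) -> bool:
        return any(self.ago.values()) or self.clash
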