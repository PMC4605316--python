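"""Target prediction and interaction validation.

Two independent in-house predictors emulate the published consensus
strategy: a seed-match predictor (canonical miRNA seed classes 8mer /
7mer-m8 / 7mer-A1 over positions 2-8 of the sRNA) and a full-length duplex
predictor (target windows complementary to the whole sRNA within a small
substitution budget). Only (sRNA, gene) pairs supported by overlapping
sites from BOTH predictors survive as consensus sites. Consensus sites are
then validated against AGO1-4 CLIP peaks/read sets and CLASH chimeras, and
screened for antisense origin (biogenesis locus under the binding site on
the opposite strand of the target gene).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .datamodel import (
    AlignmentHit,
    ClashChimera,
    GeneModel,
    GenomicInterval,
    TargetSite,
    revcomp,
)

AGO_PROTEINS = ("AGO1", "AGO2", "AGO3", "AGO4")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# sequence-level scanners (tested directly against brute-force oracles)


def scan_seed_matches(srna: str, target: str) -> list[tuple[int, int, str]]:
    """Seed matches of ``srna`` in ``target`` (both 5'->3', DNA alphabet).

    The match core is the reverse complement of sRNA positions 2-7; the
    class refines by the position-8 match (the target base 5' of the core
    complementary to sRNA position 8) and the A anchor opposite position 1
    (the target base 3' of the core). Returns (start, end, seed_class)
    site intervals in target coordinates; class ``none`` marks a bare 6mer.
    """
    if len(srna) < 8:
        raise ValueError("sRNA shorter than 8 nt has no defined seed")
    core = revcomp(srna[1:7])
    m8_base = _COMP[srna[7]]
    out = []
    pos = target.find(core)
    while pos != -1:
        m8 = pos >= 1 and target[pos - 1] == m8_base
        a1 = pos + 6 < len(target) and target[pos + 6] == "A"
        if m8 and a1:
            out.append((pos - 1, pos + 7, "8mer"))
        elif m8:
            out.append((pos - 1, pos + 6, "7mer-m8"))
        elif a1:
            out.append((pos, pos + 7, "7mer-A1"))
        else:
            out.append((pos, pos + 6, "none"))
        pos = target.find(core, pos + 1)
    return out


def scan_duplex_windows(
    srna: str, target: str, max_mm: int = 2, wobble_allowance: int = 0
) -> list[tuple[int, int]]:
    """Windows of ``target`` complementary to the whole sRNA.

    A window of length ``len(srna)`` counts one mismatch per non-pairing
    position when aligned antiparallel to the sRNA. G:U pairs count as
    mismatches by default; ``wobble_allowance`` forgives up to that many of
    them. Returns (window start, effective mismatches) for windows with at
    most ``max_mm`` effective mismatches.
    """
    L = len(srna)
    if len(target) < L:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(srna).encode(), dtype=np.uint8)
    srev = np.frombuffer(srna[::-1].encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    mm = (windows != rc).sum(axis=1)
    if wobble_allowance > 0:
        g, tt = ord("G"), ord("T")
        wob = (((srev == g) & (windows == tt)) | ((srev == tt) & (windows == g))).sum(axis=1)
        mm = mm - np.minimum(wob, wobble_allowance)
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]


# ---------------------------------------------------------------------------
# gene-model level predictors


def _region_sites(gene: GeneModel, regions: Sequence[str]):
    for region in regions:
        for t0, seq in gene.region_sequence(region):
            yield region, t0, seq


def predict_seed_sites(
    srna_id: str,
    srna_seq: str,
    genes: Sequence[GeneModel],
    regions: Sequence[str] = ("3UTR",),
    include_6mer: bool = False,
) -> list[TargetSite]:
    """Seed-predictor sites of one sRNA across gene regions (default 3'UTR).

    Bare 6mer matches (class ``none``) are dropped unless requested, so a
    reported site always carries at least a 7mer-class seed.
    """
    sites = []
    for gene in genes:
        for region, t0, seq in _region_sites(gene, regions):
            for s, e, cls in scan_seed_matches(srna_seq, seq):
                if cls == "none" and not include_6mer:
                    continue
                tstart, tend = t0 + s, t0 + e
                sites.append(
                    TargetSite(
                        srna_id=srna_id,
                        gene_id=gene.gene_id,
                        region=region,
                        tstart=tstart,
                        tend=tend,
                        genomic=gene.transcript_to_genomic(tstart, tend),
                        seed_class=cls,
                        seed_predictor=True,
                    )
                )
    return sites


def predict_duplex_sites(
    srna_id: str,
    srna_seq: str,
    genes: Sequence[GeneModel],
    max_duplex_mismatches: int = 2,
    regions: Sequence[str] = ("3UTR",),
    wobble_allowance: int = 0,
) -> list[TargetSite]:
    """Duplex-predictor sites: full-length near-complementary target windows."""
    sites = []
    for gene in genes:
        for region, t0, seq in _region_sites(gene, regions):
            for s, mm in scan_duplex_windows(
                srna_seq, seq, max_duplex_mismatches, wobble_allowance
            ):
                tstart, tend = t0 + s, t0 + s + len(srna_seq)
                sites.append(
                    TargetSite(
                        srna_id=srna_id,
                        gene_id=gene.gene_id,
                        region=region,
                        tstart=tstart,
                        tend=tend,
                        genomic=gene.transcript_to_genomic(tstart, tend),
                        duplex_mismatches=mm,
                        duplex_predictor=True,
                    )
                )
    return sites


def consensus_sites(
    seed_sites: Sequence[TargetSite],
    duplex_sites: Sequence[TargetSite],
    genes_by_id: Optional[Mapping[str, GeneModel]] = None,
) -> list[TargetSite]:
    """Pair-level consensus of the two predictors.

    Keeps (sRNA, gene) pairs where a seed site and a duplex site overlap by
    at least one transcript nucleotide; the merged site spans the union of
    the two intervals and carries both predictor flags.
    """
    by_pair: dict[tuple[str, str], list[TargetSite]] = {}
    for site in duplex_sites:
        by_pair.setdefault(site.key, []).append(site)
    merged: dict[tuple[str, str, int, int], TargetSite] = {}
    for seed in seed_sites:
        for dup in by_pair.get(seed.key, []):
            if seed.region != dup.region:
                continue
            if seed.tstart < dup.tend and dup.tstart < seed.tend:
                t0, t1 = min(seed.tstart, dup.tstart), max(seed.tend, dup.tend)
                key = (*seed.key, t0, t1)
                if key in merged:
                    continue
                if genes_by_id is not None:
                    genomic = genes_by_id[seed.gene_id].transcript_to_genomic(t0, t1)
                else:
                    genomic = _union_projection(seed, dup)
                merged[key] = TargetSite(
                    srna_id=seed.srna_id,
                    gene_id=seed.gene_id,
                    region=seed.region,
                    tstart=t0,
                    tend=t1,
                    genomic=genomic,
                    duplex_mismatches=dup.duplex_mismatches,
                    seed_class=seed.seed_class,
                    seed_predictor=True,
                    duplex_predictor=True,
                )
    return sorted(
        merged.values(), key=lambda s: (s.srna_id, s.gene_id, s.tstart, s.tend)
    )


def _union_projection(a: TargetSite, b: TargetSite) -> list[GenomicInterval]:
    pieces = sorted(a.genomic + b.genomic, key=lambda iv: (iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for iv in pieces:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            out[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end), last.strand)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# interaction evidence


def clip_support(
    sites: Sequence[TargetSite],
    ago_peaks: Mapping[str, Sequence[GenomicInterval]],
    ago_reads: Mapping[str, Iterable[str]],
    srna_seqs: Mapping[str, str],
    require_read: bool = True,
) -> list[TargetSite]:
    """Flag AGO1-4 support per site.

    A protein's flag fires iff the site's genomic projection overlaps one of
    that protein's CLIP peaks by >= 1 nt AND (by default) the sRNA sequence
    occurs exactly in that protein's CLIP read set; flags are independent
    across proteins.
    """
    unknown = set(ago_peaks) - set(AGO_PROTEINS)
    if unknown:
        raise ValueError(f"unknown AGO labels: {sorted(unknown)}")
    read_sets = {k: set(v) for k, v in ago_reads.items()}
    for site in sites:
        seq = srna_seqs[site.srna_id]
        for protein in AGO_PROTEINS:
            peaks = ago_peaks.get(protein, ())
            hit = any(p.overlaps(g) for p in peaks for g in site.genomic)
            if hit and require_read:
                hit = seq in read_sets.get(protein, set())
            site.ago[protein] = bool(hit)
    return list(sites)


def _hamming_le(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


def clash_support(
    sites: Sequence[TargetSite],
    chimeras: Sequence[ClashChimera],
    srna_seqs: Mapping[str, str],
    clash_slop_nt: int = 25,
    srna_max_mm: int = 1,
) -> list[TargetSite]:
    """Flag CLASH support: a chimera whose sRNA segment matches the sRNA
    (within ``srna_max_mm`` substitutions) and whose target fragment
    overlaps the site's genomic projection expanded by ``clash_slop_nt``."""
    for site in sites:
        seq = srna_seqs[site.srna_id]
        expanded = [g.expanded(clash_slop_nt) for g in site.genomic]
        site.clash = any(
            _hamming_le(c.srna_segment, seq, srna_max_mm)
            and any(c.fragment.overlaps(g) for g in expanded)
            for c in chimeras
        )
    return list(sites)


def detect_antisense_origin(
    sites: Sequence[TargetSite],
    hits_by_srna: Mapping[str, Sequence[AlignmentHit]],
    genes_by_id: Mapping[str, GeneModel],
) -> list[TargetSite]:
    """Flag sites whose sRNA has a genomic locus under the binding site on
    the strand opposite the target gene (antisense-origin pairs)."""
    for site in sites:
        gene = genes_by_id[site.gene_id]
        site.antisense = any(
            hit.interval.strand != gene.strand
            and any(hit.interval.overlaps(g) for g in site.genomic)
            for hit in hits_by_srna.get(site.srna_id, ())
        )
    return list(sites)
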