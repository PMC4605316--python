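"""Genomic origin annotation of sRNA loci and repeat consensus profiles.

Each aligned locus is classed exon / ncRNA / repeat / intron / intergenic;
the per-sRNA primary class resolves across loci by the fixed priority
exon > ncRNA > repeat > intron > intergenic (a repeat inside an intron is
called repeat). Gene-model classes are strand-aware — an sRNA only
originates from an exon or intron transcribed in the gene's sense — while
repeat and transcriptionally-active-region (TAR) overlap are
strand-agnostic. Repeat-derived loci are additionally projected onto the
family consensus to build per-position abundance profiles compared between
tumor and normal groups.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel import (
    AlignmentHit,
    AnnotationCall,
    ConsensusProfile,
    GeneModel,
    GenomicInterval,
    RepeatElement,
)
from .stats import bh_qvalues, round_half_even, welch_ttest

CLASS_PRIORITY = ("exon", "ncRNA", "repeat", "intron", "intergenic")
_RANK = {c: i for i, c in enumerate(CLASS_PRIORITY)}


def _tree(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def _query(trees: Mapping[str, IntervalTree], iv: GenomicInterval):
    tree = trees.get(iv.chrom)
    return tree.overlap(iv.start, iv.end) if tree is not None else ()


def classify_loci(
    hits: Sequence[AlignmentHit],
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement],
    srna_ids: Optional[Mapping[str, str]] = None,
    genome_lengths: Optional[Mapping[str, int]] = None,
) -> list[AnnotationCall]:
    """Classify every aligned locus of every sRNA and resolve primary classes.

    ``srna_ids`` optionally maps sequence -> identifier for reporting;
    otherwise the sequence itself identifies the sRNA.
    """
    coding_exons = _tree(
        (ex, g) for g in genes if g.biotype == "protein_coding" for ex in g.exons
    )
    nc_exons = _tree(
        (ex, g) for g in genes if g.biotype != "protein_coding" for ex in g.exons
    )
    gene_bodies = _tree((g.interval, g) for g in genes if g.biotype == "protein_coding")
    repeat_tree = _tree((r.interval, r) for r in repeats)

    by_srna: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        if genome_lengths is not None:
            limit = genome_lengths.get(hit.interval.chrom)
            if limit is None or hit.interval.end > limit:
                raise ValueError(f"hit beyond genome bounds: {hit.interval}")
        name = srna_ids.get(hit.seq, hit.seq) if srna_ids else hit.seq
        by_srna.setdefault(name, []).append(hit)

    calls = []
    for name in sorted(by_srna):
        locus_classes = []
        families = set()
        for hit in by_srna[name]:
            iv = hit.interval
            cls = "intergenic"
            if any(iv.strand == g.data.strand for g in _query(coding_exons, iv)):
                cls = "exon"
            elif any(iv.strand == g.data.strand for g in _query(nc_exons, iv)):
                cls = "ncRNA"
            else:
                rep_hits = list(_query(repeat_tree, iv))
                if rep_hits:
                    cls = "repeat"
                    families.update(r.data.family for r in rep_hits)
                elif any(iv.strand == g.data.strand for g in _query(gene_bodies, iv)):
                    cls = "intron"
            locus_classes.append((iv, cls))
        class_set = frozenset(c for _iv, c in locus_classes)
        primary = min(class_set, key=_RANK.__getitem__)
        calls.append(
            AnnotationCall(
                srna_id=name,
                locus_classes=locus_classes,
                primary_class=primary,
                class_set=class_set,
                repeat_families=frozenset(families),
            )
        )
    return calls


def summarize_annotation(
    calls_or_counts, total_n: int, mode: str = "primary"
) -> pd.DataFrame:
    """Per-class counts and percentages of ``total_n`` (2-decimal,
    round-half-even).

    ``mode='primary'`` counts each sRNA once by its primary class;
    ``mode='all_classes'`` counts an sRNA in every class of its class set,
    so counts may sum beyond ``total_n``. A plain mapping class -> count is
    also accepted (printed summaries re-expressed as percentages).
    """
    if total_n < 1:
        raise ValueError("total_n must be >= 1")
    if isinstance(calls_or_counts, Mapping):
        counts = dict(calls_or_counts)
    else:
        counts = {}
        for call in calls_or_counts:
            if mode == "primary":
                counts[call.primary_class] = counts.get(call.primary_class, 0) + 1
            elif mode == "all_classes":
                for cls in call.class_set:
                    counts[cls] = counts.get(cls, 0) + 1
            else:
                raise ValueError(f"unknown mode {mode!r}")
    rows = [
        (cls, counts[cls], round_half_even(100.0 * counts[cls] / total_n, 2))
        for cls in CLASS_PRIORITY
        if cls in counts
    ]
    for cls in sorted(set(counts) - set(CLASS_PRIORITY)):
        rows.append((cls, counts[cls], round_half_even(100.0 * counts[cls] / total_n, 2)))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


def tar_overlap(
    calls: Sequence[AnnotationCall],
    tar_intervals: Sequence[GenomicInterval],
    restrict_to_noncoding: bool = True,
) -> tuple[dict[str, bool], float]:
    """Flag sRNAs whose loci overlap transcriptionally active regions.

    The flag fires on >= 1 nt overlap of any locus with any TAR interval
    (strand-agnostic, half-open semantics: abutting intervals do not
    overlap). The summary fraction's denominator is, by default, the sRNAs
    whose class set excludes ``exon`` (the non-coding candidates).
    """
    trees = _tree((iv, None) for iv in tar_intervals)
    flags: dict[str, bool] = {}
    for call in calls:
        flags[call.srna_id] = any(bool(_query(trees, iv)) for iv, _cls in call.locus_classes)
        call.tar_overlap = flags[call.srna_id]
    if restrict_to_noncoding:
        denom = [c for c in calls if "exon" not in c.class_set]
    else:
        denom = list(calls)
    fraction = (
        sum(1 for c in denom if flags[c.srna_id]) / len(denom) if denom else float("nan")
    )
    return flags, fraction


def map_to_consensus(hit: AlignmentHit, copy: RepeatElement) -> Optional[int]:
    """Map a hit's 5'-most genomic base onto the family consensus.

    For a '+' orientation copy, consensus position = consensus_offset +
    (hit.start - copy.start). For a '-' orientation copy positions reflect
    through the copy: consensus position = consensus_offset +
    (copy_length - 1 - (hit.start - copy.start)). Returns None when the
    mapped position falls outside the consensus (insertion relative to it).
    """
    rel = hit.interval.start - copy.interval.start
    if rel < 0 or rel >= len(copy.interval):
        return None
    if copy.orientation == "+":
        pos = copy.consensus_offset + rel
    else:
        pos = copy.consensus_offset + (len(copy.interval) - 1 - rel)
    return pos if 0 <= pos < copy.consensus_length else None


def consensus_profile(
    hits: Sequence[AlignmentHit],
    repeats: Sequence[RepeatElement],
    rpm_weights: Mapping[str, float],
    family: str,
    group: str = "",
    normalize: bool = False,
) -> ConsensusProfile:
    """Accumulate RPM-weighted sRNA 5' starts along a family consensus.

    Each hit restricted to a copy of ``family`` adds the sRNA's RPM weight
    at the mapped consensus coordinate; out-of-range positions are dropped
    and their weight counted. Weight is conserved: profile sum + dropped
    weight equals the summed input weights of mapped hits.
    """
    copies = [r for r in repeats if r.family == family]
    if not copies:
        raise ValueError(f"unknown repeat family {family!r}")
    length = copies[0].consensus_length
    tree = _tree((r.interval, r) for r in copies)
    weights = np.zeros(length, dtype=float)
    dropped = 0.0
    for hit in hits:
        overlapping = _query(tree, hit.interval)
        if not overlapping:
            continue
        copy = min((o.data for o in overlapping), key=lambda r: (r.interval.start, r.interval.end))
        w = float(rpm_weights.get(hit.seq, 0.0))
        pos = map_to_consensus(hit, copy)
        if pos is None:
            dropped += w
        else:
            weights[pos] += w
    profile = ConsensusProfile(family, weights, "raw", group, dropped)
    return profile.normalized() if normalize else profile


def profile_group_test(
    profiles_by_sample: Mapping[str, ConsensusProfile],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-consensus-position Welch t-tests between two sample groups.

    Profiles must be sum-to-1 normalized per sample; q-values are
    Benjamini-Hochberg across positions and the summary counts positions
    with raw p < 0.05.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    mat_a = np.vstack([profiles_by_sample[s].weights for s in group_a])
    mat_b = np.vstack([profiles_by_sample[s].weights for s in group_b])
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("profile lengths differ between groups")
    n_pos = mat_a.shape[1]
    t_vals = np.full(n_pos, np.nan)
    p_vals = np.full(n_pos, np.nan)
    for i in range(n_pos):
        try:
            t_vals[i], p_vals[i] = welch_ttest(mat_a[:, i], mat_b[:, i])
        except ValueError:
            pass
    table = pd.DataFrame(
        {"position": np.arange(n_pos), "t": t_vals, "p": p_vals, "q_bh": bh_qvalues(p_vals)}
    )
    tested = int(np.isfinite(p_vals).sum())
    significant = int((p_vals[np.isfinite(p_vals)] < 0.05).sum())
    summary = {
        "positions_tested": tested,
        "positions_p_lt_0.05": significant,
        "fraction_significant": significant / tested if tested else float("nan"),
    }
    return table, summary
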