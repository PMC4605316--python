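"""Unique-read catalog and the abundance/recurrence filtering cascade.

The cascade collapses pooled per-sample read sets into a unique-sequence
count matrix, removes sequences matching known mature miRNAs, and keeps a
sequence only if (i) some experimental condition accumulates at least
``min_reads`` copies of it and (ii) it is observed in at least
``min_conditions`` distinct conditions. Alignment is Hamming-distance
matching (no indels) on both strands, mirroring an ungapped short-read
mapper run with a fixed mismatch budget.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError
from .datamodel import AlignmentHit, CountMatrix, GenomicInterval, SampleMeta, revcomp

log = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlignmentResult(NamedTuple):
    hits: list[AlignmentHit]
    rejected: dict[str, str]           # sequence -> reason code


def collapse_reads(
    read_sets: Mapping[str, Sequence[str]], samples: Sequence[SampleMeta]
) -> CountMatrix:
    """Collapse per-sample reads into a unique-sequence count matrix.

    Cell (seq, sample) is the exact-duplicate count of that sequence in that
    sample; column sums therefore equal per-sample input read counts.
    """
    ids = [s.sample_id for s in samples]
    missing = [i for i in ids if i not in read_sets]
    if missing:
        raise ValueError(f"read sets missing for samples: {missing}")
    counters = {}
    for sid in ids:
        reads = read_sets[sid]
        if len(reads) == 0:
            log.warning("sample %s has no reads; zero column emitted", sid)
        counters[sid] = Counter(reads)
    all_seqs = sorted(set().union(*[set(c) for c in counters.values()]) or set())
    data = {
        sid: np.array([counters[sid].get(seq, 0) for seq in all_seqs], dtype=np.int64)
        for sid in ids
    }
    counts = pd.DataFrame(data, index=pd.Index(all_seqs, name="sequence"))
    return CountMatrix(counts, samples)


def _encode(seq: str) -> Optional[np.ndarray]:
    try:
        return np.frombuffer(seq.encode(), dtype=np.uint8)
    except Exception:                  # pragma: no cover
        return None


def align_short_reads(
    sequences: Iterable[str],
    genome: Mapping[str, str],
    max_mm: int = 2,
    report_all: bool = False,
    min_length: int = 15,
) -> AlignmentResult:
    """Find all Hamming-distance genomic matches of each sequence.

    Both strands are scanned (a minus-strand hit means the reverse
    complement of the genomic window equals the read within ``max_mm``
    substitutions). With ``report_all`` every hit with at most ``max_mm``
    mismatches is returned; otherwise only hits in the best
    (minimum-mismatch) stratum of each read. Hits are ordered by
    (chrom, start, strand) per read; reads with non-ACGT symbols or shorter
    than ``min_length`` are rejected with a reason code.
    """
    chrom_arrays = {
        chrom: np.frombuffer(seq.encode(), dtype=np.uint8) for chrom, seq in genome.items()
    }
    hits: list[AlignmentHit] = []
    rejected: dict[str, str] = {}
    for seq in sequences:
        if len(seq) < min_length:
            rejected[seq] = "too_short"
            continue
        if set(seq) - set("ACGT"):
            rejected[seq] = "non_acgt"
            continue
        fwd = np.frombuffer(seq.encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
        seq_hits: list[tuple[str, int, str, int]] = []
        for chrom in sorted(chrom_arrays):
            garr = chrom_arrays[chrom]
            if len(garr) < len(fwd):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(garr, len(fwd))
            for strand, probe in (("+", fwd), ("-", rev)):
                # '-' hit: genomic forward window equals revcomp(read).
                mm = (windows != probe).sum(axis=1)
                for pos in np.nonzero(mm <= max_mm)[0]:
                    seq_hits.append((chrom, int(pos), strand, int(mm[pos])))
        if not seq_hits:
            continue
        if not report_all:
            best = min(h[3] for h in seq_hits)
            seq_hits = [h for h in seq_hits if h[3] == best]
        seq_hits.sort(key=lambda h: (h[0], h[1], h[2]))
        for chrom, pos, strand, mm_count in seq_hits:
            hits.append(
                AlignmentHit(
                    seq,
                    GenomicInterval(chrom, pos, pos + len(seq), strand),
                    mm_count,
                    all_hits=report_all,
                )
            )
    return AlignmentResult(hits, rejected)


def exclude_known_mirnas(
    cm: CountMatrix, known: Iterable[str], max_mm: int = 0
) -> tuple[CountMatrix, list[str]]:
    """Remove rows matching a known mature miRNA within ``max_mm`` substitutions.

    The default is exact sequence identity; with a mismatch allowance only
    equal-length sequences are compared (substitutions, no indels).
    """
    known_set = set(known)
    if not known_set:
        raise ValueError("known miRNA set is empty")
    excluded = []
    if max_mm == 0:
        excluded = [seq for seq in cm.sequences if seq in known_set]
    else:
        by_len: dict[int, list[np.ndarray]] = {}
        for k in sorted(known_set):
            by_len.setdefault(len(k), []).append(np.frombuffer(k.encode(), dtype=np.uint8))
        for seq in cm.sequences:
            probes = by_len.get(len(seq))
            if not probes:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            if any(int((arr != p).sum()) <= max_mm for p in probes):
                excluded.append(seq)
        log.info("excluded %d known-miRNA rows (<=%d mismatches)", len(excluded), max_mm)
    keep = [s for s in cm.sequences if s not in set(excluded)]
    return cm.subset(keep), excluded


def apply_presence_filters(
    cm: CountMatrix, min_reads: int = 5, min_conditions: int = 2
) -> tuple[CountMatrix, pd.DataFrame]:
    """Abundance and recurrence filters.

    A row survives iff (a) its summed count within at least one condition
    reaches ``min_reads`` and (b) it has a nonzero count in at least
    ``min_conditions`` distinct conditions. Presence in a condition means
    count >= 1. The diagnostics table records which clause failed per row.
    """
    cond_cols = cm.condition_columns()
    if min_conditions > len(cond_cols):
        raise ConfigError(
            f"min_conditions={min_conditions} exceeds the {len(cond_cols)} available conditions"
        )
    cond_sums = pd.DataFrame(
        {cond: cm.counts[cols].sum(axis=1) for cond, cols in cond_cols.items()}
    )
    max_condition_count = cond_sums.max(axis=1)
    n_conditions_present = (cond_sums > 0).sum(axis=1)
    abundance_ok = max_condition_count >= min_reads
    recurrence_ok = n_conditions_present >= min_conditions
    diagnostics = pd.DataFrame(
        {
            "max_condition_count": max_condition_count,
            "n_conditions_present": n_conditions_present,
            "abundance_ok": abundance_ok,
            "recurrence_ok": recurrence_ok,
            "kept": abundance_ok & recurrence_ok,
        }
    )
    kept = [s for s, ok in diagnostics["kept"].items() if ok]
    return cm.subset(kept), diagnostics


def rpm_normalize(cm: CountMatrix, library_sizes: Optional[pd.Series] = None) -> CountMatrix:
    """Attach a reads-per-million layer: count * 1e6 / column library size.

    ``library_sizes`` defaults to the matrix's own column sums; pass the
    unfiltered library sizes when normalizing a filtered matrix so that RPM
    still refers to the sequenced library. Columns with zero library size
    yield all-zero RPM (with a warning) rather than NaN.
    """
    lib = (library_sizes if library_sizes is not None else cm.counts.sum(axis=0)).astype(float)
    lib = lib.reindex(cm.counts.columns)
    zero = lib[lib == 0].index.tolist()
    if zero:
        log.warning("zero library size for samples %s; RPM set to 0", zero)
    safe = lib.replace(0, np.nan)
    rpm = (cm.counts * 1e6).div(safe, axis=1).fillna(0.0)
    return CountMatrix(cm.counts, cm.samples, rpm)
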