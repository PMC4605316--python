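"""End-to-end orchestration of the rsRNA discovery cascade.

Stage order: catalog (collapse, known-miRNA exclusion, abundance/recurrence
filters, RPM) -> targeting (two-predictor consensus) -> interaction
validation (AGO CLIP, CLASH, antisense) -> differential expression ->
biogenesis (dependence calls, hairpin, motifs) -> anti-correlation ->
annotation (origin classes, TAR). Every input sequence appears exactly once
in the output with a final status; a candidate is a potential rsRNA iff it
passes the filters, has a consensus target, interaction support and a
two-fold differential expression call. All clauses are conjunctive, so the
final set is independent of stage order even though rejection statuses
name the first failing stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate, biogenesis, catalog, io as rio, stats, targeting
from .config import PipelineConfig
from .datamodel import (
    AlignmentHit,
    AnnotationCall,
    ClashChimera,
    CountMatrix,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    RsRNARecord,
    SampleMeta,
    revcomp,
)

log = logging.getLogger(__name__)

STAGES = (
    "catalog", "targeting", "validation", "differential",
    "biogenesis", "correlation", "annotation",
)


@dataclass
class PipelineInputs:
    """In-memory inputs for one run (load from disk with ``from_dir``)."""

    samples: list[SampleMeta]
    genome: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatElement] = field(default_factory=list)
    tar_intervals: list[GenomicInterval] = field(default_factory=list)
    known_mirnas: list[str] = field(default_factory=list)
    read_sets: Optional[dict] = None
    count_matrix: Optional[CountMatrix] = None
    ago_peaks: dict = field(default_factory=dict)
    ago_reads: dict = field(default_factory=dict)
    chimeras: list[ClashChimera] = field(default_factory=list)
    perturbations: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    source: str = "memory"

    @classmethod
    def from_bundle(cls, bundle) -> "PipelineInputs":
        ref = bundle.truth.reference
        return cls(
            samples=bundle.samples,
            genome=ref.genome_str(),
            genes=ref.genes,
            repeats=ref.repeats,
            tar_intervals=ref.tar_intervals,
            known_mirnas=[seq for _id, seq in ref.known_mirnas],
            read_sets=bundle.read_sets,
            count_matrix=bundle.count_matrix,
            ago_peaks=bundle.ago_peaks,
            ago_reads=bundle.ago_reads,
            chimeras=bundle.chimeras,
            perturbations=bundle.perturbations,
            expression=bundle.expression,
            source="bundle",
        )

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PipelineInputs":
        """Load the on-disk bundle layout written by ``simulate.write_bundle``."""
        indir = Path(indir)

        def need(name: str) -> Path:
            path = indir / name
            if not path.exists():
                raise FileNotFoundError(f"required input {name} missing from {indir}")
            return path

        genome = rio.read_genome(need("genome.fa"))
        genes, repeats, _ = rio.read_models(need("models.gff3"))
        rio.attach_spliced_sequences(genes, genome)
        tar = []
        if (indir / "tar.bed").exists():
            tar = [iv for iv, _ in rio.read_bed(indir / "tar.bed")]
        samples = rio.read_samples(need("samples.tsv"))
        read_sets = None
        if (indir / "reads").is_dir():
            read_sets = {
                s.sample_id: [seq for _id, seq in rio.read_sequences(indir / "reads" / f"{s.sample_id}.fa")]
                for s in samples
            }
        cm = None
        if (indir / "counts.tsv").exists():
            rpm_path = indir / "rpm.tsv" if (indir / "rpm.tsv").exists() else None
            cm = rio.read_count_matrix(indir / "counts.tsv", indir / "samples.tsv", rpm_path)
        known = [seq for _id, seq in rio.read_sequences(need("known_mirnas.fa"))]
        ago_peaks, ago_reads = {}, {}
        for protein in targeting.AGO_PROTEINS:
            peak_path = indir / f"peaks_{protein}.bed"
            if peak_path.exists():
                ago_peaks[protein] = [iv for iv, _ in rio.read_bed(peak_path)]
            reads_path = indir / f"clipreads_{protein}.fa"
            if reads_path.exists():
                ago_reads[protein] = Counter(seq for _id, seq in rio.read_sequences(reads_path))
        chimeras = []
        if (indir / "chimeras.tsv").exists():
            chimeras = rio.read_chimeras(indir / "chimeras.tsv")
        perturbations = {}
        if (indir / "perturb").is_dir():
            for path in sorted((indir / "perturb").glob("*.fa")):
                perturbations[path.stem] = Counter(
                    seq for _id, seq in rio.read_sequences(path)
                )
        expression = {}
        for layer in ("rnaseq", "microarray", "protein"):
            path = indir / f"expr_{layer}.tsv"
            if path.exists():
                expression[layer] = rio.read_expression(path)
        return cls(
            samples=samples,
            genome=genome,
            genes=genes,
            repeats=repeats,
            tar_intervals=tar,
            known_mirnas=known,
            read_sets=read_sets,
            count_matrix=cm,
            ago_peaks=ago_peaks,
            ago_reads=ago_reads,
            chimeras=chimeras,
            perturbations=perturbations,
            expression=expression,
            source=str(indir),
        )


@dataclass
class PipelineResult:
    records: list[RsRNARecord]
    table: pd.DataFrame
    stage_counts: dict
    spectrum: pd.DataFrame
    manifest: dict
    count_matrix: CountMatrix
    sites: list
    annotation_calls: list[AnnotationCall]
    de_calls: list
    anticorr: dict


def _hairpin_window(
    hit: AlignmentHit, genome: Mapping[str, str], flank: int
) -> Optional[tuple[str, tuple[int, int]]]:
    """Extract the +/- flank window around a locus, oriented along the read.

    Returns (window sequence, sRNA interval in window coordinates)."""
    iv = hit.interval
    chrom_seq = genome[iv.chrom]
    w0 = max(0, iv.start - flank)
    w1 = min(len(chrom_seq), iv.end + flank)
    window = chrom_seq[w0:w1]
    if iv.strand == "+":
        s0 = iv.start - w0
    else:
        window = revcomp(window)
        s0 = w1 - iv.end
    return window, (s0, s0 + len(iv))


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Execute the full cascade and integrate per-candidate records."""
    config.validate()
    stage_counts: dict[str, int] = {}

    # --- catalog ----------------------------------------------------------
    if inputs.count_matrix is not None:
        cm_all = inputs.count_matrix
        if cm_all.rpm is None:
            cm_all = catalog.rpm_normalize(cm_all)
    elif inputs.read_sets is not None:
        cm_all = catalog.collapse_reads(inputs.read_sets, inputs.samples)
    else:
        raise ValueError("stage catalog: neither read sets nor a count matrix supplied")
    stage_counts["input_sequences"] = len(cm_all)
    if inputs.known_mirnas:
        cm_nomir, excluded = catalog.exclude_known_mirnas(
            cm_all, inputs.known_mirnas, config.known_mirna_max_mm
        )
    else:
        cm_nomir, excluded = cm_all, []
    stage_counts["after_known_mirna_exclusion"] = len(cm_nomir)
    cm_kept, diagnostics = catalog.apply_presence_filters(
        cm_nomir, config.min_reads, config.min_conditions
    )
    # RPM refers to the full sequenced library, not the filtered survivors
    cm_kept = catalog.rpm_normalize(cm_kept, cm_all.counts.sum(axis=0))
    stage_counts["after_presence_filters"] = len(cm_kept)

    survivors = cm_kept.sequences
    seq_to_id = {seq: f"sRNA-{i + 1:06d}" for i, seq in enumerate(sorted(survivors))}
    id_to_seq = {v: k for k, v in seq_to_id.items()}

    # --- alignment (all loci) --------------------------------------------
    aln = catalog.align_short_reads(
        survivors, inputs.genome, config.max_genome_mismatches, report_all=True
    )
    hits_by_seq: dict[str, list[AlignmentHit]] = {}
    for hit in aln.hits:
        hits_by_seq.setdefault(hit.seq, []).append(hit)
    hits_by_id = {seq_to_id[seq]: hits for seq, hits in hits_by_seq.items()}

    # --- targeting --------------------------------------------------------
    coding = [g for g in inputs.genes if g.biotype == "protein_coding"]
    genes_by_id = {g.gene_id: g for g in inputs.genes}
    all_consensus = []
    for seq in survivors:
        sid = seq_to_id[seq]
        seed = targeting.predict_seed_sites(sid, seq, coding, config.scan_regions)
        duplex = targeting.predict_duplex_sites(
            sid, seq, coding, config.max_duplex_mismatches,
            config.scan_regions, config.wobble_allowance,
        )
        all_consensus.extend(targeting.consensus_sites(seed, duplex, genes_by_id))
    stage_counts["consensus_sites"] = len(all_consensus)
    srna_seqs_by_id = {seq_to_id[s]: s for s in survivors}

    # --- interaction validation ------------------------------------------
    if inputs.ago_peaks:
        targeting.clip_support(
            all_consensus, inputs.ago_peaks, inputs.ago_reads, srna_seqs_by_id,
            require_read=config.clip_require_read,
        )
    if inputs.chimeras:
        targeting.clash_support(
            all_consensus, inputs.chimeras, srna_seqs_by_id,
            config.clash_slop_nt, config.clash_srna_max_mm,
        )
    targeting.detect_antisense_origin(all_consensus, hits_by_id, genes_by_id)

    # --- differential expression -----------------------------------------
    de_calls, de_summary = stats.fold_change_flags(
        cm_kept, config.fold_change_min, config.pseudocount
    )

    # --- biogenesis -------------------------------------------------------
    # hairpin/motif analysis is run for the Microprocessor-dependent subset
    # only, mirroring the workflow (the structural question is whether those
    # candidates sit in a canonical pri-miRNA context)
    min_window = 2 * config.min_stem_pairs + config.min_loop_nt
    profiles: dict[str, object] = {}
    for seq in survivors:
        sid = seq_to_id[seq]
        profile = biogenesis.build_profile(sid, seq, inputs.perturbations, None, None, config)
        hits = hits_by_seq.get(seq)
        if profile.dgcr8_dependent == "dependent" and hits:
            best_mm = min(h.mismatches for h in hits)
            best = next(h for h in hits if h.mismatches == best_mm)
            extracted = _hairpin_window(best, inputs.genome, config.flank_bp)
            if extracted and len(extracted[0]) >= min_window:
                profile = biogenesis.build_profile(
                    sid, seq, inputs.perturbations, extracted[0], extracted[1], config
                )
        profiles[sid] = profile

    # --- anti-correlation -------------------------------------------------
    pair_set = sorted({site.key for site in all_consensus})
    srna_rpm = cm_kept.rpm.rename(index=seq_to_id)
    anticorr: dict[str, pd.DataFrame] = {}
    for layer, matrix in inputs.expression.items():
        shared = set(srna_rpm.columns) & set(matrix.columns)
        if len(shared) < 3:
            log.warning("expression layer %s shares <3 samples; skipped", layer)
            continue
        anticorr[layer] = stats.anticorrelation_screen(
            srna_rpm, matrix, pair_set, config.pcc_max, config.p_max,
            config.log_transform_correlations,
        )

    # --- annotation -------------------------------------------------------
    genome_lengths = {c: len(s) for c, s in inputs.genome.items()}
    calls = annotate.classify_loci(
        aln.hits, inputs.genes, inputs.repeats, seq_to_id, genome_lengths
    )
    calls_by_id = {c.srna_id: c for c in calls}
    if inputs.tar_intervals:
        annotate.tar_overlap(calls, inputs.tar_intervals)

    # --- integrate --------------------------------------------------------
    sites_by_id: dict[str, list] = {}
    for site in all_consensus:
        sites_by_id.setdefault(site.srna_id, []).append(site)
    known_set = set(inputs.known_mirnas)
    records = []
    for seq in cm_all.sequences:
        rec = RsRNARecord(srna_id=seq_to_id.get(seq, ""), sequence=seq)
        if seq in known_set:
            rec.known_mirna = True
            rec.status = "rejected:known_mirna"
            records.append(rec)
            continue
        diag = diagnostics.loc[seq]
        rec.abundance_ok = bool(diag["abundance_ok"])
        rec.recurrence_ok = bool(diag["recurrence_ok"])
        rec.n_conditions_present = int(diag["n_conditions_present"])
        if not rec.abundance_ok:
            rec.status = "rejected:abundance"
            records.append(rec)
            continue
        if not rec.recurrence_ok:
            rec.status = "rejected:recurrence"
            records.append(rec)
            continue
        sid = seq_to_id[seq]
        sites = sites_by_id.get(sid, [])
        rec.consensus_targets = len({s.gene_id for s in sites})
        for protein in targeting.AGO_PROTEINS:
            rec.ago[protein] = any(s.ago.get(protein, False) for s in sites)
        rec.clash = any(s.clash for s in sites)
        rec.antisense = any(s.antisense for s in sites)
        rec.de_flag = bool(de_summary.loc[seq, "de_flag"])
        rec.de_conditions_up_tumor = int(de_summary.loc[seq, "up_in_tumor"])
        rec.de_conditions_up_normal = int(de_summary.loc[seq, "up_in_normal"])
        rec.biogenesis = profiles.get(sid)
        for layer, table in anticorr.items():
            sub = table[(table["srna_id"] == sid) & table["passed"]]
            rec.anticorr_hits[layer] = int(len(sub))
        rec.annotation = calls_by_id.get(sid)
        if rec.consensus_targets == 0:
            rec.status = "rejected:no_target"
        elif not rec.any_interaction():
            rec.status = "rejected:no_interaction"
        elif not rec.de_flag:
            rec.status = "rejected:not_de"
        else:
            rec.status = "potential_rsRNA"
        records.append(rec)
    stage_counts["with_consensus_target"] = sum(
        1 for r in records if r.consensus_targets > 0
    )
    stage_counts["with_interaction_support"] = sum(
        1 for r in records if r.consensus_targets > 0 and r.any_interaction()
    )
    stage_counts["potential_rsRNA"] = sum(1 for r in records if r.status == "potential_rsRNA")

    assoc = {
        r.sequence: (r.any_interaction() if r.consensus_targets else False) for r in records
    }
    spectrum = recurrence_spectrum_report(cm_all, assoc)
    table = records_table(records)
    manifest = {
        "config": dataclasses.asdict(config),
        "input_source": inputs.source,
        "n_samples": len(inputs.samples),
        "stage_counts": stage_counts,
        "input_digest": _digest(cm_all),
    }
    return PipelineResult(
        records=records,
        table=table,
        stage_counts=stage_counts,
        spectrum=spectrum,
        manifest=manifest,
        count_matrix=cm_kept,
        sites=all_consensus,
        annotation_calls=calls,
        de_calls=de_calls,
        anticorr=anticorr,
    )


def _digest(cm: CountMatrix) -> str:
    h = hashlib.sha256()
    h.update("|".join(cm.sequences).encode())
    h.update(cm.counts.to_numpy().tobytes())
    return h.hexdigest()[:16]


def recurrence_spectrum_report(
    cm: CountMatrix, interaction_flags: Mapping[str, bool]
) -> pd.DataFrame:
    """Number of sRNAs present in >= k conditions, split by interaction
    association (presence in a condition = count >= 1)."""
    cond_cols = cm.condition_columns()
    presence = pd.DataFrame(
        {cond: (cm.counts[cols].sum(axis=1) > 0) for cond, cols in cond_cols.items()}
    )
    n_present = presence.sum(axis=1)
    rows = []
    for k in range(1, len(cond_cols) + 1):
        seqs = n_present[n_present >= k].index
        n = len(seqs)
        n_assoc = sum(1 for s in seqs if interaction_flags.get(s, False))
        rows.append(
            (
                k,
                n,
                n_assoc / n if n else np.nan,
                (n - n_assoc) / n if n else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["k", "n_srnas", "fraction_associated", "fraction_unassociated"]
    )


def records_table(records: Sequence[RsRNARecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        bio = r.biogenesis
        ann = r.annotation
        rows.append(
            {
                "srna_id": r.srna_id,
                "sequence": r.sequence,
                "status": r.status,
                "known_mirna": r.known_mirna,
                "abundance_ok": r.abundance_ok,
                "recurrence_ok": r.recurrence_ok,
                "n_conditions_present": r.n_conditions_present,
                "consensus_targets": r.consensus_targets,
                "ago1": r.ago.get("AGO1", False),
                "ago2": r.ago.get("AGO2", False),
                "ago3": r.ago.get("AGO3", False),
                "ago4": r.ago.get("AGO4", False),
                "clash": r.clash,
                "antisense": r.antisense,
                "de_flag": r.de_flag,
                "de_up_tumor": r.de_conditions_up_tumor,
                "de_up_normal": r.de_conditions_up_normal,
                "dicer_dependent": bio.dicer_dependent if bio else None,
                "dgcr8_dependent": bio.dgcr8_dependent if bio else None,
                "drosha_dependent": bio.drosha_dependent if bio else None,
                "hairpin_found": bio.hairpin_found if bio else None,
                "in_stem": bio.in_stem if bio else None,
                "all_three_motifs": bio.all_three_motifs if bio else None,
                "anticorr_rnaseq": r.anticorr_hits.get("rnaseq", 0),
                "anticorr_microarray": r.anticorr_hits.get("microarray", 0),
                "anticorr_protein": r.anticorr_hits.get("protein", 0),
                "primary_class": ann.primary_class if ann else None,
                "class_set": ",".join(sorted(ann.class_set)) if ann else None,
                "tar_overlap": ann.tar_overlap if ann else None,
            }
        )
    return pd.DataFrame(rows)


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write the fixed-name outputs of a run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_table(out / "records.tsv", result.table)
    rio.write_table(out / "spectrum.tsv", result.spectrum)
    rio.write_count_matrix(
        result.count_matrix, out / "kept_counts.tsv", out / "kept_samples.tsv", out / "kept_rpm.tsv"
    )
    for layer, table in result.anticorr.items():
        rio.write_table(out / f"anticorr_{layer}.tsv", table)
    rio.write_json(out / "manifest.json", result.manifest)
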