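"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ via Biopython, GFF3 via gffutils, BED6 and TSV tables via
pandas. All coordinates are converted to the internal 0-based half-open
convention on ingest (GFF3 arrives 1-based inclusive, BED is already
half-open); sequences are uppercased with U normalized to T. The NA token
in every TSV is the literal string ``NA``. Real numbers are serialized
with 12 significant digits so that write -> read round-trips are lossless
at documented precision.

GFF3 attribute contract for repeats (type ``repeat_region``): ``family``,
``consensus_offset`` (lowest consensus coordinate the copy covers),
``consensus_length``, ``orientation``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ClashChimera,
    CountMatrix,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SampleMeta,
    normalize_seq,
    to_rna,
)

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.12g"


class ParseError(ValueError):
    """Malformed record in an input file."""


class SchemaError(ValueError):
    """A table is missing required columns."""


# ---------------------------------------------------------------------------
# sequences


def read_sequences(
    path: str | Path, fmt: Optional[str] = None, return_alphabet: bool = False
):
    """Read FASTA or FASTQ into a list of (id, sequence).

    Sequences are uppercased and U is normalized to T; the original
    alphabet is recorded and returned as ``"rna"``/``"dna"`` when
    ``return_alphabet`` is set. An empty file yields an empty list.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    fmt = fmt.lower()
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported sequence format {fmt!r}")
    records = []
    saw_u = False
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt), start=1):
            raw = str(rec.seq).upper()
            if not rec.id:
                raise ParseError(f"{path}: record {i} has an empty identifier")
            if not raw:
                raise ParseError(f"{path}: record {i} ({rec.id}) has an empty sequence")
            bad = set(raw) - set("ACGTUN")
            if bad:
                raise ParseError(
                    f"{path}: record {i} ({rec.id}) contains invalid symbols {sorted(bad)}"
                )
            saw_u = saw_u or ("U" in raw)
            records.append((rec.id, normalize_seq(raw)))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: malformed {fmt} record near record {len(records) + 1}: {exc}") from exc
    if return_alphabet:
        return records, ("rna" if saw_u else "dna")
    return records


def write_sequences(
    path: str | Path,
    records: Iterable[tuple[str, str]],
    fmt: str = "fasta",
    rna: bool = False,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            out = to_rna(seq) if rna else seq
            if fmt == "fasta":
                fh.write(f">{name}\n{out}\n")
            elif fmt == "fastq":
                fh.write(f"@{name}\n{out}\n+\n{'I' * len(out)}\n")
            else:
                raise ValueError(f"unsupported sequence format {fmt!r}")


def read_genome(path: str | Path) -> dict[str, str]:
    return dict(read_sequences(path, "fasta"))


# ---------------------------------------------------------------------------
# GFF3 / BED


def _gff_interval(feature, path) -> GenomicInterval:
    start = feature.start - 1          # GFF3 is 1-based inclusive
    end = feature.end
    if end <= start:
        raise ParseError(
            f"{path}: coordinate inversion in {feature.featuretype} "
            f"{feature.id or '?'} ({feature.start}..{feature.end})"
        )
    strand = feature.strand if feature.strand in ("+", "-") else "+"
    return GenomicInterval(feature.seqid, start, end, strand)


def read_models(
    gff_path: str | Path, bed_paths: Sequence[str | Path] = ()
) -> tuple[list[GeneModel], list[RepeatElement], list[GenomicInterval]]:
    """Read gene models and repeats from GFF3 plus plain intervals from BEDs."""
    gff_path = Path(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    repeats: list[RepeatElement] = []
    children: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_rows = []
    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype == "gene":
            gene_rows.append(feat)
        elif ftype == "repeat_region":
            iv = _gff_interval(feat, gff_path)
            try:
                family = feat.attributes["family"][0]
                offset = int(feat.attributes["consensus_offset"][0])
                length = int(feat.attributes["consensus_length"][0])
            except (KeyError, IndexError, ValueError) as exc:
                raise ParseError(
                    f"{gff_path}: repeat_region {feat.id or '?'} lacks "
                    "family/consensus_offset/consensus_length attributes"
                ) from exc
            orientation = feat.attributes.get("orientation", ["+"])[0]
            repeats.append(RepeatElement(iv, family, offset, length, orientation))
        elif ftype in {"exon", "five_prime_UTR", "CDS", "three_prime_UTR"}:
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise ParseError(f"{gff_path}: {ftype} without Parent attribute")
            iv = _gff_interval(feat, gff_path)
            children.setdefault(parents[0], {}).setdefault(ftype, []).append(iv)
    for feat in gene_rows:
        iv = _gff_interval(feat, gff_path)
        gid = feat.id or feat.attributes.get("ID", ["?"])[0]
        sub = children.get(gid, {})
        biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=iv,
                exons=sub.get("exon", [iv]),
                biotype=biotype,
                five_utr=sorted(sub.get("five_prime_UTR", [])),
                cds=sorted(sub.get("CDS", [])),
                three_utr=sorted(sub.get("three_prime_UTR", [])),
            )
        )
    intervals: list[GenomicInterval] = []
    for bed in bed_paths:
        intervals.extend(iv for iv, _name in read_bed(bed))
    return genes, repeats, intervals


def write_gff3(
    path: str | Path,
    genes: Sequence[GeneModel] = (),
    repeats: Sequence[RepeatElement] = (),
) -> None:
    lines = ["##gff-version 3"]

    def row(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return "\t".join(
            [iv.chrom, "rsrna", ftype, str(iv.start + 1), str(iv.end), ".", iv.strand, ".", attrs]
        )

    for gene in genes:
        lines.append(row(gene.interval, "gene", f"ID={gene.gene_id};biotype={gene.biotype}"))
        for ex in gene.exons:
            lines.append(row(ex, "exon", f"Parent={gene.gene_id}"))
        for name, parts in (
            ("five_prime_UTR", gene.five_utr),
            ("CDS", gene.cds),
            ("three_prime_UTR", gene.three_utr),
        ):
            for iv in parts:
                lines.append(row(iv, name, f"Parent={gene.gene_id}"))
    for i, rep in enumerate(repeats):
        attrs = (
            f"ID=repeat{i};family={rep.family};consensus_offset={rep.consensus_offset};"
            f"consensus_length={rep.consensus_length};orientation={rep.orientation}"
        )
        lines.append(row(rep.interval, "repeat_region", attrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED6 (or BED3) into (interval, name) pairs."""
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 fields")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ParseError(f"{path}:{lineno}: coordinate inversion {start}..{end}")
        name = parts[3] if len(parts) > 3 else f"feature{lineno}"
        strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
        out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(path: str | Path, records: Iterable[tuple[GenomicInterval, str]]) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# tables


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """TSV with a header row; validates required columns; NA token is 'NA'."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FORMAT, index=index)


def write_samples(path: str | Path, samples: Sequence[SampleMeta]) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.condition_id, s.state, s.assay) for s in samples],
        columns=["sample_id", "condition_id", "state", "assay"],
    )
    write_table(path, df)


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = read_table(path, required=["sample_id", "condition_id", "state", "assay"])
    return [
        SampleMeta(str(r.sample_id), str(r.condition_id), str(r.state), str(r.assay))
        for r in df.itertuples()
    ]


def write_count_matrix(
    cm: CountMatrix,
    counts_path: str | Path,
    samples_path: str | Path,
    rpm_path: Optional[str | Path] = None,
) -> None:
    out = cm.counts.copy()
    out.insert(0, "sequence", out.index)
    write_table(counts_path, out)
    write_samples(samples_path, cm.samples)
    if rpm_path is not None and cm.rpm is not None:
        rout = cm.rpm.copy()
        rout.insert(0, "sequence", rout.index)
        write_table(rpm_path, rout)


def read_count_matrix(
    counts_path: str | Path,
    samples_path: str | Path,
    rpm_path: Optional[str | Path] = None,
) -> CountMatrix:
    samples = read_samples(samples_path)
    df = read_table(counts_path, required=["sequence"])
    df = df.set_index("sequence")
    df.index = df.index.map(normalize_seq)
    df.index.name = "sequence"
    missing = [s.sample_id for s in samples if s.sample_id not in df.columns]
    if missing:
        raise SchemaError(f"{counts_path}: missing sample columns {missing}")
    counts = df[[s.sample_id for s in samples]].astype(np.int64)
    rpm = None
    if rpm_path is not None:
        rdf = read_table(rpm_path, required=["sequence"]).set_index("sequence")
        rdf.index = rdf.index.map(normalize_seq)
        rpm = rdf[[s.sample_id for s in samples]].astype(float)
    return CountMatrix(counts, samples, rpm)


def write_expression(path: str | Path, matrix: pd.DataFrame, id_column: str = "gene_id") -> None:
    if (matrix.select_dtypes(include=[np.number]) < 0).any().any():
        raise ValueError("negative abundance values in expression matrix")
    out = matrix.copy()
    out.insert(0, id_column, out.index)
    write_table(path, out)


def read_expression(path: str | Path, id_column: str = "gene_id") -> pd.DataFrame:
    df = read_table(path, required=[id_column]).set_index(id_column)
    return df.astype(float)


def write_ct_table(path: str | Path, ct: pd.DataFrame) -> None:
    out = ct.copy()
    out.insert(0, "entity", out.index)
    write_table(path, out)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=["entity"]).set_index("entity")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: Ct table needs at least 2 sample columns")
    return df.astype(float)


def write_chimeras(path: str | Path, chimeras: Iterable[ClashChimera]) -> None:
    rows = [
        (
            c.read_id,
            c.srna_segment,
            c.fragment.chrom,
            c.fragment.start,
            c.fragment.end,
            c.fragment.strand,
            c.gene_id if c.gene_id is not None else NA_TOKEN,
        )
        for c in chimeras
    ]
    df = pd.DataFrame(
        rows,
        columns=["read_id", "srna_seq", "target_chrom", "target_start", "target_end", "target_strand", "gene_id"],
    )
    write_table(path, df)


def read_chimeras(path: str | Path) -> list[ClashChimera]:
    df = read_table(
        path,
        required=["read_id", "srna_seq", "target_chrom", "target_start", "target_end", "target_strand"],
    )
    out = []
    for r in df.itertuples():
        frag = GenomicInterval(
            str(r.target_chrom), int(r.target_start), int(r.target_end), str(r.target_strand)
        )
        gene = None
        if "gene_id" in df.columns and pd.notna(r.gene_id):
            gene = str(r.gene_id)
        out.append(ClashChimera(str(r.read_id), normalize_seq(str(r.srna_seq)), frag, gene))
    return out


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def attach_spliced_sequences(genes: Sequence[GeneModel], genome: dict[str, str]) -> None:
    """Fill ``spliced_seq`` for each gene from the genome (strand-aware)."""
    from .datamodel import revcomp

    for gene in genes:
        parts = [genome[ex.chrom][ex.start:ex.end] for ex in gene.exons]
        seq = "".join(parts)
        gene.spliced_seq = seq if gene.strand == "+" else revcomp(seq)
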