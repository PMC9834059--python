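"""File-format readers and writers: SAM/BAM, FASTA/FASTQ, GTF, BED, TSV,
and an HDF5 signal container.

Orientation convention: :class:`~tailcap.models.AlignmentRecord` stores the
read in cDNA orientation (adapter/tail first).  SAM stores reverse-strand
alignments reference-forward, so sequences and soft-clip lengths are
flipped on the way in and out; round-tripping a record through SAM is
lossless.  Tails in TSV outputs are written RNA-sense.  All coordinates
are 0-based half-open internally; SAM (1-based) and GTF (1-based closed)
are converted at the boundary; BED is native.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignmentRecord,
    AnnotationBundle,
    Squiggle,
    TranscriptAnnotation,
    revcomp,
)

logger = logging.getLogger(__name__)


# --- FASTA / FASTQ ---------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Name -> sequence mapping from a FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(name, sequence, quality-string) triples; validates lengths per record."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                (
                    rec.id,
                    str(rec.seq).upper(),
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ: {exc}") from exc
    return out


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {name!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# --- SAM / BAM -------------------------------------------------------------


def write_sam(
    alignments: list[AlignmentRecord],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write alignments as SAM (or BAM when the path ends in .bam).

    Records are stored reference-forward per the SAM convention: for
    reverse-strand alignments the cDNA-orientation sequence is
    reverse-complemented and the soft-clip lengths swap ends.  The
    simulator's alignments are gapless, so the CIGAR is clip/M/clip.
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            if not aln.mapped:
                a.is_unmapped = True
                a.query_sequence = aln.read_sequence
                fh.write(a)
                continue
            if aln.contig not in tid:
                raise ValueError(
                    f"{aln.read_id}: contig {aln.contig!r} absent from header"
                )
            span = aln.ref_end - aln.ref_start
            if aln.strand == "-":
                a.is_reverse = True
                a.query_sequence = revcomp(aln.read_sequence)
                cigar = [(4, aln.clip_end), (0, span), (4, aln.clip_start)]
            else:
                a.query_sequence = aln.read_sequence
                cigar = [(4, aln.clip_start), (0, span), (4, aln.clip_end)]
            a.cigar = [(op, ln) for op, ln in cigar if ln > 0]
            a.reference_id = tid[aln.contig]
            a.reference_start = aln.ref_start
            a.mapping_quality = 60
            fh.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read SAM/BAM into cDNA-orientation alignment records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                out.append(
                    AlignmentRecord(
                        read_id=a.query_name,
                        contig="*",
                        strand="+",
                        ref_start=0,
                        ref_end=1,
                        clip_start=0,
                        clip_end=0,
                        read_sequence=a.query_sequence or "",
                        mapped=False,
                    )
                )
                continue
            cigar = a.cigartuples or []
            left_clip = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
            right_clip = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
            seq = a.query_sequence or ""
            if a.is_reverse:
                seq = revcomp(seq)
                clip_start, clip_end = right_clip, left_clip
                strand = "-"
            else:
                clip_start, clip_end = left_clip, right_clip
                strand = "+"
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    strand=strand,
                    ref_start=a.reference_start,
                    ref_end=a.reference_end,
                    clip_start=clip_start,
                    clip_end=clip_end,
                    read_sequence=seq,
                    mapped=True,
                )
            )
    return out


# --- GTF -------------------------------------------------------------------


def write_gtf(annotation: AnnotationBundle, path: str | Path) -> None:
    """Minimal GTF: one exon feature per exon, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in annotation.transcripts:
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.contig}\ttailcap\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    raise ValueError(f"GTF attribute {key!r} missing in: {attrs!r}")


def read_gtf(path: str | Path, contigs: dict[str, str] | None = None) -> AnnotationBundle:
    """Parse exon features from a GTF into transcripts.

    Exons listed out of order are sorted with a logged warning; malformed
    lines raise with the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            tid = _gtf_attr(attrs, "transcript_id")
            gid = _gtf_attr(attrs, "gene_id")
            try:
                biotype = _gtf_attr(attrs, "gene_biotype")
            except ValueError:
                biotype = "protein_coding"
            if tid not in raw:
                raw[tid] = {
                    "gene_id": gid,
                    "contig": contig,
                    "strand": strand,
                    "biotype": biotype,
                    "exons": [],
                }
                order.append(tid)
            raw[tid]["exons"].append((s, e))
    transcripts = []
    for tid in order:
        rec = raw[tid]
        exons = rec["exons"]
        if exons != sorted(exons):
            logger.warning("transcript %s: exons out of order; sorted", tid)
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                contig=rec["contig"],
                strand=rec["strand"],
                exons=exons,
                biotype=rec["biotype"],
            )
        )
    return AnnotationBundle(transcripts=transcripts, contigs=contigs or {})


# --- BED -------------------------------------------------------------------


def write_three_prime_bed(alignments: list[AlignmentRecord], path: str | Path) -> None:
    """One BED line per mapped read marking its RNA 3'-end coordinate."""
    with open(path, "w") as fh:
        for aln in alignments:
            if not aln.mapped:
                continue
            end = aln.rna_three_prime_end
            fh.write(
                f"{aln.contig}\t{end}\t{end + 1}\t{aln.read_id}\t0\t"
                f"{aln.gene_strand}\n"
            )


# --- TSV with metadata headers ---------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Tab-separated table with ``# key: value`` metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                metadata[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, metadata


# --- signal container -------------------------------------------------------


def write_signals(squiggles: list[Squiggle], path: str | Path) -> None:
    """HDF5 container: one group per read with samples + metadata."""
    with h5py.File(path, "w") as fh:
        for sq in squiggles:
            if sq.read_id in fh:
                raise ValueError(f"duplicate read_id {sq.read_id!r}")
            grp = fh.create_group(sq.read_id)
            grp.create_dataset("samples", data=np.asarray(sq.samples, np.float32))
            grp.attrs["sampling_rate"] = float(sq.sampling_rate)
            grp.attrs["basecalled_length"] = int(sq.basecalled_length)


def read_signals(path: str | Path) -> list[Squiggle]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with h5py.File(path, "r") as fh:
        for read_id in fh:
            grp = fh[read_id]
            out.append(
                Squiggle(
                    read_id=read_id,
                    samples=np.asarray(grp["samples"], dtype=np.float64),
                    sampling_rate=float(grp.attrs["sampling_rate"]),
                    basecalled_length=int(grp.attrs["basecalled_length"]),
                )
            )
    return out
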