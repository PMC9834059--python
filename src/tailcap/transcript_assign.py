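"""3'-end read filtering, isoform assignment and RPM quantification.

The library chemistry captures each RNA from its 3' end, so a read's
alignment boundary on the transcript 3' side is a direct measurement of
where that molecule ended.  Reads whose 3' end does not fall near any
annotated exon end are internal degradation products and are filtered out;
reads near an annotated transcript end are assigned to the isoform whose
end they match within a +/-10 nt window (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AlignmentRecord, AnnotationBundle, TranscriptAnnotation

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10


@dataclass
class AssignmentResult:
    """Outcome of matching one read's 3' end against candidate isoforms.

    ``status`` is one of assigned / unassigned / ambiguous; ``distance`` is
    the signed offset (read 3' end minus annotated end, in transcript
    orientation: positive = read extends past the annotated end).
    """

    read_id: str
    transcript_id: str | None
    distance: int | None
    window: int
    status: str

    def __post_init__(self) -> None:
        if self.status == "assigned" and abs(self.distance) > self.window:
            raise ValueError(
                f"{self.read_id}: assigned at distance {self.distance} outside "
                f"window {self.window}"
            )


@dataclass
class ExpressionTable:
    """Per-gene counts and reads-per-million, with library size."""

    table: pd.DataFrame  # gene_id, biotype, count, rpm
    library_size: int


def _signed_distance(read_end: int, annot_end: int, strand: str) -> int:
    """Signed read-vs-annotation 3'-end offset in transcript orientation."""
    d = read_end - annot_end
    return d if strand == "+" else -d


def filter_complete_reads(
    alignments: list[AlignmentRecord],
    annotation: AnnotationBundle,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Keep reads whose 3' end lies within ``window`` nt of any exon end.

    The read 3' end is strand-resolved (the cDNA read start corresponds to
    the RNA 3' end) and compared against the exon ends of genes on the
    matching strand.  Returns the kept alignments plus a rejects table
    with a per-read reason; reads on unknown contigs are dropped with a
    logged warning.
    """
    index = annotation.exon_end_index()
    known_contigs = {c for c, _ in index}
    kept: list[AlignmentRecord] = []
    rejects: list[dict] = []
    for aln in alignments:
        if not aln.mapped:
            rejects.append({"read_id": aln.read_id, "reason": "unmapped"})
            continue
        key = (aln.contig, aln.gene_strand)
        if aln.contig not in known_contigs:
            logger.warning(
                "read %s on unknown contig %s; dropped", aln.read_id, aln.contig
            )
            rejects.append({"read_id": aln.read_id, "reason": "unknown_contig"})
            continue
        ends = index.get(key)
        if ends is None or len(ends) == 0:
            rejects.append({"read_id": aln.read_id, "reason": "no_exon_end_on_strand"})
            continue
        end = aln.rna_three_prime_end
        i = int(np.searchsorted(ends, end))
        near = min(
            abs(end - ends[j]) for j in (i - 1, i) if 0 <= j < len(ends)
        )
        if near <= window:
            kept.append(aln)
        else:
            rejects.append(
                {"read_id": aln.read_id, "reason": "three_prime_end_internal"}
            )
    return kept, pd.DataFrame(rejects, columns=["read_id", "reason"])


def assign_to_isoform(
    read: AlignmentRecord,
    candidates: list[TranscriptAnnotation],
    window: int = DEFAULT_WINDOW,
) -> AssignmentResult:
    """Assign a read to the isoform whose annotated 3' end is nearest.

    The minimizing candidate is assigned if its absolute distance is at
    most ``window`` (inclusive); a tie between distinct transcripts at the
    minimal distance yields an ambiguous result; no candidate within the
    window yields unassigned.
    """
    eligible = [
        c
        for c in candidates
        if c.contig == read.contig and c.strand == read.gene_strand
    ]
    if not eligible:
        return AssignmentResult(read.read_id, None, None, window, "unassigned")
    end = read.rna_three_prime_end
    dists = [
        (_signed_distance(end, c.three_prime_end, c.strand), c) for c in eligible
    ]
    best = min(abs(d) for d, _ in dists)
    if best > window:
        return AssignmentResult(read.read_id, None, None, window, "unassigned")
    winners = [(d, c) for d, c in dists if abs(d) == best]
    if len({c.transcript_id for _, c in winners}) > 1:
        return AssignmentResult(read.read_id, None, None, window, "ambiguous")
    d, c = winners[0]
    return AssignmentResult(read.read_id, c.transcript_id, int(d), window, "assigned")


def assign_all(
    alignments: list[AlignmentRecord],
    annotation: AnnotationBundle,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Assign every alignment; returns a table with gene_id filled in.

    Candidates for each read are all annotated transcripts on its contig
    and gene strand; a read whose nearest ends belong to two different
    genes at equal distance is ambiguous, never double-counted.
    """
    by_key: dict[tuple[str, str], list[TranscriptAnnotation]] = {}
    for t in annotation.transcripts:
        by_key.setdefault((t.contig, t.strand), []).append(t)
    gene_by_tid = {t.transcript_id: t.gene_id for t in annotation.transcripts}
    rows = []
    for aln in alignments:
        res = assign_to_isoform(
            aln, by_key.get((aln.contig, aln.gene_strand), []), window
        )
        rows.append(
            {
                "read_id": res.read_id,
                "transcript_id": res.transcript_id or "",
                "gene_id": gene_by_tid.get(res.transcript_id, ""),
                "distance": res.distance if res.distance is not None else np.nan,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def quantify_rpm(
    assignments: pd.DataFrame, annotation: AnnotationBundle
) -> ExpressionTable:
    """Per-gene read counts and reads-per-million over assigned reads.

    RPM = count * 1e6 / total assigned reads, so RPM sums to 1e6 across
    counted genes.  Biotype is carried from the annotation (first
    transcript of each gene) for breakdown tables.
    """
    assigned = assignments[assignments["status"] == "assigned"]
    total = len(assigned)
    if total == 0:
        raise ValueError("no assigned reads to quantify")
    counts = assigned.groupby("gene_id").size()
    biotype = {
        g: ts[0].biotype for g, ts in annotation.genes.items()
    }
    table = pd.DataFrame(
        {
            "gene_id": counts.index,
            "biotype": [biotype.get(g, "unknown") for g in counts.index],
            "count": counts.values,
            "rpm": counts.values * 1e6 / total,
        }
    ).reset_index(drop=True)
    return ExpressionTable(table=table, library_size=total)
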