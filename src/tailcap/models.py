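"""Shared domain types for 3'-end-capture cDNA tail analysis.

The library chemistry reads each RNA from its 3' end: reverse transcription
is template-switch initiated, so every cDNA read begins with a known DNA
adapter, followed by the tail (poly(T) in cDNA sense) and then the insert.
Types here are the common currency between the simulator, the signal-level
tail caller, and the alignment-based modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def cdna_to_rna_tail(cdna_tail: str) -> str:
    """Convert a cDNA-sense tail to RNA sense (5'->3', terminal bases last).

    The cDNA read runs 3'->5' relative to the RNA, so the RNA-sense tail is
    the reverse complement with T written as U.
    """
    return revcomp(cdna_tail).replace("T", "U")


def rna_tail_to_cdna(rna_tail: str) -> str:
    """Inverse of :func:`cdna_to_rna_tail`."""
    return revcomp(rna_tail.replace("U", "T"))


@dataclass
class Squiggle:
    """One read's raw current trace plus sampling metadata."""

    read_id: str
    samples: np.ndarray
    sampling_rate: float = 4000.0
    basecalled_length: int = 0

    @property
    def sample_count(self) -> int:
        return int(len(self.samples))


@dataclass
class AlignmentRecord:
    """Minimal alignment for 3'-end assignment and pileup profiling.

    ``read_sequence`` is stored in cDNA orientation (the orientation in which
    the molecule traversed the pore): adapter remnant and tail first, insert
    last.  ``clip_start``/``clip_end`` are soft-clip lengths at the cDNA
    start/end.  ``strand`` is the alignment orientation on the reference
    ('+' forward, '-' reverse); a cDNA read of a forward-strand transcript
    aligns on the reverse strand.
    """

    read_id: str
    contig: str
    strand: str
    ref_start: int
    ref_end: int
    clip_start: int
    clip_end: int
    read_sequence: str
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"{self.read_id}: empty reference span")
        if self.clip_start < 0 or self.clip_end < 0:
            raise ValueError(f"{self.read_id}: negative soft-clip length")

    @property
    def rna_three_prime_end(self) -> int:
        """Genomic coordinate of the RNA 3' end captured by this read.

        The cDNA read starts at the RNA 3' end, so for a reverse-strand
        alignment the 3' end is the rightmost reference coordinate
        (half-open end), and for a forward-strand alignment the leftmost.
        """
        return self.ref_end if self.strand == "-" else self.ref_start

    @property
    def gene_strand(self) -> str:
        """Strand of the transcript this read derives from."""
        return "+" if self.strand == "-" else "-"

    @property
    def tail_side_clip(self) -> str:
        """Soft-clipped bases on the tail side (cDNA start), cDNA sense."""
        return self.read_sequence[: self.clip_start]

    @property
    def aligned_sequence(self) -> str:
        """The mapped portion of the read, cDNA orientation."""
        end = len(self.read_sequence) - self.clip_end
        return self.read_sequence[self.clip_start : end]

    def aligned_on_reference(self) -> str:
        """Mapped bases laid out along the forward reference strand."""
        aligned = self.aligned_sequence
        return revcomp(aligned) if self.strand == "-" else aligned


@dataclass
class TranscriptAnnotation:
    """A transcript with exon structure; coordinates 0-based half-open."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' end.

        For '+' transcripts this is the half-open end of the last exon; for
        '-' transcripts the start of the first exon (both half-open style so
        a read 3' end exactly at the annotated end has distance zero).
        """
        return self.end if self.strand == "+" else self.start

    @property
    def exon_ends(self) -> list[int]:
        """Strand-appropriate 3'-side boundary of each exon."""
        if self.strand == "+":
            return [e for _, e in self.exons]
        return [s for s, _ in self.exons]


@dataclass
class AnnotationBundle:
    """Transcript annotation plus the reference sequences it refers to."""

    transcripts: list[TranscriptAnnotation]
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            # an empty bundle is legal input for the read filter
            pass

    @property
    def genes(self) -> dict[str, list[TranscriptAnnotation]]:
        out: dict[str, list[TranscriptAnnotation]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def gene_of(self, transcript_id: str) -> str:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t.gene_id
        raise KeyError(transcript_id)

    def exon_end_index(self) -> dict[tuple[str, str], np.ndarray]:
        """Sorted exon-end coordinates keyed by (contig, gene strand)."""
        ends: dict[tuple[str, str], set[int]] = {}
        for t in self.transcripts:
            key = (t.contig, t.strand)
            ends.setdefault(key, set()).update(t.exon_ends)
        return {k: np.array(sorted(v)) for k, v in ends.items()}
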