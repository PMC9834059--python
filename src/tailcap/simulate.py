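"""Synthetic squiggles, reads, alignments and annotation with known truth.

The simulator emulates the read layout produced by template-switching
3'-end-capture cDNA sequencing:

    [sequencing-adapter stub][DNA adapter, 31 nt][tail, T-rich in cDNA
    sense][insert]

At the signal level each base contributes one current segment whose mean is
looked up from a k-mer pore model, whose duration is drawn from a shifted
geometric dwell distribution (minimum 3 samples), and whose samples carry
Gaussian noise.  At the read level, alignments carry the tail as a soft
clip on the cDNA-start side, with optional adapter remnants and
substitution errors, and a 3'-end offset from the annotated transcript end.

A registry of the twelve synthetic cDNA standards used to benchmark tail
length and tail composition calling is included; their designed tails are
the ground truth for the exact-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    AlignmentRecord,
    AnnotationBundle,
    Squiggle,
    TranscriptAnnotation,
    cdna_to_rna_tail,
    revcomp,
    rna_tail_to_cdna,
)

#: Body of the duplex DNA adapter that template switching appends to every
#: cDNA 5' end (terminal randomized N excluded).  In base-called reads the
#: tail lies immediately 3' of this sequence.
ADAPTER_DNA = "CTTCCGATCACTTGCCTGTCGCTCTATCTTC"

#: RNA oligo annealed to the DNA adapter during template switching
#: (rG...rG with a 3' C3 spacer), stored here DNA-alphabet for reference.
ADAPTER_RNA_COMPLEMENT = "GAAGATAGAGCGACAGGCAAGTGATCGGAAG"

#: Current level (pA-like units) of the fixed sequencing-adapter stub that
#: precedes every simulated squiggle; deliberately outside the k-mer level
#: range so the adapter boundary is detectable without base-calling.
STUB_LEVEL = 40.0
STUB_SAMPLES = 200

# Per-base current contributions and position weights of the additive k-mer
# model.  Levels are composition-dominated with the central positions
# weighted most, which is what makes homopolymer stretches look like long
# low-variance segments (the property tail segmentation relies on).
_BASE_LEVEL = {"A": 118.0, "C": 86.0, "G": 72.0, "T": 100.0}
_POSITION_WEIGHTS = {
    4: (0.15, 0.35, 0.35, 0.15),
    5: (0.10, 0.15, 0.50, 0.15, 0.10),
    6: (0.05, 0.10, 0.35, 0.35, 0.10, 0.05),
}


@dataclass
class PoreModel:
    """k-mer -> (mean current, sd) lookup table."""

    k: int
    levels: dict[str, tuple[float, float]]

    def mean(self, kmer: str) -> float:
        return self.levels[kmer][0]

    def sd(self, kmer: str) -> float:
        return self.levels[kmer][1]

    def validate(self) -> None:
        expected = 4 ** self.k
        if len(self.levels) != expected:
            raise ValueError(f"pore model has {len(self.levels)} entries, expected {expected}")
        for kmer, (_, sd) in self.levels.items():
            if sd <= 0:
                raise ValueError(f"non-positive sd for {kmer}")
        homs = {self.mean(b * self.k) for b in "ACGT"}
        if len(homs) != 4:
            raise ValueError("homopolymer k-mers do not map to distinct levels")


@dataclass
class StandardRecord:
    """One synthetic cDNA standard: adapter + designed tail + insert."""

    name: str
    full_sequence: str
    adapter_prefix: str
    design_tail_length: int
    design_tail_composition: str
    series: str

    def __post_init__(self) -> None:
        if not self.full_sequence.startswith(self.adapter_prefix):
            raise ValueError(f"{self.name}: sequence does not begin with the adapter")
        a = len(self.adapter_prefix)
        t = len(self.design_tail_composition)
        if self.full_sequence[a : a + t] != self.design_tail_composition:
            raise ValueError(f"{self.name}: tail is not adjacent to the adapter")

    @property
    def tail_nt_span(self) -> tuple[int, int]:
        """Half-open base interval of the designed tail within the sequence."""
        a = len(self.adapter_prefix)
        return (a, a + len(self.design_tail_composition))

    @property
    def rna_tail(self) -> str:
        """Designed tail in RNA sense (terminal additions last)."""
        return cdna_to_rna_tail(self.design_tail_composition)

    @property
    def insert(self) -> str:
        return self.full_sequence[self.tail_nt_span[1] :]


@dataclass
class SquiggleTruth:
    """Ground truth accompanying one simulated squiggle."""

    read_id: str
    true_tail_nt: int
    tail_sample_span: tuple[int, int]
    adapter_sample_span: tuple[int, int]
    dwell_mean: float
    seed: int


# The twelve ultramer standards: six spanning designed tail lengths
# 0/15/30/60/90/120 nt and six probing tail composition (terminal U/C/G
# additions and internal G interruptions; tails written in cDNA sense).
_STANDARD_SEQUENCES: list[tuple[str, str]] = [
    ("cDNA_pA_standard_0",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATGAAAAATGCTTGTTTGCAACCCTATATAGAA"),
    ("cDNA_pA_standard_15",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATGAAAAATGCTTGTTTG"),
    ("cDNA_pA_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_pA_standard_60",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAG"),
    ("cDNA_pA_standard_90",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGG"),
    ("cDNA_pA_standard_120",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATT"),
    ("cDNA_p29A_pU1_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCATTTTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_p27A_pU3_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCAAATTTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_p25A_pU5_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCAAAAATTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_p25A_pC5_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCGGGGGTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_p25A_pG5_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCCCCCCTTTTTTTTTTTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
    ("cDNA_pA_internalG_standard_30",
     "CTTCCGATCACTTGCCTGTCGCTCTATCTTCTTTTCTTTTCTTTTCTTTTTTTTTTTTTTTGTAAATAGAAATAGACTAGCTCCACTTTTAAGAATTATTTATGCAATTAAATACATGGGTGACCAAAAGAGCGGGCGGATACACGCGTCACCACAAGCAGAATAAAAGGTAAACCTGAAATTGTTTTAACATAAAATG"),
]

_LENGTH_SERIES = {f"cDNA_pA_standard_{n}" for n in (0, 15, 30, 60, 90, 120)}

#: Insert prefix shared by all standards; used to delimit the designed tail.
_INSERT_PROBE = "GTAAATAGAAATAGAC"


def standards_registry() -> list[StandardRecord]:
    """The twelve synthetic cDNA standards with their designed tails."""
    records = []
    a = len(ADAPTER_DNA)
    for name, seq in _STANDARD_SEQUENCES:
        insert_at = seq.index(_INSERT_PROBE, a)
        tail = seq[a:insert_at]
        series = "length_series" if name in _LENGTH_SERIES else "composition_series"
        records.append(
            StandardRecord(
                name=name,
                full_sequence=seq,
                adapter_prefix=ADAPTER_DNA,
                design_tail_length=len(tail),
                design_tail_composition=tail,
                series=series,
            )
        )
    return records


def make_pore_model(k: int = 5, seed: int = 0) -> PoreModel:
    """Build a deterministic additive k-mer current model.

    Each k-mer level is a position-weighted sum of per-base contributions
    plus a seeded k-mer-specific deviation, so composition dominates the
    level (as in real pore chemistries) while every k-mer remains distinct.
    Poly-A and poly-T levels are pushed at least two standard deviations
    away from every adapter k-mer so the adapter/tail boundary is always
    resolvable.
    """
    if k not in (4, 5, 6):
        raise ValueError(f"k must be 4, 5 or 6, got {k}")
    rng = np.random.default_rng(seed)
    weights = _POSITION_WEIGHTS[k]
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    jitter = rng.normal(0.0, 1.0, size=len(kmers))
    sds = rng.uniform(0.8, 1.2, size=len(kmers))
    levels: dict[str, tuple[float, float]] = {}
    for i, kmer in enumerate(kmers):
        mean = sum(w * _BASE_LEVEL[b] for w, b in zip(weights, kmer)) + jitter[i]
        levels[kmer] = (float(mean), float(sds[i]))

    # Enforce >= 2 sd separation between the tail/poly-A homopolymers and
    # every k-mer occurring in the DNA adapter body.
    adapter_kmers = {ADAPTER_DNA[i : i + k] for i in range(len(ADAPTER_DNA) - k + 1)}
    for hom in ("T" * k, "A" * k):
        hmean, hsd = levels[hom]
        for akm in sorted(adapter_kmers):
            amean, asd = levels[akm]
            min_sep = 2.0 * max(hsd, asd)
            if abs(amean - hmean) < min_sep:
                direction = 1.0 if amean >= hmean else -1.0
                levels[akm] = (hmean + direction * min_sep, asd)
    model = PoreModel(k=k, levels=levels)
    model.validate()
    return model


def _infer_tail_span(sequence: str) -> tuple[int, int]:
    """Locate the designed tail in a cDNA sequence.

    Standards are recognized by exact sequence; otherwise, if the sequence
    begins with the DNA adapter, the tail is taken as the maximal T run
    following it.  Sequences without the adapter are treated as tail-free.
    """
    for name, seq in _STANDARD_SEQUENCES:
        if seq == sequence:
            a = len(ADAPTER_DNA)
            insert_at = sequence.index(_INSERT_PROBE, a)
            return (a, insert_at)
    if sequence.startswith(ADAPTER_DNA):
        a = len(ADAPTER_DNA)
        j = a
        while j < len(sequence) and sequence[j] == "T":
            j += 1
        return (a, j)
    return (0, 0)


def _draw_dwells(rng: np.random.Generator, n: int, dwell_mean: float) -> np.ndarray:
    """Shifted geometric dwell times: minimum 3 samples, mean ``dwell_mean``."""
    if dwell_mean < 3:
        raise ValueError("dwell_mean must be >= 3 samples per nt")
    if dwell_mean == 3:
        return np.full(n, 3, dtype=np.int64)
    p = 1.0 / (dwell_mean - 2.0)
    return 2 + rng.geometric(p, size=n).astype(np.int64)


def simulate_squiggle(
    cdna_sequence: str,
    pore: PoreModel,
    dwell_mean: float = 10.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    tail_nt_span: tuple[int, int] | None = None,
    read_id: str = "sim_read",
) -> tuple[Squiggle, SquiggleTruth]:
    """Simulate one squiggle for a cDNA sequence.

    The signal is a fixed 200-sample adapter stub followed by one current
    segment per base: level from the k-mer context (right-aligned at the
    sequence end), dwell from the shifted geometric distribution, Gaussian
    noise of ``noise_sd``.  Fully reproducible from ``seed``.
    """
    if not cdna_sequence:
        raise ValueError("empty cDNA sequence")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    seq = cdna_sequence.upper()
    n = len(seq)
    k = pore.k
    if tail_nt_span is None:
        tail_nt_span = _infer_tail_span(seq)

    dwells = _draw_dwells(rng, n, dwell_mean)
    levels = np.empty(n)
    for i in range(n):
        j = min(i, n - k)
        levels[i] = pore.mean(seq[j : j + k]) if n >= k else _BASE_LEVEL[seq[i]]
    signal = np.concatenate(
        [np.full(STUB_SAMPLES, STUB_LEVEL), np.repeat(levels, dwells)]
    )
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=len(signal))

    base_starts = STUB_SAMPLES + np.concatenate([[0], np.cumsum(dwells)])
    ts, te = tail_nt_span
    tail_span = (int(base_starts[ts]), int(base_starts[te]))
    if ts == te:
        tail_span = (int(base_starts[ts]), int(base_starts[ts]))
    adapter_end = STUB_SAMPLES
    if seq.startswith(ADAPTER_DNA):
        adapter_end = int(base_starts[len(ADAPTER_DNA)])
    squiggle = Squiggle(
        read_id=read_id,
        samples=signal.astype(np.float64),
        basecalled_length=n,
    )
    truth = SquiggleTruth(
        read_id=read_id,
        true_tail_nt=te - ts,
        tail_sample_span=tail_span,
        adapter_sample_span=(0, adapter_end),
        dwell_mean=float(dwell_mean),
        seed=seed,
    )
    return squiggle, truth


# ---------------------------------------------------------------------------
# Read / alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class TailSpec:
    """One component of the tail distribution used by the read simulator.

    ``class_label`` is the RNA-sense composition class; ``run_len`` is the
    number of non-A bases (terminal run length for Term-*, count of
    interior substitutions for Int-*).
    """

    class_label: str
    length: int = 30
    run_len: int = 3
    weight: float = 1.0


def make_tail_rna(spec: TailSpec, rng: np.random.Generator) -> str:
    """Materialize one RNA-sense tail string from a spec component."""
    L, r = spec.length, spec.run_len
    label = spec.class_label
    if L == 0:
        return ""
    if label == "All-A":
        return "A" * L
    if label.startswith("Term-"):
        base = label[-1]
        r = min(r, L)
        return "A" * (L - r) + base * r
    if label.startswith("Int-"):
        base = label[-1]
        if L < 3:
            return "A" * L
        interior = np.arange(1, L - 1)
        pos = rng.choice(interior, size=min(r, len(interior)), replace=False)
        tail = np.array(list("A" * L))
        tail[pos] = base
        return "".join(tail)
    raise ValueError(f"unknown tail class {label!r}")


def simulate_annotation(
    n_genes: int = 8,
    seed: int = 0,
    two_isoform_fraction: float = 0.5,
    contig: str = "synth1",
    gene_length: int = 400,
    spacing: int = 200,
) -> AnnotationBundle:
    """Random single-exon annotation on one synthetic contig.

    A fraction of genes carries two isoforms sharing a 5' end but with 3'
    ends at least 60 nt apart, exercising isoform assignment.  Strands
    alternate.  The contig sequence is random with padding on both sides so
    simulated reads can overhang annotated ends.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptAnnotation] = []
    pos = spacing
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        gid = f"gene{g:03d}"
        start, end = pos, pos + gene_length
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=f"{gid}.t1", gene_id=gid, contig=contig,
                strand=strand, exons=[(start, end)],
            )
        )
        if rng.random() < two_isoform_fraction:
            shift = int(rng.integers(60, 150))
            if strand == "+":
                exons = [(start, end - shift)]
            else:
                exons = [(start + shift, end)]
            transcripts.append(
                TranscriptAnnotation(
                    transcript_id=f"{gid}.t2", gene_id=gid, contig=contig,
                    strand=strand, exons=exons,
                )
            )
        pos = end + spacing
    contig_len = pos + spacing
    seq = "".join(rng.choice(list("ACGT"), size=contig_len))
    return AnnotationBundle(transcripts=transcripts, contigs={contig: seq})


DEFAULT_TAIL_SPECS = [TailSpec("All-A", length=30)]


def simulate_alignment_set(
    annotation: AnnotationBundle,
    n_reads: int,
    tail_spec: list[TailSpec] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    offset_range: tuple[int, int] = (-20, 20),
    insert_len: int = 80,
    adapter_remnant_prob: float = 0.5,
    transcript_weights: dict[str, float] | None = None,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Simulate soft-clipped alignments with per-read tail ground truth.

    Each read derives from one transcript; its RNA 3' end is offset from
    the annotated end by an integer drawn uniformly from ``offset_range``
    (inclusive).  The cDNA read is [optional adapter remnant][cDNA tail]
    [insert], with the adapter+tail soft-clipped and substitution errors
    applied at ``error_rate``.  The truth table records the clean RNA-sense
    tail, its class label, and the offset.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not annotation.transcripts:
        raise ValueError("annotation must contain at least one transcript")
    if not (0 <= error_rate < 0.2):
        raise ValueError("error_rate must be in [0, 0.2)")
    specs = tail_spec if tail_spec is not None else DEFAULT_TAIL_SPECS
    rng = np.random.default_rng(seed)
    weights = np.array([s.weight for s in specs], dtype=float)
    weights = weights / weights.sum()

    txs = annotation.transcripts
    if transcript_weights is None:
        tx_w = np.full(len(txs), 1.0 / len(txs))
    else:
        tx_w = np.array([transcript_weights.get(t.transcript_id, 0.0) for t in txs])
        tx_w = tx_w / tx_w.sum()

    lo, hi = offset_range
    records: list[AlignmentRecord] = []
    truth_rows = []
    for i in range(n_reads):
        read_id = f"simread_{i:06d}"
        t = txs[int(rng.choice(len(txs), p=tx_w))]
        spec = specs[int(rng.choice(len(specs), p=weights))]
        rna_tail = make_tail_rna(spec, rng)
        offset = int(rng.integers(lo, hi + 1))
        contig_seq = annotation.contigs[t.contig]

        if t.strand == "+":
            g3 = t.three_prime_end + offset
            ref_start, ref_end = g3 - insert_len, g3
            insert_rna = contig_seq[ref_start:ref_end]
            aln_strand = "-"
        else:
            g3 = t.three_prime_end - offset
            ref_start, ref_end = g3, g3 + insert_len
            insert_rna = revcomp(contig_seq[ref_start:ref_end])
            aln_strand = "+"

        adapter = ADAPTER_DNA if rng.random() < adapter_remnant_prob else ""
        cdna_tail = rna_tail_to_cdna(rna_tail)
        cdna_insert = revcomp(insert_rna)
        read = adapter + cdna_tail + cdna_insert
        if error_rate > 0:
            read = _apply_substitutions(read, error_rate, rng)
        records.append(
            AlignmentRecord(
                read_id=read_id,
                contig=t.contig,
                strand=aln_strand,
                ref_start=ref_start,
                ref_end=ref_end,
                clip_start=len(adapter) + len(cdna_tail),
                clip_end=0,
                read_sequence=read,
            )
        )
        truth_rows.append(
            {
                "read_id": read_id,
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "tail_rna": rna_tail,
                "class_label": spec.class_label,
                "offset": offset,
                "had_adapter": bool(adapter),
            }
        )
    return records, pd.DataFrame(truth_rows)


def _apply_substitutions(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(read))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"))
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)
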