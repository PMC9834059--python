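"""Tail extraction from soft-clipped bases, composition classes and profiles.

In 3'-end-capture cDNA reads the tail is not part of the reference
alignment: it appears as soft-clipped bases between the sequencing adapter
and the first mapped base.  This module trims residual adapter, converts
the clip to RNA sense, filters out reads whose adapter was not removed
(A-content rule), bins tails into seven composition classes on the last 30
nucleotides, and builds per-position base-probability profiles over the
last 20 nucleotides.

Composition classes (RNA sense, terminal additions at the 3' end):
All-A, Int-G/Int-U/Int-C (internal non-A bases), Term-G/Term-U/Term-C
(non-A bases at the 3' terminus).  Terminal classification takes
precedence over internal: terminal additions are the biological signal of
interest (e.g. terminal uridylation marking transcripts for decay).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .models import AlignmentRecord, cdna_to_rna_tail

TAIL_CLASSES = ("All-A", "Int-G", "Int-U", "Int-C", "Term-G", "Term-U", "Term-C")

RNA_BASES = ("A", "C", "G", "U")


@dataclass
class TrimReport:
    read_id: str
    trimmed_bases: int
    adapter_identity: float
    trimmed: bool


@dataclass
class TailSequence:
    """RNA-sense tail of one read, 5'->3' (terminal additions last)."""

    read_id: str
    rna_sense_bases: str
    source: str = "softclip"

    @property
    def a_fraction(self) -> float:
        """Percent A among the tail bases."""
        if not self.rna_sense_bases:
            return 0.0
        return 100.0 * self.rna_sense_bases.count("A") / len(self.rna_sense_bases)


@dataclass
class CompositionProfile:
    """Per-position base probabilities over the last N nucleotides.

    ``table`` is indexed by offset from the 3' terminus (-1 = terminal
    base, -N = deepest), with columns A/C/G/U plus a coverage column; the
    base probabilities at each covered position sum to one.
    """

    last_n: int
    table: pd.DataFrame


def trim_end_adapter(
    read_bases: str,
    adapter: str,
    end_threshold: float = 50.0,
    extra_end_trim: int = 0,
    read_id: str = "read",
    end: str = "start",
) -> tuple[str, TrimReport]:
    """Remove an adapter from a read end if it aligns well enough.

    The adapter is aligned (edit-distance, infix mode) against a window at
    the requested read end; if its identity, 100 * (adapter length - edit
    distance) / adapter length, reaches ``end_threshold`` percent, the
    aligned span plus ``extra_end_trim`` further bases inward is removed.
    Defaults mirror the established end-trimming practice for this
    chemistry (threshold 50, no extra trim).
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 bases long")
    if end not in ("start", "end"):
        raise ValueError("end must be 'start' or 'end'")
    window_len = min(len(read_bases), int(1.5 * len(adapter)) + extra_end_trim)
    if window_len == 0:
        return read_bases, TrimReport(read_id, 0, 0.0, False)
    window = read_bases[:window_len] if end == "start" else read_bases[-window_len:]
    aln = edlib.align(adapter, window, mode="HW", task="locations")
    dist = aln["editDistance"]
    identity = 100.0 * (len(adapter) - dist) / len(adapter)
    if identity < end_threshold or not aln["locations"]:
        return read_bases, TrimReport(read_id, 0, max(identity, 0.0), False)
    if end == "start":
        cut = max(e + 1 for _, e in aln["locations"]) + extra_end_trim
        cut = min(cut, len(read_bases))
        trimmed = read_bases[cut:]
        n_trim = cut
    else:
        offset = len(read_bases) - window_len
        cut = offset + min(s for s, _ in aln["locations"]) - extra_end_trim
        cut = max(cut, 0)
        trimmed = read_bases[:cut]
        n_trim = len(read_bases) - cut
    return trimmed, TrimReport(read_id, n_trim, identity, True)


def extract_tail(
    alignment: AlignmentRecord,
    adapter: str,
    end_threshold: float = 50.0,
    extra_end_trim: int = 0,
) -> TailSequence | None:
    """Pull the RNA-sense tail out of an alignment's soft-clipped bases.

    The tail-side soft clip (cDNA start, between adapter and first mapped
    base) is taken, residual adapter is trimmed from its outer end, and
    the remainder is reverse-complemented to RNA sense (T -> U).  Returns
    None when no clipped tail bases remain.
    """
    if alignment.clip_start == 0 and alignment.clip_end == 0:
        return None
    clip = alignment.tail_side_clip
    if not clip:
        return None
    trimmed, _ = trim_end_adapter(
        clip, adapter, end_threshold, extra_end_trim, alignment.read_id, end="start"
    )
    if not trimmed:
        return None
    return TailSequence(
        read_id=alignment.read_id, rna_sense_bases=cdna_to_rna_tail(trimmed)
    )


def filter_a_content(tail: TailSequence, threshold: float = 80.0) -> bool:
    """Keep a tail iff strictly more than ``threshold`` percent of its
    bases are A (RNA sense).

    The strict inequality is deliberate: the filter exists to drop reads
    whose adapter was never trimmed, and a tail at exactly the threshold
    is discarded.
    """
    if not tail.rna_sense_bases:
        raise ValueError(f"{tail.read_id}: empty tail")
    return tail.a_fraction > threshold


def classify_tail(
    tail: TailSequence, last_n: int = 30, terminal_precedence: bool = True
) -> str:
    """Assign one of the seven composition classes on the last ``last_n`` nt.

    All-A if the window is pure A; otherwise Term-X when the 3'-terminal
    base is a non-A base X (terminal additions outrank internal ones when
    ``terminal_precedence``); otherwise Int-X for the most frequent
    internal non-A base (ties broken by proximity to the 3' end).  Tails
    shorter than the window are classified on their full length.
    """
    seq = tail.rna_sense_bases
    window = seq[-min(last_n, len(seq)) :]
    if not window:
        raise ValueError(f"{tail.read_id}: empty tail")
    non_a = [b for b in window if b != "A"]
    if not non_a:
        return "All-A"
    terminal = window[-1]

    def internal_class(bases: list[str]) -> str:
        counts = Counter(bases)
        top = max(counts.values())
        tied = {b for b, c in counts.items() if c == top}
        if len(tied) == 1:
            return f"Int-{tied.pop()}"
        for b in reversed(window):
            if b in tied:
                return f"Int-{b}"
        raise AssertionError("unreachable")

    if terminal != "A":
        if terminal_precedence:
            return f"Term-{terminal}"
        internal = [b for b in window[:-1] if b != "A"]
        return internal_class(internal) if internal else f"Term-{terminal}"
    return internal_class(non_a)


def positional_profile(
    tails: list[TailSequence], last_n: int = 20
) -> CompositionProfile:
    """Base probability per position in the last ``last_n`` nt.

    Tails are right-justified at the 3' terminus; a tail shorter than
    ``last_n`` contributes only to the positions it covers.
    """
    if not tails:
        raise ValueError("no tails to profile")
    counts = np.zeros((last_n, len(RNA_BASES)), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    for tail in tails:
        seq = tail.rna_sense_bases
        for offset in range(1, min(last_n, len(seq)) + 1):
            base = seq[-offset]
            if base in base_idx:
                counts[offset - 1, base_idx[base]] += 1
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / coverage[:, None]
    probs = np.where(coverage[:, None] > 0, probs, 0.0)
    table = pd.DataFrame(
        probs, columns=list(RNA_BASES), index=[-(i + 1) for i in range(last_n)]
    )
    table["coverage"] = coverage
    table.index.name = "position"
    return CompositionProfile(last_n=last_n, table=table)


def classify_alignments(
    alignments: list[AlignmentRecord],
    adapter: str,
    a_threshold: float = 80.0,
    last_n: int = 30,
    end_threshold: float = 50.0,
    extra_end_trim: int = 0,
) -> pd.DataFrame:
    """End-to-end per-read tail composition table.

    Columns: read_id, tail_seq (RNA sense), a_fraction, tail_class
    ('Discarded' for tails failing the A-content filter), and a reason for
    reads without an extractable tail.
    """
    rows = []
    for aln in alignments:
        tail = extract_tail(aln, adapter, end_threshold, extra_end_trim)
        if tail is None or not tail.rna_sense_bases:
            rows.append(
                {
                    "read_id": aln.read_id,
                    "tail_seq": "",
                    "a_fraction": np.nan,
                    "tail_class": "",
                    "reason": "no_softclip_tail",
                }
            )
            continue
        keep = filter_a_content(tail, a_threshold)
        rows.append(
            {
                "read_id": aln.read_id,
                "tail_seq": tail.rna_sense_bases,
                "a_fraction": tail.a_fraction,
                "tail_class": classify_tail(tail, last_n) if keep else "Discarded",
                "reason": "" if keep else "a_content_below_threshold",
            }
        )
    return pd.DataFrame(rows)
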