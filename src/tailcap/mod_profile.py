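"""Pileup-based mismatch/drop-off profiling for RNA-modification detection.

Certain RNA modifications disturb reverse transcription and base-calling,
leaving elevated mismatch frequencies and read-end drop-offs at the
modified site.  This module builds per-position pileups from alignments,
masks low-signal positions, and contrasts the mismatch profiles of two
read populations (e.g. precursor vs processed isoforms defined by their
3' ends), ranking positions by the absolute frequency difference.

Conventions: deletions relative to the reference count as mismatches
(reverse-transcription drop events manifest as deletions; configurable);
insertions are ignored.  Each read's drop-off is attributed to its last
aligned position in RNA orientation — the position where reverse
transcription stopped: the alignment end nearest the RNA 5' direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AlignmentRecord

BASES = ("A", "C", "G", "T")

DEFAULT_MASK_THRESHOLD = 0.1


@dataclass
class SiteProfile:
    contig: str
    position: int  # 0-based
    coverage: int
    match: int
    mismatch: int
    base_counts: dict[str, int] = field(default_factory=dict)
    dropoff: int = 0

    @property
    def mismatch_frequency(self) -> float | None:
        """Mismatch fraction, or None where there is no coverage."""
        if self.coverage == 0:
            return None
        return self.mismatch / self.coverage

    @property
    def dropoff_rate(self) -> float | None:
        if self.coverage == 0:
            return None
        return self.dropoff / self.coverage


@dataclass
class IsoformProfileDelta:
    position: int
    freq_a: float | None
    freq_b: float | None
    delta: float | None
    masked: bool


def build_pileup(
    alignments: list[AlignmentRecord],
    reference: str,
    contig: str,
    count_deletions: bool = True,
) -> list[SiteProfile]:
    """Per-position match/mismatch/drop-off counts along a reference.

    Soft-clipped bases are excluded; each aligned base is compared to the
    reference at its position.  With ``count_deletions`` (default), bases
    the aligner skipped inside the span would also count as mismatches —
    the simulator emits gapless alignments, so in practice every position
    in a read's span carries a base.  The drop-off of a read is the
    reference position where reverse transcription terminated: ``ref_start``
    for reverse-strand alignments (RNA 5'-most at the left edge) and
    ``ref_end - 1`` for forward-strand alignments.
    """
    n = len(reference)
    cov = np.zeros(n, dtype=np.int64)
    match = np.zeros(n, dtype=np.int64)
    base_counts = {b: np.zeros(n, dtype=np.int64) for b in BASES}
    dropoff = np.zeros(n, dtype=np.int64)
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.contig != contig:
            raise ValueError(
                f"{aln.read_id}: contig {aln.contig!r} does not match "
                f"reference contig {contig!r}"
            )
        if aln.ref_end > n:
            raise ValueError(
                f"{aln.read_id}: span [{aln.ref_start}, {aln.ref_end}) exceeds "
                f"reference length {n}"
            )
        seq = aln.aligned_on_reference().upper()
        span = aln.ref_end - aln.ref_start
        if len(seq) != span:
            # indel-containing alignment: compare over the shared prefix and
            # treat the missing reference positions as deletions
            pad = span - len(seq)
            seq = seq + "-" * pad if pad > 0 else seq[:span]
        for off, base in enumerate(seq):
            pos = aln.ref_start + off
            cov[pos] += 1
            if base in base_counts:
                base_counts[base][pos] += 1
            if base == reference[pos].upper():
                match[pos] += 1
        stop = aln.ref_start if aln.strand == "-" else aln.ref_end - 1
        dropoff[stop] += 1
    profiles = []
    for pos in range(n):
        counted = int(sum(base_counts[b][pos] for b in BASES))
        mm = int(cov[pos] - match[pos])
        if not count_deletions:
            # deletions/ambiguous bases drop out of both numerator and coverage
            mm = int(counted - match[pos])
            c = counted
        else:
            c = int(cov[pos])
        profiles.append(
            SiteProfile(
                contig=contig,
                position=pos,
                coverage=c,
                match=int(match[pos]),
                mismatch=mm,
                base_counts={b: int(base_counts[b][pos]) for b in BASES},
                dropoff=int(dropoff[pos]),
            )
        )
    return profiles


def flag_modified_sites(
    profiles: list[SiteProfile],
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> pd.DataFrame:
    """Sites with mismatch frequency >= ``mask_threshold``.

    A frequency exactly at the threshold is flagged (strictly lower is
    masked).  Zero-coverage sites are reported masked with a missing-data
    reason and no frequency.  The local drop-off rate accompanies each
    flag since modification-stalled reverse transcription elevates both.
    """
    rows = []
    for p in profiles:
        freq = p.mismatch_frequency
        if freq is None:
            rows.append(
                {
                    "contig": p.contig,
                    "position": p.position,
                    "coverage": 0,
                    "mismatch_frequency": np.nan,
                    "dropoff_rate": np.nan,
                    "flagged": False,
                    "reason": "no_coverage",
                }
            )
            continue
        flagged = freq >= mask_threshold
        rows.append(
            {
                "contig": p.contig,
                "position": p.position,
                "coverage": p.coverage,
                "mismatch_frequency": freq,
                "dropoff_rate": p.dropoff_rate,
                "flagged": flagged,
                "reason": "" if flagged else "below_mask_threshold",
            }
        )
    return pd.DataFrame(rows)


def compare_profiles(
    pop_a: list[AlignmentRecord],
    pop_b: list[AlignmentRecord],
    reference: str,
    contig: str,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> list[IsoformProfileDelta]:
    """Per-site mismatch-frequency difference between two read populations.

    ``delta`` = freq(A) - freq(B); positions where both populations sit
    below ``mask_threshold`` (or lack coverage) are masked.  Sort the
    unmasked output by |delta| to rank candidate modified sites.
    """
    if not pop_a or not pop_b:
        raise ValueError("both populations must be non-empty")
    prof_a = build_pileup(pop_a, reference, contig)
    prof_b = build_pileup(pop_b, reference, contig)
    deltas = []
    for a, b in zip(prof_a, prof_b):
        fa, fb = a.mismatch_frequency, b.mismatch_frequency
        if fa is None or fb is None:
            deltas.append(IsoformProfileDelta(a.position, fa, fb, None, True))
            continue
        masked = fa < mask_threshold and fb < mask_threshold
        deltas.append(IsoformProfileDelta(a.position, fa, fb, fa - fb, masked))
    return deltas


def rank_outliers(deltas: list[IsoformProfileDelta]) -> pd.DataFrame:
    """Unmasked positions ordered by decreasing |delta|."""
    rows = [
        {
            "position": d.position,
            "freq_a": d.freq_a,
            "freq_b": d.freq_b,
            "delta": d.delta,
            "abs_delta": abs(d.delta),
        }
        for d in deltas
        if not d.masked and d.delta is not None
    ]
    out = pd.DataFrame(
        rows, columns=["position", "freq_a", "freq_b", "delta", "abs_delta"]
    )
    return out.sort_values(
        ["abs_delta", "position"], ascending=[False, True]
    ).reset_index(drop=True)
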