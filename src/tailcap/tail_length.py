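"""Per-read polyA/polyT tail length estimation from raw current signal.

The estimator follows the duration-ratio principle: the tail homopolymer
produces a long low-variance stretch of current; its duration, divided by
the read's per-nucleotide translocation rate, gives the tail length in
nucleotides.  The rate is derived from the read's own base-called length
and total (non-stub) signal duration, so it self-adjusts to per-read speed
variation.

Pipeline: :func:`normalize_signal` (robust median/MAD scaling) ->
:func:`segment_tail` (adapter boundary detection + variance-based
homopolymer run finding with gap merging) -> :func:`call_tail_length`
(duration ratio with k-mer context padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import Squiggle
from .simulate import STUB_SAMPLES


@dataclass
class NormalizedSignal:
    read_id: str
    z: np.ndarray
    center: float
    scale: float
    basecalled_length: int | None = None


@dataclass
class TailSegment:
    """Half-open sample interval called as the tail homopolymer."""

    start: int
    end: int
    mean_level: float
    variance: float

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class TailCall:
    read_id: str
    tail_samples: int
    rate: float
    tail_length_nt: float
    status: str  # called | zero_tail | unreliable


@dataclass
class TailParams:
    """Tunable parameters of the signal-level tail caller.

    ``var_threshold`` is in squared normalized units; with robust scaling
    the within-homopolymer variance is dominated by measurement noise
    (~1e-3) while windows straddling two k-mer levels typically exceed
    0.01, so 0.005 separates the two regimes.  ``max_gap_samples`` must
    exceed the duration of a single-base interruption, which disturbs k
    consecutive k-mer contexts (~k * dwell samples), so interrupted tails
    are bridged into one segment; ``level_tol`` restricts merging to runs
    at the same homopolymer level, preventing chaining into the insert.
    ``adapter_nt``/``adapter_skip_fraction`` skip most of the 31-nt DNA
    adapter that the chemistry places between the stub and the tail.
    ``context_pad_nt`` compensates the k-1 transition k-mers at the
    segment edges that do not read as pure homopolymer signal.
    """

    smooth_window: int = 5
    var_window: int = 25
    var_threshold: float = 0.003
    noise_var_mult: float = 6.0
    min_segment_samples: int = 90
    min_core_samples: int = 50
    max_gap_samples: int = 80
    nominal_rate: float = 10.0
    level_tol: float = 0.25
    tail_level_band: tuple[float, float] = (-2.0, 0.6)
    adapter_nt: int = 31
    adapter_skip_fraction: float = 0.75
    start_tolerance_nt: float = 18.0
    adapter_stub_samples: int = STUB_SAMPLES
    context_pad_nt: float = 2.0
    rate_bounds: tuple[float, float] = (3.0, 50.0)


DEFAULT_PARAMS = TailParams()


def normalize_signal(squiggle: Squiggle) -> NormalizedSignal:
    """Robustly center and scale a squiggle: z = (x - median) / (1.4826 MAD).

    Falls back to the standard deviation when the MAD is zero; a signal
    with zero spread is rejected as degenerate.  Requires >= 100 samples.
    """
    x = np.asarray(squiggle.samples, dtype=np.float64)
    if len(x) < 100:
        raise ValueError(f"{squiggle.read_id}: too short ({len(x)} samples; need >= 100)")
    center = float(np.median(x))
    mad = float(np.median(np.abs(x - center)))
    scale = 1.4826 * mad
    if scale == 0.0:
        scale = float(np.std(x))
    if scale == 0.0:
        raise ValueError(f"{squiggle.read_id}: degenerate signal (zero spread)")
    return NormalizedSignal(
        read_id=squiggle.read_id,
        z=(x - center) / scale,
        center=center,
        scale=scale,
        basecalled_length=squiggle.basecalled_length or None,
    )


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    c = np.cumsum(np.concatenate([[0.0], x]))
    out = (c[w:] - c[:-w]) / w
    return out


def _rolling_var(x: np.ndarray, w: int) -> np.ndarray:
    c1 = np.cumsum(np.concatenate([[0.0], x]))
    c2 = np.cumsum(np.concatenate([[0.0], x * x]))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    return np.maximum(s2 / w - (s1 / w) ** 2, 0.0)


def detect_adapter_boundary(z: np.ndarray, smooth_window: int = 5) -> int:
    """Largest level change-point in the first quarter of the read.

    The sequencing-adapter stub sits at a level outside the k-mer range, so
    the stub-to-sequence transition is the dominant jump early in the read.
    """
    sm = _moving_mean(z, smooth_window)
    lag = max(smooth_window, 5)
    quarter = max(len(sm) // 4, lag + 1)
    d = np.abs(sm[lag:quarter] - sm[: quarter - lag])
    if len(d) == 0:
        return 0
    return int(np.argmax(d) + lag)


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    if not mask.any():
        return []
    idx = np.nonzero(mask)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def segment_tail(
    norm: NormalizedSignal,
    params: TailParams = DEFAULT_PARAMS,
    adapter_boundary_hint: int | None = None,
) -> TailSegment | None:
    """Locate the tail homopolymer segment, or return None if absent.

    After the adapter boundary, rolling-variance windows below
    ``var_threshold`` mark homopolymer-like signal.  Runs separated by gaps
    of at most ``max_gap_samples`` whose flanking levels agree within
    ``level_tol`` are merged (bridging single-base interruptions in the
    tail).  The merged run nearest the adapter boundary that spans at least
    ``min_segment_samples`` is returned; absence is a value, not an error.
    """
    z = norm.z
    sm = _moving_mean(z, params.smooth_window)
    boundary = (
        adapter_boundary_hint
        if adapter_boundary_hint is not None
        else detect_adapter_boundary(z, params.smooth_window)
    )
    # Skip most of the fixed DNA adapter between stub and tail; the skip is
    # rate-aware so it scales with per-read translocation speed.
    if norm.basecalled_length:
        rate = (len(z) - params.adapter_stub_samples) / norm.basecalled_length
        skip = int(params.adapter_skip_fraction * params.adapter_nt * rate)
    else:
        rate = params.nominal_rate
        skip = params.var_window
    # duration thresholds are stated at the nominal translocation rate and
    # rescaled by the read's own rate
    rate_scale = rate / params.nominal_rate
    min_segment = params.min_segment_samples * rate_scale
    min_core = params.min_core_samples * rate_scale
    max_gap = params.max_gap_samples * rate_scale
    search_from = min(boundary + max(skip, params.var_window), len(sm))
    region = sm[search_from:]
    if len(region) <= params.var_window:
        return None
    # Adaptive threshold: the robust scale shrinks when the tail dominates
    # the read, inflating normalized noise, so the homopolymer criterion is
    # referenced to the read's own high-frequency noise floor.
    diffs = np.diff(z)
    sigma2 = float(np.median(diffs * diffs)) / 0.9098
    threshold = max(
        params.var_threshold, params.noise_var_mult * sigma2 / params.smooth_window
    )
    var = _rolling_var(region, params.var_window)
    mask = var < threshold
    runs = _runs_from_mask(mask)
    if not runs:
        return None
    # window index i covers samples [i, i + var_window): widen accordingly
    spans = [(a, b + params.var_window - 1) for a, b in runs]
    levels = [float(np.mean(region[a:b])) for a, b in spans]

    # merged entries: (start, end, level, longest contiguous sub-run)
    merged: list[tuple[int, int, float, int]] = []
    for (a, b), lev in zip(spans, levels):
        if merged:
            pa, pb, plev, pcore = merged[-1]
            gap = a - pb
            if gap <= max_gap and abs(lev - plev) <= params.level_tol:
                wa, wb = pb - pa, b - a
                merged[-1] = (
                    pa, b, (plev * wa + lev * wb) / (wa + wb), max(pcore, b - a)
                )
                continue
        merged.append((a, b, lev, b - a))

    # Tails are adapter-adjacent by construction: a candidate run must
    # start no later than shortly after the estimated adapter end.
    if norm.basecalled_length:
        adapter_end_est = boundary + params.adapter_nt * rate
        start_limit = adapter_end_est + params.start_tolerance_nt * rate
    else:
        start_limit = search_from + 10 * params.var_window
    # The tail is poly(T) in cDNA sense: its current band sits at or below
    # the read's median level, unlike A-rich stretches.
    lo_band, hi_band = params.tail_level_band
    # A genuine tail also contains one long uninterrupted core run; chains
    # of short coincidentally level-matched runs do not.
    candidates = [
        m
        for m in merged
        if m[1] - m[0] >= min_segment
        and m[3] >= min_core
        and search_from + m[0] <= start_limit
        and lo_band <= m[2] <= hi_band
    ]
    if not candidates:
        return None
    # take the longest anchored run (ties: nearest the adapter)
    a, b, lev, _ = min(candidates, key=lambda m: (-(m[1] - m[0]), m[0]))
    start = search_from + a
    end = min(search_from + b, len(z))
    return TailSegment(
        start=int(start),
        end=int(end),
        mean_level=lev,
        variance=float(np.var(z[start:end])),
    )


def call_tail_length(
    squiggle: Squiggle,
    segment: TailSegment | None,
    params: TailParams = DEFAULT_PARAMS,
) -> TailCall:
    """Convert a tail segment duration to nucleotides via the duration ratio.

    The per-read translocation rate is the self-consistent solution of
    "rate = non-tail samples / non-tail bases", which equals total non-stub
    samples divided by the base-called read length.  With a segment the
    call is segment duration / rate plus the k-mer context pad; with no
    segment the read is a zero-tail call.
    """
    if squiggle.basecalled_length <= 0:
        raise ValueError(f"{squiggle.read_id}: base-called length must be positive")
    if segment is None:
        return TailCall(squiggle.read_id, 0, float("nan"), 0.0, "zero_tail")
    total_eff = squiggle.sample_count - params.adapter_stub_samples
    if total_eff <= 0:
        raise ValueError(f"{squiggle.read_id}: no signal beyond the adapter stub")
    rate = total_eff / squiggle.basecalled_length
    lo, hi = params.rate_bounds
    if not (lo <= rate <= hi):
        return TailCall(squiggle.read_id, segment.n_samples, rate, 0.0, "unreliable")
    tail_samples_eff = segment.n_samples + params.context_pad_nt * rate
    tail_nt = tail_samples_eff / rate
    return TailCall(
        read_id=squiggle.read_id,
        tail_samples=int(round(tail_samples_eff)),
        rate=float(rate),
        tail_length_nt=float(tail_nt),
        status="called",
    )


def estimate_tail(
    squiggle: Squiggle, params: TailParams = DEFAULT_PARAMS
) -> TailCall:
    """Normalize, segment and call one squiggle end to end."""
    norm = normalize_signal(squiggle)
    seg = segment_tail(norm, params)
    return call_tail_length(squiggle, seg, params)
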