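"""Per-unit tail-length summaries and divergence testing.

Tail lengths are summarized per gene, transcript or composition class,
keeping only units with strictly more than ``min_reads`` supporting reads.
Divergence across groups (timepoints, isoforms, classes) is tested per
unit with the Kruskal-Wallis rank test (tie-corrected; exact permutation
for small samples) and corrected across units with Benjamini-Hochberg.
Two significance policies are exposed — raw p < alpha and BH-adjusted
q < alpha — because both conventions are common for this kind of scan;
every output row records which policy produced its flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
DEFAULT_ALPHA = 0.05
PERMUTATION_N_MAX = 20

REQUIRED_COLUMNS = ("read_id", "unit", "tail_length_nt")


@dataclass
class GroupComparison:
    unit: str
    groups: list[str]
    n_per_group: list[int]
    h_statistic: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    policy: str = "q"
    method: str = "asymptotic"


@dataclass
class DivergenceScan:
    """Scan results plus the headline fractions under both policies."""

    comparisons: list[GroupComparison]
    skipped: pd.DataFrame
    alpha: float
    fraction_significant_q: float = float("nan")
    fraction_significant_p: float = float("nan")
    policy: str = "q"

    @property
    def fraction_significant(self) -> float:
        return (
            self.fraction_significant_q
            if self.policy == "q"
            else self.fraction_significant_p
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit": c.unit,
                    "n_groups": len(c.groups),
                    "n_total": sum(c.n_per_group),
                    "h_statistic": c.h_statistic,
                    "p_value": c.p_value,
                    "q_value": c.q_value,
                    "significant": c.significant,
                    "policy": c.policy,
                    "method": c.method,
                }
                for c in self.comparisons
            ]
        )


def _check_table(table: pd.DataFrame, unit: str, group: str | None = None) -> None:
    if table.empty:
        raise ValueError("empty tail table")
    needed = {"read_id", unit, "tail_length_nt"}
    if group is not None:
        needed.add(group)
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"tail table missing columns: {sorted(missing)}")
    if (table["tail_length_nt"] < 0).any():
        raise ValueError("negative tail lengths in table")


def summarize_tails(
    table: pd.DataFrame,
    unit: str = "gene_id",
    min_reads: int = DEFAULT_MIN_READS,
    group: str | None = None,
) -> pd.DataFrame:
    """Median / IQR / count per unit (optionally per group within unit).

    Units (or unit-group cells) with count strictly greater than
    ``min_reads`` are retained — a unit with exactly ``min_reads`` reads
    is excluded.
    """
    _check_table(table, unit, group)
    keys = [unit] if group is None else [unit, group]
    g = table.groupby(keys)["tail_length_nt"]
    out = g.agg(
        n="size",
        median_tail="median",
        q25=lambda x: float(np.percentile(x, 25)),
        q75=lambda x: float(np.percentile(x, 75)),
    ).reset_index()
    out["iqr"] = out["q75"] - out["q25"]
    return out[out["n"] > min_reads].reset_index(drop=True)


def _kruskal_permutation(groups: list[np.ndarray], max_perm: int = 200_000) -> tuple[float, float, str]:
    """Exact (or near-exact) permutation Kruskal-Wallis p-value.

    Enumerates all assignments of the pooled values to group slots when
    feasible, otherwise Monte-Carlo samples them with a fixed generator;
    the p-value is the fraction of permutations with H at least as large
    as observed (including the identity, so p > 0 always).
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = _kw_h(groups)
    n = len(pooled)
    idx = np.arange(n)

    def h_of(perm: np.ndarray) -> float:
        parts, at = [], 0
        for s in sizes:
            parts.append(pooled[perm[at : at + s]])
            at += s
        return _kw_h(parts)

    # number of distinct assignments = multinomial(n; sizes)
    from math import comb

    total, rem = 1, n
    for s in sizes[:-1]:
        total *= comb(rem, s)
        rem -= s
    if total <= max_perm:
        count = 0
        n_perm = 0
        for combo in _multiset_splits(idx, sizes):
            n_perm += 1
            if h_of(combo) >= h_obs - 1e-12:
                count += 1
        return h_obs, count / n_perm, "exact_permutation"
    rng = np.random.default_rng(0)
    count = 1  # identity permutation
    for _ in range(max_perm):
        perm = rng.permutation(n)
        if h_of(perm) >= h_obs - 1e-12:
            count += 1
    return h_obs, count / (max_perm + 1), "mc_permutation"


def _multiset_splits(idx: np.ndarray, sizes: list[int]):
    """All ways to split indices into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield idx
        return
    for first in itertools.combinations(range(len(idx)), sizes[0]):
        mask = np.zeros(len(idx), dtype=bool)
        mask[list(first)] = True
        rest = idx[~mask]
        for tail in _multiset_splits(rest, sizes[1:]):
            yield np.concatenate([idx[mask], tail])


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic (0 when all values tie)."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    at, h = 0, 0.0
    for g in groups:
        r = ranks[at : at + len(g)]
        at += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_test(
    groups: list[np.ndarray], permutation_n_max: int = PERMUTATION_N_MAX
) -> tuple[float, float, str]:
    """Kruskal-Wallis H and p for >= 2 groups.

    All-identical values across groups are a degenerate case with no rank
    information: H = 0, p = 1.  Small totals (n <= ``permutation_n_max``)
    use an exact permutation p instead of the chi-square asymptotics.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, "degenerate_ties"
    if len(pooled) <= permutation_n_max:
        return _kruskal_permutation(groups)
    h, p = stats.kruskal(*groups)
    return float(h), float(p), "asymptotic"


def divergence_scan(
    table: pd.DataFrame,
    unit: str = "transcript_id",
    grouping: str = "group",
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    policy: str = "q",
) -> DivergenceScan:
    """Per-unit Kruskal-Wallis scan with BH correction across units.

    Groups within a unit are eligible only with strictly more than
    ``min_reads`` reads; units with fewer than two eligible groups are
    skipped with a reason.  The summary fraction of significant units is
    reported under both the BH q < alpha and the raw p < alpha policies;
    ``policy`` picks which one sets the per-unit significant flag.
    """
    if policy not in ("q", "p"):
        raise ValueError("policy must be 'q' or 'p'")
    _check_table(table, unit, grouping)
    comparisons: list[GroupComparison] = []
    skipped: list[dict] = []
    for unit_value, sub in table.groupby(unit):
        groups, labels, sizes = [], [], []
        for g_value, gsub in sub.groupby(grouping):
            if len(gsub) > min_reads:
                groups.append(gsub["tail_length_nt"].to_numpy())
                labels.append(str(g_value))
                sizes.append(len(gsub))
        if len(groups) < 2:
            skipped.append(
                {"unit": str(unit_value), "reason": "fewer_than_two_eligible_groups"}
            )
            continue
        h, p, method = kruskal_test(groups)
        comparisons.append(
            GroupComparison(
                unit=str(unit_value),
                groups=labels,
                n_per_group=sizes,
                h_statistic=h,
                p_value=p,
                policy=policy,
                method=method,
            )
        )
    skipped_df = pd.DataFrame(skipped, columns=["unit", "reason"])
    if not comparisons:
        return DivergenceScan(comparisons, skipped_df, alpha, policy=policy)
    pvals = np.array([c.p_value for c in comparisons])
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for c, q in zip(comparisons, qvals):
        c.q_value = float(q)
        c.significant = (c.q_value < alpha) if policy == "q" else (c.p_value < alpha)
    n = len(comparisons)
    return DivergenceScan(
        comparisons=comparisons,
        skipped=skipped_df,
        alpha=alpha,
        fraction_significant_q=float(np.sum(qvals < alpha)) / n,
        fraction_significant_p=float(np.sum(pvals < alpha)) / n,
        policy=policy,
    )
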