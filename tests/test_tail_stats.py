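import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tailcap.tail_stats import (
    divergence_scan,
    kruskal_test,
    summarize_tails,
)


def _table(groups: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """groups: unit -> group label -> tail lengths."""
    rows = []
    i = 0
    for unit, by_group in groups.items():
        for label, values in by_group.items():
            for v in values:
                rows.append(
                    {"read_id": f"r{i}", "transcript_id": unit, "group": label,
                     "tail_length_nt": float(v)}
                )
                i += 1
    return pd.DataFrame(rows)


# --- summarize_tails ---------------------------------------------------------


def test_summarize_min_reads_strict():
    # exhaustive sweep around the boundary: exactly min_reads is excluded
    for n in range(5, 16):
        table = _table({"t1": {"g": list(range(n))}})
        out = summarize_tails(table, unit="transcript_id", min_reads=10)
        assert (len(out) == 1) == (n > 10), n


def test_summarize_median_and_iqr():
    table = _table({"t1": {"g": [0, 0, 100] * 4}})
    out = summarize_tails(table, unit="transcript_id", min_reads=10)
    assert out.iloc[0]["median_tail"] == 0.0
    assert out.iloc[0]["n"] == 12


def test_summarize_empty_and_negative_rejected():
    with pytest.raises(ValueError):
        summarize_tails(pd.DataFrame(), unit="transcript_id")
    bad = _table({"t1": {"g": [5.0]}})
    bad.loc[0, "tail_length_nt"] = -1.0
    with pytest.raises(ValueError):
        summarize_tails(bad, unit="transcript_id")


def test_summarize_median_invariant_under_group_relabeling():
    table = _table({"t1": {"g1": list(range(20)), "g2": list(range(50, 70))}})
    a = summarize_tails(table, unit="transcript_id", min_reads=10, group="group")
    relabeled = table.copy()
    relabeled["group"] = relabeled["group"].map({"g1": "z9", "g2": "a0"})
    b = summarize_tails(relabeled, unit="transcript_id", min_reads=10, group="group")
    assert sorted(a["median_tail"]) == sorted(b["median_tail"])


# --- kruskal_test ------------------------------------------------------------


def test_kw_matches_scipy_asymptotic():
    rng = np.random.default_rng(0)
    groups = [rng.normal(30, 10, 40), rng.normal(35, 10, 40), rng.normal(30, 10, 40)]
    h, p, method = kruskal_test(groups)
    h_ref, p_ref = sps.kruskal(*groups)
    assert method == "asymptotic"
    assert h == pytest.approx(h_ref)
    assert p == pytest.approx(p_ref)


def test_kw_degenerate_identical_values():
    h, p, method = kruskal_test([np.zeros(30), np.zeros(40)])
    assert h == 0.0 and p == 1.0 and method == "degenerate_ties"


def test_kw_two_group_permutation_vs_bruteforce():
    # exact permutation p for n <= 8 checked against direct enumeration of
    # all label assignments using the rank-sum statistic
    a = np.array([1.0, 5.0, 7.0, 9.0])
    b = np.array([2.0, 3.0, 4.0, 6.0])
    h_obs, p_obs, method = kruskal_test([a, b])
    assert method == "exact_permutation"
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = len(pooled), len(a)

    def h_stat(idx_a):
        ra = ranks[list(idx_a)].sum()
        rb = ranks.sum() - ra
        h = 12.0 / (n * (n + 1)) * (ra**2 / na + rb**2 / (n - na)) - 3 * (n + 1)
        return h

    h_ref = h_stat(range(na))
    assert h_obs == pytest.approx(h_ref)
    combos = list(itertools.combinations(range(n), na))
    count = sum(h_stat(c) >= h_ref - 1e-12 for c in combos)
    assert p_obs == pytest.approx(count / len(combos))


def test_kw_errors():
    with pytest.raises(ValueError):
        kruskal_test([np.ones(3)])
    with pytest.raises(ValueError):
        kruskal_test([np.ones(3), np.array([])])


# --- divergence_scan ---------------------------------------------------------


def test_scan_skips_units_without_two_eligible_groups():
    table = _table({
        "ok": {"g1": list(range(15)), "g2": list(range(15))},
        "one_group": {"g1": list(range(15))},
        "small": {"g1": list(range(5)), "g2": list(range(5))},
    })
    scan = divergence_scan(table, min_reads=10)
    assert [c.unit for c in scan.comparisons] == ["ok"]
    assert set(scan.skipped["unit"]) == {"one_group", "small"}


def test_scan_power_two_groups():
    # medians 30 vs 90 with sd 10, n=50: significant after BH
    rng = np.random.default_rng(4)
    table = _table({
        "diff": {"a": list(rng.normal(30, 10, 50)), "b": list(rng.normal(90, 10, 50))},
        "same": {"a": list(rng.normal(30, 10, 50)), "b": list(rng.normal(30, 10, 50))},
    })
    scan = divergence_scan(table, min_reads=10, policy="q")
    by_unit = {c.unit: c for c in scan.comparisons}
    assert by_unit["diff"].significant
    assert not by_unit["same"].significant


def test_scan_null_calibration_500_units():
    # all groups from one distribution: fraction significant under raw p
    # approximates alpha, and BH keeps it at or below alpha
    rng = np.random.default_rng(8)
    groups = {}
    for u in range(500):
        groups[f"u{u}"] = {
            "a": list(np.abs(rng.normal(30, 10, 20))),
            "b": list(np.abs(rng.normal(30, 10, 20))),
        }
    scan = divergence_scan(_table(groups), min_reads=10, alpha=0.05)
    assert abs(scan.fraction_significant_p - 0.05) < 0.03
    assert scan.fraction_significant_q <= 0.05


def test_scan_bh_monotone_and_q_ge_p():
    rng = np.random.default_rng(12)
    groups = {
        f"u{u}": {"a": list(rng.normal(30, 10, 20)),
                  "b": list(rng.normal(30 + u, 10, 20))}
        for u in range(12)
    }
    scan = divergence_scan(_table(groups), min_reads=10)
    frame = scan.to_frame().sort_values("p_value")
    assert (frame["q_value"].values >= frame["p_value"].values - 1e-12).all()
    assert (np.diff(frame["q_value"].values) >= -1e-12).all()


def test_scan_single_test_q_equals_p():
    rng = np.random.default_rng(3)
    table = _table({"only": {"a": list(rng.normal(30, 10, 20)),
                             "b": list(rng.normal(40, 10, 20))}})
    scan = divergence_scan(table, min_reads=10)
    c = scan.comparisons[0]
    assert c.q_value == pytest.approx(c.p_value)


def test_scan_constant_values_not_significant():
    table = _table({"flat": {"a": [30.0] * 20, "b": [30.0] * 20}})
    scan = divergence_scan(table, min_reads=10)
    c = scan.comparisons[0]
    assert c.p_value == 1.0 and not c.significant


def test_scan_policy_flag():
    with pytest.raises(ValueError):
        divergence_scan(_table({"u": {"a": [1] * 15, "b": [2] * 15}}), policy="x")
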