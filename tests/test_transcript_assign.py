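import numpy as np
import pandas as pd
import pytest

from tailcap.models import AlignmentRecord, AnnotationBundle, TranscriptAnnotation
from tailcap.simulate import simulate_alignment_set, simulate_annotation
from tailcap.transcript_assign import (
    assign_all,
    assign_to_isoform,
    filter_complete_reads,
    quantify_rpm,
)


def _read_at(end, gene_strand="+", read_id="r", contig="c", span=80):
    """A read whose RNA 3' end sits at ``end`` on the given gene strand."""
    if gene_strand == "+":
        # forward-strand gene -> reverse-strand alignment; 3' end = ref_end
        return AlignmentRecord(read_id, contig, "-", end - span, end, 0, 0,
                               "A" * span)
    return AlignmentRecord(read_id, contig, "+", end, end + span, 0, 0,
                           "A" * span)


def _tx(tid, end, strand="+", gene=None, length=400, contig="c"):
    if strand == "+":
        exons = [(end - length, end)]
    else:
        exons = [(end, end + length)]
    return TranscriptAnnotation(tid, gene or tid.split(".")[0], contig, strand, exons)


# --- filter_complete_reads ---------------------------------------------------


def test_filter_keeps_exact_and_drops_internal():
    bundle = AnnotationBundle([_tx("g1.t1", 1000)], contigs={"c": ""})
    kept, rejects = filter_complete_reads(
        [_read_at(1000, read_id="exact"), _read_at(950, read_id="internal")],
        bundle,
    )
    assert [a.read_id for a in kept] == ["exact"]
    assert rejects.set_index("read_id").loc["internal", "reason"] == (
        "three_prime_end_internal"
    )


def test_filter_window_sweep_inclusive():
    bundle = AnnotationBundle([_tx("g1.t1", 1000)], contigs={"c": ""})
    for offset in range(-20, 21):
        kept, _ = filter_complete_reads([_read_at(1000 + offset)], bundle, window=10)
        assert bool(kept) == (abs(offset) <= 10), offset


def test_filter_empty_annotation_drops_all_with_reason():
    bundle = AnnotationBundle([], contigs={})
    kept, rejects = filter_complete_reads([_read_at(100), _read_at(200)], bundle)
    assert kept == []
    assert len(rejects) == 2
    assert (rejects["reason"] == "unknown_contig").all()


def test_filter_unknown_contig_warns_and_drops(caplog):
    bundle = AnnotationBundle([_tx("g1.t1", 1000)], contigs={"c": ""})
    read = _read_at(1000, contig="other")
    with caplog.at_level("WARNING"):
        kept, rejects = filter_complete_reads([read], bundle)
    assert kept == [] and rejects.iloc[0]["reason"] == "unknown_contig"
    assert any("unknown contig" in r.message for r in caplog.records)


def test_filter_strand_resolved():
    # an exon end on '+' does not rescue a read from a '-' gene
    bundle = AnnotationBundle([_tx("g1.t1", 1000, strand="+")], contigs={"c": ""})
    kept, _ = filter_complete_reads([_read_at(1000, gene_strand="-")], bundle)
    assert kept == []


# --- assign_to_isoform -------------------------------------------------------


def test_assign_window_sweep_exactly_pm10():
    tx = _tx("g1.t1", 1000)
    for offset in range(-20, 21):
        res = assign_to_isoform(_read_at(1000 + offset), [tx], window=10)
        if abs(offset) <= 10:
            assert res.status == "assigned"
            assert res.distance == offset
        else:
            assert res.status == "unassigned"


def test_assign_nearest_of_two_isoforms():
    t1, t2 = _tx("g1.t1", 1000), _tx("g1.t2", 1100, gene="g1")
    res = assign_to_isoform(_read_at(1096), [t1, t2])
    assert res.transcript_id == "g1.t2"
    assert res.distance == -4


def test_assign_tie_is_ambiguous():
    t1, t2 = _tx("g1.t1", 996), _tx("g1.t2", 1004, gene="g1")
    res = assign_to_isoform(_read_at(1000), [t1, t2])
    assert res.status == "ambiguous"
    assert res.transcript_id is None


def test_assign_strand_flip_changes_comparison():
    plus = _tx("g1.t1", 1000, strand="+")
    minus = _tx("g2.t1", 1000, strand="-")
    read_plus = _read_at(1000, gene_strand="+")
    read_minus = _read_at(1000, gene_strand="-")
    assert assign_to_isoform(read_plus, [plus, minus]).transcript_id == "g1.t1"
    assert assign_to_isoform(read_minus, [plus, minus]).transcript_id == "g2.t1"


def test_assign_signed_distance_orientation():
    # positive distance = read extends past the annotated 3' end
    plus = _tx("g1.t1", 1000, strand="+")
    assert assign_to_isoform(_read_at(1005), [plus]).distance == 5
    minus = _tx("g2.t1", 2000, strand="-")
    read = _read_at(1995, gene_strand="-")  # 5 nt past the end, 3'-ward
    assert assign_to_isoform(read, [minus]).distance == 5


def test_assign_count_conservation(annotation):
    records, _ = simulate_alignment_set(annotation, 300, seed=2)
    table = assign_all(records, annotation)
    counts = table["status"].value_counts()
    assert counts.sum() == 300
    assert set(counts.index) <= {"assigned", "unassigned", "ambiguous"}


def test_assign_recovers_simulated_transcript(annotation):
    # reads at zero offset from isoform ends must recover the truth
    records, truth = simulate_alignment_set(
        annotation, 200, seed=3, offset_range=(0, 0)
    )
    table = assign_all(records, annotation).set_index("read_id")
    # only genes whose two isoform ends are >2*window apart are unambiguous
    for row in truth.itertuples():
        res = table.loc[row.read_id]
        assert res["status"] == "assigned"
        assert res["transcript_id"] == row.transcript_id


# --- quantify_rpm ------------------------------------------------------------


def _assignments(counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    for gene, n in counts.items():
        for i in range(n):
            rows.append(
                {"read_id": f"{gene}_{i}", "gene_id": gene,
                 "transcript_id": f"{gene}.t1", "status": "assigned"}
            )
    return pd.DataFrame(rows)


def test_rpm_definition_and_sum():
    bundle = AnnotationBundle(
        [_tx("gA.t1", 1000), _tx("gB.t1", 5000)], contigs={"c": ""}
    )
    expr = quantify_rpm(_assignments({"gA": 5, "gB": 15}), bundle)
    t = expr.table.set_index("gene_id")
    assert expr.library_size == 20
    assert t.loc["gA", "rpm"] == pytest.approx(5 * 1e6 / 20)
    assert t["rpm"].sum() == pytest.approx(1e6, abs=1e-6)


def test_rpm_single_gene_is_million():
    bundle = AnnotationBundle([_tx("gA.t1", 1000)], contigs={"c": ""})
    expr = quantify_rpm(_assignments({"gA": 7}), bundle)
    assert expr.table.iloc[0]["rpm"] == pytest.approx(1e6)


def test_rpm_zero_assigned_invalid():
    bundle = AnnotationBundle([_tx("gA.t1", 1000)], contigs={"c": ""})
    empty = pd.DataFrame({"read_id": [], "gene_id": [], "status": []})
    with pytest.raises(ValueError):
        quantify_rpm(empty, bundle)


def test_rpm_replicate_correlation():
    # two libraries sampled from one abundance truth: per-gene log-RPM
    # correlation >= 0.95
    rng = np.random.default_rng(19)
    annotation = simulate_annotation(n_genes=30, seed=21, two_isoform_fraction=0.0)
    txs = [t.transcript_id for t in annotation.transcripts]
    abundance = rng.lognormal(0.0, 1.0, size=len(txs))
    weights = dict(zip(txs, abundance / abundance.sum()))
    rpms = []
    for seed in (101, 202):
        records, _ = simulate_alignment_set(
            annotation, 4000, seed=seed, transcript_weights=weights,
            offset_range=(-5, 5),
        )
        table = assign_all(records, annotation)
        expr = quantify_rpm(table, annotation).table.set_index("gene_id")["rpm"]
        rpms.append(expr)
    joined = pd.concat(rpms, axis=1, keys=["a", "b"]).dropna()
    assert len(joined) >= 25
    r = np.corrcoef(np.log10(joined["a"]), np.log10(joined["b"]))[0, 1]
    assert r >= 0.95
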