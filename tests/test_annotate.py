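import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sncaging.annotate import (AnnotationError, ReadSet, annotate,
                               annotate_cohort, class_summary, collapse_reads,
                               coverage, family_matrix, length_profile,
                               match_with_mismatch, rpm_normalize)
from sncaging.reference import PanelRecord, ReferencePanel

from conftest import TSRS


def naive_scan(read: str, parent: str, max_mm: int):
    """Oracle: check every placement with a character-by-character count."""
    hits = []
    for start in range(len(parent) - len(read) + 1):
        mm = sum(a != b for a, b in zip(read, parent[start:start + len(read)]))
        if mm <= max_mm:
            hits.append((start + 1, mm))
    return hits


def _panel_of(*records):
    return ReferencePanel([PanelRecord(*r) for r in records])


# ------------------------------------------------------------- collapsing


def test_collapse_counts_and_length_filter():
    rs = collapse_reads(["ACGU", "ACGT", "ACGT"])
    assert rs.total_clean_reads == 3
    assert rs.counts == {}  # 4-nt reads are below the gel window

    rs = collapse_reads(["ACGTACGTACGTACGTACGT"] * 3)
    assert rs.counts == {"ACGTACGTACGTACGTACGT": 3}
    assert rs.total_clean_reads == 3


def test_collapse_unifies_u_and_case():
    rs = collapse_reads(["acguacguacguacgu", "ACGTACGTACGTACGT"])
    assert rs.counts == {"ACGTACGTACGTACGT": 2}


def test_collapse_empty_input():
    rs = collapse_reads([])
    assert rs.counts == {} and rs.total_clean_reads == 0


# --------------------------------------------------------------- matching


def test_exact_substring_hit_reported_at_correct_start(panel):
    parent = panel["rRNA-28S"].sequence
    read = parent[9:29]  # 1-based start 10, 20 nt
    hits = match_with_mismatch(read, parent, 1, "rRNA-28S")
    assert any(h.start == 10 and h.mismatches == 0 for h in hits)


def test_two_substitutions_rejected_at_one_mismatch(panel):
    parent = panel["rRNA-28S"].sequence
    read = list(parent[9:29])
    for i in (3, 12):
        read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
    hits = match_with_mismatch("".join(read), parent, 1)
    assert not any(h.start == 10 for h in hits)


def test_repeated_placement_returns_all_hits_sorted():
    parent = "AAGG" + "ACGTACGTACGTACGTT" + "ACGTACGTACGTACGTT" + "CC"
    read = "ACGTACGTACGTACGTT"
    hits = match_with_mismatch(read, parent, 0)
    starts = [h.start for h in hits]
    assert starts == sorted(starts) and {5, 22} <= set(starts)


@settings(deadline=None, max_examples=40)
@given(st.data())
def test_vectorized_scan_equals_naive_oracle(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    parent = "".join(rng.choice(list("ACGT"), size=60))
    L = data.draw(st.integers(15, 30))
    start = data.draw(st.integers(0, 60 - 30))
    read = list(parent[start:start + L])
    # possibly inject up to 2 substitutions
    for _ in range(data.draw(st.integers(0, 2))):
        i = data.draw(st.integers(0, L - 1))
        read[i] = data.draw(st.sampled_from("ACGT"))
    read = "".join(read)
    for max_mm in (0, 1):
        got = [(h.start, h.mismatches)
               for h in match_with_mismatch(read, parent, max_mm)]
        assert got == naive_scan(read, parent, max_mm)


def test_mismatch_monotonicity(panel, rng):
    parent = panel["rRNA-18S"].sequence
    for _ in range(20):
        s = rng.integers(0, len(parent) - 20)
        read = list(parent[s:s + 20])
        i = rng.integers(0, 20)
        read[i] = "ACGT"[rng.integers(0, 4)]
        read = "".join(read)
        h0 = {(h.start, h.mismatches)
              for h in match_with_mismatch(read, parent, 0)}
        h1 = {(h.start, h.mismatches)
              for h in match_with_mismatch(read, parent, 1)}
        assert h0 <= h1


# ------------------------------------------------------------- assignment


@pytest.fixture()
def toy_panel():
    trna = "GCAT" * 17 + "TCCA"  # 72 nt, CCA-terminated
    rrna = "TTGACCGGTA" * 8  # 80 nt
    return _panel_of(("tRNA-X", "tRNA", "genomic", trna),
                     ("rRNA-X", "rRNA", "genomic", rrna))


def test_read_matching_single_class_assigned_there(toy_panel):
    read = toy_panel["rRNA-X"].sequence[10:30]
    rs = ReadSet({read: 5}, 5)
    ann = annotate(rs, toy_panel)
    assert ann.class_totals["rRNA"] == 5
    assert sum(c for (cls, *_), c in ann.tensor.items() if cls == "rRNA") == 5


def test_perfect_match_preempts_one_mismatch_across_classes(toy_panel):
    # read is an exact rRNA substring; one substitution would also place
    # it on the tRNA — build the converse: exact on rRNA, 1-mm on tRNA
    rrna = toy_panel["rRNA-X"].sequence
    read = rrna[0:20]
    # craft a panel where the tRNA contains the read with one mismatch
    mutated = read[:10] + ("A" if read[10] != "A" else "C") + read[11:]
    trna = mutated + "G" * 49 + "CCA"
    panel = _panel_of(("tRNA-X", "tRNA", "genomic", trna),
                      ("rRNA-X", "rRNA", "genomic", rrna))
    ann = annotate(ReadSet({read: 3}, 3), panel)
    # tRNA outranks rRNA in precedence, but its hit carries a mismatch
    assert ann.class_totals["rRNA"] == 3 and ann.class_totals["tRNA"] == 0


def test_precedence_breaks_equal_mismatch_ties(toy_panel):
    shared = "ACGTACGTACGTACGTACGT"
    trna = shared + "C" * 49 + "CCA"
    rrna = shared + "G" * 60
    panel = _panel_of(("tRNA-X", "tRNA", "genomic", trna),
                      ("rRNA-X", "rRNA", "genomic", rrna))
    ann = annotate(ReadSet({shared: 2}, 2), panel)
    assert ann.class_totals["tRNA"] == 2  # tRNA > rRNA


def test_multi_placement_count_split_equally():
    parent = "AATT" + "ACGTACGTACGTACGTC" + "ACGTACGTACGTACGTC"
    panel = _panel_of(("rRNA-X", "rRNA", "genomic", parent))
    read = "ACGTACGTACGTACGTC"
    ann = annotate(ReadSet({read: 4}, 4), panel)
    cells = {k: v for k, v in ann.tensor.items()}
    assert len(cells) == 2
    assert all(v == pytest.approx(2.0) for v in cells.values())
    assert ann.class_totals["rRNA"] == 4  # totals stay integral


def test_count_conservation(small_cohort):
    sid = small_cohort.sample_ids[0]
    ann = annotate_cohort({sid: small_cohort.reads[sid]},
                          small_cohort.panel,
                          small_cohort.design.depth)[sid]
    assert ann.unannotated + sum(ann.class_totals.values()) == \
        ann.total_clean_reads
    assert sum(ann.tensor.values()) == pytest.approx(
        sum(ann.class_totals.values()))


def test_unmatched_read_counted_as_unannotated(toy_panel):
    ann = annotate(ReadSet({"T" * 20: 7}, 10), toy_panel)
    assert ann.unannotated == 10  # 7 unmatched + 3 outside the read set
    assert sum(ann.class_totals.values()) == 0


# ---------------------------------------------------------- normalization


def test_rpm_arithmetic():
    row = rpm_normalize({"f": 5}, 20)
    assert row["f"] == pytest.approx(250_000.0)
    assert rpm_normalize({"f": 0}, 20)["f"] == 0.0


def test_rpm_rejects_zero_total():
    with pytest.raises(AnnotationError):
        rpm_normalize({"f": 1}, 0)


def test_rpm_scale_invariance(small_cohort):
    sid = small_cohort.sample_ids[0]
    reads = small_cohort.reads[sid]
    ann1 = annotate_cohort({sid: reads}, small_cohort.panel,
                           small_cohort.design.depth)
    doubled = {s: 2 * c for s, c in reads.items()}
    ann2 = annotate_cohort({sid: doubled}, small_cohort.panel,
                           2 * small_cohort.design.depth)
    m1 = family_matrix(ann1)
    m2 = family_matrix(ann2)
    pd.testing.assert_frame_equal(m1, m2)


# ------------------------------------------------- profiles and coverage


def test_length_profile_single_read():
    parent = "A" * 30 + "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTA"
    panel = _panel_of(("rRNA-X", "rRNA", "genomic", parent))
    read = parent[30:74]  # 44 nt
    ann = annotate_cohort({"s1": {read: 6}}, panel, 12)
    prof = length_profile(ann, classes=("rRNA",))
    assert prof.loc["s1", 44] == pytest.approx(6 / 12 * 1e6)
    assert prof.drop(columns=[44]).loc["s1"].sum() == 0


def test_length_profile_equals_tensor_marginal(small_cohort):
    sids = small_cohort.sample_ids[:3]
    ann = annotate_cohort({s: small_cohort.reads[s] for s in sids},
                          small_cohort.panel, small_cohort.design.depth)
    prof = length_profile(ann, parents=["rRNA-28S"])
    for sid in sids:
        marg = {}
        for (cls, parent, _s, L), c in ann[sid].tensor.items():
            if parent == "rRNA-28S":
                marg[L] = marg.get(L, 0.0) + c
        scale = 1e6 / ann[sid].total_clean_reads
        for L, c in marg.items():
            assert prof.loc[sid, L] == pytest.approx(c * scale)


def test_length_profile_empty_filter_rejected(small_cohort):
    sid = small_cohort.sample_ids[0]
    ann = annotate_cohort({sid: small_cohort.reads[sid]},
                          small_cohort.panel, small_cohort.design.depth)
    with pytest.raises(AnnotationError):
        length_profile(ann, classes=())


def test_coverage_single_hit_span():
    rng = np.random.default_rng(5)
    parent = "".join(rng.choice(list("ACGT"), size=80))
    panel = _panel_of(("rRNA-X", "rRNA", "genomic", parent))
    read = parent[9:26]  # start 10, L 17
    ann = annotate_cohort({"s1": {read: 2}}, panel, 4)
    cov = coverage(ann, panel, "rRNA-X", {"s1": "g"})
    r = 2 / 4 * 1e6
    sub = cov.set_index("position")
    inside = sub.loc[10:26, "mean"]
    assert np.allclose(inside, r)
    assert sub.loc[9, "mean"] == 0 and sub.loc[27, "mean"] == 0
    assert (sub["sem"] == 0).all()  # single sample: SEM reported as 0


def test_coverage_mean_and_sem_two_samples():
    rng = np.random.default_rng(6)
    parent = "".join(rng.choice(list("ACGT"), size=80))
    panel = _panel_of(("rRNA-X", "rRNA", "genomic", parent))
    read = parent[9:26]
    ann = annotate_cohort({"s1": {read: 1}, "s2": {read: 3}}, panel, 10)
    cov = coverage(ann, panel, "rRNA-X", {"s1": "g", "s2": "g"})
    r = 1e5  # RPM of one count in 10 reads
    at = cov.set_index("position").loc[15]
    # coverage r and 3r: mean 2r, sd = sqrt(2)*r, SEM = r
    assert at["mean"] == pytest.approx(2 * r)
    assert at["sem"] == pytest.approx(r)


def test_coverage_conserves_column_sums():
    # multi-placement read: total coverage mass == L x assigned RPM
    parent = "AATT" + "ACGTACGTACGTACGTC" + "ACGTACGTACGTACGTC"
    panel = _panel_of(("rRNA-X", "rRNA", "genomic", parent))
    read = "ACGTACGTACGTACGTC"
    ann = annotate_cohort({"s1": {read: 4}}, panel, 8)
    cov = coverage(ann, panel, "rRNA-X", {"s1": "g"})
    total = cov["mean"].sum()
    rpm = 4 / 8 * 1e6
    assert total == pytest.approx(len(read) * rpm)


def test_coverage_unknown_parent_rejected(toy_panel):
    ann = annotate_cohort({"s1": {"ACGT" * 5: 1}}, toy_panel, 1)
    with pytest.raises(AnnotationError, match="unknown parent"):
        coverage(ann, toy_panel, "nope", {"s1": "g"})


# ------------------------------------------------------------- round trip


def test_simulated_reads_reannotate_to_truth(small_cohort):
    """Every simulated read recovers its truth (parent, start) at 0 mm."""
    panel = small_cohort.panel
    ann = annotate_cohort(small_cohort.reads, panel,
                          small_cohort.design.depth)
    for sid in small_cohort.sample_ids:
        obs = {}
        for (cls, parent, start, L), c in ann[sid].tensor.items():
            obs[(parent, start, L)] = obs.get((parent, start, L), 0.0) + c
        truth = small_cohort.truth_counts[sid]
        assert ann[sid].unannotated == 0
        for key, c in truth.items():
            assert obs.get(key, 0.0) == pytest.approx(c)
    summary = class_summary(ann)
    assert (summary["unannotated"] == 0).all()
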