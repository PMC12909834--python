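import numpy as np
import pandas as pd
import pytest

from sncaging.coexpression import (CoexpressionError, cluster_families,
                                   enrich_all_clusters, fisher_mt_enrichment,
                                   pairwise_spearman, top_cluster)

from conftest import fisher_bruteforce, spearman_bruteforce


def _expr(cols: dict, n=None):
    return pd.DataFrame(cols, index=[f"s{i}" for i in
                                     range(len(next(iter(cols.values()))))])


# ----------------------------------------------------- pairwise correlation


def test_family_self_correlation_is_one(rng):
    E = _expr({"a": rng.random(8), "b": rng.random(8)})
    C = pairwise_spearman(E)
    assert np.allclose(np.diag(C), 1.0)
    assert C.equals(C.T)


def test_monotone_pair_fully_correlated(rng):
    x = rng.random(10)
    C = pairwise_spearman(_expr({"f": x, "g": 2 * x, "h": rng.random(10)}))
    assert C.loc["f", "g"] == pytest.approx(1.0)


def test_matrix_matches_per_pair_bruteforce(rng):
    E = pd.DataFrame(rng.integers(0, 40, size=(9, 10)).astype(float),
                     columns=[f"f{i}" for i in range(10)])
    C = pairwise_spearman(E)
    for i in range(10):
        for j in range(i + 1, 10):
            expect = spearman_bruteforce(E.iloc[:, i], E.iloc[:, j])
            assert C.iloc[i, j] == pytest.approx(expect)


def test_zero_variance_families_excluded(rng):
    E = _expr({"a": rng.random(6), "flat": np.full(6, 3.0),
               "b": rng.random(6)})
    C = pairwise_spearman(E)
    assert "flat" not in C.columns


def test_too_few_samples_rejected():
    with pytest.raises(CoexpressionError):
        pairwise_spearman(_expr({"a": [1.0, 2.0]}))


# --------------------------------------------------------------- clustering


def test_two_perfect_blocks_recovered(rng):
    base1, base2 = rng.random(12), rng.random(12)
    cols = {f"a{i}": base1 + rng.random(12) * 1e-3 for i in range(3)}
    cols |= {f"b{i}": base2 + rng.random(12) * 1e-3 for i in range(3)}
    C = pairwise_spearman(_expr(cols))
    asg = cluster_families(C, 2)
    la = {asg.labels[f] for f in ("a0", "a1", "a2")}
    lb = {asg.labels[f] for f in ("b0", "b1", "b2")}
    assert len(la) == 1 and len(lb) == 1 and la != lb


def test_complete_linkage_merge_heights_match_hand_agglomeration():
    # four points on a line (0, 1, 4, 10), embedded as constant rows of
    # a square matrix so row distances are 2|v_i - v_j| (factor sqrt(4)).
    # Hand agglomeration (complete linkage) on |v_i - v_j|: merge {a,b}
    # at 1; then {a,b}-{c} at max(4,3)=4; finally {d} at max(10,9,6)=10.
    v = np.array([0.0, 1.0, 4.0, 10.0])
    C = pd.DataFrame(np.tile(v[:, None], (1, 4)), index=list("abcd"),
                     columns=list("abcd"))
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist
    Z = hierarchy.linkage(pdist(C.to_numpy()), method="complete")
    heights = sorted(Z[:, 2])
    assert heights == pytest.approx([2.0, 8.0, 20.0])  # 2x hand heights
    asg = cluster_families(C, 2)
    assert asg.labels["a"] == asg.labels["b"] == asg.labels["c"]
    assert asg.labels["d"] != asg.labels["a"]


def test_family_order_permutation_invariance(rng):
    E = pd.DataFrame(rng.random((10, 6)),
                     columns=[f"f{i}" for i in range(6)])
    C = pairwise_spearman(E)
    perm = C.sample(frac=1, axis=0, random_state=0)
    perm = perm.loc[:, perm.index]
    a = cluster_families(C, 3)
    b = cluster_families(perm, 3)

    def partition(asg):
        groups = {}
        for fam, cl in asg.labels.items():
            groups.setdefault(cl, set()).add(fam)
        return {frozenset(g) for g in groups.values()}

    assert partition(a) == partition(b)


def test_oversized_k_rejected(rng):
    C = pairwise_spearman(pd.DataFrame(rng.random((5, 3)),
                                       columns=list("abc")))
    with pytest.raises(CoexpressionError):
        cluster_families(C, 4)


def test_heatmap_leaf_order_covers_all_families(rng):
    C = pairwise_spearman(pd.DataFrame(rng.random((8, 6)),
                                       columns=[f"f{i}" for i in range(6)]))
    asg = cluster_families(C, 3)
    assert sorted(asg.leaf_order) == sorted(C.columns)


# ------------------------------------------------------------------ Fisher


def _make_assignment(members: dict[str, int]):
    fams = sorted(members)
    C = pd.DataFrame(np.eye(len(fams)), index=fams, columns=fams)
    from sncaging.coexpression import ClusterAssignment
    return ClusterAssignment(pd.Series(members), np.empty((0, 4)),
                             len(set(members.values())), fams)


def _enrichment_for_table(a, b, c, d):
    members = {}
    origins = {}
    i = 0
    for count, (cl, mt) in [(a, (1, True)), (b, (1, False)),
                            (c, (2, True)), (d, (2, False))]:
        for _ in range(count):
            members[f"f{i}"] = cl
            origins[f"f{i}"] = "mitochondrial" if mt else "genomic"
            i += 1
    asg = _make_assignment(members)
    return fisher_mt_enrichment(asg, pd.Series(origins), 1)


def test_balanced_table_hand_enumeration():
    res = _enrichment_for_table(3, 1, 1, 3)
    assert res.pvalue == pytest.approx(34 / 70, rel=1e-9)
    assert res.table == (3, 1, 1, 3)
    assert res.odds_ratio == pytest.approx(9.0)


def test_extreme_table_hand_enumeration():
    res = _enrichment_for_table(10, 0, 0, 10)
    assert res.pvalue == pytest.approx(2 / 184756, rel=1e-9)
    assert np.isinf(res.odds_ratio)


def test_degenerate_margin_flagged():
    res = _enrichment_for_table(0, 3, 0, 5)  # no mitochondrial families
    assert res.degenerate and res.pvalue == 1.0


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 12, size=4)
        if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
            continue  # degenerate margins / empty cluster
        res = _enrichment_for_table(int(a), int(b), int(c), int(d))
        assert res.pvalue == pytest.approx(
            fisher_bruteforce(int(a), int(b), int(c), int(d)), rel=1e-9)


def test_all_cluster_report_applies_bonferroni():
    members = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3}
    origins = {f: ("mitochondrial" if f in "ab" else "genomic")
               for f in members}
    asg = _make_assignment(members)
    table = enrich_all_clusters(asg, pd.Series(origins))
    assert len(table) == 3
    assert (table["p_adj"] >= table["p"]).all()
    assert (table["p_adj"] <= 1.0).all()


# --------------------------------------------------- simulated mt recovery


def test_top_cluster_prefers_blocks_over_pairs(rng):
    base = rng.normal(size=30)
    cols = {f"blk{i}": base + rng.normal(0, 0.05, 30) for i in range(4)}
    cols["p1"] = rng.normal(size=30)
    cols["p2"] = cols["p1"] + rng.normal(0, 1e-4, 30)  # near-perfect pair
    cols["lone"] = rng.normal(size=30)
    C = pairwise_spearman(pd.DataFrame(cols,
                                       index=[f"s{i}" for i in range(30)]))
    asg = cluster_families(C, 3)
    top = top_cluster(C, asg)
    # the near-perfect pair has the higher mean correlation but is not a
    # block; the 4-family block wins under the size floor
    assert set(asg.members(top)) == {"blk0", "blk1", "blk2", "blk3"}


def test_simulated_mt_block_is_top_and_enriched(counts_cohort):
    fam = counts_cohort.family_rpm(classes=("rRNA", "tRNA",
                                            "mt_rRNA", "mt_tRNA"))
    C = pairwise_spearman(fam)
    asg = cluster_families(C, 5)
    top = top_cluster(C, asg)
    res = fisher_mt_enrichment(asg, pd.Series(counts_cohort.panel.origins()),
                               top)
    a, b, c, d = res.table
    assert a == 4  # all four mt families inside the tested block
    assert res.pvalue < 0.01
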