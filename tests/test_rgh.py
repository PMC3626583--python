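"""RGH classification grammar, cluster detection, NJ phylogeny, sequence support."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cucumap import rgh
from cucumap import synthetic_data as sd


def _gene(gid, start, end, chrom="chr1", scaffold="s1", domains=("NB",)):
    return rgh.RghGene(gid, scaffold, start, end, domains, chrom)


# ---------------------------------------------------------------------------
# Classification grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "domains,expected",
    [
        (("CC", "NB", "LRR"), "CNL"),
        (("TIR", "NB", "LRR"), "TNL"),
        (("NB",), "N"),
        (("CC", "NB"), "CN"),
        (("TIR", "NB"), "TN"),
        (("NB", "LRR"), "NL"),
        (("other", "NB", "other", "LRR"), "NL"),
        (("LRR", "NB"), "N"),  # LRR before NB is not a C-terminal LRR
        (("CC", "NB", "NB", "LRR"), "CNL"),
    ],
)
def test_class_grammar(domains, expected):
    assert rgh.classify_architecture(domains) == expected


def test_no_nb_is_not_an_rgh():
    with pytest.raises(rgh.NotAnRghError):
        rgh.classify_architecture(("CC", "LRR"))


def test_cc_and_tir_together_unclassified_with_warning():
    with pytest.warns(UserWarning, match="unclassified"):
        assert rgh.classify_architecture(("CC", "TIR", "NB")) == rgh.UNCLASSIFIED


@given(st.lists(st.sampled_from(["CC", "TIR", "NB", "LRR", "other"]), min_size=1, max_size=6))
def test_classification_total_and_deterministic(domains):
    import warnings

    if "NB" not in domains:
        with pytest.raises(rgh.NotAnRghError):
            rgh.classify_architecture(domains)
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = rgh.classify_architecture(domains)
        b = rgh.classify_architecture(domains)
    assert a == b
    assert a in rgh.RGH_CLASSES or a == rgh.UNCLASSIFIED


def test_class_counts_sum_to_input(default_truth):
    counts = rgh.class_counts(default_truth.rgh_genes)
    assert sum(counts.values()) == len(default_truth.rgh_genes) == 70
    assert counts == {"CNL": 25, "TNL": 19, "NL": 17, "TN": 5, "N": 3, "CN": 1}


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------


def test_two_genes_within_window_form_cluster():
    genes = [_gene("a", 1, 3000), _gene("b", 500_000, 503_000)]
    clusters = rgh.detect_clusters(genes)
    assert len(clusters) == 1
    assert clusters[0].members == ["a", "b"]


def test_exact_one_mbp_span_is_not_a_cluster():
    # strict reading: span must be < 1,000,000 bp
    genes = [_gene("a", 1, 3000), _gene("b", 997_001, 1_000_000)]
    assert rgh.detect_clusters(genes) == []
    genes = [_gene("a", 1, 3000), _gene("b", 997_000, 999_999)]
    assert len(rgh.detect_clusters(genes)) == 1


def _oracle_clusters(positions, max_span=1_000_000):
    """O(n^2) all-windows oracle: for every start, the farthest end index with
    span below threshold, then a left-to-right cover of maximal runs."""
    n = len(positions)
    reach = []
    for i in range(n):
        j_best = i
        for j in range(i, n):
            if positions[j][1] - positions[i][0] + 1 < max_span:
                j_best = j
        reach.append(j_best)
    out, i = [], 0
    while i < n:
        j = reach[i]
        if j > i:
            out.append(list(range(i, j + 1)))
        i = j + 1
    return out


def test_cluster_detection_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(1, 25))
        starts = np.sort(rng.integers(1, 5_000_000, n))
        genes = [_gene(f"g{k:02d}", int(s), int(s) + 2999) for k, s in enumerate(starts)]
        got = [c.members for c in rgh.detect_clusters(genes)]
        expected = [[f"g{k:02d}" for k in run]
                    for run in _oracle_clusters([(g.start_bp, g.end_bp) for g in genes])]
        assert got == expected


def test_planted_table_cluster_sizes_recovered(default_truth):
    genes = [rgh.RghGene(g.id, g.scaffold_id, g.start_bp, g.end_bp,
                         g.domain_architecture, g.chromosome)
             for g in default_truth.rgh_genes]
    clusters = rgh.detect_clusters(genes)
    assert len(clusters) == 9
    clustered = sum(len(c.members) for c in clusters)
    assert clustered == 52
    assert round(100 * clustered / len(genes)) == 74


# ---------------------------------------------------------------------------
# Cluster statistics
# ---------------------------------------------------------------------------


def _cluster(n, span_bp):
    genes = [f"g{k}" for k in range(n)]
    return rgh.RghCluster("c1", "chr1", ("s1",), genes, span_bp, 1, span_bp)


@pytest.mark.parametrize("n,span_kb,expected", [(5, 43.4, 11.5), (11, 288.8, 3.8), (2, 200.0, 1.0)])
def test_density_per_100kb(n, span_kb, expected):
    stats = rgh.cluster_stats(_cluster(n, int(span_kb * 1000)))
    assert stats["density_per_100kb"] == expected


def test_density_formula_inverts_to_member_count():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        span = int(rng.integers(10_000, 999_000))
        c = _cluster(n, span)
        assert c.density_per_100kb * c.span_kb / 100.0 == pytest.approx(n)


def test_zero_span_cluster_reports_infinite_density_with_warning():
    genes = [f"g{k}" for k in range(2)]
    with pytest.warns(UserWarning, match="zero physical span"):
        stats = rgh.cluster_stats(rgh.RghCluster("c0", "chr1", ("s1",), genes, 0, 100, 99))
    assert stats["density_per_100kb"] == float("inf")


def test_genetic_span_from_tag_positions():
    stats = rgh.cluster_stats(_cluster(2, 100_000), {"g0": 10.0, "g1": 12.5})
    assert stats["genetic_span_cm"] == 2.5


# ---------------------------------------------------------------------------
# NB domain extraction
# ---------------------------------------------------------------------------


def test_nb_extraction_spans():
    pep = "M" * 9 + "NBDOMAIN" * 15 + "X" * 71  # 200 aa
    assert rgh.extract_nb_domain(pep, (1, len(pep))) == pep
    assert len(rgh.extract_nb_domain(pep, (10, 129))) == 120
    with pytest.raises(rgh.AnnotationError):
        rgh.extract_nb_domain(pep, (10, 300))


def test_incomplete_nb_domains_excluded_from_phylogeny(default_truth):
    nb = rgh.nb_domain_set(default_truth.rgh_genes)
    assert len(nb) == 58  # 70 genes, 12 with incomplete NB spans


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def test_nj_reconstructs_hand_built_additive_matrix():
    names = ["A", "B", "C", "D"]
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    tree = rgh.nj_from_distances(names, d)
    assert tree.bipartitions() == {frozenset({"A", "B"})}
    # exact branch lengths: A:1 B:2 C:3 D:4, internal edge 1
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                assert tree.leaf_distance(a, b) == pytest.approx(d[i, j], abs=1e-12)


def test_nj_three_taxa_three_point_formulas():
    names = ["A", "B", "C"]
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
    tree = rgh.nj_from_distances(names, d)
    # l(A) = (2+3-5)/2 = 0, l(B) = 2, l(C) = 3
    assert tree.leaf_distance("A", "B") == pytest.approx(2.0)
    assert tree.leaf_distance("A", "C") == pytest.approx(3.0)
    assert tree.leaf_distance("B", "C") == pytest.approx(5.0)


def test_nj_matches_skbio_on_random_additive_matrices():
    """Independent oracle: scikit-bio's NJ on random additive matrices gives
    the same topology (bipartition set)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(4, 9))
        names, dist = _random_additive_matrix(rng, n)
        ours = rgh.nj_from_distances(names, dist).bipartitions()
        sk = skbio_nj(DistanceMatrix(dist, names))
        all_leaves = frozenset(names)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n - 1:
                theirs.add(rgh._canon(side, all_leaves))
        assert ours == theirs


def _random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> exact leaf distance
    matrix.  Each agglomeration node records every leaf's path length to the
    current subtree root, so cross-subtree pair distances are exact."""
    names = [f"t{k}" for k in range(n)]
    d = np.zeros((n, n))
    nodes = [{k: 0.0} for k in range(n)]  # leaf index -> distance to subtree root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        la, lb = rng.uniform(0.5, 3.0, 2)
        for leaf_a, da in a.items():
            for leaf_b, db in b.items():
                d[leaf_a, leaf_b] = d[leaf_b, leaf_a] = da + la + db + lb
        merged = {leaf: dd + la for leaf, dd in a.items()}
        merged.update({leaf: dd + lb for leaf, dd in b.items()})
        nodes.append(merged)
    return names, d


def test_nj_needs_three_sequences():
    with pytest.raises(rgh.AnnotationError):
        rgh.nj_from_distances(["A", "B"], np.zeros((2, 2)))


def test_p_distance_pairwise_gap_deletion():
    names, d = rgh.p_distance_matrix({"a": "AAAA", "b": "AA-T", "c": "AAAT"})
    i, j = names.index("a"), names.index("b")
    assert d[i, j] == pytest.approx(1 / 3)  # 3 shared columns, 1 mismatch
    with pytest.raises(rgh.AnnotationError):
        rgh.p_distance_matrix({"a": "AAA", "b": "AAAA"})


def test_bootstrap_supports_reproducible_and_bounded(default_truth):
    nb = dict(list(rgh.nb_domain_set(default_truth.rgh_genes).items())[:12])
    t1 = rgh.nj_tree(nb, n_bootstrap=100, seed=5)
    t2 = rgh.nj_tree(nb, n_bootstrap=100, seed=5)
    assert t1.support == t2.support
    assert all(0.0 <= s <= 100.0 for s in t1.support.values())


def test_planted_clades_recovered_with_high_support(default_truth):
    """The two planted NB motif clades (CNL-like / TNL-like) are recovered as
    bipartitions with >= 95% bootstrap support."""
    nb = rgh.nb_domain_set(default_truth.rgh_genes)
    tree = rgh.nj_tree(nb, n_bootstrap=200, seed=2)
    all_leaves = frozenset(nb)
    for clade_name in ("CNL", "TNL"):
        clade = frozenset(g.id for g in default_truth.rgh_genes
                          if g.nb_span and g.clade == clade_name)
        support = tree.support.get(rgh._canon(clade, all_leaves))
        assert support is not None and support >= 95.0


# ---------------------------------------------------------------------------
# EST support / orthologs
# ---------------------------------------------------------------------------


def test_est_support_thresholds(seq_truth, rng):
    truth, bundle = seq_truth
    gene = truth.rgh_genes[0]
    cds = bundle.gene_cds[gene.id]
    # planted exact copy: supported
    assert rgh.est_support(cds, [("e1", cds, "leaf")])[0]
    # 94% identity stays below the 95% threshold
    low = sd._mutate(np.random.default_rng(1), cds, 0.06, "ACGT")
    assert not rgh.est_support(cds, [("e1", low, "leaf")])[0]
    # 80% coverage stays below the 90% threshold
    frag = cds[: int(0.8 * len(cds))]
    assert not rgh.est_support(cds, [("e1", frag, "leaf")])[0]
    # empty set flagged "no data"
    supported, hits, tissues = rgh.est_support(cds, [])
    assert (supported, hits, tissues) == (False, 0, {"no data": 0})


def test_all_expressed_genes_have_est_support(seq_truth):
    truth, bundle = seq_truth
    by_gene = {}
    for e in bundle.ests:
        by_gene.setdefault(e.gene_id, []).append((e.id, e.sequence, e.tissue))
    n_supported = sum(
        rgh.est_support(bundle.gene_cds[g.id], by_gene.get(g.id, []))[0]
        for g in truth.rgh_genes)
    assert n_supported == len(truth.rgh_genes) == 70


def test_ortholog_calling_rules(seq_truth):
    truth, bundle = seq_truth
    fixture = sd.simulate_ortholog_set(truth, bundle.gene_cds, seed=4,
                                       n_subject_duplicates=1)
    query = {g.id: (bundle.gene_cds[g.id], g.chromosome, g.start_bp)
             for g in truth.rgh_genes}
    subject = {s.id: (s.sequence, s.chromosome, s.position_bp)
               for s in fixture.subject_genes}
    calls = {c.query_id: c for c in rgh.call_orthologs(query, subject,
                                                       fixture.synteny_blocks)}
    orthologs = {q for q, c in calls.items() if c.status == "ortholog"}
    in_synteny = {q for q, c in calls.items() if c.in_synteny}
    assert orthologs == fixture.expected_orthologs
    assert in_synteny == fixture.expected_in_synteny
    # the planted duplicate is rejected as paralogous
    dup_query = sorted(fixture.expected_orthologs ^ {
        c.query_id for c in calls.values() if c.status in ("ortholog", "paralogous")})
    assert any(c.status == "paralogous" for c in calls.values())
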