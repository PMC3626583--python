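"""Two-point estimation, map functions, grouping, ordering, cleaning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cucumap import linkage as lk
from cucumap import synthetic_data as sd
from cucumap.genotypes import F2, RIL, GenotypeMatrix


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r,fn,expected",
    [
        (0.0, "kosambi", 0.0),
        (0.0, "haldane", 0.0),
        (0.2, "kosambi", 21.18),
        (0.2, "haldane", 25.54),
    ],
)
def test_map_function_closed_forms(r, fn, expected):
    assert lk.rf_to_cm(r, fn) == pytest.approx(expected, abs=5e-3)


def test_map_function_inverses():
    assert lk.cm_to_rf(0.0, "kosambi") == 0.0
    assert lk.cm_to_rf(21.18, "kosambi") == pytest.approx(0.2, abs=1e-3)


@given(st.floats(min_value=0.0, max_value=0.499), st.sampled_from(["kosambi", "haldane"]))
def test_map_function_roundtrip(r, fn):
    assert lk.cm_to_rf(lk.rf_to_cm(r, fn), fn) == pytest.approx(r, abs=1e-10)


@given(st.floats(min_value=1e-4, max_value=0.4999))
def test_kosambi_below_haldane(r):
    # partial interference compresses distances relative to no interference
    assert lk.rf_to_cm(r, "kosambi") < lk.rf_to_cm(r, "haldane")


def test_map_function_domain_errors():
    with pytest.raises(lk.LinkageError):
        lk.rf_to_cm(0.5)
    with pytest.raises(lk.LinkageError):
        lk.cm_to_rf(-1.0)


# ---------------------------------------------------------------------------
# Pairwise estimation
# ---------------------------------------------------------------------------


def test_ril_identical_vectors_give_zero_rf():
    col = ["A", "B", "A", "B", "B", "A"]
    est = lk.estimate_rf(col, col, RIL)
    assert est.r_hat == 0.0
    assert est.lod > 0
    assert est.n_informative == 6


def test_ril_observed_third_corrects_to_quarter():
    # R = 2/6 = 1/3  ->  r = R / (2(1-R)) = 0.25
    a = ["A", "A", "A", "B", "B", "B"]
    b = ["A", "A", "B", "A", "B", "B"]
    est = lk.estimate_rf(a, b, RIL)
    assert est.r_hat == pytest.approx(0.25, abs=1e-12)
    assert lk.ril_observed_to_meiotic(1 / 3) == pytest.approx(0.25, abs=1e-12)


def test_ril_heterozygotes_warn_and_become_missing():
    a = ["A", "H", "A", "B"]
    b = ["A", "A", "A", "B"]
    with pytest.warns(UserWarning, match="missing"):
        est = lk.estimate_rf(a, b, RIL)
    assert est.n_informative == 3


def test_estimate_rf_no_informative_pairs_errors():
    with pytest.raises(lk.LinkageError):
        lk.estimate_rf(["A", "-"], ["-", "B"], RIL)


def _grid_mle(counts: np.ndarray) -> float:
    """Independent oracle: 1e-4-step grid search of the F2 multinomial
    likelihood over r in [0, 0.5]."""
    rs = np.arange(0.0, 0.5 + 1e-12, 1e-4)
    q = 1 - rs
    p = {
        (0, 0): q * q / 4, (2, 2): q * q / 4,
        (0, 2): rs * rs / 4, (2, 0): rs * rs / 4,
        (0, 1): rs * q / 2, (1, 0): rs * q / 2, (1, 2): rs * q / 2, (2, 1): rs * q / 2,
        (1, 1): (q * q + rs * rs) / 2,
    }
    ll = np.zeros_like(rs)
    for (i, j), probs in p.items():
        n = counts[i, j]
        if n > 0:
            with np.errstate(divide="ignore"):
                ll = ll + n * np.log(probs)
    return float(rs[int(np.argmax(ll))])


def test_f2_em_matches_grid_search_oracle():
    """EM estimate equals the grid-search MLE within 1e-4 on random pairs."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        true_r = rng.uniform(0.02, 0.45)
        d = lk.rf_to_cm(true_r, "haldane")
        cfg = sd.TruthConfig(n_chromosomes=1, chromosome_length_cm=max(2 * d, 20),
                             markers_per_chromosome=2, scaffolds_per_chromosome=2,
                             cluster_plan=[], singletons_per_chromosome=(0,),
                             class_counts={}, n_incomplete_nb=0, n_unanchorable=0,
                             suppression=(), marker_jitter=0.0,
                             seed=int(rng.integers(1 << 30)))
        truth = sd.simulate_truth(cfg)
        truth.markers[1].true_cm = truth.markers[0].true_cm + d
        m = sd.simulate_population(truth, sd.CrossDesign(
            "F2", 100, missing_rate=0.0, genotyping_error_rate=0.0,
            seed=int(rng.integers(1 << 30)), apply_suppression=False))
        counts = lk._pair_class_counts(m.calls)[:, :, 0, 1]
        est = lk.estimate_rf(m.calls[0], m.calls[1], F2)
        oracle = _grid_mle(counts)
        assert abs(min(est.r_hat, 0.5) - oracle) <= 1e-4 + 5e-5


def test_f2_em_recovers_simulated_r():
    """At 10 cM (simulated under the inverse of the map function used to set
    the distance), the EM estimate falls within 3 binomial s.e. of truth."""
    r_true = lk.cm_to_rf(10.0, "haldane")  # simulation is interference-free
    cfg = sd.TruthConfig(n_chromosomes=1, chromosome_length_cm=30,
                         markers_per_chromosome=2, scaffolds_per_chromosome=2,
                         cluster_plan=[], singletons_per_chromosome=(0,), class_counts={},
                         n_incomplete_nb=0, n_unanchorable=0, suppression=(),
                         marker_jitter=0.0, seed=9)
    truth = sd.simulate_truth(cfg)
    truth.markers[0].true_cm, truth.markers[1].true_cm = 5.0, 15.0
    m = sd.simulate_population(truth, sd.CrossDesign(
        "F2", 5000, missing_rate=0.0, genotyping_error_rate=0.0, seed=10))
    est = lk.estimate_rf(m.calls[0], m.calls[1], F2)
    se = math.sqrt(r_true * (1 - r_true) / (2 * 5000))  # 2n gametes
    assert abs(est.r_hat - r_true) < 3 * se


def test_lod_zero_iff_unlinked():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 3, 2000).astype(np.int8)
    b = rng.integers(0, 3, 2000).astype(np.int8)
    est = lk.estimate_rf(a, b, F2)
    assert 0.0 <= est.r_hat <= 0.5
    assert est.lod >= 0
    if est.r_hat == 0.5:
        assert est.lod == 0.0


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def test_grouping_recovers_two_chromosomes():
    cfg = sd.TruthConfig(n_chromosomes=2, markers_per_chromosome=8,
                         scaffolds_per_chromosome=2, cluster_plan=[],
                         singletons_per_chromosome=(0, 0), class_counts={},
                         n_incomplete_nb=0, n_unanchorable=0, suppression=(), seed=8)
    truth = sd.simulate_truth(cfg)
    m = sd.simulate_population(truth, sd.CrossDesign("F2", 150, seed=8))
    groups = lk.group_markers(lk.estimate_rf_matrix(m))
    truth_groups = {}
    for mk in truth.markers:
        truth_groups.setdefault(mk.chromosome, set()).add(mk.id)
    assert sorted(map(set, groups), key=min) == sorted(truth_groups.values(), key=min)


def test_grouping_infinite_threshold_gives_singletons():
    rng = np.random.default_rng(1)
    m = GenotypeMatrix([f"m{i}" for i in range(5)], [f"i{j}" for j in range(20)],
                       rng.integers(0, 3, (5, 20)).astype(np.int8), F2)
    groups = lk.group_markers(lk.estimate_rf_matrix(m), lod_threshold=float("inf"))
    assert all(len(g) == 1 for g in groups)
    assert len(groups) == 5


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


def test_ordering_matches_exhaustive_sarf_minimum():
    """Greedy + 2-opt reaches the exhaustive-permutation SARF minimum for
    groups of <= 8 markers (20 random instances)."""
    rng = np.random.default_rng(7)
    for inst in range(20):
        n = int(rng.integers(4, 9))
        cfg = sd.TruthConfig(n_chromosomes=1, markers_per_chromosome=n,
                             chromosome_length_cm=40, scaffolds_per_chromosome=2,
                             cluster_plan=[], singletons_per_chromosome=(0,),
                             class_counts={}, n_incomplete_nb=0, n_unanchorable=0,
                             suppression=(), seed=300 + inst)
        truth = sd.simulate_truth(cfg)
        m = sd.simulate_population(truth, sd.CrossDesign("F2", 150, seed=400 + inst))
        table = lk.estimate_rf_matrix(m)
        order = lk.order_markers(m.marker_ids, table)
        best = min(
            lk.sarf(list(p), table) for p in itertools.permutations(m.marker_ids)
        )
        assert lk.sarf(order, table) == pytest.approx(best, abs=1e-9)


def test_two_marker_order_is_canonical():
    m = GenotypeMatrix(["b", "a"], ["i1", "i2", "i3"],
                       np.array([[0, 2, 0], [0, 2, 0]], dtype=np.int8), RIL)
    table = lk.estimate_rf_matrix(m)
    assert lk.order_markers(["b", "a"], table) == ["a", "b"]


def test_ordering_recovers_true_order_at_n200():
    cfg = sd.TruthConfig(n_chromosomes=1, markers_per_chromosome=30,
                         scaffolds_per_chromosome=2, cluster_plan=[],
                         singletons_per_chromosome=(0,), class_counts={},
                         n_incomplete_nb=0, n_unanchorable=0, suppression=(), seed=31)
    truth = sd.simulate_truth(cfg)
    m = sd.simulate_population(truth, sd.CrossDesign("F2", 200, seed=32))
    table = lk.estimate_rf_matrix(m)
    order = lk.order_markers(m.marker_ids, table)
    true_cm = {mk.id: mk.true_cm for mk in truth.markers}
    from scipy.stats import spearmanr

    r, _ = spearmanr(range(len(order)), [true_cm[x] for x in order])
    assert abs(r) >= 0.99


# ---------------------------------------------------------------------------
# Double-crossover cleaning
# ---------------------------------------------------------------------------


def test_cleaning_error_free_matrix_has_no_flags():
    cfg = sd.TruthConfig(n_chromosomes=1, markers_per_chromosome=10,
                         chromosome_length_cm=5.0,  # tight map: doubles absent
                         scaffolds_per_chromosome=2, cluster_plan=[],
                         singletons_per_chromosome=(0,), class_counts={},
                         n_incomplete_nb=0, n_unanchorable=0, suppression=(), seed=12)
    truth = sd.simulate_truth(cfg)
    m = sd.simulate_population(truth, sd.CrossDesign(
        "F2", 100, missing_rate=0.0, genotyping_error_rate=0.0, seed=13))
    order = [mk.id for mk in sorted(truth.markers, key=lambda x: x.true_cm)]
    _, report = lk.clean_double_crossovers(m, order)
    assert sum(report.values()) == 0


def test_cleaning_flags_planted_switch():
    calls = np.array([[0], [2], [0]], dtype=np.int8)  # A -> B -> A in one line
    m = GenotypeMatrix(["m1", "m2", "m3"], ["i1"], calls, RIL)
    cleaned, report = lk.clean_double_crossovers(m, ["m1", "m2", "m3"])
    assert report == {"m1": 0, "m2": 1, "m3": 0}
    assert cleaned.row("m2")[0] == -1


def test_cleaning_flag_count_tracks_planted_error_rate():
    """On a tight map, flags approximate the planted error count (+-25%)."""
    cfg = sd.TruthConfig(n_chromosomes=1, markers_per_chromosome=60,
                         chromosome_length_cm=10.0, scaffolds_per_chromosome=2,
                         cluster_plan=[], singletons_per_chromosome=(0,),
                         class_counts={}, n_incomplete_nb=0, n_unanchorable=0,
                         suppression=(), seed=14)
    truth = sd.simulate_truth(cfg)
    m = sd.simulate_population(truth, sd.CrossDesign(
        "F2", 200, missing_rate=0.0, genotyping_error_rate=0.01, seed=15))
    order = [mk.id for mk in sorted(truth.markers, key=lambda x: x.true_cm)]
    _, report = lk.clean_double_crossovers(m, order)
    planted = 0.01 * 60 * 200
    assert planted * 0.75 <= sum(report.values()) <= planted * 1.25


# ---------------------------------------------------------------------------
# Component map construction
# ---------------------------------------------------------------------------


def test_two_marker_fully_linked_map():
    row = np.tile([0, 2], 15).astype(np.int8)
    calls = np.vstack([row, row])
    m = GenotypeMatrix(["m1", "m2"], [f"i{k}" for k in range(30)], calls, RIL)
    res = lk.build_component_map(m, lk.MapParams(clean=False))
    lg = res.component_map.linkage_groups[0]
    assert [l.cm for l in lg.loci] == [0.0, 0.0]
    assert len(res.component_map.linkage_groups) == 1


def test_component_map_total_length_within_15_percent(default_truth, three_populations):
    res = lk.build_component_map(three_populations["CSS-F2"], lk.MapParams())
    total = res.component_map.total_length_cm
    assert len(res.component_map.linkage_groups) == 7
    assert abs(total - 700.0) / 700.0 < 0.15


def test_adding_markers_grows_locus_count(three_populations):
    m = three_populations["CSS-F2"]
    base = m.subset(m.marker_ids[:40])
    extended = m.subset(m.marker_ids[:48])
    res_a = lk.build_component_map(base, lk.MapParams())
    res_b = lk.build_component_map(extended, lk.MapParams())
    assert res_b.component_map.n_loci == res_a.component_map.n_loci + 8
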