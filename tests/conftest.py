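import numpy as np
import pytest
from hypothesis import settings

from cucumap import linkage as lk
from cucumap import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_truth() -> sd.TruthGenome:
    """Coordinate-scale truth: 7x100 cM, 50 markers/chr, 70 RGHs, 9 clusters."""
    return sd.simulate_truth(sd.TruthConfig(seed=3))


@pytest.fixture(scope="session")
def seq_truth():
    """Scaled-down sequence-bearing truth (12 markers/chr) with sequences."""
    cfg = sd.TruthConfig.small_sequence_scale(seed=4)
    cfg.markers_per_chromosome = 12
    truth = sd.simulate_truth(cfg)
    bundle = sd.simulate_sequences(truth, seed=4)
    return truth, bundle


@pytest.fixture(scope="session")
def three_populations(default_truth):
    """The three emulated mapping populations (F2 n=92, RIL n=148, RIL n=77)."""
    designs = [
        sd.CrossDesign("F2", 92, seed=11, apply_suppression=False, name="CSS-F2"),
        sd.CrossDesign("RIL", 148, seed=12, apply_suppression=False, name="CSS-RIL"),
        sd.CrossDesign("RIL", 77, seed=13, apply_suppression=True, name="CSH-RIL"),
    ]
    return {d.name: sd.simulate_population(default_truth, d) for d in designs}


@pytest.fixture(scope="session")
def component_maps(default_truth, three_populations):
    """Component maps, rf tables and missing counts for the three populations."""
    pos = default_truth.marker_positions()
    marker_lg = {m: lg for m, (lg, _) in pos.items()}
    maps, tables, missing = {}, {}, {}
    for name, matrix in three_populations.items():
        res = lk.build_component_map(matrix, lk.MapParams(), name=name)
        cmap = lk.relabel_linkage_groups(res.component_map, marker_lg)
        cmap.name = name
        maps[name] = cmap
        tables[name] = res.rf_table
        missing.update(res.cleaned_matrix.missing_counts())
    return maps, tables, missing


def two_marker_ril_truth(distance_cm: float, seed: int) -> sd.TruthGenome:
    """Minimal one-chromosome truth with two markers a given distance apart."""
    n_cm = max(distance_cm * 2 + 10, 20)
    cfg = sd.TruthConfig(
        n_chromosomes=1, chromosome_length_cm=n_cm, markers_per_chromosome=2,
        scaffolds_per_chromosome=2, cluster_plan=[], singletons_per_chromosome=(0,),
        class_counts={}, n_incomplete_nb=0, n_unanchorable=0, suppression=(),
        marker_jitter=0.0, seed=seed,
    )
    truth = sd.simulate_truth(cfg)
    truth.markers[0].true_cm = 5.0
    truth.markers[1].true_cm = 5.0 + distance_cm
    return truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
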