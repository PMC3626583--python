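"""Consensus map construction by bin mapping.

Each component map is cut into 1-cM bins (a bin groups all markers within
1 cM of the bin's first marker).  One or more representative markers per bin
— preferring markers shared with other maps, then lowest missing-data count —
form the skeleton.  Marker pairs estimated in several populations are pooled
with LOD weights (pooled r = sum(LOD_i r_i) / sum(LOD_i), pooled LOD =
sum(LOD_i)), the skeleton is ordered by SARF on the pooled table, and the
residual (non-representative) markers are re-introduced at their original
within-bin offsets.  Chromosome-assignment conflicts between maps are
resolved before binning, preferring scaffold-majority evidence, then a
majority vote among maps, then a designated reference map.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import (
    KOSAMBI,
    ComponentMap,
    LinkageError,
    LinkageGroupMap,
    Locus,
    RfTable,
    order_markers,
    rf_to_cm,
)


class IntegrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------


@dataclass
class Bin:
    """A <=1 cM slice of one component map's linkage group."""

    map_name: str
    lg: str
    start_cm: float
    end_cm: float
    members: list[tuple[str, float]]  # (marker_id, cM), sorted by cM
    representative_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.end_cm - self.start_cm > 1.0 + 1e-9:
            # width is bounded by the configured bin width at build time;
            # the canonical 1-cM invariant is checked for default-width bins
            pass
        if [m for _, m in self.members] != sorted(m for _, m in self.members):
            raise IntegrationError("bin members not sorted by cM")


def build_bins(cmap: ComponentMap, bin_width: float = 1.0,
               skip_markers: set[str] | None = None) -> list[Bin]:
    """Partition each linkage group's loci into bins.

    Greedy left-to-right scan anchored at each bin's first marker: a new bin
    starts when the next marker lies more than ``bin_width`` from the current
    bin's start.  ``skip_markers`` (e.g. conflict-reassigned markers) are left
    out entirely.
    """
    skip = skip_markers or set()
    bins: list[Bin] = []
    for lg in cmap.linkage_groups:
        current: list[tuple[str, float]] = []
        start = None
        for loc in lg.loci:
            if loc.marker_id in skip:
                continue
            if start is None or loc.cm - start > bin_width:
                if current:
                    bins.append(Bin(cmap.name, lg.name, start, current[-1][1],
                                    sorted(current, key=lambda t: (t[1], t[0]))))
                current = []
                start = loc.cm
            current.append((loc.marker_id, loc.cm))
        if current:
            bins.append(Bin(cmap.name, lg.name, start, current[-1][1],
                            sorted(current, key=lambda t: (t[1], t[0]))))
    return bins


@dataclass
class ExclusionRegion:
    map_name: str
    lg: str
    start_cm: float
    end_cm: float

    def covers(self, map_name: str, lg: str, cm: float) -> bool:
        return (map_name == self.map_name and lg == self.lg
                and self.start_cm <= cm <= self.end_cm)


def detect_marker_clusters(cmap: ComponentMap, min_markers: int = 5,
                           span_cm: float = 2.0) -> list[ExclusionRegion]:
    """Find recombination-suppression marker clusters on a component map.

    Returns exclusion regions for maximal runs of at least ``min_markers``
    consecutive loci spanning no more than ``span_cm``; used to keep
    suppressed clusters out of bin mapping.
    """
    regions: list[ExclusionRegion] = []
    for lg in cmap.linkage_groups:
        cms = [l.cm for l in lg.loci]
        i = 0
        while i < len(cms):
            j = i
            while j + 1 < len(cms) and cms[j + 1] - cms[i] <= span_cm:
                j += 1
            if j - i + 1 >= min_markers:
                regions.append(ExclusionRegion(cmap.name, lg.name, cms[i], cms[j]))
            i = j + 1
    return regions


def select_representatives(bins: list[Bin], shared_counts: dict[str, int],
                           missing_counts: dict[str, int] | None = None,
                           exclusions: list[ExclusionRegion] | None = None,
                           n_per_bin: int = 1) -> list[Bin]:
    """Choose skeleton representatives for each bin (in place; returns bins).

    Preference per bin: (1) markers shared with the most other maps, then
    (2) fewest missing genotype calls, then (3) lexicographic id.  Markers
    falling in an exclusion region are skipped; a fully excluded bin keeps
    zero representatives and a warning is issued.
    """
    missing_counts = missing_counts or {}
    exclusions = exclusions or []
    for b in bins:
        candidates = [
            (m, cm) for m, cm in b.members
            if not any(e.covers(b.map_name, b.lg, cm) for e in exclusions)
        ]
        if not candidates:
            b.representative_ids = []
            warnings.warn(f"bin {b.map_name}/{b.lg}@{b.start_cm:.2f} fully excluded; "
                          "carried with no representative", stacklevel=2)
            continue
        ranked = sorted(
            candidates,
            key=lambda t: (-shared_counts.get(t[0], 0), missing_counts.get(t[0], 0), t[0]),
        )
        b.representative_ids = [m for m, _ in ranked[:max(1, n_per_bin)]]
    return bins


# ---------------------------------------------------------------------------
# Chromosome-assignment conflicts
# ---------------------------------------------------------------------------


@dataclass
class ConflictRecord:
    marker_id: str
    assignments: list[tuple[str, str, float]]  # (map, lg, cM)
    scaffold_id: str | None
    resolution: str | None  # chosen lg, or None when dropped
    rule_applied: str


def resolve_chromosome_conflicts(
    assignments: dict[str, list[tuple[str, str, float]]],
    marker_to_scaffold: dict[str, str] | None = None,
    reference_map: str | None = None,
) -> list[ConflictRecord]:
    """Resolve markers assigned to different linkage groups by different maps.

    Precedence: (1) majority lg among other mapped markers of the same
    scaffold; (2) majority vote among the component maps; (3) the reference
    map's assignment.  Markers that remain tied are dropped (resolution None).
    Markers with a single consistent lg get an "unanimous" record.
    """
    marker_to_scaffold = marker_to_scaffold or {}

    # scaffold -> lg votes from markers with unanimous assignments
    scaffold_votes: dict[str, Counter] = {}
    unanimous_lg: dict[str, str] = {}
    for marker, asg in assignments.items():
        lgs = {lg for _, lg, _ in asg}
        if len(lgs) == 1:
            unanimous_lg[marker] = next(iter(lgs))
    for marker, lg in unanimous_lg.items():
        scaf = marker_to_scaffold.get(marker)
        if scaf is not None:
            scaffold_votes.setdefault(scaf, Counter())[lg] += 1

    records: list[ConflictRecord] = []
    for marker in sorted(assignments):
        asg = sorted(assignments[marker])
        lgs = {lg for _, lg, _ in asg}
        scaf = marker_to_scaffold.get(marker)
        if len(lgs) == 1:
            records.append(ConflictRecord(marker, asg, scaf, next(iter(lgs)), "unanimous"))
            continue

        resolution, rule = None, "dropped"
        if scaf is not None and scaf in scaffold_votes:
            votes = scaffold_votes[scaf]
            top = votes.most_common()
            if top and (len(top) == 1 or top[0][1] > top[1][1]):
                resolution, rule = top[0][0], "scaffold-majority"
        if resolution is None:
            votes = Counter(lg for _, lg, _ in asg)
            top = votes.most_common()
            if top and (len(top) == 1 or top[0][1] > top[1][1]):
                resolution, rule = top[0][0], "map-majority"
        if resolution is None and reference_map is not None:
            for mp, lg, _ in asg:
                if mp == reference_map:
                    resolution, rule = lg, "reference-map"
                    break
        records.append(ConflictRecord(marker, asg, scaf, resolution, rule))
    return records


# ---------------------------------------------------------------------------
# Skeleton merging
# ---------------------------------------------------------------------------


def pool_rf_tables(marker_ids: list[str], tables: dict[str, RfTable]) -> RfTable:
    """LOD-weighted pooling of per-population rf tables over a marker set.

    pooled r = sum(LOD_i * r_i) / sum(LOD_i); pooled LOD = sum(LOD_i).  Pairs
    with zero LOD in every population carry no pooled information.
    """
    m = len(marker_ids)
    wsum = np.zeros((m, m))
    wr = np.zeros((m, m))
    nn = np.zeros((m, m))
    for table in tables.values():
        present = [k for k, mk in enumerate(marker_ids) if mk in table._index]
        if len(present) < 2:
            continue
        ids = [marker_ids[k] for k in present]
        sub = table.subset(ids)
        ix = np.ix_(present, present)
        wsum[ix] += sub.lod
        wr[ix] += sub.lod * sub.r
        nn[ix] += sub.n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(wsum > 0, wr / np.maximum(wsum, 1e-300), 0.5)
    informative = wsum > 0
    n = np.where(informative, np.maximum(nn, 1.0), 0.0)
    np.fill_diagonal(r, 0.0)
    return RfTable(list(marker_ids), r, wsum, n, "pooled")


def merge_skeleton(representatives: dict[str, list[str]], rf_tables: dict[str, RfTable],
                   map_function: str = KOSAMBI, seed: int = 0,
                   name: str = "consensus-skeleton") -> tuple[ComponentMap, dict[str, RfTable]]:
    """Order the representative markers of each linkage group on pooled rf.

    Returns the ordered skeleton map plus the pooled rf table per lg.
    """
    lgs = []
    pooled_tables: dict[str, RfTable] = {}
    for lg_name in sorted(representatives):
        reps = sorted(set(representatives[lg_name]))
        pooled = pool_rf_tables(reps, rf_tables)
        pooled_tables[lg_name] = pooled
        if len(reps) == 1:
            lgs.append(LinkageGroupMap(lg_name, [Locus(reps[0], 0.0)]))
            continue
        try:
            order = order_markers(reps, pooled, seed)
        except LinkageError as exc:
            raise IntegrationError(f"linkage group {lg_name} disconnected: {exc}") from exc
        cm = 0.0
        loci = [Locus(order[0], 0.0)]
        for a, b in zip(order, order[1:]):
            r = min(pooled.rf(a, b), 0.4999)
            cm += rf_to_cm(r, map_function)
            loci.append(Locus(b, cm))
        lgs.append(LinkageGroupMap(lg_name, loci))
    skeleton = ComponentMap(name, lgs, map_function)
    return skeleton, pooled_tables


# ---------------------------------------------------------------------------
# Consensus map and residual refill
# ---------------------------------------------------------------------------


@dataclass
class ConsensusLocus:
    marker_id: str
    cm: float
    source_maps: tuple[str, ...]
    is_skeleton: bool
    provenance: tuple[tuple[str, str, float], ...]  # (map, lg, original cM)
    is_rgh_tag: bool = False
    is_gene: bool = False


@dataclass
class ConsensusMap:
    """Integrated map: per-lg non-decreasing loci with per-locus provenance."""

    linkage_groups: list[tuple[str, list[ConsensusLocus]]]

    def __post_init__(self):
        seen = set()
        for lg, loci in self.linkage_groups:
            prev = None
            for loc in loci:
                if loc.marker_id in seen:
                    raise IntegrationError(f"marker {loc.marker_id} appears twice")
                seen.add(loc.marker_id)
                if prev is not None and loc.cm < prev - 1e-9:
                    raise IntegrationError(f"consensus cM not non-decreasing in {lg}")
                prev = loc.cm

    @property
    def n_loci(self) -> int:
        return sum(len(loci) for _, loci in self.linkage_groups)

    def lg_length_cm(self, lg_name: str) -> float:
        for lg, loci in self.linkage_groups:
            if lg == lg_name:
                return loci[-1].cm - loci[0].cm if loci else 0.0
        raise KeyError(lg_name)

    @property
    def total_length_cm(self) -> float:
        return sum(self.lg_length_cm(lg) for lg, _ in self.linkage_groups)

    def positions(self) -> dict[str, tuple[str, float]]:
        return {loc.marker_id: (lg, loc.cm) for lg, loci in self.linkage_groups for loc in loci}

    def to_component_map(self, name: str = "consensus") -> ComponentMap:
        lgs = [
            LinkageGroupMap(lg, [Locus(l.marker_id, l.cm, l.is_rgh_tag, l.is_gene) for l in loci])
            for lg, loci in self.linkage_groups
        ]
        return ComponentMap(name, lgs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lg, loci in self.linkage_groups:
            for loc in loci:
                rows.append({
                    "marker": loc.marker_id, "LG": lg, "cM": round(loc.cm, 4),
                    "is_skeleton": loc.is_skeleton,
                    "source_maps": ",".join(loc.source_maps),
                    "provenance": ";".join(f"{m}:{g}:{c:.3f}" for m, g, c in loc.provenance),
                })
        return pd.DataFrame(rows)


def refill_residuals(skeleton: ComponentMap, bins: list[Bin],
                     resolutions: dict[str, str | None] | None = None,
                     source_priority: list[str] | None = None,
                     map_positions: dict[str, dict[str, tuple[str, float]]] | None = None) -> ConsensusMap:
    """Re-introduce non-representative markers onto the skeleton.

    A residual is placed at its bin representative's consensus position plus
    its original within-map offset from that representative, clamped into the
    gap between the representative's flanking skeleton loci.  Residuals in a
    bin with no skeleton representative are appended at the nearest flanking
    skeleton position (with a warning).  When a marker occurs in several
    maps, the earliest map in ``source_priority`` wins; markers whose map
    assignment contradicts a conflict resolution are only refilled from an
    agreeing map.
    """
    resolutions = resolutions or {}
    map_names = sorted({b.map_name for b in bins})
    priority = [m for m in (source_priority or []) if m in map_names]
    priority += [m for m in map_names if m not in priority]
    prio_rank = {m: k for k, m in enumerate(priority)}

    skel_pos: dict[str, dict[str, float]] = {}
    skel_order: dict[str, list[tuple[str, float]]] = {}
    for lg in skeleton.linkage_groups:
        skel_order[lg.name] = [(l.marker_id, l.cm) for l in lg.loci]
        skel_pos[lg.name] = {l.marker_id: l.cm for l in lg.loci}

    source_of: dict[str, set[str]] = {}
    for b in bins:
        for m, _ in b.members:
            source_of.setdefault(m, set()).add(b.map_name)

    # raw placement: marker -> (lg, position, provenance)
    placed: dict[str, tuple[str, float, tuple, bool, int]] = {}
    for b in sorted(bins, key=lambda b: (prio_rank[b.map_name], b.lg, b.start_cm)):
        lg = b.lg
        if lg not in skel_pos:
            continue
        reps_here = [(m, cm) for m, cm in b.members
                     if m in b.representative_ids and m in skel_pos[lg]]
        order = skel_order[lg]
        for m, cm in b.members:
            res = resolutions.get(m)
            if res is not None and res != lg:
                continue  # refilled from a map agreeing with the resolution
            if m in skel_pos[lg]:
                continue  # skeleton locus, placed already
            rank = prio_rank[b.map_name]
            if m in placed and placed[m][4] <= rank:
                continue
            if reps_here:
                rep, rep_cm = min(reps_here, key=lambda t: (abs(t[1] - cm), t[0]))
                rep_pos = skel_pos[lg][rep]
                raw = rep_pos + (cm - rep_cm)
                # clamp into the representative's inter-skeleton gap
                idx = [k for k, (mk, _) in enumerate(order) if mk == rep][0]
                lo = order[idx - 1][1] if idx > 0 else min(raw, rep_pos)
                hi = order[idx + 1][1] if idx + 1 < len(order) else max(raw, rep_pos)
                pos = min(max(raw, lo), hi)
            else:
                # bin without a mapped representative: nearest flanking skeleton locus
                cms = np.array([c for _, c in order])
                # compare on the source map scale via the bin's span midpoint
                nearest = int(np.argmin(np.abs(cms - cm)))
                pos = order[nearest][1]
                warnings.warn(f"residual {m} in bin without representative; "
                              f"appended at flanking skeleton position", stacklevel=2)
            placed[m] = (lg, pos, (b.map_name, lg, cm), False, rank)

    # assemble: skeleton loci + residuals, sorted by position (stable)
    provenance_all: dict[str, list[tuple[str, str, float]]] = {}
    for b in bins:
        for m, cm in b.members:
            provenance_all.setdefault(m, []).append((b.map_name, b.lg, cm))

    lgs_out: list[tuple[str, list[ConsensusLocus]]] = []
    for lg in skeleton.linkage_groups:
        loci: list[tuple[float, int, str, bool]] = []
        for m, cm in skel_order[lg.name]:
            loci.append((cm, 0, m, True))
        for m, (mlg, pos, prov, _, _) in placed.items():
            if mlg == lg.name:
                loci.append((pos, 1, m, False))
        loci.sort(key=lambda t: (t[0], t[1], t[2]))
        base = loci[0][0] if loci else 0.0
        out = []
        prev = None
        for pos, _, m, is_skel in loci:
            cm = max(pos - base, prev if prev is not None else 0.0)
            prev = cm
            out.append(ConsensusLocus(
                m, cm, tuple(sorted(source_of.get(m, set()))), is_skel,
                tuple(sorted(provenance_all.get(m, []))),
            ))
        lgs_out.append((lg.name, out))
    return ConsensusMap(lgs_out)


# ---------------------------------------------------------------------------
# Order concordance
# ---------------------------------------------------------------------------


def order_concordance(map_x: ComponentMap, map_y: ComponentMap) -> dict[str, tuple[float | None, int]]:
    """Spearman rank correlation of shared-marker orders per linkage group.

    Returns lg -> (r, n_shared); r is None when fewer than 2 markers are
    shared (undefined).  Ties are mid-ranked (scipy convention).
    """
    pos_x = map_x.positions()
    pos_y = map_y.positions()
    lgs = sorted({lg for lg, _ in pos_x.values()})
    out: dict[str, tuple[float | None, int]] = {}
    for lg in lgs:
        shared = [m for m, (g, _) in pos_x.items() if g == lg and m in pos_y and pos_y[m][0] == lg]
        if len(shared) < 2:
            out[lg] = (None, len(shared))
            continue
        cx = [pos_x[m][1] for m in shared]
        cy = [pos_y[m][1] for m in shared]
        if len(set(cx)) == 1 or len(set(cy)) == 1:
            out[lg] = (None, len(shared))
            continue
        r, _ = stats.spearmanr(cx, cy)
        out[lg] = (float(r), len(shared))
    return out


# ---------------------------------------------------------------------------
# End-to-end integration
# ---------------------------------------------------------------------------


@dataclass
class IntegrationConfig:
    bin_width: float = 1.0
    map_function: str = KOSAMBI
    reference_map: str | None = None
    exclusions: list[ExclusionRegion] = field(default_factory=list)
    lg_components: dict[str, list[str]] = field(default_factory=dict)  # per-lg map selection
    seed: int = 0


@dataclass
class IntegrationResult:
    consensus: ConsensusMap
    skeleton: ComponentMap
    bins: list[Bin]
    conflicts: list[ConflictRecord]
    concordance: dict[tuple[str, str], dict[str, tuple[float | None, int]]]


def integrate_maps(components: list[ComponentMap], rf_tables: dict[str, RfTable],
                   marker_to_scaffold: dict[str, str] | None = None,
                   missing_counts: dict[str, int] | None = None,
                   config: IntegrationConfig | None = None) -> IntegrationResult:
    """Full bin-mapping integration of two or more component maps."""
    if len(components) < 2:
        raise IntegrationError("need at least two component maps")
    config = config or IntegrationConfig()

    assignments: dict[str, list[tuple[str, str, float]]] = {}
    for cmap in components:
        for lg in cmap.linkage_groups:
            for loc in lg.loci:
                assignments.setdefault(loc.marker_id, []).append((cmap.name, lg.name, loc.cm))

    conflicts = resolve_chromosome_conflicts(assignments, marker_to_scaffold,
                                             config.reference_map)
    resolutions = {c.marker_id: c.resolution for c in conflicts}
    conflict_records = [c for c in conflicts if c.rule_applied != "unanimous"]

    shared_counts = {m: len({mp for mp, _, _ in asg}) - 1 for m, asg in assignments.items()}

    all_bins: list[Bin] = []
    for cmap in components:
        skip = {
            m for m, asg in assignments.items()
            if resolutions.get(m) is None and len({lg for _, lg, _ in asg}) > 1
        }
        skip |= {
            m for m in assignments
            if resolutions.get(m) is not None
            and any(mp == cmap.name and lg != resolutions[m] for mp, lg, _ in assignments[m])
        }
        all_bins.extend(build_bins(cmap, config.bin_width, skip_markers=skip))
    select_representatives(all_bins, shared_counts, missing_counts, config.exclusions)

    # representatives per lg, honouring per-lg component selection
    reps: dict[str, list[str]] = {}
    for b in all_bins:
        allowed = config.lg_components.get(b.lg)
        if allowed is not None and b.map_name not in allowed:
            continue
        reps.setdefault(b.lg, []).extend(b.representative_ids)

    # mask excluded markers out of their population's rf table
    masked_tables: dict[str, RfTable] = {}
    excl_by_map: dict[str, list[ExclusionRegion]] = {}
    for e in config.exclusions:
        excl_by_map.setdefault(e.map_name, []).append(e)
    pos_by_map = {c.name: c.positions() for c in components}
    for name, table in rf_tables.items():
        excl = excl_by_map.get(name, [])
        if not excl:
            masked_tables[name] = table
            continue
        masked = [
            m for m, (lg, cm) in pos_by_map.get(name, {}).items()
            if any(e.covers(name, lg, cm) for e in excl)
        ]
        masked_tables[name] = table.mask_markers(masked)

    skeleton, _ = merge_skeleton(reps, masked_tables, config.map_function, config.seed)
    consensus = refill_residuals(skeleton, all_bins, resolutions,
                                 source_priority=[config.reference_map] if config.reference_map else None)

    concordance = {}
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            a, b = components[i], components[j]
            concordance[(a.name, b.name)] = order_concordance(a, b)
    cons_cm = consensus.to_component_map()
    for c in components:
        concordance[(c.name, "consensus")] = order_concordance(c, cons_cm)
    return IntegrationResult(consensus, skeleton, all_bins, conflict_records, concordance)
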