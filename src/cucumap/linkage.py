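"""Two-point linkage analysis and component genetic map construction.

The estimator for codominant F2 data is a maximum-likelihood EM over the nine
two-locus genotype classes; the double heterozygote mixes the two phases
(probability ((1-r)^2 + r^2)/2) and contributes its expected recombinant-gamete
count in the E step.  For recombinant inbred lines (selfed to fixation) the
observed recombinant fraction R between homozygous lines is converted to the
meiotic recombination frequency with the Haldane-Waddington relation
r = R / (2(1 - R)).

Genetic distances use the Kosambi map function by default (Haldane optional):

    Kosambi  d = 25 ln((1+2r)/(1-2r))        Haldane  d = -50 ln(1-2r)

Marker ordering minimises SARF (sum of adjacent recombination fractions) by
greedy seriation from the strongest-linked pair followed by 2-opt refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import F2, MISSING, RIL, GenotypeMatrix, ril_heterozygotes_to_missing

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_R_LO = 1e-6
_R_HI = 0.4999

KOSAMBI = "kosambi"
HALDANE = "haldane"


class LinkageError(ValueError):
    """Raised on estimation/ordering contract violations."""


# ---------------------------------------------------------------------------
# Pairwise recombination-fraction estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseRf:
    """Recombination-fraction estimate for one marker pair.

    ``r_hat`` is the meiotic recombination frequency in [0, 0.5]; ``lod`` is
    log10 L(r_hat) - log10 L(0.5); both are symmetric in the pair.
    """

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int
    population_kind: str

    def __post_init__(self):
        if not (0.0 <= self.r_hat <= 0.5):
            raise LinkageError(f"r_hat {self.r_hat} outside [0, 0.5]")
        if self.lod < 0:
            raise LinkageError(f"negative LOD {self.lod}")


def _pair_class_counts(calls: np.ndarray) -> np.ndarray:
    """All-pairs 3x3 two-locus genotype class counts.

    calls: int8 (m, n).  Returns float64 (3, 3, m, m) where entry [i, j, a, b]
    counts individuals with call i at marker a and call j at marker b.
    """
    ind = [(calls == k).astype(np.float64) for k in (0, 1, 2)]
    counts = np.empty((3, 3, calls.shape[0], calls.shape[0]))
    for i in range(3):
        for j in range(3):
            counts[i, j] = ind[i] @ ind[j].T
    return counts


def _f2_class_probs(r: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    q = 1.0 - r
    corner = q * q / 4.0
    swap = r * r / 4.0
    single = r * q / 2.0
    centre = (q * q + r * r) / 2.0
    return {
        (0, 0): corner, (2, 2): corner,
        (0, 2): swap, (2, 0): swap,
        (0, 1): single, (1, 0): single, (1, 2): single, (2, 1): single,
        (1, 1): centre,
    }


def _f2_log10_lik(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    probs = _f2_class_probs(np.asarray(r, dtype=float))
    ll = np.zeros(np.broadcast(counts[0, 0], r).shape)
    for (i, j), p in probs.items():
        n = counts[i, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n > 0, n * np.log10(np.maximum(p, 1e-300)), 0.0)
        ll = ll + term
    return ll


def _f2_em(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM on 3x3 class-count arrays; returns (r_hat, lod, n)."""
    n = counts.sum(axis=(0, 1))
    n_single = counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1]
    n_double = counts[0, 2] + counts[2, 0]
    n_hh = counts[1, 1]
    denom = 2.0 * np.maximum(n, 1.0)

    r = np.full(n.shape, 0.25)
    for _ in range(_EM_MAX_ITER):
        w = r * r / ((1.0 - r) ** 2 + r * r)
        r_new = (n_single + 2.0 * n_double + 2.0 * n_hh * w) / denom
        r_new = np.clip(r_new, _R_LO, _R_HI)
        delta = np.abs(r_new - r).max() if r_new.size else 0.0
        r = r_new
        if delta < _EM_TOL:
            break

    lod = _f2_log10_lik(counts, r) - _f2_log10_lik(counts, np.full_like(r, 0.5))
    # boundary tidy-up: estimates at the clamp report as unlinked / fully linked
    r = np.where(r >= _R_HI - 1e-12, 0.5, r)
    r = np.where(r <= _R_LO + 1e-12, 0.0, r)
    lod = np.maximum(lod, 0.0)
    lod = np.where(r >= 0.5, 0.0, lod)
    return r, lod, n


def _ril_estimates(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised RIL estimates; returns (r_hat, lod, n_informative, R_obs)."""
    a = (calls == 0).astype(np.float64)
    b = (calls == 2).astype(np.float64)
    parental = a @ a.T + b @ b.T
    recomb = a @ b.T + b @ a.T
    n = parental + recomb
    with np.errstate(divide="ignore", invalid="ignore"):
        big_r = np.where(n > 0, recomb / np.maximum(n, 1.0), np.nan)
    big_r_c = np.clip(big_r, 0.0, 0.5 - 1e-12)
    r = np.where(big_r >= 0.5, 0.5, big_r_c / (2.0 * (1.0 - big_r_c)))
    r = np.minimum(r, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(parental > 0, parental * np.log10(np.maximum(1.0 - big_r_c, 1e-300) / 0.5), 0.0)
        lod = lod + np.where(recomb > 0, recomb * np.log10(np.maximum(big_r_c, 1e-300) / 0.5), 0.0)
    lod = np.maximum(lod, 0.0)
    lod = np.where(r >= 0.5, 0.0, lod)
    return r, lod, n, big_r


def _coerce(col):
    from .genotypes import encode_calls

    return encode_calls(col)


# ---------------------------------------------------------------------------
# Rf tables
# ---------------------------------------------------------------------------


@dataclass
class RfTable:
    """Symmetric pairwise recombination-fraction/LOD table over a marker set."""

    marker_ids: list[str]
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray
    population_kind: str | None = None

    def __post_init__(self):
        self._index = {m: i for i, m in enumerate(self.marker_ids)}

    def has(self, a: str, b: str) -> bool:
        return a in self._index and b in self._index and self.n[self._index[a], self._index[b]] > 0

    def get(self, a: str, b: str) -> PairwiseRf:
        i, j = self._index[a], self._index[b]
        if self.n[i, j] <= 0:
            raise LinkageError(f"no informative individuals for pair ({a}, {b})")
        ma, mb = sorted((a, b))
        return PairwiseRf(ma, mb, float(self.r[i, j]), float(self.lod[i, j]),
                          int(self.n[i, j]), self.population_kind or "pooled")

    def rf(self, a: str, b: str, default: float = 0.5) -> float:
        if not self.has(a, b):
            return default
        return float(self.r[self._index[a], self._index[b]])

    def subset(self, marker_ids) -> "RfTable":
        idx = [self._index[m] for m in marker_ids]
        return RfTable(
            list(marker_ids),
            self.r[np.ix_(idx, idx)].copy(),
            self.lod[np.ix_(idx, idx)].copy(),
            self.n[np.ix_(idx, idx)].copy(),
            self.population_kind,
        )

    def mask_markers(self, marker_ids) -> "RfTable":
        """Zero out the information of the given markers (their pairs stop
        contributing to pooled estimates)."""
        out = RfTable(list(self.marker_ids), self.r.copy(), self.lod.copy(),
                      self.n.copy(), self.population_kind)
        idx = [self._index[m] for m in marker_ids if m in self._index]
        out.lod[idx, :] = 0.0
        out.lod[:, idx] = 0.0
        out.n[idx, :] = 0.0
        out.n[:, idx] = 0.0
        return out


def estimate_rf_matrix(matrix: GenotypeMatrix) -> RfTable:
    """All-pairs recombination fractions and LOD scores for one population."""
    if matrix.population_kind == RIL and (matrix.calls == 1).any():
        matrix = ril_heterozygotes_to_missing(matrix)
    if matrix.population_kind == F2:
        counts = _pair_class_counts(matrix.calls)
        r, lod, n = _f2_em(counts)
    else:
        r, lod, n, _ = _ril_estimates(matrix.calls)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return RfTable(list(matrix.marker_ids), r, lod, n, matrix.population_kind)


def _estimate_pair(col_a, col_b, population_kind, marker_a, marker_b) -> PairwiseRf:
    a = _coerce(col_a).astype(np.int8)
    b = _coerce(col_b).astype(np.int8)
    if a.shape != b.shape:
        raise LinkageError("genotype vectors have different lengths")
    calls = np.vstack([a, b])
    if population_kind == RIL and (calls == 1).any():
        warnings.warn("heterozygous calls in RIL data treated as missing", stacklevel=2)
        calls = calls.copy()
        calls[calls == 1] = MISSING
    if population_kind == F2:
        counts = _pair_class_counts(calls)
        r, lod, n = _f2_em(counts)
    elif population_kind == RIL:
        r, lod, n, _ = _ril_estimates(calls)
    else:
        raise LinkageError(f"unknown population kind {population_kind!r}")
    if n[0, 1] <= 0:
        raise LinkageError(f"no informative individuals for pair ({marker_a}, {marker_b})")
    ma, mb = sorted((marker_a, marker_b))
    return PairwiseRf(ma, mb, float(r[0, 1]), float(lod[0, 1]), int(n[0, 1]), population_kind)


def estimate_rf(col_a, col_b, population_kind: str, marker_a: str = "a", marker_b: str = "b") -> PairwiseRf:
    """Estimate recombination fraction and LOD for one marker pair.

    F2 codominant data: EM maximum likelihood over the nine genotype classes.
    RIL data: observed recombinant fraction R corrected to meiotic r via
    r = R / (2(1-R)), capped at 0.5.  Heterozygous RIL calls are treated as
    missing with a warning.
    """
    return _estimate_pair(col_a, col_b, population_kind, marker_a, marker_b)


def ril_observed_to_meiotic(big_r: float) -> float:
    """Haldane-Waddington correction for selfed RILs at fixation."""
    if not 0.0 <= big_r <= 1.0:
        raise LinkageError(f"observed fraction {big_r} outside [0, 1]")
    if big_r >= 0.5:
        return 0.5
    return min(0.5, big_r / (2.0 * (1.0 - big_r)))


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------


def rf_to_cm(r: float, map_function: str = KOSAMBI) -> float:
    """Convert a recombination fraction to centimorgans."""
    if not 0.0 <= r < 0.5:
        raise LinkageError(f"recombination fraction {r} outside [0, 0.5)")
    if map_function == KOSAMBI:
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    if map_function == HALDANE:
        return -50.0 * math.log(1.0 - 2.0 * r)
    raise LinkageError(f"unknown map function {map_function!r}")


def cm_to_rf(d: float, map_function: str = KOSAMBI) -> float:
    """Exact inverse of :func:`rf_to_cm`."""
    if d < 0:
        raise LinkageError(f"negative map distance {d}")
    if map_function == KOSAMBI:
        return 0.5 * math.tanh(d / 50.0)
    if map_function == HALDANE:
        return 0.5 * (1.0 - math.exp(-d / 50.0))
    raise LinkageError(f"unknown map function {map_function!r}")


# ---------------------------------------------------------------------------
# Grouping, ordering, cleaning
# ---------------------------------------------------------------------------


def group_markers(table: RfTable, lod_threshold: float = 6.0, rf_threshold: float = 0.30) -> list[list[str]]:
    """Partition markers into linkage groups.

    Single-linkage transitive closure over pairs with lod >= lod_threshold and
    r_hat <= rf_threshold.  Groups are returned sorted by (and internally
    containing) lexicographically sorted marker ids; singletons are returned
    as one-marker groups (unlinked markers).
    """
    ids = table.marker_ids
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    linked = (table.lod >= lod_threshold) & (table.r <= rf_threshold) & (table.n > 0)
    ii, jj = np.nonzero(np.triu(linked, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[str]] = {}
    for k, m in enumerate(ids):
        groups.setdefault(find(k), []).append(m)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: g[0])
    return out


def sarf(order: list[str], table: RfTable) -> float:
    """Sum of adjacent recombination fractions for a marker order (absent
    pairs count as 0.5)."""
    return float(sum(table.rf(a, b) for a, b in zip(order, order[1:])))


def _check_connected(markers: list[str], table: RfTable) -> None:
    remaining = set(markers)
    stack = [markers[0]]
    seen = {markers[0]}
    while stack:
        cur = stack.pop()
        for m in markers:
            if m not in seen and table.has(cur, m):
                seen.add(m)
                stack.append(m)
    if seen != remaining:
        comps = [sorted(seen), sorted(remaining - seen)]
        raise LinkageError(f"rf table disconnected within group; components {comps}")


def order_markers(markers, table: RfTable, seed: int = 0) -> list[str]:
    """Order a linkage group by minimising SARF.

    Greedy seriation from the strongest-linked (highest-LOD) pair, extending
    at whichever end has the smallest rf to an unplaced marker, followed by
    2-opt segment reversals to a local optimum.  The orientation is
    canonicalised so the lexicographically smaller terminal marker comes
    first.  Deterministic (ties broken lexicographically); ``seed`` is
    accepted for interface stability.
    """
    markers = sorted(markers)
    if len(markers) < 2:
        return list(markers)
    _check_connected(markers, table)
    if len(markers) == 2:
        return markers

    sub = table.subset(markers)
    m = len(markers)
    # seed pair: max LOD, ties by smaller rf then lexicographic pair
    best = None
    for i in range(m):
        for j in range(i + 1, m):
            key = (-sub.lod[i, j], sub.r[i, j], markers[i], markers[j])
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i0, j0 = best
    path = [i0, j0]
    unplaced = [k for k in range(m) if k not in (i0, j0)]

    while unplaced:
        cand = None
        for k in unplaced:
            for end, pos in (("head", path[0]), ("tail", path[-1])):
                rr = sub.r[pos, k] if sub.n[pos, k] > 0 else 0.5
                key = (rr, markers[k], 0 if end == "head" else 1)
                if cand is None or key < cand[0]:
                    cand = (key, k, end)
        _, k, end = cand
        if end == "head":
            path.insert(0, k)
        else:
            path.append(k)
        unplaced.remove(k)

    def edge(a, b):
        return sub.r[a, b] if sub.n[a, b] > 0 else 0.5

    improved = True
    while improved:
        improved = False
        for i in range(0, len(path) - 1):
            for j in range(i + 1, len(path)):
                # reverse path[i:j+1]
                delta = 0.0
                if i > 0:
                    delta += edge(path[i - 1], path[j]) - edge(path[i - 1], path[i])
                if j < len(path) - 1:
                    delta += edge(path[i], path[j + 1]) - edge(path[j], path[j + 1])
                if delta < -1e-12:
                    path[i : j + 1] = path[i : j + 1][::-1]
                    improved = True
        # single-marker relocation pass (keeps the 2-opt local optimum honest)
        n_path = len(path)
        for i in range(n_path):
            for j in range(n_path + 1):
                if j in (i, i + 1):
                    continue
                delta = 0.0
                if i > 0:
                    delta -= edge(path[i - 1], path[i])
                if i < n_path - 1:
                    delta -= edge(path[i], path[i + 1])
                if 0 < i < n_path - 1:
                    delta += edge(path[i - 1], path[i + 1])
                if 0 < j < n_path:
                    if j - 1 != i and j != i:
                        delta -= edge(path[j - 1], path[j])
                left = path[j - 1] if j > 0 else None
                right = path[j] if j < n_path else None
                if left is not None and left != path[i]:
                    delta += edge(left, path[i])
                if right is not None and right != path[i]:
                    delta += edge(path[i], right)
                if delta < -1e-12:
                    node = path.pop(i)
                    jj = j if j < i else j - 1
                    path.insert(jj, node)
                    improved = True
                    break
            else:
                continue
            break

    order = [markers[k] for k in path]
    if order[-1] < order[0]:
        order.reverse()
    return order


def clean_double_crossovers(matrix: GenotypeMatrix, order: list[str], window: int = 3):
    """Flag calls implying a local double crossover and set them missing.

    Within each individual, a call is flagged when its nearest non-missing
    neighbours on both sides (within ``(window-1)//2`` markers of the ordered
    map) agree with each other but differ from it.  Returns
    ``(cleaned_matrix, report)`` where report counts flags per marker.
    """
    if window < 3 or window % 2 == 0:
        raise LinkageError("window must be an odd integer >= 3")
    half = (window - 1) // 2
    idx = [matrix.marker_ids.index(m) for m in order]
    calls = matrix.calls.copy()
    sub = calls[idx]  # ordered view (copy indexing)
    flags = np.zeros(sub.shape, dtype=bool)
    n_ord = len(idx)
    for pos in range(n_ord):
        centre = sub[pos]
        left = np.full(centre.shape, MISSING, dtype=np.int8)
        for off in range(1, half + 1):
            if pos - off < 0:
                break
            take = (left == MISSING) & (sub[pos - off] != MISSING)
            left[take] = sub[pos - off][take]
        right = np.full(centre.shape, MISSING, dtype=np.int8)
        for off in range(1, half + 1):
            if pos + off >= n_ord:
                break
            take = (right == MISSING) & (sub[pos + off] != MISSING)
            right[take] = sub[pos + off][take]
        flags[pos] = (
            (centre != MISSING)
            & (left != MISSING)
            & (right != MISSING)
            & (left == right)
            & (centre != left)
        )
    sub[flags] = MISSING
    calls[idx] = sub
    report = {order[p]: int(flags[p].sum()) for p in range(n_ord)}
    cleaned = GenotypeMatrix(list(matrix.marker_ids), list(matrix.individuals), calls,
                             matrix.population_kind)
    return cleaned, report


# ---------------------------------------------------------------------------
# Component maps
# ---------------------------------------------------------------------------


@dataclass
class Locus:
    marker_id: str
    cm: float
    is_rgh_tag: bool = False
    is_gene: bool = False


@dataclass
class LinkageGroupMap:
    name: str
    loci: list[Locus]

    def marker_ids(self) -> list[str]:
        return [l.marker_id for l in self.loci]

    @property
    def length_cm(self) -> float:
        return self.loci[-1].cm - self.loci[0].cm if self.loci else 0.0


@dataclass
class ComponentMap:
    """An ordered genetic map: linkage groups of (marker, cM) loci.

    cM positions are non-decreasing within a group and start at 0.0.
    """

    name: str
    linkage_groups: list[LinkageGroupMap]
    map_function: str = KOSAMBI
    population_kind: str | None = None

    def __post_init__(self):
        seen = set()
        for lg in self.linkage_groups:
            prev = None
            for loc in lg.loci:
                if loc.marker_id in seen:
                    raise LinkageError(f"duplicate marker {loc.marker_id} in map {self.name}")
                seen.add(loc.marker_id)
                if prev is not None and loc.cm < prev - 1e-9:
                    raise LinkageError(f"cM not non-decreasing in {self.name}/{lg.name}")
                prev = loc.cm
            if lg.loci and abs(lg.loci[0].cm) > 1e-9:
                raise LinkageError(f"first locus of {self.name}/{lg.name} not at 0.0")

    def positions(self) -> dict[str, tuple[str, float]]:
        return {
            loc.marker_id: (lg.name, loc.cm)
            for lg in self.linkage_groups
            for loc in lg.loci
        }

    @property
    def n_loci(self) -> int:
        return sum(len(lg.loci) for lg in self.linkage_groups)

    @property
    def total_length_cm(self) -> float:
        return sum(lg.length_cm for lg in self.linkage_groups)

    def group(self, name: str) -> LinkageGroupMap:
        for lg in self.linkage_groups:
            if lg.name == name:
                return lg
        raise KeyError(name)


@dataclass
class MapParams:
    map_function: str = KOSAMBI
    lod_threshold: float = 6.0
    rf_threshold: float = 0.30
    clean: bool = True
    window: int = 3
    seed: int = 0


@dataclass
class MapBuildResult:
    component_map: ComponentMap
    rf_table: RfTable
    cleaned_matrix: GenotypeMatrix
    clean_report: dict[str, int]
    groups: list[list[str]]


def build_component_map(matrix: GenotypeMatrix, params: MapParams | None = None,
                        name: str = "map") -> MapBuildResult:
    """Build an ordered component map from a genotype matrix.

    Pipeline: pairwise rf/LOD estimation, single-linkage grouping, SARF
    ordering per group, double-crossover cleaning against that order,
    re-estimation on the cleaned calls, and cumulative cM via the map
    function on adjacent pairs.
    """
    params = params or MapParams()
    if matrix.population_kind == RIL and (matrix.calls == 1).any():
        matrix = ril_heterozygotes_to_missing(matrix)
    table = estimate_rf_matrix(matrix)
    groups = group_markers(table, params.lod_threshold, params.rf_threshold)

    orders = [order_markers(g, table, params.seed) if len(g) > 1 else list(g) for g in groups]

    cleaned = matrix
    report: dict[str, int] = {}
    if params.clean:
        for order in orders:
            if len(order) >= params.window:
                cleaned, rep = clean_double_crossovers(cleaned, order, params.window)
                report.update(rep)
    table2 = estimate_rf_matrix(cleaned) if params.clean else table

    lgs = []
    for order in sorted(orders, key=min):
        cm = 0.0
        loci = [Locus(order[0], 0.0)]
        for a, b in zip(order, order[1:]):
            r = min(table2.rf(a, b), 0.4999)
            cm += rf_to_cm(r, params.map_function)
            loci.append(Locus(b, cm))
        lgs.append(LinkageGroupMap(f"LG_{min(order)}", loci))
    cmap = ComponentMap(name, lgs, params.map_function, matrix.population_kind)
    return MapBuildResult(cmap, table2, cleaned, report, groups)


def relabel_linkage_groups(cmap: ComponentMap, marker_to_lg: dict[str, str]) -> ComponentMap:
    """Rename each linkage group to the majority label of its markers.

    Used to harmonise de-novo group names ("LG_<marker>") with chromosome
    names known from marker-scaffold metadata before map integration.
    """
    new_lgs = []
    for lg in cmap.linkage_groups:
        votes: dict[str, int] = {}
        for m in lg.marker_ids():
            lab = marker_to_lg.get(m)
            if lab is not None:
                votes[lab] = votes.get(lab, 0) + 1
        name = max(sorted(votes), key=lambda k: votes[k]) if votes else lg.name
        new_lgs.append(LinkageGroupMap(name, list(lg.loci)))
    new_lgs.sort(key=lambda g: g.name)
    return ComponentMap(cmap.name, new_lgs, cmap.map_function, cmap.population_kind)
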