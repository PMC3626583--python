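"""NB-LRR resistance-gene homolog (RGH) annotation and phylogeny.

Genes carrying a nucleotide-binding (NB) domain are classified into six
architecture classes by the order of their annotated domains: an optional
coiled-coil (CC) or Toll/interleukin-1-receptor (TIR) domain before the NB
gives a C or T prefix, an optional leucine-rich-repeat (LRR) domain after the
NB gives an L suffix — N, CN, NL, TN, TNL, CNL.  A cluster is a maximal run
of two or more consecutive genes on a chromosome spanning less than 1 Mbp.
The NB-domain phylogeny is a neighbor-joining tree on amino-acid p-distances
(pairwise gap deletion) with column-resampling bootstrap support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

RGH_CLASSES = ("N", "CN", "NL", "TN", "TNL", "CNL")
UNCLASSIFIED = "unclassified"

EST_MIN_IDENTITY = 0.95
EST_MIN_COVERAGE = 0.90
ORTHOLOG_MIN_IDENTITY = 0.90
ORTHOLOG_MIN_COVERAGE = 0.95
CLUSTER_MAX_SPAN_BP = 1_000_000


class AnnotationError(ValueError):
    pass


class NotAnRghError(AnnotationError):
    """Raised when a gene lacks the obligatory NB domain."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class RghGene:
    """A positioned NB-containing gene with an ordered domain architecture."""

    id: str
    scaffold_id: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    domains: tuple[str, ...]
    chromosome: str | None = None
    peptide: str = ""
    nb_domain_span: tuple[int, int] | None = None  # 1-based inclusive aa coords
    rgh_class: str = ""

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise AnnotationError(f"gene {self.id}: start_bp > end_bp")
        if not self.rgh_class:
            self.rgh_class = classify_architecture(self.domains)


@dataclass
class RghCluster:
    id: str
    chromosome: str
    scaffold_ids: tuple[str, ...]
    members: list[str]
    span_bp: int  # first member start to last member end, inclusive
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise AnnotationError("a cluster needs >= 2 members")
        if self.span_bp >= CLUSTER_MAX_SPAN_BP:
            raise AnnotationError("cluster span must be below 1 Mbp")

    @property
    def span_kb(self) -> float:
        return self.span_bp / 1000.0

    @property
    def density_per_100kb(self) -> float:
        return 100.0 * len(self.members) / self.span_kb


# ---------------------------------------------------------------------------
# Classification grammar
# ---------------------------------------------------------------------------


def classify_architecture(domains) -> str:
    """Classify an ordered domain list into one of the six NB-LRR classes.

    NB is obligatory (NotAnRghError otherwise).  CC before the first NB gives
    the C prefix, TIR before it the T prefix (mutually exclusive; both present
    yields "unclassified" with a warning); LRR after the last NB gives the L
    suffix.
    """
    domains = tuple(domains)
    if not domains:
        raise AnnotationError("empty domain list")
    if "NB" not in domains:
        raise NotAnRghError(f"no NB domain in {domains}")
    first_nb = domains.index("NB")
    last_nb = len(domains) - 1 - domains[::-1].index("NB")
    has_cc = "CC" in domains[:first_nb]
    has_tir = "TIR" in domains[:first_nb]
    has_lrr = "LRR" in domains[last_nb + 1 :]
    if has_cc and has_tir:
        warnings.warn(f"both CC and TIR before NB in {domains}; unclassified", stacklevel=2)
        return UNCLASSIFIED
    prefix = "C" if has_cc else "T" if has_tir else ""
    suffix = "L" if has_lrr else ""
    return prefix + "N" + suffix


def class_counts(genes) -> dict[str, int]:
    """Count genes per class; accepts RghGene objects, anything exposing
    ``rgh_class``/``domain_architecture``, or plain domain lists."""
    counts = {c: 0 for c in RGH_CLASSES}
    for g in genes:
        if getattr(g, "rgh_class", ""):
            cls = g.rgh_class
        elif hasattr(g, "domains"):
            cls = classify_architecture(g.domains)
        elif hasattr(g, "domain_architecture"):
            cls = classify_architecture(g.domain_architecture)
        else:
            cls = classify_architecture(g)
        counts[cls] = counts.get(cls, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Cluster detection and statistics
# ---------------------------------------------------------------------------


def detect_clusters(genes, max_span_bp: int = CLUSTER_MAX_SPAN_BP) -> list[RghCluster]:
    """Greedy left-to-right maximal-run cluster detection.

    Per chromosome (scaffold for unanchored genes), consecutive genes are
    accreted while the run's total span (first start to last end, inclusive)
    stays strictly below ``max_span_bp``; runs of >= 2 genes are clusters.
    Unpositioned genes are skipped with a warning.
    """
    by_region: dict[str, list[RghGene]] = {}
    for g in genes:
        region = g.chromosome or g.scaffold_id
        if not region:
            warnings.warn(f"gene {g.id} has no position; skipped", stacklevel=2)
            continue
        by_region.setdefault(region, []).append(g)

    clusters: list[RghCluster] = []
    cid = 1
    for region in sorted(by_region):
        gs = sorted(by_region[region], key=lambda g: (g.start_bp, g.id))
        i = 0
        while i < len(gs):
            j = i
            while (j + 1 < len(gs)
                   and gs[j + 1].end_bp - gs[i].start_bp + 1 < max_span_bp):
                j += 1
            if j > i:
                run = gs[i : j + 1]
                span = run[-1].end_bp - run[0].start_bp + 1
                clusters.append(RghCluster(
                    f"cluster{cid}", region, tuple(sorted({g.scaffold_id for g in run})),
                    [g.id for g in run], span, run[0].start_bp, run[-1].end_bp,
                ))
                cid += 1
            i = j + 1
    return clusters


def cluster_stats(cluster: RghCluster,
                  map_positions: dict[str, float] | None = None) -> dict:
    """Span (kb), density (RGHs per 100 kb, 1 decimal) and genetic span (cM).

    ``map_positions`` maps member gene ids (or their tag markers) to consensus
    cM; the genetic span is max - min over positioned members, or None.
    """
    span_kb = cluster.span_kb
    if span_kb <= 0:
        warnings.warn(f"{cluster.id} has zero physical span; density undefined", stacklevel=2)
        density = float("inf")
    else:
        density = round(100.0 * len(cluster.members) / span_kb, 1)
    genetic = None
    if map_positions:
        cms = [map_positions[m] for m in cluster.members if m in map_positions]
        if cms:
            genetic = max(cms) - min(cms)
    return {
        "cluster_id": cluster.id,
        "n_members": len(cluster.members),
        "span_kb": round(span_kb, 1),
        "density_per_100kb": density,
        "genetic_span_cm": None if genetic is None else round(genetic, 1),
    }


# ---------------------------------------------------------------------------
# NB domain extraction
# ---------------------------------------------------------------------------


def extract_nb_domain(peptide: str, nb_span: tuple[int, int]) -> str:
    """Extract the NB-domain substring ([start, end] 1-based inclusive)."""
    start, end = nb_span
    if not 1 <= start <= end <= len(peptide):
        raise AnnotationError(f"NB span {nb_span} outside peptide of length {len(peptide)}")
    return peptide[start - 1 : end]


def nb_domain_set(genes) -> dict[str, str]:
    """NB-domain peptides of all genes with a complete span (others excluded,
    mirroring the exclusion of proteins with incomplete NB domains)."""
    out = {}
    for g in genes:
        span = g.nb_domain_span if isinstance(g, RghGene) else g.nb_span
        if span is not None:
            out[g.id] = extract_nb_domain(g.peptide, span)
    return out


# ---------------------------------------------------------------------------
# Neighbor-joining phylogeny with bootstrap
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])
        out: frozenset[str] = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out


@dataclass
class PhyloTree:
    """Unrooted NJ tree with bootstrap support per internal bipartition."""

    root: TreeNode  # trifurcating pseudo-root (standard unrooted NJ output)
    leaf_names: tuple[str, ...]
    support: dict[frozenset[str], float] = field(default_factory=dict)  # % in [0,100]

    def bipartitions(self) -> set[frozenset[str]]:
        return _bipartitions(self.root, frozenset(self.leaf_names))

    def leaf_distance(self, a: str, b: str) -> float:
        paths: dict[str, list[tuple[int, float]]] = {}
        _leaf_paths(self.root, [], paths)
        pa, pb = paths[a], paths[b]
        i = 0
        while i < min(len(pa), len(pb)) and pa[i][0] == pb[i][0]:
            i += 1
        return sum(d for _, d in pa[i:]) + sum(d for _, d in pb[i:])

    def newick(self) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if not node.children:
                body = node.name
            else:
                inner = ",".join(fmt(c, d) for c, d in node.children)
                label = ""
                side = node.leaves()
                canon = _canon(side, frozenset(self.leaf_names))
                if canon in self.support:
                    label = f"{self.support[canon]:.0f}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"


def _leaf_paths(node: TreeNode, acc: list[tuple[int, float]],
                out: dict[str, list[tuple[int, float]]]) -> None:
    if not node.children:
        out[node.name] = acc
    for child, dist in node.children:
        _leaf_paths(child, acc + [(id(child), dist)], out)


def _canon(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _bipartitions(root: TreeNode, all_leaves: frozenset[str]) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        for child, _ in node.children:
            side = child.leaves()
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(_canon(side, all_leaves))
            walk(child)

    walk(root)
    return out


def p_distance_matrix(seqs: dict[str, str], gap: str = "-") -> tuple[list[str], np.ndarray]:
    """Amino-acid p-distance with pairwise gap deletion.

    Sequences must be aligned (equal length).  Raises if any pair has no
    shared non-gap column.
    """
    names = sorted(seqs)
    lengths = {len(seqs[n]) for n in names}
    if len(lengths) != 1:
        raise AnnotationError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(seqs[n]) for n in names])
    valid = arr != gap
    d = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        both = valid[i] & valid
        shared = both.sum(axis=1)
        if (shared == 0).any():
            j = int(np.nonzero(shared == 0)[0][0])
            if j != i:
                raise AnnotationError(f"no shared non-gap columns for {names[i]}/{names[j]}")
        diff = ((arr[i] != arr) & both).sum(axis=1)
        d[i] = np.where(shared > 0, diff / np.maximum(shared, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return names, d


def nj_from_distances(names: list[str], dist: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining; reconstructs additive matrices exactly.

    Negative branch lengths are clamped to 0.  Ties in the Q criterion break
    on the lexicographically smallest joined pair, so the topology is
    deterministic.
    """
    n = len(names)
    if n < 3:
        raise AnnotationError("neighbor joining needs >= 3 sequences")
    nodes = [TreeNode(name=nm) for nm in names]
    labels = [tuple(sorted([nm])) for nm in names]
    d = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (m - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        cand = [(int(a), int(b)) for a, b in cand if a < b]
        if len(cand) == 1:
            ai, bi = cand[0]
        else:  # deterministic tie-break on the joined labels
            ai, bi = min(
                cand,
                key=lambda ab: (min(labels[active[ab[0]]], labels[active[ab[1]]]),
                                max(labels[active[ab[0]]], labels[active[ab[1]]])),
            )
        i, j = active[ai], active[bi]
        li = 0.5 * d[i, j] + (rowsum[ai] - rowsum[bi]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_d])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(children=[(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)),
                              (nodes[k], max(lk, 0.0))])
    return PhyloTree(root, tuple(sorted(names)))


def nj_tree(aligned: dict[str, str], n_bootstrap: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree on p-distances with column-resampling bootstrap support.

    Support per internal bipartition is the percentage of bootstrap
    replicates containing it; deterministic for a fixed seed.
    """
    names, dist = p_distance_matrix(aligned)
    tree = nj_from_distances(names, dist)
    if n_bootstrap <= 0:
        return tree
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    arr = np.array([list(aligned[n]) for n in names])
    L = arr.shape[1]
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, L)
        boot = {n: "".join(arr[i, cols]) for i, n in enumerate(names)}
        try:
            bnames, bdist = p_distance_matrix(boot)
        except AnnotationError:
            continue
        btree = nj_from_distances(bnames, bdist)
        for bp in btree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_bootstrap for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# Sequence support: EST evidence and ortholog calling
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, max(0, len(seq) - k + 1))}


def _share_seed(a: str, b: str, k: int = 21) -> bool:
    if len(a) < k or len(b) < k:
        return True
    kmers = _kmer_set(a, k)
    return any(b[i : i + k] in kmers for i in range(0, len(b) - k + 1, k // 2))


def alignment_identity_coverage(query: str, subject: str) -> tuple[float, float]:
    """Local-alignment identity and query coverage.

    identity = identical columns / aligned columns; coverage = aligned query
    span / query length.
    """
    al = _aligner()
    alns = al.align(query, subject)
    if len(alns) == 0:
        return 0.0, 0.0
    best = alns[0]
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    qspan = best.aligned[0][-1][1] - best.aligned[0][0][0] if len(best.aligned[0]) else 0
    coverage = qspan / len(query) if query else 0.0
    return float(identity), float(coverage)


def est_support(gene_seq: str, ests, min_identity: float = EST_MIN_IDENTITY,
                min_coverage: float = EST_MIN_COVERAGE) -> tuple[bool, int, dict[str, int]]:
    """EST-expression evidence screen for one gene.

    ``ests`` is an iterable of (id, sequence, tissue) triples (or EstContig
    objects).  A hit needs identity >= 95% and coverage of >= 90% of the gene
    (query) length.  Returns (supported, hit_count, per-tissue hit counts).
    An empty EST set returns (False, 0, {"no data": 0}).
    """
    ests = list(ests)
    if not ests:
        return False, 0, {"no data": 0}
    hits = 0
    per_tissue: dict[str, int] = {}
    for e in ests:
        eid, seq, tissue = (e.id, e.sequence, e.tissue) if hasattr(e, "sequence") else e
        if not _share_seed(gene_seq, seq):
            continue
        identity, coverage = alignment_identity_coverage(gene_seq, seq)
        if identity >= min_identity and coverage >= min_coverage:
            hits += 1
            per_tissue[tissue] = per_tissue.get(tissue, 0) + 1
    return hits > 0, hits, per_tissue


@dataclass
class OrthologCall:
    query_id: str
    ortholog_id: str | None
    in_synteny: bool
    status: str  # ortholog / paralogous / no hit / below threshold


def _single_copy(gene_id: str, seq: str, genome: dict[str, str],
                 min_identity: float, min_coverage: float) -> bool:
    for other_id, other_seq in genome.items():
        if other_id == gene_id:
            continue
        if not _share_seed(seq, other_seq):
            continue
        identity, coverage = alignment_identity_coverage(seq, other_seq)
        if identity > min_identity and coverage > min_coverage:
            return False
    return True


def call_orthologs(query_genes, subject_genes, synteny_blocks,
                   min_identity: float = ORTHOLOG_MIN_IDENTITY,
                   min_coverage: float = ORTHOLOG_MIN_COVERAGE) -> list[OrthologCall]:
    """Reciprocal-best ortholog calling with single-copy and synteny checks.

    ``query_genes``/``subject_genes``: dicts id -> (sequence, chromosome,
    position_bp).  A pair is orthologous when the best reciprocal match has
    identity > 90% and coverage > 95% and neither sequence has another
    same-genome match above those thresholds ("paralogous" otherwise).
    ``synteny_blocks``: (q_chrom, q_start, q_end, s_chrom, s_start, s_end).
    """
    q_seqs = {k: v[0] for k, v in query_genes.items()}
    s_seqs = {k: v[0] for k, v in subject_genes.items()}

    best_for_query: dict[str, tuple[str, float, float]] = {}
    best_for_subject: dict[str, tuple[str, float]] = {}
    for qid in sorted(query_genes):
        qseq = q_seqs[qid]
        best = None
        for sid in sorted(subject_genes):
            sseq = s_seqs[sid]
            if not _share_seed(qseq, sseq):
                continue
            identity, coverage = alignment_identity_coverage(qseq, sseq)
            score = identity * min(coverage, 1.0)
            if best is None or score > best[3]:
                best = (sid, identity, coverage, score)
        if best:
            best_for_query[qid] = best[:3]
            sid, _, _, score = best
            if sid not in best_for_subject or score > best_for_subject[sid][1]:
                best_for_subject[sid] = (qid, score)

    calls: list[OrthologCall] = []
    for qid in sorted(query_genes):
        _, q_chrom, q_pos = query_genes[qid]
        best = best_for_query.get(qid)
        if best is None:
            calls.append(OrthologCall(qid, None, False, "no hit"))
            continue
        sid, identity, coverage = best
        if identity <= min_identity or coverage <= min_coverage:
            calls.append(OrthologCall(qid, None, False, "below threshold"))
            continue
        if best_for_subject.get(sid, (None,))[0] != qid:
            calls.append(OrthologCall(qid, None, False, "paralogous"))
            continue
        if not _single_copy(qid, q_seqs[qid], q_seqs, min_identity, min_coverage) or \
           not _single_copy(sid, s_seqs[sid], s_seqs, min_identity, min_coverage):
            calls.append(OrthologCall(qid, None, False, "paralogous"))
            continue
        _, s_chrom, s_pos = subject_genes[sid]
        in_syn = any(
            qc == q_chrom and qs <= q_pos <= qe and sc == s_chrom and ss <= s_pos <= se
            for qc, qs, qe, sc, ss, se in synteny_blocks
        )
        calls.append(OrthologCall(qid, sid, in_syn, "ortholog"))
    return calls
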