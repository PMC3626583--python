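"""Ground-truth genomes, crosses and sequence fixtures.

The generator emulates the structure of a cultivated-cucumber mapping study:
a seven-chromosome genome of ~100 cM per chromosome carrying codominant
SSR-like markers, draft-genome scaffolds, clustered NB-LRR resistance-gene
homologs (RGHs), F2 and selfed-RIL mapping populations with missing data and
genotyping error, and a recombination-suppressed region that reproduces the
marker-clustering artifact seen in inter-subspecific RIL maps.

Meiosis is modelled as a homogeneous Poisson crossover process (rate
length_cM/100 per chromosome, no interference), thinned inside suppression
regions by the configured multiplier.  RILs are selfed to fixation by
default, matching the Haldane-Waddington correction applied downstream.

Default RGH conditions: 70 genes in six architecture classes
(CNL 25, TNL 19, NL 17, TN 5, N 3, CN 1), 52 of them in nine clusters of
sizes (2, 11, 3, 4, 2, 7, 5, 12, 6) each spanning under 1 Mbp, 58 genes with
complete NB domains, and 3 genes on short marker-free scaffolds that cannot
be anchored genetically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .genotypes import F2, MISSING, RIL, GenotypeMatrix

DOMAIN_GRAMMAR = {
    "N": ("NB",),
    "CN": ("CC", "NB"),
    "NL": ("NB", "LRR"),
    "TN": ("TIR", "NB"),
    "TNL": ("TIR", "NB", "LRR"),
    "CNL": ("CC", "NB", "LRR"),
}

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


class ConfigError(ValueError):
    """Raised when a generation parameter is out of range (names the field)."""


# ---------------------------------------------------------------------------
# Truth types
# ---------------------------------------------------------------------------


@dataclass
class Chromosome:
    name: str
    length_cm: float
    length_bp: int


@dataclass
class MarkerTruth:
    id: str
    chromosome: str
    true_cm: float
    scaffold_id: str
    scaffold_offset_bp: int
    position_bp: int  # chromosome coordinate, 1-based


@dataclass
class Scaffold:
    id: str
    chromosome: str
    start_bp: int  # chromosome coordinates, 1-based inclusive
    end_bp: int
    sequence: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class RghTruth:
    id: str
    scaffold_id: str
    chromosome: str
    start_bp: int  # chromosome coordinates, 1-based inclusive
    end_bp: int
    domain_architecture: tuple[str, ...]
    rgh_class: str
    peptide: str
    nb_span: tuple[int, int] | None  # 1-based inclusive aa coordinates
    clade: str  # planted phylogenetic clade (CNL-like or TNL-like NB motif)
    expressed: bool = True
    anchorable: bool = True
    cluster_id: int | None = None


@dataclass
class SuppressionRegion:
    chromosome: str
    start_cm: float
    end_cm: float
    multiplier: float


@dataclass
class TruthGenome:
    chromosomes: list[Chromosome]
    markers: list[MarkerTruth]
    scaffolds: list[Scaffold]
    rgh_genes: list[RghTruth]
    suppression_regions: list[SuppressionRegion]
    config_hash: str = ""

    def validate(self) -> None:
        chrom = {c.name: c for c in self.chromosomes}
        scaf = {s.id: s for s in self.scaffolds}
        for m in self.markers:
            c = chrom[m.chromosome]
            if not 0.0 <= m.true_cm <= c.length_cm:
                raise ConfigError(f"marker {m.id} cM outside chromosome")
        by_chrom: dict[str, list[Scaffold]] = {}
        for s in self.scaffolds:
            by_chrom.setdefault(s.chromosome, []).append(s)
        for ss in by_chrom.values():
            ss = sorted(ss, key=lambda s: s.start_bp)
            for a, b in zip(ss, ss[1:]):
                if b.start_bp <= a.end_bp:
                    raise ConfigError(f"scaffolds {a.id} and {b.id} overlap")
        for g in self.rgh_genes:
            s = scaf[g.scaffold_id]
            if not (s.start_bp <= g.start_bp <= g.end_bp <= s.end_bp):
                raise ConfigError(f"gene {g.id} outside its scaffold")
        for r in self.suppression_regions:
            if not 0.0 <= r.multiplier <= 1.0:
                raise ConfigError("suppression multiplier outside [0, 1]")

    def marker_positions(self) -> dict[str, tuple[str, float]]:
        return {m.id: (m.chromosome, m.true_cm) for m in self.markers}

    def marker_scaffolds(self) -> dict[str, str]:
        return {m.id: m.scaffold_id for m in self.markers}

    def scaffold_chromosomes(self) -> dict[str, str]:
        return {s.id: s.chromosome for s in self.scaffolds}

    def content_hash(self) -> str:
        payload = {
            "chromosomes": [asdict(c) for c in self.chromosomes],
            "markers": [asdict(m) for m in self.markers],
            "scaffolds": [asdict(s) for s in self.scaffolds],
            "rgh_genes": [asdict(g) for g in self.rgh_genes],
            "suppression": [asdict(r) for r in self.suppression_regions],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ClusterPlan:
    chromosome: int  # 1-based chromosome number
    size: int
    span_bp: int


def default_cluster_plan() -> list[ClusterPlan]:
    # nine clusters of sizes (2, 11, 3, 4, 2, 7, 5, 12, 6) = 52 clustered genes
    plan = [
        (2, 2, 857_300),
        (2, 11, 288_800),
        (2, 3, 413_400),
        (2, 4, 109_500),
        (3, 2, 59_600),
        (3, 7, 950_000),
        (4, 5, 43_400),
        (5, 12, 258_300),
        (7, 6, 94_400),
    ]
    return [ClusterPlan(*p) for p in plan]


def default_class_counts() -> dict[str, int]:
    return {"CNL": 25, "TNL": 19, "NL": 17, "TN": 5, "N": 3, "CN": 1}


@dataclass
class TruthConfig:
    """Parameters of :func:`simulate_truth` (defaults are the study conditions)."""

    n_chromosomes: int = 7
    chromosome_length_cm: float = 100.0
    chromosome_length_bp: int = 15_000_000
    markers_per_chromosome: int = 50
    scaffolds_per_chromosome: int = 8
    marker_jitter: float = 0.10  # fraction of the mean spacing
    cluster_plan: list[ClusterPlan] = field(default_factory=default_cluster_plan)
    singletons_per_chromosome: tuple[int, ...] = (4, 4, 2, 1, 4, 2, 1)
    class_counts: dict[str, int] = field(default_factory=default_class_counts)
    n_incomplete_nb: int = 12
    n_unanchorable: int = 3
    gene_length_bp: int = 3000
    peptide_length: int = 250
    nb_span: tuple[int, int] = (61, 180)
    suppression: tuple = ((5, 35.0, 55.0, 0.1), (7, 25.0, 45.0, 0.1))
    cluster_rule_bp: int = 1_000_000  # detection threshold consistent with the plan
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chromosome_length_bp", "markers_per_chromosome",
                     "scaffolds_per_chromosome", "gene_length_bp", "peptide_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.chromosome_length_cm <= 0:
            raise ConfigError("chromosome_length_cm must be positive")
        if len(self.singletons_per_chromosome) != self.n_chromosomes:
            raise ConfigError("singletons_per_chromosome length != n_chromosomes")
        for p in self.cluster_plan:
            if p.size < 2:
                raise ConfigError("cluster_plan size must be >= 2")
            if not 1 <= p.chromosome <= self.n_chromosomes:
                raise ConfigError("cluster_plan chromosome out of range")
            if p.span_bp >= self.cluster_rule_bp:
                raise ConfigError("cluster_plan span_bp must be below cluster_rule_bp")
        if not 1 <= self.nb_span[0] <= self.nb_span[1] <= self.peptide_length:
            raise ConfigError("nb_span outside peptide")
        for chrom, lo, hi, mult in self.suppression:
            if not 0.0 <= mult <= 1.0:
                raise ConfigError("suppression multiplier outside [0, 1]")
            if not 0.0 <= lo < hi <= self.chromosome_length_cm:
                raise ConfigError("suppression interval outside chromosome")

    def scaled(self, bp_scale: float) -> "TruthConfig":
        """Scaled-down physical profile (genetic scale untouched); used for
        sequence-bearing fixtures so runtimes stay small."""
        gene_len = max(240, int(self.gene_length_bp * bp_scale * 10))
        return replace(
            self,
            chromosome_length_bp=max(1, int(self.chromosome_length_bp * bp_scale)),
            cluster_plan=[
                ClusterPlan(p.chromosome, p.size,
                            max(p.size * (gene_len + 10), int(p.span_bp * bp_scale)))
                for p in self.cluster_plan
            ],
            gene_length_bp=gene_len,
            cluster_rule_bp=max(10_000, int(self.cluster_rule_bp * bp_scale)),
        )

    @classmethod
    def small_sequence_scale(cls, **kw) -> "TruthConfig":
        return cls(**kw).scaled(1.0 / 25.0)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class CrossDesign:
    """Design of a simulated cross (F2 intercross or selfed RIL)."""

    kind: str  # F2 or RIL
    n_individuals: int
    selfing_generations: int | None = None  # None = self to fixation (RIL only)
    missing_rate: float = 0.03
    genotyping_error_rate: float = 0.005
    seed: int = 0
    apply_suppression: bool = True
    name: str = ""

    def validate(self) -> None:
        if self.kind not in (F2, RIL):
            raise ConfigError("kind must be F2 or RIL")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate outside [0, 1)")
        if not 0.0 <= self.genotyping_error_rate < 1.0:
            raise ConfigError("genotyping_error_rate outside [0, 1)")
        if self.selfing_generations is not None and self.selfing_generations < 1:
            raise ConfigError("selfing_generations must be >= 1")


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------


def _tile_indices(n_groups: int, n_tiles: int) -> list[int]:
    if n_groups > n_tiles:
        raise ConfigError("more RGH groups than scaffolds on a chromosome")
    if n_groups == 0:
        return []
    return sorted({int(round(x)) for x in np.linspace(0, n_tiles - 1, n_groups)}) if n_groups > 1 else [n_tiles // 2]


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float, alphabet: str) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    n_mut = int(round(rate * len(chars)))
    pos = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for p in pos:
        choices = [c for c in alphabet if c != chars[p]]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def simulate_truth(config: TruthConfig | None = None) -> TruthGenome:
    """Generate a deterministic ground-truth genome from a configuration."""
    config = config or TruthConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    chromosomes = [
        Chromosome(f"chr{i + 1}", config.chromosome_length_cm, config.chromosome_length_bp)
        for i in range(config.n_chromosomes)
    ]

    # scaffolds: equal tiles per chromosome (short unanchorable ones carved later)
    scaffolds: list[Scaffold] = []
    tiles_by_chrom: dict[str, list[Scaffold]] = {}
    counter = 1
    for c in chromosomes:
        bounds = np.linspace(0, c.length_bp, config.scaffolds_per_chromosome + 1).astype(int)
        tiles = []
        for k in range(config.scaffolds_per_chromosome):
            s = Scaffold(f"scaffold{counter:05d}", c.name, int(bounds[k]) + 1, int(bounds[k + 1]))
            tiles.append(s)
            counter += 1
        tiles_by_chrom[c.name] = tiles
        scaffolds.extend(tiles)

    # markers: near-even spacing with jitter
    markers: list[MarkerTruth] = []
    for ci, c in enumerate(chromosomes):
        n = config.markers_per_chromosome
        spacing = c.length_cm / max(1, n - 1)
        pos = np.linspace(0.0, c.length_cm, n)
        pos = pos + rng.uniform(-0.5, 0.5, n) * spacing * config.marker_jitter
        pos = np.sort(np.clip(pos, 0.0, c.length_cm))
        for mi, p in enumerate(pos):
            bp = int(round(p / c.length_cm * (c.length_bp - 1))) + 1
            markers.append(MarkerTruth(f"SSR{ci + 1:02d}{mi + 1:03d}", c.name, float(p), "", 0, bp))

    # RGH genes: clusters then singletons, one group per scaffold tile
    class_pool: list[str] = []
    for cls in ("CNL", "TNL", "NL", "TN", "N", "CN"):
        class_pool += [cls] * config.class_counts.get(cls, 0)
    rng.shuffle(class_pool)
    n_genes = len(class_pool)

    groups: list[tuple[int, int, int]] = []  # (chrom 1-based, size, span_bp); singleton span 0
    for p in config.cluster_plan:
        groups.append((p.chromosome, p.size, p.span_bp))
    for ci, n_single in enumerate(config.singletons_per_chromosome):
        for _ in range(n_single):
            groups.append((ci + 1, 1, 0))
    if sum(g[1] for g in groups) != n_genes:
        raise ConfigError("class_counts total != cluster_plan + singletons total")

    by_chrom: dict[int, list[tuple[int, int, int]]] = {}
    for g in groups:
        by_chrom.setdefault(g[0], []).append(g)

    genes: list[RghTruth] = []
    clade_base = {
        "CNL": _random_seq(rng, AA, config.nb_span[1] - config.nb_span[0] + 1),
        "TNL": _random_seq(rng, AA, config.nb_span[1] - config.nb_span[0] + 1),
    }
    gene_no = 1
    cluster_no = 1
    class_iter = iter(class_pool)
    gl = config.gene_length_bp
    singleton_genes: list[RghTruth] = []
    for chrom_no in sorted(by_chrom):
        cname = f"chr{chrom_no}"
        tiles = tiles_by_chrom[cname]
        chrom_groups = by_chrom[chrom_no]
        t_idx = _tile_indices(len(chrom_groups), len(tiles))
        while len(t_idx) < len(chrom_groups):  # collision fallback
            for k in range(len(tiles)):
                if k not in t_idx:
                    t_idx.append(k)
                    break
            t_idx.sort()
        for (_, size, span), tk in zip(chrom_groups, t_idx):
            tile = tiles[tk]
            centre = (tile.start_bp + tile.end_bp) // 2
            cid = None
            if size >= 2:
                if span >= config.cluster_rule_bp:
                    raise ConfigError("cluster span must be below cluster_rule_bp")
                first_start = centre - span // 2
                starts = np.linspace(first_start, first_start + span - gl, size).astype(int)
                cid = cluster_no
                cluster_no += 1
            else:
                starts = np.array([centre - gl // 2])
            for s0 in starts:
                cls = next(class_iter)
                clade = cls if cls in ("CNL", "TNL") else (
                    "CNL" if cls in ("CN",) else "TNL" if cls in ("TN",) else
                    ("CNL" if rng.random() < 0.5 else "TNL")
                )
                nb = _mutate(rng, clade_base[clade], 0.05, AA)
                pre = _random_seq(rng, AA, config.nb_span[0] - 1)
                post = _random_seq(rng, AA, config.peptide_length - config.nb_span[1])
                gene = RghTruth(
                    id=f"RGH{gene_no:03d}",
                    scaffold_id=tile.id,
                    chromosome=cname,
                    start_bp=int(s0),
                    end_bp=int(s0) + gl - 1,
                    domain_architecture=DOMAIN_GRAMMAR[cls],
                    rgh_class=cls,
                    peptide=pre + nb + post,
                    nb_span=config.nb_span,
                    clade=clade,
                    cluster_id=cid,
                )
                genes.append(gene)
                if size == 1:
                    singleton_genes.append(gene)
                gene_no += 1

    # incomplete NB domains (excluded from phylogeny)
    if config.n_incomplete_nb:
        pick = rng.choice(len(genes), size=config.n_incomplete_nb, replace=False)
        for k in pick:
            genes[k].nb_span = None

    # unanchorable genes: move onto short carved scaffolds without markers
    marker_bp = {c.name: sorted(m.position_bp for m in markers if m.chromosome == c.name)
                 for c in chromosomes}
    for gene in singleton_genes[: config.n_unanchorable]:
        tile = next(s for s in scaffolds if s.id == gene.scaffold_id)
        pad = max(2000, gl)
        lo, hi = None, None
        pts = [tile.start_bp] + [b for b in marker_bp[gene.chromosome]
                                 if tile.start_bp <= b <= tile.end_bp] + [tile.end_bp]
        for a, b in zip(pts, pts[1:]):
            if b - a > gl + 2 * pad + 2:
                lo, hi = a + pad, a + pad + gl + pad
                break
        if lo is None:
            raise ConfigError("no marker-free stretch for an unanchorable scaffold")
        short = Scaffold(f"scaffold{counter:05d}", gene.chromosome, lo, hi)
        counter += 1
        # split the tile around the carved window
        scaffolds.remove(tile)
        left = Scaffold(tile.id, tile.chromosome, tile.start_bp, lo - 1)
        right = Scaffold(f"scaffold{counter:05d}", tile.chromosome, hi + 1, tile.end_bp)
        counter += 1
        scaffolds.extend([left, short, right])
        tiles_by_chrom[gene.chromosome] = sorted(
            [s for s in scaffolds if s.chromosome == gene.chromosome],
            key=lambda s: s.start_bp,
        )
        gene.scaffold_id = short.id
        gene.start_bp = lo + pad
        gene.end_bp = gene.start_bp + gl - 1
        gene.anchorable = False

    # assign markers to scaffolds
    scaffolds.sort(key=lambda s: (s.chromosome, s.start_bp))
    for m in markers:
        for s in scaffolds:
            if s.chromosome == m.chromosome and s.start_bp <= m.position_bp <= s.end_bp:
                m.scaffold_id = s.id
                m.scaffold_offset_bp = m.position_bp - s.start_bp
                break
        else:  # pragma: no cover
            raise ConfigError(f"marker {m.id} not covered by any scaffold")

    suppression = [
        SuppressionRegion(f"chr{c}", lo, hi, mult) for c, lo, hi, mult in config.suppression
        if c <= config.n_chromosomes
    ]

    genes.sort(key=lambda g: (g.chromosome, g.start_bp))
    truth = TruthGenome(chromosomes, markers, scaffolds, genes, suppression,
                        config_hash=config.config_hash())
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _crossover_points(rng, length_cm: float, regions: list[SuppressionRegion]) -> np.ndarray:
    n = rng.poisson(length_cm / 100.0)
    pts = rng.uniform(0.0, length_cm, n)
    if regions:
        keep = np.ones(len(pts), dtype=bool)
        for reg in regions:
            inside = (pts >= reg.start_cm) & (pts <= reg.end_cm)
            keep &= ~inside | (rng.random(len(pts)) < reg.multiplier)
        pts = pts[keep]
    return np.sort(pts)


def _meiosis(rng, hap_a: np.ndarray, hap_b: np.ndarray, marker_cm: np.ndarray,
             length_cm: float, regions) -> np.ndarray:
    pts = _crossover_points(rng, length_cm, regions)
    phase = (np.searchsorted(pts, marker_cm) + rng.integers(0, 2)) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_population(truth: TruthGenome, design: CrossDesign) -> GenotypeMatrix:
    """Simulate a genotype matrix for one cross from the truth genome.

    F2 individuals are formed from two independent F1 gametes; RILs are selfed
    to the configured generation (default: fixation).  Genotyping error
    (symmetric re-draw among the other valid codes) is applied before missing
    data.
    """
    design.validate()
    if not truth.markers:
        raise ConfigError("truth genome has no markers")
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])

    by_chrom: dict[str, list[MarkerTruth]] = {}
    for m in truth.markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: m.true_cm)
    chrom_len = {c.name: c.length_cm for c in truth.chromosomes}
    regions_by_chrom: dict[str, list[SuppressionRegion]] = {}
    if design.apply_suppression:
        for reg in truth.suppression_regions:
            regions_by_chrom.setdefault(reg.chromosome, []).append(reg)

    marker_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for cname in sorted(by_chrom):
        ms = by_chrom[cname]
        marker_ids += [m.id for m in ms]
        cm = np.array([m.true_cm for m in ms])
        L = chrom_len[cname]
        regs = regions_by_chrom.get(cname, [])
        nm = len(ms)
        calls = np.empty((nm, design.n_individuals), dtype=np.int8)
        h0 = np.zeros(nm, dtype=np.int8)
        h1 = np.ones(nm, dtype=np.int8)
        for ind in range(design.n_individuals):
            if design.kind == F2:
                g1 = _meiosis(rng, h0, h1, cm, L, regs)
                g2 = _meiosis(rng, h0, h1, cm, L, regs)
                calls[:, ind] = g1 + g2
            else:
                pair = (h0.copy(), h1.copy())
                gen = 0
                max_gen = design.selfing_generations or 200
                while gen < max_gen:
                    g1 = _meiosis(rng, pair[0], pair[1], cm, L, regs)
                    g2 = _meiosis(rng, pair[0], pair[1], cm, L, regs)
                    pair = (g1, g2)
                    gen += 1
                    if design.selfing_generations is None and (pair[0] == pair[1]).all():
                        break
                geno = pair[0] + pair[1]
                if design.selfing_generations is None and (geno == 1).any():  # pragma: no cover
                    geno[geno == 1] = MISSING
                calls[:, ind] = geno
        blocks.append(calls)

    calls = np.vstack(blocks)
    valid = (0, 1, 2) if design.kind == F2 else (0, 2)
    if design.kind == RIL and (calls == 1).any():
        raise ConfigError("RIL simulation produced heterozygous calls (contract violation)")

    if design.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < design.genotyping_error_rate
        err &= calls != MISSING
        idx = np.nonzero(err)
        for i, j in zip(*idx):
            others = [v for v in valid if v != calls[i, j]]
            calls[i, j] = others[int(rng.integers(0, len(others)))]
    if design.missing_rate > 0:
        calls[rng.random(calls.shape) < design.missing_rate] = MISSING

    individuals = [f"{design.name or design.kind}_{k + 1:03d}" for k in range(design.n_individuals)]
    return GenotypeMatrix(marker_ids, individuals, calls, design.kind)


# ---------------------------------------------------------------------------
# Sequence fixtures (scaffold FASTA, peptides, ESTs, primers)
# ---------------------------------------------------------------------------


@dataclass
class EstParams:
    contigs_per_gene: int = 2
    identity: float = 0.98
    coverage: float = 0.97
    tissues: tuple[str, ...] = ("leaf", "root")
    unexpressed_identity: float = 0.90  # below the 95% support threshold


@dataclass
class PrimerParams:
    primer_length: int = 20
    product_length: int = 300
    n_multicopy: int = 3
    n_nohit: int = 2


@dataclass
class PlantedAmplicon:
    marker_id: str
    scaffold_id: str
    start_bp: int  # scaffold coordinates, 1-based inclusive
    end_bp: int


@dataclass
class PrimerPair:
    marker_id: str
    fwd: str
    rev: str
    label: str  # planted truth: unique / multi-copy / no hit
    amplicons: list[PlantedAmplicon] = field(default_factory=list)


@dataclass
class EstContig:
    id: str
    sequence: str
    tissue: str
    gene_id: str
    planted_identity: float


@dataclass
class SequenceBundle:
    scaffold_sequences: dict[str, str]
    gene_cds: dict[str, str]
    peptides: dict[str, str]
    ests: list[EstContig]
    primers: list[PrimerPair]


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_sequences(truth: TruthGenome, est_params: EstParams | None = None,
                       primer_params: PrimerParams | None = None, seed: int = 0) -> SequenceBundle:
    """Generate scaffold/EST/primer sequence fixtures with planted truth.

    Every expressed RGH receives EST contigs passing the support thresholds
    (>=95% identity, >=90% query coverage); unexpressed genes receive a contig
    below the identity threshold.  Every marker gets exactly one planted
    amplicon except the configured multi-copy (two planted copies) and no-hit
    (absent primers) markers.  Intended for scaled-down physical profiles.
    """
    est_params = est_params or EstParams()
    primer_params = primer_params or PrimerParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    seqs: dict[str, list[str]] = {}
    for s in sorted(truth.scaffolds, key=lambda x: x.id):
        seqs[s.id] = list(_random_seq(rng, NT, s.length_bp))

    scaffold_by_id = {s.id: s for s in truth.scaffolds}

    # gene CDS = scaffold substring at the gene coordinates
    gene_cds: dict[str, str] = {}
    for g in truth.rgh_genes:
        s = scaffold_by_id[g.scaffold_id]
        lo = g.start_bp - s.start_bp
        hi = g.end_bp - s.start_bp + 1
        gene_cds[g.id] = "".join(seqs[g.scaffold_id][lo:hi])

    # primers with planted amplicons
    primers: list[PrimerPair] = []
    plen = primer_params.primer_length
    prod = primer_params.product_length
    markers = sorted(truth.markers, key=lambda m: m.id)
    n_special = primer_params.n_multicopy + primer_params.n_nohit
    multicopy_ids = {m.id for m in markers[-n_special:-primer_params.n_nohit]} if primer_params.n_multicopy else set()
    nohit_ids = {m.id for m in markers[-primer_params.n_nohit:]} if primer_params.n_nohit else set()

    used: dict[str, list[tuple[int, int]]] = {g.scaffold_id: [] for g in truth.rgh_genes}
    for g in truth.rgh_genes:
        s = scaffold_by_id[g.scaffold_id]
        used.setdefault(g.scaffold_id, []).append((g.start_bp - s.start_bp, g.end_bp - s.start_bp))

    def free(scaf_id: str, lo: int, hi: int) -> bool:
        return all(hi < a or lo > b for a, b in used.get(scaf_id, []))

    extra_copies: list[tuple[str, str]] = []  # (marker_id, amplicon_seq)
    for m in markers:
        if m.id in nohit_ids:
            fwd = _random_seq(rng, NT, plen)
            rev = _random_seq(rng, NT, plen)
            primers.append(PrimerPair(m.id, fwd, rev, "no hit"))
            continue
        s = scaffold_by_id[m.scaffold_id]
        off = m.scaffold_offset_bp
        if off + prod > s.length_bp:
            off = max(0, s.length_bp - prod)
        tries = 0
        limit = max(1, s.length_bp - prod)
        while not free(m.scaffold_id, off, off + prod - 1):
            off = (off + prod) % limit
            tries += 1
            if tries > s.length_bp // prod + 2:
                raise ConfigError(f"no free amplicon site on {m.scaffold_id}")
        template = "".join(seqs[m.scaffold_id][off:off + prod])
        fwd = template[:plen]
        rev = revcomp(template[-plen:])
        used.setdefault(m.scaffold_id, []).append((off, off + prod - 1))
        amp = PlantedAmplicon(m.id, m.scaffold_id, off + 1, off + prod)
        label = "multi-copy" if m.id in multicopy_ids else "unique"
        pair = PrimerPair(m.id, fwd, rev, label, [amp])
        primers.append(pair)
        if m.id in multicopy_ids:
            extra_copies.append((m.id, template))

    # plant second copies for multi-copy markers on other scaffolds
    if extra_copies:
        scaf_cycle = [s for s in sorted(truth.scaffolds, key=lambda x: x.id)
                      if s.length_bp > 4 * prod]
        ci = 0
        for marker_id, template in extra_copies:
            placed = False
            while not placed:
                s = scaf_cycle[ci % len(scaf_cycle)]
                ci += 1
                origin = next(p for p in primers if p.marker_id == marker_id)
                if s.id == origin.amplicons[0].scaffold_id:
                    continue
                for off in range(prod, s.length_bp - 2 * prod, prod):
                    if free(s.id, off, off + prod - 1):
                        seqs[s.id][off:off + prod] = list(template)
                        used.setdefault(s.id, []).append((off, off + prod - 1))
                        origin.amplicons.append(PlantedAmplicon(marker_id, s.id, off + 1, off + prod))
                        placed = True
                        break

    # EST contigs
    ests: list[EstContig] = []
    for g in sorted(truth.rgh_genes, key=lambda x: x.id):
        cds = gene_cds[g.id]
        if g.expressed:
            for k in range(est_params.contigs_per_gene):
                tissue = est_params.tissues[k % len(est_params.tissues)]
                span = int(round(est_params.coverage * len(cds)))
                start = (len(cds) - span) // 2
                contig = _mutate(rng, cds[start:start + span], 1.0 - est_params.identity, NT)
                ests.append(EstContig(f"EST_{g.id}_{k + 1}", contig, tissue, g.id,
                                      est_params.identity))
        else:
            contig = _mutate(rng, cds, 1.0 - est_params.unexpressed_identity, NT)
            ests.append(EstContig(f"EST_{g.id}_low", contig, est_params.tissues[0], g.id,
                                  est_params.unexpressed_identity))

    scaffold_sequences = {sid: "".join(chars) for sid, chars in seqs.items()}
    for s in truth.scaffolds:
        s.sequence = scaffold_sequences[s.id]
    peptides = {g.id: g.peptide for g in truth.rgh_genes}
    return SequenceBundle(scaffold_sequences, gene_cds, peptides, ests, primers)


def write_fixture_bundle(truth: TruthGenome, matrices: dict[str, GenotypeMatrix],
                         sequences: SequenceBundle | None, out_dir, seed: int = 0) -> dict:
    """Write a complete fixture bundle and return its manifest.

    Files: truth marker map (TSV), per-population genotype matrices,
    annotations, and (when sequences are given) scaffold/peptide/EST FASTA and
    primer TSV.  The manifest lists paths, the seed and the truth config hash.
    """
    import json
    from pathlib import Path

    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    import pandas as pd

    marker_df = pd.DataFrame(
        [{"marker": m.id, "LG": m.chromosome, "cM": round(m.true_cm, 6),
          "scaffold": m.scaffold_id, "offset_bp": m.scaffold_offset_bp} for m in truth.markers]
    )
    marker_df.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    paths["truth_markers"] = str(out / "truth_markers.tsv")

    for name, matrix in matrices.items():
        p = out / f"genotypes_{name}.tsv"
        matrix.write(p)
        paths[f"genotypes_{name}"] = str(p)

    cio.write_annotations(truth.rgh_genes, out / "annotations.tsv")
    paths["annotations"] = str(out / "annotations.tsv")

    if sequences is not None:
        cio.write_fasta(sequences.scaffold_sequences, out / "scaffolds.fasta")
        cio.write_fasta(sequences.peptides, out / "rgh_peptides.fasta")
        cio.write_fasta({e.id: e.sequence for e in sequences.ests}, out / "ests.fasta")
        cio.write_primers(sequences.primers, out / "primers.tsv")
        paths.update({
            "scaffolds": str(out / "scaffolds.fasta"),
            "peptides": str(out / "rgh_peptides.fasta"),
            "ests": str(out / "ests.fasta"),
            "primers": str(out / "primers.tsv"),
        })

    manifest = {
        "seed": seed,
        "config_hash": truth.config_hash,
        "truth_hash": truth.content_hash(),
        "files": paths,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Planted linkage-group conflicts and ortholog fixtures
# ---------------------------------------------------------------------------


def plant_lg_conflicts(cmap, truth: TruthGenome, n_conflicts: int = 33, seed: int = 0,
                       min_scaffold_support: int = 2):
    """Corrupt the linkage-group assignment of ``n_conflicts`` markers in a
    component map (emulating conflicting chromosome locations between maps).

    Only markers whose scaffold carries at least ``min_scaffold_support``
    other markers are corrupted, so scaffold-majority evidence can resolve
    every planted conflict.  Returns ``(corrupted_map, planted)`` with
    planted mapping marker_id -> (true_lg, wrong_lg).
    """
    from .linkage import ComponentMap, LinkageGroupMap, Locus

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    scaffold_members: dict[str, list[str]] = {}
    for m in truth.markers:
        scaffold_members.setdefault(m.scaffold_id, []).append(m.id)
    mapped = {loc.marker_id for lg in cmap.linkage_groups for loc in lg.loci}

    eligible = []
    used_scaffolds: set[str] = set()
    for m in sorted(truth.markers, key=lambda x: x.id):
        if m.id not in mapped or m.scaffold_id in used_scaffolds:
            continue
        support = [x for x in scaffold_members[m.scaffold_id] if x != m.id and x in mapped]
        if len(support) >= min_scaffold_support:
            eligible.append(m.id)
            used_scaffolds.add(m.scaffold_id)
    if len(eligible) < n_conflicts:
        raise ConfigError(f"only {len(eligible)} markers eligible for conflict planting")
    chosen = sorted(rng.choice(eligible, size=n_conflicts, replace=False).tolist())

    lg_of = {loc.marker_id: lg.name for lg in cmap.linkage_groups for loc in lg.loci}
    lg_names = [lg.name for lg in cmap.linkage_groups]
    planted: dict[str, tuple[str, str]] = {}
    moves: dict[str, list[str]] = {}
    for mk in chosen:
        true_lg = lg_of[mk]
        wrong = [n for n in lg_names if n != true_lg]
        wrong_lg = wrong[int(rng.integers(0, len(wrong)))]
        planted[mk] = (true_lg, wrong_lg)
        moves.setdefault(wrong_lg, []).append(mk)

    new_lgs = []
    for lg in cmap.linkage_groups:
        loci = [loc for loc in lg.loci if loc.marker_id not in planted]
        incoming = moves.get(lg.name, [])
        span = loci[-1].cm if loci else 1.0
        for mk in incoming:
            loci.append(Locus(mk, float(rng.uniform(0, span))))
        loci.sort(key=lambda l: (l.cm, l.marker_id))
        base = loci[0].cm if loci else 0.0
        loci = [Locus(l.marker_id, l.cm - base, l.is_rgh_tag, l.is_gene) for l in loci]
        new_lgs.append(LinkageGroupMap(lg.name, loci))
    return ComponentMap(cmap.name, new_lgs, cmap.map_function, cmap.population_kind), planted


@dataclass
class SubjectGene:
    id: str
    sequence: str
    chromosome: str
    position_bp: int


@dataclass
class OrthologFixture:
    subject_genes: list[SubjectGene]
    synteny_blocks: list[tuple[str, int, int, str, int, int]]
    expected_orthologs: set[str]  # query genes with a planted ortholog
    expected_in_synteny: set[str]


def simulate_ortholog_set(truth: TruthGenome, gene_cds: dict[str, str], seed: int = 0,
                          n_no_hit: int = 2, n_low_identity: int = 3,
                          n_in_synteny: int = 57, identity: float = 0.97,
                          n_subject_duplicates: int = 0) -> OrthologFixture:
    """Plant a subject ("melon-like") gene set for ortholog/synteny calling.

    All query genes get high-identity single-copy subject counterparts except
    ``n_no_hit`` genes with no counterpart and ``n_low_identity`` genes with a
    diverged one below threshold; ``n_in_synteny`` of the ortholog pairs fall
    inside planted synteny blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    genes = sorted(truth.rgh_genes, key=lambda g: g.id)
    no_hit = {g.id for g in genes[:n_no_hit]}
    low_id = {g.id for g in genes[n_no_hit:n_no_hit + n_low_identity]}
    ortho = [g for g in genes if g.id not in no_hit and g.id not in low_id]

    subject_genes: list[SubjectGene] = []
    blocks: list[tuple[str, int, int, str, int, int]] = []
    expected_in_synteny: set[str] = set()
    spacing = 100_000
    pos: dict[str, int] = {}
    for g in genes:
        if g.id in no_hit:
            continue
        rate = (1.0 - identity) if g.id not in low_id else 0.30
        seq = _mutate(rng, gene_cds[g.id], rate, NT)
        schrom = "m" + g.chromosome
        p = pos.get(schrom, 0) + spacing
        pos[schrom] = p
        subject_genes.append(SubjectGene("m" + g.id, seq, schrom, p))
    if n_subject_duplicates:
        for g in ortho[:n_subject_duplicates]:
            schrom = "m" + g.chromosome
            p = pos.get(schrom, 0) + spacing
            pos[schrom] = p
            subject_genes.append(SubjectGene("m" + g.id + "_dup", gene_cds[g.id], schrom, p))

    # synteny blocks around the first n_in_synteny ortholog pairs
    subj_by_id = {s.id: s for s in subject_genes}
    covered = 0
    for g in ortho:
        if covered >= n_in_synteny:
            break
        s = subj_by_id["m" + g.id]
        blocks.append((g.chromosome, g.start_bp - 50_000, g.end_bp + 50_000,
                       s.chromosome, s.position_bp - 50_000, s.position_bp + 50_000))
        expected_in_synteny.add(g.id)
        covered += 1

    dup_base = {("m" + g.id) for g in ortho[:n_subject_duplicates]}
    expected = {g.id for g in ortho if ("m" + g.id) not in dup_base or n_subject_duplicates == 0}
    if n_subject_duplicates:
        expected -= {g.id for g in ortho[:n_subject_duplicates]}
        expected_in_synteny -= {g.id for g in ortho[:n_subject_duplicates]}
    return OrthologFixture(subject_genes, blocks, expected, expected_in_synteny)
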