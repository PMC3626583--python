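# Methods

This note documents the models, estimators, defaults and design choices
behind `cucumap`, and what the synthetic-data generator does and does not
emulate.

## Genetic model and estimators

**Meiosis.** Crossovers are simulated as a homogeneous Poisson process with
rate length_cM/100 per chromosome per gamete — i.e. no crossover
interference, which makes the Haldane map function exact for the simulator.
Interference handling is an *analysis* choice, not a simulation choice: the
mapping code defaults to Kosambi (the customary choice for plant SSR maps)
and can be switched to Haldane per map; the choice is recorded in map
metadata.  On interference-free data Kosambi understates distances by ~2% at
2 cM spacing, which is visible in the component-map lengths.

**Recombination suppression** is modelled by thinning crossover points that
fall inside a configured interval by a multiplier in [0, 1].  With the
default multiplier 0.1 over two 20 cM regions this reproduces the
marker-clustering artifact of inter-subspecific RIL maps: the suppressed
map compresses those regions into ~2 cM marker clusters, its per-chromosome
order concordance with other maps drops there, and the integration step must
exclude those clusters to recover a clean consensus.

**F2 estimator.** For codominant F2 calls the likelihood is a multinomial
over the nine two-locus genotype classes; only the double-heterozygote class
is phase-ambiguous, with probability ((1−r)² + r²)/2.  EM iterates the
expected recombinant-gamete count (the double heterozygote contributes
2r²/((1−r)²+r²)); initialisation r = 0.25, convergence |Δr| < 1e−8, at most
1000 iterations, r clamped to [1e−6, 0.4999] during iteration to avoid
boundary degeneracy.  Estimates at the clamp are reported as exactly 0 or
0.5, and LOD is forced to 0 exactly when r̂ = 0.5.  The EM path is verified
against an independent 1e−4-step grid search of the same likelihood.

**RIL estimator.** RILs are selfed to fixation by default (the generator
iterates selfing until every locus is homozygous), so the observed
recombinant fraction R between lines relates to the meiotic r by
r = R/(2(1−R)), capped at 0.5.  Heterozygous calls in RIL input are treated
as missing with a warning (the simulator treats RIL heterozygote *output* as
a contract violation instead).  LOD uses the binomial likelihood on the
observed scale.

**Grouping** is single-linkage transitive closure over pairs with
LOD ≥ 6 and r̂ ≤ 0.30.  The LOD default is deliberately above the classical 3:
with ~350 markers there are tens of thousands of unlinked pairs per
population and a single false edge would fuse two chromosomes under single
linkage; LOD 6 puts the expected number of false edges per run around 1e−2,
while true adjacent pairs (~2 cM at n ≥ 77) sit far above it.

**Ordering** minimises SARF (sum of adjacent recombination fractions):
greedy seriation seeded at the highest-LOD pair, extension at whichever end
has the smallest rf to an unplaced marker, then alternating 2-opt segment
reversals and single-marker relocations (both delta-evaluated) to a joint
local optimum.  Orientation is canonicalised to put the lexicographically
smaller terminal marker first; all tie-breaks are lexicographic, so the
result is deterministic.  For groups of ≤ 8 markers the result is tested
against the exhaustive-permutation minimum.  No multipoint maximum-likelihood
refinement is attempted; distances are adjacent-pair estimates — a documented
simplification relative to multipoint regression mapping.

**Double-crossover cleaning** flags a call whose nearest non-missing
neighbours inside a 3-marker window agree with each other but differ from
it, and sets it missing.  The stage order is estimate → group → order →
clean → re-estimate: cleaning needs a marker order, so it runs after
ordering and the adjacent distances are recomputed on the cleaned calls.
On dense maps this removes genotyping errors almost one-for-one; at wider
spacings it also censors some genuine double recombinants, biasing RIL map
lengths downward by roughly 2R per interval (~6–10% at the default 2 cM
spacing).  That bias is visible and accepted: the consensus-length check
budgets ±15%.

## Map integration

Bins are built by a greedy left-to-right scan anchored at each bin's first
marker (a new bin starts when the next locus lies > 1 cM from the current
bin's start), so bins partition each map and never exceed the bin width.
Representatives prefer markers shared with the most other maps, then fewest
missing calls, then lexicographic id.  Chromosome-assignment conflicts are
resolved before binning — scaffold majority among unanimously mapped markers
of the same scaffold, then map majority, then the designated reference map;
unresolvable markers are dropped with a report entry — so reassigned markers
never seed bins.

Pooling uses LOD weights: r̄ = Σ LODᵢrᵢ / Σ LODᵢ and pooled LOD = Σ LODᵢ
(pairs with zero LOD everywhere carry no information).  LOD weighting is an
information-weighting surrogate chosen because the reference implementation's
internals ("mean recombination frequencies and combined LOD scores") are not
published; it is a fixed point for identical estimates and is recorded in
metadata.  Exclusion regions (for suppressed marker clusters) are generic
`(map, lg, cM-interval)` config; excluded markers neither seed bins nor
contribute their population's rf estimates to pooling, and a helper detects
such clusters automatically (≥5 consecutive loci within 2 cM).  Per-lg
component selection (using a different map set for a problematic chromosome)
is plain config, not hard-coded.

Residuals are re-introduced at (representative's consensus position) +
(their original offset from that representative on the source map), clamped
into the representative's inter-skeleton gap; a residual whose bin has no
mapped representative is appended at the nearest flanking skeleton position
with a warning.  When a marker occurs in several maps the reference map's
bin wins.  How residuals were positioned within bins in the original
procedure is unstated; the offset rule is this package's documented choice.

## RGH annotation

The class grammar requires an NB domain; CC before the first NB gives the C
prefix, TIR the T prefix (both present → unclassified with a warning — no
such case occurs in practice), LRR after the last NB gives the L suffix.
"Maximum 1 Mbp" for clusters is read strictly (< 1,000,000 bp from first
member start to last member end, inclusive coordinates), and clustering is
greedy maximal-run accretion per chromosome, verified against an O(n²)
all-windows oracle.  Cluster membership uses same-chromosome windowing;
same-scaffold residence is reported, not required.

The NB phylogeny uses amino-acid p-distance with pairwise gap deletion and
Saitou–Nei neighbor joining (Studier–Keppler Q criterion, deterministic
lexicographic tie-break, negative branch lengths clamped to 0) — it
reconstructs additive matrices exactly and is cross-checked against
scikit-bio's implementation in the tests.  Bootstrap support is the
percentage of column-resampling replicates containing each internal
bipartition, with a fixed seed.  Sequence-support screens (EST evidence,
ortholog calling) use biopython's local PairwiseAligner behind a 21-mer seed
prefilter; identity = identical columns / aligned columns, coverage =
aligned query span / query length.  Upstream HMM/COILS domain-search
thresholds are carried as annotation metadata only — the classifier consumes
already-annotated domain lists.

## Physical anchoring

In silico PCR is exact matching (IUPAC degeneracy honoured; no mismatch
tolerance by default, configurable, with no 3′-end special-casing): the
forward primer and the reverse-complemented reverse primer must face each
other within 2,000 bp.  Labels are genome-wide across all scaffolds of one
assembly.  Coordinates are 1-based inclusive internally; BED exports are
0-based half-open.  Scaffolds anchor to the majority linkage group of their
uniquely assigned mapped markers (ties → unanchored with a warning);
orientation comes from the sign of the within-scaffold cM-vs-bp slope, and
single-marker scaffolds are anchored but unoriented.  The fallback for
failed PCR is exact primer-site search only.

## Synthetic-data generator: what it emulates, and what it does not

Defaults are the emulated study conditions: a 7-chromosome genome of 100 cM
per chromosome; 50 codominant SSR-like markers per chromosome (near-even
spacing with 10% jitter — chosen dense enough that call-level cleaning stays
near-unbiased, see above); 8 scaffold tiles per chromosome; populations F2
n=92, RIL n=148 and suppressed RIL n=77 with 3% missing data and 0.5%
genotyping error (symmetric re-draw among the other valid codes, applied
before missing); 70 RGH genes in classes CNL 25 / TNL 19 / NL 17 / TN 5 /
N 3 / CN 1, of which 52 sit in nine clusters of sizes (2, 11, 3, 4, 2, 7, 5,
12, 6), 58 have complete ~120-aa NB domains drawn from two diverged motif
families (so the phylogeny has a planted two-clade answer), and 3 sit on
short marker-free scaffolds and cannot be anchored.  One cluster's span is
planted at 950 kb rather than its nominal 1,143 kb so the planted truth
respects the strict < 1 Mbp cluster rule it is meant to exercise.

Physical coordinates use a uniform cM↔bp relation within each chromosome.
Sequence-bearing fixtures (scaffold FASTA, ESTs, primers) use a scaled-down
physical profile (default bp scale 1/25: 600 kb per chromosome, cluster rule
scaled proportionally, 1.2 kb genes) so that exhaustive PCR scans and
alignments complete in seconds; coordinate-only analyses (cluster detection
at the true 1 Mbp rule, the population genetics) always run at full scale.
These problem sizes are the package's own choices for a desk-scale testbed.

Not emulated: nucleotide-level mutation/coalescent realism, read-level
sequencing, crossover interference (the populations' true interference model
is unknowable from the emulated setting; the Poisson default is documented
rather than inferred), segregation distortion, dominant markers, or outbred
populations.  Passing tests therefore demonstrate correctness of the
estimators and bookkeeping under the stated model — not robustness to, e.g.,
interference misspecification or distorted segregation in real populations.

## Numerical conventions

Missing genotype code "-"; pairs with either call missing are excluded from
that pair's likelihood.  r ∈ [0, 0.5] and LOD ≥ 0 everywhere; map-function
round-trips are exact to 1e−10.  Report rounding: cM and densities to one
decimal, percentages to one decimal, mean spacing to two decimals; the mean
adjacent-marker spacing divides total cM by (total loci − number of linkage
groups), i.e. the count of adjacent intervals.  Zero-span clusters report an
infinite-density sentinel with a warning.  All randomness flows from one
master seed through named child seeds (numpy SeedSequence), and every
pipeline artifact is hashed into the run manifest so re-runs are verifiably
identical.

## Known limitations

Component-map and consensus lengths are systematically a few percent short
of the simulated truth (Kosambi-on-Haldane-data plus cleaning censorship, as
quantified above).  The ordering heuristic guarantees only a local SARF
optimum for large groups (exhaustively verified up to 8 markers; order
recovery ≥ 0.99 Spearman at the default scale).  The in silico PCR fallback
does not implement scored alignment search.  The alignment screens are
fixture-scale tools, not a BLAST replacement.
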