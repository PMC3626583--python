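# cucumap

Consensus genetic-map integration and NB-LRR resistance-gene-homolog (RGH)
analysis for cucumber-scale plant genomes.

Cultivated cucumber (*Cucumis sativus*, 2n = 14, ~367 Mbp, ~750 cM) has a
very narrow genetic base, so no single cross yields a dense genetic map.  The
standard remedy is a **consensus map**: several population-specific maps are
merged through their shared markers with a bin-mapping strategy.  The same
mapping framework is what lets the genome's **NB-LRR disease-resistance gene
homologs** — the largest class of plant R genes, organised in physical
clusters — be placed on the map and tied to the physical assembly.  `cucumap`
implements that whole computational pipeline as a tested, reusable library,
together with a synthetic-data generator that plants ground truth for every
stage, so each step is verifiable without any external data.

## What it computes

**Two-point linkage.** For codominant F2 data the recombination fraction *r*
is the maximum-likelihood estimate over the nine two-locus genotype classes,
found by EM (the double heterozygote mixes the two phases with probability
((1−r)² + r²)/2). For selfed recombinant inbred lines at fixation the
observed recombinant fraction *R* is corrected to the meiotic
*r* = *R* / (2(1 − *R*)) (Haldane–Waddington).  LOD = log₁₀ L(r̂) − log₁₀ L(0.5).

**Map distances.** Kosambi *d* = 25 ln((1+2r)/(1−2r)) by default, Haldane
*d* = −50 ln(1−2r) optionally; exact closed-form inverses.

**Grouping and ordering.** Single-linkage grouping over pairs with
LOD ≥ threshold and r̂ ≤ threshold; within a group, marker order minimises
SARF (the sum of adjacent recombination fractions) by greedy seriation from
the strongest-linked pair plus 2-opt/relocation refinement.  Calls implying a
local double crossover within a 3-marker window are set missing before
distances are computed.

**Bin-mapping integration.** Each component map is cut into ≤1 cM bins; per
bin a representative is chosen (shared with the most other maps, then fewest
missing calls).  Markers assigned to different chromosomes by different maps
are resolved by scaffold-majority evidence, then map majority, then a
reference map.  Pairs estimated in several populations are pooled with LOD
weights (r̄ = Σ LODᵢ rᵢ / Σ LODᵢ), the pooled table is re-ordered, and the
residual markers are re-introduced at their original within-bin offsets.
Marker-cluster regions of recombination-suppressed maps can be excluded.

**RGH annotation.** The obligatory NB domain plus optional N-terminal CC or
TIR and C-terminal LRR yield the six classes N / CN / NL / TN / TNL / CNL.
A cluster is a maximal run of ≥2 genes spanning < 1 Mbp; density is
100 · members / span(kb).  NB domains feed a Saitou–Nei neighbor-joining tree
on amino-acid p-distances (pairwise gap deletion) with column-resampling
bootstrap support.  EST support requires ≥95% identity and ≥90% query
coverage; orthologs require reciprocal-best hits at >90% identity / >95%
coverage with both sequences single-copy.

**Physical anchoring.** In silico PCR (exact, IUPAC-aware, both strands)
labels each marker unique / no hit / multi-copy genome-wide; scaffolds anchor
to the majority linkage group of their uniquely assigned markers; coverage is
anchored bp / genome bp, and genetic–physical colinearity is summarised per
chromosome with Spearman's rank correlation.

## Worked example

```bash
python examples/03_consensus_map.py
```

simulates three mapping populations (F2 n=92, RIL n=148, suppressed RIL
n=77) from one 7 × 100 cM truth, corrupts 33 chromosome assignments, and
integrates:

```
CSS-F2: 350 loci, 679.3 cM
CSS-RIL: 350 loci, 632.8 cM
CSH-RIL: 350 loci, 588.7 cM

consensus: 350 loci in 7 linkage groups, 628.6 cM
planted conflicts resolved correctly: 33/33 (scaffold-majority evidence)
worst per-chromosome order recovery: Spearman |r| = 1.0000
```

Each component map recovers its population's usable information (the
suppressed RIL map is shortest, as expected); the consensus accounts for
every unique marker, resolves all planted conflicts from scaffold evidence,
and reproduces the true marker order exactly.  The other examples
(`examples/01…06`) walk through simulation, single-map construction, RGH
classification and clustering, the NB phylogeny, and PCR-based anchoring the
same way.  The same stages are available as a pipeline:

```bash
cucumap all --seed 1 --out cucumap_out
```

which writes every artifact (maps, consensus with provenance, classified
genes, clusters BED, Newick tree, amplicons, anchor report, summary tables)
as plain TSV/FASTA/Newick/BED plus a manifest of SHA-256 hashes; a re-run
with the same configuration is byte-identical.

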