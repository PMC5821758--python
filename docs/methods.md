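# Methods

## Model and procedure

`cadnet` implements a locus-to-module analysis for coronary artery
disease (CAD) genetics in five stages. The assumptions are:

- **Evidence is binary and locus-scoped.** Gene-to-locus linking
  (proximity windows, eQTL lookups, chromatin-interaction calls,
  deleteriousness predictions) happens upstream; the pipeline consumes
  six 0/1 flags per (locus, gene). Flag categories are ranked 1..6 and
  weighted 2^(L−1), so the weights {1, 2, 4, 8, 16, 32} make a single
  higher-ranked category outweigh all lower categories combined. The
  rank assignment is configurable (`category_ranks`); the default uses
  the conventional enumeration order of the six criteria, placing the
  mouse-knockout category at rank 6. Ties at the locus maximum all count
  as candidates; loci whose genes all score 0 are unassigned.
- **Expression gating is a median threshold.** A gene is expressed in a
  tissue when its median log2 intensity across samples is ≥ 5.0
  (boundary inclusive). The same rule applies to every tissue,
  including whole blood and the arterial tissues.
- **PPI extension is tissue-gated and two-pass.** Protein interactions
  with confidence ≥ 0.5 (inclusive; duplicate unordered pairs collapsed
  to the maximum confidence) may join a network only when both
  interactors are expressed in one common tissue of that network. Pass 1
  recruits partners of co-expression genes; pass 2 adds interactions
  among the recruited proteins but recruits no new nodes. For a
  cross-tissue network the gate is satisfied by any one of its tissues.
  Running the extension on its own output adds nothing, because pass-1
  seeding is restricted to nodes of co-expression origin.
- **Modules come from Girvan–Newman with a modularity cut.** Edge
  betweenness is recomputed after every removal; among tied maxima the
  lexicographically smallest edge is removed, making the dendrogram
  deterministic. Modularity of every partition is evaluated on the
  original graph; the maximum-modularity partition is selected, earliest
  (coarsest) on ties. A fixed block count is available as an alternative
  cut (`cut=K`). Graphs are treated as undirected and unweighted
  throughout. No minimum module size is imposed.
- **Feasibility scoring is additive.** Distance uses unweighted shortest
  paths on the full RGPN against the full (significant + suggestive)
  candidate list; module *selection* uses the significant-only list.
  The integrated score is the plain sum of the six components and lies
  in [−2, 12]; the module score is the mean over members and inherits
  the bounds.

## The CAD/Tox expression component

The pipeline normalises both expression compartments to liver, which is
deliberately excluded from both tissue groups and used only as the
divisor (it belongs to both compartments, so it cancels platform
offsets between the log2 microarray and linear FPKM scales):

1. CAD side: per-tissue median per gene, the two arterial tissues (AAW,
   IMA) averaged into one, each tissue divided by the liver median,
   mean over tissues. Ratios are taken on the values as stored
   (log2 medians); this is a documented knob, as is everything below.
2. Tox side: exact zeros replaced by 0.5 FPKM (to survive log
   transformation), genes tagged LOWDATA/FAIL removed, duplicate gene
   rows averaged (mean), per-tissue median divided by liver, mean over
   tissues.
3. Each side is min–max transformed to [0, 1] across genes — the
   simplest map achieving the stated codomain.
4. For genes present on both sides, log2((cad + ε)/(tox + ε)) with
   pseudocount ε = 0.01 (the min–max step produces exact zeros, so a
   small stabiliser is required; it only affects the ranking of genes
   within ~ε of the boundary) is linearly min–max scaled to [−2, 2].
   The cohort therefore attains −2 and +2 exactly at its argmin/argmax
   genes. Genes absent from either side score 0 (neutral).

## Statistics

All enrichment tests are right-tail Fisher exact tests (enrichment
only): p = hypergeometric upper tail P(X ≥ overlap), odds ratio
a·d/(b·c) with ∞ when b·c = 0 and a·d > 0, and the degenerate all-zero
table defined as (OR 1, p 1). GO tests are BH-corrected per module; the
headline ("main") term is the minimum q, ties resolved toward the larger
overlap then lexicographically. ATC drug-set tests are reported at raw
right-tail P < 0.05 without correction — drug sets are few (14) and the
raw-p convention keeps the per-group calls comparable. The
cardiometabolic contrast restricts the universe to drug-targeted genes,
so its counts can never exceed the overall drug-target counts. The
enrichment universe defaults to the union of all RGPN nodes.

Validation ranks scored modules descending, splits them into five
contiguous rank blocks whose sizes differ by at most one (larger blocks
at the top; boundary ties broken by module id), and adds a TOP group of
the 25 highest-scoring modules (a subgroup of the 5th quintile). The
per-module statistics are the percentage of nodes targeted by
cardiometabolic drugs and the ratio of cardiometabolic to other drug
targets; a zero denominator is capped at a configurable maximum
(default 10) rather than dropped, so modules with only cardiometabolic
targets still enter the group means. Group contrasts use the two-sided
two-sample Kolmogorov–Smirnov test, asymptotic by default with an exact
small-sample option; stars follow *p < 0.05, **p < 0.01, ***p < 0.001.

## The synthetic-data generator

The generator emulates a seven-tissue atherosclerosis expression study
(AAW, IMA, LIV, SM, SF, VF, WB) plus six toxicity-profiling tissues
(liver, heart, kidney, cerebral cortex, pancreas, testis):

- **Expression** is a two-component model per (gene, tissue): normal
  background around 4.0 and expressed class around 7.0 (sd 0.5 each) on
  the log2 scale, so the 5.0 threshold separates the classes with a
  known, small confusion rate (the planted-expressed recovery exceeds
  95% by a wide margin at 10 samples/tissue). Tox tissues exponentiate
  the same model to an FPKM-like linear scale, with 5% zero inflation
  and LOWDATA/FAIL tags at 2%/1%, exercising the zero-replacement and
  quality-filter rules. The per-gene liver level is drawn once and
  feeds both panels, mirroring liver's shared-reference role. Vascular
  presence fractions are uniform on [0.5, 1] for planted-present genes
  and [0, 0.5) otherwise.
- **Evidence** gives each locus one causal gene whose flags occupy the
  highest-ranked categories, with strictly more flags than any co-locus
  gene; with k+1 top-weighted flags it dominates any k-flag gene under
  every 2^(L−1) weighting, so planted causal genes are recoverable by
  construction. Non-causal genes draw each flag Bernoulli(0.1), capped
  at five flags. Loci are significant or suggestive with probability
  0.5 each.
- **Networks** are planted-partition graphs (default three blocks per
  network, intra-block edge probability 0.8, inter-block 0.02 — a
  regime where Girvan–Newman recovers the blocks at Jaccard ≥ 0.8)
  over genes actually called expressed in the network's tissue(s);
  every third network spans two tissues. The PPI table mixes
  within-block, between-block, extension (recruiting extra proteins)
  and decoy pairs with confidences spanning [0.2, 1], so the 0.5 filter
  always has rows to remove.
- **Annotations** sample drug targets (1–3 drug rows each, ~30%
  cardiometabolic, cardiometabolic drugs biased to ATC group C),
  kinase/GPCR families (union-collapsed), mouse-phenotype genes and
  flat GO terms from the gene universe.
- A separate **module-score benchmark** generator emulates the
  post-scoring state (100 modules, sizes 15–40, Gaussian scores) and
  optionally plants cardiometabolic target rows with probability rising
  linearly in score rank (0.35 at the top). It calibrates the
  validation statistics: the planted effect is rejected by the Q5-vs-Q1
  KS test at α = 0.01 in ≥ 95% of replicates, while the null
  configuration keeps the type-I rate at the nominal 5%.

What the generator does **not** emulate: LD structure, genotypes, raw
probe-level data, correlated co-expression noise (edges are independent
Bernoulli draws), ontology structure in GO (flat sets only), or
realistic drug polypharmacology. Passing tests therefore demonstrate
correctness of the algorithms and statistics under the stated planted
models, not performance on real cohort data, where evidence flags are
noisier and community structure far weaker.

## Numerical choices and degenerate inputs

- Deterministic tie-breaks everywhere randomness is absent from the
  model: lexicographic edge choice in Girvan–Newman, earliest partition
  on modularity ties, module blocks ordered by size then smallest
  member, quintile boundary ties by module id.
- Degenerate cases are defined, not errors, where the analysis can
  proceed: modularity of an edgeless graph is 0; an empty locus is
  unassigned; an empty KS sample is an error (no ECDF exists); an
  all-zero Fisher table gives p = 1; a module with no drug-targeted
  member gets cardiometabolic p = 1 on a zero table.
- All simulation randomness flows through seeded numpy Generator
  substreams keyed (seed, stage), so identical configurations produce
  byte-identical artifacts; the pipeline manifest records the full
  configuration, seed and package version.
- Default problem sizes (6–8 networks of 24–36 nodes, 12–30 loci,
  10 samples/tissue, 200-replicate calibrations) keep a full pipeline
  run under a second and the entire test suite under half a minute on
  one CPU; they are chosen as the smallest sizes at which every
  planted-recovery and calibration property is statistically
  well-powered.

## Known limitations

- The exact [0,1] transform and [−2,2] scaling of the expression
  component, and the scale (log2 vs linear) of the liver ratio, are
  open choices; the defaults above are the simplest maps with the
  required codomains, and alternatives would change gene-level scores
  but not the bounds or the pipeline contracts.
- Girvan–Newman recomputes betweenness after every removal (O(nm) per
  step); it is intended for the hundreds-of-nodes networks this
  analysis produces, not for graphs with millions of edges.
- The asymptotic KS p-value is conservative for very small groups
  (quintiles of one or two modules); use the exact option or more
  simulated networks when group sizes are tiny.
- Annotation sets are consumed as flat symbol sets; no GO graph
  propagation, no symbol-history resolution beyond the provided
  offline symbol map.
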