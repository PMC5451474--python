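# Methods

`mirnatime` implements an integrated temporal miRNA–mRNA analysis for a
two-breed, eight-stage developmental design in which each (breed, stage)
small-RNA library is a single pooled sample: no biological replicates exist,
so differential expression rests on an exact conditional test for tag
counts, and downstream structure (stage-group catalogues, target
prediction, short time-series clustering, network assembly) is built from
deterministic, rule-based operations. Every stage is exercisable on
synthetic data with known ground truth.

## Exact tag-count test

For a tag counted `x` times among `N1` mapped tags in one library and `y`
times among `N2` in another, the count in library 2 given library 1 follows

    p(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

the posterior predictive of a Poisson rate under a flat prior — a negative
binomial with size `x+1` and success probability `N1/(N1+N2)`. The lower
and upper tails are

    C = P(Y <= y | x),   D = P(Y >= y | x),

and the two-sided p-value doubles the smaller tail, `p = min(1, 2 min(C, D))`
(the doubling convention is the standard symmetric choice for exact
conditional tests; the source method leaves the combination rule
unstated). Numerically, the point mass is evaluated in log space through
log-gamma, and the tails use the closed form `C = I_{N1/(N1+N2)}(x+1, y+1)`
(regularized incomplete beta) rather than term-by-term summation: this is
exact to double precision, free of overflow for counts up to 1e7, and
vectorizes over entire count matrices, which matters for the
2,000-replicate calibration runs. The term-by-term summation survives as
the independent test oracle (exact rational arithmetic on a 31×31 grid at
three library-size ratios).

Two caveats are deliberate:

- **Notation.** The method as published writes the point mass as `p(x|y)`
  but sums `p(y|x)`; the conditional-on-`x` form is implemented.
- **Exchange symmetry.** `p(x, y, N1, N2)` and `p(y, x, N2, N1)` are *not*
  identical: conditioning on the first versus the second count differs by
  the conditional point mass. The discrepancy is bounded by twice the
  larger point mass (verified exhaustively at small counts) and vanishes
  with sequencing depth; the tests assert exactly that.

**Fold change** is computed on the normalized (TPM) scale with a
pseudocount of 0.5 tag-equivalents per library,
`log2(((y+0.5)/N2) / ((x+0.5)/N1))`, oriented so that a positive value
means higher expression in the second-listed library; the pipeline orders
comparisons so "up" always means higher in the reference (lean) breed.

**FDR.** The rank-based adjustment `p·m/rank` is provided in two modes:
`literal` (exactly that formula, ties sharing the maximal rank of their
group) and the default `monotone`, which applies the step-up running
minimum from the largest rank so adjusted values are non-decreasing in p —
the literal formula alone can invert the ordering. Two significance rule
sets are predefined: the global catalogue rule (p ≤ 0.005, FDR ≤ 0.01,
|log2FC| ≥ 0.5) and the per-stage pairwise rule (fold change ≥ 2, p < 0.05).

## Stage-group catalogue, ordination, enrichment

The eight stages split into embryonic G1 (35E–77E) and postnatal G2
(2P–180P). A miRNA joins a group's up (down) set when it is flagged in that
direction in **at least one** stage of the group; a miRNA flagged in
opposite directions at different stages of one group is retained in both
sets (with a warning) since the Venn arithmetic permits overlap. A pooled
mode — summing each breed's counts over a group's stages and testing once —
is provided as the alternative reading of group-level DE.

PCA ordination treats libraries as observations and miRNAs as variables,
mean-centres variables (covariance PCA, no unit-variance scaling) after
log2(TPM+1), and decomposes by SVD; for determinism the loading of largest
magnitude in each component is made positive. Term enrichment is the
one-sided hypergeometric tail `P(X >= overlap)` with the same FDR
adjustment; the annotation is a flat term→members table, with no ontology
propagation.

## Target prediction

The seed is miRNA nucleotides 2–8 from the 5′ end; a site is an exact
Watson–Crick 7-mer match of the seed's reverse complement on the UTR sense
strand (7mer-m8-like). Wobble pairing, 8mer/7mer-A1 classes, conservation
and context scoring are out of scope; a `site_class` field is reserved for
extension. Inputs are normalized for case and U/T (miRNAs may be RNA,
UTRs DNA), coordinates are 1-based inclusive externally and 0-based
half-open internally, and `N` never matches. The expected background rate
of a fixed 7-mer in a random 500-nt UTR is 494·4⁻⁷ ≈ 0.030 sites, which
the scanner reproduces within Monte-Carlo error.

## Short time-series clustering

Model profiles are integer series of length T starting at 0 with
successive changes bounded by `c` units, a universe of `(2c+1)^(T-1)`
candidates; defaults `c = 2`, `m = 50` follow the classic STEM v1.1
settings. `m` representatives are chosen greedily under the distance
`1 − Pearson r`: the first pick maximizes the summed distance to all
candidates, each later pick maximizes the minimum distance to the selected
set, ties breaking to the lowest id — fully deterministic. The all-flat
profile stays in the universe but is excluded from selection and
assignment (its correlation is undefined), and constant gene series are
excluded with a recorded reason rather than coerced.

Genes are assigned to the best-correlated representative after anchoring
each log2 series at its first time point (the profile convention; Pearson
correlation is unaffected by the anchoring, which exists so that plotted
series and profiles are comparable). With T = 4 stages per group all 24
time-point permutations are enumerated (sampling with a seed is used for
T ≥ 6); the mean assigned count over permutations is the expected count,
and the observed count is tested against `Binomial(n_assigned,
expected/n)` with Bonferroni correction over the selected profiles,
significant at corrected p < 0.05. The pipeline runs clustering on
log2(FPKM + 0.001); the small pseudocount keeps zeros finite without
compressing the dynamic range of moderately expressed genes.

## Network assembly

Predicted miRNA→gene pairs are joined with an offline gene–gene score
table (STRING-export dialect; 0–1000 integer scores are auto-detected by
the column maximum and divided by 1000). Gene–gene edges must pass
`score_min` (default 0.4, the conventional medium-confidence cut-off).
The graph is undirected — regulatory directionality is a node-type
attribute, not an edge direction. By default all targeted genes are kept
(so an empty score table still yields the miRNA–target graph);
`require_interaction=True` restricts genes to those incident to at least
one passing gene–gene edge, the rule that trims a target list to its
interacting core. Exports: SIF (Cytoscape-loadable), GraphML (full
attributes, round-trip tested), and a degree table with deterministic
hub ranking.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not raw sequencing:

- **Tag counts.** Baseline relative abundances are log-normal(0, 1.25) —
  heavy-tailed, so a few miRNAs dominate the library as in real small-RNA
  data, while keeping any single miRNA's expected share of a 200-miRNA
  library below ~10% so that planted effects cannot swallow the library's
  mass balance. Counts are Poisson around `library_size × abundance` (default
  1e6 tags; a negative-binomial option with dispersion θ models
  extra-Poisson spread of pooled libraries, but Poisson is the default so
  the exact test's type-I behaviour is interpretable). A planted effect of
  `e` log2 units splits symmetrically across breeds (×2^(e/2) and
  ×2^(−e/2)) and the unplanted background is renormalized per library so
  each column's expected total stays at `library_size`; planted miRNAs
  then have expected log2 TPM ratio exactly `e`, while background miRNAs
  absorb a small opposite compositional shift — the same counter-effect
  real TPM normalization exhibits. Planting a large fraction of library
  mass therefore visibly shifts the background, which is a property of
  compositional data, not an artifact.
- **Expression profiles.** Each gene's log2 series is
  `amplitude × template + N(0, sd)` (default sd 0.25) with FPKM = 2^series
  and the template recorded per gene.
- **UTRs.** Uniform random DNA (default 500 nt) with the seed complement
  of each planted (miRNA, gene) pair overwritten at a recorded,
  non-overlapping position; chance occurrences of planted motifs are
  recorded as collisions.
- **Interactions.** Uniform scores in [0.4, 1] for designated pairs, with
  validated/predicted flags, deduplicated on unordered pairs.

What the generator does **not** emulate: biological replicates (the design
pools samples into one library per breed–stage), sequencing error and
adaptor artifacts, miRNA biogenesis, correlated gene–gene expression, and
isoform structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data features.

All generators draw from `numpy.random.default_rng([seed, salt])` with a
distinct salt per generator, so a single seed yields independent but fully
reproducible streams.

## Calibration and problem sizes

The self-checks run at these sizes, chosen to give tight Monte-Carlo error
while keeping the whole suite interactive: type-I calibration at 200
miRNAs × 2,000 replicate null comparisons (observed ≈ 0.048 at the 0.05
level — slightly conservative, as the doubled discrete tail guarantees);
power at 20 planted four-fold miRNAs among 200 over 50 datasets (all 20
recovered on average; rule-level false positives ≈ 0.1–0.2%); profile
recovery at 100 planted-template genes (noise sd 0.25) among 900
unstructured background genes against 50 representatives. The planted
template used in the recovery checks is the first greedily-selected
representative — deterministic and maximally separated from the rest of
the universe.

## Known limitations

- No replicate-aware dispersion estimation; the exact test treats each
  pooled library as one Poisson draw, so biological variance between
  animals is invisible to it.
- The per-stage FDR family is each comparison's full miRNA list; how a
  multi-comparison global family should be assembled is configurable
  rather than fixed.
- Seed matching is a deliberately minimal 7-mer exact rule; it
  over-predicts relative to context-aware methods.
- Profile ids depend on the enumeration and selection parameters; they are
  stable within this implementation but not comparable to other tools'
  numbering.
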