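# Methods

## Gene-content model

The unit of comparison is the pham: a family of homologous phage genes.
The package takes gene→pham assignments as given (long-format TSV,
`genome  gene  pham`) and never constructs families from sequence itself;
the genome × pham count matrix (`PhamTable`) is the central object. All
shared-content statistics use presence/absence of phams — a paralogous
second copy changes gene counts and CCI's numerator but never a shared-pham
percentage or a conserved-pham test. An *orpham* is a pham whose total gene
count across the whole dataset is exactly one (one gene, not one genome:
a pham with two copies in a single genome is not an orpham).

## Nucleotide clustering

Cluster membership follows the similarity-span rule: two genomes belong
together when DNA similarity covers more than half of their lengths.
Similarity is approximated without an aligner: exact shared words of
length `w` (both strands; reverse-complement hits recorded in forward
coordinates of both sequences) are widened to w-length intervals,
intervals separated by at most `merge_gap` are merged, and the union
length is divided by the genome length. Defaults: `w = 10` (the
conventional dotplot word length), `merge_gap = 3w` — enough to bridge
isolated point mutations without inventing gapped alignment.

Two numerical caveats are intrinsic to the method:

- **Word length must scale with genome length.** The expected chance
  coverage from w-mer collisions grows like `L_a·L_b / 4^w`; at 2 kb and
  w = 10 it is negligible, but 30 kb toy genomes need w ≈ 14 or spurious
  matches blanket the sequence. The analysis driver for sequence
  clustering uses w = 14 for exactly this reason.
- **The span relation is not transitive.** Clusters are connected
  components (single linkage) of the graph whose edges are pairs
  exceeding the threshold on *both* genomes (`rule="both"`; `"either"`
  is available). Components are the only automation invariant to input
  order; manually curated clusters can differ near the boundary. The
  rule's sharpness shows up honestly in the analyses: genome pairs whose
  true sharing hovers near 50% fall on either side by sampling noise.

Cluster labels are A, B, C… by descending size, ties broken by the
lexicographically smallest member id. Subclusters re-run the same
procedure within one cluster at a stricter threshold (the criterion for
subcluster boundaries is not standardised; a second threshold is this
package's operationalisation) and are labelled A1, A2, …

## Diversity and isolation indices

Defined in the README; implementation notes: conserved-pham tests use
presence (count ≥ 1); all indices are percentages in [0, 100], with a
`--fraction` / `as_fraction` flag for a 0–1 scale because both conventions
circulate for CCI; single-genome clusters report CLASP/CAP/CCI as N/A
(a cohesion statistic of one genome is vacuous) but CPV (trivially 0) and
CII are defined. CII of a cluster equal to the whole population returns
100 with a warning — there is no outside population to be isolated from.

## Rarefaction

Monte-Carlo, uniform random genome permutations without replacement
(default 10,000 iterations, the convention for this analysis; the spread
stabilises far earlier). Per iteration the discovery rank of every pham is
the minimum permutation rank of its member genomes — a grouped minimum
(`np.minimum.reduceat`) over a pham-grouped index array, O(presence
entries) per iteration, which makes 10,000 iterations on a 627-genome
collection a few seconds. A bincount of discovery ranks yields the
per-step new-pham increments; their cumulative sum is the accumulation
curve, so `mean_phams` and `mean_new_phams` are exactly consistent by
construction. SDs use the population formula (divide by the iteration
count); at 10,000 iterations the difference from the sample formula is
negligible but the choice is fixed for bit-reproducibility. The
confidence band is mean ± 2 SD. With a fixed seed results are
bit-reproducible; the exhaustive-enumeration oracle in the tests checks
the Monte-Carlo against all permutations for small tables.

CLASP resampling draws, per sample size (default 5/10/20/30) and
iteration (default 20), a uniform subset *without replacement within the
subset*; independent iterations may repeat subsets. (A subset drawn with
replacement would duplicate genomes and corrupt the pairwise definition,
so that reading of "iterations performed with replacement" is rejected.)

## Pangenome models

Closed: `N(n) = Pham_max·n/(K_m+n)`; open adds `C·n`. Estimation follows
the linearisation route: Hanes–Woolf regression (OLS of n/y on n; slope
1/Pham_max, intercept K_m/Pham_max), fit by default to the first half of
sample sizes — the early curve determines the hyperbola while the tail
determines the linear term — with the goodness-of-fit r always the
Pearson correlation of the observed curve against the model prediction
over the *full* range. Hanes–Woolf is kept as the estimator (rather than
nonlinear least squares) because the linearisation is algebraically exact
on model-generated data and keeps the procedure transparent; noiseless
curves return their parameters to machine precision.

The influx rate C is seeded by the plateau estimator — the mean of the
last `tail_window` new-pham increments (default: last 10% of sample
sizes, at least 10 points, at most half the curve) — and then refined by
fixed-point iteration inside `fit_open_model`: subtract the fitted
hyperbola's own tail increments from the observed ones, re-estimate C,
re-fit, repeat to convergence. The refinement matters whenever K_m is not
small relative to N (the hyperbola then still contributes increments in
the tail and the raw plateau over-estimates C); at the true parameters
the procedure is exactly a fixed point, which is what makes noiseless
recovery exact. Updates are clamped at C ≥ 0 with a warning — an influx
rate is non-negative, and on closed or very short curves an unclamped
iteration can run away negative.

Degenerate inputs: non-positive y anywhere in the fit range is an error
(the linearisation divides by y); a non-positive Hanes–Woolf slope means
the data are not hyperbola-like and is an error rather than a nonsense
parameter set; a constant curve is handled naturally as the saturated
limit (Pham_max = y, K_m → 0).

## Synthetic populations

`generate_population` draws, per genome: all core phams of its cluster;
Bernoulli(accessory_prob) from the cluster's accessory pool;
Bernoulli(global_prob) from a population-wide pool (cross-cluster
sharing, which strictly lowers CII); Poisson(influx_rate) novel phams
from an unbounded label space — never reused, so every influx pham is an
orpham and the rarefaction increment tail converges to the influx rate,
which is the ground truth the model fits are judged against. One gene per
included pham by default; `mean_extra_genes` adds Poisson-distributed
paralogous duplicates of already-present phams.

The `table1_like` preset encodes the study conditions the package is
exercised under: 20 clusters whose sizes (232, 109, 45, … 2) and mean
genes per genome (31–240) mirror a large real collection's uneven
profile, 8 singleton genomes whose private genes are orphams by
construction (>30% orpham content), a 300-pham global pool at p = 0.1,
and influx 2.5 novel phams/genome. Per cluster, core ≈ 0.4 and accessory
pool ≈ 1.2 of the target gene count at p = 0.5, so expected distinct
phams per genome ≈ the target.

Toy sequences give each pham one canonical random segment
(length ~ N(mean, sd), default 300 ± 50 bp, floored at 30 bp); a genome
is the concatenation of its phams' canonicals in sorted pham order, each
copy independently point-mutated. What this does *not* emulate: gene
order/synteny (sorted concatenation is arbitrary), rearrangements,
indels, GC/codon structure, intergenic DNA, and realistic homologue
divergence. Passing the sequence-clustering tests therefore shows the
span machinery and the >50% rule are implemented correctly — not that
the rule would behave identically on real genomes, where similarity
detection is an alignment problem.

## Problem sizes

The analyses run the full 627-genome preset (10,000 rarefaction
iterations — seconds at this scale thanks to the reduceat formulation).
The sequence-clustering analysis simulates a 54-genome subset because
all-pairs exact-word dotplots are quadratic in both genome count and
length, and every property of interest is visible at that size. Test
configurations use 200–300 genomes and 500–2,000 iterations where a
statistical property is asserted, and enumerable sizes (≤ 6 genomes)
where an exhaustive oracle is the comparison.

## Known limitations

- Pham construction (protein clustering) is out of scope; garbage
  assignments in, garbage indices out.
- The span approximation has no gapped alignment and no masking of
  low-complexity repeats; real genomes with long exact repeats inflate
  spans.
- Connected-component clustering can chain distinct groups through one
  bridging genome — a faithful rendering of the rule, not a defect of the
  implementation, but worth knowing.
- The influx estimate C absorbs *any* source of per-genome novelty in
  the tail (e.g. rare accessory phams of under-sampled clusters), so on
  heterogeneous collections it is an upper bound on true external influx;
  per-cluster curves are the cleaner estimate.
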