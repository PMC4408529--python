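# phagepan

Comparative gene-content analysis for collections of phage genomes:
cluster assignment from nucleotide similarity spans, per-cluster diversity
and isolation indices, rarefaction of gene-family discovery, and
closed-vs-open pangenome model fitting — with a synthetic population
generator so the whole pipeline is testable end to end without any
external data.

## The problem

Phage genomes are mosaics: modules with distinct evolutionary histories,
exchanged horizontally. Large collections of phages isolated on a single
bacterial host sort into *clusters* of genomes sharing nucleotide
similarity over more than half their lengths, yet clusters differ wildly
in how cohesive and how genetically isolated they are. Comparing genomes
by *gene content* — grouping genes into families of homologues
("phamilies", phams) and asking which genomes carry which phams — exposes
this structure, and resampling the collection asks a sharper question: is
the gene pool closed (a hyperbolic, saturating discovery curve) or open,
continuously fed new gene families by horizontal influx from outside the
host's neighbourhood?

The package is written for computational phage biologists and for anyone
studying pangenome openness with gene-family accumulation curves.

## The statistics at the core

For a cluster with members' distinct-pham sets \(S_1..S_k\):

- **CLASP** — mean over genome pairs of the shared-pham percentage,
  each pair averaged between the partners:
  `100 · mean_{i<j} (|S_i∩S_j|/|S_i| + |S_i∩S_j|/|S_j|)/2`
- **CAP** — phams conserved in *every* member as a percentage of the mean
  phams per member.
- **CPV** — percentage of the cluster's pham union *not* conserved in all
  members.
- **CCI** — mean genes per genome as a percentage of the cluster's total
  phams (identical single-copy genomes ⇒ exactly 100).
- **CII** — percentage of the cluster's phams absent from every genome
  outside the cluster.

Rarefaction draws random genome orderings without replacement and averages
the cumulative distinct-pham count N_phams(n). Two models are fit by
Hanes–Woolf regression (ordinary least squares of n/y on n, which is exact
on noiseless data):

    closed:  N_phams(n) = Pham_max · n / (K_m + n)
    open:    N_phams(n) = C · n + Pham_max · n / (K_m + n)

`C` is the influx rate — the expected number of novel gene families each
additional genome contributes — estimated from the plateau of the
per-genome new-pham increments and refined jointly with the hyperbola.

## Worked example

The `analysis/` scripts run the full study on a simulated collection of
627 genomes in 28 clusters (sizes 2–232 plus 8 singletons, influx rate
2.5 novel phams/genome):

```
$ python analysis/01_simulate_population.py --seed 0
generated 627 genomes in 28 clusters
  89778 genes over 5849 phams (15.3 genes/pham)
  1608 novel influx phams (configured rate 2.5/genome)

$ python analysis/02_gene_content.py
89778 genes assembled into 5849 phams (15.35 genes/pham)
2335 orphams = 40% of phams

$ python analysis/05_rarefaction.py --seed 0
all 627 genomes: 5849 phams total; mean new phams over the last 10% of
sampling: 3.80/genome (10000 iterations)
cluster A (232 genomes): 1043 phams; tail new phams 2.59/genome
cluster B (109 genomes): 760 phams; tail new phams 2.76/genome

$ python analysis/06_pangenome_models.py
all (627 genomes):
  closed hyperbola: Pham_Max=5242, K_m=66.8, r=0.9618
  open model:       C=3.40 new phams/genome, Pham_Max=3845, K_m=41.3, r=0.99880
cluster_A (232 genomes):
  closed hyperbola: Pham_Max=797, K_m=15.7, r=0.8834
  open model:       C=2.56 new phams/genome, Pham_Max=457, K_m=2.3, r=0.99886
open model correlates better on 3/3 curves
```

Reading the output: the closed hyperbola cannot follow an accumulation
curve that never saturates (r ≈ 0.88–0.96), while the open model tracks it
(r ≈ 0.999) and its linear term recovers the influx the generator
injected — 2.56–2.61 new phams/genome inside single clusters against a
ground truth of 2.5. The whole-collection estimate (3.40) runs higher
because the eight orpham-rich singleton genomes and the cross-cluster
gene pool also deliver novelty per genome sampled; the per-cluster curves
are the cleaner read-out, which is why both are computed.

`analysis/03_sequence_clusters.py` and `analysis/04_diversity_indices.py`
cover the nucleotide-span clustering (with its honest boundary cases —
pairs at 49–52% span sit exactly at the >50% rule) and the per-cluster
index report with CLASP subsample stability.

A `phagepan` console command exposes the same steps
(`simulate`, `phams`, `cluster`, `indices`, `heatmap`, `rarefy`, `fit`,
`nexus`, `all`) for ad-hoc use on external gene-assignment tables.

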