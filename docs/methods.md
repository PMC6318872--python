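# Methods

This note records the models and procedures implemented in `mhbcircuit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
want written down.

## Study design and data model

The package analyses a 2×2 factorial community experiment: a host plant
grown alone or with an ectomycorrhizal fungus and/or a rhizosphere
bacterium, with replicated root metatranscriptomes (3 replicates per
condition by default, 12 samples). Inputs are per-sample read→candidate-gene
alignments (a read may align to several genes, possibly in different
organisms), a gene catalog (id, organism, length in bp), the design table,
a gene→GO-BP annotation map, and per-condition phenotypes (percent
mycorrhization, shoot/root biomass). Reads are the unit throughout; the
package neither aligns reads nor models paired-end fragments, matching the
50-bp single-end setting it targets.

## Bootstrapped RPKM quantification

Each bootstrap iteration assigns every multi-aligned read uniformly at
random to exactly one of its candidate genes; uniquely aligned reads always
count for their gene. RPKM_g = n_g / (L_g/10³ · N/10⁶), where N counts each
read once regardless of its number of alignments, so the per-iteration
library size is constant. Mean and SD are taken across iterations (sample
SD, ddof = 1; integer count accumulators with a constant-count fast path,
so unambiguous genes report their closed-form RPKM with SD exactly 0).

* `iterations` — default 10,000; tests and the acceptance script use
  200–500, which changes the Monte-Carlo error of the mean as 1/√iterations
  and nothing else.
* This implementation re-assigns multi-mapped reads only; it does **not**
  resample reads with replacement. The SD therefore reflects alignment
  ambiguity, not counting noise. This is the narrower of the two possible
  readings of bootstrap quantification and is flagged here deliberately.

Expression significance: p = Φ((0 − mean)/SD), the normal probability that
expression ≤ 0 given the bootstrap mean and SD. Zero is the only null point
that makes "significantly expressed" coherent; SD = 0 degenerates to p = 0
(mean > 0) or 1. BH adjustment is applied per sample (pooling across
samples would mix libraries of different depth); a gene is expressed when
q < 0.05 **and** mean RPKM > 2. Genes never expressed in any sample are
excluded from differential testing to reduce the multiplicity burden
(configurable).

Normalization: log2(mean RPKM + pseudocount), pseudocount 1 RPKM (zeros must
be logged somehow; 1 keeps the origin at 0), then quantile normalization.
Ties within a column receive the mean of the reference values they span, so
exact ties stay tied; with ties present the sorted columns then agree only
up to tie blocks, and tie-averaged normalization is idempotent only on
tie-free data. A `ties="order"` mode breaks ties positionally and makes the
column distributions exactly identical and the map idempotent; the default
is the tie-averaging mode because it does not invent order among equal
values.

## Permutation two-factor ANOVA

Classical fixed-effects two-way ANOVA per gene (factors: fungus presence,
bacterium presence, interaction), computed via residual projectors with
Type II sums of squares, so unbalanced designs degrade gracefully; on the
balanced 2×2 design Type II equals the textbook decomposition (verified
against statsmodels to 1e-10 relative). Constant genes are assigned F = 0
rather than a ratio of projection round-off.

Significance is by unrestricted permutation of whole sample labels, the
same schedule for every gene and all three factors, with the add-one
estimator p = (1 + #{F\* ≥ F}) / (1 + n_perm) so p = 0 is impossible.
Default n_perm = 10,000 (tests use 499–1,999). Note that a permutation that
happens to reproduce the factor's grouping recreates F exactly and counts
toward the numerator, so the minimum p is attained only when no sampled
permutation preserves the split.

BH is applied per factor across genes; a gene is SDE when significant for
at least one factor. A `correction="raw"` flag thresholds the raw
permutation p-values instead — the two conventions coexist in practice and
the choice is surfaced rather than hidden. The SDE set is partitioned into
the seven regions of the three-set Venn diagram.

## Co-regulation clustering

K-means (Euclidean, K-means++, best of 25 restarts) on per-sample
normalized log2 values, gene-wise mean-centered so distance reflects the
shape of the response rather than absolute expression (full z-scoring via
`scale="zscore"`). K is chosen by the mean silhouette coefficient over
K = 2…12, ties toward smaller K; the silhouette uses the full pairwise
distance matrix (fine for 10³–10⁴ genes; subsample upstream for more).

Cluster profiles are per-condition means of (log2 expression − the gene's
own baseline-condition mean), averaged over member genes and replicates, so
the baseline column is identically 0. The mycorrhization-correlated cluster
is the argmax Pearson correlation between profile and the percent-
mycorrhization vector over the four conditions; its significance is
z = (r − mean r_others) / sd(r_others) with a one-tailed upper normal p
(the claim is "higher than the others"; the reference SD uses ddof = 1).
With four support points the correlation itself is coarse; the z-reference
against the other clusters is what carries the inference.

## Annotation enrichment

Exact cumulative hypergeometric upper tail P(X ≥ k) for k annotated members
in a cluster of n, against the background of all annotated host genes
(other organisms are excluded). Raw p < 0.05, no multiple-testing
correction by default (a BH option exists but is off): per-cluster
vocabularies are small and the screen downstream demands uniqueness anyway.
Terms are tested exactly as annotated; no ontology-graph ancestor
propagation is performed. A term is uniquely enriched when enriched in
exactly one cluster.

## Bayesian network and Boolean circuit

Nodes: one per cluster (mean member expression per sample) plus two
presence nodes carrying the design indicators. Cluster nodes are
discretized by quantile binning; **binary states are the default**. The
downstream circuit is Boolean, and with 12 samples a 3-bin split (4/4/4)
cuts the ON/OFF groups of an XOR-responding node across bins, destroying
exactly the dependency the search must find; 3 bins remain available via
`n_bins`.

Structure search: greedy hill climbing over add/delete/reverse edge moves
under three hard constraints — acyclicity, ≤5 parents per node, presence
nodes may not be children. Two search details matter and are deliberate:

* **Score.** BIC by default (multinomial log-likelihood −
  0.5·log N·q·(r−1)); BDeu (ESS configurable, default 1) via
  `score="bdeu"`. At n = 12, BDeu systematically prefers many-state
  expression proxies of the design factors over the factors themselves;
  BIC's dimension penalty keeps the noise-free binary presence nodes
  competitive, which is a prerequisite for recovering presence-driven
  logic at all.
* **The XOR pathology.** A node regulated by the XOR of two inputs is
  marginally independent of each input, so no single-edge addition is ever
  score-improving and a pure single-edge climb can neither discover the
  pair nor swap a trapped parent set for it. The climb therefore also
  evaluates a constant-size *presence-replacement* move (set a cluster
  node's parents to the best of the ≤4 subsets of the presence nodes), and
  one deterministic restart starts from the per-node best presence subset.
  Remaining restarts (default 20 total) start from random sparse DAGs.
  Score is non-decreasing along each accepted trajectory; move ties break
  in canonical node order, so results are reproducible for a fixed seed.

The best network is transitively reduced (if A→B, B→C and A→C all exist,
A→C is removed); reduction is unique for DAGs and verified against a
brute-force path oracle in tests.

Gate fitting: every node is binarized per condition — a cluster node is ON
iff its condition-mean log2 fold change vs baseline exceeds
`up_threshold` = 0.5 (dead zone: anything ≤ 0.5, including strong
down-regulation, is OFF; regulated clusters in this design sit well outside
±0.5). For each cluster node with parents, the Boolean function with the
fewest mismatches over the four conditions is found by exhaustive search
(2^(2^k) candidates for k ≤ 3; larger parent sets are first reduced by
greedy selection of ≤3 informative parents). Ties break toward fewer
dependent inputs, then the smaller canonical truth-table index. Labels
(CONST0/1, ID, NOT, AND, OR, NAND, NOR, XOR, XNOR, GENERIC-k) depend only
on the function restricted to its relevant inputs, hence are invariant to
parent order. "MHB activity" is reported as the binary state of the
mycorrhization-correlated cluster — the circuit's output node.

Sensor screen: (i) clusters whose fitted gate depends on both presence
inputs; (ii) sensor-class terms (default {GO:0048544}) enriched in such a
cluster; (iii) uniquely so. Returns the member genes carrying qualifying
terms with per-criterion flags.

With 12 samples the structure search is weakly determined; the package
treats the *gate on the planted/designated cluster*, not the full edge
list, as the reproducible object. `CircuitResults.xor_gate_on(genes)`
implements that check.

## Community statistics

A read is attributed to every organism among its candidate genes (any-hit),
so per-organism percentages may exceed 100% by construction. Presence
enrichment: fold = ratio of group means of per-sample percentages,
one-tailed Welch t-test (the simplest test defensible at n = 3 per group;
if both groups are constant the t statistic is undefined and p degenerates
to 0.5/0/1 by the sign of the mean difference). Fold and p are scale-
invariant in the percentages.

## The synthetic generator

`synthetic.generate_experiment` emulates: three co-resident genomes with
very unequal shares (host ≥ 99% of reads), log-uniform baseline gene
abundances spanning three orders of magnitude, planted co-regulation
clusters with per-condition log2 fold changes (the `fig3-like` preset
carries six patterns: down-everywhere, mycorrhization-tracking,
bacterium-down, fungus-only-up defense, the XOR pattern, bacterium-up),
lognormal replicate noise on expected counts with Poisson sampling,
multi-alignment via 1–3 uniform decoy genes on a configurable fraction of
reads (cross-organism decoys allowed), planted term enrichments over a
random GO background, and a mycorrhization phenotype that is 0 wherever the
fungus is absent and ~1.7× higher when the bacterium accompanies it.

Defaults, chosen once: 1200/120/60 genes (host/fungus/bacterium), gene
lengths U(300, 3000) bp, 200,000 reads per sample — set so the median gene
receives tens of reads, i.e. the per-gene coverage regime of a real
RNA-seq study at a catalog scaled down ~30× — `multimap_fraction` 0.10,
`noise_sd` 0.25 (natural-log scale ≈ 0.36 log2 units between replicates),
microbial read shares 0.10%/0.005% when absent with 12×/3× boosts when
present.

What it does **not** emulate: nucleotide sequences, quality scores or
alignment-error structure; sequence-similarity-driven multi-mapping (decoys
are uniform over the catalog, so cross-organism ambiguity is far more
aggressive than reality — with multimapping on, organism read shares are
dominated by decoys, which is why presence folds are measured on
multimap-free generations); isoforms; library-preparation biases; batch
effects. Passing recovery tests therefore demonstrates correctness of the
inference chain under its own assumptions, not robustness to artifacts the
generator does not model.

## Problem sizes in tests and the acceptance script

The suite runs a scaled experiment (300/40/20 genes, 20 genes per planted
cluster, 60,000 reads/sample, 200 bootstrap iterations, 499 permutations,
10 network restarts) chosen to preserve per-gene coverage and effect sizes
while keeping the full suite under a minute of compute for the synthetic
stages; the acceptance script additionally fits one full-size experiment
(1200 host genes, 200,000 reads/sample, 500 iterations, 1,999 permutations)
and measures XOR recovery over 20 independent scaled replications. At the
scaled size the silhouette often selects K = 4–5 rather than the planted 6
because two planted pattern pairs are strongly correlated; the XOR cluster
itself separates cleanly, which is what the recovery statistic tracks.

## Known limitations

* The bootstrap quantifies ambiguity, not biological or counting variance;
  its SD is an underestimate of total uncertainty.
* Permutation ANOVA at n_perm = 10,000 cannot produce p below ~1e-4;
  FDR-adjusted inference near that floor is resolution-limited.
* With 12 samples the learned network is one of many near-equivalent
  structures; only presence-rooted gate logic is treated as stable.
* Enrichment without ancestor propagation under-counts general GO terms;
  the planted-vocabulary tests are unaffected, real GO annotations would
  benefit from upstream propagation.
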