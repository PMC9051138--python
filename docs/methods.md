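# Methods

## Problem and approach

Metagenomic binning groups assembled contigs into bins so that each bin
contains the contigs of one genome. `siambin` is a semi-supervised binner:
beyond the unsupervised signals every binner uses (tetranucleotide
composition and per-sample read depth), it exploits pairwise constraints
that can be manufactured or harvested cheaply:

* **must-link** pairs — each sufficiently long contig is split in half; the
  two halves provably come from one genome;
* **cannot-link** pairs — two contigs whose confident taxonomic annotations
  disagree, or two contigs that carry the same single-copy marker gene,
  should not share a bin.

A siamese autoencoder is trained on these constraints and its embedding
replaces the raw features for clustering. Clustering is community detection
(two-level map equation / Infomap) on a sparsified similarity graph,
followed by optional marker-guided reclustering of bins that appear to
contain more than one genome.

## Features

Contigs shorter than a minimum length are excluded from binning. The
default minimum is 2500 bp, lowered to 1000 bp when contigs of 1000–2500 bp
hold less than 5% of the total basepairs (the fraction is configurable):
when short contigs are rare they are cheap to include.

Each surviving contig is represented by its canonical 4-mer relative
frequencies: 256 tetranucleotides collapse into 136 reverse-complement
equivalence classes; counts over all overlapping windows (windows containing
N are skipped deterministically) receive a pseudo-count of 1e-5 and are
normalized to sum to one. The pseudo-count is added to every class before
the normalizing sum so the vector is a proper distribution — this also keeps
every entry strictly positive, which the contrastive geometry assumes.

Abundance is the mean per-base read depth of a contig in a sample, consumed
as summary statistics (mean and population variance of the per-base depth)
through a TSV contract, so the package needs no alignment tooling; a helper
converts per-base depth arrays to these summaries. When **N ≥ 5** samples
are available, the model input is the 136 k-mer frequencies followed by the
N abundances, each divided by a per-sample scale s = 100·⌈ā/100⌉ (ā = mean
abundance over the sample's filtered contigs; ā = 0 maps to s = 100) that
brings depths to the 0–1 range of the frequencies. With fewer samples the
model input is the k-mer vector alone and abundance instead enters the
similarity (below). The scale's averaging population (filtered contigs of
the sample) is a package choice; any fixed population of comparable
magnitude would serve.

## Constraints

The must-link splitting threshold is chosen by a scan over the distinct
observed contig lengths: the largest length L such that contigs ≥ L still
hold ≥ 98% of all basepairs, floored at 4000 bp so each half supports
stable composition and coverage estimates. A contig of length L yields
fragments of ⌈L/2⌉ and ⌊L/2⌋ bp named `<id>_1`/`<id>_2`; fragments carry
their own k-mer profiles and inherit the parent's coverage (depth is locally
homogeneous at half-contig scale), and they exist only for training — the
original contig remains the unit of binning.

Cannot-link pairs are emitted between contigs whose species annotations
differ with both scores strictly above 0.95, or whose genus annotations
differ with both scores strictly above 0.80. Additionally, the single-copy
marker family observed on the largest number of distinct contigs (ties
broken lexicographically) defines seed contigs, all pairs of which become
cannot-links: a single-copy gene appears once per genome, so its carriers
represent distinct genomes. Richer seed-selection schemes (median marker
count, expectation-maximization seeding) exist; the single most prevalent
marker is the simplest rule with the same justification and is isolated
behind one function. Cannot-link pairs are generated between original
contigs only — fragments carry the parent's annotation, so fragment pairs
would merely duplicate parent pairs at four times the training cost. The
pooled cannot-link set is capped at four million pairs by uniform seeded
subsampling.

## The siamese autoencoder

Encoder F → 512 → 512 → 100 and decoder 100 → 512 → 512 → F, where the
first two layers of each half are followed by batch normalization, leaky
ReLU, and dropout (rate 0.2), and the encoder output layer is linear.
Hidden sizes are configurable; nothing downstream depends on them. The two
siamese branches share all weights (implemented by passing both pair members
through the same layers as one batch).

Two losses are optimized jointly with equal weight by Adam (learning rate
1e-3):

* contrastive, over constraint pairs: mean of y·d² + (1−y)·max(1−d, 0)²
  with d the Euclidean embedding distance and y = 1 for must-link pairs;
* reconstruction: mean squared error between the decoder output and the
  input, over **all** contigs each epoch, not only constrained ones, so the
  embedding preserves structure shared by all genomes.

Each epoch iterates over all constraint pairs in shuffled batches (default
1024 pairs); the shuffled full contig set is chunked to match the number of
pair batches so both losses contribute to every optimizer step. Default 20
epochs. Epochs, batch size, loss weighting and learning rate are package
defaults, exposed in `NetworkConfig`. The network is implemented directly
on NumPy with hand-written backpropagation and is gradient-checked against
central finite differences in the test suite; training and inference are
deterministic for a fixed seed on a single CPU device. Inference runs in
evaluation mode (running batch-norm statistics, dropout off).

Trained models serialize to a self-describing container holding a format
version, the architecture configuration, the feature regime (k-mer only vs
k-mer plus N abundances) and all weights; applying a model to data with a
different feature dimension or regime is an error. This enables the
pretrain workflow: train once on one or more samples, apply unchanged to
others. Pretraining on several samples concatenates per-sample profiles and
constraints; constraints never cross samples.

## Similarity and clustering

The similarity of two contigs is S = 1 − min(d, 1) when N ≥ 5 (abundance is
inside the embedding) and S = 1 − min(d·a, 1) otherwise, where d is the
Euclidean embedding distance and a is the coverage-divergence term: per-base
depth of each contig in each sample is modeled as a normal distribution
(mean and variance from the coverage summaries), and a is the symmetrized
Kullback–Leibler divergence ½[KL(P‖Q) + KL(Q‖P)] averaged over samples.
Symmetrization is required for an undirected graph weight. The divergence
is clamped to [1e-6, 1−1e-6] before use as a multiplier — the lower clamp
prevents the degenerate S ≈ 1-for-all when coverages coincide — and
variances are floored at 1e-4·mean + 1e-6 so constant-depth contigs do not
break the closed form.

From the implicit complete graph, each node nominates its `max_edges`
(default 200) highest-weight incident edges (ties broken lexicographically
by neighbor id; zero weights never nominated) and the kept edge set is the
union of nominations. The same construction on the original feature vectors
(with the same abundance multiplier in the N < 5 regime) gives a second
graph, and only edges present in both survive, weights taken from the
embedded graph — removing edges the embedding introduced that have no
support in the raw features. Communities are found with Infomap
(python-igraph), one seeded trial of the two-level map equation;
python-igraph draws randomness from Python's `random` module, which is
seeded locally for the call.

Bins whose mean single-copy-marker count exceeds one (total marker hits
divided by panel size; a clean complete bin scores 1.0) are optionally
re-split (on by default, `--no-recluster` to disable): k is the maximum
copy number of any single marker in the bin, the initial centers are the k
carriers of the most duplicated marker (ties by descending length), the
feature space is the embedding concatenated with the scaled abundances, and
a weighted k-means (sample weights = contig lengths in bp, tolerance 1e-4,
up to 300 iterations; scikit-learn) runs to convergence. Choosing k from
marker copy number ties the number of output bins to the direct evidence of
genome multiplicity. Finally, bins smaller than 200 kbp (configurable) are
dropped and their contigs reported unbinned; surviving bins are named
`bin_<index>` by descending total basepairs.

Ablation variants mirror the semi-supervision study: `nosemi` clusters the
raw feature vectors with no model; `m` additionally inserts weight-1 edges
for must-link pairs (on the unsplit catalogue these collapse to self-pairs,
so `m` coincides with `nosemi` — recorded here for transparency); `c`
deletes edges between cannot-link pairs; `mc` does both.

### Binning modes

`single` and `coassembly` bin one contig catalogue (abundance may span
several samples). `multi` expects contigs labeled `<sample>:<name>`; each
sample is binned separately while abundance information from all samples is
used, and bin ids are prefixed with the sample, so bins never mix samples.

## Synthetic communities

The generator plants a known genome structure and emits every pipeline
input. Each genome is sampled from its own order-2 Markov chain over ACGT
whose 16 transition rows are Dirichlet draws (concentration 8 per symbol)
centered on uniform — enough compositional idiosyncrasy that 10 kb
fragments of different genomes are farther apart in 4-mer space than
fragments of one genome, which is precisely the assumption composition-based
binning rests on. Defaults describe a desk-scale but non-trivial study:
20 genomes × 300 kb in 3 samples; contig lengths log-normal (median 20 kb,
σ = 0.4, clipped to 4–60 kb, the genome's final remnant may be shorter);
per-genome per-sample abundance log-normal (median 20×, σ = 1.0) with 10%
log-normal contig-level jitter; depth variance = mean × 1.5 (Poisson plus
moderate overdispersion); taxonomy labels per genome (distinct species,
genera shared by pairs) with scores uniform on [0.85, 1.0] and a 5% chance
per contig of a swapped species label; a panel of 10 single-copy markers
placed once per genome on contigs ≥ 2500 bp.

The "hard" preset adds two strain pairs — copies of base genomes with 1%
random substitutions, sharing the parent's species label, with per-sample
abundance equal to the parent's times a log-normal ratio (σ = 0.2). Such
strains are nearly inseparable by composition and only moderately separable
by coverage, so graph clustering tends to merge them into one bin carrying
every marker twice; this is exactly the situation the marker-guided
reclustering step exists to resolve, and the preset exercises that path.

What passing on these fixtures does **not** show: robustness to chimeric or
repeat-collapsed contigs, to assembly fragmentation below the length filter,
to annotation biases that are correlated rather than independent across
contigs, or to real inter-genome compositional similarity (real genera can
be compositionally closer than independent Dirichlet draws). Real-data
performance must be established on real data.

## Numerical and design notes

* All tie-breaks (edge nomination, seed selection, marker choice, bin
  naming) are lexicographic or by explicit keys — the pipeline is
  bit-reproducible for fixed inputs and seed.
* Training uses float32 for throughput; losses are accumulated in float64.
  The gradient checks run the pure loss functions in float64.
* Problem sizes in the test suite and acceptance script (communities of
  6–22 genomes of 120–300 kb, 12-node exhaustive map-equation checks) are
  chosen so the whole suite runs on a laptop-class single CPU in minutes
  while still exercising every pipeline path at non-toy scale.
* Degenerate inputs: empty constraint classes, contigs with no valid 4-mer
  window, missing coverage records, and regime/dimension mismatches at
  model application are hard errors, not warnings.
* The per-node edge budget (`max_edges` = 200) exceeds the node count of
  the default synthetic communities, so sparsification there reduces to
  dropping zero-similarity edges; the budget matters at real-data scale.

## Known limitations

* The Maxbin2-style seed-contig predictor is reduced to the
  most-prevalent-marker rule (see Constraints); its output shape (a set of
  seed contigs, one per putative genome) is the same, but counts can differ
  from the original heuristic on incomplete marker tables.
* The `m` variant is a no-op relative to `nosemi` when must-links come only
  from splitting (the only built-in source).
* Only two-level map-equation partitioning is implemented (no hierarchical
  modules, single trial).
* No BAM ingestion; coverage enters via the documented TSV contract or
  per-base depth arrays.
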