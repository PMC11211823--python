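# Methods

`motifsyntax` interprets sequence-to-function neural networks for mRNA
regulation: it discovers cis-acting motifs from convolutional neurons, decides
each motif's contribution direction, and quantifies epistasis between
co-occurring motif pairs by combinatorial in-silico mutagenesis. A simulation
module plants known motif effects and interactions so the whole pipeline can
be scored against ground truth.

## The predictor

The predictor is a hybrid convolutional + recurrent network mapping a one-hot
encoded RNA sequence (channels A, C, G, U, optionally plus codon-frame and
splice-junction tracks) to a scalar such as mean ribosome load (MRL) or a
half-life z-score. Each of `n_blocks` blocks applies LayerNorm (over channels,
per position), a valid 1-D convolution, ReLU, and non-overlapping max pooling;
a GRU consumes the final feature map and its last hidden state feeds a small
dense head. Two standing variants mirror the two use cases — 4 blocks for MRL
from 5'UTRs, 6 blocks for half-life from full mRNAs (6 input channels) — and
simulation benchmarks use a light 3-block variant (receptive fields 5 / 14 /
32 nt at strides 1 / 2 / 4 for kernel width 5 and pool width 2).

The network is implemented directly in numpy with manual backpropagation and
Adam (optionally with decoupled weight decay and dropout on the GRU/dense
head). All randomness — initialisation, minibatch order, dropout masks — is
derived from a single integer seed, so training is bit-reproducible.
Gradients are validated against central finite differences in the test suite.

Numerical choices that matter:

* **Ceil-mode pooling.** Pooling keeps a partial last window instead of
  dropping the remainder. Floor-mode pooling silently discards the last few
  nucleotides of a 50-nt sequence after three blocks, making the model blind
  to motifs planted near the 3' end (measured as a ~5x larger prediction
  error there); ceil mode removes the effect.
* **Padding masking.** Variable-length batches are zero-padded; convolution
  windows touching padding are excluded from pooling maxima via -inf
  substitution and the GRU output is read at each sequence's last valid step,
  so padding content never influences predictions (tested).
* **Optimisation defaults.** Adam at learning rate 5e-3, batch 128, early
  stopping on validation MSE with patience 8 (best-epoch weights restored),
  plus halving of the learning rate after 4 stall epochs. Lower learning
  rates (1e-3) reliably stall below the achievable accuracy on motif-count
  tasks with this engine. Small datasets (< 10,000 sequences) switch to batch
  32, dropout 0.15 and several training restarts with different
  initialisations (best validation model kept), which counters both
  memorisation and optimisation noise.
* **Loss.** Mean squared error on the raw label scale; evaluation reports
  Pearson r, R^2 = 1 - SSres/SStot, and MSE.
* **Splitting.** Train/validation/test 80/10/10 by a seeded MD5 hash of each
  record id, so splits are stable across runs and machines.

## Motif discovery (neuron interpretation)

For a chosen conv layer, every neuron's per-position post-ReLU activations
are scanned over the dataset. Each sequence contributes its maximally
activating receptive-field window as a candidate seqlet; the top 0.5% of
candidates (at least 200 where available, ties broken by sequence id and
position) are kept. Receptive fields follow the standard recursion
r_l = r_{l-1} + (k_l - 1) j_{l-1} and are verified in tests by a perturbation
oracle (base flips inside the window may change the activation; flips outside
never do).

A single neuron often responds to several distinct patterns (a multifaceted
neuron); averaging its seqlets into one PPM blurs them. Seqlets are therefore
clustered on their one-hot encodings with k-means and each cluster becomes its
own PPM (position-wise frequencies with a total pseudo-count of 1/sqrt(n)).
Two model-selection policies are provided:

* **silhouette** (default): k in 1..max_clusters by mean silhouette, with
  k = 1 below 0.1 — appropriate for narrow early-layer windows where facets
  differ in most columns;
* **fixed** (deliberate overclustering): for wide deep-layer windows the
  many random background columns dominate pairwise distances and silhouettes
  fall below 0.1 even when real facet structure exists, so silhouette
  selection collapses everything into one blurred PPM. Overclustering at a
  fixed k recovers coherent facets; surplus near-duplicate clusters are
  harmless because downstream results are deduplicated.

Deep-layer clusters whose PPM contains two disjoint high-information
subregions (mean column information >= 0.5 bits over >= 4 columns, single-
column dips bridged, clusters with < 10 members ignored) propose candidate
motif *pairs*: each subregion is matched against the annotation/discovered
motif set by best ungapped similarity (>= 0.75), and two distinct matches
emit the pair. Because facet granularity (pair identity x within-window
offset) is unknown a priori, the screen pools proposals across all layers
whose receptive field can hold two motifs, two seqlet depths (200 and 800)
and several cluster counts (4, 8, 12, 16), then deduplicates. This makes the
proposal step insensitive to any single resolution choice.

## Motif similarity and annotation

A query PPM is compared to a library by the best ungapped alignment over all
offsets with >= 4 overlapping columns; the reported score is the mean
column-wise Pearson correlation over the overlap (zero-variance columns
contribute 0; no reverse complement — RNA is single-stranded). Significance
uses a column-permutation null: query columns are shuffled, rescored, and the
add-one-smoothed exceedance fraction is the p-value; Benjamini–Hochberg across
all (query, target) pairs gives q-values, with q <= 0.001 flagged as
significantly similar.

The *test statistic* for the permutation test is the overlap-adjusted value
mean_correlation x sqrt(overlap) rather than the raw mean: a shuffle that
happens to align 4 columns onto their partners at a short-overlap offset ties
a perfect raw score, which puts a hard floor (~2e-4 for a 12-column motif) on
attainable p-values and makes q <= 0.001 unreachable even for an exact match.
The sqrt(overlap) scaling — the z-scale of a mean of roughly independent
column correlations — restores discrimination between short lucky overlaps
and genuine full-length matches. Null p-values remain uniform (KS-tested).

## Contribution analysis

For each neuron the dataset splits into activating sequences (maximum
positional activation above gamma = 0.5 of the neuron's dataset-wide maximum;
post-ReLU "> 0" alone is too permissive in deep layers) and the rest. Label
distributions are compared with a two-sided Mann–Whitney U test — labels such
as MRL are not Gaussian, and the uAUG shortcut even makes them bimodal — with
BH correction across the neurons of a run and alpha = 0.05. The direction is
an association between activation and label, not a causal claim; groups under
10 members are reported as underpowered.

## Interaction (epistasis) analysis

Motif instances are located by log-odds scanning (pseudo-probability 0.01,
uniform background, threshold 0.8 of the maximum attainable score, overlapping
same-motif matches merged keeping the best; motifs with under 2 bits of total
information are rejected as unscannable). For every sequence carrying
disjoint instances of motifs A and B (up to 400 best-matching carriers), four
predictions are taken: o (intact), a (B scrambled), b (A scrambled), n (both
scrambled), where scrambling replaces the instance window with uniform-random
bases and 8 independent scrambles are averaged so scramble noise largely
cancels from the paired comparison.

A two-sided Wilcoxon signed-rank test compares (o-n) with (a-n)+(b-n) across
carriers (>= 10 required; exact null distribution at small n, validated
against full sign-flip enumeration). Classification follows the standard
judgment rules: for same-sign motifs, joint > sum means synergy for positive
pairs and antagonism for negative pairs (and vice versa); no significant
difference is additive; for mixed signs the one-directional comparisons
(o-n) vs (a-n) and (o-n) vs (b-n) detect sign epistasis (if both trigger, the
result is reported as sign with a flag). No multiple-testing correction is
applied across pairs by default (raw Wilcoxon p-values are reported); a BH
option exists at the API level via the returned p-values.

**Motif signs for classification.** The judgment rules need each motif's
effect direction. When callers do not supply contribution-analysis signs,
they are inferred from the mutagenesis marginals themselves: a signed-rank
test of a-n (respectively b-n) against zero. This matters for pure-pair
designed datasets: when every sequence carries exactly one motif pair, the
carrier-vs-noncarrier label differences used by contribution analysis sum to
zero over motifs for *any* pair weighting and effect sizes (a simple
accounting identity), so at least one motif always receives a wrong or null
marginal sign no matter how large the dataset. The mutagenesis marginal
measures the effect direction directly on the model and is immune to this
composition artifact; the label-based contribution results are still computed
and reported alongside.

## Simulation benchmark

The generator emulates MPRA-style random-library experiments at desk scale.
The default library holds four consensus-like motifs (~1.66 bits/column,
0.95 consensus probability): an m6A-like element GGACUG, a PUF-like element
UGUAUAUA, an AU-rich element CCAUUUAC and a GC-rich element CCGCAGC. Lengths
of 6–8 nt keep chance co-occurrence of any two motifs in a 50-nt random
sequence below ~1 in 20,000 sequences, so random datasets carry essentially
no motif-pair signal — the premise the random/designed contrast turns on.
(With 5-nt motifs at ~4.5% chance presence each, pair co-occurrence is common
enough that the model genuinely learns one interaction even from random data;
the random-data claim is sensitive to motif length in exactly this way.)

Labels follow y = sum_m e_m I(m present) + sum_{ij} s_ij e_ij I(both present)
+ N(0, sigma^2) with defaults e_m = 1, e_ij = 1, sigma = 0.3; s_ij is +1 for
synergistic and -1 for antagonistic pairs. Presence is determined by scanning
the finished sequence, so chance occurrences count exactly like planted ones.
The default interaction set makes one pair synergistic and one antagonistic;
the dense option makes all six pairs of the 4-motif library epistatic
(alternating types), which is what the benchmark scores against.

* **Random datasets** are i.i.d. uniform over A/C/G/U.
* **Designed datasets** give every sequence one motif pair drawn uniformly
  from the six unordered pairs, instances sampled column-wise from the PPMs
  and placed at uniform-random disjoint positions, uniform background
  elsewhere. About 30% of sampled instances carry a mismatch, score below the
  scan threshold and are labelled absent; these are the dataset's natural
  single-motif and motif-free examples. They are essential: forcing every
  instance to be detectable removes all non-pair examples, the model then
  never observes single-motif sequences, and the mutagenesis marginals become
  out-of-distribution — measured as a collapse of recovery from 6/6 to 0/6.
* An optional uAUG penalty subtracts a constant from AUG-containing
  sequences, reproducing the bimodal label distribution of random-5'UTR MPRA
  data; `filter_uaug` removes AUG-containing sequences (exact AUG-free
  probability for uniform 50-mers is 0.4583 by the match-progress automaton —
  the popular independence approximation (1-1/64)^48 ~ 0.47 overstates it).
  Bimodality is quantified by the BIC margin of a 2- vs 1-component Gaussian
  mixture (no dip-test implementation is used).

`recovery_benchmark` closes the loop: generate, split, train the 3-block
model (restarts at small n; aborts — or optionally continues — if validation
r < 0.2), interpret layer 1 for motif signs reporting, screen candidate pairs
from deep neurons, classify each proposed pair by mutagenesis, and report the
true positive rate: the fraction of planted interactions recovered as a
proposed pair with the correct class. At small n the mutagenesis phase
averages predictions over all training restarts that learned (validation
r >= 0.2): a single weak model's single-motif predictions — exactly what the
marginals a-n and b-n read off — are noisy and seed-dependent, and the
restart ensemble damps those idiosyncratic errors (measured: per-seed
recovery at n = 2,000 moves from a 0-3/6 spread to 3/6 on nearly every
seed). Proposals and contribution analysis use the best single member, since
neuron activations cannot be averaged across differently initialised
networks.

Benchmark problem sizes are 20,000 sequences for the full designed/random
contrast and 2,000 for the reduced designed dataset (5 seeds, median), with
interpretation capped at a 10,000-sequence subsample; these desk-scale sizes
reproduce the qualitative regime of the full-scale (280,000-sequence) study:
designed data recovers 6/6 interactions, random data 0/6, and the
2,000-sequence designed data a median of 3/6 — precisely the synergistic
pairs, whose label contrast (3 vs a background of 2) the weak small-data
model encodes more saliently than the antagonistic ones (1 vs 2, which
average out toward additivity in its marginals).

## What the synthetic data does and does not show

The generator produces fixed-length, uniform-background sequences with
independent planted effects and pairwise interactions. It does not emulate
secondary structure, positional effects (e.g. uAUG distance to the start
codon), motif density or length variation of real UTRs, correlated effect
sizes, or measurement error models of polysome profiling. Passing benchmarks
therefore demonstrate that the interpretation pipeline recovers what a model
has learned under enriched vs unenriched pair signal — not that any
particular biological motif pair interacts.

## Known limitations

* The deep-neuron pair screen requires both motifs of a pair to fall within
  one receptive field; with 50-nt sequences and a 32-nt deep field this
  usually holds, but widely separated pairs in longer sequences would need
  deeper models or an exhaustive `all_pairs` scan.
* Sign epistasis never arises under the default generator (all planted
  effects positive); the mixed-sign path is validated against hand-built
  oracles instead.
* Mutagenesis on 6-channel (track-encoded) models is unsupported: scrambling
  changes the sequence but the codon-frame/splice tracks of real transcripts
  are not recomputed.
* The contribution module's label-marginal signs are unidentifiable on
  pure-pair designed data (see above); they remain faithful for natural and
  random datasets.
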