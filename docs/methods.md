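# Methods

## The modelling problem

A shotgun-sequenced soil sample yields millions of read pairs, each of which
may be assigned a species (by k-mer classification or translated alignment)
and/or a gene-family function (a KEGG orthologue, "K-number"). Abundance-only
models discard the link between the two. This package represents each sample
as an undirected weighted graph: species nodes connect to the K-numbers their
reads also map to, with the number of supporting read pairs as the edge
weight; a habitat node connects to long-term environment feature nodes
(20-year means of air temperature and 0–7 cm soil water) with the feature
value as the weight. The regression target is the sample's soil organic
carbon (SOC) in g kg⁻¹. Node features are deliberately minimal — two bits,
`is_function` and `central_carbon` (membership of the central carbon
metabolism pathway) — so that everything else the model uses must come from
graph structure and edge weights.

## Annotation merging

Several annotation tools process the same reads; counting a read once per
tool would inflate abundances. Per `(read, sample, kind)` group the record
with the longest mapped length wins; exact ties go to the `diamond` dialect,
and a tie between two non-diamond dialects follows the fixed precedence
diamond > kraken2 > humann3 so the merge is a deterministic, order-independent,
idempotent function of the record set. Species–function pair counts are taken
over reads whose surviving taxon and function records coexist, regardless of
which tool produced each — the merge already arbitrated confidence, and
requiring a common tool would discard the deliberately complementary
annotations.

## Normalisation and diversity

Counts-per-million supports two denominators: all read pairs of the sample
(`cpm_total`) or mapped reads only (`cpm_mapped`, rows then sum to exactly
10⁶). Rarefaction is an exact multivariate-hypergeometric subsample to a
common depth. Alpha diversity is computed from closed forms on integer
counts: richness S, Shannon entropy H in nats, Gini–Simpson 1−Σp², Pielou
J = H/ln S (reported missing when S ≤ 1 rather than dividing by zero), Hill
numbers q=0,1,2 (S, eᴴ, 1/Σp²), and Chao1 in the bias-corrected form
S + f₁(f₁−1)/(2(f₂+1)), which stays finite when no doubletons are observed;
the classic f₁²/(2f₂) variant is available by flag. scikit-bio implements the
same formulas and serves as an independent oracle in the tests, never as the
implementation.

## The graph regressor

The architecture is a fixed 10-stage listing: four single-head graph
attention stages (2→32→32→32→128), a graph convolution stage (128→128), a
fixed-size max pooling, a second 128→128 stage, flatten, and dense 128→32→1.
Two listing ambiguities had to be resolved and are our choices, not claims
about the original code:

* **Pooling placement.** The fixed-size max pool between the two convolution
  stages is realised as a node-dimension max readout producing one 128-vector
  per graph; the following 128→128 stage acts on that pooled vector as a
  dense transform.
* **Edge weights.** The convolution stage consumes edge weights through
  symmetric normalisation; whether the attention stages see weights at all
  was open. They do here: each attention logit receives an additive learned
  scalar times sign(w)·log1p(|w|). Without this term the model's only
  weight-sensitive channel is *inversely* degree-normalised (a larger weight
  shrinks every other normalised message at the node), which made the
  interpreter's weight-substitution response anti-monotone and unstable in
  sign; the bounded log-scale term gives attention a direct, monotone view of
  the weight.

Numerical choices, with reasons:

* **Degree normalisation over |w|.** Environment edges carry signed values
  (a sub-zero long-term temperature is a legitimate weight). Degrees are
  computed from |w| with self-loops of weight one, so every degree is ≥ 1,
  |norm| ≤ 1, and the weight's sign survives in the message. Naive signed
  degrees produced normalisation factors of order 10¹² and destroyed
  training.
* **Decoupled weight decay.** Training uses Adam with learning rate 0.001
  and weight decay 0.1 for 100 epochs, batches of 32, L1 loss. The decay is
  decoupled (applied as lr·wd·w outside the adaptive step). Folding 0.1·w
  into the gradient instead lets the decay term dominate the normalised step
  whenever loss gradients are small, which empirically collapses the network
  to a constant predictor.
* **Target standardisation.** Targets are z-scored on the training portion
  and predictions unscaled. Adam's steps are scale-invariant (~lr per step),
  so a raw SOC scale of hundreds of g kg⁻¹ is unreachable within the printed
  epoch budget; on the standardised scale the same budget suffices. A side
  effect: with the zero-initialised output bias, an untrained model predicts
  the training mean, so the no-training control equals the null model by
  construction.
* **Protocol.** 85/15 train/test split with |train| = ⌊0.85 n⌋ at random
  state 40 (so n=20 → 17/3 and n=184 → 156/28), 5-fold CV on the training
  portion only, rectified-linear nonlinearities between stages, attention
  logits through leaky-ReLU (slope 0.2). Inference has no stochastic layers;
  predictions are deterministic and invariant to node reordering.

The autodiff engine under the model is a ~300-line reverse-mode tape over
NumPy with exactly the primitives message passing needs (matmul, gather,
segment sum/max/softmax); every primitive and the full forward pass are
checked against central finite differences in the test suite.

## Impact scores

For each species–function pair, the observed weight range is taken across
all samples with absence counting as weight 0 (count semantics). Per sample,
the pair's weight is substituted by the global minimum and the global
maximum — inserting the edge, and any missing endpoint with its usual
features, when the sample lacks it, since otherwise the maximum substitution
is undefined — and the impact is the difference of the two predictions. For
any predictor affine in edge weights this reduces exactly to
coefficient × (max − min), identical in every sample; the tests hold the
implementation to that closed form and to a brute-force graph-rebuild oracle
for nonlinear predictors. Ranking is by signed mean impact descending with
lexicographic tie-breaks (an absolute-value mode exists). The coverage
contrast compares SOC between (sample, pair) observations with and without
coverage using the pooled-variance two-sample t with df = n₁+n₂−2 (Welch by
flag).

## The synthetic cohort

The generator emulates the statistical shape of a global topsoil survey at
desk scale; defaults are the conditions all stochastic tests run under.

* **Size.** 200 samples, 30 species, 40 K-numbers, 2 000–4 000 read pairs
  per sample with 20% left unassigned. Real surveys are ~184 samples ×
  ~10⁵ features at ~10⁶ read pairs; sizes here keep a full train/interpret
  cycle under a minute while leaving count noise realistic.
* **Counts.** Per-species gamma-Poisson mixtures (negative-binomial
  marginals, gamma shape 1.5) with 35% per-sample zero-inflation for
  background species, drawn independently per species under a depth budget
  (overshoot is thinned hypergeometrically). Independence matters: a
  multinomial draw couples every species to every other through the shared
  total, which wipes out univariate feature-selection signal that the
  analysis assumes detectable.
* **Signal.** SOC = 120 + Σ effects + noise, clipped to the observed field
  range (8, 392) g kg⁻¹. Six predictive species (4 positive, 2 negative)
  each contribute 18 g kg⁻¹ per SD of their CPM (CPM against total reads, so
  components are independent); one long-term temperature feature contributes
  −12 g kg⁻¹ per SD; Gaussian noise SD 10. Two genome-streamlined pairs are
  planted on two further species that carry no abundance effect: the
  designated function takes a 45% share of its host's function-mapped reads,
  is absent (count exactly 0, and the SOC bonus of 60 g kg⁻¹ withheld) in
  30% of samples, and is marked as central-carbon in the node features — in
  this cohort the planted carbon-cycling functions *are* the central-carbon
  pathway membership.
* **Reads.** Every count expands to one read record from a winning dialect;
  configurable fractions receive conflicting shorter-mapping decoys (10%)
  or equal-length ties that only the diamond rule resolves (5%), so
  re-merging the read table reproduces the matrices exactly.

What the generator does **not** emulate: phylogenetic correlation between
species, compositional biases of real library preparation, habitat-dependent
community shifts (habitat labels are decorative by default, keeping the
planted signal attributable), and the 10⁵-feature dimensionality of real
cohorts. Passing tests therefore demonstrate that the machinery recovers a
known signal under controlled sparsity and noise — not field-scale
performance.

## Known limitations

* The graph regressor's published accuracy on the real 184-sample survey is
  not reproducible here by design (the raw data is an external archive);
  synthetic results stand in with ground truth instead.
* Impact scores substitute one edge at a time; strongly interacting pairs
  can mask each other, and the signed mean can understate pairs whose effect
  flips sign across habitats (the per-sample columns and the absolute
  ranking mode are the diagnostic).
* The permutation-importance contrast inserts absent edges at weight 0;
  attention still sees the inserted connectivity, so a model that encodes
  presence purely through connectivity will show small impacts for
  presence-driven pairs. The log-weight attention term mitigates this by
  construction.
* Training at the printed hyperparameters is stable but modest in capacity;
  on cohorts whose signal lives mostly in node *identity* (which the 2-bit
  features cannot express) the model cannot beat the null, as intended.
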