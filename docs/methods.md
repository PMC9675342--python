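# Methods

`playseq` analyses sequences of discrete, coded behavioural actions ("play
elements") to ask two questions: which elements follow which others more
often than chance, and whether elements organise into higher-level clusters
— "games" — of elements that transition into one another at high rates and
are positionally interchangeable. The pipeline was designed for
individual-level play sequences extracted from video-coded social play
bouts, but applies to any event log of timestamped discrete elements.

## Data model

An **ethogram** defines the repertoire: each element has a category
(contact, non-contact, object, signal), a kind (countable *event* vs
continuous *state*), a continuous-state flag, and optionally an a-priori
"lump target" — a similar element it is merged into if too rare. An **event
log** has one row per element onset (`bout_id, player_id, onset_s,
element`); rows of one player that share an onset were coded as
simultaneous and form one step's active set. Two reserved tokens mark
interruptions: `BREAK` (the player momentarily stopped playing) and
`MISSING` (out of view). A bout involves several players; the analysis unit
is the **individual-bout**, one player's steps within one bout. Durations
are deliberately ignored throughout: only the order of element onsets is
analysed.

## Pre-processing

1. **Lumping** (`lump_min_count`, default 20 occurrences): elements rarer
   than the threshold are replaced by their lump target wherever they
   occur. Replacement is transitive and iterated to a fixpoint, because a
   target may itself be rare; rare elements without a target are retained.
   Occurrences are counted as raw active-set appearances over all bouts
   jointly, before run collapse (the counting base is a package convention;
   either choice changes little because the continuous states are, by
   construction, the common elements). Duplicates that lumping creates
   inside one step collapse to a single token and are tallied in the
   lumping report.
2. **State-run collapse**: continuous states are re-marked at every change
   while active, which would flood sequences with repeats that do not
   represent choices. While a continuous-state element stays in consecutive
   steps' active sets, only its first occurrence is kept; absence from a
   step or an intervening `BREAK` ends the activity, and a later
   reappearance counts anew. "In a row" therefore means continuously active
   across steps, not adjacency in the linearized string. Events are never
   collapsed.
3. **Linearization**: simultaneous elements have no recorded order, and no
   a-priori primacy is defensible; each step's elements are emitted in
   uniformly random order. All transition estimates are averages over an
   ensemble of `n_linearizations` (default 1,000) such random orders, which
   is why transition counts are generally fractional. Ensembles are
   reproducible: each linearization draws from a counter-derived child of
   one master seed, so results do not depend on consumption order.

The fixed order is lump → collapse → linearize.

## Transition statistics

First-order counts record how often each consequent immediately follows
each antecedent, never across `BREAK`/`MISSING` or bout boundaries;
conditional probabilities are row-normalized counts. Significance is
assessed against a bout-preserving permutation null: all non-marker tokens
across all bouts are pooled and dealt back uniformly at random to the
non-marker slots, preserving exactly the per-bout slot counts, the global
element frequencies, and the marker positions. Each of the `n_permutations`
(default 1,000) randomisations starts from a fresh linearization of the
observed data, so co-occurrence noise is folded into the null. The p-value
is the fraction of randomisations whose permuted conditional probability
reaches the observed value; ties count against significance (the
conservative choice). A transition is reported significant when p ≤ `alpha`
(0.01) *and* it was observed at least `min_transition_count` (5) times.
Within-bout (rather than pooled) reassignment is available as an option.
Robustness is quantified by resampling individual-bouts with replacement
(`n_bootstrap`, default 1,000) and reporting the 2.5th/97.5th percentile
interval and the max−min spread of each transition probability, alongside
the antecedent's occurrence count — transitions of rare antecedents are
volatile and should be read with caution.

Higher-order antecedent tuples (up to three elements) are used only for
prediction; significance testing is confined to simple
antecedent→consequent pairs.

## Prediction

Predictability of the next element is measured by repeated hold-out
validation: fit on a random `train_fraction` (95%) of individual-bouts,
predict every element in the rest that has the required number of
non-marker antecedents, repeat `kfold_reps` times with a fresh
linearization each repetition. The model is an interpolated, add-one
(Laplace) smoothed n-gram: every observed antecedent row receives one
pseudo-occurrence for each vocabulary element and is renormalized, and the
score of consequent *x* after antecedents (a, b, c) is the product
P(x|c)·P(x|b,c)·P(x|a,b,c), with unseen tuples contributing the uniform
floor 1/|V|. The product form lets sparse high-order tuples borrow strength
from their suffixes. Two scoring modes are reported because "correct
classification" can be operationalised two ways: `expected_match` (the
probability the model assigns to the true element — the expected accuracy
of probability-matched guessing, and the default) and `argmax` (modal
prediction, lexicographic tie-break). The order-0 model predicts from base
occurrence probabilities alone, so its expected-match accuracy equals
Σᵢ pᵢ·p̂ᵢ. A categorical naive Bayes classifier over the same antecedent
windows (class = consequent, features = antecedent positions, add-one
smoothing, argmax scoring) provides an optimised comparison that assumes
antecedent positions are independent given the class.

## Similarity clustering

Each element is represented by its vector of outgoing first-order
transition probabilities; elements used at similar sequence positions have
similar vectors ("synonyms"). Vectors are embedded in 2-D with UMAP and
clustered by k-means on the embedded Euclidean distances, with k chosen to
maximise mean silhouette over k ∈ [2, min(20, n−1)]; a solution is
acceptable when its silhouette exceeds `silhouette_threshold` (0.3).
Because the embedding is stochastic, the procedure is repeated
`n_embedding_runs` (default 50) times with epoch counts drawn uniformly in
[0.5, 1.5] × `mean_epochs` (default 7,000); the modal k across runs is the
consensus, the run with that k and the highest silhouette is reported, and
pairwise co-assignment frequencies across runs quantify stability. "Most
likely cluster solution" is operationalised as modal-k-then-max-silhouette.
A Ward dendrogram on the winning run's embedded coordinates, cut at k,
gives the hierarchical view (exported as Newick); its silhouette is
reported alongside the k-means one, since either labelling could underlie a
published silhouette. UMAP hyperparameters other than epochs keep the
algorithm's canonical defaults (15 neighbours, min_dist 0.1), exposed as
arguments; the neighbourhood shrinks automatically with a warning for small
repertoires.

## Transition network

Significant transitions form a directed weighted network: nodes are
elements, edge weights are conditional transition probabilities, each dyad
can carry two edges (A→B and B→A), and self-loops (elements significantly
following themselves) are kept. Elements with no significant transition are
excluded from the node set and reported as a separate isolates group.
Communities are found by maximising Newman–Girvan weighted modularity
Q = Σ_c [W_c/W − (S_c/2W)²] on the direction-collapsed (weight-summed)
graph, because the modularity objective is defined on undirected weights;
stored edges and exports keep their directions. Self-loops are excluded
from the modularity objective — they inflate within-community weight
trivially — but remain in the network. Up to `exact_community_limit`
(default 12) nodes the true maximum is found by exhaustive partition
enumeration; larger networks use seeded Louvain with greedy single-node
refinement, and the partition is labelled with the method used. A partition
is acceptable when Q > `modularity_threshold` (0.3). The within-community
transition share is compared with a chance expectation obtained by
permuting community labels across nodes (sizes preserved,
`n_label_perms` = 1,000 draws); partitions from the similarity and network
routes are compared by adjusted Rand index and normalized mutual
information over their shared elements.

## Synthetic data generator

The generator plants known structure so every stage can be scored against
ground truth. `make_game_structure` builds a block transition matrix: each
element's row places `within_mass` (default 0.9) uniformly on its own
game's elements and the rest uniformly outside; defaults are 6 games × 10
elements, matching a post-lumping repertoire of about 60–70 elements.
`simulate_bouts` draws bout lengths from a log-normal (σ = 0.8) truncated
to [3, 181] with mean 30.3 — the empirical shape of coded play bouts — and
gives each bout 2–4 players with independent per-player sequences (the
analysis treats partner behaviour as noise). Steps carry a second
simultaneous element with probability `cooccur_rate` (0.1), `BREAK` markers
are inserted at rate 0.02 (the chain restarts from base rates after a
break), and seven designated state elements persist across a geometric
number of steps so that run collapse is exercised.

Four generator rules keep the planted structure exactly recoverable, all
consequences of the coding convention that a continuous state cannot be
re-initiated while it is already active:

- state persistence is truncated before any re-initiation of the same
  element, so collapse removes exactly the persistence listings and nothing
  else;
- planted transition rows of state elements carry no self-loop mass (a
  state repetition is indistinguishable from continuation);
- a co-occurring element is drawn with its companion excluded (an active
  set cannot contain an element twice);
- the structureless control (`simulate_null_bouts`, iid tokens from base
  probabilities with the same bout-shape machinery) contains only event
  elements, because state persistence plus collapse forbids step-adjacent
  repeats and is therefore itself a form of sequential structure that would
  violate the control's defining property that no transition exceeds
  chance.

An order-2 variant (`make_order2_structure`) fixes a preferred consequent
for every antecedent *pair* (emitted with probability `concentration`, rest
uniform), so first-order prediction captures only the marginal preference
while second-order prediction captures the rule — used to verify that
accuracy rises with antecedent order and plateaus when the data carry no
higher-order signal.

What the generator does **not** emulate: partner-contingent responses and
turn-taking, element durations, age or individual differences,
non-adjacent dependencies, and unbalanced repertoire frequencies (base
rates are uniform by default). Passing recovery tests therefore shows the
machinery is correct and well-calibrated under the stated generative
assumptions, not that real play data will yield equally clean structure.

## Numerical and design choices

- **Tie handling**: permutation p-values use ≥ (ties count against
  significance); argmax prediction breaks ties lexicographically.
- **Determinism**: one master seed (`rng_seed`); per-stage and
  per-linearization child seeds are derived with `numpy.random.SeedSequence`
  spawning, so identical configurations reproduce byte-identical CSV/JSON
  artifacts (floats are serialized at fixed precision) and stages can be
  re-run in isolation.
- **Degenerate inputs**: a repertoire with a single element yields p = 1
  everywhere; identical embedded points yield a flagged degenerate
  one-cluster solution; elements never observed as antecedents get zero
  profile rows and are flagged; an empty significant-edge set yields an
  empty network with a warning.
- **Problem sizes in the test suite**: the statistical tests run at
  reduced but still well-powered sizes (e.g. 200–300 bouts, 200
  linearizations, 1,000 permutations, 10–200 repetitions), chosen so each
  property is resolved several standard errors away from its threshold.
- **Known limitations**: the permutation null treats post-collapse tokens
  as freely exchangeable, while collapse itself forbids step-adjacent state
  repeats; on real data this makes tests on state-element rows slightly
  anticonservative. The exhaustive community search is exponential (Bell
  numbers) and is capped at `exact_community_limit`; above it the Louvain
  result is a high-quality heuristic, not a certificate. Bootstrap
  resampling uses the individual-bout as the exchangeable unit.
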