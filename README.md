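# playseq

Transition structure, next-element predictability, and "games" in coded
behavioural play sequences.

Social play — in young primates and many other animals — looks chaotic:
players string together dozens of distinct actions ("play elements", e.g.
*Hit*, *Bipedal*, *Chase*) in rapid succession. `playseq` tests whether
such sequences are random or rule-like, using methods borrowed from
language analysis. It is written for ethologists working with event logs
from behavioural video coding (one row per element onset, per player, per
bout), but applies to any sequence of timestamped discrete elements.

The pipeline answers three questions:

1. **Which transitions exceed chance?** First-order conditional
   probabilities P(consequent | antecedent) are computed from element
   sequences (simultaneous elements are ordered at random and all
   statistics averaged over 1,000 such linearizations) and tested against a
   bout-preserving permutation null: element identities are reassigned at
   random across bouts while per-bout element counts, global element
   frequencies, and the positions of Break/missing markers are held fixed.
   A transition is significant when its observed probability exceeds the
   permuted one in ≥ 99% of 1,000 randomisations and it occurred ≥ 5
   times. Bootstrap resampling of individual-bouts gives percentile
   intervals for each transition probability.
2. **How predictable is the next element?** Laplace-smoothed n-gram models
   of order 0–3 are evaluated by repeated 95%/5% hold-out validation.
   Higher-order scores interpolate by multiplying the conditional
   probabilities of an antecedent tuple and its suffixes, e.g.
   score(x | a,b,c) = P(x|c) · P(x|b,c) · P(x|a,b,c). A categorical naive
   Bayes classifier over the same antecedent windows is the optimised
   comparison.
3. **Do elements form games?** Two complementary routes: (i) elements are
   clustered by the similarity of their outgoing transition-probability
   vectors (UMAP to 2-D, k-means with silhouette-selected k, Ward
   dendrogram, consensus over 50 stochastic runs); (ii) the network of
   significant transitions is partitioned by maximising Newman–Girvan
   modularity Q = Σ_c [W_c/W − (S_c/2W)²] (exhaustively up to 12 nodes,
   seeded Louvain with refinement above). Partitions are compared by
   adjusted Rand index, and the within-community share of transitions is
   compared against a label-permutation expectation.

A synthetic-data module generates sequences with *planted* game structure
(block-structured transition matrices, realistic bout lengths of 3–181
elements with mean ≈ 30, 2–4 players per bout, co-occurring elements,
continuous-state elements, Breaks) plus a matched structureless control,
so every stage is testable against known ground truth without any coded
video data.

## Worked example

Simulate three planted games of five elements each, then run the full
pipeline:

```bash
playseq simulate --out events.csv --ethogram-out ethogram.csv \
    --truth truth.json --n-games 3 --elements-per-game 5 --n-bouts 60 --seed 11

cat > cfg.yaml <<'YAML'
n_linearizations: 100
n_permutations: 500
n_bootstrap: 200
kfold_reps: 20
n_embedding_runs: 5
mean_epochs: 1000
rng_seed: 11
YAML

playseq run --config cfg.yaml --events events.csv --ethogram ethogram.csv --out run1
python -m json.tool run1/summary.json
```

prints

```json
{
    "community_method": "louvain_refined",
    "modularity": 0.6664181885,
    "modularity_acceptable": true,
    "n_communities": 3,
    "n_elements": 15,
    "n_individual_bouts": 182,
    "n_observed_transitions": 219,
    "n_significant_transitions": 68,
    "partition_ari": 1.0,
    "partition_nmi": 1.0,
    "similarity_acceptable": true,
    "similarity_k": 3,
    "similarity_silhouette": 0.6489701066,
    "within_community_expected": 0.3556749854,
    "within_community_observed": 0.8855527393,
    "within_community_ratio": 2.4897807710
}
```

Reading this: of 219 observed transitions, 68 beat the permutation null;
both clustering routes find exactly the three planted games and agree
perfectly with each other (ARI = 1); the cluster solution is
well-separated (silhouette 0.65 > 0.3) and the network strongly modular
(Q = 0.67 > 0.3); 89% of transitions stay within a community where 36%
would be expected under random labels — a 2.5-fold excess. The run
directory also contains per-transition test results
(`transition_tests.csv`), bootstrap intervals, per-order prediction
accuracies (`accuracy.csv`), cluster memberships, a Newick dendrogram, the
GraphML network, and a `manifest.json` recording config, seeds and stage
timings; re-running with the same seed reproduces every artifact
byte-for-byte.

Subcommands `playseq transitions|predict|cluster|network` run single
stages; the same functionality is available as a library
(`import playseq`).

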