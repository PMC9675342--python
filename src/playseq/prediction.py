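"""Next-element predictability via interpolated, Laplace-smoothed n-grams.

How well does knowing the previous one, two, or three play elements predict
the next one?  Transition tables of each order are estimated on a training
split, Laplace smoothing assigns one pseudo-occurrence to every unseen
(antecedent, consequent) pair, and higher-order predictions interpolate by
multiplying the conditional probabilities of the full antecedent tuple and
all its suffixes — so an antecedent triple seen only once still borrows
strength from its shorter suffixes.  Accuracy is evaluated by repeated
k-fold validation: fit on 95% of individual-bouts, predict every scoreable
element in the held-out 5%.

Two scoring modes are provided.  ``expected_match`` scores the probability
the model assigns to the true element (the expected accuracy of
probability-matched guessing); ``argmax`` scores the modal prediction.
An order-0 model predicts from base occurrence probabilities alone.
A naive Bayes classifier over the same antecedent windows serves as an
optimised comparison that assumes antecedent positions are independent.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from sklearn.naive_bayes import CategoricalNB

from .io_model import MARKERS, IndividualBout, PipelineConfig
from .preprocess import ElementSequence, linearize_all
from .transition_stats import MAX_ORDER, count_transitions


@dataclass
class NGramModel:
    """Laplace-smoothed conditional tables up to ``max_order``.

    ``smoothed_tables[k]`` maps each observed antecedent k-tuple to a dense
    probability vector over the vocabulary; unobserved tuples fall back to
    the uniform Laplace floor ``1/|V|`` at scoring time.
    """

    max_order: int
    vocabulary: tuple[str, ...]
    smoothed_tables: dict[int, dict[tuple[str, ...], np.ndarray]]
    base_probs: np.ndarray  # aligned with vocabulary

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {el: i for i, el in enumerate(self.vocabulary)}

    @property
    def n_elements(self) -> int:
        return len(self.vocabulary)


def fit_ngram_model(
    training_sequences: Sequence[ElementSequence], max_order: int = 3
) -> NGramModel:
    """Fit smoothed transition tables of orders 1..max_order plus base rates."""
    if not 1 <= max_order <= MAX_ORDER:
        raise ValueError(f"max_order must be in 1..{MAX_ORDER}")
    vocab = sorted(
        {t for s in training_sequences for t in s.tokens if t not in MARKERS}
    )
    if not vocab:
        raise ValueError("training data contains no elements")
    index = {el: i for i, el in enumerate(vocab)}
    V = len(vocab)

    tables: dict[int, dict[tuple[str, ...], np.ndarray]] = {}
    for order in range(1, max_order + 1):
        counts = count_transitions(training_sequences, order)
        smoothed: dict[tuple[str, ...], np.ndarray] = {}
        for ant, row in counts.table.items():
            vec = np.ones(V, dtype=np.float64)  # one pseudo-occurrence everywhere
            for cons, c in row.items():
                vec[index[cons]] += c
            smoothed[ant] = vec / vec.sum()
        tables[order] = smoothed

    base = np.ones(V, dtype=np.float64)
    for s in training_sequences:
        for t in s.tokens:
            if t not in MARKERS:
                base[index[t]] += 1.0
    base /= base.sum()
    return NGramModel(
        max_order=max_order,
        vocabulary=tuple(vocab),
        smoothed_tables=tables,
        base_probs=base,
        _index=index,
    )


def _score_vector(model: NGramModel, antecedents: tuple[str, ...]) -> np.ndarray:
    """Unnormalized interpolated scores for every vocabulary element."""
    if len(antecedents) > model.max_order:
        raise ValueError("antecedent tuple longer than model max_order")
    if len(antecedents) == 0:
        return model.base_probs.copy()
    floor = np.full(model.n_elements, 1.0 / model.n_elements)
    score = np.ones(model.n_elements, dtype=np.float64)
    for k in range(1, len(antecedents) + 1):
        suffix = antecedents[-k:]
        row = model.smoothed_tables[k].get(suffix)
        score *= row if row is not None else floor
    return score


def interpolated_score(
    model: NGramModel, antecedents: tuple[str, ...], consequent: str
) -> float:
    """Product of smoothed conditionals over all suffixes of the antecedents.

    For antecedents (a, b, c) this is
    P(x | c) * P(x | b, c) * P(x | a, b, c); with one antecedent it reduces
    to the plain smoothed first-order probability.  Antecedent tuples never
    seen in training contribute the uniform Laplace floor 1/|V|.
    """
    if consequent not in model._index:
        raise ValueError(f"consequent {consequent!r} not in vocabulary")
    return float(_score_vector(model, antecedents)[model._index[consequent]])


def predict_distribution(
    model: NGramModel, antecedents: tuple[str, ...]
) -> dict[str, float]:
    """Interpolated scores over the vocabulary, normalized to sum to 1."""
    score = _score_vector(model, antecedents)
    score /= score.sum()
    return dict(zip(model.vocabulary, score.tolist()))


@dataclass
class AccuracyReport:
    order: int
    mode: str
    mean_accuracy: float
    per_bout: list[float]
    reps: int
    n_scored_tokens: int = 0


def _scoreable_windows(
    tokens: tuple[str, ...], order: int
) -> list[tuple[tuple[str, ...], str]]:
    """(antecedents, truth) pairs whose window does not cross a marker."""
    out = []
    if order == 0:
        return [((), t) for t in tokens if t not in MARKERS]
    for i in range(len(tokens) - order):
        window = tokens[i : i + order + 1]
        if any(t in MARKERS for t in window):
            continue
        out.append((tuple(window[:-1]), window[-1]))
    return out


def _split_folds(
    n_bouts: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_test = max(1, int(round((1.0 - train_fraction) * n_bouts)))
    perm = rng.permutation(n_bouts)
    return perm[n_test:], perm[:n_test]


def kfold_accuracy(
    bouts: Sequence[IndividualBout],
    order: int,
    mode: str,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> AccuracyReport:
    """Repeated hold-out accuracy of order-``order`` prediction.

    Each repetition linearizes the bouts afresh, holds out a random
    ``1 - train_fraction`` share of individual-bouts (at least one), fits the
    n-gram model on the rest, and scores every held-out token that has the
    required number of non-marker antecedents.  Per-bout accuracies are
    averaged within a repetition and across repetitions.
    """
    if mode not in {"expected_match", "argmax"}:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 0..{MAX_ORDER}")
    if len(bouts) < 2:
        raise ValueError("need at least 2 individual-bouts")
    fit_order = max(1, order)
    per_bout: list[float] = []
    n_scored = 0
    for _ in range(config.kfold_reps):
        sequences = linearize_all(bouts, rng)
        train_idx, test_idx = _split_folds(len(bouts), config.train_fraction, rng)
        model = fit_ngram_model([sequences[i] for i in train_idx], fit_order)
        for i in test_idx:
            windows = _scoreable_windows(sequences[i].tokens, order)
            scores = []
            for ants, truth in windows:
                if truth not in model._index:
                    continue
                if mode == "expected_match":
                    vec = _score_vector(model, ants)
                    scores.append(vec[model._index[truth]] / vec.sum())
                else:
                    vec = _score_vector(model, ants)
                    # lexicographic tie-break: first max over sorted vocabulary
                    scores.append(float(int(np.argmax(vec)) == model._index[truth]))
            if scores:
                per_bout.append(float(np.mean(scores)))
                n_scored += len(scores)
    if not per_bout:
        raise ValueError("no scoreable tokens in any held-out bout")
    return AccuracyReport(
        order=order,
        mode=mode,
        mean_accuracy=float(np.mean(per_bout)),
        per_bout=per_bout,
        reps=config.kfold_reps,
        n_scored_tokens=n_scored,
    )


def naive_bayes_accuracy(
    bouts: Sequence[IndividualBout],
    order: int,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> AccuracyReport:
    """Repeated hold-out accuracy of a categorical naive Bayes classifier.

    The class is the consequent; the features are the previous ``order``
    elements, treated as independent given the class, with add-one
    smoothing.  Same fold scheme and argmax scoring as ``kfold_accuracy``.
    With a single antecedent feature this coincides with smoothed
    first-order argmax prediction.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}")
    vocab = sorted(
        {el for b in bouts for s in b.steps for el in s.active}
    )
    index = {el: i for i, el in enumerate(vocab)}
    V = len(vocab)
    per_bout: list[float] = []
    n_scored = 0
    for _ in range(config.kfold_reps):
        sequences = linearize_all(bouts, rng)
        train_idx, test_idx = _split_folds(len(bouts), config.train_fraction, rng)
        X_rows, y_rows = [], []
        for i in train_idx:
            for ants, truth in _scoreable_windows(sequences[i].tokens, order):
                X_rows.append([index[a] for a in ants])
                y_rows.append(index[truth])
        if len(set(y_rows)) < 1:
            continue
        clf = CategoricalNB(alpha=1.0, min_categories=V)
        clf.fit(np.asarray(X_rows), np.asarray(y_rows))
        for i in test_idx:
            windows = _scoreable_windows(sequences[i].tokens, order)
            if not windows:
                continue
            X_test = np.asarray([[index[a] for a in ants] for ants, _ in windows])
            truths = np.asarray([index[t] for _, t in windows])
            pred = clf.predict(X_test)
            per_bout.append(float(np.mean(pred == truths)))
            n_scored += len(windows)
    if not per_bout:
        raise ValueError("no scoreable tokens in any held-out bout")
    return AccuracyReport(
        order=order,
        mode="naive_bayes",
        mean_accuracy=float(np.mean(per_bout)),
        per_bout=per_bout,
        reps=config.kfold_reps,
        n_scored_tokens=n_scored,
    )
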