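"""Transition counting, bout-preserving permutation null, and bootstrap.

The central question — which consequents follow which antecedents more often
than chance — is answered against a null model that keeps everything about
the data fixed except element order: the number of element slots per bout,
the global occurrence probability of every element, and the positions of
Break/missing markers are preserved exactly, while element identities are
reassigned uniformly at random across the non-marker slots of all bouts.
A transition is significant when its observed conditional probability
exceeds the permuted probability in at least ``(1 - alpha)`` of the
randomisations and the transition was observed at least
``min_transition_count`` times.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .io_model import MARKERS, IndividualBout, PipelineConfig
from .preprocess import ElementSequence, linearize_all

MAX_ORDER = 3


# ---------------------------------------------------------------------------
# Count containers
# ---------------------------------------------------------------------------


@dataclass
class TransitionCounts:
    """Fractional antecedent-tuple -> consequent counts."""

    order: int
    table: dict[tuple[str, ...], dict[str, float]]

    @property
    def antecedent_totals(self) -> dict[tuple[str, ...], float]:
        return {ant: sum(row.values()) for ant, row in self.table.items()}


@dataclass
class TransitionProbabilities:
    """Row-normalized conditional probabilities P(consequent | antecedent)."""

    order: int
    table: dict[tuple[str, ...], dict[str, float]]


@dataclass(frozen=True)
class TransitionTestResult:
    antecedent: str
    consequent: str
    observed_count: float
    observed_prob: float
    null_exceed_count: int
    p_value: float
    significant: bool


@dataclass(frozen=True)
class BootstrapInterval:
    antecedent: str
    consequent: str
    pct_2_5: float
    pct_97_5: float
    range: float
    full_range: float
    antecedent_occurrences: int


def count_transitions(
    sequences: Sequence[ElementSequence], order: int = 1
) -> TransitionCounts:
    """Count adjacent (antecedent-tuple, consequent) pairs within sequences.

    Windows never span Break, missing-data markers, or sequence boundaries;
    the consequent is always a single element.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}")
    table: dict[tuple[str, ...], dict[str, float]] = {}
    for seq in sequences:
        toks = seq.tokens
        for i in range(len(toks) - order):
            window = toks[i : i + order + 1]
            if any(t in MARKERS for t in window):
                continue
            ant, cons = tuple(window[:-1]), window[-1]
            row = table.setdefault(ant, {})
            row[cons] = row.get(cons, 0.0) + 1.0
    return TransitionCounts(order=order, table=table)


def average_counts(
    ensemble: Iterable[Sequence[ElementSequence]], order: int = 1
) -> TransitionCounts:
    """Elementwise mean of per-linearization transition counts.

    Because co-occurring elements are ordered at random, counts averaged over
    the ensemble are generally not integers.
    """
    total: dict[tuple[str, ...], dict[str, float]] = {}
    n = 0
    vocab_ref: frozenset[str] | None = None
    for sequences in ensemble:
        vocab = frozenset(t for s in sequences for t in s.tokens if t not in MARKERS)
        if vocab_ref is None:
            vocab_ref = vocab
        elif vocab != vocab_ref:
            raise RuntimeError("inconsistent vocabularies across linearizations")
        counts = count_transitions(sequences, order)
        for ant, row in counts.table.items():
            acc = total.setdefault(ant, {})
            for cons, c in row.items():
                acc[cons] = acc.get(cons, 0.0) + c
        n += 1
    if n == 0:
        raise ValueError("ensemble is empty")
    return TransitionCounts(
        order=order,
        table={ant: {c: v / n for c, v in row.items()} for ant, row in total.items()},
    )


def conditional_probabilities(counts: TransitionCounts) -> TransitionProbabilities:
    table = {}
    for ant, row in counts.table.items():
        total = sum(row.values())
        if total > 0:
            table[ant] = {c: v / total for c, v in row.items()}
    return TransitionProbabilities(order=counts.order, table=table)


def filter_significant(
    results: Sequence[TransitionTestResult], config: PipelineConfig
) -> list[TransitionTestResult]:
    """Keep transitions observed at least ``min_transition_count`` times with p <= alpha."""
    return [
        r
        for r in results
        if r.observed_count >= config.min_transition_count and r.p_value <= config.alpha
    ]


# ---------------------------------------------------------------------------
# Encoded fast path: bouts as int arrays
# ---------------------------------------------------------------------------

SEP = -1  # marker or bout boundary: transitions never cross it


@dataclass
class EncodedBouts:
    """Bouts flattened to one int array for vectorized counting.

    ``base`` holds one canonical linearization (within-step order sorted),
    with ``SEP`` at marker positions and between bouts.  ``shuffle_slices``
    are the (start, length) spans of co-occurring groups to reshuffle per
    linearization; ``slot_positions`` are the indices of non-marker slots.
    """

    vocabulary: tuple[str, ...]
    base: np.ndarray
    shuffle_slices: list[tuple[int, int]]
    slot_positions: np.ndarray
    bout_slot_positions: list[np.ndarray]
    bout_bounds: list[tuple[int, int]]  # [start, end) including trailing separator

    @property
    def n_elements(self) -> int:
        return len(self.vocabulary)


def encode_bouts(bouts: Sequence[IndividualBout]) -> EncodedBouts:
    vocab = sorted({el for b in bouts for s in b.steps for el in s.active})
    code = {el: i for i, el in enumerate(vocab)}
    parts: list[int] = []
    slices: list[tuple[int, int]] = []
    bout_positions: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    for bout in bouts:
        start_bout = len(parts)
        for step in bout.steps:
            if step.is_marker:
                parts.append(SEP)
            else:
                group = sorted(step.active)
                if len(group) > 1:
                    slices.append((len(parts), len(group)))
                parts.extend(code[el] for el in group)
        end_bout = len(parts)
        span = np.asarray(parts[start_bout:end_bout], dtype=np.int64)
        bout_positions.append(start_bout + np.flatnonzero(span >= 0))
        parts.append(SEP)  # bout boundary
        bounds.append((start_bout, len(parts)))
    base = np.asarray(parts, dtype=np.int64)
    return EncodedBouts(
        vocabulary=tuple(vocab),
        base=base,
        shuffle_slices=slices,
        slot_positions=np.flatnonzero(base >= 0),
        bout_slot_positions=bout_positions,
        bout_bounds=bounds,
    )


def sample_linearization(enc: EncodedBouts, rng: np.random.Generator) -> np.ndarray:
    """A fresh random within-step ordering of the encoded token array."""
    arr = enc.base.copy()
    for start, length in enc.shuffle_slices:
        arr[start : start + length] = rng.permutation(arr[start : start + length])
    return arr


def first_order_count_matrix(arr: np.ndarray, n_elements: int) -> np.ndarray:
    a, b = arr[:-1], arr[1:]
    mask = (a >= 0) & (b >= 0)
    mat = np.zeros((n_elements, n_elements), dtype=np.float64)
    np.add.at(mat, (a[mask], b[mask]), 1.0)
    return mat


def _row_normalize(mat: np.ndarray) -> np.ndarray:
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, mat / totals, 0.0)
    return probs


def averaged_count_matrix(
    enc: EncodedBouts, n_linearizations: int, rng: np.random.Generator
) -> np.ndarray:
    mat = np.zeros((enc.n_elements, enc.n_elements), dtype=np.float64)
    for _ in range(n_linearizations):
        mat += first_order_count_matrix(sample_linearization(enc, rng), enc.n_elements)
    return mat / n_linearizations


def permute_tokens(
    enc: EncodedBouts,
    arr: np.ndarray,
    rng: np.random.Generator,
    scope: str = "pooled",
) -> np.ndarray:
    """Reassign element identities at random while preserving bout structure.

    ``pooled`` (the default null) pools all non-marker tokens across bouts
    and deals them back to the non-marker slots; ``within_bout`` shuffles
    each bout's own tokens in place.  Either way, per-bout slot counts,
    global element frequencies, and marker positions are untouched.
    """
    out = arr.copy()
    if scope == "pooled":
        pos = enc.slot_positions
        out[pos] = rng.permutation(arr[pos])
    elif scope == "within_bout":
        for pos in enc.bout_slot_positions:
            out[pos] = rng.permutation(arr[pos])
    else:
        raise ValueError(f"unknown permutation scope {scope!r}")
    return out


# ---------------------------------------------------------------------------
# Permutation test and bootstrap
# ---------------------------------------------------------------------------

_TIE_EPS = 1e-12


def permutation_null(
    bouts: Sequence[IndividualBout],
    config: PipelineConfig,
    rng: np.random.Generator,
    scope: str = "pooled",
) -> list[TransitionTestResult]:
    """Test every observed first-order transition against the permutation null.

    The observed transition table is averaged over ``n_linearizations``
    random within-step orders.  Each of the ``n_permutations`` randomisations
    draws a fresh linearization, reassigns element positions, and recomputes
    the conditional probabilities; the p-value is the fraction of
    randomisations whose permuted probability reaches the observed one (ties
    count against significance).
    """
    if config.n_permutations < 100:
        warnings.warn(
            f"n_permutations={config.n_permutations} < 100: p-values will be unstable",
            stacklevel=2,
        )
    enc = encode_bouts(bouts)
    V = enc.n_elements
    obs_counts = averaged_count_matrix(enc, config.n_linearizations, rng)
    obs_probs = _row_normalize(obs_counts)

    exceed = np.zeros((V, V), dtype=np.int64)
    for _ in range(config.n_permutations):
        arr = sample_linearization(enc, rng)
        perm = permute_tokens(enc, arr, rng, scope=scope)
        perm_probs = _row_normalize(first_order_count_matrix(perm, V))
        exceed += perm_probs >= obs_probs - _TIE_EPS

    results = []
    rows, cols = np.nonzero(obs_counts)
    for i, j in zip(rows.tolist(), cols.tolist()):
        p = exceed[i, j] / config.n_permutations
        cnt = obs_counts[i, j]
        results.append(
            TransitionTestResult(
                antecedent=enc.vocabulary[i],
                consequent=enc.vocabulary[j],
                observed_count=float(cnt),
                observed_prob=float(obs_probs[i, j]),
                null_exceed_count=int(exceed[i, j]),
                p_value=float(p),
                significant=bool(p <= config.alpha and cnt >= config.min_transition_count),
            )
        )
    results.sort(key=lambda r: (r.antecedent, r.consequent))
    return results


def bootstrap_intervals(
    bouts: Sequence[IndividualBout],
    config: PipelineConfig,
    rng: np.random.Generator,
) -> list[BootstrapInterval]:
    """Robustness intervals from resampling individual-bouts with replacement.

    Each of ``n_bootstrap`` replicates resamples the same number of
    individual-bouts, draws a fresh linearization, and recomputes first-order
    conditional probabilities; per transition we report the 2.5th/97.5th
    percentiles (and the full max-minus-min spread) together with how often
    the antecedent occurred — transitions of rare antecedents are volatile.
    """
    if len(bouts) < 2:
        raise ValueError("bootstrap needs at least 2 individual-bouts")
    enc = encode_bouts(bouts)
    V = enc.n_elements
    n_bouts = len(bouts)
    bounds = enc.bout_bounds
    bout_slices = [
        [(s - b0, l) for (s, l) in enc.shuffle_slices if b0 <= s < b1]
        for (b0, b1) in bounds
    ]
    bout_arrays = [enc.base[b0:b1] for (b0, b1) in bounds]

    obs = averaged_count_matrix(enc, min(config.n_linearizations, 100), rng)
    cells = np.nonzero(obs)
    token_counts = Counter(enc.base[enc.slot_positions].tolist())

    reps = np.empty((config.n_bootstrap, len(cells[0])), dtype=np.float64)
    for r in range(config.n_bootstrap):
        idx = rng.integers(0, n_bouts, size=n_bouts)
        parts = []
        for k in idx:
            arr = bout_arrays[k].copy()
            for s, l in bout_slices[k]:
                arr[s : s + l] = rng.permutation(arr[s : s + l])
            parts.append(arr)
        flat = np.concatenate(parts)
        probs = _row_normalize(first_order_count_matrix(flat, V))
        reps[r] = probs[cells]

    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    full = reps.max(axis=0) - reps.min(axis=0)
    out = []
    for k, (i, j) in enumerate(zip(cells[0].tolist(), cells[1].tolist())):
        out.append(
            BootstrapInterval(
                antecedent=enc.vocabulary[i],
                consequent=enc.vocabulary[j],
                pct_2_5=float(lo[k]),
                pct_97_5=float(hi[k]),
                range=float(hi[k] - lo[k]),
                full_range=float(full[k]),
                antecedent_occurrences=int(token_counts.get(i, 0)),
            )
        )
    out.sort(key=lambda r: (r.antecedent, r.consequent))
    return out
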