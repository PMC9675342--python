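"""Pre-processing of individual-bouts into linearized element sequences.

Three transformations are applied, in a fixed order:

1. **Lumping** — elements rarer than a threshold are merged into an
   a-priori-defined similar element (transitively, until no rare element with
   a target remains); rare elements without a target are retained.
2. **State-run collapse** — the continuously-coded "state" elements are
   re-marked at every change while active, which would flood the sequence
   with repeats; only the first occurrence of each continuous activity period
   is kept.  Leaving the active set (or a Break) ends the period, so a
   restart counts anew.
3. **Linearization** — elements marked simultaneously have no recorded order;
   each step's elements are emitted in uniformly random order, and analyses
   are averaged over an ensemble of such random orders.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np

from .io_model import BREAK, MISSING, Ethogram, IndividualBout, Step


@dataclass(frozen=True)
class ElementSequence:
    """One random total order of a bout's elements: a strict token sequence."""

    bout_id: str
    player_id: str
    tokens: tuple[str, ...]
    linearization_id: int = 0
    seed: int = 0


@dataclass
class LumpReport:
    """Which elements were replaced, by what, and how many occurrences moved."""

    replacements: dict[tuple[str, str], int] = field(default_factory=dict)
    collapsed_duplicates: int = 0

    def rows(self) -> list[dict]:
        return [
            {"old": old, "new": new, "count": n}
            for (old, new), n in sorted(self.replacements.items())
        ]


def occurrence_counts(bouts: Sequence[IndividualBout]) -> Counter:
    """Raw appearances of each element across all steps of all bouts."""
    counts: Counter = Counter()
    for bout in bouts:
        for step in bout.steps:
            counts.update(step.active)
    return counts


def lump_rare_elements(
    bouts: Sequence[IndividualBout],
    ethogram: Ethogram,
    min_count: int = 20,
) -> tuple[list[IndividualBout], LumpReport]:
    """Merge rare elements into their designated replacements.

    Counting and replacement iterate to a fixpoint so that chains of rare
    elements (X lumps into Y, Y itself rare) resolve fully.  An element below
    threshold without a replacement target is retained.  Duplicates created
    inside one step's active set collapse to a single token.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    current = list(bouts)
    report = LumpReport()
    while True:
        counts = occurrence_counts(current)
        rare = {
            name: ethogram.get(name).lump_target
            for name in counts
            if counts[name] < min_count and ethogram.get(name).lump_target is not None
        }
        if not rare:
            break
        replaced: list[IndividualBout] = []
        moved: Counter = Counter()
        dup_losses = 0
        for bout in current:
            new_steps = []
            for step in bout.steps:
                if step.is_marker:
                    new_steps.append(step)
                    continue
                new_active = set()
                for el in step.active:
                    tgt = rare.get(el)
                    if tgt is not None:
                        moved[(el, tgt)] += 1
                        el = tgt
                    if el in new_active:
                        dup_losses += 1
                    new_active.add(el)
                new_steps.append(Step(step.onset_s, frozenset(new_active)))
            replaced.append(IndividualBout(bout.bout_id, bout.player_id, tuple(new_steps)))
        current = replaced
        for key, n in moved.items():
            report.replacements[key] = report.replacements.get(key, 0) + n
        report.collapsed_duplicates += dup_losses
    return current, report


def collapse_state_runs(bout: IndividualBout, ethogram: Ethogram) -> IndividualBout:
    """Keep only the first occurrence of each continuous activity period.

    Applies to the designated continuous-state elements: while such an
    element stays in consecutive steps' active sets it was coded repeatedly,
    but the player made the choice to use it once.  A Break or absence from
    a step ends the activity; a later reappearance counts again.  Steps left
    empty by the collapse are dropped.  Event elements are untouched.
    """
    states = ethogram.state_elements
    prev_active: frozenset[str] = frozenset()
    new_steps: list[Step] = []
    for step in bout.steps:
        if step.is_marker:
            prev_active = frozenset()
            new_steps.append(step)
            continue
        kept = frozenset(
            el for el in step.active if el not in states or el not in prev_active
        )
        prev_active = step.active
        if kept:
            new_steps.append(Step(step.onset_s, kept))
    return IndividualBout(bout.bout_id, bout.player_id, tuple(new_steps))


def linearize(
    bout: IndividualBout, rng: np.random.Generator, linearization_id: int = 0
) -> ElementSequence:
    """Emit one random total order of the bout's elements.

    Steps are emitted in time order; within a step, co-occurring elements are
    shuffled uniformly at random (there is no a-priori primacy among them).
    Markers are emitted in place.
    """
    tokens: list[str] = []
    for step in bout.steps:
        if step.is_marker:
            tokens.append(step.marker)  # type: ignore[arg-type]
        else:
            group = sorted(step.active)
            if len(group) > 1:
                rng.shuffle(group)
            tokens.extend(group)
    return ElementSequence(
        bout.bout_id, bout.player_id, tuple(tokens), linearization_id=linearization_id
    )


def linearize_all(
    bouts: Sequence[IndividualBout], rng: np.random.Generator, linearization_id: int = 0
) -> list[ElementSequence]:
    return [linearize(b, rng, linearization_id) for b in bouts]


def linearize_ensemble(
    bouts: Sequence[IndividualBout], n: int, seed: int
) -> Iterator[list[ElementSequence]]:
    """Yield ``n`` independent full linearizations, reproducibly.

    Each linearization draws from its own counter-derived stream, so the
    ensemble does not depend on consumption order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        yield linearize_all(bouts, rng, linearization_id=i)


def preprocess_bouts(
    bouts: Sequence[IndividualBout], ethogram: Ethogram, min_count: int = 20
) -> tuple[list[IndividualBout], LumpReport]:
    """Lump rare elements, then collapse state runs, for every bout."""
    lumped, report = lump_rare_elements(bouts, ethogram, min_count)
    return [collapse_state_runs(b, ethogram) for b in lumped], report
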