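"""Synthetic play-sequence generators with known game structure.

The generator plants the structure the analysis is designed to recover: a
repertoire partitioned into "games" (blocks of elements that transition into
each other with high probability), bouts whose lengths match the empirical
shape of coded play data (3 to 181 elements, mean about 30), two to four
players per bout split into independent individual-bouts, co-occurring
simultaneous elements, continuously-active state elements that persist over
several steps (exercising run collapse), and Break markers.  Ground truth —
game memberships and the exact transition matrix — is retained so every
pipeline stage can be scored against it.  A matched null generator strings
elements together independently from their base probabilities.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    BREAK,
    Ethogram,
    EthogramElement,
    IndividualBout,
    Step,
)

DEFAULT_N_GAMES = 6
DEFAULT_ELEMENTS_PER_GAME = 10
DEFAULT_WITHIN_MASS = 0.9
DEFAULT_N_BOUTS = 300
DEFAULT_MEAN_LENGTH = 30.3
LENGTH_BOUNDS = (3, 181)
DEFAULT_N_STATES = 7


@dataclass
class GeneratorParams:
    n_games: int = DEFAULT_N_GAMES
    elements_per_game: int = DEFAULT_ELEMENTS_PER_GAME
    within_mass: float = DEFAULT_WITHIN_MASS
    cooccur_rate: float = 0.1
    break_rate: float = 0.02
    mean_bout_length: float = DEFAULT_MEAN_LENGTH
    length_bounds: tuple[int, int] = LENGTH_BOUNDS
    n_bouts: int = DEFAULT_N_BOUTS
    n_players_range: tuple[int, int] = (2, 4)
    n_state_elements: int = DEFAULT_N_STATES
    state_persist_prob: float = 0.5  # geometric continuation per step


@dataclass
class GroundTruth:
    """Planted structure: elements, game memberships, exact transition rows."""

    elements: tuple[str, ...]
    game_memberships: dict[str, int]
    transition_matrix: np.ndarray  # row-stochastic, aligned with elements
    base_probs: np.ndarray
    state_elements: frozenset[str]
    params: GeneratorParams
    seed: int = 0

    def ethogram(self) -> Ethogram:
        return Ethogram(
            tuple(
                EthogramElement(
                    name=el,
                    category="non-contact",
                    kind="state" if el in self.state_elements else "event",
                    is_continuous_state=el in self.state_elements,
                )
                for el in self.elements
            )
        )


def make_game_structure(
    n_games: int = DEFAULT_N_GAMES,
    elements_per_game: int = DEFAULT_ELEMENTS_PER_GAME,
    within_mass: float = DEFAULT_WITHIN_MASS,
    rng: np.random.Generator | None = None,
    params: GeneratorParams | None = None,
    self_loops: bool = True,
) -> GroundTruth:
    """Plant a block-structured transition matrix.

    Each element's outgoing distribution places ``within_mass`` uniformly on
    the elements of its own game (including itself when self-loops are on)
    and the remainder uniformly on all other elements.  With the defaults —
    six games of ten elements — the repertoire size matches a post-lumping
    play ethogram of about 60-70 elements.
    """
    if n_games < 1:
        raise ValueError("n_games must be >= 1")
    if not 0 < within_mass <= 1:
        raise ValueError("within_mass must lie in (0, 1]")
    if elements_per_game < 2 and not self_loops:
        raise ValueError("elements_per_game < 2 requires self-loops")
    params = params or GeneratorParams(
        n_games=n_games, elements_per_game=elements_per_game, within_mass=within_mass
    )
    n = n_games * elements_per_game
    elements = tuple(
        f"g{g + 1:02d}e{e + 1:02d}" for g in range(n_games) for e in range(elements_per_game)
    )
    games = {el: i // elements_per_game + 1 for i, el in enumerate(elements)}
    n_states = min(params.n_state_elements, n)
    # spread the state elements across games so every game feels run collapse
    state_idx = set(np.linspace(0, n - 1, n_states).astype(int).tolist())
    states = frozenset(elements[i] for i in state_idx)
    T = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        g = i // elements_per_game
        block = np.arange(g * elements_per_game, (g + 1) * elements_per_game)
        # a continuous state repeating itself is indistinguishable from
        # continuation under the coding convention, so state rows get no
        # self-loop mass
        if not self_loops or i in state_idx:
            block = block[block != i]
        T[i, block] = within_mass / len(block)
        outside = np.setdiff1d(np.arange(n), np.arange(g * elements_per_game, (g + 1) * elements_per_game))
        if len(outside) and within_mass < 1:
            T[i, outside] = (1 - within_mass) / len(outside)
        elif len(outside) == 0:
            T[i] /= T[i].sum()
    T /= T.sum(axis=1, keepdims=True)
    base = np.full(n, 1.0 / n)
    return GroundTruth(
        elements=elements,
        game_memberships=games,
        transition_matrix=T,
        base_probs=base,
        state_elements=states,
        params=params,
        seed=0,
    )


def _sample_length(params: GeneratorParams, rng: np.random.Generator) -> int:
    """Log-normal bout length truncated to the observed range.

    sigma = 0.8 gives the right-skewed shape of coded play bouts; mu is set
    so the untruncated mean equals ``mean_bout_length``.
    """
    sigma = 0.8
    mu = np.log(params.mean_bout_length) - sigma**2 / 2
    lo, hi = params.length_bounds
    for _ in range(1000):
        length = int(round(rng.lognormal(mu, sigma)))
        if lo <= length <= hi:
            return length
    return int(np.clip(round(params.mean_bout_length), lo, hi))


def _chain_to_steps(
    chain: list[str | None],
    cochain: list[str | None],
    truth_states: frozenset[str],
    persist_prob: float,
    rng: np.random.Generator,
) -> tuple[Step, ...]:
    """Lay a token chain onto timestamped steps with persisting states.

    ``chain[t]`` is the element initiated at step t (None for a Break);
    ``cochain[t]`` an optional second simultaneous initiation.  State
    elements are re-listed in following steps' active sets for a geometric
    number of steps, as a coder marking all active elements would.
    Persistence always ends before the same element is initiated again, so
    that state-run collapse recovers exactly the planted chain — the
    generated structure is fully known, at the cost of never emulating a
    re-initiation that is indistinguishable from continuous activity.
    """
    next_init: dict[str, list[int]] = {}
    for idx in range(len(chain) - 1, -1, -1):
        for el in (chain[idx], cochain[idx]):
            if el is not None:
                next_init.setdefault(el, []).append(idx)

    def _steps_until_reinit(el: str, t: int) -> int:
        stack = next_init.get(el, [])
        while stack and stack[-1] <= t:
            stack.pop()
        return (stack[-1] - t) if stack else len(chain)

    steps: list[Step] = []
    persisting: dict[str, int] = {}  # element -> remaining steps
    t = 0.0
    for idx, (tok, co) in enumerate(zip(chain, cochain)):
        t += float(rng.uniform(0.5, 1.5))
        if tok is None:
            persisting.clear()
            steps.append(Step(onset_s=t, marker=BREAK))
            continue
        initiated = {tok} | ({co} if co is not None else set())
        active = set(initiated) | set(persisting)
        for el in list(persisting):
            persisting[el] -= 1
            if persisting[el] <= 0:
                del persisting[el]
        for el in initiated:
            if el in truth_states:
                dur = rng.geometric(1 - persist_prob) - 1
                # stop early enough that the next initiation is not absorbed
                dur = min(dur, _steps_until_reinit(el, idx) - 2)
                if dur > 0:
                    persisting[el] = dur
        steps.append(Step(onset_s=t, active=frozenset(active)))
    return tuple(steps)


def _simulate_chain(
    n_tokens: int,
    T: np.ndarray | None,
    base: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> tuple[list[int | None], list[int | None]]:
    """Token index chain with optional co-occurrence and Breaks.

    Returns (main, co): per step the main initiated element index, an
    optional simultaneous one, or None for a Break.  Transitions condition
    on the most recent element (the co-occurring one when present, since it
    was initiated last in truth); after a Break the chain restarts from the
    base distribution.
    """
    n = len(base)
    main: list[int | None] = []
    co: list[int | None] = []
    prev: int | None = None
    emitted = 0
    while emitted < n_tokens:
        if prev is not None and rng.uniform() < params.break_rate:
            main.append(None)
            co.append(None)
            prev = None
            continue
        if prev is None or T is None:
            cur = int(rng.choice(n, p=base))
        else:
            cur = int(rng.choice(n, p=T[prev]))
        second: int | None = None
        if emitted + 1 < n_tokens and rng.uniform() < params.cooccur_rate:
            # a step's active set cannot hold the same element twice, so the
            # co-occurring element is drawn with its companion excluded
            row = (base if T is None else T[cur]).copy()
            row[cur] = 0.0
            if row.sum() > 0:
                second = int(rng.choice(n, p=row / row.sum()))
        main.append(cur)
        co.append(second)
        prev = second if second is not None else cur
        emitted += 1 + (second is not None)
    return main, co


def _build_bouts(
    truth_elements: tuple[str, ...],
    truth_states: frozenset[str],
    T: np.ndarray | None,
    base: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> list[IndividualBout]:
    bouts: list[IndividualBout] = []
    for b in range(params.n_bouts):
        bout_id = f"bout{b + 1:04d}"
        n_players = int(rng.integers(params.n_players_range[0], params.n_players_range[1] + 1))
        for p in range(n_players):
            length = _sample_length(params, rng)
            main, co = _simulate_chain(length, T, base, params, rng)
            chain = [truth_elements[i] if i is not None else None for i in main]
            cochain = [truth_elements[i] if i is not None else None for i in co]
            steps = _chain_to_steps(
                chain, cochain, truth_states, params.state_persist_prob, rng
            )
            if not steps:
                continue
            bouts.append(IndividualBout(bout_id, f"player{p + 1}", steps))
    return bouts


def simulate_bouts(truth: GroundTruth, rng: np.random.Generator) -> list[IndividualBout]:
    """Simulate individual-bouts from the planted first-order chain."""
    return _build_bouts(
        truth.elements,
        truth.state_elements,
        truth.transition_matrix,
        truth.base_probs,
        truth.params,
        rng,
    )


def simulate_null_bouts(
    base_probs: np.ndarray | Sequence[float],
    params: GeneratorParams,
    rng: np.random.Generator,
    elements: tuple[str, ...] | None = None,
) -> list[IndividualBout]:
    """Structureless control: tokens drawn independently from base rates.

    Same bout-shape machinery (lengths, players, co-occurrence, Breaks) but
    no transition structure — the ground truth is that no transition exceeds
    chance.  The control contains only event elements: continuous-state
    persistence is itself sequential structure (run collapse forbids
    step-adjacent repeats), so including states would violate the stated
    null invariant.
    """
    base = np.asarray(base_probs, dtype=np.float64)
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("base_probs must sum to 1")
    if elements is None:
        elements = tuple(f"e{i + 1:02d}" for i in range(len(base)))
    return _build_bouts(elements, frozenset(), None, base, params, rng)


# ---------------------------------------------------------------------------
# Order-2 variant: the consequent depends on the two previous elements
# ---------------------------------------------------------------------------


@dataclass
class Order2Truth:
    elements: tuple[str, ...]
    pair_map: np.ndarray  # preferred consequent for each (prev2, prev1)
    concentration: float
    base_probs: np.ndarray


def make_order2_structure(
    n_elements: int = 12,
    concentration: float = 0.7,
    rng: np.random.Generator | None = None,
) -> Order2Truth:
    """Second-order generator for testing the gain of longer antecedents.

    For every antecedent pair (a, b) a preferred consequent is fixed at
    random; it is emitted with probability ``concentration`` and the rest of
    the mass is uniform.  Because the preferred consequent depends jointly
    on both antecedents, first-order prediction captures only the marginal
    preference and second-order prediction captures the full rule.
    """
    rng = rng or np.random.default_rng()
    elements = tuple(f"e{i + 1:02d}" for i in range(n_elements))
    pair_map = rng.integers(0, n_elements, size=(n_elements, n_elements))
    return Order2Truth(
        elements=elements,
        pair_map=pair_map,
        concentration=concentration,
        base_probs=np.full(n_elements, 1.0 / n_elements),
    )


def simulate_order2_bouts(
    truth: Order2Truth,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> list[IndividualBout]:
    """Simulate bouts whose next element depends on the previous two."""
    n = len(truth.elements)
    uniform = np.full(n, 1.0 / n)
    bouts: list[IndividualBout] = []
    for b in range(params.n_bouts):
        bout_id = f"bout{b + 1:04d}"
        n_players = int(
            rng.integers(params.n_players_range[0], params.n_players_range[1] + 1)
        )
        for p in range(n_players):
            length = _sample_length(params, rng)
            toks: list[int] = []
            while len(toks) < length:
                if len(toks) < 2:
                    toks.append(int(rng.choice(n, p=uniform)))
                    continue
                target = int(truth.pair_map[toks[-2], toks[-1]])
                if rng.uniform() < truth.concentration:
                    toks.append(target)
                else:
                    toks.append(int(rng.choice(n, p=uniform)))
            steps = tuple(
                Step(onset_s=float(t + 1), active=frozenset({truth.elements[i]}))
                for t, i in enumerate(toks)
            )
            bouts.append(IndividualBout(bout_id, f"player{p + 1}", steps))
    return bouts
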