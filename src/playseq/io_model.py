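"""Core data model and tabular I/O for coded play-sequence data.

The pipeline operates on event logs exported from behavioural video coding:
one row per play-element onset, grouped into bouts of social play and split
per player into *individual-bouts* (the analysis unit).  Two reserved tokens
mark interruptions: ``BREAK`` (the player momentarily stopped playing) and
``MISSING`` (the player was out of view).  Transitions never span either.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

BREAK = "BREAK"
MISSING = "MISSING"
MARKERS = frozenset({BREAK, MISSING})

VALID_CATEGORIES = frozenset({"contact", "non-contact", "object", "signal"})
VALID_KINDS = frozenset({"event", "state"})


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


@dataclass(frozen=True)
class EthogramElement:
    name: str
    category: str = "non-contact"
    kind: str = "event"
    is_continuous_state: bool = False
    lump_target: str | None = None


@dataclass(frozen=True)
class Ethogram:
    """The repertoire of play elements with lumping and state annotations."""

    elements: tuple[EthogramElement, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.elements]
        if not names:
            raise ValidationError("ethogram contains no elements")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FormatError(f"duplicate element names: {sorted(dupes)}")
        known = set(names)
        bad = {e.name for e in self.elements if e.name in MARKERS}
        if bad:
            raise ValidationError(f"reserved marker tokens used as elements: {sorted(bad)}")
        for e in self.elements:
            if e.lump_target is not None and e.lump_target not in known:
                raise ValidationError(
                    f"element {e.name!r} lumps into unknown target {e.lump_target!r}"
                )
            if e.category not in VALID_CATEGORIES:
                raise ValidationError(f"element {e.name!r}: bad category {e.category!r}")
            if e.kind not in VALID_KINDS:
                raise ValidationError(f"element {e.name!r}: bad kind {e.kind!r}")
        # lump chains must terminate
        targets = {e.name: e.lump_target for e in self.elements}
        for start in names:
            seen = {start}
            cur = targets[start]
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cyclic lump chain involving {start!r}")
                seen.add(cur)
                cur = targets[cur]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.elements)

    @property
    def state_elements(self) -> frozenset[str]:
        return frozenset(e.name for e in self.elements if e.is_continuous_state)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.elements)

    def get(self, name: str) -> EthogramElement:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def resolve_lump(self, name: str) -> str:
        """Follow lump links to the terminal replacement element."""
        cur = name
        while True:
            tgt = self.get(cur).lump_target
            if tgt is None:
                return cur
            cur = tgt


@dataclass(frozen=True)
class EventRecord:
    bout_id: str
    player_id: str
    onset_s: float
    element: str


@dataclass(frozen=True)
class Step:
    """One time point of an individual-bout: the set of active elements, or a marker."""

    onset_s: float
    active: frozenset[str] = frozenset()
    marker: str | None = None  # BREAK or MISSING

    @property
    def is_marker(self) -> bool:
        return self.marker is not None


@dataclass(frozen=True)
class IndividualBout:
    """One player's timestamped element-sets within a single play bout."""

    bout_id: str
    player_id: str
    steps: tuple[Step, ...]

    def __post_init__(self) -> None:
        onsets = [s.onset_s for s in self.steps]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError(
                f"bout {self.bout_id}/{self.player_id}: onsets not strictly increasing"
            )
        for s in self.steps:
            if s.is_marker:
                if s.marker not in MARKERS or s.active:
                    raise ValidationError("marker steps carry no active elements")
            elif not s.active:
                raise ValidationError("non-marker steps need a non-empty active set")

    @property
    def key(self) -> tuple[str, str]:
        return (self.bout_id, self.player_id)


@dataclass
class PipelineConfig:
    """Every numeric threshold and size used across the pipeline.

    Defaults follow the study's analysis settings: lumping threshold of 20
    occurrences per element, significance at alpha = 0.01 for transitions
    observed at least five times, 1,000 linearizations / permutations /
    bootstrap resamples, 95% training split repeated 1,000 times, antecedents
    up to order 3, 50 embedding runs around 7,000 epochs, and the 0.3
    acceptability thresholds for silhouette and modularity.
    """

    lump_min_count: int = 20
    min_transition_count: int = 5
    alpha: float = 0.01
    n_linearizations: int = 1000
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    train_fraction: float = 0.95
    kfold_reps: int = 1000
    max_order: int = 3
    n_embedding_runs: int = 50
    mean_epochs: int = 7000
    silhouette_threshold: float = 0.3
    modularity_threshold: float = 0.3
    exact_community_limit: int = 12
    n_label_perms: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lump_min_count",
            "min_transition_count",
            "n_linearizations",
            "n_permutations",
            "n_bootstrap",
            "kfold_reps",
            "max_order",
            "n_embedding_runs",
            "mean_epochs",
            "n_label_perms",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_ETHOGRAM_COLUMNS = ["name", "category", "kind", "is_continuous_state", "lump_target"]
_EVENT_COLUMNS = ["bout_id", "player_id", "onset_s", "element"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_ethogram(path: str | Path) -> Ethogram:
    """Read an element-definition table (CSV/TSV with a header row).

    Expected columns: ``name, category, kind, is_continuous_state,
    lump_target`` — an empty lump_target means the element is never lumped.
    """
    df = _read_table(path)
    missing = [c for c in _ETHOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ethogram missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("ethogram contains no elements")
    elements = []
    for row in df.itertuples(index=False):
        flag = str(row.is_continuous_state).strip().lower() in {"1", "true", "yes"}
        target = row.lump_target.strip() or None
        elements.append(
            EthogramElement(
                name=row.name.strip(),
                category=row.category.strip(),
                kind=row.kind.strip(),
                is_continuous_state=flag,
                lump_target=target,
            )
        )
    return Ethogram(tuple(elements))


def read_events(path: str | Path, ethogram: Ethogram) -> list[IndividualBout]:
    """Read a coded event log into individual-bouts.

    One row per element onset (``bout_id, player_id, onset_s, element``).
    Rows of one player sharing an onset merge into a single step's active
    set — they were marked simultaneously at coding time.  ``BREAK`` and
    ``MISSING`` rows become marker steps.
    """
    df = _read_table(path)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    df = df.copy()
    df["onset_s"] = df["onset_s"].astype(float)
    if not df["onset_s"].map(lambda v: v >= 0 and v == v).all():
        raise ValidationError("onsets must be finite and >= 0")
    known = set(ethogram.names) | MARKERS
    offenders = sorted(set(df["element"]) - known)
    if offenders:
        raise ValidationError(f"unknown element tokens: {offenders}")

    bouts: list[IndividualBout] = []
    df = df.sort_values(["bout_id", "player_id", "onset_s"], kind="stable")
    for (bout_id, player_id), grp in df.groupby(["bout_id", "player_id"], sort=True):
        steps: list[Step] = []
        for onset, tick in grp.groupby("onset_s", sort=True):
            tokens = set(tick["element"])
            marks = tokens & MARKERS
            if marks:
                if tokens - marks or len(marks) > 1:
                    raise ValidationError(
                        f"bout {bout_id}/{player_id} at {onset}: marker mixed with elements"
                    )
                steps.append(Step(onset_s=float(onset), marker=next(iter(marks))))
            else:
                steps.append(Step(onset_s=float(onset), active=frozenset(tokens)))
        bouts.append(IndividualBout(str(bout_id), str(player_id), tuple(steps)))
    return bouts


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.10g"


def write_events(bouts: Sequence[IndividualBout], path: str | Path) -> None:
    """Write individual-bouts back to the event-log CSV layout."""
    rows = []
    for bout in bouts:
        for step in bout.steps:
            if step.is_marker:
                rows.append((bout.bout_id, bout.player_id, step.onset_s, step.marker))
            else:
                for el in sorted(step.active):
                    rows.append((bout.bout_id, bout.player_id, step.onset_s, el))
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_ethogram(ethogram: Ethogram, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.name, e.category, e.kind, str(e.is_continuous_state).lower(), e.lump_target or "")
            for e in ethogram.elements
        ],
        columns=_ETHOGRAM_COLUMNS,
    )
    df.to_csv(path, index=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(FLOAT_FORMAT % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(results, path: str | Path, format: str = "csv") -> None:
    """Serialize a result table or mapping with deterministic ordering.

    ``results`` may be a DataFrame, a sequence of dataclasses/dicts (CSV), or
    any JSON-serializable mapping (JSON).  Floats are written at a fixed
    precision so identical runs produce byte-identical files.
    """
    path = Path(path)
    if format == "csv":
        if isinstance(results, pd.DataFrame):
            df = results
        else:
            rows = [
                dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in results
            ]
            df = pd.DataFrame(rows)
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    elif format == "json":
        if dataclasses.is_dataclass(results):
            results = dataclasses.asdict(results)
        with open(path, "w") as fh:
            json.dump(_round_floats(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
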