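"""Questionnaire scoring and the dyadic data model.

Social-network questionnaires yield, for every ordered pair of distinct
classmates (a *dyad*), a set of item responses.  This module turns those
responses into valued sociomatrices — relationship strength ``S``,
reciprocation ``R = Sᵀ − S``, actor-attribute "giving"/"receiving"
broadcasts — and vectorizes named matrix sets into a dyad-level design
table for regression.

The universal currency is :class:`DyadicMatrix`: a square valued matrix
over an ordered actor list with a structurally masked (NaN) diagonal.
Self-ties are never analysed; self-allocations are stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemSchema",
    "DyadicMatrix",
    "GroupData",
    "score_relationship_strength",
    "build_reciprocation",
    "build_attribute_matrix",
    "vectorize_dyads",
    "offdiag_indices",
    "read_adjacency_csv",
]


class ValidationError(ValueError):
    """Raised when input data violate the schema or matrix contracts."""


# ---------------------------------------------------------------------------
# Item schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Item:
    """One questionnaire item.

    Parameters
    ----------
    name
        Column name in the long-format dyad table.
    kind
        ``"binary"`` (responses in {0, 1}) or ``"ordinal"`` (integer range).
    min_value, max_value
        Inclusive response range.
    is_strength
        Whether the item contributes to the summed relationship-strength
        score.
    """

    name: str
    kind: str
    min_value: float
    max_value: float
    is_strength: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal"):
            raise ValidationError(f"item {self.name!r}: unknown kind {self.kind!r}")
        if self.min_value > self.max_value:
            raise ValidationError(f"item {self.name!r}: min_value > max_value")
        if self.kind == "binary" and (self.min_value, self.max_value) != (0, 1):
            raise ValidationError(f"item {self.name!r}: binary items must have range {{0,1}}")


@dataclass(frozen=True)
class ItemSchema:
    """Declarative description of a questionnaire's items.

    ``divisor`` is the maximum possible summed strength score; link weights
    are summed strength responses divided by it, so the maximum weight is
    always 1 and the minimum is (sum of strength minima) / divisor.
    """

    items: tuple[Item, ...]
    divisor: float

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValidationError("divisor must be positive")
        expected = sum(it.max_value for it in self.strength_items)
        if expected != self.divisor:
            raise ValidationError(
                f"divisor {self.divisor} != sum of strength item maxima {expected}"
            )

    @property
    def strength_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.is_strength)

    @property
    def min_link_weight(self) -> float:
        """Smallest achievable link weight (every strength item at its floor)."""
        return sum(it.min_value for it in self.strength_items) / self.divisor

    @property
    def max_link_weight(self) -> float:
        return 1.0

    def item(self, name: str) -> Item:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @classmethod
    def study1(cls) -> "ItemSchema":
        """Eight-item schema: five strength items summing to a max of 8.

        Strength items: three binaries (time outside school, academic
        work, confide bad news), relationship nature (−1 negative … 4 best
        friend) and relative trust (−1, 0, 1).  Familial tie, romantic tie
        and duration of acquaintance are carried but not strength-scored.
        """
        return cls(
            items=(
                Item("familial", "binary", 0, 1),
                Item("romantic", "binary", 0, 1),
                Item("time_outside", "binary", 0, 1, is_strength=True),
                Item("academic_work", "binary", 0, 1, is_strength=True),
                Item("confide", "binary", 0, 1, is_strength=True),
                Item("nature", "ordinal", -1, 4, is_strength=True),
                Item("trust", "ordinal", -1, 1, is_strength=True),
                Item("duration", "ordinal", 0, 20),
            ),
            divisor=8,
        )

    @classmethod
    def study2(cls) -> "ItemSchema":
        """Single-gender replication schema: six strength items, max sum 9.

        Adds a conflict-resolution item (−1, 0, 1) to the Study-1 strength
        set and replaces duration-in-years with a binary primary-school
        acquaintance indicator (``duration1``).
        """
        return cls(
            items=(
                Item("time_outside", "binary", 0, 1, is_strength=True),
                Item("academic_work", "binary", 0, 1, is_strength=True),
                Item("confide", "binary", 0, 1, is_strength=True),
                Item("nature", "ordinal", -1, 4, is_strength=True),
                Item("trust", "ordinal", -1, 1, is_strength=True),
                Item("conflict", "ordinal", -1, 1, is_strength=True),
                Item("duration1", "binary", 0, 1),
            ),
            divisor=9,
        )


# ---------------------------------------------------------------------------
# DyadicMatrix
# ---------------------------------------------------------------------------

def offdiag_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the n(n−1) off-diagonal cells, row-major."""
    rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    return rows, cols


@dataclass
class DyadicMatrix:
    """Square valued matrix over an ordered actor list, diagonal masked.

    The diagonal is structurally NaN.  Off-diagonal NaN means *missing*,
    which is distinct from zero (zero is a meaningful scale point).
    """

    actors: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.actors = [str(a) for a in self.actors]
        if len(set(self.actors)) != len(self.actors):
            raise ValidationError("actor labels must be unique")
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.actors)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"values shape {self.values.shape} does not match {n} actors"
            )
        if n < 2:
            raise ValidationError("a dyadic matrix needs at least 2 actors")
        np.fill_diagonal(self.values, np.nan)

    @property
    def n(self) -> int:
        return len(self.actors)

    def offdiag_values(self) -> np.ndarray:
        """Off-diagonal cells as a 1-D vector in fixed row-major order."""
        r, c = offdiag_indices(self.n)
        return self.values[r, c]

    def transpose(self) -> "DyadicMatrix":
        return DyadicMatrix(list(self.actors), self.values.T, kind=self.kind)

    def permute(self, pi: Sequence[int]) -> "DyadicMatrix":
        """Relabel actors: cell (i, j) of the result is cell (pi[i], pi[j])."""
        pi = np.asarray(pi, dtype=int)
        if sorted(pi.tolist()) != list(range(self.n)):
            raise ValidationError("pi must be a bijection on actor indices")
        return DyadicMatrix(
            list(self.actors), self.values[np.ix_(pi, pi)], kind=self.kind
        )

    def to_csv(self, path: str | Path) -> None:
        """Write an adjacency CSV: actor IDs in first row and column, empty
        diagonal cells."""
        df = pd.DataFrame(self.values, index=self.actors, columns=self.actors)
        df.to_csv(path, index_label="")

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN pattern
        if not isinstance(other, DyadicMatrix):
            return NotImplemented
        return self.actors == other.actors and np.array_equal(
            self.values, other.values, equal_nan=True
        )


def read_adjacency_csv(path: str | Path, kind: str = "generic") -> DyadicMatrix:
    """Read an adjacency CSV written by :meth:`DyadicMatrix.to_csv`."""
    df = pd.read_csv(path, index_col=0)
    actors = [str(a) for a in df.index]
    if [str(c) for c in df.columns] != actors:
        raise ValidationError(f"{path}: row and column actor IDs differ")
    return DyadicMatrix(actors, df.to_numpy(dtype=float), kind=kind)


@dataclass
class GroupData:
    """One classroom network: outcome, predictors and actor attributes."""

    group_id: str
    actors: pd.DataFrame                      # actor_id, gender, attribute totals
    Y: DyadicMatrix                           # allocation matrix
    predictors: dict[str, DyadicMatrix]
    group_code: int
    points_to_self: pd.Series | None = None

    def __post_init__(self) -> None:
        order = list(self.Y.actors)
        for name, M in self.predictors.items():
            if M.actors != order:
                raise ValidationError(
                    f"group {self.group_id}: predictor {name!r} actor order "
                    "differs from the outcome matrix"
                )
        if "actor_id" in self.actors.columns:
            ids = self.actors["actor_id"].astype(str)
            if ids.duplicated().any():
                raise ValidationError(
                    f"group {self.group_id}: duplicate actor_id in actor table"
                )
        if "gender" in self.actors.columns:
            g = self.actors["gender"].dropna()
            if not g.isin([0, 1]).all():
                raise ValidationError(
                    f"group {self.group_id}: gender must be coded 0/1"
                )

    @property
    def n(self) -> int:
        return self.Y.n


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------

def _actor_order(responses: pd.DataFrame, actors: Sequence[str] | None) -> list[str]:
    if actors is not None:
        return [str(a) for a in actors]
    seen: dict[str, None] = {}
    for col in ("ego", "alter"):
        for a in responses[col].astype(str):
            seen.setdefault(a, None)
    return list(seen)


def score_relationship_strength(
    responses: pd.DataFrame,
    schema: ItemSchema,
    actors: Sequence[str] | None = None,
) -> DyadicMatrix:
    """Score long-format item responses into a relationship-strength matrix.

    ``responses`` has columns ``ego``, ``alter`` and one column per strength
    item; each (ego, alter) dyad may appear at most once.  The link weight
    is the sum of the strength-item responses divided by the schema divisor,
    so weights live in [schema.min_link_weight, 1].  Dyads absent from the
    table are *missing* (NaN), never zero.

    Raises
    ------
    ValidationError
        On self-dyads, duplicate dyads, responses outside an item's range,
        or unknown actor labels (when ``actors`` is given).
    """
    order = _actor_order(responses, actors)
    index = {a: i for i, a in enumerate(order)}
    strength = schema.strength_items
    for it in strength:
        if it.name not in responses.columns:
            raise ValidationError(f"responses lack strength item column {it.name!r}")

    ego = responses["ego"].astype(str).to_numpy()
    alter = responses["alter"].astype(str).to_numpy()
    if (ego == alter).any():
        bad = ego[ego == alter][0]
        raise ValidationError(f"self-dyad for actor {bad!r}")
    pairs = list(zip(ego, alter))
    if len(set(pairs)) != len(pairs):
        seen: set[tuple[str, str]] = set()
        for p in pairs:
            if p in seen:
                raise ValidationError(f"duplicate dyad {p[0]!r}->{p[1]!r}")
            seen.add(p)
    for a in np.concatenate([ego, alter]):
        if a not in index:
            raise ValidationError(f"unknown actor label {a!r}")

    for it in schema.items:
        if it.name not in responses.columns:
            continue
        col = responses[it.name].to_numpy(dtype=float)
        ok = np.isnan(col) | ((col >= it.min_value) & (col <= it.max_value))
        if not ok.all():
            k = int(np.nonzero(~ok)[0][0])
            raise ValidationError(
                f"item {it.name!r}: response {col[k]} outside "
                f"[{it.min_value}, {it.max_value}] for dyad "
                f"{ego[k]!r}->{alter[k]!r}"
            )

    n = len(order)
    values = np.full((n, n), np.nan)
    total = np.zeros(len(responses))
    for it in strength:
        total = total + responses[it.name].to_numpy(dtype=float)
    total /= schema.divisor
    rows = np.fromiter((index[a] for a in ego), dtype=int, count=len(ego))
    cols = np.fromiter((index[a] for a in alter), dtype=int, count=len(alter))
    values[rows, cols] = total
    return DyadicMatrix(order, values, kind="strength")


def build_reciprocation(S: DyadicMatrix) -> DyadicMatrix:
    """Reciprocation matrix R = Sᵀ − S.

    R(i, j) = S(j, i) − S(i, j): positive cells mean the alter reports a
    stronger tie toward ego than ego reports back (in-link exceeds
    out-link).  R is antisymmetric, so its off-diagonal cells sum to zero.
    """
    return DyadicMatrix(
        list(S.actors), S.values.T - S.values, kind="reciprocation"
    )


def build_attribute_matrix(
    actors: Sequence[str],
    values: Mapping[str, float] | pd.Series,
    mode: str,
    kind: str | None = None,
) -> DyadicMatrix:
    """Broadcast a per-actor attribute across rows (giving) or columns
    (receiving).

    ``giving`` encodes a sender effect, M(i, j) = value(i); ``receiving`` a
    receiver effect, M(i, j) = value(j).  Missing attribute values
    propagate as missing cells.
    """
    if mode not in ("giving", "receiving"):
        raise ValidationError(f"mode must be 'giving' or 'receiving', got {mode!r}")
    if isinstance(values, pd.Series):
        values = {str(k): v for k, v in values.items()}
    order = [str(a) for a in actors]
    for a in values:
        if str(a) not in order:
            raise ValidationError(f"unknown actor label {a!r}")
    v = np.array([float(values.get(a, np.nan)) for a in order])
    n = len(order)
    M = np.tile(v[:, None], (1, n)) if mode == "giving" else np.tile(v[None, :], (n, 1))
    return DyadicMatrix(order, M, kind=kind or f"attribute_{mode}")


def vectorize_dyads(matrices: Mapping[str, DyadicMatrix]) -> pd.DataFrame:
    """Stack named matrices into a dyad design table.

    One row per ordered off-diagonal dyad in fixed row-major order (n
    actors → n(n−1) rows), columns ``ego``, ``alter`` plus one per matrix.
    Rows with missing values are kept (NaN) so callers can drop them
    listwise with a logged count; the dyad identity travels with the row.
    """
    if not matrices:
        raise ValidationError("no matrices given")
    mats = dict(matrices)
    first = next(iter(mats.values()))
    order = first.actors
    for name, M in mats.items():
        if M.actors != order:
            raise ValidationError(f"matrix {name!r} has a different actor order")
    r, c = offdiag_indices(first.n)
    out = pd.DataFrame(
        {
            "ego": [order[i] for i in r],
            "alter": [order[j] for j in c],
        }
    )
    for name, M in mats.items():
        out[name] = M.values[r, c]
    return out
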