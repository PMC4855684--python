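"""Directional backward elimination over permutation-regression models.

Non-significant terms are removed one at a time, always the droppable
term whose *two-tailed* p-value is closest to 1, and the model is refit —
with a fresh permutation null — after every removal.  Two protection
rules shape the path: a main effect is never dropped while its
interaction term is still in the model, and terms named in
``forced_retention`` (e.g. a main effect kept to interpret a focal
group interaction) are never dropped at all.  Significance is judged at
each term's assigned tail: one-tailed for sign-hypothesized terms,
two-tailed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .network_data import ValidationError
from .qap import QapModelResult

__all__ = ["SelectionConfig", "EliminationStep", "EliminationTrace", "backward_eliminate"]

INTERACTION_SUFFIX = ":group"

FitFunc = Callable[[Sequence[str], int], QapModelResult]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    directional_terms: Mapping[str, int] = field(default_factory=dict)
    forced_retention: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class EliminationStep:
    model_terms: tuple[str, ...]
    dropped_term: str
    p_two_tailed: float
    result: QapModelResult


@dataclass(frozen=True)
class EliminationTrace:
    steps: tuple[EliminationStep, ...]
    final: QapModelResult | None
    final_terms: tuple[str, ...]

    @property
    def dropped_terms(self) -> tuple[str, ...]:
        return tuple(s.dropped_term for s in self.steps)


def main_effect_of(term: str) -> str | None:
    """The main-effect name a group-interaction term refers to, if any."""
    if term.endswith(INTERACTION_SUFFIX):
        return term[: -len(INTERACTION_SUFFIX)]
    return None


def backward_eliminate(
    initial_terms: Sequence[str],
    fit: FitFunc,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> EliminationTrace:
    """Run directional backward elimination from the full model.

    ``fit(terms, seed)`` must refit the model on exactly ``terms`` with a
    permutation stream derived from ``seed``; permutations are re-drawn at
    every step from a master seed sequence.  Elimination stops when every
    remaining droppable term is significant at the configured alpha with
    its assigned tail.  If all terms are eliminated and an empty model is
    not fittable, ``final`` is None (pure backward: no term re-enters).

    Ties in the drop criterion (possible at coarse permutation counts)
    are broken by dropping the term entered *later* in the initial order.
    """
    config = config or SelectionConfig()
    terms = list(initial_terms)
    if not terms:
        raise ValidationError("empty initial term set")
    if len(set(terms)) != len(terms):
        raise ValidationError("duplicate terms")
    entry_order = {t: i for i, t in enumerate(terms)}
    master = np.random.SeedSequence(seed)

    steps: list[EliminationStep] = []
    while True:
        step_seed = int(master.spawn(1)[0].generate_state(1)[0] % 2**31)
        try:
            result = fit(terms, step_seed)
        except ValidationError:
            if not terms:           # all terms eliminated, no null model
                return EliminationTrace(tuple(steps), None, ())
            raise
        if not terms:
            return EliminationTrace(tuple(steps), result, ())

        protected = set(config.forced_retention)
        for t in terms:
            m = main_effect_of(t)
            if m is not None and m in terms:
                protected.add(m)

        candidates = []
        for t in terms:
            tr = result.term(t)
            if tr.p < config.alpha:     # significant at the assigned tail
                continue
            if t in protected:
                continue
            candidates.append((tr.p_two_tailed, entry_order[t], t))
        if not candidates:
            return EliminationTrace(tuple(steps), result, tuple(terms))

        # drop the term with two-tailed p closest to 1; ties -> later entry
        candidates.sort(key=lambda x: (x[0], x[1]))
        p_two, _, drop = candidates[-1]
        steps.append(
            EliminationStep(
                model_terms=tuple(terms),
                dropped_term=drop,
                p_two_tailed=p_two,
                result=result,
            )
        )
        terms.remove(drop)
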