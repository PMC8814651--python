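"""Personalized goal ranking.

Each answer contributes a 0-5 priority score to its linked goal(s); every
goal's total is that contribution plus its fixed expert ranking weight
(0.01-0.24). Because priority contributions are integers and the 24 weights
are pairwise-distinct two-decimal fractions below 1, totals are tie-free on
any conforming instrument, and a respondent with zero need everywhere gets
the goals in plain weight-descending order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ResponseError
from .instrument import Instrument, Item
from .scoring import Answer, Response, resolve_option

__all__ = [
    "GoalPriority",
    "GoalPriorityList",
    "item_ips",
    "priority_scores",
    "prioritize",
    "top_k",
    "priority_table",
]

#: Cap on the summed priority contribution per goal, preserving the
#: weight-as-tiebreaker semantics for configs mapping a goal to many items.
IPS_CAP = 5

DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class GoalPriority:
    goal_id: str
    ips_component: int
    weight_component: float
    rank: int

    @property
    def total(self) -> float:
        return self.ips_component + self.weight_component


class GoalPriorityList(list):
    """Ranked goal priorities (rank 1 first). A plain list with helpers."""

    def by_goal(self) -> dict[str, GoalPriority]:
        return {gp.goal_id: gp for gp in self}

    def goal_ids(self) -> list[str]:
        return [gp.goal_id for gp in self]


def item_ips(item: Item, answer: Answer) -> dict[str, int]:
    """Priority contributions of one answer, per linked goal.

    Single-goal items yield that goal's option score. Situation-choice items
    yield the selected situation's score for its goal and 0 for siblings.
    """
    option = resolve_option(item, answer)
    return {g: option.ips_for(g) for g in item.goal_ids}


def _totals(inst: Instrument, resp: Response) -> dict[str, int]:
    missing = [i.item_id for i in inst.items if i.item_id not in resp.answers]
    if missing:
        raise ResponseError(
            f"respondent {resp.respondent_id!r}: missing answers for {missing}"
        )
    contrib = {g.goal_id: 0 for g in inst.goals}
    for item in inst.items:
        for goal_id, value in item_ips(item, resp.answers[item.item_id]).items():
            contrib[goal_id] += value
    return {g: min(v, IPS_CAP) for g, v in contrib.items()}


def prioritize(inst: Instrument, resp: Response) -> GoalPriorityList:
    """Rank all goals by descending total priority, ranks 1..N without gaps.

    Ties are unreachable on conforming instruments; defensively, higher
    expert weight wins, then ascending goal id.
    """
    contrib = _totals(inst, resp)
    order = sorted(
        inst.goals,
        key=lambda g: (-(contrib[g.goal_id] + g.expert_weight), -g.expert_weight, g.goal_id),
    )
    return GoalPriorityList(
        GoalPriority(
            goal_id=g.goal_id,
            ips_component=contrib[g.goal_id],
            weight_component=g.expert_weight,
            rank=rank,
        )
        for rank, g in enumerate(order, start=1)
    )


def priority_scores(inst: Instrument, resp: Response) -> dict[str, GoalPriority]:
    """Per-goal priorities (ranks included), keyed by goal id."""
    return prioritize(inst, resp).by_goal()


def top_k(gpl: GoalPriorityList, k: int = DEFAULT_TOP_K) -> list[str]:
    """The k highest-priority goal ids, best first."""
    if not 1 <= k <= len(gpl):
        raise ValueError(f"k must be in 1..{len(gpl)}, got {k}")
    return [gp.goal_id for gp in gpl[:k]]


def priority_table(
    inst: Instrument, responses: Iterable[Response]
) -> pd.DataFrame:
    """Long-format ranking table for a batch of responses.

    Columns: respondent_id, rank, goal_id, ips_component, weight_component,
    total.
    """
    rows = []
    for resp in responses:
        for gp in prioritize(inst, resp):
            rows.append(
                {
                    "respondent_id": resp.respondent_id,
                    "rank": gp.rank,
                    "goal_id": gp.goal_id,
                    "ips_component": gp.ips_component,
                    "weight_component": gp.weight_component,
                    "total": gp.total,
                }
            )
    return pd.DataFrame(rows)


def top_k_assignments(
    inst: Instrument, responses: Iterable[Response], k: int = DEFAULT_TOP_K
) -> dict[str, list[str]]:
    """Map respondent id to their top-k goal ids."""
    return {r.respondent_id: top_k(prioritize(inst, r), k) for r in responses}
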