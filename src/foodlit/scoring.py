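"""Per-item overall scores and the rescaled 0-100 food-literacy score."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import DataError, ResponseError
from .instrument import AnswerOption, Instrument, Item

__all__ = [
    "Response",
    "FoodLiteracyScore",
    "ScorePolicy",
    "resolve_option",
    "item_ios",
    "overall_score",
    "score_table",
    "read_responses_csv",
    "write_responses_csv",
]

Answer = Union[int, str]


@dataclass(frozen=True)
class Response:
    """One respondent's selected option per item.

    Answers map item id to either a 0-based option index or an option label.
    """

    respondent_id: str
    answers: Mapping[str, Answer]


@dataclass(frozen=True)
class ScorePolicy:
    """Scoring policy flags.

    missing
        ``"strict"`` — error on any unanswered item (default);
        ``"rescale"`` — score answered items against their own maximum.
    situations
        ``"include"`` — situation-choice items contribute their configured
        overall scores (default); ``"exclude"`` — drop them from both the
        numerator and the denominator.
    """

    missing: str = "strict"
    situations: str = "include"

    def __post_init__(self):
        if self.missing not in ("strict", "rescale"):
            raise ValueError(f"unknown missing-data policy {self.missing!r}")
        if self.situations not in ("include", "exclude"):
            raise ValueError(f"unknown situation policy {self.situations!r}")


@dataclass(frozen=True)
class FoodLiteracyScore:
    respondent_id: str
    ios_sum: int
    score_pct: float
    per_item_ios: Mapping[str, int]
    max_ios_sum: int
    rescaled: bool = False
    missing_items: tuple[str, ...] = ()


def resolve_option(item: Item, answer: Answer) -> AnswerOption:
    """Resolve an answer given as a 0-based index or an option label."""
    if isinstance(answer, bool):
        raise ResponseError(f"item {item.item_id}: invalid answer {answer!r}")
    if isinstance(answer, int):
        if not 0 <= answer < len(item.options):
            raise ResponseError(
                f"item {item.item_id}: option index {answer} outside "
                f"0..{len(item.options) - 1}"
            )
        return item.options[answer]
    label = str(answer).strip()
    for opt in item.options:
        if opt.label == label:
            return opt
    # permissive second pass: integer-looking strings are indices
    if label.lstrip("-").isdigit():
        return resolve_option(item, int(label))
    raise ResponseError(f"item {item.item_id}: unknown answer {answer!r}")


def item_ios(item: Item, answer: Answer) -> int:
    """The 0-6 overall score carried by the selected option."""
    return resolve_option(item, answer).ios


def overall_score(
    inst: Instrument, resp: Response, policy: ScorePolicy = ScorePolicy()
) -> FoodLiteracyScore:
    """Sum the per-item overall scores and rescale to a 0-100 percentage.

    The percentage is ``100 * ios_sum / max_attainable`` where the maximum
    is 6 per scored item (102 for the bundled instrument). Raises
    :class:`~foodlit.errors.ResponseError` for unanswered items under the
    strict missing-data policy.
    """
    items = [
        it
        for it in inst.items
        if not (policy.situations == "exclude" and it.format == "situation_choice")
    ]
    missing = [it.item_id for it in items if it.item_id not in resp.answers]
    if missing and policy.missing == "strict":
        raise ResponseError(
            f"respondent {resp.respondent_id!r}: missing answers for {missing}"
        )

    per_item: dict[str, int] = {}
    max_sum = 0
    for it in items:
        if it.item_id in missing:
            continue
        per_item[it.item_id] = item_ios(it, resp.answers[it.item_id])
        max_sum += it.max_ios
    if max_sum == 0:
        raise ResponseError(
            f"respondent {resp.respondent_id!r}: no scorable items answered"
        )
    ios_sum = sum(per_item.values())
    return FoodLiteracyScore(
        respondent_id=resp.respondent_id,
        ios_sum=ios_sum,
        score_pct=100.0 * ios_sum / max_sum,
        per_item_ios=per_item,
        max_ios_sum=max_sum,
        rescaled=bool(missing),
        missing_items=tuple(missing),
    )


def score_table(
    inst: Instrument,
    responses: Iterable[Response],
    policy: ScorePolicy = ScorePolicy(),
) -> pd.DataFrame:
    """Score a batch of responses into a tidy table.

    Columns: ``respondent_id, ios_sum, score_pct`` followed by one
    ``ios_<item_id>`` column per item.
    """
    rows = []
    for resp in responses:
        s = overall_score(inst, resp, policy)
        row = {
            "respondent_id": s.respondent_id,
            "ios_sum": s.ios_sum,
            "score_pct": s.score_pct,
        }
        for item_id, value in s.per_item_ios.items():
            row[f"ios_{item_id}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular I/O


def read_responses_csv(path: Union[str, Path], inst: Instrument) -> list[Response]:
    """Read responses from CSV: one row per respondent, one column per item.

    Values may be option labels or 0-based option indices. A
    ``respondent_id`` column is required.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot read responses from {path}: {exc}") from exc
    if "respondent_id" not in df.columns:
        raise DataError(f"{path}: missing required column 'respondent_id'")
    known = set(inst.item_ids)
    unknown = [c for c in df.columns if c != "respondent_id" and c not in known]
    if unknown:
        raise DataError(f"{path}: columns do not match instrument items: {unknown}")
    responses = []
    for i, row in df.iterrows():
        answers = {}
        for item_id in inst.item_ids:
            if item_id not in df.columns:
                continue
            val = row[item_id]
            if pd.isna(val):
                continue  # handled by the scoring missing-data policy
            answers[item_id] = val
        responses.append(Response(respondent_id=str(row["respondent_id"]), answers=answers))
    if not responses:
        raise DataError(f"{path}: no respondent rows found")
    return responses


def write_responses_csv(
    path: Union[str, Path], inst: Instrument, responses: Iterable[Response]
) -> None:
    """Write responses with answers rendered as option labels."""
    rows = []
    for resp in responses:
        row: dict[str, object] = {"respondent_id": resp.respondent_id}
        for item_id, answer in resp.answers.items():
            item = inst.item(item_id)
            row[item_id] = resolve_option(item, answer).label
        rows.append(row)
    cols = ["respondent_id"] + [i for i in inst.item_ids]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)
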