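"""Instrument data model: goals, items, answer options, loading and validation.

An instrument couples a set of behaviour-change goals (each carrying a
distinct expert ranking weight) to screener items whose answer options carry
two scores:

* ``ios`` (item overall score, 0-6) — summed into the overall 0-100
  food-literacy score;
* ``ips`` (item priority score, 0-5) — a need signal feeding the per-goal
  prioritization.

Instruments are serialized as YAML (see ``data/bundled_iflt.yaml`` for the
canonical bundled file and the schema-by-example). :func:`load_instrument`
and :func:`dump_instrument` round-trip losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .errors import InstrumentSchemaError, InstrumentValidationError

__all__ = [
    "Goal",
    "AnswerOption",
    "Item",
    "Instrument",
    "Violation",
    "bundled_iflt",
    "load_instrument",
    "dump_instrument",
    "validate_instrument",
    "DOMAINS",
    "ITEM_FORMATS",
]

DOMAINS = ("plan", "select", "prepare", "eat", "information")
ITEM_FORMATS = ("likert7", "frequency", "always_never", "situation_choice")

#: Formats that must offer exactly seven answer options.
SEVEN_OPTION_FORMATS = ("likert7", "frequency", "always_never")


@dataclass(frozen=True)
class Goal:
    goal_id: str
    label: str
    domain: str
    expert_weight: float


@dataclass(frozen=True)
class AnswerOption:
    label: str
    ios: int
    ips: int
    #: For multi-goal items: explicit per-goal need signals. ``None`` means
    #: the flat ``ips`` applies to every goal linked to the item; an empty
    #: mapping means the option signals no need for any goal.
    per_goal_ips: Optional[Mapping[str, int]] = None

    def ips_for(self, goal_id: str) -> int:
        if self.per_goal_ips is None:
            return self.ips
        return int(self.per_goal_ips.get(goal_id, 0))


@dataclass(frozen=True)
class Item:
    item_id: str
    text: str
    format: str
    options: tuple[AnswerOption, ...]
    goal_ids: tuple[str, ...]
    reverse_keyed: bool = False
    reconstructed: bool = False
    #: Optional record of the external expert relevance panel:
    #: ``{"experts": n, "agree": k}`` with k raters scoring the item 3-4.
    content_validity: Optional[Mapping[str, int]] = None

    @property
    def max_ios(self) -> int:
        return max(o.ios for o in self.options)

    @property
    def min_ios(self) -> int:
        return min(o.ios for o in self.options)

    def option_labels(self) -> list[str]:
        return [o.label for o in self.options]


@dataclass(frozen=True)
class Instrument:
    name: str
    version: str
    goals: tuple[Goal, ...]
    items: tuple[Item, ...]
    notes: tuple[str, ...] = ()

    def goal(self, goal_id: str) -> Goal:
        try:
            return self._goal_index[goal_id]
        except KeyError:
            raise KeyError(f"unknown goal id {goal_id!r}") from None

    def item(self, item_id: str) -> Item:
        try:
            return self._item_index[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    @property
    def goal_ids(self) -> list[str]:
        return [g.goal_id for g in self.goals]

    @property
    def item_ids(self) -> list[str]:
        return [i.item_id for i in self.items]

    @property
    def max_ios_sum(self) -> int:
        """Largest attainable sum of item overall scores."""
        return sum(i.max_ios for i in self.items)

    @property
    def _goal_index(self) -> dict[str, Goal]:
        return {g.goal_id: g for g in self.goals}

    @property
    def _item_index(self) -> dict[str, Item]:
        return {i.item_id: i for i in self.items}


@dataclass(frozen=True)
class Violation:
    """A single structural-invariant breach, keyed by config field path."""

    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.message}"


# ---------------------------------------------------------------------------
# parsing


def _require(mapping: Mapping, key: str, path: str):
    if key not in mapping:
        raise InstrumentSchemaError(f"{path}.{key}", "missing required field")
    return mapping[key]


def _parse_int(value, path: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise InstrumentSchemaError(path, f"expected an integer, got {value!r}")
    return value


def _parse_option(raw: Mapping, path: str) -> AnswerOption:
    if not isinstance(raw, Mapping):
        raise InstrumentSchemaError(path, "expected a mapping")
    label = str(_require(raw, "label", path))
    ios = _parse_int(_require(raw, "ios", path), f"{path}.ios")
    ips = _parse_int(_require(raw, "ips", path), f"{path}.ips")
    per_goal = raw.get("per_goal_ips")
    if per_goal is not None:
        if not isinstance(per_goal, Mapping):
            raise InstrumentSchemaError(f"{path}.per_goal_ips", "expected a mapping")
        per_goal = {
            str(k): _parse_int(v, f"{path}.per_goal_ips.{k}") for k, v in per_goal.items()
        }
    return AnswerOption(label=label, ios=ios, ips=ips, per_goal_ips=per_goal)


def _parse_item(raw: Mapping, path: str) -> Item:
    if not isinstance(raw, Mapping):
        raise InstrumentSchemaError(path, "expected a mapping")
    item_id = str(_require(raw, "item_id", path))
    fmt = str(_require(raw, "format", path))
    if fmt not in ITEM_FORMATS:
        raise InstrumentSchemaError(
            f"{path}.format", f"unknown format {fmt!r}; expected one of {ITEM_FORMATS}"
        )
    raw_goals = _require(raw, "goal_ids", path)
    if not isinstance(raw_goals, Sequence) or isinstance(raw_goals, str):
        raise InstrumentSchemaError(f"{path}.goal_ids", "expected a list of goal ids")
    raw_options = _require(raw, "options", path)
    if not isinstance(raw_options, Sequence):
        raise InstrumentSchemaError(f"{path}.options", "expected a list of options")
    options = tuple(
        _parse_option(o, f"{path}.options[{i}]") for i, o in enumerate(raw_options)
    )
    cv = raw.get("content_validity")
    if cv is not None:
        cv = {
            "experts": _parse_int(_require(cv, "experts", f"{path}.content_validity"),
                                  f"{path}.content_validity.experts"),
            "agree": _parse_int(_require(cv, "agree", f"{path}.content_validity"),
                                f"{path}.content_validity.agree"),
        }
    return Item(
        item_id=item_id,
        text=str(_require(raw, "text", path)),
        format=fmt,
        options=options,
        goal_ids=tuple(str(g) for g in raw_goals),
        reverse_keyed=bool(raw.get("reverse_keyed", False)),
        reconstructed=bool(raw.get("reconstructed", False)),
        content_validity=cv,
    )


def _parse_goal(raw: Mapping, path: str) -> Goal:
    if not isinstance(raw, Mapping):
        raise InstrumentSchemaError(path, "expected a mapping")
    weight = _require(raw, "expert_weight", path)
    if not isinstance(weight, (int, float)) or isinstance(weight, bool):
        raise InstrumentSchemaError(f"{path}.expert_weight", "expected a number")
    domain = str(_require(raw, "domain", path))
    if domain not in DOMAINS:
        raise InstrumentSchemaError(
            f"{path}.domain", f"unknown domain {domain!r}; expected one of {DOMAINS}"
        )
    return Goal(
        goal_id=str(_require(raw, "goal_id", path)),
        label=str(_require(raw, "label", path)),
        domain=domain,
        expert_weight=float(weight),
    )


def load_instrument(
    source: Union[str, Path, Mapping, io.IOBase], *, strict: bool = True
) -> Instrument:
    """Load an instrument from a YAML file path, YAML text, open stream, or
    an already-parsed mapping.

    With ``strict=True`` (default) the loaded instrument must pass
    :func:`validate_instrument`; violations raise
    :class:`~foodlit.errors.InstrumentValidationError`.
    """
    if isinstance(source, Mapping):
        raw = source
    else:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        elif isinstance(source, str):
            p = Path(source)
            # Treat short strings that name an existing file as paths.
            text = p.read_text(encoding="utf-8") if ("\n" not in source and p.is_file()) else source
        else:
            text = source.read()
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise InstrumentSchemaError("<root>", "expected a mapping at the top level")

    goals = tuple(
        _parse_goal(g, f"goals[{i}]") for i, g in enumerate(_require(raw, "goals", "<root>"))
    )
    items = tuple(
        _parse_item(it, f"items[{i}]") for i, it in enumerate(_require(raw, "items", "<root>"))
    )
    inst = Instrument(
        name=str(raw.get("name", "unnamed instrument")),
        version=str(raw.get("version", "0")),
        goals=goals,
        items=items,
        notes=tuple(str(n) for n in raw.get("notes", [])),
    )
    if strict:
        violations = validate_instrument(inst)
        if violations:
            raise InstrumentValidationError(violations)
    return inst


def dump_instrument(inst: Instrument) -> dict:
    """Serialize an instrument to the plain-dict form of the YAML schema."""
    out = {
        "name": inst.name,
        "version": inst.version,
        "notes": list(inst.notes),
        "goals": [
            {
                "goal_id": g.goal_id,
                "label": g.label,
                "domain": g.domain,
                "expert_weight": g.expert_weight,
            }
            for g in inst.goals
        ],
        "items": [],
    }
    for it in inst.items:
        raw_it = {
            "item_id": it.item_id,
            "text": it.text,
            "format": it.format,
            "goal_ids": list(it.goal_ids),
            "reverse_keyed": it.reverse_keyed,
            "reconstructed": it.reconstructed,
            "options": [],
        }
        if it.content_validity is not None:
            raw_it["content_validity"] = dict(it.content_validity)
        for o in it.options:
            raw_o = {"label": o.label, "ios": o.ios, "ips": o.ips}
            if o.per_goal_ips is not None:
                raw_o["per_goal_ips"] = dict(o.per_goal_ips)
            raw_it["options"].append(raw_o)
        out["items"].append(raw_it)
    return out


def instrument_to_yaml(inst: Instrument) -> str:
    return yaml.safe_dump(dump_instrument(inst), sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# validation


def validate_instrument(inst: Instrument) -> list[Violation]:
    """Check every structural invariant; returns an empty list iff all hold.

    The checks encode the bundled-instrument contract: 24 goals whose weights
    form exactly {0.01, ..., 0.24}, 17 items covering every goal, 0-6 overall
    scores, 0-5 priority scores with a zero-need option per item, and seven
    options for every ordinal-format item.
    """
    v: list[Violation] = []
    goal_ids = [g.goal_id for g in inst.goals]

    if len(inst.goals) != 24:
        v.append(Violation("goals", f"expected exactly 24 goals, found {len(inst.goals)}"))
    if len(set(goal_ids)) != len(goal_ids):
        v.append(Violation("goals", "goal ids are not unique"))

    weights = sorted(round(g.expert_weight, 2) for g in inst.goals)
    expected = [round(0.01 * k, 2) for k in range(1, len(inst.goals) + 1)]
    if weights != expected:
        v.append(
            Violation(
                "goals.expert_weight",
                f"weights must be pairwise distinct and form {{0.01..{expected[-1]:.2f}}}; got {weights}",
            )
        )

    if len(inst.items) != 17:
        v.append(Violation("items", f"expected exactly 17 items, found {len(inst.items)}"))
    item_ids = [i.item_id for i in inst.items]
    if len(set(item_ids)) != len(item_ids):
        v.append(Violation("items", "item ids are not unique"))

    covered: set[str] = set()
    for idx, it in enumerate(inst.items):
        path = f"items[{idx}]({it.item_id})"
        if not it.goal_ids:
            v.append(Violation(f"{path}.goal_ids", "item links to no goal"))
        for g in it.goal_ids:
            if g not in goal_ids:
                v.append(Violation(f"{path}.goal_ids", f"references unknown goal {g!r}"))
        covered.update(it.goal_ids)

        if it.format in SEVEN_OPTION_FORMATS and len(it.options) != 7:
            v.append(
                Violation(
                    f"{path}.options",
                    f"{it.format} items need exactly 7 options, found {len(it.options)}",
                )
            )
        if not it.options:
            v.append(Violation(f"{path}.options", "item has no options"))
            continue
        for oidx, o in enumerate(it.options):
            opath = f"{path}.options[{oidx}]"
            if not 0 <= o.ios <= 6:
                v.append(Violation(f"{opath}.ios", f"ios {o.ios} outside [0, 6]"))
            ips_values = [o.ips] if o.per_goal_ips is None else list(o.per_goal_ips.values())
            for val in ips_values:
                if not 0 <= val <= 5:
                    v.append(Violation(f"{opath}.ips", f"ips {val} outside [0, 5]"))
            if o.per_goal_ips is not None:
                for g in o.per_goal_ips:
                    if g not in it.goal_ids:
                        v.append(
                            Violation(
                                f"{opath}.per_goal_ips",
                                f"goal {g!r} is not linked to item {it.item_id}",
                            )
                        )
        labels = it.option_labels()
        if len(set(labels)) != len(labels):
            v.append(Violation(f"{path}.options", "option labels are not unique"))
        # at least one answer must signal no need on every linked goal
        if not any(
            all(o.ips_for(g) == 0 for g in it.goal_ids) for o in it.options
        ):
            v.append(Violation(f"{path}.options", "no option with a zero priority score"))
        if it.max_ios != 6:
            v.append(
                Violation(f"{path}.options", f"maximum ios is {it.max_ios}, expected 6")
            )

    uncovered = set(goal_ids) - covered
    if uncovered:
        v.append(
            Violation("goals", f"goals never referenced by any item: {sorted(uncovered)}")
        )
    return v


# ---------------------------------------------------------------------------
# bundled instrument

_BUNDLED_RESOURCE = "bundled_iflt.yaml"
_bundled_cache: Optional[Instrument] = None


def bundled_iflt() -> Instrument:
    """The bundled 24-goal / 17-item instrument, loaded from package data."""
    global _bundled_cache
    if _bundled_cache is None:
        ref = resources.files("foodlit.data").joinpath(_BUNDLED_RESOURCE)
        _bundled_cache = load_instrument(yaml.safe_load(ref.read_text(encoding="utf-8")))
    return _bundled_cache


def bundled_path() -> Path:
    """Filesystem path of the canonical bundled instrument config."""
    return Path(str(resources.files("foodlit.data").joinpath(_BUNDLED_RESOURCE)))
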