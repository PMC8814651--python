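"""Expert content-validity indices and the Flesch reading-ease formula.

The item content validity index (I-CVI) is the fraction of expert raters
scoring an item 3 or 4 on a 1-4 relevance scale; the scale index (S-CVI) is
the plain average of the item indices. Conventional relevance thresholds are
0.78 per item and 0.9 for the scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ComputationError, DataError

__all__ = [
    "ITEM_CVI_THRESHOLD",
    "SCALE_CVI_THRESHOLD",
    "ReadabilityCounts",
    "item_cvi",
    "scale_cvi",
    "cvi_flags",
    "cvi_report",
    "flesch_reading_ease",
    "count_syllables",
    "readability_counts",
]

ITEM_CVI_THRESHOLD = 0.78
SCALE_CVI_THRESHOLD = 0.9

#: Reading-ease band considered "fairly easy" for the average adult.
FAIRLY_EASY_BAND = (70.0, 80.0)


def item_cvi(ratings_for_item: Sequence[int]) -> float:
    """Fraction of raters scoring the item 3 or 4.

    Always a multiple of ``1 / len(ratings)``.
    """
    ratings = list(ratings_for_item)
    if not ratings:
        raise ComputationError("item_cvi needs at least one rating")
    for r in ratings:
        if r not in (1, 2, 3, 4):
            raise ComputationError(f"rating {r!r} outside the 1-4 relevance scale")
    return sum(1 for r in ratings if r >= 3) / len(ratings)


def scale_cvi(item_cvis: Sequence[float]) -> float:
    """Arithmetic mean of the item-level indices."""
    values = list(item_cvis)
    if not values:
        raise ComputationError("scale_cvi needs at least one item index")
    return sum(values) / len(values)


def cvi_flags(
    icvis: Sequence[float],
    scvi: float,
    *,
    item_threshold: float = ITEM_CVI_THRESHOLD,
    scale_threshold: float = SCALE_CVI_THRESHOLD,
) -> dict:
    """Relevance flags: item relevant iff I-CVI >= 0.78, scale iff S-CVI >= 0.9."""
    return {
        "items_relevant": [v >= item_threshold for v in icvis],
        "scale_relevant": scvi >= scale_threshold,
    }


def cvi_report(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-item I-CVI table from an experts x items rating grid.

    Rows are experts, columns are item ids, cells are 1-4 ratings. Returns a
    table with columns ``item_id, icvi, icvi_2dp, relevant`` plus the scale
    index in ``df.attrs["scvi"]`` / ``df.attrs["scale_relevant"]``.
    """
    if ratings.empty:
        raise DataError("expert rating matrix is empty")
    if ratings.isna().any().any():
        raise DataError("expert rating matrix has missing cells")
    icvis = {col: item_cvi([int(v) for v in ratings[col]]) for col in ratings.columns}
    scvi = scale_cvi(list(icvis.values()))
    flags = cvi_flags(list(icvis.values()), scvi)
    out = pd.DataFrame(
        {
            "item_id": list(icvis),
            "icvi": list(icvis.values()),
            "icvi_2dp": [round(v, 2) for v in icvis.values()],
            "relevant": flags["items_relevant"],
        }
    )
    out.attrs["scvi"] = scvi
    out.attrs["scvi_2dp"] = round(scvi, 2)
    out.attrs["scale_relevant"] = flags["scale_relevant"]
    return out


# ---------------------------------------------------------------------------
# readability


@dataclass(frozen=True)
class ReadabilityCounts:
    total_words: int
    total_sentences: int
    total_syllables: int

    def __post_init__(self):
        if self.total_sentences < 1:
            raise ComputationError("need at least one sentence")
        if self.total_words < self.total_sentences:
            raise ComputationError("word count below sentence count")
        if self.total_syllables < self.total_words:
            raise ComputationError("syllable count below word count")


def flesch_reading_ease(counts: ReadabilityCounts) -> float:
    """206.835 - 1.015 * (words/sentences) - 84.6 * (syllables/words).

    Depends only on the two ratios; higher scores read more easily, with
    70-80 considered fairly easy for the average adult.
    """
    return (
        206.835
        - 1.015 * (counts.total_words / counts.total_sentences)
        - 84.6 * (counts.total_syllables / counts.total_words)
    )


def is_fairly_easy(score: float) -> bool:
    lo, hi = FAIRLY_EASY_BAND
    return lo <= score <= hi


_VOWEL_GROUP = re.compile(r"[aeiouyàáâäèéêëìíîïòóôöùúûü]+", re.IGNORECASE)
_SENTENCE_END = re.compile(r"[.!?]+")
_WORD = re.compile(r"[^\W\d_]+", re.UNICODE)


def count_syllables(word: str) -> int:
    """Approximate syllable count by contiguous vowel groups (min 1).

    A crude heuristic only — language-specific hyphenation rules are out of
    scope, so scores computed from raw text are approximate by design.
    """
    return max(1, len(_VOWEL_GROUP.findall(word)))


def readability_counts(text: str) -> ReadabilityCounts:
    """Heuristic word/sentence/syllable counts for raw text."""
    words = _WORD.findall(text)
    if not words:
        raise ComputationError("no words found in text")
    sentences = len([s for s in _SENTENCE_END.split(text) if s.strip()])
    return ReadabilityCounts(
        total_words=len(words),
        total_sentences=max(1, sentences),
        total_syllables=sum(count_syllables(w) for w in words),
    )
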