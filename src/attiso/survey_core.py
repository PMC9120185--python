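"""Likert survey data model: items, response tables, dummy coding, scores.

The central container is :class:`SurveyDataset`, a respondent-by-item table
of ordinal response codes (1 = most negative ... n_levels = most positive)
with a country label per respondent.  Missing responses are stored as NaN.
Dummy coding expands each item into one binary indicator column per response
level ("attitude"); all correlation-network machinery downstream operates on
that expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Item",
    "SurveyDataset",
    "DummyMatrix",
    "LoadReport",
    "UndefinedResultError",
    "load_schema",
    "save_schema",
    "load_survey",
    "dummy_code",
    "vaccine_score",
    "cronbach_alpha",
    "VACCINE_SCORE_MIN",
    "VACCINE_SCORE_MAX",
    "SKEPTIC_THRESHOLD",
]

#: Range of the summed three-item vaccine score (three items coded 1-5).
VACCINE_SCORE_MIN = 3
VACCINE_SCORE_MAX = 15
#: A respondent scoring at or below this (all-neutral = 3*3) is a skeptic.
SKEPTIC_THRESHOLD = 9

_DEFAULT_LABELS_5 = [
    "Strongly disagree",
    "Mildly disagree",
    "Neutral",
    "Mildly agree",
    "Strongly agree",
]
_DEFAULT_LABELS_4 = [
    "Strongly disagree",
    "Mildly disagree",
    "Mildly agree",
    "Strongly agree",
]


class UndefinedResultError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


@dataclass(frozen=True)
class Item:
    """One survey question.

    Levels are coded 1 (most negative) to ``n_levels`` (most positive);
    5-level items carry a neutral middle level, 4-level items do not.
    """

    item_id: str
    topic: str = "other"
    n_levels: int = 5
    level_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_levels not in (4, 5):
            raise ValueError(f"item {self.item_id!r}: n_levels must be 4 or 5")
        if self.level_labels is None:
            labels = _DEFAULT_LABELS_5 if self.n_levels == 5 else _DEFAULT_LABELS_4
            object.__setattr__(self, "level_labels", tuple(labels))
        elif len(self.level_labels) != self.n_levels:
            raise ValueError(
                f"item {self.item_id!r}: {len(self.level_labels)} labels "
                f"for {self.n_levels} levels"
            )

    @property
    def has_neutral(self) -> bool:
        return self.n_levels == 5

    @property
    def levels(self) -> range:
        return range(1, self.n_levels + 1)


@dataclass
class LoadReport:
    """Accounting of cells coerced to missing while reading a CSV."""

    n_respondents: int = 0
    n_missing_input: int = 0
    n_out_of_range: int = 0
    n_unparseable: int = 0

    @property
    def n_coerced(self) -> int:
        return self.n_out_of_range + self.n_unparseable

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class SurveyDataset:
    """Respondent-level Likert responses with country labels.

    ``table`` has one row per respondent, a ``country`` column and one float
    column per item holding the level code or NaN for missing.
    """

    table: pd.DataFrame
    items: list[Item]
    report: LoadReport | None = None
    _by_id: dict[str, Item] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {it.item_id: it for it in self.items}
        if len(self._by_id) != len(self.items):
            raise ValueError("duplicate item ids in schema")
        if "country" not in self.table.columns:
            raise ValueError("survey table lacks a 'country' column")
        missing_cols = [i.item_id for i in self.items if i.item_id not in self.table.columns]
        if missing_cols:
            raise ValueError(f"survey table lacks item columns: {missing_cols}")
        if self.table["country"].isna().any() or (self.table["country"] == "").any():
            raise ValueError("empty country codes")
        for it in self.items:
            col = self.table[it.item_id]
            bad = col.notna() & ((col < 1) | (col > it.n_levels) | (col != np.round(col)))
            if bad.any():
                raise ValueError(f"out-of-range codes in item {it.item_id!r}")

    # -- accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> Item:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    @property
    def countries(self) -> list[str]:
        return sorted(self.table["country"].unique())

    @property
    def vaccine_items(self) -> list[Item]:
        return [it for it in self.items if it.topic == "vaccine"]

    def codes(self, item_subset: list[str] | None = None) -> pd.DataFrame:
        """Response codes (float, NaN = missing) for the given items."""
        ids = list(item_subset) if item_subset is not None else self.item_ids
        for i in ids:
            self.item(i)
        return self.table[ids]

    def restrict(self, country: str) -> "SurveyDataset":
        """Sub-dataset containing one country's respondents."""
        sub = self.table[self.table["country"] == country]
        if sub.empty:
            raise ValueError(f"no respondents for country {country!r}")
        return SurveyDataset(sub.reset_index(drop=True), self.items)

    def complete_mask(self, item_subset: list[str]) -> np.ndarray:
        """Boolean mask of respondents with no missing answer among items."""
        return self.codes(item_subset).notna().all(axis=1).to_numpy()

    def complete_cases(self, item_subset: list[str] | None = None) -> "SurveyDataset":
        """Listwise deletion: drop respondents missing any of the items."""
        ids = list(item_subset) if item_subset is not None else self.item_ids
        keep = self.complete_mask(ids)
        if not keep.any():
            raise ValueError("no complete cases remain")
        return SurveyDataset(self.table[keep].reset_index(drop=True), self.items)


@dataclass
class DummyMatrix:
    """One-hot expansion of a survey: respondents x attitudes.

    ``attitude_index`` lists (item_id, level) pairs in column order; for a
    non-missing response exactly one column of that item's block is 1, for a
    missing response the whole block is 0.
    """

    matrix: np.ndarray
    attitude_index: list[tuple[str, int]]
    item_groups: dict[str, list[int]]
    items: list[Item]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.attitude_index):
            raise ValueError("matrix width does not match attitude index")

    @property
    def n_respondents(self) -> int:
        return self.matrix.shape[0]

    def columns(self, item_id: str) -> np.ndarray:
        return self.matrix[:, self.item_groups[item_id]]

    def missing_mask(self, item_id: str) -> np.ndarray:
        """True where the respondent's answer to *item_id* is missing."""
        return self.columns(item_id).sum(axis=1) == 0

    def recover_codes(self) -> pd.DataFrame:
        """Invert the one-hot coding back to level codes (NaN = missing)."""
        out = {}
        for it in self.items:
            block = self.columns(it.item_id)
            codes = block.argmax(axis=1).astype(float) + 1
            codes[self.missing_mask(it.item_id)] = np.nan
            out[it.item_id] = codes
        return pd.DataFrame(out)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{i}:{lv}" for i, lv in self.attitude_index]
        return pd.DataFrame(self.matrix, columns=cols)


# -- schema I/O --------------------------------------------------------


def load_schema(path) -> list[Item]:
    """Read an item roster from YAML (``items:`` list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["items"] if isinstance(raw, dict) else raw
    items = []
    for e in entries:
        labels = e.get("level_labels")
        items.append(
            Item(
                item_id=e["item_id"],
                topic=e.get("topic", "other"),
                n_levels=int(e["n_levels"]),
                level_labels=tuple(labels) if labels else None,
            )
        )
    return items


def save_schema(items: list[Item], path) -> None:
    payload = {
        "items": [
            {
                "item_id": it.item_id,
                "topic": it.topic,
                "n_levels": it.n_levels,
                "level_labels": list(it.level_labels),
            }
            for it in items
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# -- operations --------------------------------------------------------


def load_survey(path, schema: list[Item]) -> SurveyDataset:
    """Read a respondent-per-row CSV against an item schema.

    Out-of-range or unparseable codes become missing and are tallied in the
    dataset's :class:`LoadReport`; an absent declared column is a hard error.
    """
    df = pd.read_csv(path, dtype={"country": str})
    if df.empty:
        raise ValueError(f"empty survey file: {path}")
    if "country" not in df.columns:
        raise ValueError("missing required column 'country'")
    for it in schema:
        if it.item_id not in df.columns:
            raise ValueError(f"missing declared item column {it.item_id!r}")

    report = LoadReport(n_respondents=len(df))
    clean = {"country": df["country"]}
    if "respondent_id" in df.columns:
        clean["respondent_id"] = df["respondent_id"]
    for it in schema:
        raw = df[it.item_id]
        report.n_missing_input += int(raw.isna().sum())
        num = pd.to_numeric(raw, errors="coerce")
        report.n_unparseable += int((num.isna() & raw.notna()).sum())
        out_of_range = num.notna() & ((num < 1) | (num > it.n_levels) | (num != np.round(num)))
        report.n_out_of_range += int(out_of_range.sum())
        num[out_of_range] = np.nan
        clean[it.item_id] = num.astype(float)
    table = pd.DataFrame(clean)
    return SurveyDataset(table, list(schema), report=report)


def dummy_code(data: SurveyDataset, item_subset: list[str] | None = None) -> DummyMatrix:
    """One-hot expand items into per-level attitude indicator columns.

    Column order is item order then ascending level.  Missing responses
    produce an all-zero block for that item.
    """
    ids = list(item_subset) if item_subset is not None else data.item_ids
    if not ids:
        raise ValueError("item_subset is empty")
    items = [data.item(i) for i in ids]
    blocks, index, groups = [], [], {}
    pos = 0
    for it in items:
        codes = data.table[it.item_id].to_numpy()
        block = (codes[:, None] == np.arange(1, it.n_levels + 1)).astype(np.int8)
        blocks.append(block)
        index.extend((it.item_id, lv) for lv in it.levels)
        groups[it.item_id] = list(range(pos, pos + it.n_levels))
        pos += it.n_levels
    return DummyMatrix(np.hstack(blocks), index, groups, items)


def _three_vaccine_items(data: SurveyDataset) -> list[Item]:
    vax = data.vaccine_items
    if len(vax) != 3:
        raise ValueError(f"expected exactly 3 vaccine items, found {len(vax)}")
    for it in vax:
        if it.n_levels != 5:
            raise ValueError(f"vaccine item {it.item_id!r} must have 5 levels")
    return vax


def vaccine_score(data: SurveyDataset) -> pd.Series:
    """Summed 3-item vaccine trust score per respondent, in [3, 15].

    All-strong-trust answers give 3*5 = 15, all-strong-distrust 3*1 = 3,
    all-neutral 9.  NaN where any of the three answers is missing.
    """
    vax = _three_vaccine_items(data)
    codes = data.codes([it.item_id for it in vax])
    score = codes.sum(axis=1, skipna=False)
    score.name = "vaccine_score"
    return score


def cronbach_alpha(data: SurveyDataset, item_subset: list[str] | None = None) -> float:
    """Cronbach's alpha internal-consistency reliability of an item set.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the summed
    score), computed on complete cases with sample (ddof=1) variances.
    """
    ids = list(item_subset) if item_subset is not None else data.item_ids
    if len(ids) < 2:
        raise ValueError("cronbach_alpha needs at least 2 items")
    codes = data.codes(ids).dropna()
    if len(codes) < 2:
        raise ValueError("cronbach_alpha needs at least 2 complete respondents")
    k = len(ids)
    total_var = codes.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedResultError("total score has zero variance")
    item_var = codes.var(ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
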