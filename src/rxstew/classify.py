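"""Label prescription courses: antibiotic / anti-hypertensive / other.

Each course's medication name is matched case-insensitively against a keyword
lexicon; the longest matching keyword wins, so combination products (which
carry their own combination keyword) never fall back to a partial-name match.
Antibiotics additionally receive an antibiotic spectrum index (ASI) score on
the 1-13 scale (1 = narrowest spectrum, 13 = broadest); antibiotics absent
from the ASI table are carried as unscored and excluded from ASI averages.

Classification is name-based (the NDC column is metadata only).  The bundled
lexicon and ASI table are package-supplied defaults, overridable by path.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigError

ASI_MIN, ASI_MAX = 1, 13

ANTIHYPERTENSIVE_SUBCLASSES = {"beta-blocker", "ACE-I", "ARB"}


def _bundled(name: str) -> Path:
    return Path(str(resources.files("rxstew").joinpath("data", name)))


@dataclass(frozen=True)
class LexiconEntry:
    keyword: str
    generic: str
    category: str  # antibiotic | antihypertensive | other
    drug_class: str
    subclass: str


class DrugLexicon:
    """Keyword lexicon; validates category coherence and keyword uniqueness."""

    def __init__(self, entries: list[LexiconEntry]):
        seen: dict[str, LexiconEntry] = {}
        by_generic: dict[str, str] = {}
        for entry in entries:
            prior = seen.get(entry.keyword)
            if prior is not None and prior != entry:
                raise ConfigError(
                    f"lexicon keyword {entry.keyword!r} maps to conflicting entries"
                )
            if by_generic.setdefault(entry.generic, entry.category) != entry.category:
                raise ConfigError(
                    f"generic {entry.generic!r} assigned to two categories"
                )
            if entry.category == "antihypertensive" and entry.subclass not in ANTIHYPERTENSIVE_SUBCLASSES:
                raise ConfigError(
                    f"anti-hypertensive subclass {entry.subclass!r} not one of "
                    f"{sorted(ANTIHYPERTENSIVE_SUBCLASSES)}"
                )
            seen[entry.keyword] = entry
        # longest keyword first => deterministic longest-match
        self.entries = sorted(seen.values(), key=lambda e: (-len(e.keyword), e.keyword))

    def match(self, medication: str) -> LexiconEntry | None:
        name = str(medication).upper()
        for entry in self.entries:
            if entry.keyword in name:
                return entry
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"keyword": e.keyword, "generic": e.generic, "category": e.category,
                 "class": e.drug_class, "subclass": e.subclass}
                for e in self.entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_lexicon(path: str | Path | None = None) -> DrugLexicon:
    """Load the keyword lexicon (bundled default when ``path`` is None)."""
    source = Path(path) if path is not None else _bundled("lexicon.csv")
    frame = pd.read_csv(source, comment="#", dtype=str, keep_default_na=False)
    required = {"keyword", "generic", "category"}
    if not required <= set(frame.columns):
        raise ConfigError(f"lexicon must have columns {sorted(required)}")
    entries = [
        LexiconEntry(
            keyword=row["keyword"].strip().upper(),
            generic=row["generic"].strip().upper(),
            category=row["category"].strip(),
            drug_class=str(row.get("class", "")).strip(),
            subclass=str(row.get("subclass", "")).strip(),
        )
        for _, row in frame.iterrows()
    ]
    bad = {e.category for e in entries} - {"antibiotic", "antihypertensive", "other"}
    if bad:
        raise ConfigError(f"unknown lexicon categories: {sorted(bad)}")
    return DrugLexicon(entries)


def load_asi(path: str | Path | None = None) -> dict[str, int]:
    """Load the generic-name -> ASI score table; scores must lie in [1, 13]."""
    source = Path(path) if path is not None else _bundled("asi_scores.csv")
    frame = pd.read_csv(source, comment="#", dtype=str, keep_default_na=False)
    table: dict[str, int] = {}
    for _, row in frame.iterrows():
        generic = row["generic"].strip().upper()
        score = int(row["asi"])
        if not ASI_MIN <= score <= ASI_MAX:
            raise ConfigError(f"ASI score for {generic} out of [1, 13]: {score}")
        table[generic] = score
    return table


def classify_name(medication: str, lexicon: DrugLexicon) -> LexiconEntry:
    """Classify one medication name; no lexicon match -> category 'other'."""
    entry = lexicon.match(medication)
    if entry is None:
        return LexiconEntry("", "", "other", "", "")
    return entry


def asi_of(generic: str, table: Mapping[str, int]) -> int | None:
    """Exact-name ASI lookup; None means unscored (excluded from averages)."""
    score = table.get(str(generic).upper())
    return int(score) if score is not None else None


def classify_courses(
    courses: pd.DataFrame,
    lexicon: DrugLexicon | None = None,
    asi_table: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Append category/class/subclass/generic/asi columns to a course table.

    Every course receives exactly one category.  The ``asi`` column is
    populated for scored antibiotics only.
    """
    lexicon = lexicon if lexicon is not None else load_lexicon()
    asi_table = asi_table if asi_table is not None else load_asi()
    labeled = courses.copy()
    cats, classes, subs, generics, scores = [], [], [], [], []
    for name in labeled["medication"].fillna(""):
        entry = classify_name(name, lexicon)
        cats.append(entry.category)
        classes.append(entry.drug_class)
        subs.append(entry.subclass)
        generics.append(entry.generic)
        if entry.category == "antibiotic":
            scores.append(asi_of(entry.generic, asi_table))
        else:
            scores.append(None)
    labeled["category"] = cats
    labeled["class"] = classes
    labeled["subclass"] = subs
    labeled["generic"] = generics
    labeled["asi"] = pd.array(scores, dtype="Int64")
    return labeled


def asi_coverage(labeled: pd.DataFrame) -> dict:
    """Report scored vs unscored antibiotic courses (for ASI aggregation)."""
    abx = labeled[labeled["category"] == "antibiotic"]
    unscored = abx[abx["asi"].isna()]
    return {
        "antibiotic_courses": int(len(abx)),
        "scored": int(abx["asi"].notna().sum()),
        "unscored": int(len(unscored)),
        "unscored_generics": sorted(unscored["generic"].unique().tolist()),
    }
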