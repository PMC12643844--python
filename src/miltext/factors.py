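"""Closed-vocabulary lexicon mapping of extracted factor terms.

Candidate terms from the semantic-graph expansion are matched against a
category lexicon (52 categories consolidated into nine broader groups, in
the style of LIWC-class dictionaries). A term increments every category
that lists it; per-post category counts are ranked into Top-k labels, and
group-level tables report, per MIL subgroup, the share of posts touching
each category.

The proprietary LIWC Chinese dictionary is not distributed; any
dictionary in the two-column TSV format can be plugged in, and a small
generic 52-category lexicon ships for tests and synthetic runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CategoryLexicon:
    """category -> term set, plus category -> group consolidation map."""

    categories: dict[str, frozenset[str]]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("lexicon has no categories")
        for cat, terms in self.categories.items():
            if not terms:
                raise ValueError(f"category {cat!r} has no terms")
            if cat not in self.group_of:
                raise ValueError(f"category {cat!r} has no group")
        self._term_index: dict[str, list[str]] = {}
        for cat, terms in self.categories.items():
            for t in terms:
                self._term_index.setdefault(t, []).append(cat)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def categories_of(self, term: str) -> list[str]:
        return self._term_index.get(term, [])

    @classmethod
    def from_files(cls, lexicon_path: str | Path, groups_path: str | Path) -> "CategoryLexicon":
        lex = pd.read_csv(lexicon_path, sep="\t", dtype=str)
        grp = pd.read_csv(groups_path, sep="\t", dtype=str)
        cats: dict[str, set[str]] = {}
        for r in lex.itertuples(index=False):
            cats.setdefault(r.category, set()).add(r.term)
        group_of = dict(zip(grp.category, grp.group))
        return cls({c: frozenset(t) for c, t in cats.items()}, group_of)


def load_toy_lexicon() -> CategoryLexicon:
    """The shipped generic 52-category lexicon (tests / synthetic runs)."""
    data = resources.files("miltext") / "data"
    return CategoryLexicon.from_files(
        str(data / "toy_lexicon.tsv"), str(data / "toy_groups.tsv")
    )


@dataclass
class FactorAssignment:
    """Per-post lexicon mapping result."""

    post_id: str
    matched: dict[str, list[str]]         # term -> categories hit
    counts: dict[str, int]                # category -> count
    unmatched: list[str] = field(default_factory=list)
    topk: list[str] = field(default_factory=list)


def map_terms(candidates: Sequence[str], lexicon: CategoryLexicon
              ) -> tuple[dict[str, int], dict[str, list[str]], list[str]]:
    """Count category hits for candidate terms.

    Each candidate increments every category containing it (multi-category
    words inflate counts, never deflate). Returns (counts, matched,
    unmatched).
    """
    counts: dict[str, int] = {}
    matched: dict[str, list[str]] = {}
    unmatched: list[str] = []
    for term in candidates:
        cats = lexicon.categories_of(term)
        if cats:
            matched[term] = list(cats)
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
        else:
            unmatched.append(term)
    return counts, matched, unmatched


def rank_topk(counts: Mapping[str, int], k: int) -> list[str]:
    """Top-k categories: count descending, then name ascending (stable)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [cat for cat, _ in ordered[:k]]


def assign_factors(post_id: str, candidates: Sequence[str],
                   lexicon: CategoryLexicon, k: int = 3) -> FactorAssignment:
    counts, matched, unmatched = map_terms(candidates, lexicon)
    return FactorAssignment(
        post_id=post_id, matched=matched, counts=counts,
        unmatched=unmatched, topk=rank_topk(counts, k),
    )


def group_proportions(assignments: Mapping[str, Sequence[FactorAssignment]],
                      lexicon: CategoryLexicon,
                      valid_groups: Iterable[str] = (
                          "S1", "S0", "P1", "P0", "S1P1", "S1P0", "S0P1", "S0P0",
                      )) -> pd.DataFrame:
    """Per-MIL-group category proportions (percent of posts, 0-100).

    ``assignments`` maps a subgroup key to that group's per-post factor
    assignments. A cell is the percentage of the group's posts whose
    counts include the category; rows need not sum to anything (posts are
    multi-label). Unknown group keys are an error; an empty group yields
    an all-zero row with a warning.
    """
    valid = set(valid_groups)
    unknown = set(assignments) - valid
    if unknown:
        raise ValueError(f"unknown group tag(s): {sorted(unknown)}")
    cats = sorted(lexicon.categories)
    rows = {}
    for grp, items in assignments.items():
        if not items:
            logger.warning("group %s has no posts; zero row emitted", grp)
            rows[grp] = {c: 0.0 for c in cats}
            continue
        n = len(items)
        rows[grp] = {
            c: 100.0 * sum(1 for a in items if a.counts.get(c, 0) > 0) / n
            for c in cats
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cats)
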