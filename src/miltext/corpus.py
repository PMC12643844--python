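"""Corpus loading, cleaning, seed screening, and accounting statistics.

Posts are short social-media messages (microblogs). Cleaning removes
noise-term-bearing posts (advertisements, link markers, platform
boilerplate) and near-duplicates; seed screening keeps posts containing at
least one keyword from a topical seed lexicon, producing a high-density
subset for annotation.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


def normalize(text: str) -> str:
    """Normalization used for all matching: Unicode NFKC + casefold.

    Chinese text has no case; the casefold matters only for Latin-token
    fixtures. NFKC collapses full-width/half-width variants, which do occur
    in microblog text.
    """
    return unicodedata.normalize("NFKC", text).casefold()


@dataclass(frozen=True)
class Post:
    """One social-media message."""

    post_id: str
    text: str
    user_id: str | None = None
    created_at: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"post {self.post_id!r}: empty text")


@dataclass
class CleaningConfig:
    """Rules for corpus cleaning.

    Parameters
    ----------
    noise_terms :
        Terms whose presence marks a post as noise (ad phrases, "http"
        link markers, boilerplate). The whole post is dropped.
    dedup_min_chars :
        Duplicate removal applies only to texts strictly longer than this
        many characters (default 10): short formulaic posts ("good night")
        are legitimately repeated, longer identical texts are reposts.
    """

    noise_terms: frozenset[str] = field(default_factory=frozenset)
    dedup_min_chars: int = 10

    def __post_init__(self) -> None:
        if self.dedup_min_chars < 0:
            raise ValueError("dedup_min_chars must be >= 0")
        self.noise_terms = frozenset(normalize(t) for t in self.noise_terms)


@dataclass(frozen=True)
class SeedLexicon:
    """A named list of seed keywords/expressions."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"seed lexicon {self.name!r} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "SeedLexicon":
        terms = _read_term_file(path)
        return cls(name=name or Path(path).stem, terms=frozenset(terms))


@dataclass
class CleaningReport:
    n_input: int = 0
    n_noise_removed: int = 0
    n_dup_removed: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_noise_removed + self.n_dup_removed


def _read_term_file(path: str | Path) -> list[str]:
    """One term per line; '#' starts a comment; blank lines ignored."""
    terms: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip()
        if term:
            terms.append(term)
    return terms


def load_noise_terms(path: str | Path) -> frozenset[str]:
    return frozenset(_read_term_file(path))


def load_posts(path: str | Path, format: str = "jsonl") -> list[Post]:
    """Load posts from a JSON-lines file.

    Each record needs ``post_id`` and a non-empty ``text``; ``user_id`` and
    ``created_at`` are optional. Malformed records (bad JSON, missing id or
    text) are skipped with a logged count rather than aborting the load.
    """
    if format != "jsonl":
        raise ValueError(f"unknown post format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    posts: list[Post] = []
    n_skipped = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            posts.append(
                Post(
                    post_id=str(rec["post_id"]),
                    text=rec["text"] if rec["text"] else None,
                    user_id=rec.get("user_id"),
                    created_at=rec.get("created_at"),
                )
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed record at %s:%d (%s)", path, lineno, exc)
    if n_skipped:
        logger.warning("%d malformed record(s) skipped in %s", n_skipped, path)
    if not posts:
        logger.warning("no posts loaded from %s", path)
    return posts


def save_posts(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {"post_id": p.post_id, "user_id": p.user_id, "text": p.text,
                   "created_at": p.created_at}
            fh.write(json.dumps({k: v for k, v in rec.items() if v is not None},
                                ensure_ascii=False) + "\n")


def clean_corpus(posts: Sequence[Post], cfg: CleaningConfig) -> tuple[list[Post], CleaningReport]:
    """Remove noise-term posts, then deduplicate long identical texts.

    Rule order: noise filter first, then dedup. A post is noise when its
    normalized text contains any noise term as a substring. Deduplication
    keys on the normalized full text and applies only to texts strictly
    longer than ``cfg.dedup_min_chars``; the first occurrence survives.
    """
    report = CleaningReport(n_input=len(posts))
    survivors: list[Post] = []
    for p in posts:
        norm = normalize(p.text)
        if any(term in norm for term in cfg.noise_terms):
            report.n_noise_removed += 1
        else:
            survivors.append(p)

    seen: set[str] = set()
    retained: list[Post] = []
    for p in survivors:
        norm = normalize(p.text)
        if len(norm) > cfg.dedup_min_chars:
            if norm in seen:
                report.n_dup_removed += 1
                continue
            seen.add(norm)
        retained.append(p)
    report.n_retained = len(retained)
    return retained, report


def screen_seeds(posts: Sequence[Post], lexicon: SeedLexicon) -> list[Post]:
    """Keep posts whose text contains >= 1 seed term (substring match).

    Matching is on normalized text; input order is preserved. An empty
    lexicon is rejected at construction time (it would silently drop
    everything).
    """
    terms = [normalize(t) for t in lexicon.terms]
    return [p for p in posts if any(t in normalize(p.text) for t in terms)]


def corpus_stats(posts: Sequence[Post]) -> dict:
    """Corpus accounting: post/user counts and per-user / per-post means.

    Means are rounded to 2 decimals. When no post carries a user id the
    per-user fields are omitted with a warning.
    """
    stats: dict = {"n_posts": len(posts)}
    if posts:
        stats["mean_chars_per_post"] = round(
            sum(len(p.text) for p in posts) / len(posts), 2
        )
    users = {p.user_id for p in posts if p.user_id is not None}
    if users:
        stats["n_users"] = len(users)
        n_with_user = sum(1 for p in posts if p.user_id is not None)
        stats["mean_posts_per_user"] = round(n_with_user / len(users), 2)
    else:
        logger.warning("no user ids present; per-user statistics omitted")
    return stats
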