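"""Data augmentation: random deletion and similarity-gated synonym swap.

A labeled post set is expanded to a task-specific target size by two
operations applied round-robin over source posts:

* random deletion of one or two *noncritical* tokens (adverbs,
  intensifiers, particles — anything a pluggable tag function marks
  deletable), which leaves the central meaning intact;
* synonym replacement, where a candidate substitute is accepted only when
  the cosine similarity between its embedding and the original token's
  embedding exceeds a threshold (default 0.80, strict inequality).

Augmented posts keep their source's label and carry a provenance tag; a
random fraction is exported to a review file for manual quality control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: default noncritical part-of-speech tags (deletable without changing meaning)
NONCRITICAL_TAGS = frozenset({"ADV", "INTENS", "PART"})


@dataclass
class AugmentConfig:
    target_size: int
    sim_threshold: float = 0.80
    max_deletions: int = 2
    qc_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sim_threshold < 1.0:
            raise ValueError("sim_threshold must be in (0, 1)")
        if self.max_deletions not in (1, 2):
            raise ValueError("max_deletions must be 1 or 2")


@dataclass
class LabeledPost:
    post_id: str
    tokens: list[str]
    label: str
    source_id: str | None = None
    aug_op: str | None = None
    tags: list[str] | None = None  # optional per-token POS tags

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


class CharNgramEmbedding:
    """Deterministic character n-gram hashing embedding.

    A lightweight, fully reproducible embedding provider: a token's vector
    is the normalized sum of hashed character n-gram one-hot projections.
    Orthographically similar tokens (shared character n-grams) get high
    cosine similarity, which is what the synonym gate needs in fixtures.
    Same text always maps to the same vector.
    """

    def __init__(self, dim: int = 64, n: tuple[int, ...] = (2, 3)):
        self.dim = dim
        self.n = n

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        padded = f"<{text}>"
        for n in self.n:
            for i in range(len(padded) - n + 1):
                gram = padded[i : i + n]
                # stable hash (Python's hash() is salted per process)
                h = 0
                for ch in gram:
                    h = (h * 131 + ord(ch)) % (2**31)
                v[h % self.dim] += 1.0
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def default_is_noncritical(token: str, tag: str | None) -> bool:
    return tag in NONCRITICAL_TAGS


def random_deletion(
    tokens: Sequence[str],
    k: int,
    rng: np.random.Generator,
    tags: Sequence[str] | None = None,
    is_noncritical: Callable[[str, str | None], bool] = default_is_noncritical,
) -> tuple[list[str], bool]:
    """Delete ``k`` (1 or 2) noncritical tokens at random.

    Critical (content) tokens are never removed. Returns the new token
    sequence and a ``changed`` flag; when no token is deletable the input
    is returned unchanged with ``changed=False``.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    tags = tags if tags is not None else [None] * len(tokens)
    deletable = [i for i, (t, g) in enumerate(zip(tokens, tags)) if is_noncritical(t, g)]
    if not deletable:
        return list(tokens), False
    k_eff = min(k, len(deletable))
    drop = set(rng.choice(deletable, size=k_eff, replace=False).tolist())
    return [t for i, t in enumerate(tokens) if i not in drop], True


def synonym_replace(
    tokens: Sequence[str],
    provider,
    threshold: float,
    rng: np.random.Generator,
    synonym_table: Mapping[str, Sequence[str]],
) -> tuple[list[str], bool]:
    """Replace one token with a semantically close synonym.

    Candidate substitutes come from ``synonym_table``; a candidate is
    accepted only if cosine(embed(original), embed(candidate)) > threshold
    (strict). Token positions are tried in random order; the first
    accepted substitution is applied. If no candidate anywhere passes the
    gate the input is returned unchanged with ``changed=False``.
    """
    order = rng.permutation(len(tokens))
    for i in order:
        tok = tokens[i]
        candidates = list(synonym_table.get(tok, ()))
        if not candidates:
            continue
        rng.shuffle(candidates)
        base = provider.embed(tok)
        for cand in candidates:
            if cand == tok:
                continue
            if cosine(base, provider.embed(cand)) > threshold:
                out = list(tokens)
                out[i] = cand
                return out, True
    return list(tokens), False


def augment_to_target(
    labeled_posts: Sequence[LabeledPost],
    cfg: AugmentConfig,
    provider=None,
    synonym_table: Mapping[str, Sequence[str]] | None = None,
    qc_path: str | Path | None = None,
) -> list[LabeledPost]:
    """Expand a labeled set to ``cfg.target_size`` posts.

    Source posts are cycled round-robin, alternating deletion and synonym
    replacement, until the target is reached; every augmented post carries
    ``source_id`` and ``aug_op`` provenance and its source's label. A
    ``cfg.qc_fraction`` random sample of the augmented items is written to
    ``qc_path`` (JSON-lines) for manual review when a path is given.
    Raises when no operation can produce further items.
    """
    if cfg.target_size < len(labeled_posts):
        raise ValueError("target_size smaller than input size")
    if not labeled_posts and cfg.target_size > 0:
        raise ValueError("cannot augment an empty input set")
    rng = np.random.default_rng(cfg.seed)
    provider = provider or CharNgramEmbedding()
    synonym_table = synonym_table or {}

    out = list(labeled_posts)
    augmented: list[LabeledPost] = []
    ops = ("del", "syn")
    n_needed = cfg.target_size - len(labeled_posts)
    attempt, stall = 0, 0
    while len(augmented) < n_needed:
        src = labeled_posts[attempt % len(labeled_posts)]
        op = ops[(attempt // len(labeled_posts)) % 2]
        attempt += 1
        if op == "del":
            k = int(rng.integers(1, cfg.max_deletions + 1))
            tokens, changed = random_deletion(src.tokens, k, rng, tags=src.tags)
        else:
            tokens, changed = synonym_replace(
                src.tokens, provider, cfg.sim_threshold, rng, synonym_table
            )
        if not changed:
            stall += 1
            if stall > 2 * len(labeled_posts):
                shortfall = n_needed - len(augmented)
                raise RuntimeError(
                    f"augmentation stalled: {shortfall} item(s) short of target"
                )
            continue
        stall = 0
        augmented.append(
            LabeledPost(
                post_id=f"{src.post_id}#aug{len(augmented)}",
                tokens=tokens,
                label=src.label,
                source_id=src.post_id,
                aug_op=op,
                tags=None,
            )
        )
    out.extend(augmented)

    if qc_path is not None and augmented:
        n_qc = max(1, int(round(cfg.qc_fraction * len(augmented))))
        idx = rng.choice(len(augmented), size=min(n_qc, len(augmented)), replace=False)
        with open(qc_path, "w", encoding="utf-8") as fh:
            for i in sorted(idx.tolist()):
                a = augmented[i]
                fh.write(json.dumps({
                    "post_id": a.post_id, "text": a.text, "label": a.label,
                    "source_id": a.source_id, "aug_op": a.aug_op,
                }, ensure_ascii=False) + "\n")
    return out
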