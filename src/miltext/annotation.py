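"""Multi-annotator label merging, agreement, and dataset accounting.

Each post is labeled independently by several annotators (default two) on
up to three binary tasks — MIL relevance (REL), search-for-meaning level
(SFM), presence-of-meaning level (POM) — with an explicit "unable to
judge" option. Consensus requires unanimity; posts with any unable vote or
with disagreeing labels are excluded from the modeling set, and the
accounting report reproduces the retained/excluded bookkeeping.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.metrics import cohen_kappa_score

TASKS = ("REL", "SFM", "POM")
LABELS = ("POSITIVE", "NEGATIVE", "UNABLE")
STATUSES = ("CONSISTENT", "INCONSISTENT", "UNABLE")


@dataclass(frozen=True)
class AnnotationRecord:
    post_id: str
    annotator_id: str
    task: str
    label: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ConsensusLabel:
    post_id: str
    task: str
    status: str
    label: str | None = None

    def __post_init__(self) -> None:
        if (self.status == "CONSISTENT") != (self.label is not None):
            raise ValueError("label present iff status CONSISTENT")


@dataclass
class FilterReport:
    """Accounting of the consensus filter for one task."""

    n_input: int
    n_inconsistent: int
    n_unable: int
    n_retained: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]

    @property
    def n_excluded(self) -> int:
        return self.n_inconsistent + self.n_unable


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV label table with columns post_id, annotator_id, task, label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"post_id", "annotator_id", "task", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return [
        AnnotationRecord(r.post_id, r.annotator_id, r.task, r.label)
        for r in df.itertuples(index=False)
    ]


def merge_consensus(
    records: Iterable[AnnotationRecord],
    task: str,
    n_annotators: int = 2,
) -> list[ConsensusLabel]:
    """Merge per-annotator labels for one task into consensus labels.

    Precedence: any UNABLE vote -> UNABLE; else any disagreement ->
    INCONSISTENT; else CONSISTENT with the unanimous label. The result is
    invariant to annotator order. Posts with fewer than ``n_annotators``
    annotations are an error (they cannot be adjudicated).
    """
    by_post: dict[str, list[str]] = defaultdict(list)
    order: list[str] = []
    for rec in records:
        if rec.task != task:
            continue
        if rec.post_id not in by_post:
            order.append(rec.post_id)
        by_post[rec.post_id].append(rec.label)

    short = [pid for pid in order if len(by_post[pid]) < n_annotators]
    if short:
        raise ValueError(
            f"{len(short)} post(s) have < {n_annotators} annotations for task "
            f"{task}: {short[:10]}"
        )

    out: list[ConsensusLabel] = []
    for pid in order:
        labels = by_post[pid]
        if "UNABLE" in labels:
            out.append(ConsensusLabel(pid, task, "UNABLE"))
        elif len(set(labels)) > 1:
            out.append(ConsensusLabel(pid, task, "INCONSISTENT"))
        else:
            out.append(ConsensusLabel(pid, task, "CONSISTENT", labels[0]))
    return out


def cohens_kappa(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    include_unable: bool = True,
) -> float:
    """Cohen's kappa between two annotators' label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal products. By default UNABLE is kept as a third category (the
    annotation task as performed); ``include_unable=False`` drops pairs
    where either annotator chose UNABLE before computing agreement.
    Perfect agreement with degenerate marginals (p_e = 1) returns 1.0.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    if not labels_a:
        raise ValueError("empty label sequences")
    a, b = list(labels_a), list(labels_b)
    if not include_unable:
        pairs = [(x, y) for x, y in zip(a, b) if "UNABLE" not in (x, y)]
        if not pairs:
            raise ValueError("no pairs left after excluding UNABLE")
        a, b = [p[0] for p in pairs], [p[1] for p in pairs]
    if a == b and len(set(a)) == 1:
        # degenerate: single shared category, p_e = p_o = 1
        return 1.0
    return float(cohen_kappa_score(a, b))


def accounting(consensus: Sequence[ConsensusLabel]) -> FilterReport:
    """Dataset accounting for one task's consensus labels.

    Retained = CONSISTENT posts; class percentages (1 decimal) are over
    the retained set.
    """
    tasks = {c.task for c in consensus}
    if len(tasks) > 1:
        raise ValueError(f"consensus mixes tasks: {sorted(tasks)}")
    status = Counter(c.status for c in consensus)
    retained = [c for c in consensus if c.status == "CONSISTENT"]
    class_counts = Counter(c.label for c in retained)
    n_ret = len(retained)
    class_percent = {
        lab: round(100.0 * cnt / n_ret, 1) for lab, cnt in class_counts.items()
    } if n_ret else {}
    return FilterReport(
        n_input=len(consensus),
        n_inconsistent=status.get("INCONSISTENT", 0),
        n_unable=status.get("UNABLE", 0),
        n_retained=n_ret,
        class_counts=dict(class_counts),
        class_percent=class_percent,
    )
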