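"""Precision evaluation of expansion retrieval via the relatedness graph.

Each retained expansion video gets a degree record (connections to the core
set); sweeping a descending total-degree threshold yields cumulative
precision / recall / F1 rows.  Percent display convention: precision to the
nearest integer, recall and F1 to one decimal, F1 computed from unrounded
precision and recall.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_model import Corpus, RelatednessEdge, VideoRecord, dedupe_edges
from .util import round_half_up

logger = logging.getLogger(__name__)


class NetworkEvalError(Exception):
    pass


def exclusion_filter(
    corpus: Corpus, treat_und_as_non_english: bool = False
) -> tuple[list[VideoRecord], Counter]:
    """Drop excluded coded expansion videos; return retained set + tally.

    A video is excluded if its ``exclusion`` flag is set (duplicate-of-core,
    missing-metadata, pre-flagged non-English) or its language tag is
    non-English.  ``"und"`` is trusted as-is unless
    ``treat_und_as_non_english`` is set.
    """
    retained: list[VideoRecord] = []
    tally: Counter = Counter()
    for v in corpus.expansion_videos:
        if v.exclusion != "none":
            tally[v.exclusion] += 1
            continue
        lang = (v.language or "und").lower()
        non_english = not lang.startswith("en") and (
            lang != "und" or treat_und_as_non_english
        )
        if non_english:
            tally["non_english"] += 1
            continue
        retained.append(v)
    if not retained:
        logger.warning("exclusion_filter: all expansion videos excluded")
    return retained, tally


@dataclass(frozen=True)
class DegreeRecord:
    """Connection counts of one expansion video to the core set."""

    video_id: str
    indegree: int  # edges core -> video
    outdegree: int  # edges video -> core

    def __post_init__(self) -> None:
        if self.indegree < 0 or self.outdegree < 0:
            raise NetworkEvalError("degrees must be nonnegative")

    @property
    def total_degree(self) -> int:
        return self.indegree + self.outdegree


def degree_metrics(
    edges: Iterable[RelatednessEdge], core_ids: set[str], new_ids: set[str]
) -> list[DegreeRecord]:
    """One DegreeRecord per new id, counting distinct core<->new edges only.

    Core and new id sets must be disjoint (dedupe duplicates first).
    """
    overlap = core_ids & new_ids
    if overlap:
        raise NetworkEvalError(
            f"core and new id sets overlap ({len(overlap)} id(s)); run dedupe first"
        )
    indeg: Counter = Counter()
    outdeg: Counter = Counter()
    for e in dedupe_edges(edges):
        if e.source_id in core_ids and e.target_id in new_ids:
            indeg[e.target_id] += 1
        elif e.source_id in new_ids and e.target_id in core_ids:
            outdeg[e.source_id] += 1
    return [
        DegreeRecord(video_id=vid, indegree=indeg[vid], outdegree=outdeg[vid])
        for vid in sorted(new_ids)
    ]


@dataclass(frozen=True)
class CurveRow:
    degree: int
    n_videos: int
    n_relevant: int
    cum_videos: int
    cum_relevant: int
    cum_precision: float  # fraction in [0, 1]
    cum_recall: float
    cum_f1: float

    @property
    def precision_pct(self) -> int:
        return int(round_half_up(100.0 * self.cum_precision))

    @property
    def recall_pct(self) -> float:
        return round_half_up(100.0 * self.cum_recall, 1)

    @property
    def f1_pct(self) -> float:
        return round_half_up(100.0 * self.cum_f1, 1)


@dataclass
class ThresholdCurve:
    """Cumulative precision/recall/F1 rows over descending degree thresholds."""

    rows: list[CurveRow]
    total_relevant: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "total_degree": r.degree,
                    "n_videos": r.n_videos,
                    "n_relevant": r.n_relevant,
                    "cum_videos": r.cum_videos,
                    "cum_relevant": r.cum_relevant,
                    "cum_precision_pct": r.precision_pct,
                    "cum_recall_pct": r.recall_pct,
                    "cum_f1_pct": r.f1_pct,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0.0 else 2.0 * p * r / (p + r)


def threshold_curve(
    records: Sequence[DegreeRecord], relevance: Mapping[str, bool]
) -> ThresholdCurve:
    """Build the cumulative threshold curve from degree records.

    Rows exist only for observed degree values, ordered descending; degree 0
    is included when observed.  Cumulative recall is relative to the total
    relevant count among the records, so the loosest row always reaches
    100% recall.  Invariant to the input ordering of records.
    """
    missing = [r.video_id for r in records if r.video_id not in relevance]
    if missing:
        raise NetworkEvalError(f"records without relevance codes: {missing[:5]}")
    total_relevant = sum(1 for r in records if relevance[r.video_id])
    if total_relevant == 0:
        raise NetworkEvalError("zero relevant videos: recall undefined")
    by_degree: dict[int, list[DegreeRecord]] = {}
    for r in records:
        by_degree.setdefault(r.total_degree, []).append(r)
    rows: list[CurveRow] = []
    cum_v = cum_r = 0
    for deg in sorted(by_degree, reverse=True):
        group = by_degree[deg]
        n_rel = sum(1 for r in group if relevance[r.video_id])
        cum_v += len(group)
        cum_r += n_rel
        p = cum_r / cum_v
        rec = cum_r / total_relevant
        rows.append(
            CurveRow(
                degree=deg,
                n_videos=len(group),
                n_relevant=n_rel,
                cum_videos=cum_v,
                cum_relevant=cum_r,
                cum_precision=p,
                cum_recall=rec,
                cum_f1=_f1(p, rec),
            )
        )
    return ThresholdCurve(rows=rows, total_relevant=total_relevant)


def precision_at(curve: ThresholdCurve, min_degree: int) -> dict:
    """Cumulative statistics at the smallest observed degree >= min_degree."""
    if not curve.rows:
        raise NetworkEvalError("empty curve")
    eligible = [r for r in curve.rows if r.degree >= min_degree]
    if not eligible:
        raise NetworkEvalError(
            f"min_degree {min_degree} above maximum observed degree "
            f"{curve.rows[0].degree}"
        )
    row = min(eligible, key=lambda r: r.degree)
    return {
        "degree": row.degree,
        "n": row.cum_videos,
        "n_relevant": row.cum_relevant,
        "precision": row.cum_precision,
        "recall": row.cum_recall,
        "f1": row.cum_f1,
        "precision_pct": row.precision_pct,
        "recall_pct": row.recall_pct,
        "f1_pct": row.f1_pct,
    }


@dataclass(frozen=True)
class SummaryRow:
    """One batch-report line per focal term: precision/recall at degree >= 1."""

    focal_term: str
    n_coded: int
    n_relevant: int  # new, nonduplicate relevant videos (set A)
    n_degree_ge_1: int  # videos with degree >= 1 (set B)
    n_relevant_degree_ge_1: int  # A intersect B

    @property
    def precision_pct(self) -> int:
        return int(round_half_up(100.0 * self.n_relevant_degree_ge_1 / self.n_degree_ge_1))

    @property
    def recall_pct(self) -> int:
        return int(round_half_up(100.0 * self.n_relevant_degree_ge_1 / self.n_relevant))


def summarize(
    focal_term: str,
    n_coded: int,
    records: Sequence[DegreeRecord],
    relevance: Mapping[str, bool],
) -> SummaryRow:
    """Batch summary from retained degree records and relevance codes."""
    n_relevant = sum(1 for r in records if relevance[r.video_id])
    ge1 = [r for r in records if r.total_degree >= 1]
    if n_relevant == 0 or not ge1:
        raise NetworkEvalError("summary undefined without relevant/connected videos")
    return SummaryRow(
        focal_term=focal_term,
        n_coded=n_coded,
        n_relevant=n_relevant,
        n_degree_ge_1=len(ge1),
        n_relevant_degree_ge_1=sum(1 for r in ge1 if relevance[r.video_id]),
    )


def summary_to_dataframe(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "focal_term": r.focal_term,
                "n_coded": r.n_coded,
                "n_relevant": r.n_relevant,
                "n_degree_ge_1": r.n_degree_ge_1,
                "n_relevant_degree_ge_1": r.n_relevant_degree_ge_1,
                "precision_pct": r.precision_pct,
                "recall_pct": r.recall_pct,
            }
            for r in rows
        ]
    )
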