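"""Recall-improvement bookkeeping for expansion retrieval.

A relevant expansion video whose text does not contain the focal term is a
recall improvement: content a focal-term-only search would miss.  The
mention check is token-level after normalization, so "colonoscopies" does
not match "colonoscopy".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .corpus_model import Corpus, VideoRecord
from .text_normalize import normalize_text
from .util import round_half_up


class EvalError(Exception):
    pass


def mentions_term(video: VideoRecord, focal: str) -> bool:
    """True iff ``focal`` appears as a normalized token of title+description."""
    if not focal:
        raise EvalError("focal term must be nonempty")
    return focal in normalize_text(video.text)


@dataclass(frozen=True)
class RecallRow:
    term: str
    n_coded: int
    n_relevant: int
    n_relevant_mentioning: int
    n_relevant_omitting: int

    def __post_init__(self) -> None:
        if self.n_relevant != self.n_relevant_mentioning + self.n_relevant_omitting:
            raise EvalError(
                f"row {self.term!r}: mentioning + omitting must equal relevant"
            )

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_coded if self.n_coded else 0.0


@dataclass
class RecallReport:
    """Per-expansion-term retrieval statistics plus column totals."""

    rows: list[RecallRow]
    focal_term: str

    @property
    def total(self) -> RecallRow:
        return RecallRow(
            term="total",
            n_coded=sum(r.n_coded for r in self.rows),
            n_relevant=sum(r.n_relevant for r in self.rows),
            n_relevant_mentioning=sum(r.n_relevant_mentioning for r in self.rows),
            n_relevant_omitting=sum(r.n_relevant_omitting for r in self.rows),
        )

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in [*self.rows, self.total]:
            recs.append(
                {
                    "term": r.term,
                    "n_coded": r.n_coded,
                    "n_relevant": r.n_relevant,
                    "pct_relevant": round_half_up(r.pct(r.n_relevant)),
                    "n_relevant_mentioning": r.n_relevant_mentioning,
                    "pct_relevant_mentioning": round_half_up(r.pct(r.n_relevant_mentioning)),
                    "n_relevant_omitting": r.n_relevant_omitting,
                    "pct_relevant_omitting": round_half_up(r.pct(r.n_relevant_omitting)),
                }
            )
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def recall_improvement(corpus: Corpus, focal: str | None = None) -> RecallReport:
    """Per-term and total counts of relevant / mentioning / omitting videos.

    Denominators are all coded-sample videos per term (relevance coded,
    i.e. not ``uncoded``).  Invariant to video ordering within terms.
    """
    focal = focal or corpus.focal_term
    if not focal:
        raise EvalError("no focal term given")
    coded = [v for v in corpus.expansion_videos if v.relevance != "uncoded"]
    if not coded:
        raise EvalError("no coded expansion videos: cannot build recall report")
    terms: list[str] = []
    per_term: dict[str, list[VideoRecord]] = {}
    for v in coded:
        t = v.neighbor_term or ""
        if t not in per_term:
            per_term[t] = []
            terms.append(t)
        per_term[t].append(v)
    rows = []
    for t in terms:
        vids = per_term[t]
        rel = [v for v in vids if v.relevance == "relevant"]
        n_mention = sum(1 for v in rel if mentions_term(v, focal))
        rows.append(
            RecallRow(
                term=t,
                n_coded=len(vids),
                n_relevant=len(rel),
                n_relevant_mentioning=n_mention,
                n_relevant_omitting=len(rel) - n_mention,
            )
        )
    return RecallReport(rows=rows, focal_term=focal)


def dedupe_against_core(corpus: Corpus) -> Corpus:
    """Flag expansion videos whose id also occurs in the core set.

    Returns a new Corpus with ``exclusion="duplicate_of_core"`` set on the
    flagged records; nothing is deleted.
    """
    core_ids = corpus.core_ids
    videos = []
    for v in corpus.videos:
        if not v.is_core and v.video_id in core_ids and v.exclusion == "none":
            videos.append(replace(v, exclusion="duplicate_of_core"))
        else:
            videos.append(v)
    out = Corpus(videos=videos, edges=list(corpus.edges), focal_term=corpus.focal_term)
    truth = getattr(corpus, "ground_truth", None)
    if truth is not None:
        out.ground_truth = truth  # type: ignore[attr-defined]
    return out
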