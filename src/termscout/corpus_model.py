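"""Domain types and file I/O for video corpora, relatedness edges, and run config.

The canonical on-disk dialect is JSON Lines (one video per line, UTF-8);
CSV with quoted text fields is supported as an alternative.  Edge lists are
two-column TSV/CSV of directed ``source_id -> target_id`` pairs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

logger = logging.getLogger(__name__)

CORE_LABEL = "core"
NEIGHBOR_PREFIX = "neighbor:"

RELEVANCE_VALUES = ("relevant", "irrelevant", "uncoded")
EXCLUSION_VALUES = ("none", "non_english", "duplicate_of_core", "missing_metadata")

_VIDEO_FIELDS = (
    "video_id",
    "title",
    "description",
    "published_at",
    "language",
    "set_label",
    "relevance",
    "exclusion",
)


class CorpusError(Exception):
    """Base error for corpus construction problems."""


class ParseError(CorpusError):
    """A record or line could not be parsed."""


class IntegrityError(CorpusError):
    """A corpus invariant (e.g. unique ids within a set) was violated."""


@dataclass
class VideoRecord:
    """One video's metadata, text, set membership and coding status.

    ``set_label`` is either ``"core"`` or ``"neighbor:<term>"`` where the
    term names the expansion query that retrieved the video.
    """

    video_id: str
    title: str = ""
    description: str = ""
    published_at: str | None = None
    language: str = "und"
    set_label: str = CORE_LABEL
    relevance: str = "uncoded"
    exclusion: str = "none"

    def __post_init__(self) -> None:
        if not self.video_id:
            raise IntegrityError("video_id must be nonempty")
        if self.set_label != CORE_LABEL:
            if not self.set_label.startswith(NEIGHBOR_PREFIX) or not self.neighbor_term:
                raise IntegrityError(
                    f"set_label must be 'core' or 'neighbor:<term>', got {self.set_label!r}"
                )
        if self.relevance not in RELEVANCE_VALUES:
            raise IntegrityError(f"invalid relevance {self.relevance!r}")
        if self.exclusion not in EXCLUSION_VALUES:
            raise IntegrityError(f"invalid exclusion {self.exclusion!r}")

    @property
    def is_core(self) -> bool:
        return self.set_label == CORE_LABEL

    @property
    def neighbor_term(self) -> str | None:
        """Expansion term for neighbor-set videos, None for the core set."""
        if self.set_label.startswith(NEIGHBOR_PREFIX):
            return self.set_label[len(NEIGHBOR_PREFIX):]
        return None

    @property
    def text(self) -> str:
        """Title and description concatenated, title first."""
        return f"{self.title} {self.description}".strip()

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in _VIDEO_FIELDS}


@dataclass(frozen=True, order=True)
class RelatednessEdge:
    """A directed platform-asserted "related to" link between two video ids."""

    source_id: str
    target_id: str

    def __post_init__(self) -> None:
        if not self.source_id or not self.target_id:
            raise IntegrityError("edge endpoints must be nonempty ids")


@dataclass
class Corpus:
    """A video collection plus its relatedness edges and the focal term.

    A ``video_id`` may legitimately appear both in the core set and in one
    expansion set: that is exactly a duplicate-of-core retrieval, later
    flagged by :func:`termscout.expansion_eval.dedupe_against_core`.  Within
    a single set, ids must be unique.
    """

    videos: list[VideoRecord] = field(default_factory=list)
    edges: list[RelatednessEdge] = field(default_factory=list)
    focal_term: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for v in self.videos:
            key = (v.set_label, v.video_id)
            if key in seen:
                raise IntegrityError(
                    f"duplicate video_id {v.video_id!r} within set {v.set_label!r}"
                )
            seen.add(key)

    # -- convenience views -------------------------------------------------

    @property
    def core_videos(self) -> list[VideoRecord]:
        return [v for v in self.videos if v.is_core]

    @property
    def expansion_videos(self) -> list[VideoRecord]:
        return [v for v in self.videos if not v.is_core]

    @property
    def core_ids(self) -> set[str]:
        return {v.video_id for v in self.core_videos}

    @property
    def expansion_ids(self) -> set[str]:
        return {v.video_id for v in self.expansion_videos}

    def neighbor_terms(self) -> list[str]:
        """Expansion terms in first-appearance order."""
        terms: list[str] = []
        for v in self.videos:
            t = v.neighbor_term
            if t is not None and t not in terms:
                terms.append(t)
        return terms

    def external_edge_ids(self) -> set[str]:
        """Edge endpoints that do not resolve to any known video."""
        known = {v.video_id for v in self.videos}
        out: set[str] = set()
        for e in self.edges:
            if e.source_id not in known:
                out.add(e.source_id)
            if e.target_id not in known:
                out.add(e.target_id)
        return out


@dataclass
class RunConfig:
    """Run parameters for the full pipeline."""

    focal_term: str = "colonoscopy"
    k_neighbors: int = 6
    dim: int = 50
    window: int = 5
    epochs: int = 5
    min_count: int = 5
    algorithm: str = "cbow"  # or "skipgram"
    seed: int = 0
    stopword_list: str = "english"
    min_degree: int = 1
    treat_und_as_non_english: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise CorpusError("k_neighbors must be >= 1")
        if self.dim < 2:
            raise CorpusError("dim must be >= 2")
        if self.min_count < 1:
            raise CorpusError("min_count must be >= 1")
        if self.algorithm not in ("cbow", "skipgram"):
            raise CorpusError(f"unknown algorithm {self.algorithm!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Corpus I/O


def _record_from_mapping(data: dict, where: str) -> VideoRecord:
    if "video_id" not in data or not data["video_id"]:
        raise ParseError(f"{where}: record missing video_id")
    kwargs = {}
    for f in _VIDEO_FIELDS:
        if f in data and data[f] is not None and data[f] != "":
            kwargs[f] = data[f]
    kwargs.setdefault("published_at", None)
    try:
        return VideoRecord(**kwargs)
    except IntegrityError as exc:
        raise ParseError(f"{where}: {exc}") from exc


def read_corpus(path: str | Path, format: str = "jsonl", focal_term: str = "") -> Corpus:
    """Read a video corpus from a JSONL or CSV file.

    Raises :class:`ParseError` naming the offending line on malformed
    records, :class:`IntegrityError` on duplicate ids within a set.
    """
    path = Path(path)
    videos: list[VideoRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    data = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
                if not isinstance(data, dict):
                    raise ParseError(f"{path}:{lineno}: record is not an object")
                videos.append(_record_from_mapping(data, f"{path}:{lineno}"))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                videos.append(_record_from_mapping(row, f"{path}:{lineno}"))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return Corpus(videos=videos, focal_term=focal_term)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for v in corpus.videos:
                fh.write(json.dumps(v.to_dict(), ensure_ascii=False, sort_keys=True))
                fh.write("\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_VIDEO_FIELDS))
            writer.writeheader()
            for v in corpus.videos:
                writer.writerow(v.to_dict())
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Edge I/O


def read_edges(path: str | Path) -> list[RelatednessEdge]:
    """Read a two-column directed edge list (TSV or CSV, sniffed per line).

    Self-loops are dropped (count logged); duplicate ordered pairs are
    deduplicated.  Order of first appearance is preserved.
    """
    path = Path(path)
    edges: list[RelatednessEdge] = []
    seen: set[tuple[str, str]] = set()
    n_loops = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            parts = [p.strip() for p in parts]
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: expected two-column id pair")
            src, dst = parts
            if src == dst:
                n_loops += 1
                continue
            if (src, dst) in seen:
                continue
            seen.add((src, dst))
            edges.append(RelatednessEdge(src, dst))
    if n_loops:
        logger.info("read_edges: dropped %d self-loop(s) from %s", n_loops, path)
    return edges


def write_edges(edges: Iterable[RelatednessEdge], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.source_id}\t{e.target_id}\n")


def dedupe_edges(edges: Iterable[RelatednessEdge]) -> list[RelatednessEdge]:
    """Distinct directed non-loop edges, first-appearance order."""
    seen: set[tuple[str, str]] = set()
    out: list[RelatednessEdge] = []
    for e in edges:
        key = (e.source_id, e.target_id)
        if e.source_id == e.target_id or key in seen:
            continue
        seen.add(key)
        out.append(e)
    return out
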