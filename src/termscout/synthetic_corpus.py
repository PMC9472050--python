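"""Seeded generator of platform-like video corpora for offline testing.

Text is a mixture of unigram topic distributions: a focal topic whose
vocabulary includes the focal term and planted brand-like neighbor tokens,
plus disjoint background topics.  Relevant expansion videos draw from the
focal topic and connect to core videos with probability ``p_edge_rel`` per
core video; irrelevant ones use ``p_edge_irr``.  Non-English videos use a
disjoint vocabulary and never receive forced edges.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_model import Corpus, RelatednessEdge, VideoRecord


class GeneratorError(Exception):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_core: int = 50
    n_expansion_per_term: int = 25
    focal_term: str = "colonoscopy"
    planted_neighbor_terms: tuple[str, ...] = ("suprep", "plenvu", "miralax")
    focal_topic_words: tuple[str, ...] = (
        "prep", "bowel", "clean", "kit", "doctor", "procedure", "screening",
        "clinic", "drink", "fasting", "gallon", "scope", "polyp", "colon",
    )
    background_vocab_size: int = 60
    n_background_topics: int = 3
    title_len: tuple[int, int] = (4, 8)
    description_len: tuple[int, int] = (15, 40)
    p_focal_cooccur: float = 0.6
    p_relevant: float = 0.4
    p_mention: float = 0.55
    p_edge_rel: float = 0.2
    p_edge_irr: float = 0.01
    p_non_english: float = 0.0
    p_duplicate: float = 0.0
    p_missing_metadata: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_focal_cooccur", "p_relevant", "p_mention", "p_edge_rel",
            "p_edge_irr", "p_non_english", "p_duplicate", "p_missing_metadata",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1], got {p}")
        if self.n_core < 1 or self.n_expansion_per_term < 0:
            raise GeneratorError("counts must be positive")
        for lo, hi in (self.title_len, self.description_len):
            if lo < 1 or hi < lo:
                raise GeneratorError("length ranges must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """Planted parameters and realized counts for a generated corpus."""

    config: GeneratorConfig
    n_videos: int
    n_core: int
    n_relevant: int
    n_irrelevant: int
    n_mentioning_relevant: int
    n_duplicates: int
    n_non_english: int
    n_missing_metadata: int
    n_retained: int  # expansion videos surviving the exclusion rules
    relevance_by_id: dict[str, bool]


def _draw_tokens(rng: np.random.Generator, vocab: Sequence[str], probs: np.ndarray, n: int) -> list[str]:
    idx = rng.choice(len(vocab), size=n, p=probs)
    return [vocab[i] for i in idx]


def _topic_probs(rng: np.random.Generator, size: int) -> np.ndarray:
    w = rng.dirichlet(np.full(size, 0.8))
    return w


def generate(config: GeneratorConfig) -> Corpus:
    """Generate a corpus with ground truth attached as ``corpus.ground_truth``."""
    rng = np.random.default_rng(config.seed)
    focal = config.focal_term
    planted = list(config.planted_neighbor_terms)

    focal_vocab = [focal, *planted, *config.focal_topic_words]
    bg_vocabs = []
    for t in range(config.n_background_topics):
        bg_vocabs.append(
            [f"bg{t}w{j:03d}" for j in range(config.background_vocab_size)]
        )
    foreign_vocab = [f"xx{j:03d}" for j in range(30)]

    # fixed per-corpus topic distributions
    focal_probs = _topic_probs(rng, len(focal_vocab))
    # keep focal term and planted brands prominent in the focal topic
    focal_probs[0] = max(focal_probs[0], 0.15)
    for i in range(1, 1 + len(planted)):
        focal_probs[i] = max(focal_probs[i], 0.10)
    focal_probs /= focal_probs.sum()
    bg_probs = [_topic_probs(rng, len(v)) for v in bg_vocabs]
    foreign_probs = _topic_probs(rng, len(foreign_vocab))

    def focal_doc(n_title: int, n_desc: int, force_focal: bool) -> tuple[str, str]:
        title = _draw_tokens(rng, focal_vocab, focal_probs, n_title)
        desc = _draw_tokens(rng, focal_vocab, focal_probs, n_desc)
        if rng.random() < config.p_focal_cooccur and planted:
            desc[int(rng.integers(len(desc)))] = planted[int(rng.integers(len(planted)))]
        if force_focal and focal not in title and focal not in desc:
            title[int(rng.integers(len(title)))] = focal
        return " ".join(title), " ".join(desc)

    def background_doc(n_title: int, n_desc: int) -> tuple[str, str]:
        t = int(rng.integers(config.n_background_topics))
        title = _draw_tokens(rng, bg_vocabs[t], bg_probs[t], n_title)
        desc = _draw_tokens(rng, bg_vocabs[t], bg_probs[t], n_desc)
        return " ".join(title), " ".join(desc)

    def lengths() -> tuple[int, int]:
        nt = int(rng.integers(config.title_len[0], config.title_len[1] + 1))
        nd = int(rng.integers(config.description_len[0], config.description_len[1] + 1))
        return nt, nd

    videos: list[VideoRecord] = []
    core_ids: list[str] = []
    for i in range(config.n_core):
        vid = f"core{i:04d}"
        nt, nd = lengths()
        title, desc = focal_doc(nt, nd, force_focal=True)
        videos.append(
            VideoRecord(
                video_id=vid, title=title, description=desc,
                language="en", set_label="core", relevance="uncoded",
            )
        )
        core_ids.append(vid)

    truth_rel: dict[str, bool] = {}
    n_rel = n_irr = n_mention = 0
    n_dup = n_foreign = n_missing = n_retained = 0
    edges: list[RelatednessEdge] = []
    expansion: list[VideoRecord] = []

    serial = 0
    for term in planted:
        for _j in range(config.n_expansion_per_term):
            serial += 1
            vid = f"new{serial:05d}"
            set_label = f"neighbor:{term}"
            nt, nd = lengths()

            if rng.random() < config.p_missing_metadata:
                n_missing += 1
                expansion.append(
                    VideoRecord(
                        video_id=vid, title="", description="", language="und",
                        set_label=set_label, relevance="irrelevant",
                        exclusion="missing_metadata",
                    )
                )
                truth_rel[vid] = False
                continue

            if rng.random() < config.p_non_english:
                n_foreign += 1
                title = " ".join(_draw_tokens(rng, foreign_vocab, foreign_probs, nt))
                desc = " ".join(_draw_tokens(rng, foreign_vocab, foreign_probs, nd))
                expansion.append(
                    VideoRecord(
                        video_id=vid, title=title, description=desc, language="es",
                        set_label=set_label, relevance="irrelevant",
                    )
                )
                truth_rel[vid] = False
                continue

            duplicate = rng.random() < config.p_duplicate and core_ids
            relevant = rng.random() < config.p_relevant
            if relevant:
                title, desc = focal_doc(nt, nd, force_focal=False)
                mentions = rng.random() < config.p_mention
                toks = (title + " " + desc).split()
                if mentions and focal not in toks:
                    toks[int(rng.integers(len(toks)))] = focal
                elif not mentions:
                    toks = [t for t in toks if t != focal] or ["prep"]
                title = " ".join(toks[:nt])
                desc = " ".join(toks[nt:]) or "prep"
                n_rel += 1
                n_mention += int(mentions)
            else:
                title, desc = background_doc(nt, nd)
                n_irr += 1

            if duplicate:
                vid = core_ids[int(rng.integers(len(core_ids)))]
                # one duplicate copy per core id at most (set-level uniqueness)
                if any(v.video_id == vid and not v.is_core for v in expansion):
                    vid = f"new{serial:05d}"
                    duplicate = False
            if duplicate:
                n_dup += 1
            else:
                n_retained += 1
            expansion.append(
                VideoRecord(
                    video_id=vid, title=title, description=desc, language="en",
                    set_label=set_label,
                    relevance="relevant" if relevant else "irrelevant",
                )
            )
            truth_rel[vid] = relevant

            p_edge = config.p_edge_rel if relevant else config.p_edge_irr
            hits = np.nonzero(rng.random(len(core_ids)) < p_edge)[0]
            for h in hits:
                if rng.random() < 0.5:
                    edges.append(RelatednessEdge(core_ids[int(h)], vid))
                else:
                    edges.append(RelatednessEdge(vid, core_ids[int(h)]))

    videos.extend(expansion)
    corpus = Corpus(videos=videos, edges=edges, focal_term=focal)
    corpus.ground_truth = GroundTruth(  # type: ignore[attr-defined]
        config=config,
        n_videos=len(videos),
        n_core=config.n_core,
        n_relevant=n_rel,
        n_irrelevant=n_irr,
        n_mentioning_relevant=n_mention,
        n_duplicates=n_dup,
        n_non_english=n_foreign,
        n_missing_metadata=n_missing,
        n_retained=n_retained,
        relevance_by_id=truth_rel,
    )
    return corpus


def ground_truth_report(corpus: Corpus) -> GroundTruth:
    """Planted-parameter summary; errors on a non-generated corpus."""
    truth = getattr(corpus, "ground_truth", None)
    if truth is None:
        raise GeneratorError("corpus was not produced by generate(); no ground truth")
    return truth
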