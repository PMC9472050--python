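"""Text preprocessing: lowercase, ASCII transliteration, tokenization,
stopword removal.

Pipeline order is fixed: lowercase -> ASCII fold -> split on any
non-alphanumeric run -> drop stopwords.  Hashtag-style portmanteaus
("breastcancerawareness") survive as single tokens; numerals are kept.
No stemming or lemmatization is applied.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_model import Corpus

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
TOKEN_PATTERN = re.compile(r"^[a-z0-9]+$")


@lru_cache(maxsize=4)
def default_stopwords(name: str = "english") -> frozenset[str]:
    """Packaged stopword list (one token per line)."""
    if name != "english":
        raise ValueError(f"unknown packaged stopword list {name!r}")
    text = resources.files("termscout.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(tok for tok in text.split() if tok)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a one-token-per-line stopword file."""
    return frozenset(
        tok.strip().lower() for tok in Path(path).read_text("utf-8").splitlines() if tok.strip()
    )


def _ascii_fold(text: str) -> str:
    # transliterate where a compatibility decomposition exists, else drop
    return unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")


def normalize_text(raw: str, stopwords: frozenset[str] | set[str] | None = None) -> list[str]:
    """Normalize a raw string to an ordered list of lowercase ASCII tokens.

    Total function: any Unicode input (including empty) is accepted; emoji,
    punctuation and symbol characters are stripped; stopwords removed.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    folded = _ascii_fold(raw.lower())
    return [tok for tok in _TOKEN_SPLIT.split(folded) if tok and tok not in stopwords]


@dataclass
class TokenDoc:
    """A normalized token sequence for one video."""

    doc_id: str
    tokens: list[str]
    source_fields: tuple[str, ...] = ("title", "description")


def build_token_docs(
    corpus: Corpus, stopwords: frozenset[str] | set[str] | None = None
) -> list[TokenDoc]:
    """One TokenDoc per video (title then description), in input order.

    All-stopword videos yield an empty-token doc rather than being dropped,
    so document counts stay aligned with the corpus.
    """
    if not corpus.videos:
        raise ValueError("corpus is empty")
    if stopwords is None:
        stopwords = default_stopwords()
    docs = []
    for v in corpus.videos:
        fields = tuple(f for f in ("title", "description") if getattr(v, f))
        docs.append(TokenDoc(v.video_id, normalize_text(v.text, stopwords), fields))
    return docs
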