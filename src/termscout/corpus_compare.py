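"""Text-statistics comparison of video sets.

Builds document-feature matrices, grouped Euclidean distance matrices,
chi-square keyness contrasts (Yates-corrected), and complete-linkage
agglomerative dendrograms.  Distances between sets default to the Euclidean
distance between per-set summed count vectors; an average-of-document-pairs
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .text_normalize import TokenDoc


class CompareError(Exception):
    pass


@dataclass
class DocFeatureMatrix:
    """Rows of doc/group ids, columns of vocabulary terms, integer counts."""

    row_ids: list[str]
    terms: list[str]
    counts: np.ndarray  # (n_rows, n_terms) nonnegative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_ids), len(self.terms)):
            raise CompareError("counts shape inconsistent with row/term labels")
        if (self.counts < 0).any():
            raise CompareError("negative cell in document-feature matrix")

    def row(self, row_id: str) -> np.ndarray:
        return self.counts[self.row_ids.index(row_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_ids, columns=self.terms)


def build_dfm(
    docs: Sequence[TokenDoc], group_by: Mapping[str, str] | None = None
) -> DocFeatureMatrix:
    """Token counts per document, or summed per group when ``group_by`` maps
    doc_id -> group label.  Column vocabulary is sorted lexicographically.
    """
    if not docs:
        raise CompareError("no documents")
    vocab = sorted({tok for d in docs for tok in d.tokens})
    col = {t: j for j, t in enumerate(vocab)}
    if group_by is None:
        row_ids = [d.doc_id for d in docs]
        counts = np.zeros((len(docs), len(vocab)), dtype=np.int64)
        for i, d in enumerate(docs):
            for tok in d.tokens:
                counts[i, col[tok]] += 1
    else:
        row_ids = []
        index: dict[str, int] = {}
        for d in docs:
            g = group_by[d.doc_id]
            if g not in index:
                index[g] = len(row_ids)
                row_ids.append(g)
        counts = np.zeros((len(row_ids), len(vocab)), dtype=np.int64)
        for d in docs:
            i = index[group_by[d.doc_id]]
            for tok in d.tokens:
                counts[i, col[tok]] += 1
    return DocFeatureMatrix(row_ids=row_ids, terms=vocab, counts=counts)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise CompareError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise CompareError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise CompareError("distance matrix diagonal not zero")
        if (self.matrix < -1e-12).any():
            raise CompareError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def set_distance(dfm: DocFeatureMatrix, mode: str = "grouped") -> DistanceMatrix:
    """Euclidean distances between group feature vectors.

    ``mode="grouped"`` (default) takes the distance between summed count
    vectors — one number per set pair.  A DFM already grouped by set label
    is expected (one row per set).
    """
    if len(dfm.row_ids) < 2:
        raise CompareError("need >= 2 groups for a distance matrix")
    if mode != "grouped":
        raise CompareError(f"unknown mode {mode!r}")
    mat = cdist(dfm.counts.astype(np.float64), dfm.counts.astype(np.float64), "euclidean")
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(labels=list(dfm.row_ids), matrix=mat)


def average_pairwise_distance(
    doc_dfm: DocFeatureMatrix, group_by: Mapping[str, str]
) -> DistanceMatrix:
    """Mean Euclidean distance over all cross-set document pairs.

    Alternative reading of a per-set "average" distance; diagonal is 0.
    """
    labels: list[str] = []
    members: dict[str, list[int]] = {}
    for i, doc_id in enumerate(doc_dfm.row_ids):
        g = group_by[doc_id]
        if g not in members:
            members[g] = []
            labels.append(g)
        members[g].append(i)
    if len(labels) < 2:
        raise CompareError("need >= 2 groups for a distance matrix")
    X = doc_dfm.counts.astype(np.float64)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(X[members[labels[i]]], X[members[labels[j]]], "euclidean")
            out[i, j] = out[j, i] = float(d.mean())
    return DistanceMatrix(labels=labels, matrix=out)


@dataclass(frozen=True)
class KeynessRow:
    """Per-term 2x2 chi-square contrast between a target and reference set.

    Counts: a = term in target, b = other tokens in target,
    c = term in reference, d = other tokens in reference.
    """

    term: str
    chi2: float
    signed_direction: str  # "target" | "reference"
    a: int
    b: int
    c: int
    d: int


def yates_chi2(a: int, b: int, c: int, d: int) -> float:
    """Yates-continuity-corrected chi-square for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 * n
    return num / denom


def keyness(dfm: DocFeatureMatrix, target: str, reference: str) -> list[KeynessRow]:
    """Per-term keyness of ``target`` against ``reference`` (grouped DFM rows).

    Rows are sorted by chi2 descending (ties by term); ``signed_direction``
    marks which set over-represents the term.
    """
    for label in (target, reference):
        if label not in dfm.row_ids:
            raise CompareError(f"group {label!r} not in DFM rows")
    trow = dfm.row(target).astype(np.int64)
    rrow = dfm.row(reference).astype(np.int64)
    t_total, r_total = int(trow.sum()), int(rrow.sum())
    if t_total == 0 or r_total == 0:
        raise CompareError("keyness undefined for a zero-total group")
    rows = []
    for j, term in enumerate(dfm.terms):
        a, c = int(trow[j]), int(rrow[j])
        if a == 0 and c == 0:
            continue
        b, d = t_total - a, r_total - c
        chi2 = yates_chi2(a, b, c, d)
        direction = "target" if a / t_total >= c / r_total else "reference"
        rows.append(KeynessRow(term, chi2, direction, a, b, c, d))
    rows.sort(key=lambda r: (-r.chi2, r.term))
    return rows


def keyness_to_dataframe(rows: Sequence[KeynessRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "chi2": r.chi2,
                "signed_chi2": r.chi2 if r.signed_direction == "target" else -r.chi2,
                "direction": r.signed_direction,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
            }
            for r in rows
        ]
    )


@dataclass
class Dendrogram:
    """Ordered complete-linkage merge list: (cluster_i, cluster_j, height).

    Cluster labels are the lexicographically smallest member leaf; n leaves
    yield n-1 merges with nondecreasing heights.
    """

    leaves: list[str]
    merges: list[tuple[str, str, float]]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        sub: dict[str, str] = {leaf: leaf for leaf in self.leaves}
        rep: dict[str, str] = {leaf: leaf for leaf in self.leaves}
        prev: dict[str, float] = {leaf: 0.0 for leaf in self.leaves}
        root = self.leaves[0]
        for a, b, h in self.merges:
            na = f"{sub[a]}:{(h - prev[a]) / 2:.6g}"
            nb = f"{sub[b]}:{(h - prev[b]) / 2:.6g}"
            new = min(a, b)
            sub[new] = f"({na},{nb})"
            prev[new] = h
            root = new
        return sub[root] + ";"


def hcluster_complete(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with the complete (maximum) linkage rule.

    Deterministic: among tied minimum-distance cluster pairs, the pair with
    lexicographically smallest (label_i, label_j) merges first.
    """
    n = len(dist.labels)
    if n < 2:
        raise CompareError("need >= 2 items to cluster")
    # active clusters: representative label -> set of leaf indices
    clusters: dict[str, set[int]] = {lab: {i} for i, lab in enumerate(dist.labels)}
    D = dist.matrix
    merges: list[tuple[str, str, float]] = []
    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        labs = sorted(clusters)
        for i, la in enumerate(labs):
            for lb in labs[i + 1 :]:
                h = max(D[x, y] for x in clusters[la] for y in clusters[lb])
                if best is None or h < best[0] - 1e-15:
                    best = (h, la, lb)
        assert best is not None
        h, la, lb = best
        merges.append((la, lb, h))
        merged = clusters.pop(la) | clusters.pop(lb)
        clusters[min(la, lb)] = merged
    return Dendrogram(leaves=list(dist.labels), merges=merges)
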