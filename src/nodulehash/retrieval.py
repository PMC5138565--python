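"""Cluster-pruned Hamming-space retrieval with distance tie-breaking.

A query is answered in three stages: (1) rank the cluster centers by squared
feature-space distance to the query and keep the ``m_candidates`` nearest
clusters; (2) encode the query with the trained hash functions; (3) rank the
candidate-cluster records by code inner product, descending.  Records with
equal inner product are ordered by the distance of their *cluster* to the
query (closer cluster first); remaining ties fall back to ascending record
id so the ordering is total and exactly reproducible.

Retrieval drives a benign/malignant majority vote over the returned
neighbours (ties vote malignant), and the evaluation report measures mean
precision@p plus overall and per-class classification accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterModel
from .features import FeatureConfig, Standardizer, assemble_feature_vector
from .hashing import HashModel, code_inner_products, encode
from .synthetic import NoduleImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HashDatabase:
    """Packed codes, cluster memberships and labels of the indexed images."""

    ids: np.ndarray  # (n,) unique string ids
    codes: np.ndarray  # (n, ceil(r/8)) packed uint8
    labels: np.ndarray  # (n,) 0/1
    cluster_ids: np.ndarray  # (n,) in {0..k-1}
    clusters: ClusterModel
    hash_model: HashModel
    standardizer: Standardizer
    feature_config: FeatureConfig

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise ValueError("record ids must be unique")
        if not ((self.cluster_ids >= 0) & (self.cluster_ids < self.clusters.k)).all():
            raise ValueError("cluster ids out of range")
        nbytes = (self.hash_model.r + 7) // 8
        if self.codes.shape != (n, nbytes):
            raise ValueError("packed code width does not match the model's code length")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class QueryResult:
    """Top-p retrieved records and the majority-vote class prediction."""

    ids: np.ndarray
    sims: np.ndarray  # code inner products, descending
    cluster_distances: np.ndarray  # squared distance of each record's cluster
    labels: np.ndarray
    predicted_label: int

    def __len__(self) -> int:
        return len(self.ids)


def candidate_clusters(
    q: np.ndarray, centers: np.ndarray, m_candidates: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the m nearest cluster centers (squared Euclidean), ascending.

    Returns ``(order, d)`` where ``d[i]`` is the squared distance to center i
    and ``order`` lists the selected clusters nearest-first, ties broken by
    lower cluster index.
    """
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0]
    if not 1 <= m_candidates <= k:
        raise ValueError(f"m_candidates={m_candidates} must be in [1, k={k}]")
    d = ((centers - np.asarray(q, dtype=float)[None, :]) ** 2).sum(axis=1)
    order = np.argsort(d, kind="stable")[:m_candidates]
    return order, d


def code_inner_product(code_q: np.ndarray, code_x: np.ndarray, r: int) -> int:
    """Inner product of two packed codes: r - 2 * popcount(xor), in [-r, r]."""
    return int(code_inner_products(code_q, np.atleast_2d(code_x), r)[0])


def _rank(
    sims: np.ndarray, dists: np.ndarray, ids: np.ndarray, p: int
) -> np.ndarray:
    """Total order: sim descending, then cluster distance ascending, then id."""
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    order = np.lexsort((id_rank, dists, -sims))
    return order[:p]


def retrieve_from_features(
    q_std: np.ndarray, db: HashDatabase, m_candidates: int | None = None, p: int = 5
) -> QueryResult:
    """Pruned retrieval for an already-standardized query feature vector."""
    if len(db) == 0:
        raise ValueError("database is empty")
    if p < 1:
        raise ValueError("p must be >= 1")
    if m_candidates is None:
        m_candidates = db.clusters.k
    cand, d = candidate_clusters(q_std, db.clusters.centers, m_candidates)
    pool = np.flatnonzero(np.isin(db.cluster_ids, cand))
    if p > pool.size:
        logger.warning("requested p=%d exceeds candidate pool of %d records", p, pool.size)
    code_q = encode(q_std[None, :], db.hash_model)[0]
    sims = code_inner_products(code_q, db.codes[pool], db.hash_model.r)
    dists = d[db.cluster_ids[pool]]
    top = _rank(sims, dists, db.ids[pool], min(p, pool.size))
    sel = pool[top]
    labels = db.labels[sel]
    return QueryResult(
        ids=db.ids[sel],
        sims=sims[top],
        cluster_distances=dists[top],
        labels=labels,
        predicted_label=_majority(labels),
    )


def prune_retrieve(
    query: NoduleImage, db: HashDatabase, m_candidates: int | None = None, p: int = 5
) -> QueryResult:
    """Full query path: extract features, standardize with the *training*
    standardizer, encode, prune, rank."""
    fv = assemble_feature_vector(query, db.feature_config)
    q_std = db.standardizer.apply(fv.values)
    return retrieve_from_features(q_std, db, m_candidates, p)


def _majority(labels: np.ndarray) -> int:
    benign = int((labels == 0).sum())
    malignant = int((labels == 1).sum())
    return 0 if benign > malignant else 1  # ties are malignant


def classify_majority(result: QueryResult) -> int:
    """Benign (0) iff benign labels strictly outnumber malignant among the
    returned neighbours; otherwise malignant (1)."""
    if len(result) == 0:
        raise ValueError("empty retrieval result")
    return _majority(result.labels)


def precision_at_p(result: QueryResult, query_label: int) -> float:
    """Fraction of returned records whose label matches the query's."""
    if len(result) == 0:
        raise ValueError("empty retrieval result")
    return float((result.labels == query_label).mean())


@dataclass(frozen=True)
class EvaluationReport:
    """Retrieval precision and majority-vote accuracy over a test set."""

    mean_precision_at_p: float
    accuracy_overall: float
    accuracy_benign: float | None  # None when the stratum is empty
    accuracy_malignant: float | None
    n_queries: int
    p: int
    m_candidates: int

    def to_dict(self) -> dict:
        return {
            "mean_precision_at_p": self.mean_precision_at_p,
            "accuracy_overall": self.accuracy_overall,
            "accuracy_benign": self.accuracy_benign,
            "accuracy_malignant": self.accuracy_malignant,
            "n_queries": self.n_queries,
            "p": self.p,
            "m_candidates": self.m_candidates,
        }


def evaluate_features(
    Q_std: np.ndarray,
    query_labels: np.ndarray,
    db: HashDatabase,
    m_candidates: int | None = None,
    p: int = 5,
) -> EvaluationReport:
    """Evaluate retrieval over standardized query vectors with known labels."""
    query_labels = np.asarray(query_labels)
    if Q_std.shape[0] == 0:
        raise ValueError("test set is empty")
    m = m_candidates if m_candidates is not None else db.clusters.k
    precisions, predictions = [], []
    for q, lab in zip(Q_std, query_labels):
        res = retrieve_from_features(q, db, m, p)
        precisions.append(precision_at_p(res, int(lab)))
        predictions.append(res.predicted_label)
    predictions = np.asarray(predictions)
    correct = predictions == query_labels

    def stratum(lab: int) -> float | None:
        sel = query_labels == lab
        return float(correct[sel].mean()) if sel.any() else None

    return EvaluationReport(
        mean_precision_at_p=float(np.mean(precisions)),
        accuracy_overall=float(correct.mean()),
        accuracy_benign=stratum(0),
        accuracy_malignant=stratum(1),
        n_queries=int(Q_std.shape[0]),
        p=p,
        m_candidates=m,
    )


def evaluate(
    db: HashDatabase,
    test_images: list[NoduleImage],
    m_candidates: int | None = None,
    p: int = 5,
) -> EvaluationReport:
    """Per-query precision@p and majority-vote accuracy over test images."""
    if not test_images:
        raise ValueError("test set is empty")
    Q = np.array(
        [assemble_feature_vector(img, db.feature_config).values for img in test_images]
    )
    Q_std = db.standardizer.apply(Q)
    labels = np.array([img.label for img in test_images])
    overlap = np.isin([img.id for img in test_images], db.ids)
    if overlap.any():
        logger.info("%d test ids also present in the database", int(overlap.sum()))
    return evaluate_features(Q_std, labels, db, m_candidates, p)
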