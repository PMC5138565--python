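"""Model/results interface tying feature standardization, spectral
partitioning, supervised hashing and the pruned-search index together.

`NoduleRetrieval` is constructed from a feature matrix with benign/malignant
labels (or directly from images / a DataFrame); `fit()` standardizes the
features, partitions the database by spectral clustering, trains the KSH
hash functions and encodes every record, returning a `NoduleRetrievalResults`
that answers queries, evaluates test sets, reports fit diagnostics and
persists to a model directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clustering, hashing, retrieval
from .features import (
    FeatureConfig,
    Standardizer,
    extract_feature_matrix,
    feature_names,
    fit_standardizer,
)
from .synthetic import NoduleImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetrievalConfig:
    """Build-time knobs of the retrieval index.

    Defaults follow the method's operating point: 48-bit codes, 35 clusters,
    8 candidate clusters, top-5 neighbours.  ``n_clusters``, ``m_anchor`` and
    ``l_label_samples`` are clipped to the training-set size at fit time for
    small databases.
    """

    bits: int = 48
    n_clusters: int = 35
    m_candidates: int = 8
    p: int = 5
    m_anchor: int = 300
    l_label_samples: int = 1000
    sigma: float | None = None  # kernel bandwidth; None = median heuristic
    delta: float | None = None  # similarity bandwidth; None = median heuristic
    features: FeatureConfig = field(default_factory=FeatureConfig)


class NoduleRetrieval:
    """Hashing-and-pruning retrieval model over labelled lesion features."""

    def __init__(
        self,
        X: np.ndarray,
        labels: np.ndarray,
        ids: np.ndarray | None = None,
        config: RetrievalConfig | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels).astype(int)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X must be (n, d) with one label per row")
        if ids is None:
            ids = np.array([f"img-{i:05d}" for i in range(self.X.shape[0])])
        self.ids = np.asarray(ids).astype(str)
        self.config = config or RetrievalConfig()

    @classmethod
    def from_images(
        cls, images: list[NoduleImage], config: RetrievalConfig | None = None
    ) -> "NoduleRetrieval":
        config = config or RetrievalConfig()
        X = extract_feature_matrix(images, config.features)
        labels = np.array([img.label for img in images])
        ids = np.array([img.id for img in images])
        return cls(X, labels, ids=ids, config=config)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: RetrievalConfig | None = None
    ) -> "NoduleRetrieval":
        """Build from a table with columns id, label, f1..f104."""
        cols = feature_names()
        missing = [c for c in cols + ["label"] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing[:5]}...")
        ids = df["id"].to_numpy() if "id" in df.columns else None
        return cls(df[cols].to_numpy(float), df["label"].to_numpy(), ids=ids, config=config)

    def fit(self, seed: int = 0) -> "NoduleRetrievalResults":
        """Standardize, cluster, train the hash functions, encode the database."""
        cfg = self.config
        n = self.X.shape[0]
        standardizer = fit_standardizer(self.X)
        Z = standardizer.apply(self.X)

        k = min(cfg.n_clusters, n)
        if k < cfg.n_clusters:
            logger.info("clipping n_clusters from %d to n=%d", cfg.n_clusters, n)
        clusters = clustering.spectral_cluster(Z, k=k, delta=cfg.delta, seed=seed)

        l = min(cfg.l_label_samples, n)
        m_anchor = min(cfg.m_anchor, l - 1)
        if m_anchor < 1:
            raise ValueError("training set too small to select kernel anchors")
        hash_model, diagnostics = hashing.train_ksh(
            Z,
            self.labels,
            r=cfg.bits,
            m_anchor=m_anchor,
            l=l,
            sigma=cfg.sigma,
            seed=seed,
        )
        codes = hashing.encode(Z, hash_model)
        db = retrieval.HashDatabase(
            ids=self.ids,
            codes=codes,
            labels=self.labels,
            cluster_ids=clusters.assignments,
            clusters=clusters,
            hash_model=hash_model,
            standardizer=standardizer,
            feature_config=cfg.features,
        )
        return NoduleRetrievalResults(
            model=self, db=db, diagnostics=diagnostics, seed=seed
        )


@dataclass(frozen=True)
class NoduleRetrievalResults:
    """A fitted retrieval index: query, evaluate, summarize, persist."""

    model: NoduleRetrieval | None
    db: retrieval.HashDatabase
    diagnostics: hashing.TrainingDiagnostics | None
    seed: int

    @property
    def config(self) -> RetrievalConfig:
        return self.model.config if self.model is not None else RetrievalConfig()

    def query(
        self,
        query: NoduleImage | np.ndarray,
        m_candidates: int | None = None,
        p: int | None = None,
    ) -> retrieval.QueryResult:
        """Retrieve the top-p neighbours of an image (or raw 104-feature vector)."""
        cfg = self.config
        m = m_candidates if m_candidates is not None else min(cfg.m_candidates, self.db.clusters.k)
        p = p if p is not None else cfg.p
        if isinstance(query, NoduleImage):
            return retrieval.prune_retrieve(query, self.db, m, p)
        q_std = self.db.standardizer.apply(np.asarray(query, dtype=float))
        return retrieval.retrieve_from_features(q_std, self.db, m, p)

    def evaluate(
        self,
        test: list[NoduleImage] | tuple[np.ndarray, np.ndarray],
        m_candidates: int | None = None,
        p: int | None = None,
    ) -> retrieval.EvaluationReport:
        """Mean precision@p and majority-vote accuracies on a held-out set.

        ``test`` is either a list of images or an ``(X, labels)`` pair of raw
        (unstandardized) feature vectors.
        """
        cfg = self.config
        m = m_candidates if m_candidates is not None else min(cfg.m_candidates, self.db.clusters.k)
        p = p if p is not None else cfg.p
        if isinstance(test, (list, tuple)) and test and isinstance(test[0], NoduleImage):
            return retrieval.evaluate(self.db, list(test), m, p)
        X, labels = test
        Q_std = self.db.standardizer.apply(np.asarray(X, dtype=float))
        return retrieval.evaluate_features(Q_std, np.asarray(labels), self.db, m, p)

    def summary(self) -> str:
        """Plain-text fit summary: configuration, cluster occupancy, objective."""
        db = self.db
        counts = np.bincount(db.cluster_ids, minlength=db.clusters.k)
        lines = [
            "Nodule hashing-and-pruning retrieval index",
            "=" * 44,
            f"database size:        {len(db)}",
            f"  benign / malignant: {int((db.labels == 0).sum())} / {int((db.labels == 1).sum())}",
            f"code length r:        {db.hash_model.r} bits",
            f"kernel anchors:       {db.hash_model.anchors.shape[0]} (sigma={db.hash_model.sigma:.4g})",
            f"clusters k:           {db.clusters.k} (delta={db.clusters.delta:.4g})",
            f"  occupancy:          min {counts.min()}, median {int(np.median(counts))}, max {counts.max()}",
            f"fit seed:             {self.seed}",
        ]
        if self.diagnostics is not None:
            tr = self.diagnostics.objective_trace
            lines += [
                f"KSH objective Q(A):   {tr[-1]:.6g} (from {tr[0]:.6g} over {len(tr) - 1} bits)",
                f"label samples l:      {self.diagnostics.label_matrix.S.shape[0]}",
            ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        from . import io

        io.save_results(self, directory)

    @classmethod
    def load(cls, directory) -> "NoduleRetrievalResults":
        from . import io

        return io.load_results(directory)
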