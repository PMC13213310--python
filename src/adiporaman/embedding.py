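"""UMAP embedding with seed-stability selection and silhouette evaluation.

Non-linear 2-D embeddings are sensitive to the random seed, so the embedding
is repeated across a list of seeds (default 42-51, spectral initialization)
and the *most stable* projection is retained: for each candidate the mean
Procrustes disparity (optimal translation / rotation / reflection / scaling)
to all sibling embeddings is computed and the minimizer wins, ties going to
the lowest seed.  Scaling is allowed in the alignment because UMAP
coordinates carry no absolute scale.

Cluster separability of tissue classes on the retained 2-D coordinates is
quantified by the silhouette score, and :func:`compare_before_after` runs
the whole embed -> stabilize -> silhouette chain on all channels versus the
top-k discriminant wavenumbers to measure the gain from feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_array

from .exceptions import ParameterError, UndefinedSilhouetteError
from .ranking import FeatureRanking, select_top_k

logger = logging.getLogger(__name__)

DEFAULT_SEEDS = tuple(range(42, 52))


@dataclass(frozen=True)
class UMAPConfig:
    """Embedding hyperparameters; defaults follow the umap-learn library."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    init: str = "spectral"
    seeds: tuple[int, ...] = DEFAULT_SEEDS

    def __post_init__(self) -> None:
        if self.n_components != 2:
            raise ParameterError("only 2-D embeddings are supported (scatterplot contract)")
        if not self.seeds or len(set(self.seeds)) != len(self.seeds):
            raise ParameterError("seeds must be non-empty and distinct")


@dataclass(frozen=True)
class EmbeddingResult:
    """Retained 2-D embedding with its stability and separability diagnostics."""

    coords: np.ndarray
    seed: int
    stability_disparity: float
    silhouette: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or not np.all(np.isfinite(coords)):
            raise ParameterError("coords must be a finite (n, 2) array")
        if self.stability_disparity < 0:
            raise ParameterError("stability disparity must be >= 0")
        if self.silhouette is not None and not -1 <= self.silhouette <= 1:
            raise ParameterError("silhouette must lie in [-1, 1]")


def umap_embed(X: np.ndarray, config: UMAPConfig | None = None, seed: int = 42) -> np.ndarray:
    """Single UMAP run; deterministic given the seed and input."""
    import umap  # deferred: heavy numba import

    cfg = config or UMAPConfig()
    X = check_array(X)
    if X.shape[0] <= cfg.n_neighbors:
        raise ParameterError(
            f"need more than n_neighbors={cfg.n_neighbors} points, got {X.shape[0]}"
        )
    with warnings.catch_warnings():
        # umap-learn warns that a fixed random_state disables parallelism;
        # determinism is exactly what we want here.
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
            n_components=cfg.n_components,
            init=cfg.init,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def select_stable_embedding(
    embeddings: dict[int, np.ndarray] | list[tuple[int, np.ndarray]],
) -> EmbeddingResult:
    """Retain the embedding with minimal mean Procrustes disparity to siblings.

    Ties are broken by the lowest seed; the input order is irrelevant.
    """
    items = sorted(embeddings.items() if isinstance(embeddings, dict) else embeddings)
    if len(items) < 2:
        raise ParameterError("need >= 2 candidate embeddings to assess stability")
    n = items[0][1].shape[0]
    for seed, coords in items:
        if coords.shape != (n, 2):
            raise ParameterError(f"embedding for seed {seed} has shape {coords.shape}, expected ({n}, 2)")
    disparities = {}
    for seed_i, coords_i in items:
        vals = [
            procrustes(coords_i, coords_j)[2]
            for seed_j, coords_j in items
            if seed_j != seed_i
        ]
        disparities[seed_i] = float(np.mean(vals))
    best_seed = min(disparities, key=lambda s: (disparities[s], s))
    coords = dict(items)[best_seed]
    logger.info(
        "stable embedding: seed %d, mean disparity %.4g (range %.4g-%.4g)",
        best_seed, disparities[best_seed],
        min(disparities.values()), max(disparities.values()),
    )
    return EmbeddingResult(coords=coords, seed=best_seed, stability_disparity=disparities[best_seed])


def silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of the 2-D coordinates under the given labels.

    For each point, a is its mean distance to its own cluster and b the
    smallest mean distance to another cluster; the score averages
    (b - a)/max(a, b).  Undefined for fewer than two labels or singleton
    clusters.
    """
    coords = check_array(coords)
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ParameterError("one label per point required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise UndefinedSilhouetteError(f"silhouette undefined for a single label {uniq.tolist()}")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise UndefinedSilhouetteError(f"silhouette undefined: cluster {small!r} is a singleton")
    return float(silhouette_score(coords, labels, metric="euclidean"))


class StableUMAPEmbedder(BaseEstimator):
    """Multi-seed UMAP with Procrustes stability selection.

    ``fit_transform(X)`` embeds X once per seed, retains the most stable
    projection, and exposes it with diagnostics.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, 2)
        The retained coordinates.
    seed_ : int
        Seed of the retained embedding.
    stability_disparity_ : float
        Its mean Procrustes disparity to the sibling embeddings.
    candidates_ : dict of seed -> coords
        All candidate embeddings.
    """

    def __init__(
        self,
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        init: str = "spectral",
        seeds: tuple[int, ...] = DEFAULT_SEEDS,
    ) -> None:
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.init = init
        self.seeds = seeds

    def _config(self) -> UMAPConfig:
        return UMAPConfig(
            n_neighbors=self.n_neighbors, min_dist=self.min_dist,
            init=self.init, seeds=tuple(self.seeds),
        )

    def fit(self, X, y=None):
        cfg = self._config()
        X = check_array(X)
        self.candidates_ = {seed: umap_embed(X, cfg, seed) for seed in cfg.seeds}
        if len(cfg.seeds) == 1:
            only = cfg.seeds[0]
            result = EmbeddingResult(self.candidates_[only], only, 0.0)
        else:
            result = select_stable_embedding(self.candidates_)
        self.embedding_ = result.coords
        self.seed_ = result.seed
        self.stability_disparity_ = result.stability_disparity
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).embedding_


def embed_and_score(
    X: np.ndarray, labels: np.ndarray, config: UMAPConfig | None = None
) -> EmbeddingResult:
    """Embed across seeds, retain the stable projection, attach its silhouette."""
    cfg = config or UMAPConfig()
    emb = StableUMAPEmbedder(
        n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist, init=cfg.init, seeds=cfg.seeds
    )
    emb.fit(X)
    return EmbeddingResult(
        coords=emb.embedding_,
        seed=emb.seed_,
        stability_disparity=emb.stability_disparity_,
        silhouette=silhouette(emb.embedding_, labels),
    )


def compare_before_after(
    X: np.ndarray,
    axis: np.ndarray,
    ranking: FeatureRanking,
    k: int,
    labels: np.ndarray,
    config: UMAPConfig | None = None,
) -> dict:
    """Silhouette of the stable embedding on all channels vs the top-k channels.

    Returns a plain record with both scores, the retained seeds and the delta;
    serializes directly to JSON/CSV.
    """
    axis = np.asarray(axis, dtype=float)
    if k > axis.size:
        raise ParameterError(f"k={k} exceeds {axis.size} channels")
    selected = select_top_k(ranking, k)
    mask = np.isin(axis, selected)
    before = embed_and_score(X, labels, config)
    after = embed_and_score(X[:, mask], labels, config)
    return {
        "n_spectra": int(X.shape[0]),
        "n_channels_before": int(axis.size),
        "n_channels_after": int(mask.sum()),
        "silhouette_before": before.silhouette,
        "silhouette_after": after.silhouette,
        "silhouette_delta": after.silhouette - before.silhouette,
        "seed_before": before.seed,
        "seed_after": after.seed,
        "stability_disparity_before": before.stability_disparity,
        "stability_disparity_after": after.stability_disparity,
    }
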