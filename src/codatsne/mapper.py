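"""Fitted t-SNE map with an out-of-sample extension, as a scikit-learn transformer.

A fitted map alone cannot place new samples: t-SNE has no parametric
inverse.  The rule implemented here ranks training samples by the Gaussian
conditional probability of the new sample under each training sample's
calibrated bandwidth,

    sp_{0,i} = exp(-d_a^2(s_0, s_i) / 2 sigma_i^2)
               / sum_{h != i} exp(-d_a^2(s_i, s_h) / 2 sigma_i^2),

takes the k most probable training samples as nearest neighbors, and
returns the probability-weighted mean of their map coordinates,
z_0 = sum_{i<=k} w_i z'_i with w_i = sp_{0,(i)} / sum_{j<=k} sp_{0,(j)}.

Note the denominator is the *training-time* row normalizer (it sums over
training pairs only and does not include s_0); the normalizers stored at
fit time are reused verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .composition import CompositionTable, closure, clr, replace_zeros
from .tsne import TsneParams, fit_tsne

__all__ = [
    "AitchisonTSNE",
    "NeighborAssignment",
    "oos_probabilities",
    "select_neighbors",
    "embed_new",
]


@dataclass
class NeighborAssignment:
    """Top-k training neighbors of a new sample, by descending probability."""

    neighbor_indices: np.ndarray  # (k,) positions in the training table
    neighbor_ids: list[str]
    probs: np.ndarray             # sp_{0,(1)} >= ... >= sp_{0,(k)}
    weights: np.ndarray           # probs normalized over the top k; sums to 1


class AitchisonTSNE(BaseEstimator, TransformerMixin):
    """t-SNE for compositional data with weighted-nearest-neighbor transform.

    ``fit(X)`` closes the rows of the non-negative abundance matrix ``X``,
    imputes zeros, computes pairwise Aitchison (or Euclidean) distances,
    calibrates per-sample Gaussian bandwidths to the target perplexity and
    gradient-descends KL(P||Q) into ``n_components`` dimensions.
    ``transform(X_new)`` embeds unseen samples with the out-of-sample rule
    above using ``k_neighbors`` neighbors; training samples are never
    re-fit.

    Parameters
    ----------
    n_components : int, default 2
        Output dimensionality *dim*.
    perplexity : float, default 30
        Effective-neighbor target *per* for bandwidth calibration.
    max_iter : int, default 1000
        Gradient-descent steps *iter*.
    metric : {"aitchison", "euclidean"}
        High-dimensional distance.  Aitchison operates on zero-replaced
        closed compositions; Euclidean on closed values directly.
    k_neighbors : int, default 7
        *k* in the out-of-sample rule.
    zero_method : {"multiplicative", "pseudocount"}
        Zero-imputation strategy (Aitchison metric only).
    delta : float or None
        Imputation value; None picks 0.65x the smallest nonzero relative
        abundance of the training table.  The fitted value is reused for
        new samples.
    random_state : int, default 42
        Seed for map initialization.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_samples, n_components)
        Training map coordinates.
    affinity_ : AffinityModel
        Calibrated bandwidths, conditional probabilities and normalizers.
    trace_ : OptimizerTrace
        KL(P||Q) checkpoints.
    train_compositions_ : ndarray
        Closed (and, for Aitchison, zero-replaced) training rows used for
        distances to new samples.
    delta_ : float or None
        Zero-imputation value actually used.
    """

    def __init__(
        self,
        n_components: int = 2,
        perplexity: float = 30.0,
        max_iter: int = 1000,
        metric: str = "aitchison",
        k_neighbors: int = 7,
        zero_method: str = "multiplicative",
        delta: float | None = None,
        learning_rate: float = 200.0,
        early_exaggeration: float = 4.0,
        random_state: int = 42,
    ):
        self.n_components = n_components
        self.perplexity = perplexity
        self.max_iter = max_iter
        self.metric = metric
        self.k_neighbors = k_neighbors
        self.zero_method = zero_method
        self.delta = delta
        self.learning_rate = learning_rate
        self.early_exaggeration = early_exaggeration
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------

    def _tsne_params(self) -> TsneParams:
        return TsneParams(
            perplexity=self.perplexity,
            max_iter=self.max_iter,
            dim=self.n_components,
            metric=self.metric,
            seed=self.random_state,
            learning_rate=self.learning_rate,
            early_exaggeration=self.early_exaggeration,
        )

    def fit(self, X, y=None, sample_ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        closed = closure(X)
        if self.metric == "aitchison":
            if self.delta is None and np.any(closed == 0):
                nz = closed[closed > 0]
                self.delta_ = 0.65 * float(nz.min())
            else:
                self.delta_ = self.delta
            positive = (
                replace_zeros(closed, method=self.zero_method, delta=self.delta_)
                if np.any(closed == 0)
                else closed
            )
        elif self.metric == "euclidean":
            self.delta_ = None
            positive = closed
        else:
            raise ValueError(f"unknown metric {self.metric!r}")

        ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(X))]
        emb, affinity, trace = fit_tsne(positive, self._tsne_params(), sample_ids=ids)
        self.train_compositions_ = positive
        self.sample_ids_ = list(ids)
        self.embedding_ = emb.coords
        self.affinity_ = affinity
        self.trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y, **fit_params)
        return self.embedding_

    def transform(self, X) -> np.ndarray:
        """Embed new samples one by one with the out-of-sample rule."""
        check_is_fitted(self, "embedding_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: fitted with {self.n_features_in_} taxa, "
                f"got {X.shape[1]}"
            )
        return np.vstack([embed_new(self, row, self.k_neighbors)[0] for row in X])

    def transform_with_neighbors(
        self, X
    ) -> tuple[np.ndarray, list[NeighborAssignment]]:
        check_is_fitted(self, "embedding_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pairs = [embed_new(self, row, self.k_neighbors) for row in X]
        return np.vstack([z for z, _ in pairs]), [nb for _, nb in pairs]

    def fit_table(self, table: CompositionTable) -> "AitchisonTSNE":
        """Convenience: fit from a :class:`CompositionTable`."""
        return self.fit(table.values, sample_ids=table.sample_ids)


def _prepare_new_sample(mapper: AitchisonTSNE, new_sample: np.ndarray) -> np.ndarray:
    """Close and zero-impute a new sample with the mapper's fitted policy."""
    new_sample = np.asarray(new_sample, dtype=float).ravel()
    if new_sample.shape[0] != mapper.n_features_in_:
        raise ValueError(
            f"taxa mismatch: mapper fitted with {mapper.n_features_in_} taxa, "
            f"new sample has {new_sample.shape[0]}"
        )
    if np.any(new_sample < 0) or not np.all(np.isfinite(new_sample)):
        raise ValueError("new sample must be non-negative and finite")
    if new_sample.sum() <= 0:
        raise ValueError("new sample is all zeros")
    row = closure(new_sample[None, :])
    if mapper.metric == "aitchison" and np.any(row == 0):
        row = replace_zeros(row, method=mapper.zero_method, delta=mapper.delta_)
    return row[0]


def oos_probabilities(mapper: AitchisonTSNE, new_sample: np.ndarray) -> np.ndarray:
    """Conditional probabilities sp_{0,i} of a new sample vs each training sample.

    The denominator for row i is the stored training-pair normalizer, so
    the values need not (and generally do not) sum to one.
    """
    check_is_fitted(mapper, "embedding_")
    s0 = _prepare_new_sample(mapper, new_sample)
    train = mapper.train_compositions_
    if mapper.metric == "aitchison":
        diff = clr(train) - clr(s0)
    else:
        diff = train - s0
    sq_dists = np.sum(diff ** 2, axis=1)
    numer = np.exp(-sq_dists / (2.0 * mapper.affinity_.sigma_sq))
    return numer / mapper.affinity_.normalizers


def select_neighbors(
    sp: np.ndarray, k: int, sample_ids: list[str] | None = None
) -> NeighborAssignment:
    """Top-k training samples by descending sp; ties keep training order."""
    sp = np.asarray(sp, dtype=float)
    n = sp.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    order = np.argsort(-sp, kind="stable")[:k]
    probs = sp[order]
    weights = probs / probs.sum()
    ids = (
        [sample_ids[i] for i in order]
        if sample_ids is not None
        else [str(i) for i in order]
    )
    return NeighborAssignment(
        neighbor_indices=order, neighbor_ids=ids, probs=probs, weights=weights
    )


def embed_new(
    mapper: AitchisonTSNE, new_sample: np.ndarray, k: int | None = None
) -> tuple[np.ndarray, NeighborAssignment]:
    """Out-of-sample coordinates z_0 = sum_i w_i z'_i over the top-k neighbors."""
    if k is None:
        k = mapper.k_neighbors
    sp = oos_probabilities(mapper, new_sample)
    nb = select_neighbors(sp, k, mapper.sample_ids_)
    z0 = nb.weights @ mapper.embedding_[nb.neighbor_indices]
    return z0, nb
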