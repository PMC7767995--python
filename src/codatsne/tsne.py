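"""From-scratch t-SNE under a pluggable distance.

The high-dimensional similarity of sample j to sample i is a Gaussian
conditional probability

    p_{j|i} = exp(-d^2(s_i, s_j) / 2 sigma_i^2) / sum_{k != i} exp(-d^2(s_i, s_k) / 2 sigma_i^2)

whose per-sample bandwidth sigma_i^2 is calibrated so that the perplexity
2^H(P_i) (Shannon entropy H in bits) matches a user target -- the effective
number of neighbors.  Conditional probabilities are symmetrized to
p_ij = (p_{j|i} + p_{i|j}) / 2N, low-dimensional affinities q_ij use a
Student-t (Cauchy) kernel, and map coordinates are found by gradient
descent on KL(P || Q) with the standard momentum / early-exaggeration /
adaptive-gain schedule.

The distance matrix is supplied by the caller, so the same machinery runs
with the Aitchison distance (compositional data) or plain Euclidean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .composition import pairwise_distances

__all__ = [
    "TsneParams",
    "AffinityModel",
    "Embedding",
    "OptimizerTrace",
    "calibrate_bandwidths",
    "symmetrize",
    "low_dim_affinities",
    "kl_divergence",
    "fit_tsne",
]

logger = logging.getLogger(__name__)

_Q_FLOOR = 1e-12  # numerical floor on Q inside the optimizer only


@dataclass
class TsneParams:
    """Optimization and model parameters.

    perplexity (*per*) and max_iter (*iter*) are the two model-level
    tuning knobs; the optimizer controls follow the standard schedule:
    initial coordinates ~ N(0, 1e-4), learning rate 200, momentum 0.5
    switching to 0.8 at step 250, early exaggeration x4 for 100 steps.
    """

    perplexity: float = 30.0
    max_iter: int = 1000
    dim: int = 2
    metric: str = "aitchison"
    seed: int = 42
    learning_rate: float = 200.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration: float = 4.0
    early_exaggeration_iter: int = 100
    trace_every: int = 50

    def validate(self, n_samples: int) -> None:
        if not 1 <= self.perplexity <= n_samples - 1:
            raise ValueError(
                f"perplexity must lie in [1, N-1] = [1, {n_samples - 1}], "
                f"got {self.perplexity}"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.metric not in ("aitchison", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class AffinityModel:
    """Per-sample bandwidths and the affinity matrices they induce."""

    sigma_sq: np.ndarray          # (N,) Gaussian variances
    perplexity: float             # calibration target
    cond_probs: np.ndarray        # (N, N) row-stochastic p_{j|i}, zero diagonal
    P: np.ndarray                 # (N, N) symmetric p_ij, sums to 1
    normalizers: np.ndarray       # (N,) row denominators sum_{k != i} exp(.)

    @property
    def n_samples(self) -> int:
        return self.sigma_sq.shape[0]

    def realized_perplexities(self) -> np.ndarray:
        """2^H of each conditional row (H in bits)."""
        return np.array([_row_perplexity(row) for row in self.cond_probs])


@dataclass
class Embedding:
    sample_ids: list[str]
    coords: np.ndarray  # (N, dim)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class OptimizerTrace:
    iterations: list[int] = field(default_factory=list)
    kl_per_checkpoint: list[float] = field(default_factory=list)

    def record(self, iteration: int, kl: float) -> None:
        if not np.isfinite(kl) or kl < 0:
            raise FloatingPointError(f"invalid KL value {kl} at iteration {iteration}")
        self.iterations.append(int(iteration))
        self.kl_per_checkpoint.append(float(kl))


def _row_perplexity(prob_row: np.ndarray) -> float:
    pos = prob_row[prob_row > 0]
    entropy_bits = -float(np.sum(pos * np.log2(pos)))
    return float(2.0 ** entropy_bits)


def _cond_probs_for_beta(sq_dists_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Gaussian conditional probabilities for precision beta = 1/(2 sigma^2).

    Returns the probability row and the (shifted-back) normalizer.  The
    max-shift keeps the exponentials in range; the returned normalizer is
    on the original scale for reuse by the out-of-sample rule.
    """
    shift = sq_dists_row.min()
    w = np.exp(-beta * (sq_dists_row - shift))
    total = w.sum()
    return w / total, float(total * np.exp(-beta * shift))


def calibrate_bandwidths(
    dist_matrix: np.ndarray,
    perplexity: float,
    tol: float = 1e-9,
    max_steps: int = 64,
) -> AffinityModel:
    """Find sigma_i^2 so every conditional row hits the target perplexity.

    Binary search on the precision beta_i = 1/(2 sigma_i^2): the realized
    perplexity is monotone decreasing in beta, so the bracket is first
    expanded geometrically and then bisected.  Rows that fail to converge
    within ``max_steps`` fall back to the last bracket midpoint with a
    logged warning.
    """
    D = np.asarray(dist_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= perplexity <= n - 1:
        raise ValueError(f"perplexity must lie in [1, N-1] = [1, {n - 1}]")
    target_entropy = np.log2(perplexity)

    sigma_sq = np.empty(n)
    normalizers = np.empty(n)
    cond = np.zeros((n, n))
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        sq = D[i][mask[i]] ** 2
        beta, lo, hi = 1.0, 0.0, np.inf
        row, norm = _cond_probs_for_beta(sq, beta)
        for _ in range(max_steps):
            gap = np.log2(_row_perplexity(row)) - target_entropy
            if abs(gap) < tol:
                break
            if gap > 0:  # too many neighbors: increase precision
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (lo + hi) / 2.0
            row, norm = _cond_probs_for_beta(sq, beta)
        else:
            logger.warning(
                "perplexity calibration did not converge for row %d "
                "(realized %.4f, target %.4f)", i, _row_perplexity(row), perplexity
            )
        sigma_sq[i] = 1.0 / (2.0 * beta)
        normalizers[i] = norm
        cond[i][mask[i]] = row

    P = symmetrize(cond)
    return AffinityModel(
        sigma_sq=sigma_sq,
        perplexity=float(perplexity),
        cond_probs=cond,
        P=P,
        normalizers=normalizers,
    )


def symmetrize(cond_probs: np.ndarray) -> np.ndarray:
    """p_ij = (p_{j|i} + p_{i|j}) / 2N; symmetric, zero diagonal, sums to 1."""
    n = cond_probs.shape[0]
    return (cond_probs + cond_probs.T) / (2.0 * n)


def low_dim_affinities(coords: np.ndarray) -> np.ndarray:
    """Student-t map affinities q_ij = (1 + d^2)^-1 normalized over all pairs."""
    num = _t_kernel(coords)
    return num / num.sum()


def _t_kernel(coords: np.ndarray) -> np.ndarray:
    """Unnormalized (1 + ||z_i - z_j||^2)^-1 with zero diagonal."""
    y = np.asarray(coords, dtype=float)
    sq = np.sum(y ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
    np.maximum(d2, 0.0, out=d2)
    num = 1.0 / (1.0 + d2)
    np.fill_diagonal(num, 0.0)
    return num


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) = sum_{i != j} p_ij log(p_ij / q_ij), in nats."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    pos = P > 0
    if np.any(Q[pos] <= 0):
        raise ValueError("degenerate embedding: q_ij = 0 where p_ij > 0")
    return float(np.sum(P[pos] * np.log(P[pos] / Q[pos])))


def fit_tsne(
    values: np.ndarray,
    params: TsneParams,
    sample_ids: list[str] | None = None,
    dist_matrix: np.ndarray | None = None,
) -> tuple[Embedding, AffinityModel, OptimizerTrace]:
    """Run t-SNE on strictly positive compositions (or a given distance matrix).

    Fully deterministic given ``params.seed``; records KL(P||Q) against the
    unexaggerated P every ``params.trace_every`` steps plus the final step.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 4:
        raise ValueError("t-SNE needs at least 4 samples")
    params.validate(n)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if dist_matrix is None:
        dist_matrix = pairwise_distances(values, metric=params.metric)

    affinity = calibrate_bandwidths(dist_matrix, params.perplexity)
    P = affinity.P

    rng = np.random.default_rng(params.seed)
    Y = rng.normal(0.0, 1e-2, size=(n, params.dim))  # variance 1e-4

    trace = OptimizerTrace()
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)

    for it in range(params.max_iter):
        exaggerate = it < params.early_exaggeration_iter
        P_eff = P * params.early_exaggeration if exaggerate else P

        num = _t_kernel(Y)
        Q = np.maximum(num / num.sum(), _Q_FLOOR)

        if it % params.trace_every == 0:
            trace.record(it, kl_divergence(P, np.maximum(low_dim_affinities(Y), _Q_FLOOR)))

        # dC/dy_i = 4 sum_j (p_ij - q_ij) (1 + d_ij^2)^-1 (y_i - y_j)
        W = (P_eff - Q) * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite t-SNE gradient at iteration {it}")

        momentum = (
            params.momentum_early
            if it < params.momentum_switch_iter
            else params.momentum_late
        )
        same_sign = np.sign(grad) == np.sign(velocity)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.maximum(gains, 0.01, out=gains)
        velocity = momentum * velocity - params.learning_rate * gains * grad
        Y = Y + velocity
        Y = Y - Y.mean(axis=0)

    trace.record(params.max_iter, kl_divergence(P, np.maximum(low_dim_affinities(Y), _Q_FLOOR)))
    return Embedding(sample_ids=list(sample_ids), coords=Y), affinity, trace
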