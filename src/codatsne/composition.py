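"""Compositional-data geometry.

Relative-abundance vectors carry only relative information: their sample
space is the simplex, and meaningful distances must be permutation
invariant, scale invariant and subcompositionally coherent.  The Aitchison
distance -- the Euclidean distance between centered log-ratio (CLR)
transformed compositions -- satisfies all three and replaces the Euclidean
distance throughout this package.

Because log-ratios are undefined at zero, zero counts (ubiquitous in
microbiome tables) must be imputed first; :func:`replace_zeros` implements
the standard multiplicative and pseudocount strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CompositionTable",
    "closure",
    "replace_zeros",
    "clr",
    "clr_inverse",
    "aitchison_distance",
    "pairwise_distances",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class CompositionTable:
    """Samples x taxa relative-abundance table with IDs and optional labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique per-sample identifiers (rows).
    taxa_ids : sequence of str
        Unique per-taxon identifiers (columns).
    values : ndarray of shape (n_samples, n_taxa)
        Non-negative abundances.  Rows need not sum to one on input;
        use :meth:`closed` to normalize.
    labels : ndarray of shape (n_samples,), optional
        Binary class labels (1 = case, 0 = control).
    """

    sample_ids: list[str]
    taxa_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxa_ids = [str(t) for t in self.taxa_ids]
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 taxa, got {n} x {p}")
        if len(self.sample_ids) != n or len(self.taxa_ids) != p:
            raise ValueError("ID lengths do not match the value matrix shape")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample_ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            bad = np.unique(np.where(self.values < 0)[0])
            raise ValueError(
                "negative abundances in samples: "
                + ", ".join(self.sample_ids[i] for i in bad[:5])
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match sample count")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def closed(self) -> "CompositionTable":
        """Return a copy whose rows are normalized to sum to one."""
        return replace(self, values=closure(self.values, self.sample_ids))

    def is_closed(self) -> bool:
        return bool(np.allclose(self.values.sum(axis=1), 1.0, atol=_ROW_SUM_TOL))

    def subset(self, idx: np.ndarray) -> "CompositionTable":
        """Row subset preserving IDs and labels (no re-closure)."""
        idx = np.asarray(idx)
        return CompositionTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            taxa_ids=list(self.taxa_ids),
            values=self.values[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for s in ids:
        (dup if s in seen else seen).add(s)
    return dup


def closure(values: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Normalize each row of a non-negative matrix to sum to one.

    Raises
    ------
    ValueError
        If any row is entirely zero (names the offending sample).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if np.any(values < 0):
        raise ValueError("closure requires non-negative entries")
    sums = values.sum(axis=1)
    zero_rows = np.where(sums <= 0)[0]
    if zero_rows.size:
        names = (
            [sample_ids[i] for i in zero_rows[:5]]
            if sample_ids is not None
            else list(zero_rows[:5])
        )
        raise ValueError(f"all-zero rows cannot be closed: samples {names}")
    return values / sums[:, None]


def replace_zeros(
    values: np.ndarray,
    method: str = "multiplicative",
    delta: float | None = None,
) -> np.ndarray:
    """Impute zeros in closed compositions so log-ratios are defined.

    ``multiplicative``: zeros become ``delta`` and the nonzero parts of a
    row with ``z`` zeros are scaled by ``1 - z * delta``, preserving the
    ratios among nonzero parts; ``pseudocount``: ``delta`` is added to
    every entry.  Both re-close the rows afterwards.

    ``delta=None`` defaults to 0.65x the smallest nonzero relative
    abundance in the table, a standard choice that keeps the imputed value
    below anything actually observed.
    """
    values = closure(values)
    n, p = values.shape
    if delta is None:
        nz = values[values > 0]
        delta = 0.65 * float(nz.min())
    if not (0 < delta < 1.0 / p):
        raise ValueError(f"delta must lie in (0, 1/p) = (0, {1.0 / p:g}), got {delta}")
    if method == "multiplicative":
        zeros = values == 0
        z_counts = zeros.sum(axis=1)
        out = values * (1.0 - z_counts * delta)[:, None]
        out[zeros] = delta
    elif method == "pseudocount":
        out = values + delta
    else:
        raise ValueError(f"unknown zero-replacement method {method!r}")
    return closure(out)


def clr(row: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform, ``clr_i(x) = ln(x_i / g(x))``.

    ``g`` is the geometric mean; the output sums to zero.  Accepts a
    vector or a matrix (row-wise).  Scale invariant: ``clr(c*x) == clr(x)``.
    """
    x = np.asarray(row, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("clr requires strictly positive finite entries")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def clr_inverse(y: np.ndarray) -> np.ndarray:
    """Map CLR coordinates back to the simplex (softmax)."""
    y = np.asarray(y, dtype=float)
    e = np.exp(y - y.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance ``d_a(x, y) = || clr(x) - clr(y) ||_2``.

    Defined for strictly positive vectors of equal length; zero iff the
    two compositions are equal up to a positive scaling.  Sums use exact
    (compensated) summation, so the result is exactly invariant under a
    joint permutation of the parts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("aitchison_distance requires strictly positive entries")
    lx, ly = np.log(x), np.log(y)
    diff = (lx - math.fsum(lx) / lx.size) - (ly - math.fsum(ly) / ly.size)
    return math.sqrt(math.fsum(diff * diff))


def pairwise_distances(values: np.ndarray, metric: str = "aitchison") -> np.ndarray:
    """Dense symmetric distance matrix between composition rows.

    ``aitchison`` requires strictly positive (zero-replaced) rows and is
    computed as Euclidean distance between CLR rows; ``euclidean``
    operates on the (closed) values directly.
    """
    values = np.asarray(values, dtype=float)
    if metric == "aitchison":
        mat = clr(values)
    elif metric == "euclidean":
        mat = values
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(pdist(mat, metric="euclidean"))
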