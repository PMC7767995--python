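"""Synthetic compositional microbiome tables with controllable class structure.

The generative model is logistic-normal: each sample is a Gaussian vector
in CLR (log-ratio) space mapped to the simplex by the inverse CLR
(softmax).  A heavy-tailed baseline mean produces the skewed
few-dominant-taxa profiles typical of 16S genus tables; the case/control
effect is a mean shift of stated magnitude along random unit directions in
CLR space, i.e. expressed in the same geometry the Aitchison distance
measures.  Optional layers emulate the measurement process: multinomial
resampling at a sequencing depth (tags per sample), abundance-correlated
sparsity (the smallest fractions of each row are zeroed, as detection
limits do), and a per-sample positive scale confounder that mimics uneven
library size on unnormalized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CompositionTable, clr_inverse, closure

__all__ = ["SyntheticConfig", "generate", "mp_like", "icpp_like"]

# spread (sd, log units) of the baseline CLR mean across taxa; gives
# realistic dominance of a few taxa without drowning the class effect
_BASELINE_SD = 2.0


@dataclass
class SyntheticConfig:
    """Study-design parameters for one synthetic cohort.

    Parameters
    ----------
    n_case, n_control : int
        Samples per class (labels 1 and 0).
    p : int
        Number of taxa.
    effect : float
        Between-class mean separation in CLR space (log-ratio units).
    within_sd : float
        Within-class standard deviation in CLR space per coordinate.
    sparsity : float
        Expected fraction of zero entries per row, introduced by zeroing
        each row's smallest fractions.
    depth : int or None
        Sequencing depth for multinomial resampling (tags per sample);
        None keeps exact probabilities.
    scale_confound : float or None
        Spread (in log2 units) of a per-sample random scale factor
        applied to the output rows, so rows no longer sum to one — like
        raw counts with uneven library sizes.  Factors are rounded to
        powers of two, which float arithmetic absorbs exactly: closure
        and log-ratios of a confounded table are bit-identical to the
        unconfounded one, while raw Euclidean distances are not.
        None/0 disables.
    n_effect_directions : int
        Number of orthogonal CLR directions the effect is spread over.
        1 gives a symmetric two-cluster shift; m > 1 makes the case class
        a mixture of m sub-populations, each shifted along its own
        direction, so the class boundary spans an m-dimensional subspace.
    seed : int
        Generator seed; identical seeds give identical tables.
    """

    n_case: int = 40
    n_control: int = 59
    p: int = 728
    effect: float = 4.0
    within_sd: float = 1.0
    sparsity: float = 0.5
    depth: int | None = 30_000
    scale_confound: float | None = None
    n_effect_directions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        if self.p < 3:
            raise ValueError("need at least 3 taxa")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if not 1 <= self.n_effect_directions <= self.p - 1:
            raise ValueError("n_effect_directions must lie in [1, p-1]")


def _orthonormal_clr_directions(rng: np.random.Generator, p: int, m: int) -> np.ndarray:
    """m orthonormal zero-sum (CLR-subspace) direction vectors, shape (m, p)."""
    raw = rng.normal(size=(m, p))
    raw -= raw.mean(axis=1, keepdims=True)
    # Gram-Schmidt within the zero-sum hyperplane
    basis: list[np.ndarray] = []
    for v in raw:
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-8:  # pathological draw; resample deterministically
            v = rng.normal(size=p)
            v -= v.mean()
            for b in basis:
                v = v - (v @ b) * b
            norm = np.linalg.norm(v)
        basis.append(v / norm)
    return np.vstack(basis)


def generate(config: SyntheticConfig) -> CompositionTable:
    """Draw one labeled cohort under ``config``. Fully seeded."""
    # independent streams per stage so optional stages (depth, confound)
    # do not shift the draws of the others across configurations
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng, rng_depth, rng_scale, rng_perm = (np.random.default_rng(s) for s in ss)
    p, m = config.p, config.n_effect_directions
    n = config.n_case + config.n_control

    baseline = rng.normal(0.0, _BASELINE_SD, size=p)
    directions = _orthonormal_clr_directions(rng, p, m)

    means = np.tile(baseline, (n, 1))
    labels = np.concatenate([np.ones(config.n_case, int), np.zeros(config.n_control, int)])
    if m == 1:
        means[labels == 1] += (config.effect / 2.0) * directions[0]
        means[labels == 0] -= (config.effect / 2.0) * directions[0]
    else:
        comp = rng.integers(0, m, size=config.n_case)
        means[:config.n_case] += config.effect * directions[comp]

    latent = means + rng.normal(0.0, config.within_sd, size=(n, p))
    fractions = clr_inverse(latent)

    if config.depth is not None:
        counts = np.vstack([rng_depth.multinomial(config.depth, row) for row in fractions])
        fractions = closure(counts)

    if config.sparsity > 0:
        target_zeros = int(round(config.sparsity * p))
        for i in range(n):
            row = fractions[i]
            extra = target_zeros - int(np.sum(row == 0))
            if extra > 0:
                order = np.argsort(row, kind="stable")
                positive = order[row[order] > 0]
                row[positive[:extra]] = 0.0
        fractions = closure(fractions)

    values = fractions
    if config.scale_confound:
        scales = 2.0 ** np.round(rng_scale.normal(0.0, config.scale_confound, size=n))
        values = fractions * scales[:, None]

    order = rng_perm.permutation(n)  # interleave classes so folds are not blocks
    return CompositionTable(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        taxa_ids=[f"taxon_{j}" for j in range(p)],
        values=values[order],
        labels=labels[order],
    )


def _scaled_counts(n_case: int, n_control: int, n_samples: int | None) -> tuple[int, int]:
    if n_samples is None:
        return n_case, n_control
    total = n_case + n_control
    case = max(2, round(n_samples * n_case / total))
    return case, max(2, n_samples - case)


def mp_like(
    seed: int = 0,
    n_samples: int | None = None,
    n_taxa: int | None = None,
    scale_confound: float | None = None,
) -> CompositionTable:
    """Oropharyngeal-infection-style cohort: 99 samples x 728 genera, 40 case
    / 59 control, sparse rows at ~30k tags depth, one dominant axis of
    class separation (clean low-dimensional structure).

    ``n_samples``/``n_taxa`` shrink the cohort proportionally for cheap
    simulation studies.
    """
    case, control = _scaled_counts(40, 59, n_samples)
    cfg = SyntheticConfig(
        n_case=case,
        n_control=control,
        p=n_taxa or 728,
        effect=6.0,
        within_sd=1.0,
        sparsity=0.6,
        depth=30_000,
        scale_confound=scale_confound,
        n_effect_directions=1,
        seed=seed,
    )
    return generate(cfg)


def icpp_like(
    seed: int = 0,
    n_samples: int | None = None,
    n_taxa: int | None = None,
    scale_confound: float | None = None,
) -> CompositionTable:
    """Gut-microbiome-style cohort: 48 samples x 146 genera, 25 case / 23
    control, with the class effect spread over four orthogonal CLR
    directions — more complex composition whose separation needs a higher
    embedding dimensionality than the two-cluster case.
    """
    case, control = _scaled_counts(25, 23, n_samples)
    cfg = SyntheticConfig(
        n_case=case,
        n_control=control,
        p=n_taxa or 146,
        effect=6.0,
        within_sd=1.0,
        sparsity=0.4,
        depth=30_000,
        scale_confound=scale_confound,
        n_effect_directions=4,
        seed=seed,
    )
    return generate(cfg)
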