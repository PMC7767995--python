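"""Canned simulation studies used for qualitative validation.

Two study designs probe the package's central claims on synthetic cohorts:

* :func:`aitchison_vs_euclidean_study` — on a scale-confounded cohort with
  one dominant axis of class separation in log-ratio space, t-SNE built on
  the Aitchison distance should yield better held-out classification than
  t-SNE built on the Euclidean distance, for every classifier family.
* :func:`dimension_effect_study` — when the class effect is spread over
  several orthogonal log-ratio directions, a higher output dimensionality
  should not hurt (and typically helps) cross-validated accuracy.

Both are pure functions of their seeds and sized for a single CPU.
"""

from __future__ import annotations

import numpy as np

from .metrics import PipelineGrid, cv_grid_search, run_experiment
from .simulate import icpp_like, mp_like

__all__ = ["aitchison_vs_euclidean_study", "dimension_effect_study"]


def aitchison_vs_euclidean_study(
    n_seeds: int = 10,
    n_samples: int = 60,
    n_taxa: int = 100,
    scale_confound: float = 2.0,
    perplexity: float = 15.0,
    max_iter: int = 500,
    dim: int = 3,
    k: int = 7,
    base_seed: int = 0,
    families: tuple[str, ...] = ("lr", "svm", "dt"),
) -> dict:
    """Mean held-out test accuracy per family under each t-SNE metric.

    Each seed draws a fresh scale-confounded two-cluster cohort (reduced
    oropharyngeal-style preset), splits it 80/20, fits the pipeline with
    fixed parameters under both metrics, and scores the held-out samples.

    Returns ``{"aitchison": {family: {"acc": ..., "nmcc": ..., "auc": ...,
    "aupr": ...}}, "euclidean": {...}, "per_seed": {...}, "n_test": ...}``,
    each entry a mean over seeds.
    """
    measures = ("acc", "nmcc", "auc", "aupr")
    per_seed: dict = {m: {f: {q: [] for q in measures} for f in families}
                      for m in ("aitchison", "euclidean")}
    n_test = 0
    for i in range(n_seeds):
        seed = base_seed + i
        table = mp_like(seed=seed, n_samples=n_samples, n_taxa=n_taxa,
                        scale_confound=scale_confound)
        grid = PipelineGrid(per_values=[perplexity], iter_values=[max_iter],
                            dim_values=[dim], k_values=[k], seed=seed)
        for metric in ("aitchison", "euclidean"):
            out = run_experiment(table, grid, families=families, metric=metric)
            n_test = out["n_test"]
            for fam in families:
                rep = out["families"][fam]["report"].as_dict()
                for q in measures:
                    per_seed[metric][fam][q].append(rep[q])
    summary = {
        metric: {
            fam: {q: float(np.mean(vals)) for q, vals in qs.items()}
            for fam, qs in fams.items()
        }
        for metric, fams in per_seed.items()
    }
    summary["per_seed"] = per_seed
    summary["n_test"] = n_test
    return summary


def dimension_effect_study(
    n_seeds: int = 5,
    n_taxa: int = 100,
    dims: tuple[int, ...] = (2, 5),
    perplexity: float = 10.0,
    max_iter: int = 400,
    k: int = 5,
    base_seed: int = 0,
    family: str = "lr",
) -> dict:
    """Mean fivefold-CV accuracy per output dimensionality.

    Each seed draws a gut-style cohort whose class effect spans four
    orthogonal log-ratio directions and runs the pipeline grid search over
    ``dims`` only; returns ``{"mean_cv_acc": {dim: value}, "per_seed": ...}``.
    """
    per_seed: dict = {d: [] for d in dims}
    for i in range(n_seeds):
        seed = base_seed + i
        table = icpp_like(seed=seed, n_taxa=n_taxa)
        grid = PipelineGrid(per_values=[perplexity], iter_values=[max_iter],
                            dim_values=list(dims), k_values=[k], seed=seed)
        _, cv_table = cv_grid_search(table, grid, family, metric="aitchison")
        for d in dims:
            acc = float(cv_table.loc[cv_table["dim"] == d, "mean_cv_acc"].iloc[0])
            per_seed[d].append(acc)
    return {
        "mean_cv_acc": {d: float(np.mean(v)) for d, v in per_seed.items()},
        "per_seed": per_seed,
    }
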