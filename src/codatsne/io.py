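"""Delimited-text I/O and mapper serialization.

Formats: abundance TSV/CSV (rows = samples, first column = sample ID,
header = taxon names, optional designated label column), labels TSV
(sample_id, label), embedding TSV (sample_id, z1..zd), and a versioned
JSON bundle holding everything a fitted mapper needs to embed new samples.
JSON stores floats with full round-trip precision, so save/load reproduces
embeddings and out-of-sample outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import CompositionTable
from .mapper import AitchisonTSNE
from .tsne import AffinityModel, OptimizerTrace

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_labels",
    "write_labels",
    "write_embedding",
    "save_mapper",
    "load_mapper",
]

logger = logging.getLogger(__name__)

MAPPER_FORMAT_VERSION = 1


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    labels_path: str | Path | None = None,
    label_column: str | None = None,
) -> CompositionTable:
    """Read a samples x taxa table; counts are accepted (closure is the
    caller's job, and a notice is logged when rows do not sum to one)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df.pop(label_column).to_numpy(dtype=int)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        rows = np.unique(np.where(values < 0)[0]) + 2  # header + 1-based
        raise ValueError(f"negative abundances at file lines {rows.tolist()}")
    if labels_path is not None:
        lab = read_labels(labels_path)
        try:
            labels = lab.loc[df.index.astype(str)].to_numpy(dtype=int)
        except KeyError as exc:
            raise ValueError(f"labels file is missing sample IDs: {exc}") from exc
    table = CompositionTable(
        sample_ids=list(df.index.astype(str)),
        taxa_ids=list(df.columns.astype(str)),
        values=values,
        labels=labels,
    )
    logger.info("read %d samples x %d taxa from %s", table.n_samples, table.n_taxa, path)
    if not table.is_closed():
        logger.info("rows do not sum to 1 (raw counts?); closure will be applied downstream")
    return table


def write_abundance_table(table: CompositionTable, path: str | Path,
                          include_labels: bool = False) -> None:
    path = Path(path)
    df = pd.DataFrame(table.values, index=table.sample_ids, columns=table.taxa_ids)
    df.index.name = "sample_id"
    if include_labels and table.labels is not None:
        df["label"] = table.labels
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")  # lossless


def read_labels(path: str | Path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("labels file needs columns (sample_id, label)")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels(table: CompositionTable, path: str | Path) -> None:
    if table.labels is None:
        raise ValueError("table has no labels")
    pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels}).to_csv(
        Path(path), sep=_sep_for(Path(path)), index=False
    )


def write_embedding(sample_ids: list[str], coords: np.ndarray, path: str | Path) -> None:
    coords = np.atleast_2d(coords)
    cols = {f"z{j + 1}": coords[:, j] for j in range(coords.shape[1])}
    pd.DataFrame({"sample_id": sample_ids, **cols}).to_csv(
        Path(path), sep="\t", index=False
    )


def save_mapper(mapper: AitchisonTSNE, path: str | Path) -> None:
    """Serialize a fitted mapper to a versioned JSON bundle."""
    if not hasattr(mapper, "embedding_"):
        raise ValueError("mapper is not fitted")
    payload = {
        "format_version": MAPPER_FORMAT_VERSION,
        "params": mapper.get_params(),
        "delta": mapper.delta_,
        "sample_ids": mapper.sample_ids_,
        "n_features_in": mapper.n_features_in_,
        "train_compositions": mapper.train_compositions_.tolist(),
        "embedding": mapper.embedding_.tolist(),
        "sigma_sq": mapper.affinity_.sigma_sq.tolist(),
        "normalizers": mapper.affinity_.normalizers.tolist(),
        "cond_probs": mapper.affinity_.cond_probs.tolist(),
        "perplexity": mapper.affinity_.perplexity,
        "trace_iterations": mapper.trace_.iterations,
        "trace_kl": mapper.trace_.kl_per_checkpoint,
    }
    Path(path).write_text(json.dumps(payload))


def load_mapper(path: str | Path) -> AitchisonTSNE:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated mapper file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MAPPER_FORMAT_VERSION:
        raise ValueError(
            f"mapper format version mismatch: file has {version!r}, "
            f"this build reads {MAPPER_FORMAT_VERSION}"
        )
    mapper = AitchisonTSNE(**payload["params"])
    mapper.delta_ = payload["delta"]
    mapper.sample_ids_ = list(payload["sample_ids"])
    mapper.n_features_in_ = int(payload["n_features_in"])
    mapper.train_compositions_ = np.asarray(payload["train_compositions"], dtype=float)
    mapper.embedding_ = np.asarray(payload["embedding"], dtype=float)
    cond = np.asarray(payload["cond_probs"], dtype=float)
    n = cond.shape[0]
    mapper.affinity_ = AffinityModel(
        sigma_sq=np.asarray(payload["sigma_sq"], dtype=float),
        perplexity=float(payload["perplexity"]),
        cond_probs=cond,
        P=(cond + cond.T) / (2.0 * n),
        normalizers=np.asarray(payload["normalizers"], dtype=float),
    )
    trace = OptimizerTrace()
    trace.iterations = list(payload["trace_iterations"])
    trace.kl_per_checkpoint = list(payload["trace_kl"])
    mapper.trace_ = trace
    return mapper
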