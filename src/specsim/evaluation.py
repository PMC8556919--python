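"""Evaluation procedures: all-vs-all scoring, per-label-bin errors,
precision/recall for high-similarity retrieval, and same-compound score
aggregation.

All statistics are computed over unique unordered spectrum pairs. Self-pairs
(a spectrum against itself) are enumerated by the all-vs-all scorer — they
belong to the m(m+1)/2 unique-pair count — but are excluded from error and
precision/recall statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from specsim.binning import BinnedSpectrum
from specsim.labels import SimilarityLabelMatrix
from specsim.model import SiameseModel


def iter_unique_pairs(ids: Sequence) -> Iterator[tuple[int, int]]:
    """All unordered index pairs including self-pairs: m(m+1)/2 of them."""
    m = len(ids)
    for i in range(m):
        for j in range(i, m):
            yield i, j


def n_unique_pairs(m: int) -> int:
    return m * (m + 1) // 2


@dataclass
class ScoreMatrix:
    ids: list[str]
    predicted: np.ndarray
    true_labels: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=float)
        m = len(self.ids)
        if self.predicted.shape != (m, m) or self.true_labels.shape != (m, m):
            raise ValueError("matrices must be square and aligned with ids")
        if not np.allclose(self.predicted, self.predicted.T):
            raise ValueError("predicted matrix must be symmetric")
        if not np.allclose(self.true_labels, self.true_labels.T):
            raise ValueError("true_labels matrix must be symmetric")
        if np.any(self.true_labels < 0) or np.any(self.true_labels > 1):
            raise ValueError("true labels must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return n_unique_pairs(len(self.ids))

    def offdiag_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(predicted, true) over unique non-self pairs."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.predicted[iu], self.true_labels[iu]


@dataclass
class BinnedErrorReport:
    bin_edges: np.ndarray
    rmse: np.ndarray  # NaN marks an empty bin
    mae: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "rmse": [None if np.isnan(v) else float(v) for v in self.rmse],
            "mae": [None if np.isnan(v) else float(v) for v in self.mae],
            "counts": self.counts.tolist(),
        }


def all_vs_all(
    model: SiameseModel,
    binned: Sequence[BinnedSpectrum],
    labels: SimilarityLabelMatrix | None = None,
) -> ScoreMatrix:
    """Embed each spectrum once, score every unique pair by cosine.

    Compound-level labels are broadcast to spectrum pairs when a label
    matrix is supplied; otherwise true labels default to the identity
    (self-pairs 1, rest 0).
    """
    if not binned:
        raise ValueError("no spectra to score")
    emb = model.embed_many(binned)
    norms = np.linalg.norm(emb, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding produced")
    unit = emb / norms[:, None]
    predicted = unit @ unit.T
    if model.config.clip_predictions:
        predicted = np.clip(predicted, 0.0, 1.0)
    ids = [b.source_id for b in binned]
    if labels is not None:
        keys = [b.compound_key for b in binned]
        for b in binned:
            if b.compound_key is None or b.compound_key not in labels:
                raise ValueError(f"spectrum {b.source_id!r} has no label-matrix compound key")
        index = {k: i for i, k in enumerate(labels.compound_keys)}
        cols = np.array([index[k] for k in keys])
        true = labels.scores[np.ix_(cols, cols)]
    else:
        true = np.eye(len(binned))
    return ScoreMatrix(ids, predicted, true)


def binned_errors(sm: ScoreMatrix, n_bins: int = 10) -> BinnedErrorReport:
    """Per-true-label-bin RMSE and MAE over unique non-self pairs.

    Bins are equal width over [0, 1], last bin closed. Empty bins report
    NaN, never zero.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    predicted, true = sm.offdiag_pairs()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.minimum((true * n_bins).astype(int), n_bins - 1)
    rmse = np.full(n_bins, np.nan)
    mae = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    err = predicted - true
    for b in range(n_bins):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            rmse[b] = float(np.sqrt(np.mean(err[mask] ** 2)))
            mae[b] = float(np.mean(np.abs(err[mask])))
    return BinnedErrorReport(edges, rmse, mae, counts)


def pooled_rmse(sm: ScoreMatrix) -> float:
    predicted, true = sm.offdiag_pairs()
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


def precision_recall_high_similarity(
    sm: ScoreMatrix,
    label_threshold: float = 0.6,
    score_grid: Sequence[float] | None = None,
) -> list[dict]:
    """Precision/recall for retrieving pairs with true label > ``label_threshold``.

    For each grid value X the selection is all unique non-self pairs with
    predicted score > X. Precision over an empty selection is reported as
    None (missing), never 1.
    """
    predicted, true = sm.offdiag_pairs()
    positive = true > label_threshold
    n_pos = int(positive.sum())
    if n_pos == 0 or n_pos == len(true):
        raise ValueError(
            "degenerate label distribution: need pairs both above and below the label threshold"
        )
    if score_grid is None:
        score_grid = np.linspace(0.0, 0.99, 100)
    curve = []
    for x in score_grid:
        selected = predicted > x
        n_sel = int(selected.sum())
        n_hit = int((selected & positive).sum())
        curve.append({
            "score_threshold": float(x),
            "precision": (n_hit / n_sel) if n_sel else None,
            "recall": n_hit / n_pos,
            "n_selected": n_sel,
        })
    return curve


def aggregate_same_compound(
    sm: ScoreMatrix,
    compound_of: Mapping[str, str],
    iqr_threshold: float | None = None,
) -> dict:
    """Median/IQR of predictions per unordered compound-key pair.

    Spectrum self-pairs are excluded; within-compound pairs (same key) are
    aggregated under the (key, key) pair. When ``iqr_threshold`` is given,
    compound pairs with IQR >= threshold are dropped and the retained
    fraction is reported.
    """
    for sid in sm.ids:
        if sid not in compound_of:
            raise ValueError(f"spectrum id {sid!r} missing from compound map")
    samples: dict[tuple[str, str], list[float]] = {}
    truth: dict[tuple[str, str], float] = {}
    m = len(sm.ids)
    for i in range(m):
        for j in range(i + 1, m):
            pair = tuple(sorted((compound_of[sm.ids[i]], compound_of[sm.ids[j]])))
            samples.setdefault(pair, []).append(float(sm.predicted[i, j]))
            truth[pair] = float(sm.true_labels[i, j])
    table = []
    for pair, values in samples.items():
        arr = np.asarray(values)
        q25, q75 = np.quantile(arr, [0.25, 0.75], method="linear")
        table.append({
            "key_a": pair[0],
            "key_b": pair[1],
            "median": float(np.median(arr)),
            "iqr": float(q75 - q25),
            "n_spectrum_pairs": len(values),
            "true_label": truth[pair],
        })
    result = {"table": table, "retained_fraction": 1.0}
    if iqr_threshold is not None:
        retained = [row for row in table if row["iqr"] < iqr_threshold]
        result["table"] = retained
        result["retained_fraction"] = len(retained) / len(table) if table else 1.0
    return result


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
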