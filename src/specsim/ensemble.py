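"""Monte-Carlo-dropout ensembling: per-spectrum embedding draws, per-pair
score distributions, median/IQR summaries and IQR-based filtering.

Embeddings are sampled once per spectrum (``n_draws`` dropout-active forward
passes) and re-used for every pair, so a pair yields ``n_draws**2`` score
samples at the cost of only ``n_draws`` network evaluations per spectrum.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from specsim.binning import BinnedSpectrum
from specsim.model import SiameseModel, SpectrumEmbedding

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    n_draws: int = 10
    dropout_rate_override: float | None = None
    iqr_low: float = 0.25
    iqr_high: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 <= self.iqr_low < self.iqr_high <= 1.0:
            raise ValueError("require 0 <= iqr_low < iqr_high <= 1")


@dataclass
class EnsembleScore:
    median: float
    iqr: float
    n_samples: int
    id_a: str = ""
    id_b: str = ""

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("iqr must be >= 0")


def _spectrum_rng(cfg: EnsembleConfig, source_id: str) -> np.random.Generator:
    # stable per-spectrum stream so score-matrix tilings reproduce
    return np.random.default_rng((cfg.seed, zlib.crc32(source_id.encode())))


def mc_embeddings(model: SiameseModel, b: BinnedSpectrum, cfg: EnsembleConfig) -> list[SpectrumEmbedding]:
    """n_draws dropout-active embeddings of one spectrum, seeded per spectrum id."""
    rng = _spectrum_rng(cfg, b.source_id)
    rate = cfg.dropout_rate_override
    if rate is not None:
        original = [layer.rate for layer in _dropout_layers(model)]
        for layer in _dropout_layers(model):
            layer.rate = rate
    try:
        draws = [model.embed(b, dropout_active=True, rng=rng) for _ in range(cfg.n_draws)]
    finally:
        if rate is not None:
            for layer, r in zip(_dropout_layers(model), original):
                layer.rate = r
    return draws


def _dropout_layers(model: SiameseModel):
    from specsim.model import _Dropout

    return [layer for layer in model.base.layers if isinstance(layer, _Dropout)]


def _draw_matrix(draws: Sequence[SpectrumEmbedding]) -> np.ndarray:
    return np.stack([d.values for d in draws])


def ensemble_score(
    draws_a: Sequence[SpectrumEmbedding],
    draws_b: Sequence[SpectrumEmbedding],
    cfg: EnsembleConfig | None = None,
) -> EnsembleScore:
    """Median and IQR of all n_a * n_b pairwise cosine scores.

    Quantiles use linear interpolation between order statistics. Zero-norm
    draws are skipped with a warning; an all-zero draw set is an error.
    """
    cfg = cfg or EnsembleConfig()
    if not draws_a or not draws_b:
        raise ValueError("empty draw list")
    a = _draw_matrix(draws_a)
    b = _draw_matrix(draws_b)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok_a, ok_b = na > 0, nb > 0
    if not np.all(ok_a) or not np.all(ok_b):
        logger.warning("skipping %d zero-norm embedding draws",
                       int((~ok_a).sum() + (~ok_b).sum()))
    if not np.any(ok_a) or not np.any(ok_b):
        raise ValueError("all embedding draws have zero norm")
    a_unit = a[ok_a] / na[ok_a, None]
    b_unit = b[ok_b] / nb[ok_b, None]
    samples = (a_unit @ b_unit.T).ravel()
    q_low, q_high = np.quantile(samples, [cfg.iqr_low, cfg.iqr_high], method="linear")
    return EnsembleScore(
        median=float(np.median(samples)),
        iqr=float(q_high - q_low),
        n_samples=int(samples.size),
        id_a=draws_a[0].source_id,
        id_b=draws_b[0].source_id,
    )


def mc_all_vs_all(
    model: SiameseModel,
    binned: Sequence[BinnedSpectrum],
    cfg: EnsembleConfig | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Median and IQR matrices over all unique pairs (embeddings drawn once per spectrum)."""
    cfg = cfg or EnsembleConfig()
    draws = [mc_embeddings(model, b, cfg) for b in binned]
    units = []
    for d in draws:
        m = _draw_matrix(d)
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"zero-norm draw for spectrum {d[0].source_id!r}")
        units.append(m / norms[:, None])
    m_count = len(binned)
    medians = np.zeros((m_count, m_count))
    iqrs = np.zeros((m_count, m_count))
    for i in range(m_count):
        for j in range(i, m_count):
            samples = (units[i] @ units[j].T).ravel()
            q_low, q_high = np.quantile(samples, [cfg.iqr_low, cfg.iqr_high], method="linear")
            medians[i, j] = medians[j, i] = np.median(samples)
            iqrs[i, j] = iqrs[j, i] = q_high - q_low
    ids = [b.source_id for b in binned]
    return ids, medians, iqrs


def filter_by_iqr(scores: Sequence[EnsembleScore], threshold: float) -> tuple[list[EnsembleScore], float]:
    """Keep scores with ``iqr < threshold`` (strict); also return the retrieval rate."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not scores:
        raise ValueError("empty score list")
    retained = [s for s in scores if s.iqr < threshold]
    return retained, len(retained) / len(scores)


def write_score_table(scores: Sequence[EnsembleScore], path: str | Path) -> None:
    """Tab-separated ensemble score table: id_a, id_b, median, iqr, n_samples."""
    lines = ["id_a\tid_b\tmedian\tiqr\tn_samples"]
    for s in scores:
        lines.append(f"{s.id_a}\t{s.id_b}\t{s.median!r}\t{s.iqr!r}\t{s.n_samples}")
    Path(path).write_text("\n".join(lines) + "\n")
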