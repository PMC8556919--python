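"""Balanced spectrum-pair generation with on-the-fly augmentation.

The all-pairs structural-similarity distribution is heavily skewed towards
low scores, so training pairs are drawn per anchor spectrum by first picking
a similarity-score bin uniformly at random and then a partner compound whose
label with the anchor falls inside the (iteratively widened) bin. This
flattens the label histogram the network sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from specsim.binning import BinnedSpectrum
from specsim.labels import SimilarityLabelMatrix


@dataclass
class AugmentationConfig:
    """Magnitudes of the three augmentation operators.

    (1) low-intensity peak removal: a random fraction (up to
    ``removal_max_fraction``) of the non-zero bins whose *pre-transform*
    intensity is below ``removal_intensity_ceiling`` is zeroed.
    (2) intensity jitter: every remaining non-zero bin is scaled by a factor
    uniform in ``1 +/- jitter_max_fraction``.
    (3) new peak addition: up to ``max_new_peaks`` zero bins get a value
    uniform in ``(0, new_peak_intensity_ceiling]``.
    """

    removal_max_fraction: float = 0.2
    removal_intensity_ceiling: float = 0.4
    jitter_max_fraction: float = 0.4
    max_new_peaks: int = 10
    new_peak_intensity_ceiling: float = 0.01

    def __post_init__(self) -> None:
        for name in ("removal_max_fraction", "removal_intensity_ceiling", "jitter_max_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_new_peaks < 0:
            raise ValueError("max_new_peaks must be >= 0")
        if self.new_peak_intensity_ceiling < 0:
            raise ValueError("new_peak_intensity_ceiling must be >= 0")


@dataclass
class GeneratorConfig:
    n_score_bins: int = 10
    widen_step: float = 0.1
    batch_size: int = 32
    shuffle_seed: int | None = None
    cycles_per_epoch: int = 1
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    augmentation_enabled: bool = True
    compound_uniform: bool = True  # False: uniform over eligible spectra instead

    def __post_init__(self) -> None:
        if self.n_score_bins < 1:
            raise ValueError("n_score_bins must be >= 1")
        if self.widen_step <= 0:
            raise ValueError("widen_step must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cycles_per_epoch < 1:
            raise ValueError("cycles_per_epoch must be >= 1")


@dataclass
class SpectrumPair:
    binned_a: BinnedSpectrum
    binned_b: BinnedSpectrum
    label: float
    # similarity interval actually used for the draw, after widening
    bin_used: tuple[float, float] | None = None


def augment(
    b: BinnedSpectrum,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    pre_transform_values: np.ndarray | None = None,
) -> BinnedSpectrum:
    """Apply removal -> jitter -> addition to one binned spectrum.

    ``pre_transform_values`` defaults to ``b.pre_transform``; bins with a
    pre-transform intensity at or above the removal ceiling are never removed.
    """
    pre = pre_transform_values if pre_transform_values is not None else b.pre_transform
    if pre is None:
        pre = np.square(b.values)
    pre = np.asarray(pre, dtype=float)
    if pre.shape != b.values.shape:
        raise ValueError("pre_transform_values must be aligned with b.values")
    values = b.values.copy()

    # (1) low-intensity peak removal
    candidates = np.flatnonzero((values > 0) & (pre < cfg.removal_intensity_ceiling))
    if len(candidates) and cfg.removal_max_fraction > 0:
        fraction = rng.uniform(0.0, cfg.removal_max_fraction)
        n_remove = int(round(fraction * len(candidates)))
        if n_remove:
            values[rng.choice(candidates, size=n_remove, replace=False)] = 0.0

    # (2) peak intensity jitter (multiplicative, clipped at zero)
    nonzero = values > 0
    if np.any(nonzero) and cfg.jitter_max_fraction > 0:
        factors = rng.uniform(1.0 - cfg.jitter_max_fraction, 1.0 + cfg.jitter_max_fraction, size=int(nonzero.sum()))
        values[nonzero] = np.clip(values[nonzero] * factors, 0.0, None)

    # (3) new peak addition
    zeros = np.flatnonzero(values == 0)
    if len(zeros) and cfg.max_new_peaks > 0 and cfg.new_peak_intensity_ceiling > 0:
        n_new = int(rng.integers(0, min(cfg.max_new_peaks, len(zeros)) + 1))
        if n_new:
            chosen = rng.choice(zeros, size=n_new, replace=False)
            # uniform in (0, ceiling]
            values[chosen] = cfg.new_peak_intensity_ceiling * (1.0 - rng.random(n_new))

    return BinnedSpectrum(
        values=values,
        pre_transform=b.pre_transform,
        missing_fraction=b.missing_fraction,
        source_id=b.source_id,
        compound_key=b.compound_key,
    )


class PairGenerator:
    """Streams balanced, optionally augmented batches of spectrum pairs.

    Every spectrum in the pool acts as anchor exactly once per cycle
    (shuffled order); an anchor is never paired with itself but may be
    paired with another spectrum of its own compound (realizing labels of
    1.0).
    """

    def __init__(
        self,
        binned: Sequence[BinnedSpectrum],
        labels: SimilarityLabelMatrix,
        cfg: GeneratorConfig | None = None,
        seed: int | None = None,
    ):
        if not binned:
            raise ValueError("empty spectrum pool")
        self.binned = list(binned)
        self.labels = labels
        self.cfg = cfg or GeneratorConfig()
        self.seed = seed if seed is not None else self.cfg.shuffle_seed
        for b in self.binned:
            if b.compound_key is None:
                raise ValueError(f"binned spectrum {b.source_id!r} has no compound key")
            if b.compound_key not in labels:
                raise ValueError(f"compound key {b.compound_key!r} missing from label matrix")
        self.compound_keys = sorted({b.compound_key for b in self.binned})
        self._spectra_of = {key: [] for key in self.compound_keys}
        for i, b in enumerate(self.binned):
            self._spectra_of[b.compound_key].append(i)
        self._members = {k: np.asarray(v) for k, v in self._spectra_of.items()}
        self._n_members = np.array([len(self._members[k]) for k in self.compound_keys])
        # label rows restricted to the pool's compounds, in compound_keys order
        full_index = {k: i for i, k in enumerate(labels.compound_keys)}
        cols = np.array([full_index[k] for k in self.compound_keys])
        self._pool_labels = labels.scores[np.ix_(cols, cols)]
        self._key_pos = {k: i for i, k in enumerate(self.compound_keys)}

    # -- sampling ----------------------------------------------------------

    def _bin_edges(self, bin_index: int) -> tuple[float, float]:
        n = self.cfg.n_score_bins
        return bin_index / n, (bin_index + 1) / n

    def sample_partner(self, anchor_index: int, rng: np.random.Generator) -> SpectrumPair:
        """Draw a partner for one anchor spectrum under bin balancing."""
        anchor = self.binned[anchor_index]
        a_pos = self._key_pos[anchor.compound_key]
        row = self._pool_labels[a_pos]
        last_bin = self.cfg.n_score_bins - 1

        # a compound is a valid partner source if it has a spectrum != anchor
        own = np.ones(len(self.compound_keys), dtype=bool)
        if self._n_members[a_pos] == 1:
            own[a_pos] = False

        bin_index = int(rng.integers(0, self.cfg.n_score_bins))
        lo, hi = self._bin_edges(bin_index)
        closed_hi = bin_index == last_bin
        while True:
            if closed_hi or hi >= 1.0:
                in_bin = (row >= lo) & (row <= min(hi, 1.0))
            else:
                in_bin = (row >= lo) & (row < hi)
            eligible = np.flatnonzero(in_bin & own)
            if len(eligible):
                break
            if lo <= 0.0 and hi >= 1.0:
                raise ValueError("no valid partner exists for anchor "
                                 f"{anchor.source_id!r}")
            lo = max(0.0, lo - self.cfg.widen_step)
            hi = min(1.0, hi + self.cfg.widen_step)
            closed_hi = True

        if self.cfg.compound_uniform:
            partner_pos = int(rng.choice(eligible))
        else:
            # spectrum-uniform mode: weight compounds by eligible spectrum count
            weights = self._n_members[eligible].astype(float)
            if a_pos in eligible:
                weights[np.searchsorted(eligible, a_pos)] -= 1.0
            weights /= weights.sum()
            partner_pos = int(rng.choice(eligible, p=weights))

        members = self._members[self.compound_keys[partner_pos]]
        if partner_pos == a_pos:
            members = members[members != anchor_index]
        partner_index = int(rng.choice(members))
        label = float(row[partner_pos])
        return SpectrumPair(anchor, self.binned[partner_index], label, bin_used=(lo, min(hi, 1.0)))

    # -- epoch streaming ---------------------------------------------------

    def n_pairs_per_epoch(self) -> int:
        return len(self.binned) * self.cfg.cycles_per_epoch

    def epoch(self, epoch_index: int = 0) -> Iterator[list[SpectrumPair]]:
        """Yield batches for one epoch; deterministic given (seed, epoch_index)."""
        seed = self.seed if self.seed is not None else None
        rng = (
            np.random.default_rng((seed, epoch_index))
            if seed is not None
            else np.random.default_rng()
        )
        batch: list[SpectrumPair] = []
        for _ in range(self.cfg.cycles_per_epoch):
            order = rng.permutation(len(self.binned))
            for anchor_index in order:
                pair = self.sample_partner(int(anchor_index), rng)
                if self.cfg.augmentation_enabled:
                    pair = SpectrumPair(
                        augment(pair.binned_a, self.cfg.augmentation, rng),
                        augment(pair.binned_b, self.cfg.augmentation, rng),
                        pair.label,
                        pair.bin_used,
                    )
                batch.append(pair)
                if len(batch) == self.cfg.batch_size:
                    yield batch
                    batch = []
        if batch:
            yield batch


def stack_batch(batch: Sequence[SpectrumPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch of pairs -> (X_a, X_b, labels) arrays for the network."""
    xa = np.stack([p.binned_a.values for p in batch])
    xb = np.stack([p.binned_b.values for p in batch])
    y = np.array([p.label for p in batch], dtype=float)
    return xa, xb, y
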