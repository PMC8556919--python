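"""Peak filtering, intensity transform and fixed-grid binning.

The model input is a fixed-length vector over a uniform m/z grid
(default 10,000 bins from 10 to 1000 Da) reduced to the bins that were
occupied at least once in the training corpus ("known bins"). The fixed
processing order is: select -> filter_peaks -> normalize_and_transform ->
bin_spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from specsim.spectra_io import Spectrum

SCHEME_VERSION = "specsim-binning-1"


@dataclass
class BinningScheme:
    """Uniform m/z grid plus the subset of bins known to a model.

    Bins are half-open ``[left, right)``: a peak at exactly ``mz_max``
    falls outside the grid.
    """

    n_bins_total: int = 10_000
    mz_min: float = 10.0
    mz_max: float = 1000.0
    known_bins: np.ndarray = field(default_factory=lambda: np.arange(10_000))
    version_tag: str = SCHEME_VERSION

    def __post_init__(self) -> None:
        self.known_bins = np.asarray(self.known_bins, dtype=np.int64)
        if self.n_bins_total < 1:
            raise ValueError("n_bins_total must be >= 1")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if len(self.known_bins):
            if np.any(np.diff(self.known_bins) <= 0):
                raise ValueError("known_bins must be strictly increasing")
            if self.known_bins[0] < 0 or self.known_bins[-1] >= self.n_bins_total:
                raise ValueError("known_bins out of range")

    @property
    def bin_width(self) -> float:
        return (self.mz_max - self.mz_min) / self.n_bins_total

    @property
    def n_known(self) -> int:
        return int(len(self.known_bins))

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Grid bin index per m/z value; -1 for out-of-range peaks."""
        mz = np.asarray(mz, dtype=float)
        idx = np.floor((mz - self.mz_min) / self.bin_width).astype(np.int64)
        idx[(mz < self.mz_min) | (mz >= self.mz_max)] = -1
        return idx

    def known_position(self) -> np.ndarray:
        """Lookup table: grid bin index -> position in known_bins, -1 if unknown."""
        table = np.full(self.n_bins_total, -1, dtype=np.int64)
        table[self.known_bins] = np.arange(self.n_known)
        return table

    def to_dict(self) -> dict:
        return {
            "n_bins_total": self.n_bins_total,
            "mz_min": self.mz_min,
            "mz_max": self.mz_max,
            "known_bins": self.known_bins.tolist(),
            "version_tag": self.version_tag,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(
            n_bins_total=int(d["n_bins_total"]),
            mz_min=float(d["mz_min"]),
            mz_max=float(d["mz_max"]),
            known_bins=np.asarray(d["known_bins"], dtype=np.int64),
            version_tag=str(d.get("version_tag", SCHEME_VERSION)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BinningScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class BinnedSpectrum:
    """Fixed-length model input vector over a scheme's known bins.

    ``values`` holds square-root-transformed, max-normalized intensities
    (hence in [0, 1]); ``pre_transform`` holds the aligned normalized
    intensities before the square root, used by the augmentation stage.
    ``missing_fraction`` is the share of total transformed intensity that
    fell into unknown or out-of-range bins.
    """

    values: np.ndarray
    source_id: str
    missing_fraction: float = 0.0
    pre_transform: np.ndarray | None = None
    compound_key: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("binned values must be >= 0")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")
        if self.pre_transform is not None:
            self.pre_transform = np.asarray(self.pre_transform, dtype=float)
            if self.pre_transform.shape != self.values.shape:
                raise ValueError("pre_transform must be aligned with values")


def filter_peaks(s: Spectrum, rel_threshold: float = 0.001, max_peaks: int = 1000) -> Spectrum:
    """Drop peaks below ``rel_threshold`` of the maximum intensity, then keep
    at most the ``max_peaks`` highest-intensity peaks (m/z order preserved)."""
    if s.n_peaks == 0:
        raise ValueError(f"spectrum {s.identifier!r} has no peaks to filter")
    if not 0.0 <= rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in [0, 1)")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    keep = s.intensities >= rel_threshold * s.intensities.max()
    mz, intensities = s.mz[keep], s.intensities[keep]
    if len(mz) > max_peaks:
        # stable sort keeps the lower-m/z peak on intensity ties
        top = np.sort(np.argsort(intensities, kind="stable")[::-1][:max_peaks])
        mz, intensities = mz[top], intensities[top]
    return s.clone(mz=mz, intensities=intensities, raw_normalized=None)


def normalize_and_transform(s: Spectrum) -> Spectrum:
    """Normalize intensities to unit maximum, then square-root transform.

    The pre-transform normalized intensities are retained on the returned
    spectrum (``raw_normalized``) for the augmentation stage.
    """
    if s.n_peaks == 0:
        raise ValueError(f"spectrum {s.identifier!r} has no peaks")
    peak_max = s.intensities.max()
    if peak_max <= 0:
        raise ValueError(f"spectrum {s.identifier!r} has no positive intensity")
    normalized = s.intensities / peak_max
    return s.clone(intensities=np.sqrt(normalized), raw_normalized=normalized)


def fit_binning(
    training_spectra: Iterable[Spectrum],
    n_bins_total: int = 10_000,
    mz_min: float = 10.0,
    mz_max: float = 1000.0,
) -> BinningScheme:
    """Determine the known bins as those occupied by at least one training peak."""
    scheme = BinningScheme(n_bins_total, mz_min, mz_max, known_bins=np.arange(n_bins_total))
    occupied = np.zeros(n_bins_total, dtype=bool)
    for s in training_spectra:
        idx = scheme.bin_index(s.mz)
        occupied[idx[idx >= 0]] = True
    known = np.flatnonzero(occupied)
    if len(known) == 0:
        raise ValueError("no training peaks fall inside the binning range")
    return BinningScheme(n_bins_total, mz_min, mz_max, known_bins=known)


def bin_spectrum(s: Spectrum, scheme: BinningScheme) -> BinnedSpectrum:
    """Project a filtered, transformed spectrum onto the scheme's known bins.

    Multiple peaks in one bin are max-pooled. Peaks outside the m/z range or
    in unknown bins are dropped; their transformed intensity accumulates into
    ``missing_fraction`` (relative to the spectrum's total transformed
    intensity).
    """
    values = np.zeros(scheme.n_known)
    pre = np.zeros(scheme.n_known)
    raw_normalized = (
        s.raw_normalized if s.raw_normalized is not None else np.square(s.intensities)
    )
    total = float(s.intensities.sum())
    idx = scheme.bin_index(s.mz)
    pos_table = scheme.known_position()
    pos = np.where(idx >= 0, pos_table[idx], -1)
    missing = 0.0
    for p, inten, pre_val in zip(pos, s.intensities, raw_normalized):
        if p < 0:
            missing += float(inten)
        elif inten > values[p]:
            values[p] = inten
            pre[p] = pre_val
    missing_fraction = missing / total if total > 0 else (1.0 if s.n_peaks else 0.0)
    return BinnedSpectrum(
        values=values,
        pre_transform=pre,
        missing_fraction=min(missing_fraction, 1.0),
        source_id=s.identifier,
        compound_key=s.compound_key,
    )


def bin_pipeline(
    spectra: Sequence[Spectrum],
    scheme: BinningScheme,
    rel_threshold: float = 0.001,
    max_peaks: int = 1000,
) -> list[BinnedSpectrum]:
    """filter_peaks -> normalize_and_transform -> bin_spectrum for a batch."""
    return [
        bin_spectrum(normalize_and_transform(filter_peaks(s, rel_threshold, max_peaks)), scheme)
        for s in spectra
    ]
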