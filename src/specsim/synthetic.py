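"""Synthetic compound libraries with a planted spectrum-fingerprint link.

Clusters of binary fingerprints are generated by mutating per-cluster seed
patterns; each active bit maps deterministically (seeded hash) to a small
set of fragment m/z values, and replicate spectra are noisy realizations of
a compound's fragment set. Fingerprint similarity and binned-spectrum
overlap are therefore correlated by construction, which makes the whole
pipeline — including model training — exercisable at desk scale without any
external corpus.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from specsim.labels import MolecularFingerprint
from specsim.spectra_io import Spectrum, write_spectra

_LETTERS = np.array(list(string.ascii_uppercase))


@dataclass
class SyntheticConfig:
    n_clusters: int = 20
    members_per_cluster: int = 5
    fp_bits: int = 256
    bit_density: float = 0.2
    mutation_rate: float = 0.03
    fragments_per_bit: int = 1
    mz_min: float = 10.0
    mz_max: float = 1000.0
    spectra_per_compound: int = 3
    intensity_noise_sd: float = 0.1
    n_noise_peaks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "members_per_cluster", "fp_bits", "fragments_per_bit",
                     "spectra_per_compound"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("bit_density", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_noise_peaks < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise settings must be >= 0")


@dataclass
class SyntheticCompound:
    key: str  # 14-character identifier (InChIKey-prefix shaped)
    fingerprint: MolecularFingerprint
    fragment_mzs: np.ndarray

    @property
    def inchikey(self) -> str:
        """Full 27-character key (deterministic filler blocks)."""
        return f"{self.key}-{'A' * 10}-N"


def _fragment_mz(bit: int, j: int, seed: int, mz_min: float, mz_max: float) -> float:
    # splitmix-style integer hash keeps fragments deterministic per (bit, j, seed)
    h = (bit * 0x9E3779B97F4A7C15 + j * 0xBF58476D1CE4E5B9 + seed * 0x94D049BB133111EB) % (2**64)
    h ^= h >> 31
    h = (h * 0xD6E8FEB86659FD93) % (2**64)
    frac = (h % 10_000_019) / 10_000_019
    return mz_min + frac * (mz_max - mz_min) * 0.999  # keep inside [mz_min, mz_max)


def _make_key(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_LETTERS, size=14))


def generate_compounds(cfg: SyntheticConfig) -> list[SyntheticCompound]:
    """Clustered fingerprints plus deterministic bit->fragment m/z maps."""
    rng = np.random.default_rng(cfg.seed)
    compounds: list[SyntheticCompound] = []
    keys_seen: set[str] = set()
    for _ in range(cfg.n_clusters):
        seed_bits = (rng.random(cfg.fp_bits) < cfg.bit_density).astype(np.uint8)
        for _ in range(cfg.members_per_cluster):
            flips = rng.random(cfg.fp_bits) < cfg.mutation_rate
            bits = np.where(flips, 1 - seed_bits, seed_bits).astype(np.uint8)
            if not bits.any():
                bits[int(rng.integers(cfg.fp_bits))] = 1
            key = _make_key(rng)
            while key in keys_seen:
                key = _make_key(rng)
            keys_seen.add(key)
            fragments = np.array(sorted(
                _fragment_mz(int(bit), j, cfg.seed, cfg.mz_min, cfg.mz_max)
                for bit in np.flatnonzero(bits)
                for j in range(cfg.fragments_per_bit)
            ))
            compounds.append(SyntheticCompound(
                key=key,
                fingerprint=MolecularFingerprint(bits, fp_type="synthetic", n_bits=cfg.fp_bits),
                fragment_mzs=fragments,
            ))
    return compounds


def generate_spectra(compounds: Sequence[SyntheticCompound], cfg: SyntheticConfig) -> list[Spectrum]:
    """Replicate spectra per compound: fragment peaks with log-normal intensity
    noise plus a few low-intensity uniform noise peaks."""
    if not compounds:
        raise ValueError("no compounds given")
    rng = np.random.default_rng((cfg.seed, 1))
    spectra: list[Spectrum] = []
    for compound in compounds:
        n_frag = len(compound.fragment_mzs)
        # deterministic per-compound base intensities in [0.2, 1.0]
        base_rng = np.random.default_rng((cfg.seed, zlib_crc(compound.key)))
        base = 0.2 + 0.8 * base_rng.random(n_frag)
        for r in range(cfg.spectra_per_compound):
            if cfg.intensity_noise_sd > 0:
                noise = rng.lognormal(mean=0.0, sigma=cfg.intensity_noise_sd, size=n_frag)
            else:
                noise = np.ones(n_frag)
            mz = compound.fragment_mzs.copy()
            intensities = base * noise
            if cfg.n_noise_peaks > 0:
                noise_mz = rng.uniform(cfg.mz_min, cfg.mz_max, size=cfg.n_noise_peaks)
                noise_int = rng.uniform(0.005, 0.05, size=cfg.n_noise_peaks) * intensities.max()
                mz = np.concatenate([mz, noise_mz])
                intensities = np.concatenate([intensities, noise_int])
            spectra.append(Spectrum(
                identifier=f"{compound.key}_r{r}",
                mz=mz,
                intensities=intensities,
                smiles=f"*{compound.key}",  # placeholder, fingerprints are precomputed
                inchikey=compound.inchikey,
                ionmode="positive",
                precursor_mz=float(mz.max()) + 1.0,
            ))
    return spectra


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


def fingerprints_of(compounds: Sequence[SyntheticCompound]) -> dict[str, MolecularFingerprint]:
    return {c.key: c.fingerprint for c in compounds}


def write_fixture(
    compounds: Sequence[SyntheticCompound],
    spectra: Sequence[Spectrum],
    mgf_path: str | Path,
    fingerprint_path: str | Path,
) -> None:
    """Write an MGF spectrum file plus a key -> active-bit-list JSON sidecar."""
    write_spectra(spectra, mgf_path, fmt="mgf")
    sidecar = {
        "n_bits": compounds[0].fingerprint.n_bits if compounds else 0,
        "fingerprints": {c.key: c.fingerprint.on_bits.tolist() for c in compounds},
    }
    Path(fingerprint_path).write_text(json.dumps(sidecar))


def load_fingerprint_sidecar(path: str | Path) -> dict[str, MolecularFingerprint]:
    data = json.loads(Path(path).read_text())
    n_bits = int(data["n_bits"])
    out = {}
    for key, on_bits in data["fingerprints"].items():
        bits = np.zeros(n_bits, dtype=np.uint8)
        bits[np.asarray(on_bits, dtype=int)] = 1
        out[key] = MolecularFingerprint(bits, fp_type="synthetic", n_bits=n_bits)
    return out
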