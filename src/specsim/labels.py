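"""Compound-level structural-similarity label matrices from molecular fingerprints.

Spectra are grouped by the first 14 InChIKey characters (2D structure,
stereochemistry ignored); per group the modal structure string is
fingerprinted and all pairwise Tanimoto or Dice scores form the symmetric
label matrix used to supervise training.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from specsim.spectra_io import Spectrum

FP_TYPES = ("daylight", "morgan2", "morgan3")
METRICS = ("tanimoto", "dice")


@dataclass
class MolecularFingerprint:
    """Fixed-length binary substructure vector."""

    bits: np.ndarray
    fp_type: str
    n_bits: int = 2048

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if len(self.bits) != self.n_bits:
            raise ValueError(f"fingerprint length {len(self.bits)} != n_bits {self.n_bits}")

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class SimilarityLabelMatrix:
    """Symmetric compound-by-compound structural-similarity scores in [0, 1]."""

    compound_keys: list[str]
    scores: np.ndarray
    metric: str = "tanimoto"
    fp_type: str = "daylight"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        k = len(self.compound_keys)
        if self.scores.shape != (k, k):
            raise ValueError("scores shape must match number of compound keys")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("label matrix must be symmetric")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("label scores must lie in [0, 1]")
        self._index = {key: i for i, key in enumerate(self.compound_keys)}

    def label(self, key_a: str, key_b: str) -> float:
        return float(self.scores[self._index[key_a], self._index[key_b]])

    def row(self, key: str) -> np.ndarray:
        return self.scores[self._index[key]]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def save(self, path: str | Path) -> None:
        """Persist as a .npz matrix plus a JSON key sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), scores=self.scores)
        sidecar = {
            "compound_keys": self.compound_keys,
            "metric": self.metric,
            "fp_type": self.fp_type,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityLabelMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        scores = np.load(path.with_suffix(".npz"))["scores"]
        return cls(sidecar["compound_keys"], scores, sidecar["metric"], sidecar["fp_type"])


def group_by_compound(spectra: Sequence[Spectrum]) -> dict[str, list[Spectrum]]:
    """Partition spectra by the first 14 InChIKey characters."""
    groups: dict[str, list[Spectrum]] = {}
    for s in spectra:
        if s.inchikey is None:
            raise ValueError(f"spectrum {s.identifier!r} has no InChIKey")
        groups.setdefault(s.inchikey[:14], []).append(s)
    return groups


def select_representative_structure(group: Sequence[Spectrum]) -> str:
    """Most common structure string in the group; lexicographic tie-break."""
    if not group:
        raise ValueError("empty compound group")
    structures = []
    for s in group:
        if s.structure is None:
            raise ValueError(f"spectrum {s.identifier!r} has no structure annotation")
        structures.append(s.structure)
    counts = Counter(structures)
    best = max(counts)  # seed with a real key
    best_n = counts[best]
    for structure, n in counts.items():
        if n > best_n or (n == best_n and structure < best):
            best, best_n = structure, n
    return best


def _mol_from_structure(structure: str):
    from rdkit import Chem

    if not structure:
        return None
    if structure.startswith("InChI="):
        return Chem.MolFromInchi(structure)
    return Chem.MolFromSmiles(structure)


def compute_fingerprint(structure: str, fp_type: str = "daylight", n_bits: int = 2048) -> MolecularFingerprint:
    """Binary fingerprint of a SMILES or InChI string.

    ``daylight`` is the RDKit topological (path-based) fingerprint; morgan2 /
    morgan3 are circular fingerprints of radius 2 / 3. Bit patterns are
    toolkit-specific; the structure is canonicalized by the toolkit's own
    parser, so different spellings of one molecule yield identical bits.
    """
    if fp_type not in FP_TYPES:
        raise ValueError(f"unknown fingerprint type {fp_type!r}")
    mol = _mol_from_structure(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    from rdkit.Chem import rdFingerprintGenerator

    if fp_type == "daylight":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    else:
        radius = 2 if fp_type == "morgan2" else 3
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return MolecularFingerprint(arr, fp_type=fp_type, n_bits=n_bits)


def _check_compatible(a: MolecularFingerprint, b: MolecularFingerprint) -> None:
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")


def tanimoto(a: MolecularFingerprint, b: MolecularFingerprint) -> float:
    """|a AND b| / |a OR b|; a pair of all-zero fingerprints scores 0.0."""
    _check_compatible(a, b)
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    return inter / union if union else 0.0


def dice(a: MolecularFingerprint, b: MolecularFingerprint) -> float:
    """2|a AND b| / (|a| + |b|); a pair of all-zero fingerprints scores 0.0."""
    _check_compatible(a, b)
    inter = int(np.count_nonzero(a.bits & b.bits))
    total = int(np.count_nonzero(a.bits)) + int(np.count_nonzero(b.bits))
    return 2 * inter / total if total else 0.0


def build_label_matrix_from_fingerprints(
    fingerprints: Mapping[str, MolecularFingerprint],
    metric: str = "tanimoto",
) -> SimilarityLabelMatrix:
    """Pairwise similarity matrix over precomputed fingerprints (vectorized)."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    keys = list(fingerprints)
    if not keys:
        raise ValueError("no fingerprints given")
    fp_type = fingerprints[keys[0]].fp_type
    bits = np.stack([fingerprints[k].bits for k in keys]).astype(np.float64)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    if metric == "tanimoto":
        denom = counts[:, None] + counts[None, :] - inter
        scores = np.divide(inter, denom, out=np.zeros_like(inter), where=denom > 0)
    else:
        denom = counts[:, None] + counts[None, :]
        scores = np.divide(2 * inter, denom, out=np.zeros_like(inter), where=denom > 0)
    np.fill_diagonal(scores, 1.0)
    return SimilarityLabelMatrix(keys, scores, metric=metric, fp_type=fp_type)


def build_label_matrix(
    groups: Mapping[str, Sequence[Spectrum]],
    fp_type: str = "daylight",
    metric: str = "tanimoto",
    n_bits: int = 2048,
) -> SimilarityLabelMatrix:
    """Label matrix over compound groups: modal structure -> fingerprint -> metric."""
    fingerprints = {
        key: compute_fingerprint(select_representative_structure(group), fp_type, n_bits)
        for key, group in groups.items()
    }
    return build_label_matrix_from_fingerprints(fingerprints, metric=metric)
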