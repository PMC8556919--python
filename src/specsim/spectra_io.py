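"""Reading, writing and selection of annotated MS/MS spectra.

Supported text dialects are MGF (``BEGIN IONS``/``END IONS`` blocks), MSP
(``Name:``/``Num Peaks:`` records) and an internal JSON interchange format
(a list of objects with a ``peaks_json`` entry plus a flat metadata map).
Metadata keys are treated case-insensitively on input.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

_IONMODES = ("positive", "negative", "unknown")


@dataclass
class Spectrum:
    """One MS/MS spectrum: a peak list plus structure/ion-mode metadata.

    Peaks are stored sorted ascending by m/z; construction enforces
    ``mz > 0`` and ``intensity >= 0``.
    """

    identifier: str
    mz: np.ndarray
    intensities: np.ndarray
    smiles: str | None = None
    inchi: str | None = None
    inchikey: str | None = None
    ionmode: str = "unknown"
    precursor_mz: float | None = None
    metadata: dict = field(default_factory=dict)
    # pre-sqrt normalized intensities, populated by normalize_and_transform
    raw_normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.shape != self.intensities.shape:
            raise ValueError("mz and intensities must have equal length")
        if np.any(self.mz <= 0):
            raise ValueError(f"spectrum {self.identifier!r}: all m/z must be > 0")
        if np.any(self.intensities < 0):
            raise ValueError(f"spectrum {self.identifier!r}: intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensities = self.intensities[order]
            if self.raw_normalized is not None:
                self.raw_normalized = np.asarray(self.raw_normalized, dtype=float)[order]
        if self.ionmode not in _IONMODES:
            self.ionmode = "unknown"
        if self.inchikey is not None and not INCHIKEY_RE.match(self.inchikey):
            logger.warning(
                "spectrum %r: InChIKey %r does not match the 14-10-1 layout; dropping it",
                self.identifier,
                self.inchikey,
            )
            self.inchikey = None

    @property
    def n_peaks(self) -> int:
        return int(len(self.mz))

    @property
    def structure(self) -> str | None:
        """SMILES if present, else InChI, else None."""
        return self.smiles if self.smiles else (self.inchi if self.inchi else None)

    @property
    def compound_key(self) -> str | None:
        """First 14 characters of the InChIKey (2D structure, no stereochemistry)."""
        return self.inchikey[:14] if self.inchikey else None

    def clone(self, **changes) -> "Spectrum":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# parsing helpers

_META_KEYS = {
    "smiles": "smiles",
    "inchi": "inchi",
    "inchikey": "inchikey",
    "inchikey_inchi": "inchikey",
    "ionmode": "ionmode",
    "ion_mode": "ionmode",
    "pepmass": "precursor_mz",
    "precursor_mz": "precursor_mz",
    "precursormz": "precursor_mz",
    "title": "identifier",
    "spectrum_id": "identifier",
    "name": "identifier",
}


def _build_spectrum(peaks: list[tuple[float, float]], meta: dict, fallback_id: str) -> Spectrum:
    canonical: dict = {}
    extra: dict = {}
    for raw_key, value in meta.items():
        key = raw_key.strip().lower()
        if key in _META_KEYS:
            canonical[_META_KEYS[key]] = value
        else:
            extra[key] = value
    precursor = canonical.get("precursor_mz")
    if precursor is not None:
        try:
            precursor = float(str(precursor).split()[0])
        except ValueError:
            precursor = None
    ionmode = str(canonical.get("ionmode", "unknown")).strip().lower()
    peaks_arr = np.array(peaks, dtype=float).reshape(-1, 2)
    return Spectrum(
        identifier=str(canonical.get("identifier", fallback_id)),
        mz=peaks_arr[:, 0],
        intensities=peaks_arr[:, 1],
        smiles=canonical.get("smiles") or None,
        inchi=canonical.get("inchi") or None,
        inchikey=canonical.get("inchikey") or None,
        ionmode=ionmode if ionmode in _IONMODES else "unknown",
        precursor_mz=precursor,
        metadata=extra,
    )


def _parse_mgf(text: str) -> Iterable[Spectrum]:
    n_bad = 0
    blocks = re.findall(r"BEGIN IONS(.*?)END IONS", text, flags=re.S | re.I)
    for i, block in enumerate(blocks):
        meta: dict = {}
        peaks: list[tuple[float, float]] = []
        try:
            for line in block.strip().splitlines():
                line = line.strip()
                if not line:
                    continue
                if "=" in line and not line[0].isdigit():
                    key, _, value = line.partition("=")
                    meta[key] = value.strip()
                else:
                    parts = line.split()
                    peaks.append((float(parts[0]), float(parts[1])))
            yield _build_spectrum(peaks, meta, fallback_id=f"spectrum_{i}")
        except (ValueError, IndexError) as exc:
            n_bad += 1
            logger.warning("skipping malformed MGF record %d: %s", i, exc)
    if n_bad:
        logger.warning("skipped %d malformed MGF record(s)", n_bad)


def _parse_msp(text: str) -> Iterable[Spectrum]:
    n_bad = 0
    # records start at a "Name:" line
    records = re.split(r"(?im)^(?=name\s*:)", text)
    index = 0
    for record in records:
        if not record.strip():
            continue
        meta: dict = {}
        peaks: list[tuple[float, float]] = []
        in_peaks = False
        try:
            for line in record.splitlines():
                line = line.strip()
                if not line:
                    continue
                if not in_peaks and ":" in line and not line[0].isdigit():
                    key, _, value = line.partition(":")
                    key_l = key.strip().lower()
                    if key_l in ("num peaks", "numpeaks"):
                        in_peaks = True
                        continue
                    if key_l == "comments":
                        # Comments may embed quoted "key=value" entries
                        for m in re.finditer(r'"([^"=]+)=([^"]*)"', value):
                            meta[m.group(1)] = m.group(2)
                        meta[key.strip()] = value.strip()
                    else:
                        meta[key.strip()] = value.strip()
                else:
                    for pair in re.split(r"[;]", line):
                        parts = pair.split()
                        if len(parts) >= 2:
                            peaks.append((float(parts[0]), float(parts[1])))
            yield _build_spectrum(peaks, meta, fallback_id=f"spectrum_{index}")
        except (ValueError, IndexError) as exc:
            n_bad += 1
            logger.warning("skipping malformed MSP record %d: %s", index, exc)
        index += 1
    if n_bad:
        logger.warning("skipped %d malformed MSP record(s)", n_bad)


def _parse_json(text: str) -> Iterable[Spectrum]:
    data = json.loads(text)
    if not isinstance(data, list):
        raise ValueError("JSON spectrum file must contain a list of objects")
    n_bad = 0
    for i, obj in enumerate(data):
        try:
            peaks = obj["peaks_json"]
            if isinstance(peaks, str):
                peaks = json.loads(peaks)
            meta = {k: v for k, v in obj.items() if k != "peaks_json" and v is not None}
            yield _build_spectrum([(float(p[0]), float(p[1])) for p in peaks], meta, f"spectrum_{i}")
        except (KeyError, ValueError, IndexError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed JSON record %d: %s", i, exc)
    if n_bad:
        logger.warning("skipped %d malformed JSON record(s)", n_bad)


_PARSERS = {"mgf": _parse_mgf, "msp": _parse_msp, "json": _parse_json}


def read_spectra(path: str | Path, fmt: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF, MSP or JSON file.

    Parameters
    ----------
    path
        Input file path.
    fmt
        One of ``mgf``, ``msp``, ``json``. Inferred from the file suffix
        when omitted.

    Malformed records are skipped with a logged warning; records with zero
    peaks are retained (later selection stages remove them).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _PARSERS:
        raise ValueError(f"unknown spectrum format {fmt!r}; expected one of {sorted(_PARSERS)}")
    text = path.read_text()
    return list(_PARSERS[fmt](text))


def write_spectra(spectra: Sequence[Spectrum], path: str | Path, fmt: str | None = None) -> None:
    """Write spectra to MGF, MSP or internal JSON."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mgf":
        lines = []
        for s in spectra:
            lines.append("BEGIN IONS")
            lines.append(f"TITLE={s.identifier}")
            if s.precursor_mz is not None:
                lines.append(f"PEPMASS={float(s.precursor_mz)!r}")
            lines.append(f"IONMODE={s.ionmode}")
            if s.smiles:
                lines.append(f"SMILES={s.smiles}")
            if s.inchi:
                lines.append(f"INCHI={s.inchi}")
            if s.inchikey:
                lines.append(f"INCHIKEY={s.inchikey}")
            for mz, inten in zip(s.mz, s.intensities):
                lines.append(f"{float(mz)!r} {float(inten)!r}")
            lines.append("END IONS")
            lines.append("")
        path.write_text("\n".join(lines))
    elif fmt == "msp":
        lines = []
        for s in spectra:
            lines.append(f"Name: {s.identifier}")
            if s.precursor_mz is not None:
                lines.append(f"PrecursorMZ: {float(s.precursor_mz)!r}")
            lines.append(f"Ionmode: {s.ionmode}")
            if s.smiles:
                lines.append(f"SMILES: {s.smiles}")
            if s.inchi:
                lines.append(f"InChI: {s.inchi}")
            if s.inchikey:
                lines.append(f"InChIKey: {s.inchikey}")
            lines.append(f"Num Peaks: {s.n_peaks}")
            for mz, inten in zip(s.mz, s.intensities):
                lines.append(f"{float(mz)!r} {float(inten)!r}")
            lines.append("")
        path.write_text("\n".join(lines))
    elif fmt == "json":
        records = []
        for s in spectra:
            rec: dict = {"peaks_json": [[float(m), float(i)] for m, i in zip(s.mz, s.intensities)]}
            rec["title"] = s.identifier
            if s.precursor_mz is not None:
                rec["precursor_mz"] = s.precursor_mz
            rec["ionmode"] = s.ionmode
            if s.smiles:
                rec["smiles"] = s.smiles
            if s.inchi:
                rec["inchi"] = s.inchi
            if s.inchikey:
                rec["inchikey"] = s.inchikey
            records.append(rec)
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


def select_annotated_positive(
    spectra: Sequence[Spectrum],
    min_peaks: int = 5,
    mz_low: float = 10.0,
    mz_high: float = 1000.0,
) -> list[Spectrum]:
    """Keep positive-mode spectra with full structure annotation and enough peaks.

    A spectrum passes when (1) ionmode is positive, (2) it carries a valid
    InChIKey and a SMILES and/or InChI, and (3) at least ``min_peaks`` of its
    peaks (inclusive threshold) fall inside the closed interval
    ``[mz_low, mz_high]``. Input order is preserved.
    """
    if min_peaks < 1:
        raise ValueError("min_peaks must be >= 1")
    if not mz_low < mz_high:
        raise ValueError("mz_low must be < mz_high")
    selected = []
    for s in spectra:
        if s.ionmode != "positive":
            continue
        if s.inchikey is None or s.structure is None:
            continue
        in_range = int(np.count_nonzero((s.mz >= mz_low) & (s.mz <= mz_high)))
        if in_range >= min_peaks:
            selected.append(s)
    return selected
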