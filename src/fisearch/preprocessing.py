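"""MS2 reading/writing and per-spectrum normalization + top-K peak picking.

Reading goes through :mod:`pyteomics.ms2`; a spectrum with several Z
lines yields one :class:`Spectrum` per charge state.  Preprocessing keeps
the K highest-intensity peaks (ties at the cutoff broken toward lower
m/z), normalizes intensities (base peak -> 100 by default), and flags
spectra outside the precursor-mass/charge acceptance window as excluded
rather than dropping them silently.

Batch preprocessing is by contract element-wise identical to mapping the
per-spectrum function — the observable behavior any batched/tag-array
realization must preserve.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import ms2 as _pyteomics_ms2

from .chem import PROTON_MASS

__all__ = [
    "Spectrum",
    "PreprocessedSpectrum",
    "FilterParams",
    "read_ms2",
    "write_ms2",
    "preprocess_spectrum",
    "preprocess_batch",
    "preprocess_file",
]

NORMALIZATIONS = ("basepeak100", "identity", "sqrt")
CACHE_VERSION = 1


@dataclass(frozen=True)
class Spectrum:
    """A raw MS2 spectrum for a single charge state."""

    scan_id: int
    precursor_mz: float
    charge: int
    neutral_mass: float
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray


@dataclass(frozen=True)
class PreprocessedSpectrum:
    """Top-K normalized peaks of a spectrum, sorted by m/z.

    ``exclude_reason`` is None for searchable spectra; excluded spectra
    carry the reason ("precursor_mass", "charge", "zero_intensity") and
    are skipped by the search stage.
    """

    scan_id: int
    neutral_mass: float
    charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    exclude_reason: str | None = None


@dataclass(frozen=True)
class FilterParams:
    """Acceptance window applied during preprocessing."""

    min_mass: float = 500.0
    max_mass: float = 5000.0
    min_charge: int = 1
    max_charge: int = 4


def read_ms2(path: str | Path) -> list[Spectrum]:
    """Parse an MS2 file; one Spectrum per (scan, charge state).

    The Z line carries charge and the singly-protonated mass M+H; the
    neutral mass is M+H minus one proton.  Spectra without any Z line are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _pyteomics_ms2.read(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            scan = int(params["scan"][0])
            precursor_mz = float(params["precursor m/z"])
            charges = params.get("charge") or []
            mh_values = params.get("neutral mass") or []  # pyteomics: raw Z-line M+H
            mz = np.asarray(rec["m/z array"], dtype=float)
            inten = np.asarray(rec["intensity array"], dtype=float)
            if not charges:
                warnings.warn(f"scan {scan}: no Z line, spectrum skipped")
                continue
            for charge, mh in zip(charges, mh_values):
                spectra.append(
                    Spectrum(
                        scan_id=scan,
                        precursor_mz=precursor_mz,
                        charge=int(charge),
                        neutral_mass=float(mh) - PROTON_MASS,
                        peaks_mz=mz,
                        peaks_intensity=inten,
                    )
                )
    return spectra


def write_ms2(spectra: Sequence[Spectrum], path: str | Path, header: str = "fisearch") -> None:
    """Write spectra to MS2 text.  Consecutive charge states of the same
    scan are merged back into one S block with multiple Z lines."""
    path = Path(path)
    # group consecutive charge states of the same scan into one S block
    groups: list[list[Spectrum]] = []
    for s in spectra:
        if groups and groups[-1][0].scan_id == s.scan_id:
            groups[-1].append(s)
        else:
            groups.append([s])
    with open(path, "w") as fh:
        fh.write(f"H\tCreationTool\t{header}\n")
        for group in groups:
            first = group[0]
            fh.write(f"S\t{first.scan_id}\t{first.scan_id}\t{first.precursor_mz:.5f}\n")
            for s in group:
                fh.write(f"Z\t{s.charge}\t{s.neutral_mass + PROTON_MASS:.5f}\n")
            for mz, inten in zip(first.peaks_mz, first.peaks_intensity):
                fh.write(f"{mz:.5f} {inten:.5f}\n")


def _normalize(intensity: np.ndarray, rule: str) -> np.ndarray:
    if rule == "identity":
        return intensity.astype(float)
    if rule == "sqrt":
        intensity = np.sqrt(intensity)
    elif rule != "basepeak100":
        raise ValueError(f"unknown normalization {rule!r}; expected one of {NORMALIZATIONS}")
    peak = intensity.max()
    return intensity * (100.0 / peak)


def preprocess_spectrum(
    s: Spectrum | PreprocessedSpectrum,
    K: int = 100,
    normalization: str = "basepeak100",
    filters: FilterParams = FilterParams(),
) -> PreprocessedSpectrum:
    """Normalize intensities and keep the K most intense peaks.

    Ties at the K-th rank are broken toward the lower-m/z peak so the
    retained set is deterministic.  Preprocessing is idempotent for a
    fixed (K, normalization).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mz = np.asarray(s.peaks_mz, dtype=float)
    inten = np.asarray(s.peaks_intensity, dtype=float)

    reason = None
    if not (filters.min_mass <= s.neutral_mass <= filters.max_mass):
        reason = "precursor_mass"
    elif not (filters.min_charge <= s.charge <= filters.max_charge):
        reason = "charge"
    elif inten.size == 0 or inten.max() <= 0:
        reason = "zero_intensity"

    if reason is None:
        # an already-preprocessed input is not re-normalized (idempotence)
        if isinstance(s, PreprocessedSpectrum):
            normalization = "identity"
        # sort by (-intensity, mz), keep first K, restore m/z order
        order = np.lexsort((mz, -inten))[:K]
        keep = np.sort(order)
        mz, inten = mz[keep], _normalize(inten, normalization)[keep]

    return PreprocessedSpectrum(
        scan_id=s.scan_id,
        neutral_mass=s.neutral_mass,
        charge=s.charge,
        peaks_mz=mz,
        peaks_intensity=inten,
        exclude_reason=reason,
    )


def preprocess_batch(
    batch: Iterable[Spectrum],
    K: int = 100,
    normalization: str = "basepeak100",
    filters: FilterParams = FilterParams(),
) -> list[PreprocessedSpectrum]:
    """Preprocess a batch; identical to mapping :func:`preprocess_spectrum`."""
    return [preprocess_spectrum(s, K, normalization, filters) for s in batch]


def _content_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_file(
    ms2_path: str | Path,
    cache_dir: str | Path,
    K: int = 100,
    normalization: str = "basepeak100",
    filters: FilterParams = FilterParams(),
) -> tuple[list[PreprocessedSpectrum], bool]:
    """Preprocess an MS2 file with a dataset-level cache.

    Returns ``(spectra, cache_hit)``.  A sidecar JSON records K, the
    normalization rule, a format version and the source content hash;
    preprocessing reruns only when any of these change.
    """
    ms2_path = Path(ms2_path)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    sidecar = cache_dir / (ms2_path.stem + ".preprocess.json")
    cached = cache_dir / (ms2_path.stem + ".preprocessed.json")

    meta = {
        "version": CACHE_VERSION,
        "K": K,
        "normalization": normalization,
        "filters": [filters.min_mass, filters.max_mass, filters.min_charge, filters.max_charge],
        "content_hash": _content_hash(ms2_path),
    }
    if sidecar.exists() and cached.exists():
        if json.loads(sidecar.read_text()) == meta:
            return _load_cached(cached), True

    result = preprocess_batch(read_ms2(ms2_path), K, normalization, filters)
    _store_cached(result, cached)
    sidecar.write_text(json.dumps(meta, indent=1))
    return result, False


def _store_cached(spectra: Sequence[PreprocessedSpectrum], path: Path) -> None:
    payload = [
        {
            "scan_id": s.scan_id,
            "neutral_mass": s.neutral_mass,
            "charge": s.charge,
            "mz": s.peaks_mz.tolist(),
            "intensity": s.peaks_intensity.tolist(),
            "exclude_reason": s.exclude_reason,
        }
        for s in spectra
    ]
    path.write_text(json.dumps(payload))


def _load_cached(path: Path) -> list[PreprocessedSpectrum]:
    return [
        PreprocessedSpectrum(
            scan_id=d["scan_id"],
            neutral_mass=d["neutral_mass"],
            charge=d["charge"],
            peaks_mz=np.array(d["mz"]),
            peaks_intensity=np.array(d["intensity"]),
            exclude_reason=d["exclude_reason"],
        )
        for d in json.loads(path.read_text())
    ]
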