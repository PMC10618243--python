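"""Theoretical spectra and the fragment-ion index.

The index holds two sorted views of the peptide database D:

* a mass-sorted peptide array — ``peptide_id`` is the rank of each entry
  after a *stable* sort by neutral mass, so the "smaller index" tie-break
  used during scoring is well defined;
* an m/z-sorted fragment array over all theoretical b/y ions of all
  peptides, again stably sorted, so fragments at equal m/z keep their
  generation order and entries from the same peptide stay adjacent.

Fragment m/z values are stored as floating point and queried with
tolerance-window binary search; no integer binning is performed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import MASS_TABLE, MassTable
from .digestion import ModForm

__all__ = [
    "IndexParams",
    "PeptideEntry",
    "FragmentIonIndex",
    "generate_ions",
    "build_index",
    "precursor_window",
    "fragment_window",
    "save_index",
    "load_index",
]

SERIES_B = 0
SERIES_Y = 1
_SERIES_CODE = {"b": SERIES_B, "y": SERIES_Y}
_SERIES_NAME = {v: k for k, v in _SERIES_CODE.items()}

INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexParams:
    """Fragment-generation settings baked into an index."""

    series: tuple[str, ...] = ("b", "y")
    max_fragment_charge: int = 3

    def __post_init__(self) -> None:
        if self.max_fragment_charge < 1:
            raise ValueError("max_fragment_charge must be >= 1")
        for s in self.series:
            if s not in _SERIES_CODE:
                raise ValueError(f"unsupported ion series {s!r}")


@dataclass(frozen=True)
class PeptideEntry:
    """A database peptide: one modified form with a dense stable id."""

    peptide_id: int
    sequence: str
    mods: tuple[tuple[int, float, str], ...]
    neutral_mass: float
    protein_refs: tuple[str, ...] = ()


class NoFragmentsError(ValueError):
    """Peptide too short to fragment (length < 2)."""


class EmptyIndexError(ValueError):
    """Index construction was given no peptides."""


def generate_ions(
    entry: PeptideEntry | ModForm,
    series: Sequence[str] = ("b", "y"),
    max_charge: int = 3,
    table: MassTable = MASS_TABLE,
) -> list[tuple[float, str, int]]:
    """Theoretical fragment ions of a peptide as ``(mz, series, charge)``.

    For each prefix length k = 1..len-1 the b_k neutral mass is the sum of
    the first k residue masses plus modification deltas on those sites;
    y_k is the sum of the last k residues, their mods, and one water.
    m/z at charge z is ``(neutral + z * proton) / z``.  The total count is
    ``(len - 1) * |series| * max_charge``.
    """
    seq = entry.sequence
    n = len(seq)
    if n < 2:
        raise NoFragmentsError(f"cannot fragment peptide of length {n}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    mod_delta = np.zeros(n)
    for pos, delta, _name in entry.mods:
        mod_delta[pos] += delta
    residue = np.array([table.mass_of(ch) for ch in seq]) + mod_delta
    prefix = np.cumsum(residue)

    # Neutral fragment masses for cut positions k = 1..n-1.
    b_neutral = prefix[:-1]
    y_neutral = prefix[-1] - prefix[:-1] + table.water_mass

    ions: list[tuple[float, str, int]] = []
    for z in range(1, max_charge + 1):
        for s in series:
            neutral = b_neutral if s == "b" else y_neutral
            for m in neutral:
                ions.append(((m + z * table.proton_mass) / z, s, z))
    return ions


@dataclass(frozen=True)
class FragmentIonIndex:
    """The searchable database: mass-sorted peptides + m/z-sorted fragments."""

    peptides: tuple[PeptideEntry, ...]
    peptide_masses: np.ndarray          # float64, non-decreasing
    frag_mz: np.ndarray                 # float64, non-decreasing
    frag_peptide_id: np.ndarray         # int64
    frag_series: np.ndarray             # int8, SERIES_B / SERIES_Y
    frag_charge: np.ndarray             # int8
    params: IndexParams = field(default_factory=IndexParams)

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def num_fragments(self) -> int:
        return len(self.frag_mz)


def build_index(
    entries: Sequence[ModForm],
    params: IndexParams = IndexParams(),
    table: MassTable = MASS_TABLE,
) -> FragmentIonIndex:
    """Build the fragment-ion index from modified-peptide precursors.

    Peptides are stably sorted by neutral mass (ties keep input/canonical
    order) and renumbered 0..D-1; all fragments are generated in peptide-id
    order and then stably sorted by m/z.
    """
    if not entries:
        raise EmptyIndexError("cannot build an index from zero peptides")

    masses = np.array([e.neutral_mass for e in entries])
    order = np.argsort(masses, kind="stable")
    peptides = tuple(
        PeptideEntry(
            peptide_id=new_id,
            sequence=entries[old].sequence,
            mods=entries[old].mods,
            neutral_mass=entries[old].neutral_mass,
            protein_refs=tuple(entries[old].protein_refs),
        )
        for new_id, old in enumerate(order)
    )

    mz_list: list[float] = []
    pid_list: list[int] = []
    series_list: list[int] = []
    charge_list: list[int] = []
    for pep in peptides:
        for mz, s, z in generate_ions(pep, params.series, params.max_fragment_charge, table):
            mz_list.append(mz)
            pid_list.append(pep.peptide_id)
            series_list.append(_SERIES_CODE[s])
            charge_list.append(z)

    frag_mz = np.array(mz_list)
    frag_order = np.argsort(frag_mz, kind="stable")
    return FragmentIonIndex(
        peptides=peptides,
        peptide_masses=masses[order],
        frag_mz=frag_mz[frag_order],
        frag_peptide_id=np.array(pid_list, dtype=np.int64)[frag_order],
        frag_series=np.array(series_list, dtype=np.int8)[frag_order],
        frag_charge=np.array(charge_list, dtype=np.int8)[frag_order],
        params=params,
    )


def precursor_window(index: FragmentIonIndex, query_mass: float, delta_m: float) -> tuple[int, int]:
    """Half-open peptide-id range with |mass - query| <= delta_m.

    Both boundaries are inclusive in mass; candidates sitting exactly on a
    window edge are in, which keeps closed/open results nested.
    """
    if delta_m < 0:
        raise ValueError("delta_m must be >= 0")
    lo = int(np.searchsorted(index.peptide_masses, query_mass - delta_m, side="left"))
    hi = int(np.searchsorted(index.peptide_masses, query_mass + delta_m, side="right"))
    return lo, hi


def fragment_window(index: FragmentIonIndex, query_mz: float, delta_f: float) -> tuple[int, int]:
    """Half-open fragment-array range with |mz - query_mz| <= delta_f."""
    if delta_f < 0:
        raise ValueError("delta_f must be >= 0")
    lo = int(np.searchsorted(index.frag_mz, query_mz - delta_f, side="left"))
    hi = int(np.searchsorted(index.frag_mz, query_mz + delta_f, side="right"))
    return lo, hi


def save_index(index: FragmentIonIndex, path: str | Path) -> None:
    """Serialize an index to a versioned binary file (.npz container)."""
    meta = {
        "format_version": INDEX_FORMAT_VERSION,
        "series": list(index.params.series),
        "max_fragment_charge": index.params.max_fragment_charge,
        "peptides": [
            {
                "sequence": p.sequence,
                "mods": [list(m) for m in p.mods],
                "neutral_mass": p.neutral_mass,
                "protein_refs": list(p.protein_refs),
            }
            for p in index.peptides
        ],
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        peptide_masses=index.peptide_masses,
        frag_mz=index.frag_mz,
        frag_peptide_id=index.frag_peptide_id,
        frag_series=index.frag_series,
        frag_charge=index.frag_charge,
    )


def load_index(path: str | Path, expected_params: IndexParams | None = None) -> FragmentIonIndex:
    """Load a serialized index, validating format version and parameters."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"index format version {meta.get('format_version')} != {INDEX_FORMAT_VERSION}"
            )
        params = IndexParams(
            series=tuple(meta["series"]),
            max_fragment_charge=int(meta["max_fragment_charge"]),
        )
        if expected_params is not None and params != expected_params:
            raise ValueError(f"index params {params} do not match requested {expected_params}")
        peptides = tuple(
            PeptideEntry(
                peptide_id=i,
                sequence=p["sequence"],
                mods=tuple((int(a), float(b), str(c)) for a, b, c in p["mods"]),
                neutral_mass=float(p["neutral_mass"]),
                protein_refs=tuple(p["protein_refs"]),
            )
            for i, p in enumerate(meta["peptides"])
        )
        return FragmentIonIndex(
            peptides=peptides,
            peptide_masses=data["peptide_masses"],
            frag_mz=data["frag_mz"],
            frag_peptide_id=data["frag_peptide_id"],
            frag_series=data["frag_series"],
            frag_charge=data["frag_charge"],
            params=params,
        )
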