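"""In-silico enzymatic digestion and enumeration of fixed/variable PTM forms.

Trypsin cleaves C-terminal to K/R; cleavage is suppressed when the next
residue is proline (the suppression is a flag, on by default).  Peptides
with up to ``max_missed_cleavages`` retained internal sites are emitted,
filtered by length on the unmodified sequence; the mass window is applied
per modified form, since a variable PTM can move a peptide across a mass
boundary in either direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .chem import (
    MASS_TABLE,
    InvalidResidueError,
    MassTable,
    Modification,
    peptide_neutral_mass,
)

__all__ = [
    "DigestParams",
    "ModForm",
    "digest_protein",
    "enumerate_modforms",
    "read_fasta",
]


@dataclass(frozen=True)
class DigestParams:
    """Digestion and peptide-filter settings.

    Defaults mirror a standard tryptic open-search database build:
    2 missed cleavages, peptide lengths 6-46 residues, peptide masses
    500-5000 Da.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_len: int = 6
    max_len: int = 46
    min_mass: float = 500.0
    max_mass: float = 5000.0
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass > max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages < 0")
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")


def _validate_sequence(sequence: str, table: MassTable) -> None:
    for ch in sequence:
        if ch not in table.residue_mass:
            raise InvalidResidueError(f"unknown residue {ch!r}")


def digest_protein(
    sequence: str,
    params: DigestParams,
    *,
    apply_length_filter: bool = True,
    table: MassTable = MASS_TABLE,
) -> list[tuple[str, int]]:
    """Tryptic peptides of a protein as ``(peptide, start_offset)`` pairs.

    Offsets are 0-based; peptides occupy the half-open interval
    ``[start, start + len)`` on the protein.  Output order is
    deterministic: ascending start offset, then ascending length.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    _validate_sequence(sequence, table)

    # Cleavage points: index i means a cut between i-1 and i.
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if params.proline_rule and sequence[i + 1] == "P":
                continue
            cuts.append(i + 1)
    cuts.append(len(sequence))

    peptides: list[tuple[str, int]] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(cuts))):
            start, stop = cuts[a], cuts[b]
            pep = sequence[start:stop]
            if apply_length_filter and not (params.min_len <= len(pep) <= params.max_len):
                continue
            peptides.append((pep, start))
    peptides.sort(key=lambda p: (p[1], len(p[0])))
    return peptides


@dataclass(frozen=True)
class ModForm:
    """One modified form of a peptide: sequence + site/delta assignments.

    ``mods`` is a tuple of ``(position, delta_mass, name)`` sorted by
    position; fixed-modification sites are included.  ``neutral_mass`` is
    the modified neutral monoisotopic mass.
    """

    sequence: str
    mods: tuple[tuple[int, float, str], ...]
    neutral_mass: float
    protein_refs: tuple[str, ...] = ()


def enumerate_modforms(
    peptide: str,
    fixed_mods: Sequence[Modification] = (),
    variable_mods: Sequence[Modification] = (),
    max_var_mods: int = 5,
    *,
    mass_range: tuple[float, float] | None = None,
    table: MassTable = MASS_TABLE,
) -> list[ModForm]:
    """All PTM variants of ``peptide`` with at most ``max_var_mods`` variable mods.

    Fixed modifications are applied to every occurrence of their targets
    in every form.  Variable forms are site-subsets of total size <=
    ``max_var_mods`` with at most one variable modification per site;
    fixed-modified sites are not available to variable mods.  Forms come
    out in canonical order: the fixed-only form first, then ascending by
    subset size and site tuple.  ``mass_range``, when given, drops forms
    whose modified neutral mass falls outside ``(lo, hi)`` inclusive.
    """
    if max_var_mods < 0:
        raise ValueError("max_var_mods must be >= 0")
    _validate_sequence(peptide, table)

    fixed_sites: list[tuple[int, float, str]] = []
    fixed_positions: set[int] = set()
    for mod in fixed_mods:
        for i, ch in enumerate(peptide):
            if ch in mod.targets:
                fixed_sites.append((i, mod.delta_mass, mod.name))
                fixed_positions.add(i)
    fixed_sites.sort()

    # (position, mod) slots eligible for variable modification, in
    # position order then menu order -- this fixes the canonical output order.
    slots: list[tuple[int, Modification]] = []
    for i, ch in enumerate(peptide):
        if i in fixed_positions:
            continue
        for mod in variable_mods:
            if not mod.fixed and ch in mod.targets:
                slots.append((i, mod))

    forms: list[ModForm] = []

    def emit(var_sites: tuple[tuple[int, Modification], ...]) -> None:
        mods = tuple(sorted(fixed_sites + [(i, m.delta_mass, m.name) for i, m in var_sites]))
        mass = peptide_neutral_mass(peptide, [(i, d) for i, d, _ in mods], table)
        if mass_range is not None and not (mass_range[0] <= mass <= mass_range[1]):
            return
        forms.append(ModForm(sequence=peptide, mods=mods, neutral_mass=mass))

    max_k = min(max_var_mods, len(slots))
    for k in range(0, max_k + 1):
        for combo in itertools.combinations(slots, k):
            positions = [i for i, _ in combo]
            if len(set(positions)) != len(positions):  # one mod per site
                continue
            emit(combo)
    return forms


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(header, sequence)`` pairs.

    Multi-line sequences are joined; ``*`` stop codons are stripped; any
    other non-residue character raises with file/line context.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append((header, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence data before first '>' header")
                seq = line.replace("*", "")
                for ch in seq:
                    if ch not in MASS_TABLE.residue_mass:
                        raise InvalidResidueError(f"{path}:{lineno}: invalid residue {ch!r}")
                chunks.append(seq)
    flush()
    return records
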