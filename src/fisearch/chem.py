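"""Mass constants, modification definitions, and the memoized log-factorial table.

All masses are monoisotopic and given in Daltons to five decimal places.
Average masses, isotope envelopes and elemental compositions are out of
scope: downstream tolerance windows (the ±1 Da closed-search window in
particular) are wide enough to absorb small cross-tool rounding
differences, so a single well-documented monoisotopic table suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MassTable",
    "Modification",
    "LogFactorialTable",
    "MASS_TABLE",
    "BUILTIN_MODIFICATIONS",
    "build_log_factorial_table",
    "peptide_neutral_mass",
]

# Monoisotopic residue masses (Da), 5 decimals.  I and L share a mass but
# remain distinct symbols; no I/L collapsing is performed anywhere.
_RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.01056
PROTON_MASS = 1.00728


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a character outside the 20-residue table."""


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses plus the water and proton constants."""

    residue_mass: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MASSES))
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS

    def mass_of(self, residue: str) -> float:
        try:
            return self.residue_mass[residue]
        except KeyError:
            raise InvalidResidueError(f"unknown residue {residue!r}") from None


#: Shared default table used throughout the package.
MASS_TABLE = MassTable()


@dataclass(frozen=True)
class Modification:
    """A residue-specific mass delta.

    A *fixed* modification is applied to every occurrence of its target
    residues; variable modifications are enumerated combinatorially up to
    a per-peptide cap (see :func:`fisearch.digestion.enumerate_modforms`).
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("modification must target at least one residue")
        object.__setattr__(self, "targets", frozenset(self.targets))


#: Modifications used by the default search configuration: fixed
#: carbamidomethylation of cysteine and the common variable PTMs.
BUILTIN_MODIFICATIONS: Mapping[str, Modification] = {
    "carbamidomethyl": Modification("carbamidomethyl", 57.02146, frozenset("C"), fixed=True),
    "oxidation": Modification("oxidation", 15.99491, frozenset("M")),
    "deamidation": Modification("deamidation", 0.98402, frozenset("NQ")),
    "phospho": Modification("phospho", 79.96633, frozenset("STY")),
}


@dataclass(frozen=True)
class LogFactorialTable:
    """Memoized log(n!) values, 0..n_max, in a configurable log base.

    Built once via the recurrence log(n!) = log(n) + log((n-1)!), which
    stays finite far past n = 20 where direct 64-bit factorials overflow.
    Scores needing n > n_max raise :class:`CapacityError` rather than
    silently computing on the fly.
    """

    values: tuple[float, ...]
    n_max: int
    log_base: float

    def __getitem__(self, n: int) -> float:
        if n < 0 or n > self.n_max:
            raise CapacityError(f"log-factorial table covers 0..{self.n_max}, got {n}")
        return self.values[n]


class CapacityError(ValueError):
    """A count exceeded the precomputed log-factorial range."""


def build_log_factorial_table(n_max: int = 120, log_base: float = 10.0) -> LogFactorialTable:
    """Precompute log(n!) for n = 0..n_max in the given base (10 or e).

    Parameters
    ----------
    n_max:
        Largest factorial argument covered; default 120.
    log_base:
        Base of all scoring logarithms; 10 by default (the X!Tandem
        hyperscore convention), ``math.e`` also supported.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if not (math.isclose(log_base, 10.0) or math.isclose(log_base, math.e)):
        raise ValueError("log_base must be 10 or e")
    ln_base = math.log(log_base)
    values = [0.0] * (n_max + 1)
    for n in range(2, n_max + 1):
        values[n] = values[n - 1] + math.log(n) / ln_base
    return LogFactorialTable(values=tuple(values), n_max=n_max, log_base=log_base)


def peptide_neutral_mass(
    sequence: str,
    mods: Iterable[tuple[int, float]] = (),
    table: MassTable = MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    ``mods`` is an iterable of ``(position, delta_mass)`` pairs with
    0-based positions into ``sequence``.  The result is the sum of
    residue masses, one water, and all modification deltas.
    """
    mass = table.water_mass
    for residue in sequence:
        mass += table.mass_of(residue)
    for pos, delta in mods:
        if not 0 <= pos < len(sequence):
            raise IndexError(f"modification position {pos} outside sequence of length {len(sequence)}")
        mass += delta
    return mass
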