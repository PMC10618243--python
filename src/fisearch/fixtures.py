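"""Seeded synthetic proteins and spectra with ground truth.

The generator emulates the shapes of a real tryptic search experiment at
desk scale: proteins are concatenations of tryptic "words" (random
residues capped by K/R) so every protein yields at least one peptide in
the standard 6-46 residue window; spectra are built from a peptide's own
theoretical b/y ions at charge 1 with rank-decaying intensities (100/rank),
plus uniform noise peaks placed away from every signal peak (rejection
beyond 2·δF), so ground-truth matched-ion counts are exact.  An optional
precursor mass shift emulates an unanticipated modification for
open-search tests.  Identical specs (including seed) produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import PROTON_MASS, Modification
from .digestion import ModForm
from .indexing import generate_ions
from .preprocessing import Spectrum, write_ms2

__all__ = ["FixtureSpec", "generate_fasta", "generate_spectra", "write_truth"]

# residues eligible inside a tryptic word: no K/R (word-internal cuts)
# and no P (avoids proline-suppressed sites at word boundaries)
_BODY_RESIDUES = "ACDEFGHILMNQSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset; fully determined by the seed."""

    n_proteins: int = 20
    peptides_per_protein: tuple[int, int] = (3, 6)
    peptide_len_range: tuple[int, int] = (6, 20)
    seed: int = 0
    spectra_per_peptide: int = 1
    noise_peaks: int = 20
    intensity_model: str = "rank"
    charge_range: tuple[int, int] = (2, 3)
    delta_f: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.peptide_len_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid peptide_len_range")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not (6 <= lo and hi <= 46):
            raise ValueError("peptide_len_range must lie within 6..46 for guaranteed recovery")


def generate_fasta(spec: FixtureSpec, path: str | Path | None = None) -> list[tuple[str, str]]:
    """Random proteins whose tryptic digests are length-valid by construction.

    Each protein is a concatenation of words: ``len-1`` non-K/R/P
    residues followed by K or R, word lengths drawn from
    ``peptide_len_range``, so zero-missed-cleavage digestion yields the
    words themselves.  Returns ``(header, sequence)`` records and
    optionally writes FASTA.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    for i in range(spec.n_proteins):
        n_words = int(rng.integers(*spec.peptides_per_protein, endpoint=True))
        words = []
        for _ in range(n_words):
            length = int(rng.integers(*spec.peptide_len_range, endpoint=True))
            body = "".join(rng.choice(list(_BODY_RESIDUES), size=length - 1))
            words.append(body + str(rng.choice(["K", "R"])))
        records.append((f"SYN{i:04d} synthetic protein {i}", "".join(words)))
    if path is not None:
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n")
                for j in range(0, len(seq), 60):
                    fh.write(seq[j : j + 60] + "\n")
    return records


def generate_spectra(
    peptides: Sequence[ModForm],
    spec: FixtureSpec,
    path: str | Path | None = None,
    mass_shift: float = 0.0,
) -> tuple[list[Spectrum], list[dict]]:
    """Spectra from theoretical b/y ions of each peptide, plus noise.

    Signal peaks are the charge-1 b/y m/z values with 100/rank
    intensities (rank order randomized per spectrum); ``mass_shift`` is
    added to the precursor only — the truth table records it so
    open-search tests know the expected precursor delta.  Returns the
    spectra and a truth table mapping scan ids to generating peptides.
    """
    rng = np.random.default_rng(spec.seed + 1)
    spectra: list[Spectrum] = []
    truth: list[dict] = []
    scan = 0
    for pep in peptides:
        ions = generate_ions(pep, ("b", "y"), max_charge=1)
        signal_mz = np.array(sorted(mz for mz, _, _ in ions))
        for _ in range(spec.spectra_per_peptide):
            scan += 1
            ranks = rng.permutation(len(signal_mz)) + 1
            intensity = 100.0 / ranks

            noise_mz: list[float] = []
            lo, hi = signal_mz[0] - 50.0, signal_mz[-1] + 50.0
            while len(noise_mz) < spec.noise_peaks:
                cand = float(rng.uniform(lo, hi))
                if np.abs(signal_mz - cand).min() > 2 * spec.delta_f:
                    noise_mz.append(cand)
            noise_int = rng.uniform(0.5, 5.0, size=len(noise_mz))

            mz = np.concatenate([signal_mz, noise_mz])
            inten = np.concatenate([intensity, noise_int])
            order = np.argsort(mz, kind="stable")

            charge = int(rng.integers(*spec.charge_range, endpoint=True))
            neutral = pep.neutral_mass + mass_shift
            spectra.append(
                Spectrum(
                    scan_id=scan,
                    precursor_mz=(neutral + charge * PROTON_MASS) / charge,
                    charge=charge,
                    neutral_mass=neutral,
                    peaks_mz=mz[order],
                    peaks_intensity=inten[order],
                )
            )
            truth.append(
                {
                    "scan_id": scan,
                    "sequence": pep.sequence,
                    "mods": pep.mods,
                    "peptide_mass": pep.neutral_mass,
                    "mass_shift": mass_shift,
                    "charge": charge,
                }
            )
    if path is not None:
        write_ms2(spectra, path)
    return spectra, truth


def write_truth(truth: Sequence[dict], path: str | Path) -> None:
    """Truth table as TSV: scan -> generating peptide and precursor shift."""
    with open(path, "w") as fh:
        fh.write("scan_id\tsequence\tmods\tpeptide_mass\tmass_shift\tcharge\n")
        for row in truth:
            mods = ";".join(f"{n}@{p}:{d:+.5f}" for p, d, n in row["mods"]) or "-"
            fh.write(
                f"{row['scan_id']}\t{row['sequence']}\t{mods}\t"
                f"{row['peptide_mass']:.5f}\t{row['mass_shift']:.5f}\t{row['charge']}\n"
            )
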