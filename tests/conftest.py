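"""Shared fixtures: tiny random databases and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import fisearch as fs
from fisearch.digestion import ModForm
from fisearch.fixtures import FixtureSpec, generate_fasta, generate_spectra

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_modforms(rng: np.random.Generator, n: int, len_range=(6, 16)) -> list[ModForm]:
    """Random unmodified peptide forms for index construction."""
    forms = []
    for _ in range(n):
        length = int(rng.integers(*len_range))
        seq = "".join(rng.choice(AA, size=length))
        forms.append(ModForm(seq, (), fs.peptide_neutral_mass(seq)))
    return forms


def fixture_dataset(seed: int, noise_peaks: int = 20, mass_shift: float = 0.0, n_proteins: int = 12):
    """Synthetic proteome + spectra + truth, with the database forms the
    pipeline would build (fixed carbamidomethyl, mass filter applied)."""
    spec = FixtureSpec(n_proteins=n_proteins, seed=seed, noise_peaks=noise_peaks)
    records = generate_fasta(spec)
    params = fs.DigestParams()
    forms: list[ModForm] = []
    seen = set()
    for _, seq in records:
        for pep, _ in fs.digest_protein(seq, params):
            for form in fs.enumerate_modforms(
                pep,
                [fs.BUILTIN_MODIFICATIONS["carbamidomethyl"]],
                mass_range=(params.min_mass, params.max_mass),
            ):
                key = (form.sequence, form.mods)
                if key not in seen:
                    seen.add(key)
                    forms.append(form)
    spectra, truth = generate_spectra(forms, spec, mass_shift=mass_shift)
    return records, forms, spectra, truth


@pytest.fixture(scope="session")
def small_index():
    rng = np.random.default_rng(42)
    return fs.build_index(random_modforms(rng, 50))


@pytest.fixture(scope="session")
def lft():
    return fs.build_log_factorial_table()
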