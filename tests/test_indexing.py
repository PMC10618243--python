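"""Theoretical ion generation and the sorted fragment-ion index."""

import numpy as np
import pytest

import fisearch as fs
from fisearch.chem import MASS_TABLE
from fisearch.digestion import ModForm
from fisearch.indexing import EmptyIndexError, IndexParams, NoFragmentsError
from conftest import random_modforms


def form(seq, mods=()):
    deltas = [(p, d) for p, d, _ in mods]
    return ModForm(seq, tuple(mods), fs.peptide_neutral_mass(seq, deltas))


class TestGenerateIons:
    def test_dipeptide_b1_y1(self):
        ions = fs.generate_ions(form("AG"), ("b", "y"), max_charge=1)
        assert len(ions) == 2
        (b_mz, _, _), (y_mz, _, _) = [i for i in ions if i[1] == "b"] + [i for i in ions if i[1] == "y"]
        assert b_mz == pytest.approx(72.04439, abs=1e-5)
        assert y_mz == pytest.approx(76.03930, abs=1e-5)

    def test_fragment_count_formula(self):
        ions = fs.generate_ions(form("ACDEFGHIKL"), ("b", "y"), max_charge=3)
        assert len(ions) == 9 * 2 * 3

    def test_higher_charge_scaling(self):
        by_charge = {}
        for mz, series, z in fs.generate_ions(form("PEPTIDEK"), ("b",), max_charge=2):
            by_charge.setdefault(z, []).append(mz)
        for m1, m2 in zip(sorted(by_charge[1]), sorted(by_charge[2])):
            neutral = m1 - MASS_TABLE.proton_mass
            assert m2 == pytest.approx((neutral + 2 * MASS_TABLE.proton_mass) / 2, abs=1e-9)

    def test_site_modification_shifts_only_covering_fragments(self):
        plain = fs.generate_ions(form("AGGA"), ("b",), 1)
        modded = fs.generate_ions(form("AGGA", ((0, 15.99491, "oxidation"),)), ("b",), 1)
        for (m0, _, _), (m1, _, _) in zip(plain, modded):
            assert m1 == pytest.approx(m0 + 15.99491, abs=1e-9)  # every b covers site 0
        modded_y = fs.generate_ions(form("AGGA", ((0, 15.99491, "oxidation"),)), ("y",), 1)
        plain_y = fs.generate_ions(form("AGGA"), ("y",), 1)
        # y1..y3 never cover the N-terminal site
        for (m0, _, _), (m1, _, _) in zip(plain_y, modded_y):
            assert m1 == pytest.approx(m0, abs=1e-9)

    def test_too_short_to_fragment(self):
        with pytest.raises(NoFragmentsError):
            fs.generate_ions(form("A"))


class TestBuildIndex:
    def test_peptide_ids_are_mass_ranks(self):
        forms = [form(s) for s in ("KKKKKKKKKK", "GGGGGG", "AAAAAAA")]  # heavy, light, mid
        idx = fs.build_index(forms)
        seqs = [p.sequence for p in idx.peptides]
        assert seqs == ["GGGGGG", "AAAAAAA", "KKKKKKKKKK"]
        assert [p.peptide_id for p in idx.peptides] == [0, 1, 2]
        assert np.all(np.diff(idx.peptide_masses) >= 0)

    def test_equal_mz_fragments_stay_in_generation_order(self):
        # identical sequences -> every fragment m/z collides; stability
        # demands entries of peptide 0 precede peptide 1 at each m/z
        idx = fs.build_index([form("AGAK"), form("AGAK")])
        for mz in np.unique(idx.frag_mz):
            pids = idx.frag_peptide_id[idx.frag_mz == mz]
            assert list(pids) == sorted(pids)

    def test_fragment_count_invariant(self, small_index):
        expected = sum(
            (len(p.sequence) - 1) * 2 * small_index.params.max_fragment_charge
            for p in small_index.peptides
        )
        assert small_index.num_fragments == expected
        assert np.all(np.diff(small_index.frag_mz) >= 0)

    def test_construction_is_deterministic(self):
        rng = np.random.default_rng(3)
        forms = random_modforms(rng, 30)
        a, b = fs.build_index(forms), fs.build_index(forms)
        assert np.array_equal(a.frag_mz, b.frag_mz)
        assert np.array_equal(a.frag_peptide_id, b.frag_peptide_id)
        assert a.peptides == b.peptides

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyIndexError):
            fs.build_index([])


class TestWindows:
    def test_precursor_window_examples(self):
        masses = [500.0, 999.0, 1000.0, 1001.0, 1500.0]
        forms = [ModForm("G" * (i + 2), (), m) for i, m in enumerate(masses)]
        idx = fs.build_index(forms)
        assert fs.precursor_window(idx, 1000.0, 1.0) == (1, 4)
        assert fs.precursor_window(idx, 2000.0, 1.0) == (5, 5)
        assert fs.precursor_window(idx, 1000.0, 0.0) == (2, 3)  # boundary inclusive

    def test_fragment_window_boundary_inclusive(self, small_index):
        mz = small_index.frag_mz[len(small_index.frag_mz) // 2]
        lo, hi = fs.fragment_window(small_index, float(mz), 0.0)
        assert hi > lo
        assert np.all(small_index.frag_mz[lo:hi] == mz)

    def test_windows_agree_with_linear_scan(self, small_index):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            q = float(rng.uniform(0, 4000))
            d = float(rng.choice([0.0, 0.01, 1.0, 100.0]))
            lo, hi = fs.fragment_window(small_index, q, d)
            mask = np.abs(small_index.frag_mz - q) <= d
            assert hi - lo == mask.sum()
            assert np.all(mask[lo:hi])
            plo, phi = fs.precursor_window(small_index, q, d)
            pmask = np.abs(small_index.peptide_masses - q) <= d
            assert phi - plo == pmask.sum()

    def test_every_fragment_found_at_its_own_mz(self, small_index):
        for i in range(0, small_index.num_fragments, 97):
            lo, hi = fs.fragment_window(small_index, float(small_index.frag_mz[i]), 0.0)
            assert lo <= i < hi


class TestSerialization:
    def test_round_trip(self, small_index, tmp_path):
        path = tmp_path / "db.npz"
        fs.save_index(small_index, path)
        loaded = fs.load_index(path)
        assert loaded.peptides == small_index.peptides
        assert np.array_equal(loaded.frag_mz, small_index.frag_mz)
        assert loaded.params == small_index.params

    def test_param_mismatch_rejected(self, small_index, tmp_path):
        path = tmp_path / "db.npz"
        fs.save_index(small_index, path)
        with pytest.raises(ValueError, match="params"):
            fs.load_index(path, expected_params=IndexParams(max_fragment_charge=2))
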