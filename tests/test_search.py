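"""Hyperscore and the indexed search vs its brute-force reference."""

import math

import numpy as np
import pytest

import fisearch as fs
from fisearch.chem import CapacityError
from fisearch.digestion import ModForm
from fisearch.preprocessing import PreprocessedSpectrum
from fisearch.search import SearchParams, search_spectrum, search_spectrum_bruteforce
from conftest import random_modforms


def query_from_peptide(pep, charge=2, noise=(), scan=1, mass_offset=0.0):
    """Spectrum whose peaks are the peptide's charge-1 b/y ions, unit intensities."""
    ions = sorted(mz for mz, _, _ in fs.generate_ions(pep, ("b", "y"), 1))
    mz = np.array(list(ions) + list(noise))
    order = np.argsort(mz)
    inten = np.concatenate([np.full(len(ions), 100.0), np.full(len(noise), 1.0)])
    return PreprocessedSpectrum(
        scan_id=scan,
        neutral_mass=pep.neutral_mass + mass_offset,
        charge=charge,
        peaks_mz=mz[order],
        peaks_intensity=inten[order],
    )


class TestHyperscore:
    def test_all_zero_inputs_score_zero(self):
        assert fs.hyperscore(0, 0, 0.0, 0.0) == 0.0

    def test_worked_value_base_10(self):
        # log10(2!) + log10(1!) + log10(10) + log10(5)
        assert fs.hyperscore(2, 1, 10.0, 5.0) == pytest.approx(2.0, abs=1e-9)

    def test_incrementing_b_count_adds_log_of_new_count(self):
        for n in range(1, 20):
            delta = fs.hyperscore(n + 1, 1, 10.0, 5.0) - fs.hyperscore(n, 1, 10.0, 5.0)
            assert delta == pytest.approx(math.log10(n + 1), abs=1e-12)

    def test_zero_sum_series_contributes_nothing(self):
        assert fs.hyperscore(0, 3, 0.0, 8.0) == pytest.approx(
            math.log10(6) + math.log10(8), abs=1e-12
        )

    def test_count_beyond_table_capacity(self, lft):
        with pytest.raises(CapacityError):
            fs.hyperscore(121, 0, 1.0, 1.0, lft)


class TestSearchSpectrum:
    def test_query_of_own_ions_finds_its_peptide(self, small_index):
        pep = small_index.peptides[10]
        psm, null, n_scored = search_spectrum(query_from_peptide(pep), small_index)
        assert psm is not None
        assert psm.peptide_id == 10
        n = len(pep.sequence) - 1
        assert psm.n_b >= n and psm.n_y >= n  # at least all charge-1 ions match
        assert null.total == n_scored >= 1

    def test_no_candidate_in_precursor_window(self, small_index):
        q = PreprocessedSpectrum(1, 4999.0, 2, np.array([500.0]), np.array([100.0]))
        psm, null, n = search_spectrum(q, small_index, SearchParams(delta_m=0.1))
        assert psm is None and null.total == 0 and n == 0

    def test_excluded_spectrum_not_searched(self, small_index):
        q = PreprocessedSpectrum(1, 1000.0, 2, np.array([500.0]), np.array([100.0]),
                                 exclude_reason="charge")
        psm, null, n = search_spectrum(q, small_index)
        assert psm is None and null.total == 0 and n == 0

    def test_engineered_tie_resolves_to_smaller_peptide_id(self):
        # identical peptides under two ids: identical masses, fragments,
        # and therefore identical hyperscores
        seq = "AGDESTVK"
        dup = ModForm(seq, (), fs.peptide_neutral_mass(seq))
        idx = fs.build_index([dup, dup])
        psm, null, n = search_spectrum(query_from_peptide(idx.peptides[1]), idx)
        assert n == 2
        assert psm.peptide_id == 0

    def test_null_histogram_totals_scored_candidates(self, small_index):
        rng = np.random.default_rng(2)
        for pep in list(small_index.peptides)[::7]:
            psm, null, n = search_spectrum(
                query_from_peptide(pep), small_index, SearchParams(delta_m=500.0)
            )
            assert null.total == n
            if psm is not None:
                assert null.psi >= math.floor(psm.hyperscore) + 1

    def test_open_top_score_never_below_closed(self, small_index):
        for pep in list(small_index.peptides)[::5]:
            q = query_from_peptide(pep)
            closed, _, _ = search_spectrum(q, small_index, SearchParams(delta_m=1.0))
            opened, _, _ = search_spectrum(q, small_index, SearchParams(delta_m=500.0))
            if closed is not None:
                assert opened is not None
                assert opened.hyperscore >= closed.hyperscore


class TestOracleEquivalence:
    def assert_same(self, a, b):
        psm_a, null_a, n_a = a
        psm_b, null_b, n_b = b
        assert n_a == n_b
        assert np.array_equal(null_a.counts, null_b.counts)
        assert (psm_a is None) == (psm_b is None)
        if psm_a is not None:
            assert psm_a.peptide_id == psm_b.peptide_id
            assert psm_a.hyperscore == psm_b.hyperscore  # bit-identical
            assert (psm_a.n_b, psm_a.n_y) == (psm_b.n_b, psm_b.n_y)

    @pytest.mark.parametrize("delta_m", [1.0, 100.0, 500.0])
    def test_indexed_equals_bruteforce_on_random_queries(self, delta_m):
        rng = np.random.default_rng(int(delta_m))
        idx = fs.build_index(random_modforms(rng, 80))
        params = SearchParams(delta_m=delta_m)
        for i in range(15):
            if i % 2 == 0:
                pep = idx.peptides[int(rng.integers(len(idx)))]
                noise = rng.uniform(100, 1800, 10)
                q = query_from_peptide(pep, noise=noise, scan=i)
            else:
                npk = int(rng.integers(10, 50))
                q = PreprocessedSpectrum(
                    i, float(rng.uniform(500, 3000)), 2,
                    np.sort(rng.uniform(100, 2000, npk)), rng.uniform(1, 100, npk),
                )
            self.assert_same(
                search_spectrum(q, idx, params),
                search_spectrum_bruteforce(q, idx, params),
            )


class TestSearchBatch:
    def _queries(self, index, n=12):
        rng = np.random.default_rng(9)
        return [
            query_from_peptide(index.peptides[int(rng.integers(len(index)))], scan=i)
            for i in range(n)
        ]

    def test_chunk_size_never_changes_results(self, small_index):
        qs = self._queries(small_index)
        r1 = fs.search_batch(qs, small_index, SearchParams(chunk_size=1))
        r512 = fs.search_batch(qs, small_index, SearchParams(chunk_size=512))
        for (p1, n1, c1), (p2, n2, c2) in zip(r1, r512):
            assert c1 == c2 and np.array_equal(n1.counts, n2.counts)
            assert (p1 is None) == (p2 is None)
            if p1 is not None:
                assert (p1.peptide_id, p1.hyperscore) == (p2.peptide_id, p2.hyperscore)

    def test_batch_equals_concatenated_half_batches(self, small_index):
        qs = self._queries(small_index)
        full = fs.search_batch(qs, small_index)
        halves = fs.search_batch(qs[:6], small_index) + fs.search_batch(qs[6:], small_index)
        for (p1, _, c1), (p2, _, c2) in zip(full, halves):
            assert c1 == c2
            if p1 is not None:
                assert p1.peptide_id == p2.peptide_id

    def test_repeated_runs_identical(self, small_index):
        qs = self._queries(small_index, n=6)
        a = fs.search_batch(qs, small_index)
        b = fs.search_batch(qs, small_index)
        for (p1, _, _), (p2, _, _) in zip(a, b):
            if p1 is not None:
                assert p1.hyperscore == p2.hyperscore and p1.peptide_id == p2.peptide_id
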