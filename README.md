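# fisearch

A reference implementation of fragment-ion-index database peptide search
for tandem mass spectrometry, covering both **closed** search (narrow
precursor tolerance, δM ≈ ±1 Da) and **open** search (wide tolerance,
δM = 100–500 Da, used to detect unanticipated modification mass shifts).

It is written for method developers and students who need a small,
fully-testable engine whose every stage can be checked against
brute-force oracles and synthetic ground truth — not for production-scale
proteome searches.

## The method

Given a protein FASTA and experimental MS/MS spectra (MS2 format):

1. **Database construction.** Proteins are digested in silico with
   trypsin (cleave after K/R, suppressed before P; ≤ 2 missed cleavages;
   peptide lengths 6–46; masses 500–5000 Da). Fixed modifications
   (carbamidomethyl-C by default) apply everywhere; variable PTMs
   (oxidation-M, deamidation-N/Q, phospho-S/T/Y) are enumerated up to 5
   per peptide. Theoretical b/y ions are generated for charges 1–3.
   Peptides are stably sorted by neutral mass (the rank is the peptide
   id) and all fragments are stably sorted by m/z, so window queries are
   binary searches and equal-m/z fragments of one peptide stay adjacent.
2. **Preprocessing.** Each spectrum is normalized (base peak → 100) and
   reduced to its top-K peaks (K = 100 by default); spectra outside the
   precursor window 500–5000 Da / charge +1..+4 are flagged excluded.
   The stage is cached per dataset and skipped on re-runs.
3. **Search.** Candidates are peptides with |M_peptide − M_query| ≤ δM.
   Every experimental peak is looked up in the fragment index within
   ±δF (0.01 Da); each hit updates the candidate's scorecard (n_b, n_y,
   matched-intensity sums). Candidates sharing ≥ 4 fragment ions are
   scored with the hyperscore

       h = log₁₀(n_b!) + log₁₀(n_y!) + log₁₀(Σ i_b) + log₁₀(Σ i_y)

   (log factorials come from a memoized table over 0..120, which stays
   finite where direct 64-bit factorials overflow at n ≥ 21). All scored
   candidates fill a unit-width histogram — the null distribution. The
   top hit is the maximal h, ties going to the smaller peptide id.
4. **Postprocessing.** The expectation value of the top hit is obtained
   by a linear least-squares fit to log₁₀ of the survival function of
   the null distribution over its tail, extrapolated to the top score:
   e = 10^(c + a·h_top). It is reported only when ≥ 4 candidates were
   scored and the tail supports a negative slope.

A deliberately naive all-pairs scorer (`search_spectrum_bruteforce`)
implements the same conventions without the index; the test suite
verifies the two agree bit-for-bit on randomized databases and queries.

## Worked example

```sh
$ fisearch fixtures fx --seed 3 --n-proteins 8   # synthetic FASTA + MS2 + truth
8 proteins, 93 spectra -> fx
$ fisearch index fx/proteins.fasta db.npz
84 peptides, 10950 fragments -> db.npz
$ fisearch search db.npz fx/spectra.ms2 out.tsv
84 PSMs -> out.tsv
$ head -3 out.tsv
scan_id	peptide	mods	neutral_mass	delta_mass	charge	hyperscore	n_b	n_y	num_candidates	e_value
1	EFETVMK	-	882.41569	0.00000	2	10.0760	6	6	1	NA
2	EFETVMKGINLFDR	-	1697.84466	0.00000	3	24.1162	13	13	1	NA
```

93 synthetic spectra were generated; 84 fall inside the 500–5000 Da
precursor window and each one is matched back to its generating peptide
(delta_mass ≈ 0, all b/y ions matched: n_b = n_y = length−1). With a
single candidate per spectrum no null distribution can be fitted, so the
e-value column reads `NA`; larger databases or open mode (`--delta-m
100`) produce enough candidates for e-values. An end-to-end run is
`fisearch pipeline fx/proteins.fasta fx/spectra.ms2 out.tsv`.

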