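# Methods

## Model and pipeline

fisearch implements fragment-ion-index database peptide search. The
database D is the set of tryptic peptides of a proteome, expanded over
post-translational modification (PTM) variants; each peptide contributes
its theoretical b/y fragment ions. A query spectrum q is matched against
D in two nested filters: a precursor filter (peptides with neutral mass
within ±δM of the query's neutral mass) and a fragment filter (index
entries within ±δF of each experimental peak). Matches accumulate into a
per-candidate scorecard — counts n_b, n_y of matched b/y index entries
and the summed normalized intensities of the matching experimental
peaks — from which the hyperscore is computed:

    h = log(n_b!) + log(n_y!) + log(Σ i_b) + log(Σ i_y)

A log term whose intensity sum is zero contributes 0, keeping scores
finite when one ion series is absent. Each (experimental peak,
theoretical fragment entry) pair within δF counts exactly once; no
per-peak cap is applied. Because fragments are generated for charges
1..3, one peak may legitimately match several entries of the same
peptide.

The hyperscores of all scored candidates of one spectrum form its null
distribution, a unit-width integer histogram indexed by floor(h); the top
hit's expectation value is extrapolated from the histogram's survival
tail (below).

## Assumptions

- Monoisotopic masses throughout; constants are fixed to five decimals
  (proton 1.00728 Da, water 18.01056 Da). No isotope-error offsets, no
  decoys, no average masses.
- Precursor tolerance δM applies to neutral monoisotopic masses, not
  m/z; the window is symmetric and inclusive at both boundaries (a
  candidate exactly on the edge is in). Boundary inclusivity is what
  makes open-mode results a superset of closed-mode results, which the
  tests assert.
- Fragment matching compares floating-point m/z directly; there is no
  integer binning of fragment masses.
- The scoring logarithm base is configurable; the default is 10, the
  established hyperscore convention. log(n!) values come from a table
  memoized via log(n!) = log(n) + log((n−1)!) for n = 0..120; scores
  needing larger counts raise a capacity error instead of computing on
  the fly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δM | 1.0 Da | precursor neutral-mass tolerance (closed); 100–500 Da in open mode |
| δF | 0.01 Da | fragment m/z tolerance |
| min_shared | 4 | matched b+y ions (jointly) required to score a candidate |
| min_hits | 4 | scored candidates required before an e-value is defined |
| top-K | 100 | peaks retained per spectrum |
| missed cleavages | 2 | trypsin, proline suppression on |
| peptide length | 6–46 | filter on the unmodified sequence |
| peptide mass | 500–5000 Da | filter on each modified form |
| max variable PTMs | 5 | per peptide, at most one per site |
| fragment charges | 1–3 | independent of precursor charge |
| precursor window | 500–5000 Da, +1..+4 | spectra outside are flagged excluded |
| chunk size | 512 | search streaming granularity; provably result-neutral |

`min_shared` counts b and y matches jointly; a per-series reading is
possible but not implemented. The length filter applies before
modification, the mass filter after: a variable PTM can move a peptide
across a mass bound, so the bound must see the modified mass.

## Numerical choices

- **Stable sorts.** Peptides are stably sorted by mass (ties keep
  canonical generation order, making the peptide id — and thus the
  "smaller index" tie-break for equal hyperscores — deterministic), and
  fragments stably by m/z (equal-m/z entries keep generation order, so
  entries of one peptide remain adjacent). Any stable sort satisfies the
  contract; numpy's stable argsort is used.
- **Bit-reproducible scoring.** The indexed path and the brute-force
  reference accumulate intensity sums in the identical order: per
  experimental peak (ascending), one fused count×intensity contribution
  per candidate per series. This makes the two paths agree exactly, not
  merely within rounding, and the equivalence tests assert `==` on
  hyperscores.
- **Histogram bins.** floor(h) with unit width; scores below 0 (possible
  when matched intensity sums are < 1 in normalized units) clamp into
  bin 0. The histogram length is floor(h_max)+1.
- **Tail fit.** Survival S(s) = Σ_{b≥s} counts[b]; the fitted tail is
  every bin strictly after the histogram mode (ties for the mode resolve
  to the smallest bin) with S > 0, requiring ≥ 4 points. The fit is
  ordinary least squares on log₁₀ S; a non-negative slope yields an
  undefined e-value with a reason code rather than a nonsensical number.
  On survivals that are exactly log-linear the fit recovers slope and
  intercept to machine precision, which the tests exploit as a closed
  form. Null counts are integers in real searches, but the fit accepts
  float arrays so exact synthetic survivals can be constructed.
- **Normalization.** The rule is configurable (base peak → 100 by
  default; identity and square-root variants). Top-K selection and any
  monotone normalization commute, so their order is irrelevant;
  re-preprocessing an already-preprocessed spectrum is a no-op by
  construction. Intensity ties at the K-th rank keep the lower-m/z peak.
- **E-value gating.** Null distributions are built from candidates that
  passed the min_shared filter (i.e., scored candidates); e-values are
  computed after that filter.

## Synthetic data

The fixture generator emulates the shapes of a tryptic search experiment
so every stage runs with no external data. Proteins are concatenations
of 3–6 tryptic "words" (6–20 random non-K/R/P residues capped by K or
R), guaranteeing each protein digests to length-valid peptides and that
no proline-suppressed sites arise. Spectra contain the generating
peptide's charge-1 b/y ions with rank-decaying intensities (100/rank,
rank order randomized per spectrum) — exercising top-K selection and the
intensity sums nontrivially — plus uniform noise peaks rejected within
2·δF of any signal peak, so ground-truth matched-ion counts are exact.
An optional precursor-only mass shift (e.g. +79.96633 Da) emulates an
unanticipated modification for open-search tests. Everything is
deterministic under the spec's seed.

What the fixtures do **not** emulate: realistic fragmentation intensity
patterns, missing fragments, chimeric spectra, isotope envelopes,
calibration drift, or retention time. Passing the recovery tests
therefore demonstrates the correctness of the indexing/scoring machinery
on spectra whose signal content is known exactly — not identification
performance on real instrument data.

Problem sizes in the test and acceptance runs (tens of proteins, a few
hundred peptide forms, ~10²–10³ spectra) are chosen so a single
brute-force cross-check of every search result remains cheap; all
reported rates are computed at those sizes.

## Design decisions

- The proline suppression rule is a flag (default on) because digestion
  tools differ on it; both behaviors are tested.
- Deamidation targets N/Q (the chemically modifiable residues);
  I and L keep distinct symbols despite equal mass.
- Peptide forms are deduplicated by (sequence, modification set),
  keeping the first parent protein.
- Batch search chunking (default 512 spectra) is purely a streaming
  knob; tests assert chunk size never changes any result. Likewise,
  batched preprocessing is defined to equal the per-spectrum map.
- The brute-force scorer lives in the package as a first-class reference
  implementation so equivalence can be re-verified anywhere; the
  pipeline never calls it.
- Index files serialize as a versioned npz container (arrays + JSON
  metadata); the loader refuses mismatched format versions or generation
  parameters.

## Known limitations

- Top-1 PSM per spectrum only; no FDR, protein inference, or rescoring.
- Only b/y series are generated (the data model admits others).
- A Gumbel-based e-value estimator is a possible alternative to the
  linear tail fit but is not implemented.
- The all-pairs reference scorer is O(|D|·peaks·ions) and intended for
  desk-scale validation only.
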