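"""Database peptide search: candidate filtering, scorecard accumulation,
hyperscore, null distributions, and top-hit selection.

For a query spectrum q the candidate peptides are those whose neutral
mass lies within ±δM of the query's neutral mass (closed search: δM ≈ 1
Da; open search: δM = 100-500 Da to catch unanticipated modification
shifts).  Every experimental peak is looked up in the m/z-sorted fragment
index within ±δF; each (peak, fragment-entry) hit on a candidate
increments that candidate's b- or y-ion count and adds the peak's
normalized intensity to the matching series sum.  Candidates sharing at
least ``min_shared`` fragment ions with q are scored with the hyperscore

    h = log(n_b!) + log(n_y!) + log(Σ i_b) + log(Σ i_y)

(logs in a configurable base, default 10; a log term with zero sum
contributes 0 so a missing series keeps the score finite).  All scored
candidates populate a unit-width integer histogram of hyperscores — the
null distribution used downstream for expectation values.  The top PSM is
the maximal hyperscore, ties resolved to the smaller peptide id.

``search_spectrum_bruteforce`` is a deliberately naive all-pairs
reference scorer implementing the same conventions without the index; it
exists so the indexed path can be validated against an independent
computation and is never called by the pipeline itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .chem import LogFactorialTable, build_log_factorial_table
from .indexing import (
    SERIES_B,
    SERIES_Y,
    FragmentIonIndex,
    fragment_window,
    generate_ions,
    precursor_window,
)
from .preprocessing import PreprocessedSpectrum

__all__ = [
    "SearchParams",
    "NullDistribution",
    "PSM",
    "hyperscore",
    "search_spectrum",
    "search_spectrum_bruteforce",
    "search_batch",
]

_DEFAULT_LFT = build_log_factorial_table()


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances and candidacy thresholds.

    delta_m : precursor neutral-mass tolerance in Da (±, inclusive).
    delta_f : fragment m/z tolerance in Da (±, inclusive).
    min_shared : minimum shared fragment ions (b+y jointly) for a
        candidate to be scored; default 4.
    min_hits : minimum scored candidates for an e-value to be defined
        downstream; default 4.
    """

    delta_m: float = 1.0
    delta_f: float = 0.01
    min_shared: int = 4
    min_hits: int = 4
    chunk_size: int = 512

    def __post_init__(self) -> None:
        if self.delta_m < 0 or self.delta_f < 0:
            raise ValueError("tolerances must be >= 0")
        if self.min_shared < 0 or self.min_hits < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class NullDistribution:
    """Unit-width integer histogram of hyperscores of all scored candidates.

    ``counts[b]`` holds the number of candidates with floor(h) == b
    (negative scores clamp into bin 0); its length is floor(h_max)+1.
    """

    counts: np.ndarray

    @property
    def psi(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _empty_null() -> NullDistribution:
    return NullDistribution(counts=np.zeros(0, dtype=np.int64))


@dataclass
class PSM:
    """A peptide-spectrum match: the best-scoring database candidate."""

    scan_id: int
    peptide_id: int
    sequence: str
    mods: tuple[tuple[int, float, str], ...]
    peptide_mass: float
    charge: int
    hyperscore: float
    n_b: int
    n_y: int
    num_candidates: int
    delta_mass: float
    e_value: float | None = None


def hyperscore(
    n_b: int,
    n_y: int,
    sum_ib: float,
    sum_iy: float,
    lft: LogFactorialTable = _DEFAULT_LFT,
) -> float:
    """Hyperscore of a candidate from its scorecard entries.

    A zero intensity sum contributes 0 rather than -inf, keeping scores
    finite when one ion series is absent.  Counts beyond the table's
    range raise a capacity error.
    """
    if sum_ib < 0 or sum_iy < 0:
        raise ValueError("intensity sums must be >= 0")
    ln_base = math.log(lft.log_base)
    score = lft[n_b] + lft[n_y]
    if sum_ib > 0:
        score += math.log(sum_ib) / ln_base
    if sum_iy > 0:
        score += math.log(sum_iy) / ln_base
    return score


def _histogram(scores: np.ndarray) -> NullDistribution:
    if scores.size == 0:
        return _empty_null()
    bins = np.clip(np.floor(scores).astype(np.int64), 0, None)
    counts = np.bincount(bins, minlength=int(bins.max()) + 1)
    return NullDistribution(counts=counts.astype(np.int64))


def _select_top(
    q: PreprocessedSpectrum,
    index: FragmentIonIndex,
    scored_ids: np.ndarray,
    scores: np.ndarray,
    nb: np.ndarray,
    ny: np.ndarray,
) -> PSM:
    best = int(np.argmax(scores))  # first maximum; ids ascending => smaller peptide_id
    pid = int(scored_ids[best])
    pep = index.peptides[pid]
    return PSM(
        scan_id=q.scan_id,
        peptide_id=pid,
        sequence=pep.sequence,
        mods=pep.mods,
        peptide_mass=pep.neutral_mass,
        charge=q.charge,
        hyperscore=float(scores[best]),
        n_b=int(nb[best]),
        n_y=int(ny[best]),
        num_candidates=len(scores),
        delta_mass=q.neutral_mass - pep.neutral_mass,
    )


def search_spectrum(
    q: PreprocessedSpectrum,
    index: FragmentIonIndex,
    params: SearchParams = SearchParams(),
    lft: LogFactorialTable = _DEFAULT_LFT,
) -> tuple[PSM | None, NullDistribution, int]:
    """Search one preprocessed spectrum against the fragment-ion index.

    Returns ``(top PSM or None, null distribution, scored-candidate
    count)``.  The PSM's e-value is left unset; postprocessing fills it
    when the scored-candidate count reaches ``params.min_hits``.
    """
    if len(index) == 0:
        raise ValueError("empty index")
    if q.exclude_reason is not None:
        return None, _empty_null(), 0

    lo, hi = precursor_window(index, q.neutral_mass, params.delta_m)
    width = hi - lo
    if width <= 0:
        return None, _empty_null(), 0

    # scorecard over the candidate window only
    nb = np.zeros(width, dtype=np.int64)
    ny = np.zeros(width, dtype=np.int64)
    sum_ib = np.zeros(width)
    sum_iy = np.zeros(width)

    # Peak-major accumulation: per peak, per candidate, one fused
    # count*intensity contribution per ion series.  The brute-force
    # reference accumulates in the identical order, so the two paths
    # agree bit-for-bit, not merely within rounding.
    for mz, inten in zip(q.peaks_mz, q.peaks_intensity):
        flo, fhi = fragment_window(index, mz, params.delta_f)
        if flo == fhi:
            continue
        pids = index.frag_peptide_id[flo:fhi]
        series = index.frag_series[flo:fhi]
        in_window = (pids >= lo) & (pids < hi)
        if not in_window.any():
            continue
        slot = pids[in_window] - lo
        is_b = series[in_window] == SERIES_B
        for mask, counts_arr, sums_arr in ((is_b, nb, sum_ib), (~is_b, ny, sum_iy)):
            slots, counts = np.unique(slot[mask], return_counts=True)
            counts_arr[slots] += counts
            sums_arr[slots] += counts * inten

    scored = np.flatnonzero(nb + ny >= params.min_shared)
    if scored.size == 0:
        return None, _empty_null(), 0
    scores = np.array(
        [hyperscore(int(nb[i]), int(ny[i]), sum_ib[i], sum_iy[i], lft) for i in scored]
    )
    null = _histogram(scores)
    psm = _select_top(q, index, scored + lo, scores, nb[scored], ny[scored])
    return psm, null, scored.size


def search_spectrum_bruteforce(
    q: PreprocessedSpectrum,
    index: FragmentIonIndex,
    params: SearchParams = SearchParams(),
    lft: LogFactorialTable = _DEFAULT_LFT,
) -> tuple[PSM | None, NullDistribution, int]:
    """All-pairs reference scorer: no fragment index, same conventions.

    Loops over every database peptide, regenerates its theoretical ions,
    and counts every (peak, ion) pair within δF once — the independent
    oracle the indexed search is validated against.
    """
    if len(index) == 0:
        raise ValueError("empty index")
    if q.exclude_reason is not None:
        return None, _empty_null(), 0

    scored_ids: list[int] = []
    scores: list[float] = []
    nbs: list[int] = []
    nys: list[int] = []
    mass_lo = q.neutral_mass - params.delta_m
    mass_hi = q.neutral_mass + params.delta_m
    for pep in index.peptides:
        if not (mass_lo <= pep.neutral_mass <= mass_hi):
            continue
        ions = generate_ions(pep, index.params.series, index.params.max_fragment_charge)
        ion_mz = np.array([mz for mz, _, _ in ions])
        ion_is_b = np.array([s == "b" for _, s, _ in ions])
        # peaks x ions boolean match matrix; each True pair counts once
        match = (ion_mz[None, :] >= (q.peaks_mz - params.delta_f)[:, None]) & (
            ion_mz[None, :] <= (q.peaks_mz + params.delta_f)[:, None]
        )
        kb = match[:, ion_is_b].sum(axis=1)  # per-peak matched b entries
        ky = match[:, ~ion_is_b].sum(axis=1)
        n_b, n_y = int(kb.sum()), int(ky.sum())
        if n_b + n_y < params.min_shared:
            continue
        # accumulate count*intensity per peak, ascending peak order
        s_ib = 0.0
        for p in np.flatnonzero(kb):
            s_ib += kb[p] * q.peaks_intensity[p]
        s_iy = 0.0
        for p in np.flatnonzero(ky):
            s_iy += ky[p] * q.peaks_intensity[p]
        scored_ids.append(pep.peptide_id)
        scores.append(hyperscore(n_b, n_y, float(s_ib), float(s_iy), lft))
        nbs.append(n_b)
        nys.append(n_y)

    if not scored_ids:
        return None, _empty_null(), 0
    scores_arr = np.array(scores)
    null = _histogram(scores_arr)
    psm = _select_top(q, index, np.array(scored_ids), scores_arr, np.array(nbs), np.array(nys))
    return psm, null, len(scored_ids)


def search_batch(
    batch: Sequence[PreprocessedSpectrum],
    index: FragmentIonIndex,
    params: SearchParams = SearchParams(),
    lft: LogFactorialTable = _DEFAULT_LFT,
) -> list[tuple[PSM | None, NullDistribution, int]]:
    """Search a batch of spectra in chunks of ``params.chunk_size``.

    Chunking is a streaming knob only; results are element-wise identical
    to mapping :func:`search_spectrum` over the batch.
    """
    out: list[tuple[PSM | None, NullDistribution, int]] = []
    chunk = max(1, params.chunk_size)
    for start in range(0, len(batch), chunk):
        for q in batch[start : start + chunk]:
            out.append(search_spectrum(q, index, params, lft))
    return out
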