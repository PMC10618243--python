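"""Expectation values via linear tail fit, result assembly, and the pipeline.

The e-value of a top hit measures the expected number of random database
candidates scoring at least as high.  It is obtained from the spectrum's
null distribution N (histogram of all scored candidates' hyperscores):
compute the survival function S(s) = Σ_{b≥s} N[b], fit a least-squares
line to log10 S over the tail bins (strictly above the histogram mode,
with S > 0), and extrapolate to the top hyperscore:

    e_value = 10^(c + a·h_top)

with slope a and intercept c.  The fit is declared undefined — with a
reason code — when fewer than ``min_hits`` candidates were scored, when
fewer than ``min_tail_points`` usable tail bins exist, or when the fitted
slope is not negative.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import BUILTIN_MODIFICATIONS, Modification, build_log_factorial_table
from .digestion import DigestParams, ModForm, digest_protein, enumerate_modforms, read_fasta
from .indexing import FragmentIonIndex, IndexParams, build_index
from .preprocessing import FilterParams, preprocess_file
from .search import PSM, NullDistribution, SearchParams, search_batch

__all__ = [
    "TailFitParams",
    "TailFitResult",
    "tail_fit_evalue",
    "write_results",
    "build_database",
    "run_pipeline",
]

logger = logging.getLogger("fisearch")


@dataclass(frozen=True)
class TailFitParams:
    """Free parameters of the survival-tail fit."""

    min_tail_points: int = 4
    min_hits: int = 4

    def __post_init__(self) -> None:
        if self.min_tail_points < 2:
            raise ValueError("min_tail_points must be >= 2")


@dataclass(frozen=True)
class TailFitResult:
    """Outcome of a tail fit: the e-value or a reason it is undefined."""

    e_value: float | None
    slope: float | None = None
    intercept: float | None = None
    reason: str | None = None


def tail_fit_evalue(
    null: NullDistribution,
    h_top: float,
    params: TailFitParams = TailFitParams(),
) -> TailFitResult:
    """Linear tail fit of the log10 survival of a null distribution.

    Tail bins start strictly after the histogram mode (ties resolved to
    the smallest bin) and include every later bin with positive survival.
    Counts are normally integers; float arrays are accepted so exactly
    log-linear synthetic survivals can be fitted without rounding.
    """
    if h_top < 0:
        raise ValueError("h_top must be >= 0")
    counts = np.asarray(null.counts, dtype=float)
    if counts.sum() < params.min_hits:
        return TailFitResult(None, reason="insufficient_hits")

    survival = counts[::-1].cumsum()[::-1]  # S(s) = sum_{b >= s} counts[b]
    mode = int(np.argmax(counts))
    tail = np.arange(mode + 1, len(counts))
    tail = tail[survival[tail] > 0]
    if len(tail) < params.min_tail_points:
        return TailFitResult(None, reason="insufficient_tail")

    slope, intercept = np.polyfit(tail, np.log10(survival[tail]), 1)
    if not slope < 0:
        return TailFitResult(None, slope=float(slope), intercept=float(intercept), reason="nonnegative_slope")
    e_value = 10.0 ** (intercept + slope * h_top)
    return TailFitResult(float(e_value), slope=float(slope), intercept=float(intercept))


_COLUMNS = (
    "scan_id",
    "peptide",
    "mods",
    "neutral_mass",
    "delta_mass",
    "charge",
    "hyperscore",
    "n_b",
    "n_y",
    "num_candidates",
    "e_value",
)


def _format_mods(mods: tuple[tuple[int, float, str], ...]) -> str:
    return ";".join(f"{name}@{pos}:{delta:+.5f}" for pos, delta, name in mods) or "-"


def write_results(psms: Sequence[PSM], path: str | Path) -> None:
    """Write PSMs to a TSV with a stable column order; undefined e-values
    appear as the literal ``NA``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for p in psms:
            writer.writerow(
                [
                    p.scan_id,
                    p.sequence,
                    _format_mods(p.mods),
                    f"{p.peptide_mass:.5f}",
                    f"{p.delta_mass:.5f}",
                    p.charge,
                    f"{p.hyperscore:.4f}",
                    p.n_b,
                    p.n_y,
                    p.num_candidates,
                    "NA" if p.e_value is None else f"{p.e_value:.6e}",
                ]
            )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: digestion, modifications, index, search, scoring."""

    digest: DigestParams = field(default_factory=DigestParams)
    fixed_mods: tuple[Modification, ...] = (BUILTIN_MODIFICATIONS["carbamidomethyl"],)
    variable_mods: tuple[Modification, ...] = ()
    max_var_mods: int = 5
    index: IndexParams = field(default_factory=IndexParams)
    search: SearchParams = field(default_factory=SearchParams)
    tail_fit: TailFitParams = field(default_factory=TailFitParams)
    filters: FilterParams = field(default_factory=FilterParams)
    top_k: int = 100
    normalization: str = "basepeak100"
    log_base: float = 10.0


def build_database(fasta_path: str | Path, config: PipelineConfig) -> FragmentIonIndex:
    """FASTA -> digested, PTM-expanded, indexed database."""
    proteins = read_fasta(fasta_path)
    logger.info("proteins: %d", len(proteins))

    forms: list[ModForm] = []
    seen: set[tuple[str, tuple]] = set()
    n_peptides = 0
    for header, seq in proteins:
        accession = header.split()[0] if header else "?"
        for pep, _start in digest_protein(seq, config.digest):
            n_peptides += 1
            for form in enumerate_modforms(
                pep,
                config.fixed_mods,
                config.variable_mods,
                config.max_var_mods,
                mass_range=(config.digest.min_mass, config.digest.max_mass),
            ):
                key = (form.sequence, form.mods)
                if key in seen:  # dedup by (sequence, mod set); keep first parent
                    continue
                seen.add(key)
                forms.append(ModForm(form.sequence, form.mods, form.neutral_mass, (accession,)))
    logger.info("peptides: %d, modified forms: %d", n_peptides, len(forms))

    index = build_index(forms, config.index)
    logger.info("fragments: %d", index.num_fragments)
    return index


def run_pipeline(
    fasta_path: str | Path,
    ms2_path: str | Path,
    out_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    cache_dir: str | Path | None = None,
) -> list[PSM]:
    """Full search: digest -> modforms -> index -> preprocess -> search -> e-values -> TSV.

    Preprocessing results are cached next to the output (or in
    ``cache_dir``); a second run with unchanged inputs and settings
    reports a cache hit and skips the stage.
    """
    out_path = Path(out_path)
    cache_dir = Path(cache_dir) if cache_dir is not None else out_path.parent / "preprocess_cache"

    index = build_database(fasta_path, config)

    spectra, cache_hit = preprocess_file(
        ms2_path, cache_dir, config.top_k, config.normalization, config.filters
    )
    kept = sum(1 for s in spectra if s.exclude_reason is None)
    logger.info(
        "spectra: %d kept, %d excluded%s",
        kept,
        len(spectra) - kept,
        " (preprocessing cache hit)" if cache_hit else "",
    )

    lft = build_log_factorial_table(log_base=config.log_base)
    results = search_batch(spectra, index, config.search, lft)

    psms: list[PSM] = []
    for psm, null, n_scored in results:
        if psm is None:
            continue
        if n_scored >= config.search.min_hits:
            fit = tail_fit_evalue(null, max(psm.hyperscore, 0.0), config.tail_fit)
            psm.e_value = fit.e_value
        psms.append(psm)
    logger.info("PSMs: %d", len(psms))

    write_results(psms, out_path)
    return psms
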