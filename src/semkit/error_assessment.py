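"""Quantifying sequencing error from draft-vs-finished alignments.

A draft (low-coverage) assembly aligned to finished-grade sequence of the
same species shows three kinds of differences: base mismatches (candidate
miscalled bases), gaps in the finished sequence (candidate insertion
errors), and gaps in the draft (candidate deletion errors). Tabulating
these by the draft base's quality bin gives per-bin difference rates
``d_esq`` (event type *e*, species *s*, bin *q*).

Differences at the highest-quality bases (bin 9, q >= 45) are taken to be
almost entirely polymorphism between the individuals sequenced, so the
bin-9 rate ``d_esQ`` is a proxy for nucleotide diversity. Subtracting it
from each lower bin yields the polymorphism-corrected error rate
``r_esq = max(d_esq - d_esQ, 0)``; at the aggregate level the corrected
rate is simply raw minus polymorphism. The same logic turns mitigation
bookkeeping into *expected* confusion counts: within a stratum a fraction
``f = d_esQ / d_esq`` of observed differences are assumed polymorphic, and
that expectation is shifted from true to false positives (and from false
to true negatives).

Sites where the draft base is ``N`` are excluded from both numerators and
denominators throughout, so previously masked bases cannot re-enter rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align_io import (
    GAP,
    N_BINS,
    QualityAlignmentBlock,
    RegionSet,
    bin_representative,
    decode_quality_char,
    iter_pair_columns,
)

__all__ = [
    "ERROR_TYPES",
    "DifferenceTable",
    "CorrectedRates",
    "ConfusionCounts",
    "IndelCall",
    "IndelSpectrum",
    "tabulate_differences",
    "collect_indel_calls",
    "polymorphism_correct",
    "confusion_adjusted",
    "roc_sweep",
    "exon_error_expectation",
    "exon_coverage_fractions",
    "indel_length_spectrum",
    "indel_quality",
]

ERROR_TYPES = ("basecall", "insertion", "deletion")

#: Indel events longer than this many bases go to the "long" bucket and are
#: excluded from length spectra (mirrors the imputation event-size limit).
MAX_INDEL_LEN = 10


# ---------------------------------------------------------------------------
# difference tabulation


@dataclass
class DifferenceTable:
    """Counts of aligned sites and differences stratified by quality bin."""

    species: str
    reference: str = ""
    sites: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS))
    diffs: dict[str, np.ndarray] = field(
        default_factory=lambda: {e: np.zeros(N_BINS) for e in ERROR_TYPES}
    )
    # (true base, draft base, bin) -> count; feeds the error-spectrum matrix
    substitutions: dict[tuple[str, str, int], float] = field(default_factory=dict)
    long_indels: dict[str, int] = field(
        default_factory=lambda: {"insertion": 0, "deletion": 0}
    )

    def rate(self, etype: str, q: int) -> float:
        """Per-kb difference rate ``d_esq`` at bin *q* (NaN if no sites)."""
        if self.sites[q] == 0:
            return float("nan")
        return 1000.0 * self.diffs[etype][q] / self.sites[q]

    def rates(self, etype: str) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.sites > 0, 1000.0 * self.diffs[etype] / self.sites, np.nan
            )

    def aggregate_rate(self, etype: str) -> float:
        total = self.sites.sum()
        if total == 0:
            return float("nan")
        return 1000.0 * self.diffs[etype].sum() / total

    def substitution_counts(
        self, max_bin: int = 8
    ) -> dict[tuple[str, str], float]:
        """Mismatch spectrum (true -> draft) summed over bins <= *max_bin*."""
        out: dict[tuple[str, str], float] = {}
        for (i, j, q), c in self.substitutions.items():
            if q <= max_bin:
                out[(i, j)] = out.get((i, j), 0.0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in ERROR_TYPES:
            for q in range(N_BINS):
                rows.append(
                    {
                        "species": self.species,
                        "type": e,
                        "bin": q,
                        "sites": self.sites[q],
                        "diffs": self.diffs[e][q],
                        "rate": self.rate(e, q),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_aggregate_rates(
        cls,
        species: str,
        rates: Mapping[str, tuple[float, float]],
        sites_per_stratum: float = 1_000_000.0,
    ) -> "DifferenceTable":
        """Build a two-bin tabulation reproducing given aggregate rates.

        *rates* maps an error type to ``(raw_per_kb, poly_per_kb)``: the
        aggregate difference rate over all bases and the bin-9 rate. Sites
        are split evenly between a low-quality bin (3) and bin 9, with
        difference counts chosen so that the table's aggregate raw rate and
        bin-9 rate equal the inputs. Useful for desk calculations from
        published summary rates.
        """
        t = cls(species=species)
        S = sites_per_stratum
        t.sites[3] = S
        t.sites[9] = S
        for e, (raw, poly) in rates.items():
            if e not in ERROR_TYPES:
                raise ValueError(f"unknown error type {e!r}")
            d9 = poly * S / 1000.0
            d3 = raw * 2 * S / 1000.0 - d9
            if d3 < 0:
                raise ValueError(f"{e}: aggregate raw {raw} incompatible with poly {poly}")
            t.diffs[e][3] = d3
            t.diffs[e][9] = d9
        return t


def indel_quality(
    block: QualityAlignmentBlock,
    species: str,
    col_start: int,
    col_end: int,
    kind: str,
    flank: int = 5,
) -> int:
    """Quality bin of an indel: the minimum over nearby draft bases.

    For an insertion (draft bases in ``[col_start, col_end)``) the minimum
    is over the inserted bases and up to *flank* draft bases on each side;
    for a deletion (draft gap) only the flanking bases contribute. Flanks
    truncated at block edges use whatever bases are available.
    """
    row = block.row(species)
    if row.quality is None:
        raise ValueError(f"{species}: no quality track")
    bins: list[int] = []
    if kind == "insertion":
        for i in range(col_start, col_end):
            if row.text[i] != GAP:
                b = decode_quality_char(row.quality[i])
                if b is not None:
                    bins.append(b)
    # left flank
    found = 0
    i = col_start - 1
    while i >= 0 and found < flank:
        if row.text[i] != GAP:
            b = decode_quality_char(row.quality[i])
            if b is not None:
                bins.append(b)
            found += 1
        i -= 1
    # right flank
    found = 0
    i = col_end
    while i < block.ncols and found < flank:
        if row.text[i] != GAP:
            b = decode_quality_char(row.quality[i])
            if b is not None:
                bins.append(b)
            found += 1
        i += 1
    return min(bins) if bins else N_BINS - 1


@dataclass
class IndelCall:
    """One candidate indel-error event in a draft-vs-reference alignment."""

    species: str
    block_index: int
    col_start: int
    col_end: int  # half-open column span
    kind: str  # insertion | deletion
    length: int
    quality: int  # quality bin

    @property
    def frame_class(self) -> int:
        return self.length % 3


def _scan_pair(
    block: QualityAlignmentBlock,
    draft: str,
    reference: str,
    regions: Optional[RegionSet],
    ref_chrom: str,
):
    """Yield per-column site/mismatch records and indel runs for one block.

    Returns ``(site_records, indel_runs)`` where site_records are tuples
    ``(bin, ref_base, draft_base, in_region)`` for doubly aligned non-N
    columns and indel_runs are ``(kind, col_start, col_end, length,
    in_region)`` for maximal gap runs.
    """
    sites = []
    runs = []
    run_kind: Optional[str] = None
    run_start = 0
    run_len = 0
    run_anchor: Optional[int] = None
    last_ref_pos: Optional[int] = None

    def flush(end_col: int) -> None:
        nonlocal run_kind, run_len
        if run_kind is not None:
            in_region = True
            if regions is not None:
                anchor = run_anchor if run_anchor is not None else 0
                in_region = regions.contains(ref_chrom, anchor)
            runs.append((run_kind, run_start, end_col, run_len, in_region))
        run_kind = None
        run_len = 0

    for col in iter_pair_columns(block, ref=reference, other=draft):
        rb, db = col.ref_base, col.other_base
        if col.ref_pos is not None:
            last_ref_pos = col.ref_pos
        if rb != GAP and db != GAP:
            flush(col.index)
            if rb != "N" and db != "N":
                in_region = regions is None or regions.contains(ref_chrom, col.ref_pos)
                q = col.other_qual
                if q is None:
                    raise ValueError(f"{draft}: aligned base without quality")
                sites.append((q, rb, db, in_region))
        elif rb == GAP:  # draft has extra bases: candidate insertion error
            if db == "N":
                flush(col.index)
                continue
            if run_kind != "insertion":
                flush(col.index)
                run_kind = "insertion"
                run_start = col.index
                run_anchor = last_ref_pos
            run_len += 1
        else:  # draft gap: candidate deletion error
            if rb == "N":
                flush(col.index)
                continue
            if run_kind != "deletion":
                flush(col.index)
                run_kind = "deletion"
                run_start = col.index
                run_anchor = last_ref_pos
            run_len += 1
    flush(block.ncols)
    return sites, runs


def tabulate_differences(
    blocks: Iterable[QualityAlignmentBlock],
    draft: str,
    reference: str,
    regions: Optional[RegionSet] = None,
) -> DifferenceTable:
    """Tabulate draft-vs-reference differences by draft quality bin.

    A mismatch of two bases counts one basecall difference at the draft
    base's bin; a maximal gap run in the reference counts one insertion
    event and a maximal run in the draft one deletion event, each binned by
    :func:`indel_quality`. Aligned sites (the denominator) are doubly
    aligned non-N columns. With *regions*, counting is restricted to
    reference coordinates inside the set.
    """
    table = DifferenceTable(species=draft, reference=reference)
    for block in blocks:
        rrow = block.row(reference)
        sites, runs = _scan_pair(block, draft, reference, regions, rrow.src)
        for q, rb, db, in_region in sites:
            if not in_region:
                continue
            table.sites[q] += 1
            if rb != db:
                table.diffs["basecall"][q] += 1
                key = (rb, db, q)
                table.substitutions[key] = table.substitutions.get(key, 0.0) + 1
        for kind, c0, c1, length, in_region in runs:
            if not in_region:
                continue
            q = indel_quality(block, draft, c0, c1, kind)
            table.diffs[kind][q] += 1
            if length > MAX_INDEL_LEN:
                table.long_indels[kind] += 1
    return table


def collect_indel_calls(
    blocks: Iterable[QualityAlignmentBlock],
    draft: str,
    reference: str,
    regions: Optional[RegionSet] = None,
    max_len: int = MAX_INDEL_LEN,
) -> tuple[list[IndelCall], dict[str, int]]:
    """Extract indel events as :class:`IndelCall` records.

    Events longer than *max_len* are excluded from the returned list but
    counted in the second return value (the "long" bucket).
    """
    calls: list[IndelCall] = []
    long_bucket = {"insertion": 0, "deletion": 0}
    for bi, block in enumerate(blocks):
        rrow = block.row(reference)
        _, runs = _scan_pair(block, draft, reference, regions, rrow.src)
        for kind, c0, c1, length, in_region in runs:
            if not in_region:
                continue
            if length > max_len:
                long_bucket[kind] += 1
                continue
            q = indel_quality(block, draft, c0, c1, kind)
            calls.append(
                IndelCall(
                    species=draft,
                    block_index=bi,
                    col_start=c0,
                    col_end=c1,
                    kind=kind,
                    length=length,
                    quality=q,
                )
            )
    return calls, long_bucket


# ---------------------------------------------------------------------------
# polymorphism correction


@dataclass
class CorrectedRates:
    """Polymorphism-adjusted error rates derived from a difference table."""

    species: str
    # per-bin corrected rate r_esq (per kb); NaN at bin 9 and empty bins
    per_bin: dict[str, np.ndarray]
    # assumed polymorphic fraction d_esQ / d_esq per bin, capped at 1
    poly_fraction: dict[str, np.ndarray]
    # aggregate Raw / Poly. / Corr. per error type
    aggregate: pd.DataFrame
    unavailable: list[str] = field(default_factory=list)

    def corrected_aggregate(self, etype: str) -> float:
        row = self.aggregate[self.aggregate["type"] == etype]
        return float(row["corrected"].iloc[0])


def polymorphism_correct(table: DifferenceTable) -> CorrectedRates:
    """Subtract the bin-9 (polymorphism) rate from each lower bin.

    Per bin: ``r_esq = max(d_esq - d_esQ, 0)`` (negative values, which
    arise from sampling noise, are clamped to zero with a warning). The
    aggregate corrected rate is the aggregate raw rate minus the bin-9
    rate, reproducing a Raw/Poly./Corr. layout. Error types with no bin-9
    sites cannot be corrected and are flagged in ``unavailable``.
    """
    per_bin: dict[str, np.ndarray] = {}
    poly_fraction: dict[str, np.ndarray] = {}
    agg_rows = []
    unavailable: list[str] = []
    have_bin9 = table.sites[N_BINS - 1] > 0
    for e in ERROR_TYPES:
        d = table.rates(e)
        raw = table.aggregate_rate(e)
        if not have_bin9:
            unavailable.append(e)
            per_bin[e] = np.full(N_BINS, np.nan)
            poly_fraction[e] = np.full(N_BINS, np.nan)
            agg_rows.append(
                {"species": table.species, "type": e, "raw": raw,
                 "poly": np.nan, "corrected": np.nan}
            )
            continue
        dQ = d[N_BINS - 1]
        r = d - dQ
        if np.any(r[~np.isnan(r)] < -1e-12):
            warnings.warn(
                f"{table.species}/{e}: negative corrected rate clamped to 0"
            )
        r = np.clip(r, 0.0, None)
        r[N_BINS - 1] = np.nan  # correction defined for q < 45 only
        per_bin[e] = r
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(d > 0, np.minimum(dQ / d, 1.0), np.nan)
        poly_fraction[e] = f
        corrected = raw - dQ
        if corrected < 0:
            warnings.warn(
                f"{table.species}/{e}: negative aggregate corrected rate clamped"
            )
            corrected = 0.0
        agg_rows.append(
            {"species": table.species, "type": e, "raw": raw, "poly": dQ,
             "corrected": corrected}
        )
    return CorrectedRates(
        species=table.species,
        per_bin=per_bin,
        poly_fraction=poly_fraction,
        aggregate=pd.DataFrame(agg_rows),
        unavailable=unavailable,
    )


# ---------------------------------------------------------------------------
# confusion counts with polymorphism adjustment


@dataclass
class ConfusionCounts:
    """Expected confusion counts after polymorphism adjustment.

    FPR is the fraction of correctly called bases that are unnecessarily
    masked; TPR the fraction of miscalled bases that are masked; PPV the
    fraction of masked bases that really were miscalled.
    """

    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else float("nan")

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d > 0 else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d > 0 else float("nan")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion_adjusted(
    strata: Iterable[tuple[float, float, float, float, float]]
) -> ConfusionCounts:
    """Sum polymorphism-adjusted confusion counts over strata.

    Each stratum is ``(masked_diffs, masked_nondiffs, unmasked_diffs,
    unmasked_nondiffs, f)`` with *f* the assumed polymorphic fraction of
    differences in that stratum. A fraction ``f`` of masked differences is
    moved from true to false positives, and of unmasked differences from
    false to true negatives. Strata with undefined *f* (NaN) contribute raw
    counts.
    """
    out = ConfusionCounts()
    for md, mn, ud, un, f in strata:
        if f is None or (isinstance(f, float) and np.isnan(f)):
            f = 0.0
        out.tp += md * (1.0 - f)
        out.fp += mn + md * f
        out.fn += ud * (1.0 - f)
        out.tn += un + ud * f
    return out


def _mask_site_records(blocks, draft, reference):
    records = []  # (bin, is_diff)
    for block in blocks:
        rrow = block.row(reference)
        sites, _ = _scan_pair(block, draft, reference, None, rrow.src)
        for q, rb, db, _ in sites:
            records.append((q, rb != db))
    return records


def roc_sweep(
    blocks: Sequence[QualityAlignmentBlock],
    draft: str,
    reference: str,
    thresholds: Sequence[int],
    mode: str = "mask",
) -> list[tuple[int, ConfusionCounts]]:
    """Polymorphism-adjusted confusion counts as the quality threshold varies.

    In ``mask`` mode the decision unit is an aligned draft base (masked iff
    its bin representative is below the threshold, in raw phred units); in
    ``indel`` mode it is an indel event (corrected iff its
    :func:`indel_quality` representative is below the threshold). TPR and
    FPR are non-decreasing in the threshold.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if mode not in ("mask", "indel"):
        raise ValueError(f"unknown mode {mode!r}")
    blocks = list(blocks)
    table = tabulate_differences(iter(blocks), draft, reference)
    corr = polymorphism_correct(table)

    out: list[tuple[int, ConfusionCounts]] = []
    if mode == "mask":
        records = _mask_site_records(blocks, draft, reference)
        f_by_bin = corr.poly_fraction["basecall"]
        for T in thresholds:
            strata: dict[int, list[float]] = {}
            for q, is_diff in records:
                st = strata.setdefault(q, [0.0, 0.0, 0.0, 0.0])
                masked = bin_representative(q) < T
                idx = (0 if is_diff else 1) if masked else (2 if is_diff else 3)
                st[idx] += 1
            out.append(
                (T, confusion_adjusted(
                    (md, mn, ud, un, f_by_bin[q])
                    for q, (md, mn, ud, un) in strata.items()
                ))
            )
    else:
        calls, _ = collect_indel_calls(iter(blocks), draft, reference, max_len=10**9)
        for T in thresholds:
            strata = {}
            for call in calls:
                st = strata.setdefault((call.kind, call.quality), [0.0, 0.0, 0.0, 0.0])
                corrected = bin_representative(call.quality) < T
                # every event is an observed difference
                st[0 if corrected else 2] += 1
            out.append(
                (T, confusion_adjusted(
                    (md, mn, ud, un, corr.poly_fraction[kind][q])
                    for (kind, q), (md, mn, ud, un) in strata.items()
                ))
            )
    return out


# ---------------------------------------------------------------------------
# descriptive statistics


def exon_coverage_fractions(
    blocks: Iterable[QualityAlignmentBlock],
    reference: str,
    species: Sequence[str],
    exons: RegionSet,
) -> dict[str, float]:
    """Fraction of exon bases covered by aligned non-N draft sequence."""
    if len(exons) == 0:
        raise ValueError("empty exon set")
    total = exons.merged().total_bp()
    covered = {sp: 0 for sp in species}
    for block in blocks:
        rrow = block.row(reference)
        for sp in species:
            if not block.has_species(sp):
                continue
            for col in iter_pair_columns(block, ref=reference, other=sp):
                if (
                    col.ref_pos is not None
                    and col.other_base not in (GAP, "N")
                    and exons.contains(rrow.src, col.ref_pos)
                ):
                    covered[sp] += 1
    return {sp: covered[sp] / total for sp in species}


def exon_error_expectation(
    rates_per_kb: Mapping[str, float],
    coverage: Mapping[str, float],
    exon_length: int = 120,
    species_scale: float = 20.0 / 14.0,
) -> float:
    """Expected error count per exon, summed over species.

    ``sum_s rate_s/1000 * coverage_s * exon_length * species_scale``, where
    *rates_per_kb* are corrected per-kb error rates (basecall or indel) and
    *coverage* the per-species covered fraction of exonic bases. The scale
    factor extrapolates from the species with finished-grade truth to the
    full species panel; incomplete coverage reduces the expectation and is
    deliberately not compensated.
    """
    if not rates_per_kb:
        raise ValueError("no per-species rates")
    total = 0.0
    for sp, rate in rates_per_kb.items():
        cov = coverage.get(sp, 0.0)
        total += (rate / 1000.0) * cov * exon_length
    return total * species_scale


@dataclass
class IndelSpectrum:
    """Length histogram of indel calls with frame-periodicity summary."""

    counts: pd.Series  # index 1..10
    periodicity: float  # fraction of events with length % 3 == 0
    n_total: int


def indel_length_spectrum(calls: Sequence[IndelCall]) -> IndelSpectrum:
    counts = pd.Series(0, index=pd.RangeIndex(1, MAX_INDEL_LEN + 1, name="length"))
    n3 = 0
    for call in calls:
        if 1 <= call.length <= MAX_INDEL_LEN:
            counts[call.length] += 1
            if call.length % 3 == 0:
                n3 += 1
    n = int(counts.sum())
    return IndelSpectrum(
        counts=counts,
        periodicity=(n3 / n) if n else 0.0,
        n_total=n,
    )
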