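"""Reading and writing of quality-augmented MAF alignments, BED regions, and FASTQ reads.

The central container is :class:`QualityAlignmentBlock`, one MAF ``a`` block
whose rows may carry a per-base quality line (MAF ``q`` lines in the UCSC
dialect: one character per alignment column, ``0``–``9`` for binned phred
scores, ``F`` for finished sequence, ``-`` at gaps).

Quality scores are handled in a reduced representation: raw phred values are
collapsed to bins of 5 phred units, with everything >= 45 in the top bin.
Bin *b* covers raw scores ``[5b, 5b+5)`` and is represented by its lower
bound ``5b``; all threshold comparisons in this package ("q < 20") are made
against that representative, so a threshold of 20 selects bins 0–3 exactly.

Coordinates are 0-based half-open throughout (native MAF/BED semantics);
rows on the ``-`` strand keep MAF semantics, i.e. ``start`` counts from the
5' end of the reverse-complemented source.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

__all__ = [
    "GAP",
    "N_BINS",
    "MafParseError",
    "QualityAlignmentBlock",
    "MafRow",
    "AlignedColumn",
    "RegionSet",
    "bin_quality",
    "bin_representative",
    "decode_quality_char",
    "encode_quality_char",
    "read_maf",
    "write_maf",
    "read_regions",
    "read_fastq_qualities",
    "iter_pair_columns",
]

GAP = "-"
N_BINS = 10
_VALID_BASES = frozenset("ACGTN-")
_QUAL_CHARS = frozenset("0123456789F-")


class MafParseError(ValueError):
    """Malformed MAF/BED input; message carries the offending line number."""


# ---------------------------------------------------------------------------
# quality binning


def bin_quality(q_raw: int) -> int:
    """Collapse a raw phred score to its 5-unit bin (0–9).

    Bin ``b`` covers raw scores ``[5b, 5b+5)``; every score >= 45 maps to
    bin 9, the "finished-grade" category.
    """
    if q_raw < 0:
        raise ValueError(f"negative phred score: {q_raw}")
    return min(q_raw // 5, N_BINS - 1)


def bin_representative(b: int) -> int:
    """Representative raw phred value of a bin: its lower bound ``5*b``."""
    if not 0 <= b < N_BINS:
        raise ValueError(f"quality bin out of range: {b}")
    return 5 * b


def decode_quality_char(c: str) -> Optional[int]:
    """Decode one MAF quality character to a bin; ``-`` (gap) -> None."""
    if c == GAP:
        return None
    if c == "F":  # finished sequence, treated as the top bin
        return 9
    if c.isdigit():
        return int(c)
    raise ValueError(f"invalid quality character: {c!r}")


def encode_quality_char(b: Optional[int]) -> str:
    if b is None:
        return GAP
    if not 0 <= b < N_BINS:
        raise ValueError(f"quality bin out of range: {b}")
    return str(b)


# ---------------------------------------------------------------------------
# MAF blocks


@dataclass
class MafRow:
    """One ``s`` line of a MAF block, plus its optional ``q`` quality line."""

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str
    quality: Optional[str] = None  # same length as text; '-' at gaps

    @property
    def species(self) -> str:
        """Species name: the ``src`` field up to the first dot."""
        return self.src.split(".", 1)[0]

    def quality_bins(self) -> Optional[list[Optional[int]]]:
        if self.quality is None:
            return None
        return [decode_quality_char(c) for c in self.quality]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.src}: bad strand {self.strand!r}")
        ungapped = len(self.text) - self.text.count(GAP)
        if ungapped != self.size:
            raise ValueError(
                f"{self.src}: size {self.size} != non-gap characters {ungapped}"
            )
        if self.quality is not None:
            if len(self.quality) != len(self.text):
                raise ValueError(f"{self.src}: quality length != text length")
            for b, q in zip(self.text, self.quality):
                if (b == GAP) != (q == GAP):
                    raise ValueError(f"{self.src}: quality gaps misaligned with text")


@dataclass
class QualityAlignmentBlock:
    """One MAF alignment block with optional per-row quality tracks."""

    rows: list[MafRow]
    score: Optional[float] = None

    @property
    def ncols(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def row(self, species: str) -> MafRow:
        for r in self.rows:
            if r.species == species or r.src == species:
                return r
        raise KeyError(f"species {species!r} not in block")

    def has_species(self, species: str) -> bool:
        try:
            self.row(species)
            return True
        except KeyError:
            return False

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("empty block")
        n = self.ncols
        for r in self.rows:
            if len(r.text) != n:
                raise ValueError(f"{r.src}: text length {len(r.text)} != {n}")
            r.validate()

    def copy(self) -> "QualityAlignmentBlock":
        return QualityAlignmentBlock(rows=[replace(r) for r in self.rows], score=self.score)


def _normalize_text(text: str, line_no: int) -> str:
    text = text.upper()
    if set(text) <= _VALID_BASES:
        return text
    cleaned = []
    for c in text:
        if c in _VALID_BASES:
            cleaned.append(c)
        else:
            cleaned.append("N")
    warnings.warn(f"line {line_no}: non-ACGTN characters mapped to N")
    return "".join(cleaned)


def read_maf(path: Union[str, Path, TextIO]) -> Iterator[QualityAlignmentBlock]:
    """Stream MAF blocks from *path*.

    ``q`` lines must follow the ``s`` line they annotate; blocks without
    ``q`` lines yield rows with ``quality=None``. ``i``/``e`` lines and
    comments are skipped.
    """
    handle: TextIO
    own = False
    if hasattr(path, "read"):
        handle = path  # type: ignore[assignment]
    else:
        handle = open(path)
        own = True
    try:
        block: Optional[QualityAlignmentBlock] = None
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#") or line.startswith("track"):
                continue
            if not line.strip():
                if block is not None:
                    _finish_block(block, line_no)
                    yield block
                    block = None
                continue
            fields = line.split()
            tag = fields[0]
            if tag == "a":
                if block is not None:
                    _finish_block(block, line_no)
                    yield block
                score = None
                for f in fields[1:]:
                    if f.startswith("score="):
                        score = float(f[len("score="):])
                block = QualityAlignmentBlock(rows=[], score=score)
            elif tag == "s":
                if block is None:
                    raise MafParseError(f"line {line_no}: 's' line outside a block")
                if len(fields) != 7:
                    raise MafParseError(f"line {line_no}: malformed 's' line")
                _, src, start, size, strand, src_size, text = fields
                block.rows.append(
                    MafRow(
                        src=src,
                        start=int(start),
                        size=int(size),
                        strand=strand,
                        src_size=int(src_size),
                        text=_normalize_text(text, line_no),
                    )
                )
            elif tag == "q":
                if block is None or not block.rows:
                    raise MafParseError(f"line {line_no}: 'q' line without 's' line")
                if len(fields) != 3:
                    raise MafParseError(f"line {line_no}: malformed 'q' line")
                _, src, qtext = fields
                row = block.rows[-1]
                if row.src != src:
                    raise MafParseError(
                        f"line {line_no}: 'q' line src {src!r} does not match "
                        f"preceding 's' line {row.src!r}"
                    )
                if len(qtext) != len(row.text):
                    raise MafParseError(f"line {line_no}: quality length != text length")
                if not set(qtext) <= _QUAL_CHARS:
                    raise MafParseError(f"line {line_no}: invalid quality characters")
                row.quality = qtext
            elif tag in ("i", "e"):
                continue
            else:
                raise MafParseError(f"line {line_no}: unknown line type {tag!r}")
        if block is not None:
            _finish_block(block, line_no)
            yield block
    finally:
        if own:
            handle.close()


def _finish_block(block: QualityAlignmentBlock, line_no: int) -> None:
    try:
        block.validate()
    except ValueError as exc:
        raise MafParseError(f"near line {line_no}: {exc}") from exc


def write_maf(
    blocks: Iterable[QualityAlignmentBlock], path: Union[str, Path, TextIO]
) -> None:
    """Write blocks as MAF; rows with qualities get a ``q`` line.

    Refuses (with the block index) any block violating its invariants, so
    ``read_maf(write_maf(B))`` reproduces ``B`` exactly.
    """
    handle: TextIO
    own = False
    if hasattr(path, "write"):
        handle = path  # type: ignore[assignment]
    else:
        handle = open(path, "w")
        own = True
    try:
        handle.write("##maf version=1\n")
        for i, block in enumerate(blocks):
            try:
                block.validate()
            except ValueError as exc:
                raise ValueError(f"block {i}: {exc}") from exc
            if block.score is not None:
                handle.write(f"a score={block.score:g}\n")
            else:
                handle.write("a\n")
            src_w = max(len(r.src) for r in block.rows)
            start_w = max(len(str(r.start)) for r in block.rows)
            size_w = max(len(str(r.size)) for r in block.rows)
            ssize_w = max(len(str(r.src_size)) for r in block.rows)
            for r in block.rows:
                handle.write(
                    f"s {r.src:<{src_w}} {r.start:>{start_w}} {r.size:>{size_w}} "
                    f"{r.strand} {r.src_size:>{ssize_w}} {r.text}\n"
                )
                if r.quality is not None:
                    pad = " " * (start_w + size_w + ssize_w + 5)
                    handle.write(f"q {r.src:<{src_w}}{pad}{r.quality}\n")
            handle.write("\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# BED regions


@dataclass
class RegionSet:
    """A set of 0-based half-open genomic intervals (BED semantics)."""

    intervals: list[tuple[str, int, int, Optional[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bp(self) -> int:
        return sum(e - s for _, s, e, _ in self.intervals)

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.intervals, key=lambda t: (t[0], t[1], t[2])))

    def merged(self) -> "RegionSet":
        """Merge overlapping/adjacent intervals (labels dropped)."""
        out: list[tuple[str, int, int, Optional[str]]] = []
        for chrom, s, e, _ in self.sorted():
            if out and out[-1][0] == chrom and s <= out[-1][2]:
                prev = out[-1]
                out[-1] = (chrom, prev[1], max(prev[2], e), None)
            else:
                out.append((chrom, s, e, None))
        return RegionSet(out)

    def _index(self):
        if not hasattr(self, "_by_chrom"):
            by: dict[str, tuple[list[int], list[int]]] = {}
            for chrom, s, e, _ in self.merged():
                by.setdefault(chrom, ([], []))
                by[chrom][0].append(s)
                by[chrom][1].append(e)
            self._by_chrom = by
        return self._by_chrom

    def contains(self, chrom: str, pos: int) -> bool:
        by = self._index()
        if chrom not in by:
            return False
        starts, ends = by[chrom]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]


def read_regions(path: Union[str, Path, TextIO]) -> RegionSet:
    """Parse a BED3+ file into a :class:`RegionSet` (overlaps preserved)."""
    handle: TextIO
    own = False
    if hasattr(path, "read"):
        handle = path  # type: ignore[assignment]
    else:
        handle = open(path)
        own = True
    intervals: list[tuple[str, int, int, Optional[str]]] = []
    try:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise MafParseError(f"line {line_no}: BED needs >=3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise MafParseError(f"line {line_no}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else None
            intervals.append((chrom, start, end, label))
    finally:
        if own:
            handle.close()
    return RegionSet(intervals)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq_qualities(path: Union[str, Path]) -> Iterator[list[int]]:
    """Yield per-read raw phred quality lists from a FASTQ file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.letter_annotations["phred_quality"]


# ---------------------------------------------------------------------------
# column iteration


@dataclass
class AlignedColumn:
    """One alignment column projected onto a (reference, other) species pair."""

    index: int
    ref_base: str
    other_base: str
    ref_qual: Optional[int]  # quality bin, None if absent or gap
    other_qual: Optional[int]
    ref_pos: Optional[int]  # source coordinate, None at gaps
    other_pos: Optional[int]


def iter_pair_columns(
    block: QualityAlignmentBlock, ref: str, other: str
) -> Iterator[AlignedColumn]:
    """Iterate columns of *block* restricted to two species.

    Source coordinates advance only at non-gap characters; columns gapped in
    both species (indels private to third species) are skipped.
    """
    rrow = block.row(ref)
    orow = block.row(other)
    rq = rrow.quality
    oq = orow.quality
    rpos = rrow.start
    opos = orow.start
    for i in range(block.ncols):
        rb = rrow.text[i]
        ob = orow.text[i]
        if rb == GAP and ob == GAP:
            continue
        col = AlignedColumn(
            index=i,
            ref_base=rb,
            other_base=ob,
            ref_qual=decode_quality_char(rq[i]) if rq is not None and rb != GAP else None,
            other_qual=decode_quality_char(oq[i]) if oq is not None and ob != GAP else None,
            ref_pos=rpos if rb != GAP else None,
            other_pos=opos if ob != GAP else None,
        )
        if rb != GAP:
            rpos += 1
        if ob != GAP:
            opos += 1
        yield col
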