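"""Sequence, alignment, and annotation input/output.

Conventions used throughout the package:

* Coordinates are 0-based, half-open internally; user-facing tables are
  1-based, inclusive.
* Minus-strand MAF rows are normalized at read time so that row 1 of every
  pairwise alignment is on the plus strand; downstream logic is strand-free.
* Ambiguity codes (``N`` and friends) are kept in sequences but treated as
  non-informative by every statistic.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "PairwiseAlignment",
    "OrthologyMap",
    "UndefinedIdentityError",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "read_bed",
    "project_onto_paralog_columns",
    "percent_identity",
    "reciprocal_overlap",
]

_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")

_COMPLEMENT_U8 = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNRYKMSWBDHV", b"TGCANYRMKSWVHDB"):
    _COMPLEMENT_U8[_a] = _b

#: Sentinel value used in projections for columns with no aligned outgroup base.
UNCOVERED = 0


class UndefinedIdentityError(ValueError):
    """Raised when percent identity is requested over zero non-gap columns."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval on one species' sequence (0-based, half-open)."""

    species: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.species == other.species
            and self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two half-open intervals: overlap / max(len)."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment of two genomic intervals.

    ``kind`` distinguishes intra-species (paralog) from inter-species
    (ortholog) alignments.  Row 1 is always plus-strand (enforced by the MAF
    reader); row 2 may be on either strand.
    """

    interval1: GenomicInterval
    text1: str
    interval2: GenomicInterval
    text2: str
    kind: str = "paralog"  # "paralog" | "ortholog"

    def __post_init__(self) -> None:
        self.text1 = self.text1.upper()
        self.text2 = self.text2.upper()
        if len(self.text1) != len(self.text2):
            raise ValueError("gapped alignment rows differ in length")
        for iv, txt in ((self.interval1, self.text1), (self.interval2, self.text2)):
            ungapped = len(txt) - txt.count("-")
            if ungapped != len(iv):
                raise ValueError(
                    f"row for {iv} has {ungapped} bases but interval length {len(iv)}"
                )
        a1 = np.frombuffer(self.text1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(self.text2.encode(), dtype=np.uint8)
        if np.any((a1 == ord("-")) & (a2 == ord("-"))):
            raise ValueError("alignment contains a gap-gap column")
        if self.kind == "paralog" and self.interval1.species != self.interval2.species:
            raise ValueError("paralog alignment rows must share a species")
        if self.kind == "ortholog" and self.interval1.species == self.interval2.species:
            raise ValueError("ortholog alignment rows must be in different species")

    def __len__(self) -> int:
        return len(self.text1)

    def row(self, which: int) -> tuple[GenomicInterval, str]:
        if which == 1:
            return self.interval1, self.text1
        if which == 2:
            return self.interval2, self.text2
        raise ValueError("row index must be 1 or 2")

    def _chars(self, which: int) -> np.ndarray:
        _, txt = self.row(which)
        return np.frombuffer(txt.encode(), dtype=np.uint8)

    def col_positions(self, which: int) -> np.ndarray:
        """Genomic position of each alignment column on the given row.

        Gap columns get -1.  For a minus-strand row the positions decrease
        along the alignment (the text runs along the reverse strand).
        """
        iv, txt = self.row(which)
        chars = self._chars(which)
        nongap = chars != ord("-")
        rank = np.cumsum(nongap) - 1
        if iv.strand == "+":
            pos = iv.start + rank
        else:
            pos = iv.end - 1 - rank
        pos = np.where(nongap, pos, -1)
        return pos.astype(np.int64)


@dataclass
class OrthologyMap:
    """Inter-species orthology relation backed by pairwise alignments.

    ``Orth(X)`` queries return, for an interval X, all mapped partner
    intervals in a chosen species, together with the backing alignment.
    """

    alignments: list[PairwiseAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for aln in self.alignments:
            if aln.interval1.species == aln.interval2.species:
                raise ValueError("orthology entries must join different species")

    def add(self, aln: PairwiseAlignment) -> None:
        if aln.interval1.species == aln.interval2.species:
            raise ValueError("orthology entries must join different species")
        self.alignments.append(aln)

    def partners(
        self, query: GenomicInterval, other_species: str
    ) -> list[tuple[GenomicInterval, PairwiseAlignment, int]]:
        """All partner intervals of ``query`` in ``other_species``.

        Returns tuples ``(partner_interval, alignment, query_row)`` where
        ``query_row`` is the row (1 or 2) of the alignment that overlaps the
        query interval.
        """
        out = []
        for aln in self.alignments:
            for qrow, prow in ((1, 2), (2, 1)):
                qiv, _ = aln.row(qrow)
                piv, _ = aln.row(prow)
                if piv.species == other_species and qiv.overlaps(query):
                    out.append((piv, aln, qrow))
        return out

    def best_alignment(
        self, query: GenomicInterval, other_species: str
    ) -> Optional[tuple[PairwiseAlignment, int]]:
        """The partner alignment with maximal overlap with ``query``, if any."""
        best, best_ov = None, 0
        for piv, aln, qrow in self.partners(query, other_species):
            qiv, _ = aln.row(qrow)
            ov = qiv.overlap_len(query)
            if ov > best_ov:
                best, best_ov = (aln, qrow), ov
        return best


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(name, uppercase sequence)`` pairs.

    Ambiguity codes are retained.  An empty file yields an empty list.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Bio error text varies
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(path, sequences: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    """MAF ``src`` fields are ``species.seq_id``; a bare name gets seq_id '.'"""
    if "." in src:
        sp, _, seq_id = src.partition(".")
        return sp, seq_id
    return src, "."


def _revcomp(text: str) -> str:
    return text.translate(_COMPLEMENT)[::-1]


def _record_to_row(rec) -> tuple[GenomicInterval, str]:
    ann = rec.annotations
    species, seq_id = _split_src(rec.id)
    size = ann["size"]
    src_size = ann["srcSize"]
    text = str(rec.seq).upper()
    if len(text) - text.count("-") != size:
        raise ValueError(f"MAF row {rec.id}: size {size} mismatches gapped text")
    if ann["strand"] in (1, "+"):
        start, strand = ann["start"], "+"
    else:
        # MAF minus-strand starts count from the reverse strand's origin.
        start, strand = src_size - ann["start"] - size, "-"
    return GenomicInterval(species, seq_id, start, start + size, strand), text


def read_maf(path, kind: Optional[str] = None) -> list[PairwiseAlignment]:
    """Read 2-row MAF blocks as :class:`PairwiseAlignment` objects.

    Minus-strand rows are converted to forward-strand coordinates; if row 1
    is on the minus strand the whole block is reverse-complemented so row 1
    is always plus-strand.  ``kind`` overrides the paralog/ortholog guess
    (same species => paralog).
    """
    out = []
    for idx, block in enumerate(AlignIO.parse(str(path), "maf")):
        if len(block) != 2:
            raise ValueError(
                f"MAF block {idx} in {path} has {len(block)} 's' lines; expected 2"
            )
        (iv1, t1), (iv2, t2) = (_record_to_row(rec) for rec in block)
        if iv1.strand == "-":
            t1, t2 = _revcomp(t1), _revcomp(t2)
            iv1 = replace(iv1, strand="+")
            iv2 = replace(iv2, strand="-" if iv2.strand == "+" else "+")
        k = kind or ("paralog" if iv1.species == iv2.species else "ortholog")
        out.append(PairwiseAlignment(iv1, t1, iv2, t2, kind=k))
    return out


def _row_to_record(iv: GenomicInterval, text: str, src_size: int) -> SeqRecord:
    if iv.strand == "+":
        start, strand = iv.start, 1
    else:
        start, strand = src_size - iv.end, -1
    rec = SeqRecord(Seq(text), id=f"{iv.species}.{iv.seq_id}", description="")
    rec.annotations = {
        "start": start,
        "size": len(iv),
        "strand": strand,
        "srcSize": src_size,
    }
    return rec


def write_maf(path, alignments: Sequence[PairwiseAlignment],
              src_sizes: Optional[dict] = None) -> None:
    """Write pairwise alignments as 2-row MAF blocks.

    ``src_sizes`` maps ``(species, seq_id)`` to the full source-sequence
    length; rows without an entry use the interval end (sufficient for
    plus-strand round trips).
    """
    src_sizes = src_sizes or {}
    blocks = []
    for aln in alignments:
        recs = []
        for which in (1, 2):
            iv, text = aln.row(which)
            size = src_sizes.get((iv.species, iv.seq_id), iv.end)
            recs.append(_row_to_record(iv, text, size))
        block = MultipleSeqAlignment(recs)
        block.annotations = {}
        blocks.append(block)
    with open(path, "w") as fh:
        AlignIO.write(blocks, fh, "maf")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED6 into ``(chrom, start, end, name)`` tuples."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"feature{lineno}"
        out.append((chrom, start, end, name))
    return out


# ---------------------------------------------------------------------------
# Projection and identity
# ---------------------------------------------------------------------------

def project_onto_paralog_columns(
    paralog: PairwiseAlignment,
    ortholog: PairwiseAlignment,
    which_row: int,
    ortholog_query_row: Optional[int] = None,
) -> np.ndarray:
    """Outgroup base aligned to each paralog-alignment column.

    For each column of ``paralog`` whose ``which_row`` base sits at genomic
    position *g*, returns the uint8 character code of the outgroup base that
    ``ortholog`` aligns to *g*, or 0 (``UNCOVERED``) when *g* is not covered
    or is aligned to a gap.  Zero overlap yields an all-uncovered projection.
    Bases are reported in the paralog row's orientation: when the ortholog's
    matching row runs on the opposite strand, they are complemented.
    """
    q_iv, _ = paralog.row(which_row)
    if ortholog_query_row is None:
        for r in (1, 2):
            riv, _ = ortholog.row(r)
            if riv.species == q_iv.species and riv.seq_id == q_iv.seq_id:
                ortholog_query_row = r
                break
        else:
            raise ValueError("ortholog alignment has no row matching the paralog row")
    other_row = 2 if ortholog_query_row == 1 else 1

    opos = ortholog.col_positions(ortholog_query_row)
    obase = ortholog._chars(other_row)
    o_iv, _ = ortholog.row(ortholog_query_row)
    if o_iv.strand != q_iv.strand:
        obase = _COMPLEMENT_U8[obase]
    covered = (opos >= 0) & (obase != ord("-"))
    opos, obase = opos[covered], obase[covered]
    order = np.argsort(opos, kind="stable")
    opos, obase = opos[order], obase[order]

    ppos = paralog.col_positions(which_row)
    proj = np.zeros(len(paralog), dtype=np.uint8)
    valid = ppos >= 0
    idx = np.searchsorted(opos, ppos[valid])
    idx = np.clip(idx, 0, max(len(opos) - 1, 0))
    if len(opos):
        hit = opos[idx] == ppos[valid]
        vals = np.where(hit, obase[idx], UNCOVERED)
        proj[np.flatnonzero(valid)] = vals
    return proj


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _is_acgt(chars: np.ndarray) -> np.ndarray:
    return np.isin(chars, _ACGT)


def percent_identity(
    aln: PairwiseAlignment, window: Optional[tuple[int, int]] = None
) -> float:
    """Fraction of matching bases over non-gap, unambiguous columns.

    ``window`` is a half-open column interval.  Raises
    :class:`UndefinedIdentityError` when no usable column remains.
    """
    c1, c2 = aln._chars(1), aln._chars(2)
    if window is not None:
        lo, hi = window
        c1, c2 = c1[lo:hi], c2[lo:hi]
    usable = _is_acgt(c1) & _is_acgt(c2)
    denom = int(usable.sum())
    if denom == 0:
        raise UndefinedIdentityError("window has no aligned unambiguous columns")
    return float((c1[usable] == c2[usable]).sum() / denom)
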