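"""Pairwise-alignment encoding for change-point segmentation.

A pairwise whole-genome alignment (colinear blocks from e.g. progressiveMauve)
is transformed into a single symbol sequence over a 16-letter alphabet: every
gap-free aligned column maps its ordered base pair (reference base, query base)
to one of ``a``..``p``. Identities land on ``{a, f, k, p}``, so the symbol
stream carries the local conservation level (and, implicitly, GC content and
transition/transversion structure). Columns containing gaps or ambiguity codes
emit nothing; block boundaries are marked with ``#`` and are treated as fixed
change-points downstream.

Reference coordinates (1-based, inclusive) are tracked per emitted symbol so
posterior profiles can be reported on the reference genome axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Seq import Seq

from .errors import ContentError, ParseError

BASES = "ACGT"
#: the 16-letter alphabet, ordered row-major by (reference base, query base)
ALPHABET = "abcdefghijklmnop"
#: symbols encoding identical aligned bases: (A,A), (C,C), (G,G), (T,T)
MATCH_SYMBOLS = frozenset("afkp")
MATCH_INDICES = np.array([0, 5, 10, 15])
BLOCK_SEPARATOR = "#"


@dataclass(frozen=True)
class EncodingTable:
    """Bijection between ordered base pairs and the 16-letter alphabet."""

    pair_to_symbol: dict = field(default_factory=lambda: {
        (r, q): ALPHABET[4 * i + j]
        for i, r in enumerate(BASES)
        for j, q in enumerate(BASES)
    })

    def __post_init__(self):
        symbols = set(self.pair_to_symbol.values())
        if len(self.pair_to_symbol) != 16 or len(symbols) != 16:
            raise ContentError("encoding table must be a bijection over 16 ordered pairs")

    @property
    def symbol_to_pair(self) -> dict:
        return {s: p for p, s in self.pair_to_symbol.items()}

    @property
    def match_symbols(self) -> frozenset:
        return frozenset(self.pair_to_symbol[(b, b)] for b in BASES)

    def encode_pair(self, ref_base: str, qry_base: str) -> str:
        return self.pair_to_symbol[(ref_base, qry_base)]

    def decode_symbol(self, symbol: str) -> tuple:
        return self.symbol_to_pair[symbol]


DEFAULT_TABLE = EncodingTable()


@dataclass
class AlignmentBlock:
    """One colinear aligned block: two gapped rows plus reference coordinates."""

    ref_id: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    ref_row: str
    qry_row: str

    def __post_init__(self):
        self.ref_row = self.ref_row.upper()
        self.qry_row = self.qry_row.upper()
        if len(self.ref_row) != len(self.qry_row):
            raise ContentError(
                f"aligned rows differ in length ({len(self.ref_row)} vs {len(self.qry_row)})"
            )
        if self.ref_start < 1 or self.ref_start > self.ref_end:
            raise ContentError(f"bad reference span {self.ref_start}-{self.ref_end}")
        span = self.ref_end - self.ref_start + 1
        nongap = len(self.ref_row) - self.ref_row.count("-")
        if span != nongap:
            raise ContentError(
                f"reference span {span} != non-gap reference characters {nongap}"
            )

    def __len__(self):
        return len(self.ref_row)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    def ref_coords(self) -> np.ndarray:
        """1-based reference coordinate per column; -1 for reference-gap columns."""
        out = np.full(len(self.ref_row), -1, dtype=np.int64)
        pos = self.ref_start
        for i, c in enumerate(self.ref_row):
            if c != "-":
                out[i] = pos
                pos += 1
        return out


@dataclass
class GenomicIntervalSpan:
    """Internal plain (start, end) 1-based inclusive span used by MaskSet."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ContentError(f"invalid interval {self.start}-{self.end}")


@dataclass
class MaskSet:
    """Reference intervals to exclude (prophages, known horizontal transfers)."""

    intervals: list

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
        spans = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError("BED line has fewer than 3 fields", path, lineno)
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"non-integer BED coordinate: {exc}", path, lineno)
                if end0 <= start0:
                    raise ParseError("empty or inverted BED interval", path, lineno)
                spans.append(GenomicIntervalSpan(start0 + 1, end0))
        return cls(spans)

    def covers(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask over an array of 1-based coordinates."""
        hit = np.zeros(coords.shape, dtype=bool)
        for iv in self.intervals:
            hit |= (coords >= iv.start) & (coords <= iv.end)
        return hit


@dataclass
class EncodedAlignment:
    """The concatenated encoded sequence with per-symbol reference coordinates.

    ``symbols`` includes the ``#`` separators; ``coords`` and ``block_index``
    are parallel to the *non-separator* symbols only.
    """

    ref_id: str
    symbols: str
    coords: np.ndarray       # 1-based reference coordinate per emitted symbol
    block_index: np.ndarray  # source block ordinal per emitted symbol

    def __post_init__(self):
        n = len(self.symbols) - self.symbols.count(BLOCK_SEPARATOR)
        if len(self.coords) != n or len(self.block_index) != n:
            raise ContentError("coordinate map length does not match symbol count")
        if self.symbols and (
            self.symbols[0] == BLOCK_SEPARATOR
            or self.symbols[-1] == BLOCK_SEPARATOR
            or BLOCK_SEPARATOR * 2 in self.symbols
        ):
            raise ContentError("'#' must occur only singly, strictly between blocks")

    @property
    def n_symbols(self) -> int:
        return len(self.coords)

    def symbol_indices(self) -> np.ndarray:
        """Integer codes 0..15 of the non-separator symbols, in order."""
        seq = self.symbols.replace(BLOCK_SEPARATOR, "")
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - ord("a")

    def fixed_boundaries(self) -> np.ndarray:
        """Boolean array over symbol gaps i (between symbol i and i+1, 0-based):
        True where a ``#`` separator makes the boundary mandatory."""
        fixed = np.zeros(max(self.n_symbols - 1, 0), dtype=bool)
        if self.n_symbols > 1:
            fixed[:] = self.block_index[:-1] != self.block_index[1:]
        return fixed

    def conservation_fraction(self) -> float:
        """Fraction of emitted symbols that encode identical aligned bases."""
        if self.n_symbols == 0:
            raise ContentError("empty encoding")
        return float(np.isin(self.symbol_indices(), MATCH_INDICES).mean())

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.symbols + "\n")

    def write_coords_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("symbol\tref_coord\tblock\n")
            seq = self.symbols.replace(BLOCK_SEPARATOR, "")
            for s, c, b in zip(seq, self.coords, self.block_index):
                fh.write(f"{s}\t{c}\t{b}\n")


def _mauve_seq_label(record) -> str:
    # Bio.AlignIO mauve ids look like "name/start-end"; keep the name part
    return record.id.split("/")[0]


def read_alignment(path, dialect: str = "xmfa") -> list:
    """Read a pairwise alignment into :class:`AlignmentBlock` objects.

    Parameters
    ----------
    path
        Alignment file.
    dialect
        ``"xmfa"`` (Mauve extended multi-FASTA, ``=`` block terminators) or
        ``"aligned-fasta"`` (one block: exactly two equal-length rows).

    Blocks are returned sorted by reference start, with reverse-reference-strand
    blocks reverse-complemented into forward reference orientation.
    """
    if dialect not in ("xmfa", "aligned-fasta"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    fmt = "mauve" if dialect == "xmfa" else "fasta"
    try:
        alignments = list(AlignIO.parse(str(path), fmt))
    except ValueError as exc:
        raise ParseError(f"cannot parse as {dialect}: {exc}", path)

    blocks = []
    for aln in alignments:
        records = list(aln)
        if len(records) != 2:
            raise ContentError(
                f"alignment block has {len(records)} rows; exactly 2 required"
            )
        ref, qry = records
        if len(ref.seq) != len(qry.seq):
            raise ContentError("aligned rows of unequal length")
        ref_row, qry_row = str(ref.seq), str(qry.seq)
        if dialect == "xmfa":
            start0 = int(ref.annotations.get("start", 0))
            end0 = int(ref.annotations.get("end", 0))
            strand = int(ref.annotations.get("strand", 1))
            if end0 <= start0:
                continue  # zero-length placeholder row
            if strand == -1:
                ref_row = str(Seq(ref_row).reverse_complement())
                qry_row = str(Seq(qry_row).reverse_complement())
            ref_start, ref_end = start0 + 1, end0
            ref_id = _mauve_seq_label(ref)
        else:
            ref_start = 1
            ref_end = len(ref_row) - ref_row.count("-")
            ref_id = ref.id
        blocks.append(
            AlignmentBlock(
                ref_id=ref_id,
                ref_start=ref_start,
                ref_end=ref_end,
                ref_row=ref_row,
                qry_row=qry_row,
            )
        )
    blocks.sort(key=lambda b: b.ref_start)
    return blocks


def apply_mask_and_min_length(blocks, mask: MaskSet | None, min_len: int = 500) -> list:
    """Drop masked columns and short blocks.

    Columns whose reference coordinate falls inside any mask interval are
    removed; removal interior to a block splits it. Surviving blocks whose
    reference span is below ``min_len`` (default 500 nt, 'at least 500'
    inclusive) are discarded.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if mask is None:
        mask = MaskSet([])
    out = []
    for block in blocks:
        coords = block.ref_coords()
        # a column is removed iff it carries a masked reference coordinate;
        # reference-gap columns survive with whichever piece they sit in
        masked = np.zeros(len(block), dtype=bool)
        has_coord = coords >= 0
        masked[has_coord] = mask.covers(coords[has_coord])
        keep = ~masked
        # contiguous runs of kept columns become sub-blocks
        edges = np.flatnonzero(np.diff(np.concatenate(([0], keep.view(np.int8), [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            sub_coords = coords[run_start:run_end]
            sub_coords = sub_coords[sub_coords >= 0]
            if sub_coords.size == 0:
                continue
            sub = AlignmentBlock(
                ref_id=block.ref_id,
                ref_start=int(sub_coords[0]),
                ref_end=int(sub_coords[-1]),
                ref_row=block.ref_row[run_start:run_end],
                qry_row=block.qry_row[run_start:run_end],
            )
            if sub.ref_span >= min_len:
                out.append(sub)
    return out


def encode_columns(blocks, table: EncodingTable = DEFAULT_TABLE) -> EncodedAlignment:
    """Encode gap-free ACGT columns of each block; join blocks with ``#``.

    Columns containing gaps, N, or any other ambiguity code emit no symbol
    (indels and ambiguous columns are excluded from the model input). Blocks
    contributing no symbols are skipped entirely so separators never touch.
    """
    if not blocks:
        raise ContentError("no alignment blocks to encode")
    pieces, coords, block_idx = [], [], []
    for bi, block in enumerate(blocks):
        ref_coords = block.ref_coords()
        syms = []
        for col, (r, q) in enumerate(zip(block.ref_row, block.qry_row)):
            if r in BASES and q in BASES:
                syms.append(table.encode_pair(r, q))
                coords.append(ref_coords[col])
                block_idx.append(bi)
        if syms:
            pieces.append("".join(syms))
    if not pieces:
        raise ContentError("no encodable (gap-free ACGT) columns in any block")
    return EncodedAlignment(
        ref_id=blocks[0].ref_id,
        symbols=BLOCK_SEPARATOR.join(pieces),
        coords=np.asarray(coords, dtype=np.int64),
        block_index=np.asarray(block_idx, dtype=np.int64),
    )


def encode_alignment_file(path, dialect="xmfa", mask=None, min_len=500,
                          table=DEFAULT_TABLE) -> EncodedAlignment:
    """Convenience: read, mask/filter, and encode in one call."""
    blocks = read_alignment(path, dialect)
    blocks = apply_mask_and_min_length(blocks, mask, min_len)
    return encode_columns(blocks, table)
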