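"""Multiple alignments: column classification, coordinate maps, small-scale MSA.

The whole-genome multiple alignment is an *input* to the pipeline (produced
by an external aligner such as MAFFT); this module consumes it.  What is
computed here:

* per-column classification (invariant / variable / gap-containing /
  ambiguous) — the raw material for variable-site counts, indel events and
  percent-identical-sites statistics;
* per-taxon coordinate maps between alignment columns and ungapped genome
  positions, used to project annotated gene intervals onto the alignment;
* a deterministic progressive aligner for marker-scale sequence sets
  (amplicons, single genes — a few kb at most), built on pairwise global
  Needleman–Wunsch alignment with affine gap costs.

Column-class precedence: a column with at least two distinct unambiguous
residues is *variable* even if it also contains gaps (its gaps still
contribute to indel events); N never creates variability on its own; an
*identical* site requires every row to carry the same A/C/G/T residue with
no gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Msa",
    "ColumnState",
    "ColumnClass",
    "ColumnClasses",
    "CoordinateMap",
    "read_alignment",
    "write_alignment",
    "classify_columns",
    "project_interval",
    "align_small",
    "DEFAULT_SCORES",
]

_GAP = ord("-")
_ACGT = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)


class ColumnState(str, Enum):
    invariant = "invariant"
    variable = "variable"
    gap_containing = "gap_containing"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class ColumnClass:
    index: int
    state: ColumnState
    is_variable: bool
    has_gap: bool
    residues: tuple[str, ...]  # non-gap characters, row order


class Msa:
    """An immutable multiple alignment over {A, C, G, T, N, -}.

    Rows are stored both as strings and as a uint8 matrix for vectorized
    column arithmetic.
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]):
        if len(taxa) != len(rows):
            raise ValueError("taxa and rows must have equal length")
        if len(rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        rows = [r.upper() for r in rows]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            bad = [t for t, r in zip(taxa, rows) if len(r) != len(rows[0])]
            raise ValueError(f"ragged alignment: row length differs for {bad}")
        self.taxa: list[str] = list(taxa)
        self.rows: list[str] = rows
        self.length: int = len(rows[0])
        self.matrix: np.ndarray = np.frombuffer(
            "".join(rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(rows), self.length)

    def __len__(self) -> int:
        return self.length

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")

    def slice_columns(self, start: int, end: int) -> "Msa":
        if not (0 <= start < end <= self.length):
            raise IndexError(f"column interval ({start}, {end}) out of range")
        return Msa(self.taxa, [r[start:end] for r in self.rows])

    def take_columns(self, indices: np.ndarray) -> "Msa":
        sub = self.matrix[:, indices]
        return Msa(self.taxa, [bytes(r).decode("ascii") for r in sub])

    def drop_columns(self, mask: np.ndarray) -> "Msa":
        """Remove columns where ``mask`` is True (e.g. a user column mask)."""
        keep = ~np.asarray(mask, dtype=bool)
        return self.take_columns(np.nonzero(keep)[0])

    def coordinate_map(self) -> "CoordinateMap":
        return CoordinateMap(self)


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file (all records the same gapped length)."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq))
    if len(rows) < 2:
        raise ValueError(f"{path}: an alignment needs at least 2 sequences")
    return Msa(taxa, rows)


def write_alignment(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(msa.taxa, msa.rows):
            fh.write(f">{taxon.replace(' ', '_')}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


# --------------------------------------------------------------------------
# Column classification
# --------------------------------------------------------------------------

class ColumnClasses(Sequence):
    """Lazy sequence of :class:`ColumnClass` plus vectorized summaries.

    ``is_variable``, ``has_gap``, ``is_identical`` and ``states`` are numpy
    arrays over columns; iterating materializes ColumnClass objects.
    """

    def __init__(self, msa: Msa):
        self._msa = msa
        m = msa.matrix
        self.has_gap = (m == _GAP).any(axis=0)
        n_distinct = np.zeros(msa.length, dtype=np.int16)
        for b in _ACGT:
            n_distinct += (m == b).any(axis=0)
        self.is_variable = n_distinct >= 2
        has_n = (m == ord("N")).any(axis=0)
        self.is_identical = (m == m[0]).all(axis=0) & np.isin(m[0], _ACGT)

        states = np.full(msa.length, 0, dtype=np.int8)  # 0 invariant
        states[has_n & (n_distinct <= 1)] = 3           # ambiguous
        states[self.has_gap] = 2                        # gap_containing
        states[self.is_variable] = 1                    # variable
        self.states = states

    _STATE_ORDER = [
        ColumnState.invariant,
        ColumnState.variable,
        ColumnState.gap_containing,
        ColumnState.ambiguous,
    ]

    def __len__(self) -> int:
        return self._msa.length

    def __getitem__(self, index):
        if isinstance(index, slice):
            return [self[i] for i in range(*index.indices(len(self)))]
        if index < 0:
            index += len(self)
        col = self._msa.matrix[:, index]
        residues = tuple(chr(b) for b in col if b != _GAP)
        return ColumnClass(
            index=index,
            state=self._STATE_ORDER[self.states[index]],
            is_variable=bool(self.is_variable[index]),
            has_gap=bool(self.has_gap[index]),
            residues=residues,
        )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "invariant": int((self.states == 0).sum()),
            "variable": int((self.states == 1).sum()),
            "gap_containing": int((self.states == 2).sum()),
            "ambiguous": int((self.states == 3).sum()),
            "n_variable_sites": int(self.is_variable.sum()),
            "n_gap_columns": int(self.has_gap.sum()),
            "n_identical_sites": int(self.is_identical.sum()),
        }


def classify_columns(msa: Msa) -> ColumnClasses:
    """Classify every alignment column; summary counts in ``.counts``."""
    return ColumnClasses(msa)


# --------------------------------------------------------------------------
# Coordinate maps
# --------------------------------------------------------------------------

class CoordinateMap:
    """Per-taxon bijections between alignment columns and ungapped positions."""

    def __init__(self, msa: Msa):
        self._msa = msa
        self._col_of_pos: dict[str, np.ndarray] = {}
        self._pos_of_col: dict[str, np.ndarray] = {}
        for taxon, row in zip(msa.taxa, msa.rows):
            arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
            nongap = arr != _GAP
            self._col_of_pos[taxon] = np.nonzero(nongap)[0]
            pos = np.cumsum(nongap) - 1
            pos[~nongap] = -1
            self._pos_of_col[taxon] = pos

    def ungapped_length(self, taxon: str) -> int:
        return len(self._col_of_pos[taxon])

    def column_of(self, taxon: str, pos: int) -> int:
        cols = self._col_of_pos[taxon]
        if not (0 <= pos < len(cols)):
            raise IndexError(
                f"position {pos} out of range for {taxon} "
                f"(ungapped length {len(cols)})"
            )
        return int(cols[pos])

    def position_of(self, taxon: str, column: int) -> int | None:
        """Ungapped position at a column, or None when the taxon is gapped."""
        p = int(self._pos_of_col[taxon][column])
        return None if p < 0 else p


def project_interval(
    cmap: CoordinateMap, taxon: str, start: int, end: int
) -> tuple[int, int]:
    """Project an ungapped half-open interval onto alignment columns.

    Returns the smallest half-open column window containing every mapped
    position; gap columns of other taxa inside the window are retained.
    """
    if end <= start:
        raise IndexError(f"empty interval ({start}, {end})")
    if start < 0 or end > cmap.ungapped_length(taxon):
        raise IndexError(
            f"interval ({start}, {end}) out of range for {taxon} "
            f"(ungapped length {cmap.ungapped_length(taxon)})"
        )
    return cmap.column_of(taxon, start), cmap.column_of(taxon, end - 1) + 1


# --------------------------------------------------------------------------
# Marker-scale progressive alignment
# --------------------------------------------------------------------------

#: default Needleman–Wunsch scores: match, mismatch, gap open, gap extend.
#: The open score is charged to the first gapped position, extend to each
#: further position (a gap of length L costs open + (L-1)·extend).
DEFAULT_SCORES = {"match": 1.0, "mismatch": -2.0, "gap_open": -5.0, "gap_extend": -1.0}

_MAX_ALIGN_LEN = 10_000


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(max(1, len(seq) - k + 1))}


def _pairwise_aligner(match, mismatch, gap_open, gap_extend):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    match: float = DEFAULT_SCORES["match"],
    mismatch: float = DEFAULT_SCORES["mismatch"],
    gap_open: float = DEFAULT_SCORES["gap_open"],
    gap_extend: float = DEFAULT_SCORES["gap_extend"],
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences with affine gap costs."""
    aligner = _pairwise_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, float(aln.score)


def align_small(
    seqs: Sequence[str],
    taxa: Sequence[str] | None = None,
    match: float = DEFAULT_SCORES["match"],
    mismatch: float = DEFAULT_SCORES["mismatch"],
    gap_open: float = DEFAULT_SCORES["gap_open"],
    gap_extend: float = DEFAULT_SCORES["gap_extend"],
) -> Msa:
    """Deterministic progressive multiple alignment for marker-scale inputs.

    Center-star strategy: the sequence with the highest total k-mer similarity
    to all others is the center; the remaining sequences are merged into the
    growing alignment in decreasing order of similarity to the center, each
    via an optimal pairwise alignment to the center row (gaps already present
    in the alignment are preserved — once a gap, always a gap).  For two
    sequences this reduces to a single optimal pairwise alignment.
    """
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        raise ValueError("align_small needs at least 2 sequences")
    for idx, s in enumerate(seqs):
        if not s:
            raise ValueError(f"sequence {idx} is empty")
        if len(s) > _MAX_ALIGN_LEN:
            raise ValueError(
                f"sequence {idx} exceeds {_MAX_ALIGN_LEN} bp; align_small is "
                "for marker-scale inputs"
            )
    if taxa is None:
        taxa = [f"seq{i}" for i in range(len(seqs))]
    taxa = list(taxa)

    # center = max total k-mer similarity; ties broken by input order
    ksets = [_kmer_set(s) for s in seqs]
    sims = np.zeros((len(seqs), len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            inter = len(ksets[i] & ksets[j])
            union = len(ksets[i] | ksets[j]) or 1
            sims[i, j] = sims[j, i] = inter / union
    center = int(np.argmax(sims.sum(axis=1)))
    order = sorted(
        (i for i in range(len(seqs)) if i != center),
        key=lambda i: (-sims[center, i], i),
    )

    aligned: dict[int, str] = {center: seqs[center]}
    center_row = seqs[center]
    for i in order:
        ga_center, ga_new, _ = pairwise_align(
            center_row.replace("-", ""), seqs[i], match, mismatch, gap_open, gap_extend
        )
        merged_center, inserts = _merge_gap_patterns(center_row, ga_center)
        aligned = {k: _apply_inserts(v, inserts) for k, v in aligned.items()}
        aligned[center] = merged_center
        aligned[i] = _project_new_row(merged_center, ga_center, ga_new, inserts)
        center_row = merged_center

    rows = [aligned[i] for i in range(len(seqs))]
    return Msa(taxa, rows)


def _merge_gap_patterns(existing: str, new: str) -> tuple[str, list[int]]:
    """Merge two gapped versions of the same ungapped sequence.

    Returns the union-gapped version of ``existing`` and the list of existing-
    string indices where a gap column from ``new`` must be inserted (indices
    refer to positions in ``existing``; duplicates mean multiple insertions).
    """
    out = []
    inserts: list[int] = []
    i = j = 0
    while i < len(existing) or j < len(new):
        ce = existing[i] if i < len(existing) else None
        cn = new[j] if j < len(new) else None
        if ce == "-" and cn == "-":
            out.append("-")
            i += 1
            j += 1
        elif ce == "-":
            out.append("-")
            i += 1
        elif cn == "-":
            out.append("-")
            inserts.append(i)
            j += 1
        else:
            out.append(ce)
            i += 1
            j += 1
    return "".join(out), inserts


def _apply_inserts(row: str, inserts: list[int]) -> str:
    """Insert gap columns into an already-aligned row at the given indices."""
    if not inserts:
        return row
    out = []
    it = iter(sorted(inserts))
    nxt = next(it, None)
    for idx, ch in enumerate(row):
        while nxt is not None and nxt == idx:
            out.append("-")
            nxt = next(it, None)
        out.append(ch)
    while nxt is not None:
        out.append("-")
        nxt = next(it, None)
    return "".join(out)


def _project_new_row(
    merged_center: str, ga_center: str, ga_new: str, inserts: list[int]
) -> str:
    """Thread the newly aligned sequence onto the merged column set."""
    # walk merged_center and ga_center in parallel over the center's residues
    out = []
    j = 0  # position in ga_center / ga_new
    for ch in merged_center:
        if ch != "-":
            # advance ga to the next center residue
            while ga_center[j] == "-":
                j += 1
            out.append(ga_new[j])
            j += 1
        else:
            # a gap column in the merged center: either it came from the new
            # pairwise alignment (center gapped there -> new residue) or from
            # an earlier round (new sequence has no character -> gap)
            if j < len(ga_center) and ga_center[j] == "-":
                out.append(ga_new[j])
                j += 1
            else:
                out.append("-")
    return "".join(out)
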