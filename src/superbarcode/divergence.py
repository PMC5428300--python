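"""Pairwise divergence matrices and per-region divergence statistics.

Between near-identical plastomes the interesting signal is tiny: a few
hundred substitutions genome-wide and a handful of short indels, almost all
in intergenic spacers.  This module computes

* the symmetric pairwise base-difference matrix (counts and percentages)
  over a whole-genome alignment;
* per-region summaries — alignment length, variable sites, indel events and
  percent identical sites — for named coding or non-coding regions;
* a divergence ranking of regions (most divergent first).

Conventions, stated because they drive the numbers:

* a pairwise difference requires both rows to carry unambiguous residues
  (A/C/G/T) that differ; columns where either row has a gap or N are
  excluded from the count;
* the percentage denominator defaults to the full alignment length
  (switchable to the pairwise ungapped column count);
* an *indel event* is a maximal run of consecutive columns sharing the same
  non-empty gap pattern (the same subset of rows gapped); adjacent runs with
  different patterns are distinct events;
* an *identical site* is a column where all rows carry the same A/C/G/T
  residue — a gap or N anywhere makes the column non-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .alignment import Msa, classify_columns

__all__ = [
    "DiffMatrix",
    "RegionStats",
    "pairwise_difference_matrix",
    "region_stats",
    "count_indel_events",
    "rank_regions",
    "count_identical_gene_alignments",
]

_ACGT_BYTES = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)

DenominatorMode = Literal["alignment_length", "pairwise_ungapped"]


@dataclass
class DiffMatrix:
    """Symmetric pairwise base-difference counts and percentages."""

    taxa: list[str]
    counts: np.ndarray      # (n, n) int
    percents: np.ndarray    # (n, n) float, rounded to 2 decimals
    denominator_mode: DenominatorMode
    denominators: np.ndarray | None = None  # unrounded denominators, if known

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape[0] != c.shape[1] or c.shape[0] != len(self.taxa):
            raise ValueError("counts must be square over the taxon list")
        if not np.array_equal(c, c.T):
            raise ValueError("counts matrix must be symmetric")
        if np.diagonal(c).any():
            raise ValueError("diagonal of counts must be zero")

    def distances(self) -> np.ndarray:
        """Unrounded p-distances (fractions, not percents)."""
        if self.denominators is not None:
            with np.errstate(invalid="ignore"):
                d = self.counts / self.denominators
            np.fill_diagonal(d, 0.0)
            return d
        return self.percents / 100.0

    def pair(self, a: str, b: str) -> int:
        return int(self.counts[self.taxa.index(a), self.taxa.index(b)])

    def pair_percent(self, a: str, b: str) -> float:
        return float(self.percents[self.taxa.index(a), self.taxa.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.taxa, columns=self.taxa)

    def write_tsv(self, path: str | Path, comments: Sequence[str] = ()) -> None:
        """Lower triangle counts, upper triangle percentages (one table)."""
        import pandas as pd

        n = len(self.taxa)
        cells = [["" for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i > j:
                    cells[i][j] = str(int(self.counts[i, j]))
                elif i < j:
                    cells[i][j] = f"{self.percents[i, j]:.2f}%"
        df = pd.DataFrame(cells, index=self.taxa, columns=self.taxa)
        with open(path, "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            df.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class RegionStats:
    """Divergence summary of one named region of the alignment."""

    region_name: str
    length_bp: int          # alignment length of the region (columns)
    variable_sites: int
    indel_events: int
    pid_percent: float      # percent identical sites, 1 decimal

    def __post_init__(self) -> None:
        if not (0 <= self.variable_sites <= self.length_bp):
            raise ValueError("variable_sites must lie in [0, length_bp]")
        if not (0.0 <= self.pid_percent <= 100.0):
            raise ValueError("pid_percent must lie in [0, 100]")


def _pair_diff_masks(msa: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-column masks for every unordered taxon pair.

    Returns (diff, comparable): diff[p, c] is True when pair p differs at
    column c with both rows unambiguous; comparable[p, c] when both rows are
    unambiguous residues.  Pairs are enumerated in (i, j), i<j order.
    """
    m = msa.matrix
    ok = np.isin(m, _ACGT_BYTES)
    n = msa.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.empty((len(pairs), msa.length), dtype=bool)
    comp = np.empty((len(pairs), msa.length), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        comp[p] = ok[i] & ok[j]
        diff[p] = comp[p] & (m[i] != m[j])
    return diff, comp


def pairwise_difference_matrix(
    msa: Msa, mode: DenominatorMode = "alignment_length"
) -> DiffMatrix:
    """Count pairwise base differences over an alignment.

    ``counts[i][j]`` is the number of columns where rows i and j both carry
    unambiguous residues that differ.  Percentages divide by the alignment
    length (default) or by each pair's count of mutually ungapped,
    unambiguous columns.
    """
    n = msa.n_taxa
    diff, comp = _pair_diff_masks(msa)
    counts = np.zeros((n, n), dtype=np.int64)
    denoms = np.full((n, n), msa.length, dtype=np.float64)
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = int(diff[p].sum())
            if mode == "pairwise_ungapped":
                denoms[i, j] = denoms[j, i] = max(int(comp[p].sum()), 1)
            p += 1
    percents = np.round(100.0 * counts / denoms, 2)
    np.fill_diagonal(percents, 0.0)
    return DiffMatrix(
        taxa=list(msa.taxa),
        counts=counts,
        percents=percents,
        denominator_mode=mode,
        denominators=denoms,
    )


def count_indel_events(msa: Msa, region: tuple[int, int] | None = None) -> int:
    """Count indel events: maximal runs of columns with one shared gap pattern.

    The gap pattern of a column is the subset of rows gapped there; a run of
    consecutive columns with the same non-empty pattern is one event.
    """
    start, end = region if region is not None else (0, msa.length)
    if not (0 <= start < end <= msa.length):
        raise IndexError(f"region ({start}, {end}) out of range")
    gaps = msa.matrix[:, start:end] == ord("-")
    if not gaps.any():
        return 0
    # encode each column's gap pattern as an integer key
    weights = (1 << np.arange(msa.n_taxa, dtype=np.uint64))
    keys = (gaps.astype(np.uint64).T * weights).sum(axis=1)
    events = 0
    prev = np.uint64(0)
    for k in keys:
        if k != 0 and k != prev:
            events += 1
        prev = k
    return events


def region_stats(
    msa: Msa, region: tuple[int, int], name: str
) -> RegionStats:
    """Summarize one region: variable sites, indel events, percent identity."""
    start, end = region
    sub = msa.slice_columns(start, end)  # raises on bad bounds
    classes = classify_columns(sub)
    length = sub.length
    identical = classes.counts["n_identical_sites"]
    return RegionStats(
        region_name=name,
        length_bp=length,
        variable_sites=classes.counts["n_variable_sites"],
        indel_events=count_indel_events(sub),
        pid_percent=round(100.0 * identical / length, 1),
    )


def rank_regions(stats: Sequence[RegionStats], top_n: int | None = None) -> list[RegionStats]:
    """Order regions most-divergent first.

    Ascending percent identical sites; ties broken by more variable sites,
    then by region name lexicographically.
    """
    if not stats:
        raise ValueError("rank_regions needs a non-empty list")
    if top_n is not None and top_n <= 0:
        raise ValueError("top_n must be positive")
    ranked = sorted(
        stats, key=lambda r: (r.pid_percent, -r.variable_sites, r.region_name)
    )
    return ranked if top_n is None else ranked[:top_n]


def count_identical_gene_alignments(
    msa: Msa, gene_regions: Mapping[str, tuple[int, int]]
) -> int:
    """Number of gene regions with zero variable sites and zero indel events."""
    n = 0
    for name, region in gene_regions.items():
        st = region_stats(msa, region, name)
        if st.variable_sites == 0 and st.indel_events == 0:
            n += 1
    return n


def write_region_table(
    stats: Sequence[RegionStats], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """TSV mirroring the divergent-region table layout."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "region": r.region_name,
                "length_bp": r.length_bp,
                "variable_sites": r.variable_sites,
                "indels": r.indel_events,
                "pid_percent": f"{r.pid_percent:.1f}",
            }
            for r in stats
        ]
    )
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)
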