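"""Barcode markers: in-silico PCR, intergenic regions, species discrimination.

A barcode marker (matK, rbcL, trnH-psbA, ITS ...) is delimited on each genome
by a forward/reverse primer pair.  This module locates primer-binding sites
under IUPAC-aware base compatibility (degenerate primer codes match any
compatible template base), extracts the amplicons, aligns them, counts
diagnostic SNPs between every pair of species, and reports which pairs a
marker — or a combination of markers — cannot distinguish.

Amplicon lengths are primer-inclusive: the product runs from the first base
of the forward-primer site to the last base of the reverse-primer site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import IUPAC_MASK, MASK_TABLE, revcomp, seq_to_bytes
from .alignment import DEFAULT_SCORES, Msa, align_small
from .divergence import pairwise_difference_matrix
from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Primer",
    "Amplicon",
    "MarkerReport",
    "in_silico_pcr",
    "list_intergenic_regions",
    "marker_snp_matrix",
    "combine_markers",
    "read_primer_table",
    "default_primers",
]


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'→3'; degenerate IUPAC codes allowed."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - set(IUPAC_MASK)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.orientation not in {"forward", "reverse"}:
            raise ValueError("orientation must be 'forward' or 'reverse'")


@dataclass(frozen=True)
class Amplicon:
    """One in-silico PCR product on a source genome.

    ``start``/``end`` are 0-based half-open on the source genome's forward
    strand; for products crossing the origin of a circular template, ``end``
    exceeds the genome length (coordinates continue past the origin).
    """

    taxon: str
    marker_name: str
    start: int
    end: int
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class MarkerReport:
    """Per-marker species-discrimination summary."""

    marker_names: list[str]
    taxa: list[str]
    pairwise_snps: np.ndarray  # symmetric int matrix, zero diagonal
    amplicon_lengths: dict[str, int] = field(default_factory=dict)
    failed_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.pairwise_snps)
        if not np.array_equal(m, m.T) or np.diagonal(m).any():
            raise ValueError("pairwise_snps must be symmetric with zero diagonal")

    @property
    def unresolved_pairs(self) -> set[tuple[str, str]]:
        """Taxon pairs with zero diagnostic SNPs (unordered, sorted tuples)."""
        out = set()
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                if self.pairwise_snps[i, j] == 0:
                    out.add(tuple(sorted((self.taxa[i], self.taxa[j]))))
        return out

    def snps(self, a: str, b: str) -> int:
        return int(self.pairwise_snps[self.taxa.index(a), self.taxa.index(b)])

    def write_tsv(self, path: str | Path, comments: Sequence[str] = ()) -> None:
        import pandas as pd

        df = pd.DataFrame(self.pairwise_snps, index=self.taxa, columns=self.taxa)
        with open(path, "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            fh.write(f"# markers: {','.join(self.marker_names)}\n")
            if self.failed_taxa:
                fh.write(f"# amplification failures: {','.join(self.failed_taxa)}\n")
            df.to_csv(fh, sep="\t")
            fh.write("#\n# unresolved pairs (0 diagnostic SNPs):\n")
            for a, b in sorted(self.unresolved_pairs):
                fh.write(f"# {a}\t{b}\n")


# --------------------------------------------------------------------------
# Primer matching
# --------------------------------------------------------------------------

def _mismatch_profile(template_masks: np.ndarray, primer: str) -> np.ndarray:
    """Mismatch count of the primer at every template start position.

    ``template_masks`` is the 4-bit mask array of the template strand the
    primer would anneal to, read in primer orientation.  Position i is a
    mismatch when the primer code and template base share no nucleotide.
    """
    k = len(primer)
    n = len(template_masks) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    pm = np.array([IUPAC_MASK[c] for c in primer], dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for t in range(k):
        mism += (template_masks[t : t + n] & pm[t]) == 0
    return mism


def _clamp_violations(template_masks: np.ndarray, primer: str, clamp: int) -> np.ndarray:
    """True where any of the primer's 3'-terminal ``clamp`` bases mismatches."""
    k = len(primer)
    n = len(template_masks) - k + 1
    if n <= 0 or clamp <= 0:
        return np.zeros(max(n, 0), dtype=bool)
    pm = np.array([IUPAC_MASK[c] for c in primer], dtype=np.uint8)
    viol = np.zeros(n, dtype=bool)
    for t in range(k - clamp, k):
        viol |= (template_masks[t : t + n] & pm[t]) == 0
    return viol


def _primer_sites(
    seq_masks: np.ndarray, primer: str, max_mismatches: int, clamp: int
) -> list[tuple[int, int]]:
    """(start, mismatches) of plus-strand annealing sites, primer 5'→3'."""
    mism = _mismatch_profile(seq_masks, primer)
    viol = _clamp_violations(seq_masks, primer, clamp)
    hits = np.nonzero((mism <= max_mismatches) & ~viol)[0]
    return [(int(i), int(mism[i])) for i in hits]


def in_silico_pcr(
    record: GenomeRecord,
    fwd: Primer,
    rev: Primer,
    marker_name: str = "",
    max_mismatches: int = 3,
    max_product: int = 5_000,
    clamp: int = 3,
) -> list[Amplicon]:
    """Locate all products a primer pair would amplify from a template.

    The forward primer anneals to one strand and the reverse primer to the
    opposite strand downstream, within ``max_product``.  Base compatibility
    is IUPAC-aware; up to ``max_mismatches`` per primer are tolerated except
    in the ``clamp`` 3'-terminal positions, which must match exactly.
    Circular templates are searched across the origin.  Products are reported
    on the forward strand of the template, ordered by start; an empty list
    means no amplification.
    """
    n = len(record.sequence)
    seq = record.sequence
    if record.circular:
        # extend so products crossing the origin are found once
        ext = min(n, max_product + max(len(fwd.sequence), len(rev.sequence)))
        seq = seq + record.sequence[:ext]
    masks = MASK_TABLE[seq_to_bytes(seq)]

    products: dict[tuple[int, int], Amplicon] = {}

    def scan(fp: Primer, rp: Primer, flipped: bool) -> None:
        # fp anneals to the plus strand of `seq`; rp's reverse complement
        # appears on the plus strand downstream
        rp_rc = revcomp(rp.sequence)
        rp_rc_masks = np.array(
            [IUPAC_MASK[c] for c in rp_rc], dtype=np.uint8
        )
        f_sites = _primer_sites(masks, fp.sequence, max_mismatches, clamp)
        # reverse primer: mismatches counted against plus strand via its RC;
        # the primer's 3' end maps to the *start* of the RC on the plus strand
        k = len(rp_rc)
        m = len(seq) - k + 1
        if m <= 0:
            return
        mism = np.zeros(m, dtype=np.int32)
        viol = np.zeros(m, dtype=bool)
        for t in range(k):
            bad = (masks[t : t + m] & rp_rc_masks[t]) == 0
            mism += bad
            if t < clamp:  # first `clamp` bases of the RC are the primer 3' end
                viol |= bad
        r_hits = {int(i): int(mism[i]) for i in np.nonzero((mism <= max_mismatches) & ~viol)[0]}
        r_starts = np.array(sorted(r_hits), dtype=np.int64)
        for f_start, f_mm in f_sites:
            if f_start >= n:  # only canonical (first-copy) forward sites
                continue
            lo = f_start + len(fp.sequence)
            hi = f_start + max_product - k
            sel = r_starts[(r_starts >= lo) & (r_starts <= hi)]
            for r_start in sel:
                end = int(r_start) + k
                prod_seq = seq[f_start:end]
                key = (f_start % n, end % n)
                if flipped:
                    amp = Amplicon(
                        taxon=record.taxon_label,
                        marker_name=marker_name,
                        start=f_start,
                        end=end,
                        sequence=revcomp(prod_seq),
                        fwd_mismatches=r_hits[int(r_start)],
                        rev_mismatches=f_mm,
                    )
                else:
                    amp = Amplicon(
                        taxon=record.taxon_label,
                        marker_name=marker_name,
                        start=f_start,
                        end=end,
                        sequence=prod_seq,
                        fwd_mismatches=f_mm,
                        rev_mismatches=r_hits[int(r_start)],
                    )
                products.setdefault(key, amp)

    # orientation 1: fwd on plus strand, rev on minus strand
    scan(fwd, rev, flipped=False)
    # orientation 2: fwd on minus strand, rev on plus strand — the product is
    # the reverse complement of the plus-strand span
    scan(rev, fwd, flipped=True)

    return sorted(products.values(), key=lambda a: (a.start, a.end))


# --------------------------------------------------------------------------
# Intergenic regions
# --------------------------------------------------------------------------

def list_intergenic_regions(
    record: GenomeRecord, deduplicate_ir: bool = True
) -> dict[str, tuple[int, int]]:
    """Name the gaps between adjacent annotated features.

    Features are ordered by start coordinate (IR-duplicated copies inside the
    IRb interval dropped first when a partition is present); each non-empty
    gap becomes a region named "upstream → downstream".  On circular records
    the wrap-around gap between the last and first feature is included.
    """
    feats = [f for f in record.features if not f.spans_origin]
    if record.partition is not None and deduplicate_ir:
        s, e = record.partition.irb
        if e > s:
            feats = [f for f in feats if not (f.start >= s and f.end <= e)]
    if len(feats) < 2:
        return {}
    feats = sorted(feats, key=lambda f: (f.start, f.end))
    regions: dict[str, tuple[int, int]] = {}
    for a, b in zip(feats, feats[1:]):
        if b.start > a.end:
            regions[f"{a.name} → {b.name}"] = (a.end, b.start)
    if record.circular:
        last, first = feats[-1], feats[0]
        gap_len = len(record.sequence) - last.end + first.start
        if 0 < gap_len:
            regions[f"{last.name} → {first.name}"] = (last.end, first.start)
    return regions


# --------------------------------------------------------------------------
# Marker discrimination
# --------------------------------------------------------------------------

def marker_snp_matrix(
    amplicons: Mapping[str, Amplicon | None],
    marker_name: str | None = None,
    aligner_params: Mapping[str, float] | None = None,
) -> MarkerReport:
    """Align one amplicon per taxon and count pairwise diagnostic SNPs.

    Taxa whose amplification failed (``None``) are excluded from the matrix
    and reported in ``failed_taxa`` with a warning.  SNP counting follows the
    whole-genome convention: both rows unambiguous and different; gap/N
    columns are excluded.
    """
    params = dict(DEFAULT_SCORES)
    if aligner_params:
        params.update(aligner_params)
    present = {t: a for t, a in amplicons.items() if a is not None}
    failed = sorted(set(amplicons) - set(present))
    for t in failed:
        logger.warning("amplification failure for taxon %s; excluded", t)
    if len(present) < 2:
        raise ValueError("marker_snp_matrix needs amplicons from >= 2 taxa")
    taxa = list(present)
    name = marker_name or next(iter(present.values())).marker_name
    msa = align_small([present[t].sequence for t in taxa], taxa=taxa, **params)
    dm = pairwise_difference_matrix(msa)
    return MarkerReport(
        marker_names=[name],
        taxa=taxa,
        pairwise_snps=dm.counts,
        amplicon_lengths={t: present[t].length_bp for t in taxa},
        failed_taxa=failed,
    )


def combine_markers(reports: Sequence[MarkerReport]) -> MarkerReport:
    """Combine markers: SNP matrices summed, unresolved pairs recomputed.

    A pair remains unresolved only when *every* marker leaves it unresolved.
    All reports must cover the same taxon set.
    """
    if not reports:
        raise ValueError("combine_markers needs at least one report")
    base = reports[0]
    taxa = list(base.taxa)
    total = np.array(base.pairwise_snps, dtype=np.int64, copy=True)
    names = list(base.marker_names)
    for rep in reports[1:]:
        if set(rep.taxa) != set(taxa):
            raise ValueError(
                f"taxon sets differ: {sorted(taxa)} vs {sorted(rep.taxa)}"
            )
        order = [rep.taxa.index(t) for t in taxa]
        total += np.asarray(rep.pairwise_snps)[np.ix_(order, order)]
        names.extend(rep.marker_names)
    return MarkerReport(marker_names=names, taxa=taxa, pairwise_snps=total)


# --------------------------------------------------------------------------
# Primer tables
# --------------------------------------------------------------------------

def read_primer_table(path: str | Path) -> dict[str, tuple[Primer, Primer]]:
    """Read a primer TSV: columns marker, name, sequence, orientation.

    Lines starting with '#' are comments.  Returns marker -> (forward,
    reverse) primer pair.
    """
    pairs: dict[str, dict[str, Primer]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "marker":  # header
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 tab-separated fields")
            marker, name, seq, orient = parts
            pairs.setdefault(marker, {})[orient] = Primer(name, seq, orient)
    out: dict[str, tuple[Primer, Primer]] = {}
    for marker, d in pairs.items():
        if set(d) != {"forward", "reverse"}:
            raise ValueError(f"marker {marker!r}: needs one forward and one reverse primer")
        out[marker] = (d["forward"], d["reverse"])
    return out


def default_primers() -> dict[str, tuple[Primer, Primer]]:
    """The barcode primer pairs shipped with the package (see data/primers.tsv)."""
    from importlib.resources import files

    return read_primer_table(str(files("superbarcode").joinpath("data/primers.tsv")))
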