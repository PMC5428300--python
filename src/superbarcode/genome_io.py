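"""Annotated plastome records: parsing, validation, quadripartite structure.

A chloroplast genome is a circular molecule of roughly 150 kb with a
quadripartite architecture: a large single-copy region (LSC), a small
single-copy region (SSC) and two inverted repeats (IRa, IRb) that are exact
reverse complements of one another.  This module parses GenBank flat files
into :class:`GenomeRecord` objects, detects the IR pair from sequence alone,
and summarizes gene content the way plastome papers report it (total gene
count, unique counts collapsing the IR-duplicated copies, intron-bearing
genes, G+C content).

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
intervals are converted on ingest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from ._seq import gc_percent, normalize_sequence, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureKind",
    "Feature",
    "QuadripartitePartition",
    "GenomeRecord",
    "GenomeStats",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "write_genbank",
    "detect_inverted_repeats",
    "genome_stats",
    "extract_feature_sequence",
    "write_stats_table",
]


class FeatureKind(str, Enum):
    protein_coding = "protein_coding"
    tRNA = "tRNA"
    rRNA = "rRNA"
    other = "other"


@dataclass(frozen=True)
class Feature:
    """One annotated element (gene, tRNA, rRNA ...) on a genome record.

    ``start``/``end`` are 0-based half-open.  A feature that spans the origin
    of a circular record has ``spans_origin=True`` and ``end`` may then be
    smaller than ``start`` (the feature runs start..L plus 0..end).
    """

    name: str
    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    intron_count: int = 0
    spans_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.intron_count < 0:
            raise ValueError("intron_count must be non-negative")
        if not self.spans_origin and self.start >= self.end:
            raise ValueError(
                f"feature {self.name!r}: start {self.start} >= end {self.end} "
                "(origin-spanning features must be flagged)"
            )

    def length(self, genome_length: int | None = None) -> int:
        if self.spans_origin:
            if genome_length is None:
                raise ValueError("genome_length required for origin-spanning feature")
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / IRa / SSC / IRb intervals tiling the circular genome.

    Each interval is (start, end), 0-based half-open on the record; an
    interval with end <= start wraps across the origin.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    ir_length: int

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {"lsc": self.lsc, "ira": self.ira, "ssc": self.ssc, "irb": self.irb}

    @staticmethod
    def interval_length(iv: tuple[int, int], genome_length: int) -> int:
        s, e = iv
        return e - s if e > s else genome_length - s + e


@dataclass
class GenomeRecord:
    """One annotated (optionally circular) plastome."""

    taxon_label: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    partition: QuadripartitePartition | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        seq, n_conv = normalize_sequence(self.sequence)
        if n_conv:
            logger.warning(
                "%s: %d ambiguous bases normalized to N", self.taxon_label, n_conv
            )
        self.sequence = seq
        self._validate_features()

    def _validate_features(self) -> None:
        n = len(self.sequence)
        seen: set[tuple] = set()
        for f in self.features:
            hi = max(f.start, f.end)
            if f.start < 0 or hi > n:
                raise ValueError(
                    f"feature {f.name!r} coordinates ({f.start}, {f.end}) exceed "
                    f"sequence length {n}"
                )
            if f.spans_origin and not self.circular:
                raise ValueError(
                    f"feature {f.name!r} spans the origin of a linear record"
                )
            key = (f.name, f.start, f.end, f.strand)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_by_name(self, name: str) -> list[Feature]:
        return [f for f in self.features if f.name == name]


@dataclass(frozen=True)
class GenomeStats:
    length_bp: int
    gc_percent: float
    n_genes_total: int
    n_unique_protein_coding: int
    n_trna: int
    n_unique_trna: int
    n_rrna_total: int
    n_unique_rrna: int
    n_intron_genes: int


_KIND_BY_FEATURE_TYPE = {
    "CDS": FeatureKind.protein_coding,
    "tRNA": FeatureKind.tRNA,
    "rRNA": FeatureKind.rRNA,
}


def read_genbank(path: str | Path, taxon_label: str | None = None) -> GenomeRecord:
    """Parse a GenBank flat file into a validated :class:`GenomeRecord`.

    CDS features become protein-coding, tRNA/rRNA features keep their kind,
    anything else annotated with a gene name becomes ``other``.  The taxon
    label is taken from the ORGANISM line unless overridden.  Compound (joined)
    locations contribute ``intron_count = parts - 1``.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq or set(seq.upper()) <= {"N"}:
        raise ValueError(f"{path}: missing or empty ORIGIN sequence block")
    label = taxon_label or rec.annotations.get("organism") or rec.id
    circular = rec.annotations.get("topology", "circular") == "circular"
    n = len(seq)

    features: list[Feature] = []
    seen: set[tuple] = set()
    for ft in rec.features:
        if ft.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        name = (
            ft.qualifiers.get("gene", [None])[0]
            or ft.qualifiers.get("locus_tag", [None])[0]
            or ft.type
        )
        start = int(ft.location.start)
        end = int(ft.location.end)
        spans_origin = False
        intron_count = 0
        if isinstance(ft.location, CompoundLocation):
            parts = sorted(
                ((int(p.start), int(p.end)) for p in ft.location.parts)
            )
            # a join touching both ends of the record is an origin-spanning
            # feature, not an intron
            if parts[0][0] == 0 and parts[-1][1] == n and len(parts) == 2:
                spans_origin = True
                start, end = parts[1][0], parts[0][1]
            else:
                intron_count = len(parts) - 1
                start, end = parts[0][0], parts[-1][1]
        if end > n or start < 0:
            raise ValueError(
                f"{path}: feature {name!r} coordinates ({start}, {end}) exceed "
                f"sequence length {n}"
            )
        kind = _KIND_BY_FEATURE_TYPE.get(ft.type, FeatureKind.other)
        if ft.type == "gene":
            continue  # kinds come from CDS/tRNA/rRNA; bare genes are redundant
        strand = "-" if ft.location.strand == -1 else "+"
        key = (name, start, end, strand)
        if key in seen:
            continue
        seen.add(key)
        features.append(
            Feature(
                name=name,
                kind=kind,
                start=start,
                end=end,
                strand=strand,
                intron_count=intron_count,
                spans_origin=spans_origin,
            )
        )
    return GenomeRecord(
        taxon_label=label, sequence=seq, circular=circular, features=features
    )


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read one or more plain (unannotated) records from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomeRecord(taxon_label=rec.id, sequence=str(rec.seq), features=[])
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord] | GenomeRecord, path: str | Path) -> None:
    if isinstance(records, GenomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.taxon_label.replace(' ', '_')}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# --------------------------------------------------------------------------
# Inverted-repeat detection
# --------------------------------------------------------------------------

def _extend_rc_pair(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximally extend seq[i:i+k] == revcomp(seq[j:j+k]) with i+k <= j.

    Returns the extended (i, j, k).  ``seq`` may be a doubled circular
    sequence; the caller bounds the intervals afterwards.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    # grow left end of left copy together with right end of right copy
    while i > 0 and j + k < n and seq[i - 1] == comp.get(seq[j + k], "?"):
        i -= 1
        k += 1
    # grow right end of left copy together with left end of right copy
    while i + k < j and seq[i + k] == comp.get(seq[j - 1], "?"):
        j -= 1
        k += 1
    return i, j, k


def detect_inverted_repeats(
    record: GenomeRecord, min_len: int = 10_000, seed_k: int = 25
) -> QuadripartitePartition | None:
    """Locate the IRa/IRb pair and derive the quadripartite partition.

    Finds the maximal-length pair of disjoint intervals whose sequences are
    exact reverse complements of each other, using k-mer seeding and maximal
    extension.  Ties on length are broken by the smallest start coordinate.
    Circular records are searched across the origin.  Returns ``None`` when no
    repeat of at least ``min_len`` exists ("no IR found" — the record is left
    unpartitioned).

    The longer of the two gaps between the repeats is reported as the LSC, the
    shorter as the SSC; the repeat copy downstream of the LSC is IRa.
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000")
    n = len(record.sequence)
    if n < 2 * min_len:
        return None
    seq = record.sequence + record.sequence if record.circular else record.sequence
    m = len(seq)

    index: dict[str, list[int]] = {}
    for i in range(0, n):  # index first copy only: every repeat has a start there
        kmer = seq[i : i + seed_k]
        index.setdefault(kmer, []).append(i)

    stride = max(1, min_len // 4)
    best: tuple[int, int, int] | None = None  # (k, i, j) maximized, then -i
    seen_pairs: set[tuple[int, int]] = set()
    for j in range(0, m - seed_k + 1, stride):
        rc_kmer = revcomp(seq[j : j + seed_k])
        for i in index.get(rc_kmer, ()):
            if i + seed_k > j:
                continue
            ei, ej, ek = _extend_rc_pair(seq, i, j, seed_k)
            if ek < min_len or ek > n:
                continue
            if record.circular and (ej + ek) - ei > n:
                continue  # copies would overlap on the circle
            if (ei, ej) in seen_pairs:
                continue
            seen_pairs.add((ei, ej))
            cand = (ek, -ei, -ej)
            if best is None or cand > (best[0], -best[1], -best[2]):
                best = (ek, ei, ej)
    if best is None:
        return None
    k, i, j = best

    def norm(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv[0] % n, iv[1] % n
        if e == 0 and iv[1] > 0:
            e = n
        return (s, e)

    rep1 = (i, i + k)
    rep2 = (j, j + k)
    # gaps on the circle between the two repeat copies
    gap_a = (i + k, j)          # between rep1 end and rep2 start
    gap_b = (j + k, i + n)      # wraps around through the origin
    len_a = gap_a[1] - gap_a[0]
    len_b = gap_b[1] - gap_b[0]
    if len_a >= len_b:
        # IRa is the repeat copy that follows the LSC in genome order
        lsc, ira, ssc, irb = gap_a, rep2, gap_b, rep1
    else:
        lsc, ira, ssc, irb = gap_b, rep1, gap_a, rep2
    return QuadripartitePartition(
        lsc=norm(lsc), ira=norm(ira), ssc=norm(ssc), irb=norm(irb), ir_length=k
    )


# --------------------------------------------------------------------------
# Gene-content summary
# --------------------------------------------------------------------------

def genome_stats(record: GenomeRecord) -> GenomeStats:
    """Summarize gene content the way plastome reports print it.

    "Unique" counts collapse IR-duplicated copies by gene name: a gene counts
    as duplicated only when a second full-length copy with the same name
    exists.  G+C is computed over A/C/G/T positions only and rounded to one
    decimal.
    """
    by_kind: dict[FeatureKind, list[Feature]] = {k: [] for k in FeatureKind}
    for f in record.features:
        by_kind[f.kind].append(f)

    def total(kind: FeatureKind) -> int:
        return len(by_kind[kind])

    def unique(kind: FeatureKind) -> int:
        return len({f.name for f in by_kind[kind]})

    intron_genes = {f.name for f in record.features if f.intron_count > 0}
    return GenomeStats(
        length_bp=len(record.sequence),
        gc_percent=gc_percent(record.sequence),
        n_genes_total=len(record.features),
        n_unique_protein_coding=unique(FeatureKind.protein_coding),
        n_trna=total(FeatureKind.tRNA),
        n_unique_trna=unique(FeatureKind.tRNA),
        n_rrna_total=total(FeatureKind.rRNA),
        n_unique_rrna=unique(FeatureKind.rRNA),
        n_intron_genes=len(intron_genes),
    )


def extract_feature_sequence(
    record: GenomeRecord, feature_name: str
) -> str | list[str]:
    """Return the (strand-corrected) sequence of a named feature.

    Minus-strand features are reverse-complemented; origin-spanning features
    are concatenated across the origin.  When the feature is duplicated (IR
    copies) a list is returned, in genome order.  Unknown names raise a
    ``KeyError`` listing near-matches.
    """
    feats = record.features_by_name(feature_name)
    if not feats:
        import difflib

        close = difflib.get_close_matches(
            feature_name, {f.name for f in record.features}, n=3
        )
        hint = f"; did you mean {', '.join(close)}?" if close else ""
        raise KeyError(f"no feature named {feature_name!r}{hint}")
    out = []
    for f in sorted(feats, key=lambda f: f.start):
        if f.spans_origin:
            s = record.sequence[f.start :] + record.sequence[: f.end]
        else:
            s = record.sequence[f.start : f.end]
        out.append(revcomp(s) if f.strand == "-" else s)
    return out[0] if len(out) == 1 else out


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (CDS/tRNA/rRNA features)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    type_by_kind = {
        FeatureKind.protein_coding: "CDS",
        FeatureKind.tRNA: "tRNA",
        FeatureKind.rRNA: "rRNA",
        FeatureKind.other: "misc_feature",
    }
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.taxon_label.replace(" ", "_")[:16] or "genome",
        name=record.taxon_label.replace(" ", "_")[:16] or "genome",
        description=f"{record.taxon_label} chloroplast genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.taxon_label,
        },
    )
    for f in sorted(record.features, key=lambda f: f.start):
        loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(
            SeqFeature(loc, type=type_by_kind[f.kind], qualifiers={"gene": [f.name]})
        )
    SeqIO.write(rec, str(path), "genbank")


_STATS_COLUMNS = [
    "taxon",
    "length_bp",
    "gc_percent",
    "n_genes_total",
    "n_unique_protein_coding",
    "n_trna",
    "n_rrna_total",
]


def write_stats_table(
    records: Sequence[GenomeRecord], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write a one-row-per-genome TSV summary table."""
    import pandas as pd

    rows = []
    for rec in records:
        st = genome_stats(rec)
        rows.append(
            {
                "taxon": rec.taxon_label,
                "length_bp": st.length_bp,
                "gc_percent": st.gc_percent,
                "n_genes_total": st.n_genes_total,
                "n_unique_protein_coding": st.n_unique_protein_coding,
                "n_trna": st.n_trna,
                "n_rrna_total": st.n_rrna_total,
            }
        )
    df = pd.DataFrame(rows, columns=_STATS_COLUMNS)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.1f")
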