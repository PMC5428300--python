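"""Synthetic plastome sets with known evolutionary truth.

The generator emulates the data regime of a congeneric plastome comparison:
nine taxa on a bifurcating tree, ~152 kb circular genomes with the
quadripartite LSC/IRa/SSC/IRb architecture, annotated protein-coding, tRNA
and rRNA genes (the IR genes duplicated), pairwise divergence of 0.1–0.6%,
substitutions enriched in intergenic spacers, short geometric-length indels
confined to single-copy spacers, and conserved primer-binding sites flanking
the barcode markers.

Because every mutation event is applied to an explicitly tracked coordinate
system, the generator emits the *true* multiple alignment (no aligner
involved) together with a :class:`SimulationTruth` record: the generating
tree, exact per-pair difference counts recomputed independently from the
final rows, the planted indel log, primer-site coordinates, and the
alignment-column intervals of every gene and spacer region.

Modelling choices (see docs/methods.md for rationale): substitutions are
uniform over the three alternative bases (JC-like); branch lengths are
expected substitutions per site averaged over the genome, so per-site rates
are normalized by the mean rate multiplier; mutations falling in IRa are
mirrored into IRb as complements, keeping revcomp(IRa) == IRb exact at every
leaf; inserted segments are inert once created (they do not mutate further
along descendant branches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from ._seq import revcomp
from .alignment import Msa
from .genome_io import Feature, FeatureKind, GenomeRecord, QuadripartitePartition
from .markers import Primer, default_primers

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MarkerDef",
    "ConfigError",
    "simulate_genomes",
    "simulate_marker_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b
_GAP = ord("-")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class MarkerDef:
    """A barcode marker planted on the genome: primer pair + interior length."""

    name: str
    fwd: Primer
    rev: Primer
    interior_length: int

    @property
    def product_length(self) -> int:
        return len(self.fwd.sequence) + self.interior_length + len(self.rev.sequence)


def _default_markers() -> tuple[MarkerDef, ...]:
    primers = default_primers()
    # interior lengths chosen to give product sizes in the ranges barcoding
    # studies report for these loci (trnH-psbA ~0.5 kb, matK ~0.9 kb, rbcL ~0.6 kb)
    spec = {"trnH-psbA": 460, "matK": 904, "rbcL": 553}
    return tuple(
        MarkerDef(name, primers[name][0], primers[name][1], interior)
        for name, interior in spec.items()
    )


@dataclass
class SimulationConfig:
    """Study-regime parameters for the plastome generator.

    Defaults mirror the congeneric-comparison regime: 9 taxa, 152 kb genomes
    with 25 kb IRs and an 18 kb SSC, pairwise divergence 0.1–0.6%, intergenic
    substitution rates 3x the coding rate, and sparse short indels restricted
    to single-copy intergenic spacers.
    """

    n_taxa: int = 9
    genome_length: int = 152_000
    ir_length: int = 25_000
    ssc_length: int = 18_000
    divergence_min: float = 0.001
    divergence_max: float = 0.006
    intergenic_multiplier: float = 3.0
    #: ordinal of a regular LSC spacer given an extra rate multiplier (hot spot)
    hot_spacer_index: int | None = None
    hot_spacer_multiplier: float = 1.0
    indel_rate: float = 0.08   # expected events per unit branch length per spacer bp
    indel_mean_length: float = 6.0
    coding_indels: bool = False
    markers: tuple[MarkerDef, ...] = field(default_factory=_default_markers)
    #: nuclear loci simulated off-plastome on an independent tree
    nuclear_markers: dict[str, int] = field(
        default_factory=lambda: {"ITS": 700}
    )
    nuclear_divergence: float = 0.010
    fixed_tree: str | None = None  # Newick; overrides the random topology
    gc_fraction: float = 0.37
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if not (0.0 <= self.divergence_min <= self.divergence_max <= 0.05):
            raise ConfigError("divergence range must lie within [0, 0.05]")
        for name, val in [
            ("intergenic_multiplier", self.intergenic_multiplier),
            ("hot_spacer_multiplier", self.hot_spacer_multiplier),
            ("indel_rate", self.indel_rate),
            ("nuclear_divergence", self.nuclear_divergence),
        ]:
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.indel_mean_length < 1:
            raise ConfigError("indel_mean_length must be >= 1")
        sc = self.genome_length - 2 * self.ir_length - self.ssc_length
        if sc < 20_000:
            raise ConfigError("genome too small for the requested IR/SSC lengths")
        if self.indel_rate > 0:
            for m in self.markers:
                if m.interior_length < 2 * self.indel_mean_length + 4:
                    raise ConfigError(
                        f"marker {m.name!r}: interior too short — expected indels "
                        "would overlap the primer sites"
                    )


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analysis must recover."""

    tree: dendropy.Tree
    newick: str
    taxa: list[str]
    pair_counts: np.ndarray                 # exact, from the final rows
    gene_regions: dict[str, tuple[int, int]]     # alignment columns
    spacer_regions: dict[str, tuple[int, int]]   # alignment columns
    hot_spacers: list[str]
    marker_spans: dict[str, tuple[int, int]]     # alignment columns, primer-inclusive
    primer_sites: dict[str, tuple[tuple[int, int], tuple[int, int]]]  # root coords
    planted_indels: list[dict]
    n_substitutions: int
    seed: int

    def pair(self, a: str, b: str) -> int:
        return int(self.pair_counts[self.taxa.index(a), self.taxa.index(b)])


# --------------------------------------------------------------------------
# Random trees
# --------------------------------------------------------------------------

def _random_tree(
    taxa: Sequence[str], rng: np.random.Generator, d_min: float, d_max: float
) -> dendropy.Tree:
    """Random bifurcating topology with branch lengths scaled so that the
    maximum pairwise path length is ``d_max`` and the minimum at least
    ``d_min`` (terminal edges are lengthened if needed)."""
    tns = dendropy.TaxonNamespace(list(taxa))
    nodes = []
    for t in taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(t)
        nd.edge.length = float(rng.uniform(0.5, 1.5))
        nodes.append(nd)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.5, 1.5))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.is_rooted = True

    # scale to the divergence window
    pdm = tree.phylogenetic_distance_matrix()
    dists = [
        pdm.patristic_distance(a, b)
        for i, a in enumerate(tns) for b in list(tns)[i + 1:]
    ]
    scale = d_max / max(dists)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    min_d = min(dists) * scale
    if min_d < d_min:
        bump = (d_min - min_d) / 2.0
        for leaf in tree.leaf_node_iter():
            leaf.edge.length += bump
    return tree


# --------------------------------------------------------------------------
# Genome layout
# --------------------------------------------------------------------------

@dataclass
class _Layout:
    sequence: np.ndarray            # uint8 root sequence
    features: list[Feature]
    partition: QuadripartitePartition
    rate: np.ndarray                # sampling rate multiplier per root position
    mirror: np.ndarray              # IRb partner index for IRa positions, else -1
    spacers: list[tuple[int, int]]  # single-copy spacer intervals (indel-capable)
    spacer_names: dict[tuple[int, int], str]
    hot_intervals: list[tuple[int, int]]
    marker_spans_root: dict[str, tuple[int, int]]
    primer_sites: dict[str, tuple[tuple[int, int], tuple[int, int]]]


def _realize_primer(seq: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes with one concrete compatible base."""
    from ._seq import IUPAC_MASK

    out = []
    for ch in seq:
        mask = IUPAC_MASK[ch]
        choices = [b for i, b in enumerate("ACGT") if mask & (1 << i)]
        out.append(choices[int(rng.integers(len(choices)))] if len(choices) > 1 else ch)
    return "".join(out)


def _build_root(config: SimulationConfig, rng: np.random.Generator) -> _Layout:
    L = config.genome_length
    ir = config.ir_length
    ssc = config.ssc_length
    lsc = L - 2 * ir - ssc
    lsc_iv = (0, lsc)
    ira_iv = (lsc, lsc + ir)
    ssc_iv = (lsc + ir, lsc + ir + ssc)
    irb_iv = (lsc + ir + ssc, L)

    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=L, p=probs)

    rate = np.zeros(L, dtype=np.float64)
    features: list[Feature] = []
    spacers: list[tuple[int, int]] = []
    hot_intervals: list[tuple[int, int]] = []
    marker_spans: dict[str, tuple[int, int]] = {}
    primer_sites: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}

    cursor = 0
    spacer_ordinal = 0

    def add_gene(name: str, kind: FeatureKind, length: int, introns: int = 0) -> None:
        nonlocal cursor
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            Feature(name=name, kind=kind, start=cursor, end=cursor + length,
                    strand=strand, intron_count=introns)
        )
        rate[cursor : cursor + length] = 1.0
        cursor += length

    def add_spacer(length: int, indel_ok: bool = True) -> None:
        nonlocal cursor, spacer_ordinal
        mult = config.intergenic_multiplier
        iv = (cursor, cursor + length)
        if (
            config.hot_spacer_index is not None
            and spacer_ordinal == config.hot_spacer_index
        ):
            mult *= config.hot_spacer_multiplier
            hot_intervals.append(iv)
        rate[iv[0] : iv[1]] = mult
        if indel_ok and length >= 12:
            spacers.append(iv)
        spacer_ordinal += 1
        cursor += length

    # ---- LSC: marker blocks first, then regular gene/spacer runs ----------
    add_gene("psbA0", FeatureKind.protein_coding, 1000)
    for m in config.markers:
        add_spacer(int(rng.integers(100, 250)))
        parts = m.name.split("-")
        up = parts[0] if len(parts) == 2 else f"{m.name}_up"
        down = parts[1] if len(parts) == 2 else f"{m.name}_dn"
        add_gene(up, FeatureKind.tRNA, 75)
        # the marker spacer: fwd primer site, interior, reverse-complemented
        # rev primer site; primer sites are immutable
        fs = cursor
        fseq = _realize_primer(m.fwd.sequence, rng)
        seq[fs : fs + len(fseq)] = np.frombuffer(fseq.encode(), dtype=np.uint8)
        rate[fs : fs + len(fseq)] = 0.0
        interior = (fs + len(fseq), fs + len(fseq) + m.interior_length)
        rate[interior[0] : interior[1]] = config.intergenic_multiplier
        spacers.append(interior)
        rseq = revcomp(_realize_primer(m.rev.sequence, rng))
        rs = interior[1]
        seq[rs : rs + len(rseq)] = np.frombuffer(rseq.encode(), dtype=np.uint8)
        rate[rs : rs + len(rseq)] = 0.0
        marker_spans[m.name] = (fs, rs + len(rseq))
        primer_sites[m.name] = ((fs, fs + len(fseq)), (rs, rs + len(rseq)))
        cursor = rs + len(rseq)
        spacer_ordinal += 1
        add_gene(down, FeatureKind.protein_coding, 1100)

    gene_no = 0
    while cursor < lsc - 2600:
        add_spacer(int(rng.integers(80, 400)))
        gene_no += 1
        if gene_no % 4 == 0:
            add_gene(f"trn{gene_no:02d}", FeatureKind.tRNA, 75)
        else:
            introns = 1 if gene_no % 7 == 0 else 0
            add_gene(
                f"gene{gene_no:03d}",
                FeatureKind.protein_coding,
                int(rng.integers(300, 1800)),
                introns,
            )
    add_spacer(lsc - cursor)

    # ---- IRa: rRNA operon + a few duplicated genes; no indels -------------
    def add_ir_spacer(length: int) -> None:
        nonlocal cursor
        rate[cursor : cursor + length] = config.intergenic_multiplier
        cursor += length

    assert cursor == ira_iv[0]
    add_ir_spacer(300)
    add_gene("rrn16", FeatureKind.rRNA, 1490)
    add_ir_spacer(250)
    add_gene("rrn23", FeatureKind.rRNA, 2810)
    add_ir_spacer(100)
    add_gene("rrn4.5", FeatureKind.rRNA, 100)
    add_ir_spacer(80)
    add_gene("rrn5", FeatureKind.rRNA, 120)
    add_ir_spacer(200)
    add_gene("trnIR1", FeatureKind.tRNA, 75)
    add_ir_spacer(150)
    add_gene("rpl2x", FeatureKind.protein_coding, 1500, introns=1)
    add_ir_spacer(ira_iv[1] - cursor)
    assert cursor == ira_iv[1]

    # ---- SSC ----------------------------------------------------------------
    sg = 0
    while cursor < ssc_iv[1] - 2600:
        add_spacer(int(rng.integers(80, 400)))
        sg += 1
        add_gene(f"sscg{sg:02d}", FeatureKind.protein_coding, int(rng.integers(400, 2000)))
    add_spacer(ssc_iv[1] - cursor)

    # ---- IRb: exact reverse complement of IRa, mirrored annotations --------
    ira_s, ira_e = ira_iv
    irb_s, irb_e = irb_iv
    seq[irb_s:irb_e] = _COMP[seq[ira_s:ira_e][::-1]]
    mirror = np.full(L, -1, dtype=np.int64)
    offsets = np.arange(ir)
    mirror[ira_s + offsets] = irb_e - 1 - offsets
    rate[irb_s:irb_e] = 0.0  # mutated only through the IRa mirror
    for f in [f for f in features if ira_s <= f.start and f.end <= ira_e]:
        s2 = irb_s + (ira_e - f.end)
        e2 = irb_s + (ira_e - f.start)
        features.append(
            Feature(
                name=f.name, kind=f.kind, start=s2, end=e2,
                strand="-" if f.strand == "+" else "+",
                intron_count=f.intron_count,
            )
        )
    cursor = irb_e

    partition = QuadripartitePartition(
        lsc=lsc_iv, ira=ira_iv, ssc=ssc_iv, irb=irb_iv, ir_length=ir
    )

    # name single-copy spacers by their flanking features
    feats_sorted = sorted(features, key=lambda f: f.start)
    spacer_names: dict[tuple[int, int], str] = {}
    for iv in spacers:
        up = [f for f in feats_sorted if f.end <= iv[0]]
        down = [f for f in feats_sorted if f.start >= iv[1]]
        uname = up[-1].name if up else "origin"
        dname = down[0].name if down else "origin"
        spacer_names[iv] = f"{uname} → {dname}"

    return _Layout(
        sequence=seq,
        features=features,
        partition=partition,
        rate=rate,
        mirror=mirror,
        spacers=spacers,
        spacer_names=spacer_names,
        hot_intervals=hot_intervals,
        marker_spans_root=marker_spans,
        primer_sites=primer_sites,
    )


# --------------------------------------------------------------------------
# Evolution along the tree
# --------------------------------------------------------------------------

@dataclass
class _Insertion:
    anchor: int   # inserted immediately before this root column
    uid: int
    seq: str
    taxon_origin: str | None = None


def _evolve_genomes(
    layout: _Layout,
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, list[_Insertion]], list[dict], int]:
    """Walk the tree, mutating a copy of the root state along every branch."""
    L = len(layout.sequence)
    rate = layout.rate
    # effective per-site rate: IRb positions diverge via their IRa partner
    effective = rate.copy()
    ira_pos = np.nonzero(layout.mirror >= 0)[0]
    effective[layout.mirror[ira_pos]] = rate[ira_pos]
    norm = effective.mean()
    if norm <= 0:
        raise ConfigError("no mutable positions in the genome layout")
    p_unit = rate / norm  # per-site substitution probability per unit branch length

    spacer_bounds = layout.spacers
    spacer_lengths = np.array([e - s for s, e in spacer_bounds], dtype=float)
    total_spacer = spacer_lengths.sum()

    leaf_chars: dict[str, np.ndarray] = {}
    leaf_inserts: dict[str, list[_Insertion]] = {}
    indel_log: list[dict] = []
    uid_counter = [0]
    n_subs = [0]

    def mutate(chars: np.ndarray, inserts: list[_Insertion], blen: float, label: str):
        # substitutions
        p = np.minimum(p_unit * blen, 0.999)
        hit = np.nonzero((rng.random(L) < p) & (chars != _GAP))[0]
        if hit.size:
            shift = rng.integers(1, 4, size=hit.size)
            base_idx = np.searchsorted(_BASES, chars[hit])
            chars[hit] = _BASES[(base_idx + shift) % 4]
            partners = layout.mirror[hit]
            has_partner = partners >= 0
            chars[partners[has_partner]] = _COMP[chars[hit[has_partner]]]
            n_subs[0] += int(hit.size)
        # indels (single-copy spacers only)
        if config.indel_rate > 0 and total_spacer > 0:
            n_events = rng.poisson(config.indel_rate * blen * total_spacer)
            for _ in range(n_events):
                si = rng.choice(len(spacer_bounds), p=spacer_lengths / total_spacer)
                s, e = spacer_bounds[si]
                length = int(rng.geometric(1.0 / config.indel_mean_length))
                if rng.random() < 0.5:  # deletion, clipped to the spacer
                    start = int(rng.integers(s, e))
                    stop = min(start + length, e)
                    chars[start:stop] = _GAP
                    indel_log.append(
                        {"taxon_branch": label, "kind": "deletion",
                         "position": start, "length": stop - start}
                    )
                else:  # insertion
                    anchor = int(rng.integers(s + 1, e))
                    ins_seq = "".join(
                        chr(b) for b in rng.choice(_BASES, size=length)
                    )
                    ins = _Insertion(anchor=anchor, uid=uid_counter[0], seq=ins_seq)
                    uid_counter[0] += 1
                    inserts.append(ins)
                    indel_log.append(
                        {"taxon_branch": label, "kind": "insertion",
                         "position": anchor, "length": length}
                    )

    branch_counter = [0]

    def walk(node: dendropy.Node, chars: np.ndarray, inserts: list[_Insertion]):
        for child in node.child_nodes():
            c_chars = chars.copy()
            c_inserts = list(inserts)
            branch_counter[0] += 1
            label = (
                child.taxon.label if child.taxon else f"internal_{branch_counter[0]}"
            )
            mutate(c_chars, c_inserts, child.edge.length or 0.0, label)
            if child.is_leaf():
                leaf_chars[child.taxon.label] = c_chars
                leaf_inserts[child.taxon.label] = c_inserts
            else:
                walk(child, c_chars, c_inserts)

    walk(tree.seed_node, layout.sequence.copy(), [])
    return leaf_chars, leaf_inserts, indel_log, n_subs[0]


def _assemble_alignment(
    taxa: Sequence[str],
    leaf_chars: dict[str, np.ndarray],
    leaf_inserts: dict[str, list[_Insertion]],
    root_length: int,
) -> tuple[Msa, np.ndarray]:
    """Build the true alignment and the root-column -> alignment-column map."""
    all_ins: dict[int, _Insertion] = {}
    for ins_list in leaf_inserts.values():
        for ins in ins_list:
            all_ins[ins.uid] = ins
    ordered = sorted(all_ins.values(), key=lambda i: (i.anchor, i.uid))

    rows = []
    for taxon in taxa:
        have = {ins.uid for ins in leaf_inserts[taxon]}
        chars = leaf_chars[taxon]
        parts = []
        prev = 0
        for ins in ordered:
            parts.append(chars[prev : ins.anchor].tobytes().decode("ascii"))
            parts.append(ins.seq if ins.uid in have else "-" * len(ins.seq))
            prev = ins.anchor
        parts.append(chars[prev:].tobytes().decode("ascii"))
        rows.append("".join(parts))

    # column index of each root column in the assembled alignment
    extra = np.zeros(root_length + 1, dtype=np.int64)
    for ins in ordered:
        extra[ins.anchor] += len(ins.seq)
    colmap = np.arange(root_length, dtype=np.int64) + np.cumsum(extra)[:root_length]
    return Msa(list(taxa), rows), colmap


def _naive_pair_counts(msa: Msa) -> np.ndarray:
    """Independent per-column recount of pairwise differences (the oracle)."""
    acgt = set(b"ACGT")
    n = msa.n_taxa
    out = np.zeros((n, n), dtype=np.int64)
    enc = [r.encode("ascii") for r in msa.rows]
    for i in range(n):
        for j in range(i + 1, n):
            c = sum(
                1
                for x, y in zip(enc[i], enc[j])
                if x != y and x in acgt and y in acgt
            )
            out[i, j] = out[j, i] = c
    return out


# --------------------------------------------------------------------------
# Public entry points
# --------------------------------------------------------------------------

def simulate_genomes(
    config: SimulationConfig | None = None,
) -> tuple[list[GenomeRecord], Msa, SimulationTruth]:
    """Generate an annotated plastome set, its true alignment, and the truth.

    Deterministic for a given config (the seed lives in the config).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxa = [f"taxon_{i+1:02d}" for i in range(config.n_taxa)]

    if config.fixed_tree is not None:
        tree = dendropy.Tree.get(data=config.fixed_tree, schema="newick")
        got = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if got != sorted(taxa):
            taxa = got  # honour the user's taxon names
    else:
        tree = _random_tree(taxa, rng, config.divergence_min, config.divergence_max)

    layout = _build_root(config, rng)
    leaf_chars, leaf_inserts, indel_log, n_subs = _evolve_genomes(
        layout, tree, config, rng
    )
    msa, colmap = _assemble_alignment(
        taxa, leaf_chars, leaf_inserts, len(layout.sequence)
    )

    def to_cols(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        cend = int(colmap[e]) if e < len(colmap) else msa.length
        return int(colmap[s]), cend

    gene_regions = {}
    for f in sorted(layout.features, key=lambda f: f.start):
        key = f.name
        if key in gene_regions:  # IR-duplicated copy: keep the first (IRa)
            continue
        gene_regions[key] = to_cols((f.start, f.end))
    spacer_regions = {
        layout.spacer_names[iv]: to_cols(iv)
        for iv in layout.spacers
        if iv in layout.spacer_names
    }
    # marker interiors are spacers too but are named by their marker span
    marker_spans = {m: to_cols(iv) for m, iv in layout.marker_spans_root.items()}
    hot = [layout.spacer_names[iv] for iv in layout.hot_intervals
           if iv in layout.spacer_names]

    truth = SimulationTruth(
        tree=tree,
        newick=tree.as_string(schema="newick").strip(),
        taxa=list(taxa),
        pair_counts=_naive_pair_counts(msa),
        gene_regions=gene_regions,
        spacer_regions=spacer_regions,
        hot_spacers=hot,
        marker_spans=marker_spans,
        primer_sites=layout.primer_sites,
        planted_indels=indel_log,
        n_substitutions=n_subs,
        seed=config.seed,
    )

    # leaf GenomeRecords: degapped sequences with projected annotations
    records = []
    cmap = msa.coordinate_map()
    for taxon in taxa:
        row = msa.row(taxon)
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        nongap = arr != _GAP
        pos = np.cumsum(nongap) - 1
        feats = []
        for f in sorted(layout.features, key=lambda f: (f.start, f.end)):
            cs, ce = to_cols((f.start, f.end))
            feats.append(
                Feature(
                    name=f.name, kind=f.kind,
                    start=int(pos[cs]) if nongap[cs] else int(pos[cs]) + 1,
                    end=int(pos[ce - 1]) + 1,
                    strand=f.strand, intron_count=f.intron_count,
                )
            )
        part_ivs = {}
        for pname, iv in layout.partition.intervals().items():
            cs, ce = to_cols(iv)
            part_ivs[pname] = (
                int(pos[cs]) if nongap[cs] else int(pos[cs]) + 1,
                int(pos[ce - 1]) + 1,
            )
        records.append(
            GenomeRecord(
                taxon_label=taxon,
                sequence=row.replace("-", ""),
                circular=True,
                features=feats,
                partition=QuadripartitePartition(
                    lsc=part_ivs["lsc"], ira=part_ivs["ira"],
                    ssc=part_ivs["ssc"], irb=part_ivs["irb"],
                    ir_length=config.ir_length,
                ),
            )
        )
    return records, msa, truth


@dataclass
class MarkerTruth:
    """Truth restricted to one marker locus."""

    marker: str
    taxa: list[str]
    pair_counts: np.ndarray
    lengths: dict[str, int]
    indels_in_span: list[dict]
    tree_newick: str


def simulate_marker_set(
    config: SimulationConfig | None = None,
    marker_name: str = "trnH-psbA",
    _presimulated: tuple | None = None,
) -> tuple[dict[str, str], MarkerTruth]:
    """True per-taxon marker sequences plus the planted truth for the span.

    Plastome markers are cut from the whole-genome simulation at the planted
    primer coordinates; nuclear markers (e.g. ITS) are simulated as an
    independent unlinked locus on its *own* random tree — emulating the
    nuclear/plastid discordance that makes combined barcodes interesting.
    """
    config = config or SimulationConfig()
    config.validate()
    plastome_names = {m.name for m in config.markers}
    if marker_name in plastome_names:
        if _presimulated is not None:
            records, msa, truth = _presimulated
        else:
            records, msa, truth = simulate_genomes(config)
        span = truth.marker_spans[marker_name]
        sub = msa.slice_columns(*span)
        seqs = {t: sub.degapped(t) for t in truth.taxa}
        indels = [
            d for d in truth.planted_indels
            if span[0] <= d["position"] < span[1]
        ]
        return seqs, MarkerTruth(
            marker=marker_name,
            taxa=truth.taxa,
            pair_counts=_naive_pair_counts(sub),
            lengths={t: len(s) for t, s in seqs.items()},
            indels_in_span=indels,
            tree_newick=truth.newick,
        )
    if marker_name in config.nuclear_markers:
        import zlib

        rng = np.random.default_rng(
            (config.seed, zlib.crc32(marker_name.encode()) % (2**31))
        )
        taxa = [f"taxon_{i+1:02d}" for i in range(config.n_taxa)]
        tree = _random_tree(taxa, rng, config.nuclear_divergence / 3,
                            config.nuclear_divergence)
        L = config.nuclear_markers[marker_name]
        root = rng.choice(_BASES, size=L)
        leaf_seqs: dict[str, np.ndarray] = {}

        def walk(node, chars):
            for child in node.child_nodes():
                c = chars.copy()
                p = min((child.edge.length or 0.0), 0.999)
                hit = np.nonzero(rng.random(L) < p)[0]
                if hit.size:
                    shift = rng.integers(1, 4, size=hit.size)
                    idx = np.searchsorted(_BASES, c[hit])
                    c[hit] = _BASES[(idx + shift) % 4]
                if child.is_leaf():
                    leaf_seqs[child.taxon.label] = c
                else:
                    walk(child, c)

        walk(tree.seed_node, root)
        seqs = {t: leaf_seqs[t].tobytes().decode("ascii") for t in taxa}
        m = Msa(taxa, [seqs[t] for t in taxa])
        return seqs, MarkerTruth(
            marker=marker_name,
            taxa=taxa,
            pair_counts=_naive_pair_counts(m),
            lengths={t: L for t in taxa},
            indels_in_span=[],
            tree_newick=tree.as_string(schema="newick").strip(),
        )
    raise KeyError(
        f"unknown marker {marker_name!r}; defined: "
        f"{sorted(plastome_names | set(config.nuclear_markers))}"
    )
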