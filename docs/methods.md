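# Methods

This note documents the conventions, models and numerical choices behind
`superbarcode`, in the order the pipeline applies them. Every convention
that drives a reported number is stated here, because at 0.1–0.6% pairwise
divergence the definitions matter as much as the arithmetic.

## Coordinates and sequence normalization

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
intervals are converted on ingest. Sequences are upper-cased, and IUPAC
ambiguity codes other than N are normalized to N with a logged warning —
deposited plastome assemblies are effectively unambiguous, and keeping a
two-symbol ambiguity model (N or not) makes every downstream count
definition crisp. Features with a second full-length copy of the same name
(the IR duplicates) are counted once in "unique" gene tallies; a gene only
counts as duplicated when a complete second copy exists, so a gene merely
straddling an IR boundary is not a duplicate.

## Inverted-repeat detection

The quadripartite partition is found from sequence alone: the maximal-length
pair of disjoint intervals whose sequences are exact reverse complements,
located by k-mer seeding (k = 25, every position of the first copy indexed,
queries strided at min_len/4 so any repeat of at least `min_len` — default
10 kb — is guaranteed a seed) followed by maximal outward extension. Ties on
length are broken by the smallest start coordinate. Circular records are
searched on the doubled sequence, so a repeat straddling the origin is found
and the partition is rotation-invariant up to interval shifts. The longer of
the two inter-repeat gaps is reported as the LSC, the shorter as the SSC;
the repeat copy following the LSC is IRa. No repeat of the requested length
is a signal ("no IR found" / `None`), not an exception, because a linear
fragment or a degraded assembly is a legitimate input.

## Column classification and region statistics

Given a whole-genome alignment (an external input — genome-scale MSA is a
solved problem and deliberately out of scope here):

* a column is **variable** when at least two distinct residues among
  {A,C,G,T} occur in it; N never creates variability on its own, and a
  column that also contains gaps still counts as variable (its gaps are
  accounted separately). This precedence makes variable-site counts,
  indel-event counts and identity percentages simultaneously well-defined.
* an **indel event** is a maximal run of consecutive columns sharing one
  identical, non-empty gap pattern (the same subset of rows gapped).
  Adjacent runs with different patterns are distinct events. This
  event-based definition (rather than counting gap columns) matches how
  plastome comparisons tabulate "indels" per region.
* an **identical site** requires every row to carry the same unambiguous
  residue; any gap or N disqualifies the column. Percent identical sites
  (PID) is identical columns over region columns, rounded to one decimal.

Pairwise difference counts require both rows unambiguous (A/C/G/T) and
different; gap/N columns are excluded. Percentages default to the full
alignment length as denominator — this reproduces the scale of published
whole-plastome tables (181 differences over a ~152 kb alignment ≈ 0.12%) —
with the pairwise-ungapped denominator available as a logged, switchable
mode. Counts print as integers; percentages to two decimals.

Regions are ranked most-divergent-first by ascending PID, ties broken by
more variable sites, then name. Genome-wide statistics use a single IR copy
(IRa, the first encountered) to avoid double-weighting the repeat.

## Marker-scale alignment

`align_small` is a deterministic progressive aligner for amplicon- and
gene-scale inputs (≤ 10 kb): optimal pairwise global alignment with affine
gap costs (Gotoh/Needleman–Wunsch, via Biopython's PairwiseAligner) merged
center-star style — the center is the sequence with the highest total k-mer
similarity, remaining sequences join in decreasing similarity order, and
existing gap columns are preserved (once a gap, always a gap). Insertions
relative to the center anchored at the same center position share a column.
For two sequences this *is* the optimal pairwise alignment, which the test
suite verifies against an independent brute-force three-state DP oracle.
Default scores: match +1, mismatch −2, gap open −5, gap extend −1, a gap of
length ℓ costing open + (ℓ−1)·extend; all overridable. At sub-percent
divergence with short isolated indels, a star guide order is equivalent in
practice to a full guide tree and keeps the procedure simple and exactly
reproducible.

## In-silico PCR

Primer sites are located under IUPAC-aware base compatibility: a primer
code matches a template base when their 4-bit nucleotide masks intersect, so
degeneracy in the primer is free and N in the template matches anything. Up
to `max_mismatches` (default 3) are tolerated per primer, except in the
three 3′-terminal positions, which must be compatible exactly — polymerase
extension starts there. Products are reported for the forward primer on
either strand with the reverse primer opposite and downstream within
`max_product` (default 5 kb), de-duplicated modulo rotation on circular
templates (the template is extended across the origin by one maximal product
length). Amplicon lengths are primer-inclusive — the product runs from the
first forward-primer base to the last reverse-primer base — which is the
convention under which typical published trnH-psbA product sizes
(~0.5 kb) are reproduced. The shipped primer table contains the four
classic barcode pairs; two of the eight sequences (trnHf_05, psbA3_f) come
from the primer literature rather than this pipeline's own sources and are
marked as externally sourced in the file; all are user-overridable.

## Marker discrimination

One amplicon per taxon is multiple-aligned with `align_small`; pairwise SNP
counts then follow the whole-genome difference-count semantics on the marker
alignment. A species pair is *unresolved* by a marker when its count is
zero. Combining markers sums the SNP matrices elementwise, so a pair stays
unresolved only if every marker leaves it unresolved. Taxa that fail to
amplify are excluded from the matrix and reported, not silently dropped.

## Trees

Neighbor joining runs on unrounded p-distances (counts over denominator).
Ties in the Q criterion are broken by the lowest taxon-index pair; negative
branch-length estimates are clamped to zero. Bootstrap support resamples
alignment columns with replacement (implemented as multinomial column
weights — identical in distribution, much faster at genome scale), rebuilds
the difference matrix and NJ tree per replicate, and scores each internal
edge of the full-data tree by the percentage of replicates containing the
same bipartition. A single seeded generator drives the whole run; a fixed
seed yields bit-identical Newick output. Supports are written as internal
node labels with branch lengths to six significant digits. Collapsing
contracts internal edges whose support is below the threshold into
polytomies; threshold 0 is the identity, above 100 gives the star tree.

Distance trees replace likelihood inference deliberately: the package's
claim surface is species delimitation and clade recovery on near-identical
genomes, where p-distances are effectively additive and NJ recovers the
generating topology (verified against planted truth); published ML
bootstrap percentages are therefore not comparable numerically and only
clade membership is ever asserted.

## The simulator

`simulate_genomes` emulates the study regime every stage is tested against:
nine taxa on a random bifurcating tree (or a user-fixed Newick), 152 kb
circular genomes with 25 kb IRs and an 18 kb SSC, annotated protein-coding /
tRNA / rRNA genes (the rRNA operon and a few genes duplicated in the IR),
intergenic spacers, and the barcode markers planted as real primer-site
sequences flanking spacer interiors.

* **Branch lengths** are expected substitutions per site averaged over the
  genome: per-site rates (1 for genes, ×3 for spacers by default, ×k for a
  designated hot spacer, 0 for primer sites) are normalized by their mean,
  so pairwise path lengths land in the configured divergence window
  (default 0.1–0.6%, the congeneric-plastome regime). Branch lengths are
  scaled so the maximum pairwise distance hits the window's top; terminal
  edges are lengthened if the minimum falls short.
* **Substitutions** are uniform over the three alternative bases (JC-like).
  At sub-percent divergence the substitution model is immaterial to count
  statistics, and the uniform model keeps truth bookkeeping exact.
* **IR mirroring**: mutations landing in IRa are applied as complements at
  the mirrored IRb position, so revcomp(IRa) == IRb holds bit-exactly at
  every leaf — the same invariant the IR detector relies on.
* **Indels** occur as Poisson events per branch, geometric lengths (mean 6),
  confined to single-copy intergenic spacers (never genes, never the IR,
  never primer sites; deletions are clipped at spacer boundaries). Inserted
  segments are inert once created — they do not mutate further along
  descendant branches. At the simulated rates (a few dozen events per
  study) this simplification is invisible to the statistics, and it keeps
  the emitted alignment exact by construction.
* **Truth**: the alignment is assembled from the tracked coordinate system,
  so it is the true alignment, not an estimate. The truth difference matrix
  is recomputed from the final rows by an independent naive per-column
  recount, which makes "computed matrix equals truth exactly" a meaningful
  two-route check rather than a tautology.

Nuclear loci (ITS by default, 700 bp at ~1% divergence) are simulated as
unlinked loci on their *own* random tree, emulating the nuclear/plastid
discordance that motivates combining markers.

What the generator does **not** emulate: sequencing/assembly error,
annotation error, structural rearrangements (inversions), heteroplasmy,
rate heterogeneity within a category, and indel evolution inside coding
sequence (available behind a flag but off by default, mirroring the
observation that congeneric plastome genes are near-identical). Passing
tests on simulated data therefore validate the *computational* pipeline —
counting, ranking, amplifying, tree building — not robustness to upstream
data-quality problems.

## Problem sizes and tolerances in the test suite

The deep end-to-end checks run one full-size study (9 taxa × 152 kb,
200 bootstrap replicates); repeated-seed checks (e.g. the hot-spacer ranking
over 20 seeds) use 40 kb genomes with proportionally scaled IR/SSC, which
preserves every per-region property while keeping the whole suite fast.
Exact equality is asserted wherever the design guarantees it (truth matrix,
planted coordinates, reproducibility); the only stochastic tolerance is on
bootstrap percentages, where the single-informative-column support test
brackets the analytic resampling probability 1−(1−1/L)^L ≈ 63.2%.

## Known limitations

* The IR detector assumes exact repeats; assemblies whose IR copies differ
  by even one base will report the longest exact sub-repeat instead.
* `align_small` is for marker-scale inputs; it refuses sequences over
  10 kb rather than degrade.
* Region statistics are computed on alignment columns, so region "length"
  is alignment length (with gaps), not any one genome's ungapped length.
* Origin-spanning annotation is supported on ingest, but intergenic-region
  enumeration skips origin-spanning features themselves.
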