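import numpy as np
import pytest

from superbarcode import (
    Feature,
    FeatureKind,
    GenomeRecord,
    MarkerReport,
    Primer,
    combine_markers,
    default_primers,
    in_silico_pcr,
    list_intergenic_regions,
    marker_snp_matrix,
)
from superbarcode._seq import revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _template_with_sites(rng, fwd, rev, before=300, interior=200, after=300):
    """Template with planted primer sites; returns (sequence, fwd_start, rev_end)."""
    left = _rand_seq(rng, before)
    mid = _rand_seq(rng, interior)
    right = _rand_seq(rng, after)
    seq = left + fwd + mid + revcomp(rev) + right
    return seq, before, before + len(fwd) + interior + len(rev)


class TestPrimer:
    def test_degenerate_codes_accepted(self):
        p = Primer("rbcLa-R", "GTAAAATCAAGTCCACCRCG", "reverse")
        assert p.sequence.endswith("RCG")

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            Primer("bad", "ACGTX")


class TestInSilicoPcr:
    def test_planted_sites_recovered_exactly(self):
        rng = np.random.default_rng(0)
        fwd = Primer("f", "ATGTCACCACAAACAGAGACTAAAGC")
        rev = Primer("r", "GTAAAATCAAGTCCACCACG", "reverse")
        seq, start, end = _template_with_sites(rng, fwd.sequence, rev.sequence)
        rec = GenomeRecord("t", seq, circular=False)
        amps = in_silico_pcr(rec, fwd, rev, max_mismatches=0)
        assert len(amps) == 1
        assert (amps[0].start, amps[0].end) == (start, end)
        assert amps[0].sequence == seq[start:end]
        assert amps[0].fwd_mismatches == amps[0].rev_mismatches == 0

    def test_iupac_degeneracy_matches_compatible_base(self):
        # R in the primer must match an A on the template
        rng = np.random.default_rng(1)
        fwd = Primer("f", "ATGTCACCACAAACAGAGACTAAAGC")
        rev = Primer("r", "GTAAAATCAAGTCCACCRCG", "reverse")
        site = "GTAAAATCAAGTCCACCACG"  # A at the R position
        seq, start, end = _template_with_sites(rng, fwd.sequence, site)
        amps = in_silico_pcr(GenomeRecord("t", seq, circular=False), fwd, rev,
                             max_mismatches=0)
        assert len(amps) == 1 and (amps[0].start, amps[0].end) == (start, end)

    def test_origin_spanning_product_found(self):
        rng = np.random.default_rng(2)
        fwd = Primer("f", "ACCGTTAGGCATTCAGGAAC")
        rev = Primer("r", "TTGGACCAGATTCGGAACCT", "reverse")
        seq, start, end = _template_with_sites(rng, fwd.sequence, rev.sequence,
                                               before=2_000, interior=150, after=2_000)
        # rotate so the product crosses the origin
        cut = start + 80
        rotated = seq[cut:] + seq[:cut]
        rec = GenomeRecord("t", rotated, circular=True)
        amps = in_silico_pcr(rec, fwd, rev)
        assert len(amps) == 1
        a = amps[0]
        assert a.length_bp == end - start
        assert a.sequence == seq[start:end]
        assert a.start == len(seq) - 80  # forward site sits before the origin

    def test_three_prime_clamp_blocks_terminal_mismatch(self):
        rng = np.random.default_rng(3)
        fwd = Primer("f", "ACCGTTAGGCATTCAGGAAC")
        rev = Primer("r", "TTGGACCAGATTCGGAACCT", "reverse")
        seq, start, end = _template_with_sites(rng, fwd.sequence, rev.sequence)
        # mutate the template base under the forward primer's 3'-terminal base
        pos = start + len(fwd.sequence) - 1
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1:]
        amps = in_silico_pcr(GenomeRecord("t", mutated, circular=False), fwd, rev,
                             max_mismatches=3)
        assert amps == []

    def test_interior_mismatches_tolerated_and_counted(self):
        rng = np.random.default_rng(4)
        fwd = Primer("f", "ACCGTTAGGCATTCAGGAAC")
        rev = Primer("r", "TTGGACCAGATTCGGAACCT", "reverse")
        seq, start, end = _template_with_sites(rng, fwd.sequence, rev.sequence)
        pos = start + 5
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1:]
        amps = in_silico_pcr(GenomeRecord("t", mutated, circular=False), fwd, rev,
                             max_mismatches=3)
        assert len(amps) == 1 and amps[0].fwd_mismatches == 1

    def test_no_site_returns_empty_list(self):
        rng = np.random.default_rng(5)
        rec = GenomeRecord("t", _rand_seq(rng, 2_000), circular=False)
        fwd = Primer("f", "ACCGTTAGGCATTCAGGAAC")
        rev = Primer("r", "TTGGACCAGATTCGGAACCT", "reverse")
        assert in_silico_pcr(rec, fwd, rev) == []

    def test_idempotent_on_own_amplicon(self):
        rng = np.random.default_rng(6)
        fwd = Primer("f", "ACCGTTAGGCATTCAGGAAC")
        rev = Primer("r", "TTGGACCAGATTCGGAACCT", "reverse")
        seq, start, end = _template_with_sites(rng, fwd.sequence, rev.sequence)
        amp = in_silico_pcr(GenomeRecord("t", seq, circular=False), fwd, rev)[0]
        again = in_silico_pcr(
            GenomeRecord("t", amp.sequence, circular=False), fwd, rev
        )
        assert len(again) == 1
        assert again[0].sequence == amp.sequence


class TestIntergenicRegions:
    def _record(self, rng, feats, length=2_000, circular=True):
        return GenomeRecord("t", _rand_seq(rng, length), circular=circular,
                            features=feats)

    def test_three_planted_genes_circular(self):
        rng = np.random.default_rng(7)
        feats = [
            Feature("a", FeatureKind.protein_coding, 100, 300),
            Feature("b", FeatureKind.protein_coding, 500, 800),
            Feature("c", FeatureKind.protein_coding, 1_200, 1_500),
        ]
        regions = list_intergenic_regions(self._record(rng, feats))
        assert regions == {
            "a → b": (300, 500),
            "b → c": (800, 1_200),
            "c → a": (1_500, 100),
        }

    def test_linear_record_has_no_wrap_region(self):
        rng = np.random.default_rng(8)
        feats = [
            Feature("a", FeatureKind.protein_coding, 100, 300),
            Feature("b", FeatureKind.protein_coding, 500, 800),
        ]
        regions = list_intergenic_regions(self._record(rng, feats, circular=False))
        assert list(regions) == ["a → b"]

    def test_abutting_genes_emit_nothing(self):
        rng = np.random.default_rng(9)
        feats = [
            Feature("a", FeatureKind.protein_coding, 100, 300),
            Feature("b", FeatureKind.protein_coding, 300, 600),
        ]
        regions = list_intergenic_regions(self._record(rng, feats, circular=False))
        assert regions == {}


class TestMarkerSnpMatrix:
    def _amplicons(self, seqs):
        from superbarcode import Amplicon

        return {
            t: Amplicon(taxon=t, marker_name="m", start=0, end=len(s),
                        sequence=s, fwd_mismatches=0, rev_mismatches=0)
            for t, s in seqs.items()
        }

    def test_identical_amplicons_leave_all_pairs_unresolved(self):
        amps = self._amplicons({t: "ACGTACGTACGT" * 5 for t in "abcd"})
        rep = marker_snp_matrix(amps)
        assert not rep.pairwise_snps.any()
        assert len(rep.unresolved_pairs) == 6

    def test_planted_substitutions_counted_exactly(self):
        rng = np.random.default_rng(10)
        base = _rand_seq(rng, 400)
        mutated = list(base)
        for pos in (50, 120, 200, 310):
            mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
        rep = marker_snp_matrix(self._amplicons({"a": base, "b": "".join(mutated)}))
        assert rep.snps("a", "b") == 4

    def test_amplification_failure_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(11)
        base = _rand_seq(rng, 300)
        amps = self._amplicons({"a": base, "b": base})
        amps["c"] = None
        rep = marker_snp_matrix(amps)
        assert rep.failed_taxa == ["c"]
        assert set(rep.taxa) == {"a", "b"}


class TestCombineMarkers:
    def _report(self, taxa, mat, name="m"):
        return MarkerReport(marker_names=[name], taxa=list(taxa),
                            pairwise_snps=np.array(mat))

    def test_complementary_markers_resolve_everything(self):
        m1 = self._report("abc", [[0, 3, 0], [3, 0, 0], [0, 0, 0]], "m1")
        m2 = self._report("abc", [[0, 0, 2], [0, 0, 5], [2, 5, 0]], "m2")
        combined = combine_markers([m1, m2])
        assert combined.unresolved_pairs == set()
        assert combined.snps("a", "b") == 3

    def test_all_zero_twin_changes_nothing(self):
        m1 = self._report("abc", [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        zero = self._report("abc", np.zeros((3, 3), dtype=int), "z")
        combined = combine_markers([m1, zero])
        assert np.array_equal(combined.pairwise_snps, m1.pairwise_snps)
        assert combined.unresolved_pairs == m1.unresolved_pairs

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(12)
        mats = []
        for _ in range(3):
            m = np.triu(rng.integers(0, 4, size=(4, 4)), 1)
            mats.append(m + m.T)
        reps = [self._report("abcd", m, f"m{i}") for i, m in enumerate(mats)]
        ab = combine_markers([reps[0], reps[1]])
        ba = combine_markers([reps[1], reps[0]])
        assert np.array_equal(ab.pairwise_snps, ba.pairwise_snps)
        abc1 = combine_markers([combine_markers([reps[0], reps[1]]), reps[2]])
        abc2 = combine_markers([reps[0], combine_markers([reps[1], reps[2]])])
        assert np.array_equal(abc1.pairwise_snps, abc2.pairwise_snps)

    def test_mismatched_taxon_sets_rejected(self):
        m1 = self._report("abc", np.zeros((3, 3), dtype=int))
        m2 = self._report("abd", np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="taxon sets"):
            combine_markers([m1, m2])


class TestShippedPrimerTable:
    def test_all_four_markers_present_with_both_orientations(self):
        table = default_primers()
        assert set(table) == {"rbcL", "matK", "trnH-psbA", "ITS"}
        for fwd, rev in table.values():
            assert fwd.orientation == "forward"
            assert rev.orientation == "reverse"

    def test_printed_primer_sequences(self):
        table = default_primers()
        assert table["rbcL"][0].sequence == "ATGTCACCACAAACAGAGACTAAAGC"
        assert table["matK"][0].sequence == "TAATTTACGATCAATTCATTC"
        assert table["ITS"][1].sequence == "TCCTCCGCTTATTGATATGC"
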