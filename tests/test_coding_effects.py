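"""coding_effects: classifier, site counting, corrections, stop census."""

import logging
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from meltdown import coding_effects as ce
from tests._oracles import oracle_codon_class

ALL_CODONS = ["".join((a, b, c)) for a in ce.BASES for b in ce.BASES for c in ce.BASES]


# ---------------------------------------------------------------------------
# classify_codon_change
# ---------------------------------------------------------------------------


def test_classifier_matches_translation_oracle_all_cases():
    """Exhaustive: 64 codons x 3 offsets x 3 alts x 2 strands vs Biopython
    translation oracle."""
    n = 0
    for codon in ALL_CODONS:
        for off in range(3):
            for strand in "+-":
                ref_tx = codon[off]
                for alt in ce.BASES:
                    alt_tx = ce.complement(alt) if strand == "-" else alt
                    if alt_tx == ref_tx:
                        continue
                    got = ce.classify_codon_change(codon, off, alt, strand)
                    assert got == oracle_codon_class(codon, off, alt, strand), (
                        codon, off, alt, strand,
                    )
                    n += 1
    assert n == 64 * 3 * 3 * 2  # 1152 informative cases


def test_classifier_worked_examples():
    # TGG (Trp) -> TAG at offset 1 is a premature stop
    assert ce.classify_codon_change("TGG", 1, "A") == "nonsense"
    # third-position wobble of a fourfold codon is synonymous
    assert ce.classify_codon_change("CTT", 2, "G") == "synonymous"
    # TAA -> TAG is a stop-to-stop exchange, i.e. synonymous
    assert ce.classify_codon_change("TAA", 2, "G") == "synonymous"
    # stop loss: TAA -> CAA (Gln)
    assert ce.classify_codon_change("TAA", 0, "C") == "stop_loss"
    # minus strand: genomic alt T complements to transcript A
    assert ce.classify_codon_change("TGG", 1, "T", strand="-") == "nonsense"


def test_classifier_error_contracts():
    with pytest.raises(ValueError):
        ce.classify_codon_change("ATG", 3, "C")
    with pytest.raises(ValueError):
        ce.classify_codon_change("ATG", 0, "A")  # alt equals ref
    assert ce.classify_codon_change("ANG", 1, "C") == "unknown"
    assert ce.classify_codon_change("ATG", 0, "N") == "unknown"


def test_damage_pair_truth_table():
    assert ce.is_damage_pair("C", "T")
    assert ce.is_damage_pair("T", "C")
    assert ce.is_damage_pair("G", "A")
    assert ce.is_damage_pair("a", "g")  # case-insensitive
    assert not ce.is_damage_pair("A", "C")
    assert not ce.is_damage_pair("A", "T")
    assert not ce.is_damage_pair("G", "C")
    assert not ce.is_damage_pair("G", "T")


# ---------------------------------------------------------------------------
# GeneModel coordinate maps
# ---------------------------------------------------------------------------


@st.composite
def gene_models(draw):
    k = draw(st.integers(1, 5))
    cursor = draw(st.integers(0, 50))
    exons = []
    for _ in range(k):
        ln = draw(st.integers(1, 30))
        exons.append((cursor, cursor + ln))
        cursor += ln + draw(st.integers(1, 20))
    strand = draw(st.sampled_from("+-"))
    return ce.GeneModel("g", "c", strand, tuple(exons))


@given(gene_models(), st.data())
def test_cds_coordinate_round_trip(g, data):
    off = data.draw(st.integers(0, g.cds_length - 1))
    pos = g.cds_to_genomic(off)
    assert g.genomic_to_cds(pos) == off


@given(gene_models())
def test_transcript_orientation(g):
    """CDS offset 0 maps to the 5'-most genomic base of translation."""
    first = g.cds_to_genomic(0)
    last = g.cds_to_genomic(g.cds_length - 1)
    if g.strand == "+":
        assert first == g.cds[0][0] and last == g.cds[-1][1] - 1
    else:
        assert first == g.cds[-1][1] - 1 and last == g.cds[0][0]


def test_genomic_to_cds_intron_is_none():
    g = ce.GeneModel("g", "c", "+", ((0, 10), (20, 30)))
    assert g.genomic_to_cds(15) is None
    assert g.genomic_to_cds(9) == 9
    assert g.genomic_to_cds(20) == 10


def test_junction_offsets_both_strands():
    g = ce.GeneModel("g", "c", "+", ((0, 10), (20, 35), (50, 70)))
    assert g.junction_offsets() == [10, 25]
    gm = ce.GeneModel("g", "c", "-", ((0, 10), (20, 35), (50, 70)))
    # minus strand: first exon in transcript order is the genomic last (20 bp)
    assert gm.junction_offsets() == [20, 35]


def test_gene_model_rejects_overlapping_exons():
    with pytest.raises(ValueError):
        ce.GeneModel("g", "c", "+", ((0, 10), (5, 20)))
    with pytest.raises(ValueError):
        ce.GeneModel("g", "c", "x", ((0, 10),))


def test_minus_strand_cds_seq():
    genome = {"c": "AAACATTTT"}  # revcomp of genomic CAT at 3..6 is ATG
    g = ce.GeneModel("g", "c", "-", ((3, 6),))
    assert g.cds_seq(genome) == "ATG"


# ---------------------------------------------------------------------------
# annotate_variants / collapse_by_severity
# ---------------------------------------------------------------------------


def _toy_gene_and_genome():
    # plus-strand single exon gene: ATG TGG CTT TAA
    genome = {"c": "TT" + "ATGTGGCTTTAA" + "TT"}
    g = ce.GeneModel("gene1", "c", "+", ((2, 14),))
    return genome, [g]


def test_annotate_variants_classes_and_noncoding():
    genome, genes = _toy_gene_and_genome()
    snps = [
        ce.SnpRecord("c", 6, "G", "A", "het"),   # TGG->TAG nonsense
        ce.SnpRecord("c", 10, "T", "G", "hom"),  # CTT->CTG synonymous
        ce.SnpRecord("c", 0, "T", "A", "het"),   # intergenic
    ]
    eff = ce.annotate_variants(snps, genes, genome)
    by_pos = {e.pos: e for e in eff}
    assert by_pos[6].effect_class == "nonsense" and by_pos[6].gene_id == "gene1"
    assert by_pos[6].codon_index == 1
    assert by_pos[6].damage_flag  # G/A pair
    assert by_pos[10].effect_class == "synonymous"
    assert by_pos[0].effect_class == "noncoding" and by_pos[0].gene_id is None


def test_annotate_variants_rejects_ref_mismatch(caplog):
    genome, genes = _toy_gene_and_genome()
    with caplog.at_level(logging.WARNING):
        eff = ce.annotate_variants([ce.SnpRecord("c", 6, "C", "A", "het")], genes, genome)
    assert eff == []
    assert "REF mismatch" in caplog.text


def test_annotate_variants_one_record_per_transcript():
    genome, genes = _toy_gene_and_genome()
    g2 = ce.GeneModel("gene2", "c", "+", ((2, 14),))
    eff = ce.annotate_variants(
        [ce.SnpRecord("c", 6, "G", "A", "het")], genes + [g2], genome
    )
    assert len(eff) == 2
    assert {e.gene_id for e in eff} == {"gene1", "gene2"}
    assert len(ce.collapse_by_severity(eff)) == 1


def test_collapse_keeps_most_severe():
    mk = lambda cls, gid: ce.VariantEffect("c", 5, "A", "C", "het", gid, 0, cls, False)
    out = ce.collapse_by_severity([mk("synonymous", "a"), mk("nonsense", "b")])
    assert len(out) == 1 and out[0].effect_class == "nonsense"


# ---------------------------------------------------------------------------
# NG86 site counting
# ---------------------------------------------------------------------------


def test_codon_site_fractions_examples():
    # Phe TTT: only T->C at position 3 is synonymous -> 1/3 syn sites
    syn, nonsyn = ce.codon_site_fractions("TTT")
    assert math.isclose(syn, 1 / 3) and math.isclose(nonsyn, 8 / 3)
    # Met ATG: no synonymous change exists
    syn, nonsyn = ce.codon_site_fractions("ATG")
    assert syn == 0.0 and nonsyn == 3.0
    # fourfold-degenerate third position: GGG (Gly) -> 3 syn changes at pos 3,
    # plus GGG->AGG(Arg)... none at pos 1/2 are synonymous -> exactly 1.0
    syn, _ = ce.codon_site_fractions("GGG")
    assert math.isclose(syn, 1.0)


def test_site_fractions_sum_to_three_for_all_codons():
    for codon in ALL_CODONS:
        syn, nonsyn = ce.codon_site_fractions(codon)
        assert math.isclose(syn + nonsyn, 3.0)
        assert 0.0 <= syn <= 3.0


def test_count_sites_excludes_terminal_stop_and_skips_internal_stops(caplog):
    genome = {"c": "ATGTTTTAA" + "ATGTAATTTTAA"}
    good = ce.GeneModel("good", "c", "+", ((0, 9),))
    bad = ce.GeneModel("bad", "c", "+", ((9, 21),))  # internal TAA
    with caplog.at_level(logging.WARNING):
        l_syn, l_nonsyn = ce.count_syn_nonsyn_sites([good, bad], genome)
    # only ATG + TTT counted: syn = 0 + 1/3, nonsyn = 3 + 8/3
    assert math.isclose(l_syn, 1 / 3)
    assert math.isclose(l_nonsyn, 3 + 8 / 3)
    assert "internal stop" in caplog.text


# ---------------------------------------------------------------------------
# Corrections and H summaries
# ---------------------------------------------------------------------------


def test_correct_het_undercall_worked_examples():
    # 30% het FNR: observed 350 het + 150 hom -> 150 + 350/0.7 = 650
    assert math.isclose(ce.correct_het_undercall(350, 150, 0.30), 650.0)
    # 0.5% FNR on 1000 het calls
    assert math.isclose(ce.correct_het_undercall(1000, 0, 0.005), 1000 / 0.995)
    # zero rate is the identity
    assert ce.correct_het_undercall(7, 3, 0.0) == 10.0


def test_correct_het_undercall_error_contracts():
    with pytest.raises(ValueError):
        ce.correct_het_undercall(1, 1, 1.0)
    with pytest.raises(ValueError):
        ce.correct_het_undercall(-1, 0, 0.1)


@given(
    st.floats(0, 1e4), st.floats(0, 1e4),
    st.floats(0, 0.99, exclude_max=False),
)
def test_correction_monotone_and_bounded(het, hom, fnr):
    out = ce.correct_het_undercall(het, hom, fnr)
    assert out >= het + hom - 1e-9  # never decreases the count


def _mk_effect(pos, cls, genotype="het", damage=False):
    return ce.VariantEffect("c", pos, "A", "C", genotype, "g", 0, cls, damage)


def test_heterozygosity_summary_arithmetic():
    effects = [_mk_effect(i, "synonymous") for i in range(13)] + [
        _mk_effect(100 + i, "nonsynonymous") for i in range(4)
    ]
    s = ce.heterozygosity_summary(effects, l_syn=10_000.0, l_nonsyn=30_000.0)
    assert math.isclose(s["syn"].H, 13 / 10_000)
    assert math.isclose(s["nonsyn"].H, 4 / 30_000)
    expected_sigma = (s["syn"].H * (1 - s["syn"].H) / 10_000) ** 0.5
    assert math.isclose(s["syn"].sigma, expected_sigma)
    assert math.isclose(ce.hn_hs_ratio(s), (4 / 30_000) / (13 / 10_000))


def test_heterozygosity_summary_filters():
    effects = [
        _mk_effect(1, "synonymous"),
        _mk_effect(2, "synonymous", genotype="hom"),  # hom: not heterozygosity
        _mk_effect(3, "synonymous", damage=True),
        _mk_effect(4, "nonsense"),  # tallied separately, not in Hn
    ]
    s = ce.heterozygosity_summary(effects, 100.0, 100.0)
    assert s["syn"].het_count == 2  # damage kept by default
    s2 = ce.heterozygosity_summary(effects, 100.0, 100.0, damage_excluded=True)
    assert s2["syn"].het_count == 1
    assert s2["nonsyn"].het_count == 0
    # het-FNR correction inflates counts by 1/(1-fnr)
    s3 = ce.heterozygosity_summary(effects, 100.0, 100.0, het_fnr=0.30)
    assert math.isclose(s3["syn"].het_count, 2 / 0.7)


def test_hn_hs_ratio_zero_hs_raises():
    s = ce.heterozygosity_summary([_mk_effect(1, "nonsynonymous")], 10.0, 10.0)
    with pytest.raises(ZeroDivisionError):
        ce.hn_hs_ratio(s)


# ---------------------------------------------------------------------------
# Stop-codon census
# ---------------------------------------------------------------------------


def _stop(pos, gid, damage=False):
    return ce.VariantEffect("c", pos, "G", "A", "het", gid, 0, "nonsense", damage)


def test_stop_census_site_vs_gene_sharing():
    a = [_stop(10, "g1"), _stop(50, "g2")]
    b = [_stop(10, "g1"), _stop(60, "g2")]  # g2 hit at a different site
    census = ce.stop_codon_census({"a": a, "b": b})
    assert census.per_sample_counts == {"a": 2, "b": 2}
    assert census.shared_sites == 1
    assert census.shared_genes == 2


def test_stop_census_damage_exclusion():
    a = [_stop(10, "g1", damage=True)]
    b = [_stop(10, "g1", damage=True)]
    census = ce.stop_codon_census({"a": a, "b": b}, damage_excluded=True)
    assert census.per_sample_counts == {"a": 0, "b": 0}
    assert census.shared_sites == 0
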