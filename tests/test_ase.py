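"""ASE statistics: AAF arithmetic, LRT behaviour, BH, balance categories,
consequence annotation with strand awareness."""

import numpy as np
import pytest
from scipy.stats import chi2

from asedit.ase import (
    GroupDesign,
    analyze_sites,
    balance_category,
    bh_adjust,
    classify_ase,
    compute_aaf,
    test_delta_aaf,
    annotate_consequence,
    AseResult,
)
from asedit.intervals import GenomicInterval
from asedit.io_formats import GeneModel, GenomeAnnotation, TranscriptModel, VariantSite
from asedit.simulate import stream


def design4() -> GroupDesign:
    return GroupDesign({"EP1": "EP", "EP2": "EP", "ML1": "ML", "ML2": "ML"})


def site4(counts_ep, counts_ml, pos=101) -> VariantSite:
    counts = {
        "EP1": counts_ep[0], "EP2": counts_ep[1],
        "ML1": counts_ml[0], "ML2": counts_ml[1],
    }
    return VariantSite("c1", pos, "A", "G", counts=counts)


class TestComputeAaf:
    def test_single_sample_fraction(self):
        s = site4([(6, 4), (6, 4)], [(6, 4), (6, 4)])
        per_sample, _, _ = compute_aaf(s, design4())
        assert per_sample["EP1"] == pytest.approx(0.4)

    def test_equal_groups_give_zero_delta(self):
        s = site4([(2, 8), (2, 8)], [(2, 8), (2, 8)])
        _, group, delta = compute_aaf(s, design4())
        assert group["EP"] == pytest.approx(0.8)
        assert delta == pytest.approx(0.0)

    def test_pooled_delta_arithmetic(self):
        # EP pooled 30/100 alt, ML pooled 70/100 -> delta -0.4
        s = site4([(35, 15), (35, 15)], [(15, 35), (15, 35)])
        _, group, delta = compute_aaf(s, design4())
        assert group["EP"] == pytest.approx(0.3)
        assert delta == pytest.approx(-0.4)

    def test_zero_depth_group_untestable(self):
        s = site4([(0, 0), (0, 0)], [(5, 5), (5, 5)])
        _, group, delta = compute_aaf(s, design4())
        assert group["EP"] is None and delta is None
        assert test_delta_aaf(s, design4()) is None


class TestDeltaAafTest:
    def test_identical_counts_give_p_one(self):
        s = site4([(10, 10), (10, 10)], [(10, 10), (10, 10)])
        assert test_delta_aaf(s, design4()) == pytest.approx(1.0)

    def test_maximal_separation_is_overwhelming(self):
        s = site4([(0, 20), (0, 20)], [(20, 0), (20, 0)])
        assert test_delta_aaf(s, design4()) < 1e-10

    def test_group_label_symmetry(self):
        rng = stream(41, "lrt-symmetry")
        for _ in range(50):
            counts = [(int(rng.integers(0, 40)), int(rng.integers(0, 40))) for _ in range(4)]
            s = site4(counts[:2], counts[2:])
            d = design4()
            p = test_delta_aaf(s, d)
            p_swapped = test_delta_aaf(s, d.swapped())
            _, _, delta = compute_aaf(s, d)
            _, _, delta_swapped = compute_aaf(s, d.swapped())
            if p is not None:
                assert p == pytest.approx(p_swapped, abs=1e-12)
            if delta is not None:
                assert delta == pytest.approx(-delta_swapped, abs=1e-12)

    def test_statistic_matches_two_by_two_g_test(self):
        """With group-level parameters the LRT reduces to the 2x2 G-test
        on (group x allele) pooled counts — checked against a direct
        contingency computation."""
        from scipy.stats import chi2_contingency

        rng = stream(42, "lrt-vs-g")
        for _ in range(30):
            table = rng.integers(1, 80, size=(2, 2))
            s = site4(
                [(int(table[0, 0]), int(table[0, 1])), (0, 0)],
                [(int(table[1, 0]), int(table[1, 1])), (0, 0)],
            )
            p = test_delta_aaf(s, design4())
            g, p_ref, _, _ = chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )
            assert p == pytest.approx(p_ref, rel=1e-9)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        # ranked: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = stream(43, "bh-oracle")
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(q_ref, abs=1e-12)

    def test_q_at_least_p(self):
        rng = stream(44, "bh-monotone")
        p = rng.uniform(0, 1, size=200)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestBalanceCategory:
    def test_even_coverage_is_true_heterozygote(self):
        s = site4([(13, 13), (12, 12)], [(13, 13), (12, 12)])
        p, cat = balance_category(s)
        assert p == pytest.approx(1.0)
        assert cat == "true_heterozygote"

    def test_ref_skew_closed_form(self):
        # pooled 90 ref / 10 alt: chi2 = 40^2/50 + 40^2/50 = 64
        s = site4([(45, 5), (45, 5)], [(0, 0), (0, 0)])
        p, cat = balance_category(s)
        assert p == pytest.approx(float(chi2.sf(64.0, 1)))
        assert p < 1e-14
        assert cat == "HeteroRef"

    def test_alt_skew_symmetric(self):
        s = site4([(5, 45), (5, 45)], [(0, 0), (0, 0)])
        p, cat = balance_category(s)
        assert p == pytest.approx(float(chi2.sf(64.0, 1)))
        assert cat == "HeteroAlt"

    def test_direction_agrees_with_exact_binomial(self):
        from scipy.stats import binomtest

        rng = stream(45, "balance-direction")
        for _ in range(60):
            r, a = int(rng.integers(0, 120)), int(rng.integers(0, 120))
            if r + a == 0:
                continue
            s = site4([(r, a), (0, 0)], [(0, 0), (0, 0)])
            _, cat = balance_category(s)
            if cat in ("HeteroRef", "HeteroAlt"):
                # direction contract: the dominant allele matches the side
                # an exact binomial test would report
                assert (cat == "HeteroRef") == (r > a)


class TestClassifyAse:
    def test_small_delta_never_flagged(self):
        s = site4([(5, 45), (5, 45)], [(8, 42), (8, 42)])
        res = AseResult(site=s, delta_aaf=0.05, p_value=1e-9)
        classify_ase([res])
        assert res.q_value == pytest.approx(1e-9)
        assert not res.ase_flag

    def test_rule_conjunction_flags_imbalanced_site(self):
        s = site4([(5, 45), (5, 45)], [(30, 20), (30, 20)])
        res = AseResult(site=s, delta_aaf=0.5, p_value=5e-7)
        classify_ase([res])
        assert res.ase_flag
        assert res.category == "HeteroAlt"

    def test_balanced_pooled_coverage_blocks_flag(self):
        # strong group difference but pooled 1:1 -> chi2 confirmation fails
        s = site4([(10, 40), (10, 40)], [(40, 10), (40, 10)])
        res = AseResult(site=s, delta_aaf=0.6, p_value=1e-12)
        classify_ase([res])
        assert res.balance_p == pytest.approx(1.0)
        assert not res.ase_flag


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

def _coding_construct(strand: str):
    """One gene with CDS 'ATGGCTAGTTGA'-style content on the given strand.

    Plus-strand layout on a 600 bp genome: exon (100, 160), CDS (110, 152)
    with 10 nt UTRs either side inside the exon.
    """
    cds_plus = "ATGGCTAGTTCACTGGAAGTCAGTTACCCGGGTACTGATTAA"  # 42 nt, 14 codons
    rng = stream(46, f"construct-{strand}")
    backbone = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=600)])
    if strand == "+":
        seq = backbone[:110] + cds_plus + backbone[152:]
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        minus_genomic = "".join(comp[b] for b in reversed(cds_plus))
        seq = backbone[:110] + minus_genomic + backbone[152:]
    gene = GeneModel(
        "g1", "cX", strand,
        [TranscriptModel(
            "t1", "protein_coding", strand,
            exons=[GenomicInterval("cX", 100, 160, strand)],
            cds=[GenomicInterval("cX", 110, 152, strand)],
        )],
    )
    return GenomeAnnotation([gene]), {"cX": seq}


class TestAnnotateConsequence:
    def test_synonymous_third_codon_position(self):
        ann, genome = _coding_construct("+")
        # codon 2 is GCT (Ala); its third base T>C gives GCC (Ala)
        pos0 = 110 + 5
        assert genome["cX"][pos0] == "T"
        site = VariantSite("cX", pos0 + 1, "T", "C", counts={})
        assert annotate_consequence(site, ann, genome) == "cds_synonymous"

    def test_missense_second_codon_position(self):
        ann, genome = _coding_construct("+")
        # codon 2 GCT second base C>A gives GAT: Ala -> Asp
        pos0 = 110 + 4
        assert genome["cX"][pos0] == "C"
        site = VariantSite("cX", pos0 + 1, "C", "A", counts={})
        assert annotate_consequence(site, ann, genome) == "cds_missense"

    def test_minus_strand_equals_reverse_complement_construct(self):
        """Annotating the minus-strand gene at the complementary base gives
        the same call as the plus-strand construct."""
        ann_p, genome_p = _coding_construct("+")
        ann_m, genome_m = _coding_construct("-")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for cds_offset, alt_plus in ((5, "C"), (4, "A"), (9, "G"), (12, "T")):
            pos_plus = 110 + cds_offset
            ref_plus = genome_p["cX"][pos_plus]
            if ref_plus == alt_plus:
                continue
            site_p = VariantSite("cX", pos_plus + 1, ref_plus, alt_plus, counts={})
            # same coding base sits mirrored inside the minus-strand CDS
            pos_minus = 110 + (41 - cds_offset)
            site_m = VariantSite(
                "cX", pos_minus + 1,
                comp[ref_plus], comp[alt_plus], counts={},
            )
            assert annotate_consequence(
                site_p, ann_p, genome_p
            ) == annotate_consequence(site_m, ann_m, genome_m)

    def test_utr_upstream_downstream_classes(self):
        ann, genome = _coding_construct("+")
        cases = {
            105: "five_prime_utr",   # exonic, before CDS start
            155: "three_prime_utr",  # exonic, after CDS end
            60: "upstream",          # 40 bp 5' of gene start, within flank
            250: "downstream",
        }
        for pos0, expected in cases.items():
            ref = genome["cX"][pos0]
            alt = "A" if ref != "A" else "C"
            site = VariantSite("cX", pos0 + 1, ref, alt, counts={})
            assert annotate_consequence(site, ann, genome) == expected, pos0

    def test_intron_noncoding_exon_and_flank_cutoff(self):
        from conftest import hand_annotation

        ann = hand_annotation()
        # intron of geneA spans (1200, 1700)
        intronic = VariantSite("chrT", 1401, "A", "G", counts={})
        assert annotate_consequence(intronic, ann, {}) == "intron"
        # exon of a CDS-less transcript
        exonic = VariantSite("chrT", 1101, "A", "G", counts={})
        assert annotate_consequence(exonic, ann, {}) == "noncoding_exon"
        # a tighter flank turns a downstream call into intergenic
        ann_p, genome_p = _coding_construct("+")
        far = VariantSite("cX", 581, genome_p["cX"][580],
                          "A" if genome_p["cX"][580] != "A" else "C", counts={})
        assert annotate_consequence(far, ann_p, genome_p) == "downstream"
        assert annotate_consequence(far, ann_p, genome_p, flank=100) == "intergenic"

    def test_reference_mismatch_raises(self):
        ann, genome = _coding_construct("+")
        pos0 = 115
        wrong = "A" if genome["cX"][pos0] != "A" else "G"
        other = "C" if wrong != "C" else "T"
        site = VariantSite("cX", pos0 + 1, wrong, other, counts={})
        with pytest.raises(ValueError, match="disagrees"):
            annotate_consequence(site, ann, genome)

    def test_planted_localization_classes_recovered(self, sim_small):
        """Generator-designed sites (codon table plants, UTR/intron/flank
        picks) are classified exactly."""
        truth = sim_small.truth.sites
        planted = truth[truth.consequence.notna()]
        assert len(planted) > 20
        by_key = {
            (r.chrom, r.pos): r.consequence for r in planted.itertuples(index=False)
        }
        ann = sim_small.reference.annotation
        genome = sim_small.reference.genome
        for site in sim_small.sites:
            want = by_key.get((site.chrom, site.pos))
            if want is not None:
                assert annotate_consequence(site, ann, genome) == want


def test_analyze_sites_q_never_below_p(sim_small):
    design = sim_small.design
    results = analyze_sites(sim_small.sites[:300], design)
    for r in results:
        if r.p_value is not None:
            assert r.q_value >= r.p_value - 1e-15
            assert 0 <= r.p_value <= 1 and 0 <= r.q_value <= 1


def test_design_validation():
    with pytest.raises(ValueError):
        GroupDesign({"a": "g1"})
    with pytest.raises(ValueError):
        GroupDesign({"a": "g1", "b": "g2", "c": "g3"})
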