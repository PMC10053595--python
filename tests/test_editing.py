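"""RNA-editing branch: strand resolution, the four editing rules, known-site
intersection, and pipeline containment."""

import pytest

from asedit.ase import AseResult, analyze_sites
from asedit.editing import (
    EditingCandidate,
    KnownEditingTable,
    canonical_reading,
    detect_editing,
    editing_filter,
    intersect_known,
    resolve_canonical,
)
from asedit.intervals import GenomicInterval
from asedit.io_formats import GeneModel, GenomeAnnotation, TranscriptModel, VariantSite
from asedit.simulate import stream
from asedit.snv_filter import run_cascade
from asedit.ssr import ssr_mask


def _gene(strand: str, chrom: str = "c1", start: int = 100, end: int = 500):
    return GeneModel(
        f"g{strand}", chrom, strand,
        [TranscriptModel(
            f"t{strand}", "protein_coding", strand,
            [GenomicInterval(chrom, start, end, strand)],
        )],
    )


def _site(pos0, ref, alt, vid=None, counts=None):
    return VariantSite("c1", pos0 + 1, ref, alt, id=vid, counts=counts or {})


class TestResolveCanonical:
    def test_a_to_g_on_plus_gene(self):
        ann = GenomeAnnotation([_gene("+")])
        assert resolve_canonical(_site(200, "A", "G"), ann) == ("A_to_I", "+")

    def test_t_to_c_on_minus_gene_is_a_to_i(self):
        ann = GenomeAnnotation([_gene("-")])
        assert resolve_canonical(_site(200, "T", "C"), ann) == ("A_to_I", "-")

    def test_g_to_a_on_plus_gene_is_not_canonical(self):
        ann = GenomeAnnotation([_gene("+")])
        assert resolve_canonical(_site(200, "G", "A"), ann) is None

    def test_c_to_u_readings(self):
        assert canonical_reading("C", "T", "+") == "C_to_U"
        assert canonical_reading("G", "A", "-") == "C_to_U"
        assert canonical_reading("A", "G", "-") is None

    def test_intergenic_uses_single_canonical_reading(self):
        ann = GenomeAnnotation([_gene("+", start=5000, end=5400)])
        # no overlapping gene: A>G is canonical on + only
        assert resolve_canonical(_site(200, "A", "G"), ann) == ("A_to_I", "+")
        assert resolve_canonical(_site(200, "G", "A"), ann) == ("C_to_U", "-")
        assert resolve_canonical(_site(200, "A", "C"), ann) is None

    def test_strand_complement_involution(self):
        """Complementing ref/alt and flipping strand preserves the type."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                for strand, flipped in (("+", "-"), ("-", "+")):
                    assert canonical_reading(ref, alt, strand) == canonical_reading(
                        comp[ref], comp[alt], flipped
                    )

    def test_overlapping_opposite_strand_genes(self):
        ann = GenomeAnnotation([_gene("+"), _gene("-")])
        # A>G: canonical on + only -> resolved to +; no conflict possible
        assert resolve_canonical(_site(200, "A", "G"), ann) == ("A_to_I", "+")


class TestEditingFilter:
    def _cand(self, counts=None, vid=None, q=1e-4, delta=0.3, pos0=150):
        site = _site(pos0, "A", "G", vid=vid,
                     counts=counts or {"s1": (30, 20), "s2": (35, 15)})
        return EditingCandidate(
            site=site, editing_type="A_to_I", resolved_strand="+",
            delta_aaf=delta, q_value=q,
        )

    SINE = [GenomicInterval("c1", 100, 400)]

    def test_aaf_ceiling_is_strict(self):
        over = self._cand(counts={"s1": (5, 15), "s2": (30, 20)})  # 0.75
        kept, audit = editing_filter([over], self.SINE)
        assert kept == [] and audit[0][1] == ["aaf_ceiling"]
        exactly = self._cand(counts={"s1": (6, 14), "s2": (30, 20)})  # 0.7
        kept, _ = editing_filter([exactly], self.SINE)
        assert len(kept) == 1

    def test_known_snp_id_excluded(self):
        kept, audit = editing_filter([self._cand(vid="rs999")], self.SINE)
        assert kept == [] and audit[0][1] == ["known_snp"]

    def test_sine_overlap_required(self):
        outside = self._cand(pos0=900)
        kept, audit = editing_filter([outside], self.SINE)
        assert kept == [] and audit[0][1] == ["sine_overlap"]
        edge_in = self._cand(pos0=399)
        edge_out = self._cand(pos0=400)
        kept, audit = editing_filter([edge_in, edge_out], self.SINE)
        assert [c.site.pos0 for c in kept] == [399]

    def test_significance_premises(self):
        weak_q = self._cand(q=0.2)
        weak_delta = self._cand(delta=0.05)
        kept, audit = editing_filter([weak_q, weak_delta], self.SINE)
        assert kept == []
        assert all(v == ["significance"] for _, v in audit)

    def test_multiple_violations_all_named(self):
        cand = self._cand(vid="rs1", q=0.5, pos0=900)
        _, audit = editing_filter([cand], self.SINE)
        assert sorted(audit[0][1]) == ["known_snp", "significance", "sine_overlap"]


class TestIntersectKnown:
    def test_exact_match_and_miss(self):
        known = KnownEditingTable()
        known.add("c1", 151, "A_to_I", "brain")
        match = EditingCandidate(_site(150, "A", "G"), "A_to_I", "+")
        miss_pos = EditingCandidate(_site(152, "A", "G"), "A_to_I", "+")
        miss_type = EditingCandidate(_site(150, "C", "T"), "C_to_U", "+")
        out = intersect_known([match, miss_pos, miss_type], known)
        assert out[0].known_site_match == "brain"
        assert out[1].known_site_match is None
        assert out[2].known_site_match is None

    def test_empty_table_gives_no_matches(self):
        cands = [EditingCandidate(_site(1, "A", "G"), "A_to_I", "+")]
        assert intersect_known(cands, KnownEditingTable())[0].known_site_match is None

    def test_duplicate_known_row_rejected(self):
        known = KnownEditingTable()
        known.add("c1", 10, "A_to_I", "brain")
        with pytest.raises(ValueError):
            known.add("c1", 10, "A_to_I", "ovary")

    def test_match_count_equals_nested_loop_join(self):
        rng = stream(51, "known-join")
        for _ in range(30):
            known_rows = {
                (f"c{int(rng.integers(1, 3))}", int(rng.integers(1, 40)),
                 ("A_to_I", "C_to_U")[int(rng.integers(2))])
                for _ in range(20)
            }
            known = KnownEditingTable()
            for chrom, pos, etype in known_rows:
                known.add(chrom, pos, etype, "t")
            cands = []
            for _ in range(25):
                chrom = f"c{int(rng.integers(1, 3))}"
                pos = int(rng.integers(1, 40))
                etype = ("A_to_I", "C_to_U")[int(rng.integers(2))]
                ref, alt = ("A", "G") if etype == "A_to_I" else ("C", "T")
                cands.append(
                    EditingCandidate(
                        VariantSite(chrom, pos, ref, alt, counts={}), etype, "+"
                    )
                )
            out = intersect_known(cands, known)
            n_matched = sum(1 for c in out if c.known_site_match is not None)
            n_oracle = sum(
                1
                for c in cands
                for (kc, kp, kt) in known_rows
                if (c.site.chrom, c.site.pos, c.editing_type) == (kc, kp, kt)
            )
            assert n_matched == n_oracle


class TestPipelineContainment:
    def test_planted_sites_survive_and_decoys_are_audited(self, sim_small):
        ref = sim_small.reference
        survivors, _ = run_cascade(
            sim_small.sites, ref.annotation, ref.paralog_intervals,
            ssr_mask(ref.genome), sim_small.design.n_samples,
        )
        results = analyze_sites(survivors, sim_small.design)
        kept, audit = detect_editing(results, ref.annotation, ref.sine_intervals)
        kept_keys = {(c.site.chrom, c.site.pos) for c in kept}
        assert kept_keys == sim_small.truth.keys_of("editing")
        truth = sim_small.truth.sites
        decoys = truth[truth.klass == "editing_decoy"]
        audit_map = {(c.site.chrom, c.site.pos): v for c, v in audit}
        for row in decoys.itertuples(index=False):
            assert audit_map.get((row.chrom, row.pos)) == [row.decoy_rule]

    def test_editing_output_contained_in_cascade_survivors(self, sim_small):
        ref = sim_small.reference
        survivors, _ = run_cascade(
            sim_small.sites, ref.annotation, ref.paralog_intervals,
            ssr_mask(ref.genome), sim_small.design.n_samples,
        )
        results = analyze_sites(survivors, sim_small.design)
        kept, _ = detect_editing(results, ref.annotation, ref.sine_intervals)
        survivor_keys = {s.key for s in survivors}
        for cand in kept:
            assert cand.site.key in survivor_keys
            # every survivor re-audits clean against all four rules
            aafs = [cand.site.aaf(s) for s in cand.site.counts]
            assert all(a is None or a <= 0.7 for a in aafs)
            assert cand.site.id is None
            assert cand.sine_interval is not None
            assert cand.q_value < 0.05 and abs(cand.delta_aaf) > 0.1

    def test_planted_type_and_strand_recovered(self, sim_small):
        truth = sim_small.truth.sites
        planted = truth[truth.klass == "editing"]
        ann = sim_small.reference.annotation
        by_key = {(s.chrom, s.pos): s for s in sim_small.sites}
        for row in planted.itertuples(index=False):
            site = by_key[(row.chrom, row.pos)]
            resolved = resolve_canonical(site, ann)
            assert resolved == (row.editing_type, row.resolved_strand)
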