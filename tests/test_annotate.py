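"""RT homology, ORF annotation, domain architecture and the intactness verdict."""
import numpy as np
import pytest

from ervi import annotate, ltr_scan, synthetic
from ervi.annotate import (
    CORE_GENES,
    ERViRecord,
    annotate_element,
    annotate_orfs,
    check_domain_architecture,
    check_intactness,
    classify_rt,
    rt_homology_search,
    six_frame_translate,
)
from ervi.ltr_scan import ProvirusCandidate


def _dummy_candidate(length=3000):
    return ProvirusCandidate(
        contig_id="c", ltr5_span=(0, 300), ltr3_span=(length - 300, length),
        element_span=(0, length),
    )


class TestSixFrameTranslate:
    def test_codon_table(self):
        frames = dict(((f, s), p) for f, s, p in six_frame_translate("ATGAAATAA"))
        assert frames[(0, "+")] == "MK*"

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(0)
        seq = synthetic.random_dna(rng, 300)
        fwd = six_frame_translate(seq)
        rev = six_frame_translate(ltr_scan.revcomp(seq))
        # forward frames of the RC are the reverse frames of the original
        fwd_minus = sorted(p for f, s, p in fwd if s == "-")
        rev_plus = sorted(p for f, s, p in rev if s == "+")
        assert fwd_minus == rev_plus

    def test_length_accounting(self):
        rng = np.random.default_rng(1)
        seq = synthetic.random_dna(rng, 300)
        for strand in "+-":
            total = sum(3 * len(p) for f, s, p in six_frame_translate(seq) if s == strand)
            assert total >= 3 * (len(seq) - 2)

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError):
            six_frame_translate("ATGXXX")


class TestRtHomology:
    def test_self_hit(self, panel):
        pg = panel.genomes["toyRV1"]
        interior = pg.seq[pg.ltr_len : len(pg.seq) - pg.ltr_len]
        hit = rt_homology_search(interior, panel)
        assert hit is not None
        assert hit.aa_len > 100
        assert hit.e_value <= 1e-5
        assert hit.query_id == "toyRV1_RT"

    def test_random_sequence_no_hit(self, panel):
        rng = np.random.default_rng(2)
        assert rt_homology_search(synthetic.random_dna(rng, 3000), panel) is None

    def test_in_frame_stop_disqualifies(self, panel):
        # premature stop inside the RT region: no qualifying hit
        background = synthetic.make_background(30_000, seed=31)
        spec = synthetic.ImplantSpec(
            element_id="x", source="toyRV1", position=15_000,
            disruptions=["premature_stop:pol"],
        )
        genome, truth = synthetic.implant_provirus(background, spec, panel, seed=31)
        s, e = truth.element_span
        interior = genome["chr1"][s + truth.ltr_len : e - truth.ltr_len]
        hit = rt_homology_search(interior, panel)
        if hit is not None:  # a stop-free sub-alignment may survive
            assert "*" not in hit.peptide

    def test_empty_panel_raises(self, panel):
        import dataclasses

        broken = dataclasses.replace(panel, rt_queries={"q": "M" + "A" * 150})
        broken.rt_queries = {}
        with pytest.raises(ValueError):
            rt_homology_search("ATG" * 100, broken)


class TestClassifyRt:
    def test_panel_rt_is_retrovirus(self, panel):
        pep = next(iter(panel.rt_queries.values()))
        assert classify_rt(pep, panel) == "retrovirus"

    def test_decoy_is_retrotransposon(self, panel):
        pep = next(iter(panel.decoy_rts.values()))
        assert classify_rt(pep, panel) == "retrotransposon"

    def test_chimera_is_unclassified(self, panel):
        retro = next(iter(panel.rt_queries.values()))
        decoy = next(iter(panel.decoy_rts.values()))
        chimera = retro[:100] + decoy[:100]  # equal halves: class scores tie
        assert classify_rt(chimera, panel) == "unclassified"

    def test_no_decoys_warns_retrovirus(self, panel):
        import dataclasses

        nodec = dataclasses.replace(panel, decoy_rts={})
        pep = next(iter(panel.rt_queries.values()))
        assert classify_rt(pep, nodec) == "retrovirus"


class TestAnnotateOrfs:
    def test_panel_element_labels_in_order(self, panel):
        pg = panel.genomes["toyRV2"]
        interior = pg.seq[pg.ltr_len : len(pg.seq) - pg.ltr_len]
        orfs = [o for o in annotate_orfs(interior, panel) if o.gene in CORE_GENES]
        assert [o.gene for o in sorted(orfs, key=lambda o: o.span)] == list(CORE_GENES)
        for o in orfs:
            assert not o.has_premature_stop
            assert o.aa_len >= panel.orf_min_len[o.gene]

    def test_frameshift_truncates_below_cutoff(self, panel):
        background = synthetic.make_background(30_000, seed=32)
        spec = synthetic.ImplantSpec(
            element_id="fs", source="toyRV3", position=15_000,
            disruptions=["frameshift:pol"],
        )
        genome, truth = synthetic.implant_provirus(background, spec, panel, seed=32)
        s, e = truth.element_span
        interior = genome["chr1"][s + truth.ltr_len : e - truth.ltr_len]
        orfs = {o.gene: o for o in annotate_orfs(interior, panel) if o.gene in CORE_GENES}
        disrupted = (
            "pol" not in orfs
            or orfs["pol"].aa_len < panel.orf_min_len["pol"]
            or orfs["pol"].has_premature_stop
        )
        assert disrupted

    def test_all_n_interior_is_empty(self, panel):
        assert annotate_orfs("N" * 600, panel) == []


class TestDomainArchitecture:
    def test_panel_pol_env_pass(self, panel):
        pg = panel.genomes["toyRV1"]
        flags, positions = check_domain_architecture(
            pg.gene_aa["pol"], pg.gene_aa["env"], panel
        )
        assert all(flags.values())
        assert positions["RT"] < positions["RH"] < positions["IN"]

    def test_poly_ile_env_has_tm(self, panel):
        env = "M" + "Q" * 50 + "I" * 19 + "Q" * 50
        flags, _ = check_domain_architecture(panel.genomes["toyRV1"].gene_aa["pol"], env, panel)
        assert flags["TM"]

    def test_out_of_order_motifs_fail(self, panel):
        # IN motif before RT motifs: whole Pol architecture absent
        pol = "M" + synthetic.IN_MOTIF + "A" * 30 + synthetic.RT_MOTIF_1 + "A" * 30 \
            + synthetic.RT_MOTIF_2 + "A" * 30 + synthetic.RH_MOTIF + "A" * 30
        flags, _ = check_domain_architecture(pol, "I" * 40, panel)
        assert not flags["RT"] and not flags["RH"] and not flags["IN"]

    def test_empty_peptide_raises(self, panel):
        with pytest.raises(ValueError):
            check_domain_architecture("", "II", panel)


class TestIntactness:
    def test_intact_element_passes(self, panel, intact_world):
        _, genome, truth = intact_world
        s, e = truth.element_span
        cand = ProvirusCandidate(
            contig_id="chr1", ltr5_span=truth.ltr5_span, ltr3_span=truth.ltr3_span,
            element_span=truth.element_span,
        )
        rec = annotate_element(genome["chr1"][s:e], cand, panel)
        assert rec.verdict == "pass"
        assert rec.fail_reasons == []

    def test_short_gag_fails_with_reason(self, panel, scanned_intact, intact_world):
        # shrink gag below the 80% cutoff by reporting a shortened aa_len
        _, genome, truth = intact_world
        s, e = truth.element_span
        rec = annotate_element(genome["chr1"][s:e], scanned_intact, panel)
        gag = next(o for o in rec.orfs if o.gene == "gag")
        gag.aa_len = panel.orf_min_len["gag"] - 1
        rec2 = check_intactness(rec, panel)
        assert rec2.verdict == "fail"
        assert "short_orf:gag" in rec2.fail_reasons

    def test_gene_order_violation(self, panel, scanned_intact, intact_world):
        _, genome, truth = intact_world
        s, e = truth.element_span
        rec = annotate_element(genome["chr1"][s:e], scanned_intact, panel)
        pro = next(o for o in rec.orfs if o.gene == "pro")
        pol = next(o for o in rec.orfs if o.gene == "pol")
        pro.span, pol.span = pol.span, pro.span
        rec2 = check_intactness(rec, panel)
        assert rec2.verdict == "fail"
        assert "order_violation" in rec2.fail_reasons

    def test_verdict_is_deterministic(self, panel, scanned_intact, intact_world):
        _, genome, truth = intact_world
        s, e = truth.element_span
        a = annotate_element(genome["chr1"][s:e], scanned_intact, panel)
        b = annotate_element(genome["chr1"][s:e], scanned_intact, panel)
        assert a.verdict == b.verdict
        assert a.fail_reasons == b.fail_reasons
        assert [(o.gene, o.span) for o in a.orfs] == [(o.gene, o.span) for o in b.orfs]

    def test_monotone_under_disruption(self, panel, decoy_world):
        # every decoy (a disruptive mutation of a passing design) must fail
        _, genome, truths = decoy_world
        for truth in truths:
            if not truth.expected_scan_hit:
                continue
            s, e = truth.element_span
            cand = ProvirusCandidate(
                contig_id="chr1", ltr5_span=truth.ltr5_span, ltr3_span=truth.ltr3_span,
                element_span=truth.element_span,
            )
            rec = annotate_element(genome["chr1"][s:e], cand, panel)
            assert rec.verdict == truth.expected_verdict
            assert synthetic.reasons_satisfied(truth.expected_fail_reasons, rec.fail_reasons), (
                truth.element_id, truth.expected_fail_reasons, rec.fail_reasons,
            )
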