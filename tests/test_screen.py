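"""Enhancer screen: interval logic, IUPAC/PWM matching, pipeline equivalence."""

from __future__ import annotations

import io as std_io

import numpy as np
import pytest
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

from aiscreen.screen import (
    BindingSite,
    EnhancerElement,
    EnhancerScreen,
    GenomicInterval,
    PWM,
    ScreenConfigurationError,
    Variant,
    allele_disruption,
    filter_elements_by_score,
    iupac_match,
    read_jaspar_pfm,
    restrict_to_ld_region,
    reverse_complement,
    scan_pwm,
    variants_at_binding_sites,
)
from aiscreen.simulate import SimulationConfig, simulate_screen_fixture


def iv(start, end, chrom="chr15", label=""):
    return GenomicInterval(chrom, start, end, label)


def var(pos, snp_id="v", chrom="chr15", a="C", b="T"):
    return Variant(chrom, pos, snp_id, a, b)


class TestIntervals:
    def test_one_based_inclusive_membership(self):
        region = iv(30782050, 30841010, label="15q13")
        kept = restrict_to_ld_region(
            [var(30782048, "tag"), var(30782050, "at_start"), var(30841010, "at_end"),
             var(30841011, "past_end")], region)
        # a tag SNP 2 bp before the printed block start is excluded, not widened in
        assert [v.snp_id for v in kept] == ["at_start", "at_end"]

    def test_chromosome_mismatch_silently_excluded(self):
        region = iv(1, 100, chrom="chr1")
        assert restrict_to_ld_region([var(50, chrom="chr2")], region) == []

    def test_empty_input(self):
        assert restrict_to_ld_region([], iv(1, 10)) == []

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            iv(10, 5)
        with pytest.raises(ValueError):
            iv(0, 5)


class TestScoreFilter:
    def test_cutoff_is_inclusive(self):
        els = [EnhancerElement(iv(1, 10), 300.0), EnhancerElement(iv(20, 30), 299.999)]
        kept = filter_elements_by_score(els)
        assert [e.score for e in kept] == [300.0]

    def test_zero_cutoff_is_identity(self):
        els = [EnhancerElement(iv(1, 10), 0.0), EnhancerElement(iv(20, 30), 5.0)]
        assert filter_elements_by_score(els, 0) == els


class TestIUPAC:
    @pytest.mark.parametrize("seq, pattern, ok", [
        ("CATCC", "YATCC", True),
        ("GATCC", "YATCC", False),
        ("GTATCT", "GTRTCT", True),
        ("ACGT", "NNNN", True),
        ("TAAATGTA", "TAAATRTA", True),
    ])
    def test_membership(self, seq, pattern, ok):
        assert iupac_match(seq, pattern) is ok

    def test_length_mismatch_and_bad_symbols(self):
        with pytest.raises(ValueError):
            iupac_match("ACG", "YATCC")
        with pytest.raises(ValueError):
            iupac_match("ACGTX"[:5], "YATCC")
        with pytest.raises(ValueError):
            iupac_match("ACGTA", "YATCZ")

    def test_reverse_complement_of_iupac(self):
        assert reverse_complement("AAYCAATCACATA") == "TATGTGATTGRTT"
        assert reverse_complement(reverse_complement("GTRTCT")) == "GTRTCT"


class TestSiteOverlap:
    def make_setup(self):
        elements = [EnhancerElement(iv(100, 200, label="e1"), 350.0),
                    EnhancerElement(iv(300, 400, label="e2"), 250.0)]
        sites = [BindingSite(iv(150, 154), "GATA2", "YATCC"),
                 BindingSite(iv(320, 325), "GATA1", "GTRTCT")]
        variants = [var(151, "in_high"), var(322, "in_low"), var(149, "outside")]
        return variants, sites, elements

    def test_only_high_scoring_parent_sites_report(self):
        variants, sites, elements = self.make_setup()
        passing = filter_elements_by_score(elements)
        hits = variants_at_binding_sites(variants, sites, passing,
                                         all_elements=elements)
        assert [h.variant.snp_id for h in hits] == ["in_high"]

    def test_exclusion_by_id(self):
        variants, sites, elements = self.make_setup()
        hits = variants_at_binding_sites(variants, sites,
                                         filter_elements_by_score(elements),
                                         exclude_ids=["in_high"],
                                         all_elements=elements)
        assert hits == []

    def test_orphan_site_is_a_configuration_error(self):
        variants, sites, elements = self.make_setup()
        orphan = BindingSite(iv(500, 505), "TF", "NNNNNN")
        with pytest.raises(ScreenConfigurationError):
            variants_at_binding_sites(variants, sites + [orphan], elements,
                                      all_elements=elements)

    def test_overlapping_sites_one_candidate_two_annotations(self):
        elements = [EnhancerElement(iv(100, 200, label="e"), 400.0)]
        sites = [BindingSite(iv(150, 154), "TF1", "YATCC"),
                 BindingSite(iv(152, 156), "TF2", "NNNNN")]
        hits = variants_at_binding_sites([var(152, "v1")], sites, elements)
        assert len(hits) == 1 and len(hits[0].annotations) == 2


class TestDisruption:
    def site(self, start=101, pattern="YATCC", strand="+"):
        return BindingSite(iv(start, start + len(pattern) - 1), "GATA2", pattern,
                           strand=strand)

    def test_both_alleles_in_degenerate_set_not_disruptive(self):
        rep = allele_disruption(var(101, a="C", b="T"), self.site(), "CATCC")
        assert rep.match_a and rep.match_b and not rep.disruptive

    def test_one_allele_outside_set_is_disruptive(self):
        rep = allele_disruption(var(101, a="C", b="G"), self.site(), "CATCC")
        assert rep.match_a and not rep.match_b and rep.disruptive

    def test_neither_allele_matches(self):
        rep = allele_disruption(var(101, a="A", b="G"), self.site(), "CATCC")
        assert not rep.match_a and not rep.match_b and not rep.disruptive

    def test_minus_strand_alleles_are_complemented_via_sequence(self):
        # pattern YATCC on the minus strand; + strand footprint is GGATR
        # at the Y position (last + base), + allele G complements to C -> match
        rep = allele_disruption(var(105, a="G", b="C"), self.site(pattern="YATCC",
                                                                  strand="-"),
                                "GGATG")
        assert rep.match_a            # G -> C on motif strand, Y covers C
        assert not rep.match_b        # C -> G fails Y
        assert rep.disruptive

    def test_variant_outside_site_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            allele_disruption(var(99), self.site(), "CATCC")


def toy_pwm():
    # strongly favours consensus TGATCAC; rows in A, C, G, T order
    counts = np.array([
        [0, 1, 18, 0, 1, 18, 0],    # A
        [1, 0, 1, 0, 17, 0, 19],    # C
        [0, 18, 0, 0, 1, 1, 0],     # G
        [18, 0, 0, 19, 0, 0, 0],    # T
    ], dtype=float)
    return PWM("AP1", counts)


class TestPWM:
    def test_consensus_scores_maximal_and_is_reported_first(self):
        pwm = toy_pwm()
        assert pwm.consensus == "TGATCAC"
        sites = scan_pwm("AA" + pwm.consensus + "AA", pwm, threshold=pwm.max_score)
        plus = [s for s in sites if s.strand == "+"]
        assert plus[0].interval.start == 3
        assert plus[0].score == pytest.approx(pwm.max_score)

    def test_threshold_above_maximum_yields_nothing(self):
        pwm = toy_pwm()
        assert scan_pwm("AA" + pwm.consensus + "AA", pwm, pwm.max_score + 1) == []

    def test_strand_symmetry_on_reverse_complement(self):
        """Scanning a sequence and its reverse complement mirrors the site list."""
        pwm = toy_pwm()
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 60)) + pwm.consensus
        L = len(seq)
        fwd = scan_pwm(seq, pwm, threshold=2.0)
        rev = scan_pwm(reverse_complement(seq), pwm, threshold=2.0)
        mirrored = sorted((L - s.interval.end + 1, {"+": "-", "-": "+"}[s.strand],
                           round(s.score, 6)) for s in fwd)
        direct = sorted((s.interval.start, s.strand, round(s.score, 6)) for s in rev)
        assert mirrored == direct

    def test_palindromic_matrix_scores_both_strands_equally(self):
        counts = np.array([
            [10, 0, 0, 10],   # A
            [0, 10, 0, 0],    # C
            [0, 0, 10, 0],    # G
            [10, 0, 0, 10],   # T
        ], dtype=float)
        pwm = PWM("pal", counts)   # consensus ACGT is not palindromic; use WCGW sets
        sites = scan_pwm("TTACGTTT", pwm, threshold=pwm.min_score)
        by_pos = {}
        for s in sites:
            by_pos.setdefault(s.interval.start, {})[s.strand] = s.score
        for pos, scores in by_pos.items():
            assert scores["+"] == pytest.approx(scores["-"])

    def test_scores_match_biopython_pssm(self):
        """Independent oracle: Bio.motifs log-odds with matched pseudocounts."""
        pwm = toy_pwm()
        m = bio_motifs.Motif(alphabet="ACGT", counts={
            b: list(pwm.counts[i]) for i, b in enumerate("ACGT")})
        pseudo = {b: pwm.pseudocount * 0.25 for b in "ACGT"}
        pssm = m.counts.normalize(pseudocounts=pseudo).log_odds(
            {b: 0.25 for b in "ACGT"})
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 50))
        expected = pssm.calculate(Seq(seq))
        got = [pwm.score(seq[i:i + len(pwm)]) for i in range(50 - len(pwm) + 1)]
        assert np.allclose(got, expected, atol=1e-4)

    def test_degenerate_windows_are_skipped(self):
        pwm = toy_pwm()
        sites = scan_pwm("NN" + pwm.consensus[:-1] + "N", pwm, threshold=-100)
        assert sites == []

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_pwm("ACG", toy_pwm(), 0.0)


JASPAR_BRACKETED = """>MA0001.1 TOY
A [ 4 19  0  0  0 ]
C [16  0 20  0  0 ]
G [ 0  1  0 20  0 ]
T [ 0  0  0  0 20 ]
"""

JASPAR_PLAIN = """>MA0001.1 TOY
A 4 19 0 0 0
C 16 0 20 0 0
G 0 1 0 20 0
T 0 0 0 0 20
"""

JASPAR_UNLABELLED = """>MA0001.1 TOY
4 19 0 0 0
16 0 20 0 0
0 1 0 20 0
0 0 0 0 20
"""


class TestJasparParsing:
    def test_dialects_parse_identically(self):
        pwms = [read_jaspar_pfm(t) for t in (JASPAR_BRACKETED, JASPAR_PLAIN,
                                             JASPAR_UNLABELLED)]
        for p in pwms[1:]:
            assert np.array_equal(p.counts, pwms[0].counts)
        assert pwms[0].tf_name == "TOY"
        assert len(pwms[0]) == 5

    def test_row_order_normalised_by_label(self):
        scrambled = ">X TOY\nT 0 0 0 0 20\nG 0 1 0 20 0\nC 16 0 20 0 0\nA 4 19 0 0 0\n"
        assert np.array_equal(read_jaspar_pfm(scrambled).counts,
                              read_jaspar_pfm(JASPAR_PLAIN).counts)

    def test_matches_biopython_parse(self):
        ours = read_jaspar_pfm(JASPAR_BRACKETED)
        theirs = bio_motifs.parse(std_io.StringIO(JASPAR_BRACKETED), "jaspar")[0]
        expected = np.array([list(theirs.counts[b]) for b in "ACGT"])
        assert np.array_equal(ours.counts, expected)

    @pytest.mark.parametrize("text, message", [
        (">X\nA 1 2\nC 1 2\nG 1 2\n", "missing matrix row"),
        (">X\nA 1 2\nC 1 2\nG 1 2\nT 1 2 3\n", "ragged"),
        (">X\nA 1 -2\nC 1 2\nG 1 2\nT 1 2\n", "line 2"),
        (">X\n1 2\n1 2\n1 2\n", "expected 4"),
    ])
    def test_errors_carry_diagnostics(self, text, message):
        with pytest.raises(ValueError, match=message):
            read_jaspar_pfm(text)


def brute_force_candidates(variants, sites, elements, regions, min_score,
                           exclude_ids):
    """Oracle: triple loop over (variant, site, element), set semantics."""
    out = []
    for v in variants:
        if regions is not None and not any(
                r.contains(v.chrom, v.pos) for r in regions):
            continue
        if v.snp_id in exclude_ids:
            continue
        hit = False
        for s in sites:
            if not s.interval.contains(v.chrom, v.pos):
                continue
            for e in elements:
                if e.score >= min_score and e.interval.contains_interval(s.interval):
                    hit = True
        if hit and v.snp_id not in out:
            out.append(v.snp_id)
    return out


class TestPipelineEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_screen_equals_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        chrom = "chrT"
        elements, sites = [], []
        for i in range(12):
            start = int(rng.integers(1, 5000))
            end = start + int(rng.integers(30, 120))
            elements.append(EnhancerElement(iv(start, end, chrom=chrom,
                                               label=f"e{i}"),
                                            float(rng.uniform(100, 500))))
        for i in range(25):
            e = elements[int(rng.integers(len(elements)))]
            w = int(rng.integers(5, 12))
            if len(e.interval) <= w:
                continue
            start = int(rng.integers(e.interval.start, e.interval.end - w + 1))
            sites.append(BindingSite(iv(start, start + w - 1, chrom=chrom),
                                     f"TF{i}", "N" * w))
        variants = [var(int(rng.integers(1, 5200)), f"v{i}", chrom=chrom)
                    for i in range(60)]
        regions = [iv(1, 2600, chrom=chrom), iv(3000, 5200, chrom=chrom)]
        exclude = ["v3", "v10"]
        res = EnhancerScreen(variants, sites, elements, regions=regions,
                             min_score=300, exclude_ids=exclude).run()
        assert res.candidate_ids == brute_force_candidates(
            variants, sites, elements, regions, 300, exclude)

    def test_filter_then_intersect_commutes_with_intersect_then_filter(self):
        variants, sites, elements = TestSiteOverlap().make_setup()
        a = variants_at_binding_sites(variants, sites,
                                      filter_elements_by_score(elements),
                                      all_elements=elements)
        b = [h for h in variants_at_binding_sites(variants, sites, elements)
             if all(ann.element.score >= 300 for ann in h.annotations)]
        assert [h.variant.snp_id for h in a] == [h.variant.snp_id for h in b]


class TestGeneratedFixture:
    def test_strata_are_recovered_exactly(self):
        cfg = SimulationConfig(seed=42)
        fx = simulate_screen_fixture(cfg)
        res = EnhancerScreen(fx.variants, fx.sites, fx.elements,
                             sequences=fx.sequences).run()
        expected = set(fx.truth.loc[fx.truth.stratum == "in_high", "snp_id"])
        assert set(res.candidate_ids) == expected
        assert len(res) == cfg.n_variants_in_high

    def test_excluding_the_pre_genotyped_variant(self):
        fx = simulate_screen_fixture(SimulationConfig(seed=42))
        res = EnhancerScreen(fx.variants, fx.sites, fx.elements,
                             exclude_ids=[fx.exclude_id]).run()
        assert len(res) == 12

    def test_all_low_scoring_elements_yield_nothing(self):
        fx = simulate_screen_fixture(SimulationConfig(seed=7))
        capped = [EnhancerElement(e.interval, min(e.score, 299.0))
                  for e in fx.elements]
        res = EnhancerScreen(fx.variants, fx.sites, capped).run()
        assert len(res) == 0

    def test_planted_disruption_annotations(self):
        fx = simulate_screen_fixture(SimulationConfig(seed=42))
        res = EnhancerScreen(fx.variants, fx.sites, fx.elements,
                             sequences=fx.sequences).run()
        df = res.to_frame()
        # planted reference allele always matches its consensus pattern
        assert df["allele_a_match"].all()
        # the alternate allele was chosen outside the degeneracy set
        assert (~df["allele_b_match"].astype(bool)).all()
        assert df["disruptive"].all()
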