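"""Safe-site selection, PAM scanning, guide filtering and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castworks import designer, simgen
from castworks.designer import (
    GuideCandidate,
    OffTargetReport,
    PamSite,
    SafeSite,
    extract_guide,
    scan_pams,
)
from castworks.dna import gc_content, random_dna, revcomp
from castworks.simgen.genome import Gene, SimGenome


class TestSafeSites:
    def test_planted_converging_gaps_all_accepted(self, design_genome):
        sites = designer.find_safe_sites(design_genome.genes,
                                         len(design_genome))
        assert len(sites) == 2
        assert all(s.accepted for s in sites)
        truth = {(t.start, t.end) for t in design_genome.planted_sites}
        assert {(s.start, s.end) for s in sites} == truth

    def test_gap_length_bounds_flagged(self):
        genes = [Gene("a", 100, 500, "+"), Gene("b", 750, 1000, "-"),
                 Gene("c", 1500, 2000, "+"), Gene("d", 2700, 3000, "-")]
        sites = designer.find_safe_sites(genes, 3000, min_len=300,
                                         max_len=600)
        flags = {s.exclusion_flags.copy().pop() if s.exclusion_flags else None
                 for s in sites}
        by_len = {s.length: s for s in sites}
        assert "too_short" in by_len[250].exclusion_flags
        assert "too_long" in by_len[700].exclusion_flags

    def test_mask_and_essential_exclusions(self):
        genes = [Gene("a", 100, 500, "+"), Gene("b", 900, 1200, "-")]
        sites = designer.find_safe_sites(
            genes, 2000, masks={"ncRNA": [(600, 650)]})
        assert sites[0].exclusion_flags == {"ncRNA"}
        sites2 = designer.find_safe_sites(genes, 2000,
                                          essential_genes={"b"})
        assert sites2[0].exclusion_flags == {"essential_flank"}
        sites3 = designer.find_safe_sites(
            genes, 2000, masks={"mobile_element": [(550, 560)]})
        assert sites3[0].exclusion_flags == {"mobile_element"}

    def test_unsorted_genes_normalised_with_warning(self):
        genes = [Gene("b", 900, 1200, "-"), Gene("a", 100, 500, "+")]
        with pytest.warns(UserWarning, match="unsorted"):
            sites = designer.find_safe_sites(genes, 2000)
        assert len(sites) == 1


def brute_force_pams(seq):
    """Enumeration oracle: CN on '+', and on '-' every position whose
    reverse-complement reading gives CN."""
    out = set()
    n = len(seq)
    for i in range(n - 1):
        if seq[i] == "C":
            out.add((i, "+"))
        if revcomp(seq[i:i + 2])[0] == "C":
            out.add((i, "-"))
    return out


class TestScanPams:
    def test_single_c_forward(self):
        assert [(p.start, p.strand) for p in scan_pams("ACGT")] == \
            [(1, "+"), (1, "-")]  # CG fwd at 1; CG revcomp at 1 too

    def test_at_only_sequence_has_no_pams(self):
        assert scan_pams("ATATATTA") == []

    def test_palindromic_ccgg_found_on_both_strands(self):
        found = {(p.start, p.strand) for p in scan_pams("CCGG")}
        assert found == brute_force_pams("CCGG")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle_on_random_dna(self, seed):
        seq = random_dna(np.random.default_rng(seed), 80)
        assert {(p.start, p.strand) for p in scan_pams(seq)} == \
            brute_force_pams(seq)

    def test_ambiguity_codes_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguity"):
            pams = scan_pams("CNNA")
        assert all(p.start != 1 for p in pams)


class TestExtractAndFilter:
    def test_guide_is_32nt_3prime_of_pam(self):
        rng = np.random.default_rng(1)
        g = random_dna(rng, 200)
        c = extract_guide(g, PamSite(50, "+"))
        assert len(c.protospacer) == 32
        assert c.protospacer == g[52:84]
        assert c.pam == g[50:52]
        cm = extract_guide(g, PamSite(100, "-"))
        assert cm.protospacer == revcomp(g[68:100])
        assert cm.pam == revcomp(g[100:102])

    def test_gc_arithmetic(self):
        proto = "GC" * 8 + "AT" * 8
        assert gc_content(proto) == 50.0

    def test_pam_too_close_to_contig_end_skipped(self):
        g = random_dna(np.random.default_rng(2), 40)
        assert extract_guide(g, PamSite(20, "+")) is None

    def test_filter_rules_record_failures(self):
        site = SafeSite(0, 1000, 1400, "a", "b")
        ok = GuideCandidate("A" * 32, "CA", "+", 1050, 1082, 50.0,
                            (1127, 1137), site_index=0)
        bad_gc = GuideCandidate("A" * 32, "CA", "+", 1050, 1082, 65.0,
                                (1127, 1137), site_index=0)
        outside = GuideCandidate("A" * 32, "CA", "+", 1318, 1350, 50.0,
                                 (1395, 1405), site_index=0)
        term = GuideCandidate("A" * 32, "CA", "+", 1100, 1132, 50.0,
                              (1177, 1187), site_index=0)
        accepted = designer.filter_guides(
            [ok, bad_gc, outside, term], site,
            terminator_mask=[(1180, 1200)])
        assert accepted == [ok]
        assert bad_gc.passes["gc"] is False
        assert outside.passes["locus_inside"] is False
        assert term.passes["terminator"] is False


class TestOffTarget:
    def test_planted_duplicate_reported_with_full_seed_match(self):
        rng = np.random.default_rng(3)
        g = random_dna(rng, 30_000)
        guide = g[4000:4032]
        g2 = g[:20_000] + guide + g[20_000 + 32:]
        rep = designer.offtarget_scan(guide, g2,
                                      exclude_interval=(3990, 4040))
        assert rep.best_hit_identity == 1.0
        assert rep.seed_matches == 10
        assert rep.n_hits_above_floor >= 1

    def test_on_target_locus_never_reports_itself(self):
        rng = np.random.default_rng(4)
        g = random_dna(rng, 20_000)
        guide = g[7000:7032]
        rep = designer.offtarget_scan(guide, g,
                                      exclude_interval=(6990, 7040))
        assert rep.best_hit_length < 32
        assert rep.best_hit_score < 64


class TestSelection:
    def _cand(self, start, seed_matches, score):
        c = GuideCandidate("A" * 32, "CA", "+", start, start + 32, 50.0,
                           (start + 81, start + 87), site_index=0,
                           passes={"gc": True})
        c.offtarget = OffTargetReport(20, 0.8, score, seed_matches, 1)
        return c

    def test_default_k_returns_three_ranked_guides(self):
        site = SafeSite(0, 0, 600, "a", "b")
        cands = [self._cand(10 * i, i % 4, 20 + i) for i in range(8)]
        chosen = designer.select_guides(site, cands, k=3)
        assert [c.rank for c in chosen] == [1, 2, 3]
        assert [c.offtarget.seed_matches for c in chosen] == [0, 0, 1]

    def test_seed_matches_dominate_ranking(self):
        site = SafeSite(0, 0, 600, "a", "b")
        risky = self._cand(0, 10, 10)
        safe = self._cand(50, 2, 60)
        assert designer.select_guides(site, [risky, safe], k=1) == [safe]

    def test_full_tie_broken_by_leftmost_coordinate(self):
        site = SafeSite(0, 0, 600, "a", "b")
        a, b = self._cand(200, 1, 30), self._cand(100, 1, 30)
        assert designer.select_guides(site, [a, b], k=1)[0].proto_start == 100

    def test_shortfall_warns_and_returns_all(self):
        site = SafeSite(0, 0, 600, "a", "b")
        with pytest.warns(UserWarning, match="only 1 of 3"):
            chosen = designer.select_guides(site, [self._cand(0, 0, 20)], k=3)
        assert len(chosen) == 1
        with pytest.warns(UserWarning, match="no accepted"):
            assert designer.select_guides(site, [], k=3) == []


@pytest.fixture(scope="module")
def designed(design_genome):
    return designer.design_guides(design_genome, k=3)


class TestPipeline:
    def test_every_emitted_guide_obeys_invariants(self, designed,
                                                  design_genome):
        sites, guides = designed
        site_map = {s.index: s for s in sites}
        assert guides, "pipeline produced no guides"
        for g in guides:
            assert len(g.protospacer) == 32
            assert g.pam[0] == "C"
            assert 40.0 <= g.gc_pct <= 60.0
            lo, hi = g.predicted_locus
            s = site_map[g.site_index]
            assert s.start <= lo and hi <= s.end
            # the protospacer is really at the recorded coordinates
            seq = design_genome.sequence[g.proto_start:g.proto_end]
            assert g.protospacer == (seq if g.strand == "+" else revcomp(seq))

    def test_three_guides_per_accepted_site(self, designed):
        sites, guides = designed
        per_site = {}
        for g in guides:
            per_site.setdefault(g.site_index, []).append(g)
        for s in sites:
            if s.accepted:
                assert len(per_site[s.index]) == 3

    def test_strand_symmetry_of_design(self):
        """Designing on the reverse-complemented genome is equivalent: the
        safe sites mirror, every accepted candidate (with its off-target
        statistics) mirrors exactly, and the selected guides carry the
        same ranking statistics per site.  The identity of selected
        guides may differ only inside exact ranking ties, where the
        deterministic leftmost-coordinate tie-break is orientation-bound
        by construction."""
        from castworks.designer import (
            extract_guide,
            filter_guides,
            find_safe_sites,
            offtarget_scan,
            scan_pams,
        )

        design_genome = simgen.make_genome(length=12_000,
                                           n_converging_pairs=1, seed=6)
        L = len(design_genome)
        rc_genes = [Gene(g.id, L - g.end, L - g.start,
                         "-" if g.strand == "+" else "+")
                    for g in reversed(design_genome.genes)]
        rc = SimGenome(revcomp(design_genome.sequence), rc_genes, name="rc")

        def accepted_stats(genome):
            seq = genome.sequence
            out = {}
            for site in find_safe_sites(genome.genes, len(seq)):
                pams = scan_pams(seq[site.start:site.end], offset=site.start)
                cands = [c for c in (extract_guide(seq, p) for p in pams)
                         if c is not None]
                for c in filter_guides(cands, site):
                    rep = offtarget_scan(
                        c, seq, exclude_interval=(max(0, c.proto_start - 7),
                                                  min(len(seq), c.proto_end + 7)))
                    out[(c.protospacer, c.pam)] = (rep.seed_matches,
                                                   rep.best_hit_score)
            return out

        assert accepted_stats(design_genome) == accepted_stats(rc)

        _, fwd_guides = designer.design_guides(design_genome, k=3)
        _, rc_guides = designer.design_guides(rc, k=3)

        def per_site_stats(guides, mirror=False):
            out = {}
            for g in guides:
                key = g.site_index
                out.setdefault(key, []).append(
                    (g.offtarget.seed_matches, g.offtarget.best_hit_score))
            return {k: sorted(v) for k, v in out.items()}

        fwd_stats = per_site_stats(fwd_guides)
        rc_stats = per_site_stats(rc_guides)
        n = max(fwd_stats) if fwd_stats else 0
        # site i in the forward genome mirrors site n-i in the reversed one
        assert fwd_stats == {n - k: v for k, v in rc_stats.items()}

    def test_terminator_mask_excludes_loci(self, design_genome):
        site = next(s for s in design_genome.planted_sites)
        masked = SimGenome(design_genome.sequence, design_genome.genes,
                           {"terminator": [(site.start, site.end)]},
                           design_genome.planted_sites)
        with pytest.warns(UserWarning, match="no accepted"):
            _, guides = designer.design_guides(masked, k=3)
        assert all(g.site_index != site.index for g in guides)
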