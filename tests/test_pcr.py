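"""In-silico PCR: site search vs a brute-force oracle, the ARMS extension
rule, and the published band patterns."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetrarms.fixtures import build_haplotype, build_template
from tetrarms.model import (
    PcrPolicy,
    PrimerSpec,
    SequenceRecord,
    SiteMismatch,
)
from tetrarms.pcr import can_extend, find_binding_sites, simulate_pcr
from tetrarms.thermo import melting_temperature

_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_sites(primer_seq, template_seq, policy):
    """Exhaustive all-offsets, both-strand enumeration (independent oracle).

    Returns a set of (strand, left, right, mismatch-positions) signatures.
    """
    tm = melting_temperature(
        primer_seq, na_mm=policy.na_mm, mg_mm=policy.mg_mm, oligo_nm=policy.oligo_nm
    )
    floor = policy.annealing_temp_c - policy.anneal_margin_c
    L, n = len(primer_seq), len(template_seq)
    out = set()
    for i in range(n - L + 1):
        window = template_seq[i : i + L]
        # forward-style: primer equals the top strand
        mm_f = tuple(L - j for j in range(L) if primer_seq[j] != window[j])
        internal = sum(1 for p in mm_f if p > 1)
        if internal <= policy.max_internal_mismatches:
            if tm - policy.tm_penalty_per_mismatch_c * len(mm_f) >= floor:
                out.add(("top", i + 1, i + L, tuple(sorted(mm_f))))
        # reverse-style: primer equals the bottom strand
        rc = window.translate(_COMP)[::-1]
        mm_r = tuple(L - m for m in range(L) if primer_seq[m] != rc[m])
        internal = sum(1 for p in mm_r if p > 1)
        if internal <= policy.max_internal_mismatches:
            if tm - policy.tm_penalty_per_mismatch_c * len(mm_r) >= floor:
                out.add(("bottom", i + 1, i + L, tuple(sorted(mm_r))))
    return out


def site_signature(site):
    return (
        site.strand,
        site.anneal_left,
        site.anneal_right,
        tuple(sorted(m.pos_from_3prime for m in site.mismatches)),
    )


def _primer(seq, orientation="forward"):
    return PrimerSpec(name="p", sequence=seq, role="outer", orientation=orientation)


class TestFindBindingSites:
    def test_outer_forward_has_one_perfect_site(self, assays, templates, policies):
        hap = templates["sika"][0]
        sites = find_binding_sites(
            assays["X221"].outer_f, hap, policies["X221"]
        )
        assert len(sites) == 1
        (site,) = sites
        assert site.strand == "top"
        assert (site.anneal_left, site.anneal_right) == (67, 87)
        assert site.mismatches == []

    def test_inner_reverse_blocked_site_on_sika(self, assays, templates, policies):
        """On the sika (C) haplotype the T-allele inner reverse primer
        anneals with its designed internal mismatch plus a 3'-terminal A.C
        mispair — the extension-blocked configuration."""
        hap = templates["sika"][0]
        sites = find_binding_sites(
            assays["X221"].inner_r, hap, policies["X221"]
        )
        assert len(sites) == 1
        (site,) = sites
        assert site.strand == "bottom"
        terminal = [m for m in site.mismatches if m.pos_from_3prime == 1]
        assert terminal == [
            SiteMismatch(1, "A", "C", "weak")
        ]
        designed = [m for m in site.mismatches if m.pos_from_3prime == 2]
        assert designed == [SiteMismatch(2, "G", "T", "weak")]
        assert not site.terminal_matched

    def test_no_overlap_template_gives_empty_list(self):
        template = SequenceRecord(id="t", seq="A" * 60)
        sites = find_binding_sites(
            _primer("GCTGATGCTACACACACGGAT"), template, PcrPolicy()
        )
        assert sites == []

    def test_effective_tm_never_exceeds_perfect_tm(self, assays, templates):
        policy = PcrPolicy(annealing_temp_c=40.0)  # lenient: keep mismatch sites
        for assay in assays.values():
            for primer in assay.primers:
                for site in find_binding_sites(primer, templates["hybrid"][0], policy):
                    assert site.effective_tm_c <= site.perfect_tm_c

    @given(data=st.data())
    def test_matches_brute_force_enumeration(self, data):
        """On short toy templates the scanner equals exhaustive enumeration."""
        rng_seq = st.text(alphabet="ACGT", min_size=40, max_size=200)
        template_seq = data.draw(rng_seq, label="template")
        start = data.draw(
            st.integers(0, len(template_seq) - 12), label="slice_start"
        )
        primer_seq = template_seq[start : start + 12]
        if data.draw(st.booleans(), label="mutate"):
            pos = data.draw(st.integers(0, 11), label="pos")
            base = data.draw(st.sampled_from("ACGT"), label="base")
            primer_seq = primer_seq[:pos] + base + primer_seq[pos + 1 :]
        policy = PcrPolicy(annealing_temp_c=25.0, max_internal_mismatches=2)
        got = {
            site_signature(s)
            for s in find_binding_sites(
                _primer(primer_seq), SequenceRecord(id="t", seq=template_seq), policy
            )
        }
        want = brute_force_sites(primer_seq, template_seq, policy)
        assert got == want


class TestCanExtend:
    def _site(self, mismatches, strand="top"):
        return type(
            "S",
            (),
            {
                "mismatches": mismatches,
                "strand": strand,
                "terminal_matched": all(m.pos_from_3prime != 1 for m in mismatches),
            },
        )()

    def test_terminal_match_extends(self):
        site = self._site([SiteMismatch(3, "C", "A", "weak")])
        assert can_extend(site, PcrPolicy(extension_rule="stringent"))

    def test_terminal_mismatch_blocks_stringent_at_62(self):
        site = self._site([SiteMismatch(1, "A", "C", "weak")])
        policy = PcrPolicy(annealing_temp_c=62.0, extension_rule="stringent")
        assert not can_extend(site, policy)

    def test_weak_terminal_mismatch_reads_through_permissive_below_60(self):
        site = self._site([SiteMismatch(1, "A", "C", "weak")])
        policy = PcrPolicy(annealing_temp_c=58.0, extension_rule="permissive")
        assert can_extend(site, policy)

    def test_weak_terminal_mismatch_blocked_permissive_at_62(self):
        site = self._site([SiteMismatch(1, "A", "C", "weak")])
        policy = PcrPolicy(annealing_temp_c=62.0, extension_rule="permissive")
        assert not can_extend(site, policy)

    def test_strong_terminal_mismatch_blocked_even_permissive_low_temp(self):
        site = self._site([SiteMismatch(1, "A", "G", "strong")])
        policy = PcrPolicy(annealing_temp_c=58.0, extension_rule="permissive")
        assert not can_extend(site, policy)

    def test_longer_exact_run_requirement(self):
        site = self._site([SiteMismatch(2, "G", "T", "weak")])
        assert can_extend(site, PcrPolicy(min_3prime_exact_run=1))
        assert not can_extend(site, PcrPolicy(min_3prime_exact_run=3))


EXPECTED_BANDS = {
    ("sika", "X221"): {486, 352},
    ("sika", "X428"): {549, 213},
    ("red", "X221"): {486, 179},
    ("red", "X428"): {549, 383},
    ("hybrid", "X221"): {486, 352, 179},
    ("hybrid", "X428"): {549, 213, 383},
    ("reindeer", "X221"): {486},
    ("reindeer", "X428"): {549},
}


class TestSimulate:
    @pytest.mark.parametrize("species,locus", sorted(EXPECTED_BANDS))
    def test_published_band_patterns(
        self, assays, templates, policies, species, locus
    ):
        amps = simulate_pcr(assays[locus], templates[species], policies[locus])
        assert amps.band_sizes == EXPECTED_BANDS[(species, locus)]

    def test_diploid_band_set_is_union_of_haplotypes(
        self, assays, templates, policies
    ):
        for locus, assay in assays.items():
            hap_c, hap_t = templates["hybrid"]
            both = simulate_pcr(assay, [hap_c, hap_t], policies[locus])
            only_c = simulate_pcr(assay, hap_c, policies[locus])
            only_t = simulate_pcr(assay, hap_t, policies[locus])
            assert both.band_sizes == only_c.band_sizes | only_t.band_sizes

    @pytest.mark.parametrize("rule", ["stringent", "permissive"])
    def test_raising_annealing_temp_never_adds_bands(
        self, assays, templates, rule
    ):
        previous = None
        for temp in (54.0, 58.0, 60.0, 62.0, 66.0, 70.0):
            policy = PcrPolicy(annealing_temp_c=temp, extension_rule=rule)
            bands = simulate_pcr(assays["X221"], templates["hybrid"], policy).band_sizes
            if previous is not None:
                assert bands <= previous
            previous = bands

    def test_raising_mismatch_budget_never_removes_sites(self, assays, templates):
        hap = templates["sika"][0]
        for primer in assays["X221"].primers:
            previous = None
            for budget in (0, 1, 2, 3, 5):
                policy = PcrPolicy(annealing_temp_c=40.0, max_internal_mismatches=budget)
                sigs = {
                    site_signature(s)
                    for s in find_binding_sites(primer, hap, policy)
                }
                if previous is not None:
                    assert previous <= sigs
                previous = sigs

    def test_low_temperature_permissive_mis_amplifies_sika(
        self, assays, templates
    ):
        """Below 60 C the weak-terminal inner reverse primer reads through on
        the sika template, adding the allele-2 band that 62 C suppresses."""
        low = PcrPolicy(annealing_temp_c=58.0, extension_rule="permissive")
        high = PcrPolicy(annealing_temp_c=62.0, extension_rule="permissive")
        bands_low = simulate_pcr(assays["X221"], templates["sika"], low).band_sizes
        bands_high = simulate_pcr(assays["X221"], templates["sika"], high).band_sizes
        assert 179 in bands_low
        assert bands_high == {486, 352}

    def test_no_amplification_is_empty_set(self, assays):
        template = SequenceRecord(id="t", seq="ACGT" * 200)
        amps = simulate_pcr(assays["X221"], template, PcrPolicy())
        assert amps.band_sizes == set()

    def test_discovery_primer_pair_product_is_730(self, templates):
        from tetrarms.fixtures import ZFX1F, ZFX1R

        policy = PcrPolicy(annealing_temp_c=55.0)
        amps = simulate_pcr([ZFX1F, ZFX1R], templates["sika"], policy)
        assert amps.band_sizes == {730}
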