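"""Mimic design: template decoding, guide/star derivation, assembly."""

import random

import pytest

from mimircraft import (
    Alphabet,
    Category,
    GENERIC_SCAFFOLD,
    MIR2022_SCAFFOLD,
    NucleicSeq,
    PROMOTERS,
    SeqError,
    align_duplex,
    assemble_design,
    choose_target_site,
    classify_alignment,
    decode_template,
    derive_guide,
    derive_star,
    design_mimic,
    revcomp,
)
from mimircraft.fixtures import MIMIR_TEMPLATE_NAMES

rna = lambda s, id="x": NucleicSeq(id, Alphabet.RNA, s)
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class TestDecode:
    def test_full_match_row(self, designs, mcherry):
        d = designs["full_match_template"]
        assert len(d.guide) == 21
        assert d.guide[1] == "U" and d.guide[19] == "C"
        # the guide arm is the one matching the transcript (up to C19)
        site = mcherry.bases[d.site_start - 1 : d.site_end].replace("T", "U")
        mm = align_duplex(d.guide, rna(site)).mismatch_positions()
        assert mm == frozenset({19})

    def test_all_mimir_guides_obey_design_rules(self, designs):
        for name in MIMIR_TEMPLATE_NAMES:
            g = designs[name].guide
            assert g[1] == "U", name
            assert g[19] == "C", name

    def test_shared_loop(self, designs):
        loops = {designs[n].loop.bases for n in MIMIR_TEMPLATE_NAMES}
        assert loops == {MIR2022_SCAFFOLD.loop}

    def test_negative_control_generic_fold(self, fixtures):
        d = decode_template(fixtures["negative_control_template"], GENERIC_SCAFFOLD)
        a5, a3 = d.star.bases, d.guide.bases
        # arms mutually near-complementary under some small register offset
        from mimircraft.design import _score_fold

        assert _score_fold(a5, a3) >= 0.7 * min(len(a5), len(a3))

    def test_too_short_precursor_is_error(self, fixtures):
        from mimircraft.seqcore import make_template

        t = make_template(rna("G" + "ACGU" * 6), PROMOTERS["T7_STD"])  # 25 nt
        with pytest.raises(SeqError):
            decode_template(t, GENERIC_SCAFFOLD)

    def test_guide_arm_is_target_matching_arm(self, designs, mcherry):
        """For every mimiR row the annotated guide's best window on the
        reporter pairs the design seed, while the star's does not."""
        from mimircraft.design import _best_site

        for name in MIMIR_TEMPLATE_NAMES:
            d = designs[name]
            (g_seed, _), _ = _best_site(d.guide.bases, mcherry), None
            assert g_seed[0] == 1, name


class TestRoundTrip:
    def test_decode_assemble_identity_all_rows(self, fixtures, designs):
        for name, d in designs.items():
            rebuilt = assemble_design(d.guide, d.star, d.scaffold, d.promoter, loop=d.loop)
            assert rebuilt.template.bases == fixtures[name].bases, name

    def test_swapping_arms_changes_template(self, fixtures, designs):
        d = designs["full_match_template"]
        swapped = assemble_design(
            NucleicSeq(d.star.id, Alphabet.RNA, d.star.bases),
            NucleicSeq(d.guide.id, Alphabet.RNA, d.guide.bases),
            GENERIC_SCAFFOLD,
            d.promoter,
            loop=d.loop,
            strict=False,
        )
        assert swapped.template.bases != fixtures["full_match_template"].bases


class TestStar:
    def test_decoded_star_nonpairing_positions(self, designs):
        """Pair-breaking star positions are exactly the scaffold's designated
        set, for every decoded mimiR, under the calibrated register."""
        sc = MIR2022_SCAFFOLD
        for name in MIMIR_TEMPLATE_NAMES:
            d = designs[name]
            bad = {
                j
                for j in range(1, sc.star_length + 1)
                if (g := sc.star_partner(j)) is not None
                and (d.star[j], d.guide[g]) not in _WC
            }
            assert bad == set(sc.star_mismatch_positions), name

    def test_star_scaffold_constant_tail(self, designs):
        """The star 3'-terminal bases are scaffold-constant across designs."""
        full = designs["full_match_template"].star.bases
        seed = designs["seed_match_template"].star.bases
        assert full[-5:] == seed[-5:]

    def test_no_mismatch_positions_gives_exact_complement(self):
        from dataclasses import replace

        sc = replace(MIR2022_SCAFFOLD, star_mismatch_positions=frozenset())
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        star = derive_star(g, sc)
        for j in range(1, sc.star_length + 1):
            gp = sc.star_partner(j)
            if gp is not None:
                assert (star[j], g[gp]) in _WC

    def test_derived_star_pairs_outside_designated_positions(self):
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        star = derive_star(g)
        sc = MIR2022_SCAFFOLD
        for j in range(1, sc.star_length + 1):
            gp = sc.star_partner(j)
            if gp is None:
                continue
            paired = (star[j], g[gp]) in _WC
            assert paired == (j not in sc.star_mismatch_positions)


class TestTargetSites:
    def test_printed_site_is_a_candidate(self, designs, mcherry):
        d = designs["full_match_template"]
        sites = choose_target_site(mcherry, (750, 962))
        starts = [int(s.id.rsplit(":", 1)[1].split("-")[0]) for s in sites]
        assert d.site_start in starts
        assert all(s.bases.endswith("A") for s in sites)
        assert starts == sorted(starts)  # deterministic position-ascending order

    def test_no_window_ending_in_a(self):
        t = NucleicSeq("t", Alphabet.DNA, "G" * 40)
        assert choose_target_site(t) == []

    def test_region_shorter_than_guide(self, mcherry):
        with pytest.raises(SeqError):
            choose_target_site(mcherry, (1, 10))


class TestDeriveGuide:
    def test_near_full_differs_only_at_19(self, designs, mcherry):
        d = designs["full_match_template"]
        site = rna(mcherry.bases[d.site_start - 1 : d.site_end].replace("T", "U"), "site")
        g = derive_guide(site, Category.NEAR_FULL)
        ideal = revcomp(site).bases
        diffs = {i + 1 for i, (a, b) in enumerate(zip(g.bases, ideal)) if a != b}
        assert diffs <= {19}
        assert g.bases == d.guide.bases  # reproduces the printed guide

    def test_central_variants_differ_only_at_stated_position(self, designs, mcherry):
        d = designs["full_match_template"]
        site = rna(mcherry.bases[d.site_start - 1 : d.site_end].replace("T", "U"), "site")
        nf = derive_guide(site, Category.NEAR_FULL)
        for cat, pos in [(Category.CENTRAL_MM_10, 10), (Category.CENTRAL_MM_11, 11)]:
            g = derive_guide(site, cat)
            diffs = {i + 1 for i, (a, b) in enumerate(zip(g.bases, nf.bases)) if a != b}
            assert diffs == {pos}
            # substituted base is non-pairing and non-wobble against the site
            aln = align_duplex(g, site)
            assert pos in aln.mismatch_positions(wobble_counts_as_match=True)

    @pytest.mark.parametrize(
        "cat",
        [
            Category.NEAR_FULL,
            Category.SEED_ONLY,
            Category.SEED_SUPPLEMENTARY,
            Category.CENTRAL_MM_10,
            Category.CENTRAL_MM_11,
            Category.CENTRAL_MM_10_11,
        ],
    )
    def test_random_sites_classify_as_requested(self, cat):
        rng = random.Random(hash(cat.value) % 2**31)
        n = 0
        while n < 200:
            site = "".join(rng.choice("ACGU") for _ in range(20)) + "A"
            g = derive_guide(rna(site, f"s{n}"), cat)
            assert classify_alignment(align_duplex(g, rna(site))) is cat
            n += 1

    def test_site_without_terminal_a_rejected(self):
        with pytest.raises(SeqError, match="5'-U"):
            derive_guide(rna("G" * 21), Category.NEAR_FULL)


class TestEndToEnd:
    def test_design_mimic_on_printed_utr(self, mcherry):
        d = design_mimic(mcherry, Category.CENTRAL_MM_10, region=(750, 962))
        assert d.pattern is Category.CENTRAL_MM_10
        assert d.guide[1] == "U" and d.guide[19] == "C"
        # the emitted template decodes back to the same design
        d2 = decode_template(d.template, MIR2022_SCAFFOLD, mcherry)
        assert d2.guide.bases == d.guide.bases
        assert d2.pattern is Category.CENTRAL_MM_10
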