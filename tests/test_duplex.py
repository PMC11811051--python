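"""Pairing model, binding-mode classification and transcript scanning."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mimircraft import (
    Alphabet,
    Category,
    DEFAULT_PATTERN,
    NucleicSeq,
    PairState,
    PatternSpec,
    Region,
    SeqError,
    align_duplex,
    classify_alignment,
    cleavage_coordinate,
    pair_state,
    revcomp,
    scan_transcript,
)

rna = lambda s, id="x": NucleicSeq(id, Alphabet.RNA, s)
rna21 = st.text(alphabet="ACGU", min_size=21, max_size=21)


# independent brute-force pairing oracle used to freeze expected values
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "U"), ("U", "G")}


def oracle_states(guide: str, site: str):
    L = len(guide)
    out = []
    for i in range(L):
        p = (guide[i], site[L - 1 - i])
        out.append("WC" if p in _WC else "WOB" if p in _WOB else "MM")
    return out


class TestPairState:
    @pytest.mark.parametrize(
        "g,s,expected",
        [
            ("G", "C", PairState.WATSON_CRICK),
            ("A", "U", PairState.WATSON_CRICK),
            ("U", "A", PairState.WATSON_CRICK),
            ("C", "G", PairState.WATSON_CRICK),
            ("G", "U", PairState.WOBBLE),
            ("U", "G", PairState.WOBBLE),
            ("C", "C", PairState.MISMATCH),
            ("A", "G", PairState.MISMATCH),
            ("N", "A", PairState.MISMATCH),
        ],
    )
    def test_table(self, g, s, expected):
        assert pair_state(g, s) is expected


class TestAlignDuplex:
    def test_full_match_guide_vs_printed_site(self, designs, mcherry):
        d = designs["full_match_template"]
        site = rna(mcherry.bases[826:847].replace("T", "U"))
        aln = align_duplex(d.guide, site)
        assert aln.mismatch_positions() == frozenset({19})
        # agrees with the exhaustive per-position oracle
        assert [
            "MM" if s is not PairState.WATSON_CRICK else "WC" for s in aln.states
        ] == ["WC" if o == "WC" else "MM" for o in oracle_states(d.guide.bases, site.bases)]

    def test_guide_vs_own_revcomp(self):
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        assert align_duplex(g, revcomp(g)).mismatch_positions() == frozenset()

    def test_seed_guide_vs_full_site(self, designs, mcherry):
        d = designs["seed_match_template"]
        site = rna(mcherry.bases[826:847].replace("T", "U"))
        mm = align_duplex(d.guide, site).mismatch_positions()
        assert mm == frozenset(range(9, 22))  # matches exactly at 1-8

    def test_length_mismatch_is_error(self):
        with pytest.raises(SeqError):
            align_duplex(rna("ACGU"), rna("ACGUA"))


class TestClassify:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("full_match_template", Category.NEAR_FULL),
            ("seed_match_template", Category.SEED_ONLY),
            ("seed_supplementary_template", Category.SEED_SUPPLEMENTARY),
            ("mismatch_10_template", Category.CENTRAL_MM_10),
            ("mismatch_11_template", Category.CENTRAL_MM_11),
            ("mismatch_10_11_template", Category.CENTRAL_MM_10_11),
        ],
    )
    def test_decoded_guides_against_printed_site(self, designs, mcherry, name, expected):
        site = rna(mcherry.bases[826:847].replace("T", "U"))
        aln = align_duplex(designs[name].guide, site)
        assert classify_alignment(aln) is expected

    def test_perfect_duplex_is_near_full(self):
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        assert classify_alignment(align_duplex(g, revcomp(g))) is Category.NEAR_FULL

    def test_seed_broken_is_none(self):
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        site = list(revcomp(g).bases)
        # break guide positions 3 and 15 (site positions 19 and 7)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for gpos in (3, 15):
            spos = 21 - gpos  # 0-based site index of the base pairing gpos
            site[spos] = g.bases[gpos - 1]  # identical base never pairs
        cat = classify_alignment(align_duplex(g, rna("".join(site))))
        assert cat is Category.NONE

    def test_wobble_flag(self):
        # G:U wobble inside the seed (guide position 5)
        g = rna("AAAAGAAAAAAAAAAAAAAAA")
        site = list(revcomp(g).bases)
        site[21 - 5] = "U"  # base pairing guide position 5
        aln = align_duplex(g, rna("".join(site)))
        strict = classify_alignment(aln)
        lenient = classify_alignment(aln, PatternSpec(wobble_counts_as_match=True))
        assert 5 in aln.mismatch_positions(False)
        assert 5 not in aln.mismatch_positions(True)
        assert lenient is Category.NEAR_FULL
        assert strict is not Category.NEAR_FULL

    @given(rna21, rna21)
    @settings(max_examples=400, deadline=None)
    def test_total_and_deterministic(self, g, s):
        aln = align_duplex(rna(g), rna(s))
        c1 = classify_alignment(aln)
        c2 = classify_alignment(aln)
        assert c1 is c2 and isinstance(c1, Category)

    @given(rna21, st.integers(13, 16))
    @settings(max_examples=200, deadline=None)
    def test_supplementary_mismatch_never_promotes(self, g, pos):
        """Breaking a supplementary pair can demote SEED_SUPPLEMENTARY to
        SEED_ONLY or NONE, never promote it to NEAR_FULL."""
        guide = rna(g)
        site = list(revcomp(guide).bases)
        before = classify_alignment(align_duplex(guide, rna("".join(site))))
        site[21 - pos] = g[pos - 1]  # identical base: guaranteed non-pairing
        after = classify_alignment(align_duplex(guide, rna("".join(site))))
        if before is Category.SEED_SUPPLEMENTARY:
            assert after in {Category.SEED_ONLY, Category.NONE}
        assert not (before is Category.SEED_SUPPLEMENTARY and after is Category.NEAR_FULL)


def brute_force_scan(guide: str, transcript: str, mode: str):
    """Per-window align+classify applied exhaustively, then greedy
    left-to-right overlap resolution -- the independent scan oracle."""
    L = len(guide)
    wins = []
    for s in range(len(transcript) - L + 1):
        w = transcript[s : s + L]
        states = oracle_states(guide, w)
        cat = classify_alignment(align_duplex(rna(guide), rna(w)))
        if mode == "seed":
            keep = all(states[i] == "WC" for i in range(8))
        elif mode == "near_full":
            keep = cat is Category.NEAR_FULL
        else:
            keep = cat is not Category.NONE
        if keep:
            wins.append((s + 1, s + L, cat))
    out, last_end = [], 0
    for w in wins:
        if w[0] > last_end:
            out.append(w)
            last_end = w[1]
    return out


class TestScan:
    def test_three_seed_sites_on_printed_construct(self, designs, mcherry):
        hits = scan_transcript(designs["seed_match_template"].guide, mcherry, mode="seed")
        assert len(hits) == 3
        starts = [h.start for h in hits]
        assert starts == sorted(starts)
        # disjoint and identically spaced
        assert all(a.end < b.start for a, b in zip(hits, hits[1:]))
        assert len({b.start - a.start for a, b in zip(hits, hits[1:])}) == 1

    def test_exact_revcomp_single_hit(self):
        g = rna("UAUGUUUCAGGUUCAGGGCGA")
        hits = scan_transcript(g, revcomp(g), mode="all")
        assert len(hits) == 1
        assert hits[0].category is Category.NEAR_FULL
        assert hits[0].mismatch_positions == frozenset()

    def test_no_seed_motif_no_hits(self, designs):
        rng = random.Random(11)
        g = designs["seed_match_template"].guide
        motif = revcomp(rna(g.bases[:8])).bases
        while True:
            t = "".join(rng.choice("ACGU") for _ in range(1000))
            if motif not in t:  # substring-search oracle for motif absence
                break
        assert scan_transcript(g, rna(t, "t"), mode="seed") == []

    @pytest.mark.parametrize("mode", ["seed", "near_full", "all"])
    def test_equivalence_with_brute_force(self, mode):
        rng = random.Random(23)
        g = "".join(rng.choice("ACGU") for _ in range(21))
        t = "".join(rng.choice("ACGU") for _ in range(1020))  # 1000 windows
        # embed a few guaranteed sites
        comp = revcomp(rna(g)).bases
        t = t[:100] + comp + t[121:600] + comp + t[621:]
        hits = scan_transcript(rna(g), rna(t, "t"), mode=mode)
        expected = brute_force_scan(g, t, mode)
        assert [(h.start, h.end, h.category) for h in hits] == expected

    def test_region_annotation(self, designs, mcherry):
        regions = [(1, 38, Region.UTR5), (39, 749, Region.CDS), (750, 962, Region.UTR3)]
        hits = scan_transcript(
            designs["seed_match_template"].guide, mcherry, annotation=regions, mode="seed"
        )
        assert all(h.region is Region.UTR3 for h in hits)

    def test_guide_longer_than_transcript(self):
        with pytest.raises(SeqError):
            scan_transcript(rna("A" * 22), rna("ACGU"))


class TestCleavage:
    def test_near_full_coordinate_arithmetic(self):
        # 21-nt guide site embedded so the window starts at position 100
        rng = random.Random(5)
        g = rna("".join(rng.choice("ACGU") for _ in range(21)))
        t = "".join(rng.choice("ACGU") for _ in range(99)) + revcomp(g).bases + "ACGU"
        hits = scan_transcript(g, rna(t, "t"), mode="near_full")
        (hit,) = [h for h in hits if h.start == 100]
        assert cleavage_coordinate(hit) == 110  # start + L - 11

    def test_central_mismatch_absent(self, designs, mcherry):
        for name in ("mismatch_10_template", "mismatch_11_template", "mismatch_10_11_template"):
            hits = scan_transcript(designs[name].guide, mcherry, mode="all")
            central = [h for h in hits if h.category.value.startswith("CENTRAL")]
            assert central and all(cleavage_coordinate(h) is None for h in central)
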