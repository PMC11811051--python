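"""Design of miRNA mimics on an endogenous hairpin scaffold.

The mimics are built on the stem-loop of Nematostella miR-2022: the guide
occupies the 3' arm of the precursor, the star strand the 5' arm, with the
endogenous loop between them.  The designed duplex carries 2-nt 3' overhangs:
under the calibrated register, star position j pairs guide position
(guide_length - 1 - j), i.e. 20 - j for 21-nt arms.  Design rules baked into
the scaffold:

* the target window is chosen so the guide starts with a 5' U (the window
  ends with A on the sense strand), matching native guide-strand bias;
* guide position 19 is always C -- the precursor's first transcribed base
  must be G for T7, and that base (star position 1) pairs guide 19;
* pair-breaking substitutions are placed in the star at positions 8, 9 and
  17 (star's own 5'->3' numbering) so the duplex is asymmetric and the
  intended strand is loaded.

This module both designs mimics from a target transcript and decodes ordered
DNA templates back into annotated parts (guide, star, loop, site).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .duplex import (
    Category,
    DuplexAlignment,
    PairState,
    PatternSpec,
    DEFAULT_PATTERN,
    align_duplex,
    classify_alignment,
    pair_state,
)
from .seqcore import (
    Alphabet,
    NucleicSeq,
    PromoterSpec,
    PROMOTERS,
    SeqError,
    dna_to_rna,
    make_template,
    revcomp,
    rna_to_dna,
    transcribe_template,
)

__all__ = [
    "Scaffold",
    "MimirDesign",
    "MIR2022_SCAFFOLD",
    "GENERIC_SCAFFOLD",
    "decode_template",
    "choose_target_site",
    "derive_guide",
    "derive_star",
    "assemble_design",
]

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


@dataclass(frozen=True)
class Scaffold:
    """A hairpin scaffold: loop, arm order, duplex register and design rules.

    ``register_offset`` r defines the duplex register: star position j pairs
    guide position (guide_length + 1 - j + r).  r = -2 gives the canonical
    2-nt 3' overhangs.  Star positions with no guide partner under the
    register (the star 3' overhang) take their bases from ``star_tail``.
    ``star_mismatch_positions`` are the star positions (star's own 5'->3'
    numbering) given pair-breaking substitutions against the guide; the
    published design additionally lists star position 1, which under this
    register pairs the guide's fixed C19 and is a change only relative to
    the unmodified target complement, so it needs no substitution here.
    """

    name: str
    loop: str  # RNA
    arm_order: str = "STAR_5PRIME_GUIDE_3PRIME"
    star_mismatch_positions: frozenset[int] = frozenset({8, 9, 17})
    fixed_guide_bases: Mapping[int, str] = field(default_factory=lambda: {19: "C"})
    guide_5prime_base: str = "U"
    guide_length: int = 21
    register_offset: int = -2
    star_tail: str = "UG"  # star 3'-overhang bases, 5'->3'

    def __post_init__(self) -> None:
        if not self.loop and self.name != "generic":
            raise ValueError("scaffold loop must be non-empty")
        if self.arm_order not in {"STAR_5PRIME_GUIDE_3PRIME", "GUIDE_5PRIME_STAR_3PRIME"}:
            raise ValueError(f"unknown arm_order {self.arm_order!r}")
        bad = [p for p in self.star_mismatch_positions if not 1 <= p <= self.star_length]
        if bad:
            raise ValueError(f"star mismatch positions {bad} outside star")

    @property
    def star_length(self) -> int:
        return self.guide_length

    def star_partner(self, star_pos: int) -> int | None:
        """Guide position paired by star position ``star_pos``, or None."""
        g = self.guide_length + 1 - star_pos + self.register_offset
        return g if 1 <= g <= self.guide_length else None


#: The miR-2022-derived scaffold, loop decoded from the packaged templates.
MIR2022_SCAFFOLD = Scaffold(name="miR-2022", loop="GUUGUCA")

#: Generic mode: no known loop (decoding folds the precursor instead) and no
#: mimiR-specific base constraints.
GENERIC_SCAFFOLD = Scaffold(
    name="generic", loop="", fixed_guide_bases={}, star_mismatch_positions=frozenset()
)


@dataclass(frozen=True)
class MimirDesign:
    """A complete designed (or decoded) mimic."""

    guide: NucleicSeq  # RNA
    star: NucleicSeq  # RNA
    loop: NucleicSeq  # RNA
    precursor: NucleicSeq  # RNA
    template: NucleicSeq  # ordered ssDNA
    promoter: PromoterSpec
    scaffold: Scaffold
    pattern: Category | None = None
    target_id: str | None = None
    site_start: int | None = None
    site_end: int | None = None

    def __post_init__(self) -> None:
        if self.scaffold.arm_order == "STAR_5PRIME_GUIDE_3PRIME":
            expected = self.star.bases + self.loop.bases + self.guide.bases
        else:
            expected = self.guide.bases + self.loop.bases + self.star.bases
        if self.precursor.bases != expected:
            raise SeqError("precursor is not the concatenation of arms and loop")


# ---------------------------------------------------------------------------
# decoding printed templates

def _score_fold(arm5: str, arm3: str, offsets: range = range(-3, 4)) -> int:
    """Best antiparallel Watson-Crick pair count between two arms."""
    best = 0
    n5, n3 = len(arm5), len(arm3)
    for off in offsets:
        score = 0
        for j in range(1, n5 + 1):
            k = n3 + 1 - j + off
            if 1 <= k <= n3 and (arm5[j - 1], arm3[k - 1]) in {
                ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")
            }:
                score += 1
        best = max(best, score)
    return best


def _split_precursor(precursor: str, scaffold: Scaffold) -> tuple[str, str, str]:
    """Split precursor RNA into (5' arm, loop, 3' arm)."""
    L = scaffold.guide_length
    if scaffold.loop:
        n = precursor.count(scaffold.loop)
        if n == 1:
            i = precursor.index(scaffold.loop)
            arm5, arm3 = precursor[:i], precursor[i + len(scaffold.loop):]
            if len(arm5) >= L and len(arm3) >= L:
                return arm5, scaffold.loop, arm3
        elif n > 1:
            raise SeqError("scaffold loop occurs more than once in precursor; ambiguous")
        # loop absent: fall through to generic fold
    # generic fold: try all loop windows leaving both arms >= guide_length,
    # keep the most mutually complementary arms
    best: tuple[int, tuple[str, str, str]] | None = None
    N = len(precursor)
    for i in range(L, N - L + 1):  # loop start (0-based)
        for j in range(i + 3, min(i + 13, N - L + 1)):  # loop end (exclusive)
            arm5, loop, arm3 = precursor[:i], precursor[i:j], precursor[j:]
            score = _score_fold(arm5, arm3)
            if best is None or score > best[0]:
                best = (score, (arm5, loop, arm3))
    if best is None:
        raise SeqError(
            f"precursor of length {N} cannot fold into two arms of >= {L} nt"
        )
    return best[1]


def decode_template(
    template: NucleicSeq,
    scaffold: Scaffold = MIR2022_SCAFFOLD,
    target: NucleicSeq | None = None,
    promoters: Sequence[PromoterSpec] | None = None,
    spec: PatternSpec = DEFAULT_PATTERN,
) -> MimirDesign:
    """Decode an ordered DNA template back into an annotated mimic design.

    The precursor is recovered via the promoter convention, split into
    5' arm / loop / 3' arm (by the scaffold loop, or by the best hairpin
    fold in generic mode), and arms are assigned guide/star per the
    scaffold's arm order.  When a target transcript is supplied, the guide
    assignment is verified against it -- the guide is the arm whose
    best-matching window on the target has fewer mismatches -- and the site
    is annotated and classified.
    """
    from .seqcore import DEFAULT_PROMOTERS

    prom, precursor = transcribe_template(template, promoters or DEFAULT_PROMOTERS)
    arm5, loop, arm3 = _split_precursor(precursor.bases, scaffold)
    if scaffold.arm_order == "STAR_5PRIME_GUIDE_3PRIME":
        guide_b, star_b = arm3, arm5
    else:
        guide_b, star_b = arm5, arm3

    base = template.id
    design = MimirDesign(
        guide=NucleicSeq(f"{base}.guide", Alphabet.RNA, guide_b),
        star=NucleicSeq(f"{base}.star", Alphabet.RNA, star_b),
        loop=NucleicSeq(f"{base}.loop", Alphabet.RNA, loop),
        precursor=replace(precursor, id=f"{base}.precursor"),
        template=template,
        promoter=prom,
        scaffold=scaffold,
    )
    if target is not None:
        design = _annotate_against_target(design, target, spec)
    return design


_WC_SET = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _best_site(arm: str, target: NucleicSeq) -> tuple[tuple[int, int], int]:
    """Best-matching window of an arm on a target.

    Windows are ranked seed-first: (design seed 1-8 fully paired, total
    Watson-Crick pairs), leftmost wins ties.  Returns (score, 1-based start).
    """
    t = dna_to_rna(target).bases
    L = len(arm)
    best_score, best_start = (-1, -1), 0
    for s in range(len(t) - L + 1):
        w = t[s : s + L]
        wc = [(arm[i], w[L - 1 - i]) in _WC_SET for i in range(L)]
        score = (int(all(wc[:8])), sum(wc))
        if score > best_score:
            best_score, best_start = score, s + 1
    return best_score, best_start


def _annotate_against_target(
    design: MimirDesign, target: NucleicSeq, spec: PatternSpec
) -> MimirDesign:
    score_g, start_g = _best_site(design.guide.bases, target)
    score_s, start_s = _best_site(design.star.bases, target)
    if score_s > score_g:
        # the 'star' arm is the one matching the transcript: swap assignment
        design = replace(
            design,
            guide=replace(design.star, id=design.guide.id),
            star=replace(design.guide, id=design.star.id),
        )
        start_g = start_s
    L = len(design.guide)
    site = NucleicSeq(
        f"{target.id}:{start_g}-{start_g + L - 1}",
        Alphabet.RNA,
        dna_to_rna(target).slice1(start_g, start_g + L - 1),
    )
    cat = classify_alignment(align_duplex(design.guide, site), spec)
    return replace(
        design,
        pattern=cat,
        target_id=target.id,
        site_start=start_g,
        site_end=start_g + L - 1,
    )


# ---------------------------------------------------------------------------
# forward design

def choose_target_site(
    transcript: NucleicSeq,
    region: tuple[int, int] | None = None,
    scaffold: Scaffold = MIR2022_SCAFFOLD,
) -> list[NucleicSeq]:
    """Enumerate candidate guide-length target windows in a region.

    A window supports a 5'-U guide iff it ends with A on the sense strand.
    Candidates are returned in ascending position order (the deterministic
    ranking); ids carry the 1-based coordinates.
    """
    t = dna_to_rna(transcript)
    lo, hi = region if region is not None else (1, len(t))
    if not 1 <= lo <= hi <= len(t):
        raise SeqError(f"region [{lo},{hi}] outside transcript of length {len(t)}")
    L = scaffold.guide_length
    if hi - lo + 1 < L:
        raise SeqError(f"region [{lo},{hi}] shorter than guide length {L}")
    out = []
    for start in range(lo, hi - L + 2):
        window = t.slice1(start, start + L - 1)
        if window.endswith("A"):
            out.append(
                NucleicSeq(f"{transcript.id}:{start}-{start + L - 1}", Alphabet.RNA, window)
            )
    return out


def _nonpairing_base(opposing: str) -> str:
    """A base forming neither a Watson-Crick pair nor a G:U wobble with
    ``opposing``.  The base identical to the opposing base always qualifies
    (A:A, C:C, G:G, U:U are all non-pairing), and for the published
    central-mismatch guides it reproduces the printed base (C facing C)."""
    return opposing


_CATEGORY_RULES: dict[Category, tuple[frozenset[int], frozenset[int]]] = {
    # category -> (positions forced to match, positions forced to mismatch)
    Category.NEAR_FULL: (frozenset(), frozenset()),
    Category.CENTRAL_MM_10: (frozenset(), frozenset({10})),
    Category.CENTRAL_MM_11: (frozenset(), frozenset({11})),
    Category.CENTRAL_MM_10_11: (frozenset(), frozenset({10, 11})),
    Category.SEED_ONLY: (
        frozenset(range(1, 9)),
        frozenset(p for p in range(9, 22) if p != 19),
    ),
    Category.SEED_SUPPLEMENTARY: (
        frozenset(range(1, 9)) | frozenset(range(13, 17)),
        frozenset(p for p in range(9, 22) if p not in {13, 14, 15, 16, 19}),
    ),
}


def derive_guide(
    site: NucleicSeq,
    category: Category,
    scaffold: Scaffold = MIR2022_SCAFFOLD,
    spec: PatternSpec = DEFAULT_PATTERN,
) -> NucleicSeq:
    """Derive the guide variant for a target window and a requested mode.

    Starts from the exact reverse complement of the site, applies the fixed
    guide bases (position 19 -> C), then converts the category's designed
    mismatch positions to non-pairing bases.  The returned guide satisfies
    ``classify_alignment(align_duplex(guide, site), spec) == category`` and
    starts with the scaffold's required 5' base.
    """
    site = dna_to_rna(site)
    L = scaffold.guide_length
    if len(site) != L:
        raise SeqError(f"site length {len(site)} != guide length {L}")
    if category not in _CATEGORY_RULES:
        raise ValueError(f"cannot derive a guide for category {category}")
    guide = list(revcomp(site).bases)  # guide position i pairs site L+1-i
    for pos, b in scaffold.fixed_guide_bases.items():
        guide[pos - 1] = b
    _, force_mm = _CATEGORY_RULES[category]
    for pos in force_mm:
        opposing = site.bases[L - pos]  # site position L+1-pos, 0-based L-pos
        guide[pos - 1] = _nonpairing_base(opposing)
    g = NucleicSeq(f"{site.id}.{category.value.lower()}.guide", Alphabet.RNA, "".join(guide))
    if g.bases[0] != scaffold.guide_5prime_base:
        raise SeqError(
            f"site {site.id!r} does not support a 5'-{scaffold.guide_5prime_base} guide "
            "(window must end with A)"
        )
    got = classify_alignment(align_duplex(g, site), spec)
    if got is not category:
        raise SeqError(f"derived guide classifies as {got}, requested {category}")
    return g


def derive_star(guide: NucleicSeq, scaffold: Scaffold = MIR2022_SCAFFOLD) -> NucleicSeq:
    """Derive the star strand: the guide's duplex partner under the register,
    with pair-breaking substitutions at the scaffold's star positions.

    Star positions without a guide partner (the 3' overhang) come from the
    scaffold's ``star_tail``.
    """
    guide = dna_to_rna(guide)
    if len(guide) != scaffold.guide_length:
        raise SeqError(f"guide length {len(guide)} != scaffold guide length")
    star: list[str] = []
    tail = iter(scaffold.star_tail)
    for j in range(1, scaffold.star_length + 1):
        g = scaffold.star_partner(j)
        if g is None:
            star.append(next(tail, "U"))
            continue
        partner = guide.bases[g - 1]
        if j in scaffold.star_mismatch_positions:
            star.append(_nonpairing_base(partner))
        else:
            star.append(_RNA_COMP[partner])
    return NucleicSeq(f"{guide.id}.star", Alphabet.RNA, "".join(star))


def assemble_design(
    guide: NucleicSeq,
    star: NucleicSeq,
    scaffold: Scaffold = MIR2022_SCAFFOLD,
    promoter: PromoterSpec = PROMOTERS["T7_STD"],
    loop: NucleicSeq | None = None,
    pattern: Category | None = None,
    target_id: str | None = None,
    site_start: int | None = None,
    site_end: int | None = None,
    strict: bool = True,
) -> MimirDesign:
    """Assemble arms and loop into a precursor and its ordered DNA template.

    ``strict`` enforces the promoter's +1 requirement on the precursor start.
    """
    guide, star = dna_to_rna(guide), dna_to_rna(star)
    loop_seq = dna_to_rna(loop).bases if loop is not None else scaffold.loop
    if not loop_seq:
        raise SeqError("no loop sequence available (generic scaffold needs an explicit loop)")
    if scaffold.arm_order == "STAR_5PRIME_GUIDE_3PRIME":
        prec_b = star.bases + loop_seq + guide.bases
    else:
        prec_b = guide.bases + loop_seq + star.bases
    for pos, b in scaffold.fixed_guide_bases.items():
        if guide[pos] != b:
            raise SeqError(f"guide position {pos} is {guide[pos]}, scaffold fixes it to {b}")
    precursor = NucleicSeq(f"{guide.id}.precursor", Alphabet.RNA, prec_b)
    template = make_template(precursor, promoter, strict=strict)
    return MimirDesign(
        guide=guide,
        star=star,
        loop=NucleicSeq(f"{guide.id}.loop", Alphabet.RNA, loop_seq),
        precursor=precursor,
        template=replace(template, id=f"{guide.id}.template"),
        promoter=promoter,
        scaffold=scaffold,
        pattern=pattern,
        target_id=target_id,
        site_start=site_start,
        site_end=site_end,
    )


def design_mimic(
    target: NucleicSeq,
    category: Category,
    region: tuple[int, int] | None = None,
    scaffold: Scaffold = MIR2022_SCAFFOLD,
    promoter: PromoterSpec = PROMOTERS["T7_STD"],
    spec: PatternSpec = DEFAULT_PATTERN,
    site_rank: int = 0,
) -> MimirDesign:
    """End-to-end design: pick a target site, derive guide and star, assemble.

    ``site_rank`` selects among candidate windows (position-ascending order).
    """
    candidates = choose_target_site(target, region, scaffold)
    if not candidates:
        raise SeqError("no candidate window supports a 5'-U guide in the region")
    if not 0 <= site_rank < len(candidates):
        raise SeqError(f"site_rank {site_rank} out of range (0..{len(candidates) - 1})")
    site = candidates[site_rank]
    start = int(site.id.rsplit(":", 1)[1].split("-")[0])
    guide = derive_guide(site, category, scaffold, spec)
    star = derive_star(guide, scaffold)
    return assemble_design(
        guide,
        star,
        scaffold,
        promoter,
        pattern=category,
        target_id=target.id,
        site_start=start,
        site_end=start + scaffold.guide_length - 1,
    )
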