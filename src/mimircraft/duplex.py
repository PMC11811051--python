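"""Antiparallel guide-target pairing, site scanning and mode classification.

A guide of length L laid antiparallel on a same-length target window pairs
guide position i (counted 1..L from the guide 5' end) with window position
L+1-i (window given 5'->3' on the transcript sense strand).  The model is
ungapped: the designed mimics contain no bulges.

Complementarity modes follow the plant-vs-bilaterian vocabulary: near-full
complementarity (cleavage-competent), seed-only (bilaterian canonical site,
guide positions 2-8), seed plus supplementary (3' positions 13-16), and
central mismatches at the cleavage site (positions 10/11).  G:U wobble pairs
are counted as mismatches by default; the designed guides avoid wobbles at
their engineered positions, and the conservative treatment is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .seqcore import Alphabet, NucleicSeq, SeqError, dna_to_rna

__all__ = [
    "PairState",
    "Category",
    "Region",
    "PatternSpec",
    "DuplexAlignment",
    "SiteHit",
    "pair_state",
    "align_duplex",
    "classify_alignment",
    "scan_transcript",
    "cleavage_coordinate",
]


class PairState(Enum):
    WATSON_CRICK = "WATSON_CRICK"
    WOBBLE = "WOBBLE"
    MISMATCH = "MISMATCH"


class Category(str, Enum):
    NEAR_FULL = "NEAR_FULL"
    SEED_ONLY = "SEED_ONLY"
    SEED_SUPPLEMENTARY = "SEED_SUPPLEMENTARY"
    CENTRAL_MM_10 = "CENTRAL_MM_10"
    CENTRAL_MM_11 = "CENTRAL_MM_11"
    CENTRAL_MM_10_11 = "CENTRAL_MM_10_11"
    NONE = "NONE"


class Region(str, Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"
    UNANNOTATED = "UNANNOTATED"


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_state(guide_base: str, site_base: str) -> PairState:
    """Pair state of a single guide base against the sense-strand site base.

    N against anything is a MISMATCH.
    """
    pair = (guide_base.upper(), site_base.upper())
    if pair in _WC:
        return PairState.WATSON_CRICK
    if pair in _WOBBLE:
        return PairState.WOBBLE
    return PairState.MISMATCH


@dataclass(frozen=True)
class PatternSpec:
    """Positional complementarity rules defining the binding modes.

    All positions are 1-based guide positions.  ``seed_interval`` (2-8,
    length 7) is the classification seed; ``design_seed_interval`` (1-8) is
    the broader interval the designed seed-match guides pair, used by
    seed-mode scanning.  ``require_position1`` additionally demands guide
    position 1 pairing for the seed classes, matching the designed guides
    whose 5'-terminal U pairs an A on the target.  ``fixed_bases`` marks
    design-constrained guide positions (19 -> C, an in vitro transcription
    requirement) that are excluded from disqualifying near-full
    classification.
    """

    seed_interval: tuple[int, int] = (2, 8)
    design_seed_interval: tuple[int, int] = (1, 8)
    supplementary_interval: tuple[int, int] = (13, 16)
    central_positions: frozenset[int] = frozenset({10, 11})
    fixed_bases: Mapping[int, str] = field(default_factory=lambda: {19: "C"})
    wobble_counts_as_match: bool = False
    near_full_max_mismatches: int = 2
    require_position1: bool = True
    required_match: frozenset[int] = frozenset()
    required_mismatch: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.required_match & self.required_mismatch:
            raise ValueError("required_match and required_mismatch overlap")

    def validate_for_length(self, guide_len: int) -> None:
        pts = [*self.seed_interval, *self.design_seed_interval,
               *self.supplementary_interval, *self.central_positions,
               *self.fixed_bases, *self.required_match, *self.required_mismatch]
        bad = [p for p in pts if not 1 <= p <= guide_len]
        if bad:
            raise ValueError(f"positions {sorted(set(bad))} outside [1, {guide_len}]")


DEFAULT_PATTERN = PatternSpec()


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position pair states of a guide against one target window.

    ``site`` is the transcript window, sense strand 5'->3'; guide position i
    annotates its pairing with site position L+1-i.
    """

    guide: NucleicSeq
    site: NucleicSeq
    states: tuple[PairState, ...]

    def __post_init__(self) -> None:
        if not (len(self.guide) == len(self.site) == len(self.states)):
            raise SeqError("guide, site and states must share one length")

    def __len__(self) -> int:
        return len(self.states)

    def state(self, guide_pos: int) -> PairState:
        return self.states[guide_pos - 1]

    def mismatch_positions(self, wobble_counts_as_match: bool = False) -> frozenset[int]:
        ok = {PairState.WATSON_CRICK}
        if wobble_counts_as_match:
            ok.add(PairState.WOBBLE)
        return frozenset(i + 1 for i, s in enumerate(self.states) if s not in ok)


def align_duplex(guide: NucleicSeq, site: NucleicSeq) -> DuplexAlignment:
    """Ungapped antiparallel alignment of equal-length guide and site (RNA)."""
    guide = dna_to_rna(guide)
    site = dna_to_rna(site)
    if len(guide) != len(site):
        raise SeqError(f"guide length {len(guide)} != site length {len(site)}")
    L = len(guide)
    states = tuple(pair_state(guide.bases[i], site.bases[L - 1 - i]) for i in range(L))
    return DuplexAlignment(guide, site, states)


def _interval_matched(aln: DuplexAlignment, interval: tuple[int, int], mm: frozenset[int]) -> bool:
    lo, hi = interval
    return not any(lo <= p <= hi for p in mm)


def classify_alignment(aln: DuplexAlignment, spec: PatternSpec = DEFAULT_PATTERN) -> Category:
    """Deterministic, mutually exclusive binding-mode classification.

    Precedence: NEAR_FULL, then the central-mismatch classes, then
    SEED_SUPPLEMENTARY, then SEED_ONLY, else NONE.  Mismatches at fixed-base
    positions (the designed C19) never disqualify NEAR_FULL and are not
    counted as central deviations.
    """
    spec.validate_for_length(len(aln))
    mm = aln.mismatch_positions(spec.wobble_counts_as_match)
    fixed = frozenset(spec.fixed_bases)
    non_fixed_mm = mm - fixed
    central = spec.central_positions

    seed_ok = _interval_matched(aln, spec.seed_interval, mm) and (
        not spec.require_position1 or 1 not in mm
    )

    # (1) near-full: few mismatches overall, none of the non-fixed ones in
    # the seed or at the cleavage site
    if len(mm) <= spec.near_full_max_mismatches and not any(
        (spec.seed_interval[0] <= p <= spec.seed_interval[1]) or p in central
        for p in non_fixed_mm
    ):
        return Category.NEAR_FULL

    # (2) central-mismatch variants: the only non-fixed deviations sit at
    # the stated central positions
    if non_fixed_mm and non_fixed_mm <= central:
        if non_fixed_mm == central:
            return Category.CENTRAL_MM_10_11
        (pos,) = non_fixed_mm
        return Category.CENTRAL_MM_10 if pos == min(central) else Category.CENTRAL_MM_11

    # (3)/(4) seed classes
    if seed_ok:
        supp_ok = _interval_matched(aln, spec.supplementary_interval, mm)
        if supp_ok and any(p in mm for p in central):
            return Category.SEED_SUPPLEMENTARY
        if not supp_ok:
            return Category.SEED_ONLY

    return Category.NONE


@dataclass(frozen=True)
class SiteHit:
    """One classified guide-binding window on a transcript.

    ``start``/``end`` are 1-based inclusive transcript coordinates of the
    guide-length window.  ``seed_start``/``seed_end`` bound the sub-window
    pairing the design seed interval (guide positions 1-8 by default) -- the
    'seed site' proper, used when measuring inter-site spacing.
    ``predicted_cleavage`` is the transcript coordinate of the phosphodiester
    bond 5' side (the bond lies between it and the following base) opposite
    guide positions 10-11; absent unless both central positions pair.
    """

    transcript_id: str
    start: int
    end: int
    region: Region
    category: Category
    mismatch_positions: frozenset[int]
    predicted_cleavage: int | None
    seed_start: int
    seed_end: int
    alignment: DuplexAlignment

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")


RegionMap = Sequence[tuple[int, int, Region]]  # 1-based inclusive intervals


def _annotate(start: int, end: int, annotation: RegionMap | None) -> Region:
    if not annotation:
        return Region.UNANNOTATED
    best, overlap = Region.UNANNOTATED, 0
    for lo, hi, reg in annotation:
        ov = min(end, hi) - max(start, lo) + 1
        if ov > overlap:
            best, overlap = Region(reg), ov
    return best


def _window_hit(
    guide: NucleicSeq,
    transcript: NucleicSeq,
    start: int,
    spec: PatternSpec,
    annotation: RegionMap | None,
) -> SiteHit:
    L = len(guide)
    window = NucleicSeq(
        f"{transcript.id}:{start}-{start + L - 1}",
        transcript.alphabet,
        transcript.slice1(start, start + L - 1),
    )
    aln = align_duplex(guide, window)
    cat = classify_alignment(aln, spec)
    cleav = None
    if aln.state(10) is PairState.WATSON_CRICK and aln.state(11) is PairState.WATSON_CRICK:
        cleav = start + L - 11
    lo, hi = spec.design_seed_interval
    return SiteHit(
        transcript_id=transcript.id,
        start=start,
        end=start + L - 1,
        region=_annotate(start, start + L - 1, annotation),
        category=cat,
        mismatch_positions=aln.mismatch_positions(spec.wobble_counts_as_match),
        predicted_cleavage=cleav,
        seed_start=start + L - hi,
        seed_end=start + L - lo,
        alignment=aln,
    )


def scan_transcript(
    guide: NucleicSeq,
    transcript: NucleicSeq,
    annotation: RegionMap | None = None,
    spec: PatternSpec = DEFAULT_PATTERN,
    mode: str = "seed",
) -> list[SiteHit]:
    """Slide a guide-length window over a transcript and report binding sites.

    Modes: ``seed`` keeps windows fully Watson-Crick matched across the
    design seed interval (guide positions 1-8 by default); ``near_full``
    keeps NEAR_FULL-classified windows; ``all`` keeps every window whose
    category is not NONE.  Overlapping candidate windows are resolved
    greedily left to right, so a transcript base belongs to at most one
    reported site.
    """
    if mode not in {"seed", "near_full", "all"}:
        raise ValueError(f"unknown scan mode {mode!r}")
    guide = dna_to_rna(guide)
    transcript = dna_to_rna(transcript)
    L = len(guide)
    if L > len(transcript):
        raise SeqError("guide longer than transcript")
    spec.validate_for_length(L)

    lo, hi = spec.design_seed_interval
    hits: list[SiteHit] = []
    last_end = 0
    for start in range(1, len(transcript) - L + 2):
        if start <= last_end:  # greedy non-overlap
            continue
        hit = _window_hit(guide, transcript, start, spec, annotation)
        if mode == "seed":
            keep = all(
                hit.alignment.state(p) is PairState.WATSON_CRICK for p in range(lo, hi + 1)
            )
        elif mode == "near_full":
            keep = hit.category is Category.NEAR_FULL
        else:
            keep = hit.category is not Category.NONE
        if keep:
            hits.append(hit)
            last_end = hit.end
    return hits


def cleavage_coordinate(hit: SiteHit) -> int | None:
    """Transcript coordinate of the predicted cleavage bond, if any.

    The bond sits between the bases pairing guide positions 11 and 10, i.e.
    between transcript positions start+L-11 and start+L-10; the returned
    value is the 5'-side coordinate.  Absent when either central position is
    not Watson-Crick paired.
    """
    return hit.predicted_cleavage
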