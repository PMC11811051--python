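"""Reporter mRNA constructs: promoter + kozak + CDS + engineered 3' UTR.

The reporter transcripts carry, in their 3' UTR, a configurable number of
8-nt seed sites at fixed spacing (the published constructs use three sites
with exactly 21 intervening bases) plus one full-length site for a
near-fully matching mimic.  "N bases apart" is measured as the count of
bases strictly between the end of one seed site and the start of the next,
with the seed site defined as the 8-nt region pairing guide positions 1-8;
both inter-site gaps of the printed construct equal 21 under this
convention.

Poly(A) handling distinguishes an encoded tail (A's present in the template,
as in the sfGFP control) from enzymatic post-transcriptional
polyadenylation, which leaves no trace in the sequence and is recorded as
metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from .duplex import (
    Category,
    PatternSpec,
    DEFAULT_PATTERN,
    Region,
    SiteHit,
    scan_transcript,
)
from .fixtures import KOZAK_EF1A
from .seqcore import (
    Alphabet,
    NucleicSeq,
    PromoterSpec,
    PROMOTERS,
    SeqError,
    dna_to_rna,
    revcomp,
    rna_to_dna,
)

__all__ = [
    "PolyA",
    "ReporterConstruct",
    "ConstructReport",
    "build_utr",
    "assemble_mrna",
    "parse_mrna",
    "validate_construct",
]

_STOPS = {"TAA", "TAG", "TGA"}
_MIN_ENCODED_POLYA = 10


@dataclass(frozen=True)
class PolyA:
    """Poly(A) mode: NONE, ENCODED(length) or ENZYMATIC (metadata only)."""

    mode: str = "NONE"  # NONE | ENCODED | ENZYMATIC
    length: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"NONE", "ENCODED", "ENZYMATIC"}:
            raise ValueError(f"unknown polyA mode {self.mode!r}")
        if self.mode == "ENCODED" and self.length <= 0:
            raise ValueError("ENCODED polyA needs a positive length")


@dataclass(frozen=True)
class ReporterConstruct:
    """Parts of a reporter mRNA, all DNA, in emitted order.

    ``leader`` holds any transcribed bases upstream of the kozak (the +1
    bases a promoter prepends).  ``kozak`` may be empty for constructs
    lacking one (flagged by validation).
    """

    promoter: PromoterSpec | None
    cds: str
    utr3: str
    kozak: str = KOZAK_EF1A
    leader: str = ""
    utr5_extra: str = ""  # bases between leader and kozak, if any
    polya: PolyA = field(default_factory=PolyA)

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        if not cds.startswith("ATG"):
            raise SeqError("CDS must begin with ATG")
        if len(cds) % 3 or cds[-3:] not in _STOPS:
            raise SeqError("CDS must be a whole number of codons ending in a stop")


def build_utr(
    base_utr: str,
    seed_site: str,
    n_sites: int,
    gap: int,
    full_site: str | None = None,
) -> str:
    """Insert seed-site copies into a UTR at uniform spacing.

    The base UTR must already contain >= 1 occurrence of ``seed_site`` (the
    'original' site); additional copies are inserted upstream of the first
    existing site, each separated from the next by exactly ``gap``
    intervening bases, taking the intervening bases from the UTR sequence
    immediately upstream.  An existing ``full_site`` is preserved; if the
    insertions would overlap it, an error is raised.
    """
    base_utr, seed_site = base_utr.upper(), seed_site.upper()
    if n_sites < 1:
        raise SeqError("n_sites must be >= 1")
    if gap < 0:
        raise SeqError("gap must be >= 0")
    existing = [m.start() for m in re.finditer(re.escape(seed_site), base_utr)]
    if not existing:
        raise SeqError("base UTR lacks the original seed site")
    missing = n_sites - len(existing)
    if missing <= 0:
        return base_utr
    first = existing[0]
    if full_site:
        fpos = base_utr.find(full_site.upper())
        if fpos != -1 and fpos < first:
            raise SeqError(
                "insertions upstream of the original site would overlap the full-match site"
            )
    prefix, suffix = base_utr[:first], base_utr[first:]
    # spacer fill cycles a neutral pattern; try the four phases in case a
    # junction accidentally recreates the site motif
    for phase in range(4):
        pat = "ACGT"[phase:] + "ACGT"[:phase]
        spacer = (pat * (gap // 4 + 1))[:gap]
        out = prefix + (seed_site + spacer) * missing + suffix
        if len(re.findall(re.escape(seed_site), out)) == n_sites:
            return out
    raise SeqError("could not place inserted sites without creating extra occurrences")


def assemble_mrna(construct: ReporterConstruct, as_template: bool = False) -> NucleicSeq:
    """Emit the construct as a sense DNA sequence (default) or as the
    reverse-complement ordered template for its promoter.

    The promoter's +1 requirement is enforced against the transcript start
    (e.g. a CleanCap-AG promoter needs the transcript to begin A,G).
    """
    tail = "A" * construct.polya.length if construct.polya.mode == "ENCODED" else ""
    transcript = (
        construct.leader
        + construct.utr5_extra
        + construct.kozak
        + construct.cds
        + construct.utr3
        + tail
    )
    prom = construct.promoter
    if prom is not None:
        if not transcript.startswith(prom.plus_one_prefix):
            raise SeqError(
                f"transcript starts {transcript[:2]!r}; promoter {prom.name} "
                f"requires {prom.plus_one_prefix!r}"
            )
        sense = prom.motif + transcript
    else:
        sense = transcript
    seq = NucleicSeq("construct", Alphabet.DNA, sense)
    return revcomp(seq) if as_template else seq


def parse_mrna(
    mrna: NucleicSeq,
    promoters: Sequence[PromoterSpec] = (
        PROMOTERS["T7_PHI25"],
        PROMOTERS["T7_CLEANCAP_AG"],
        PROMOTERS["T7_STD"],
        PROMOTERS["SP6"],
    ),
    kozak: str = KOZAK_EF1A,
) -> ReporterConstruct:
    """Split a printed sense-strand mRNA template row into its parts.

    Recognizes an optional leading promoter motif (preferring the motif
    whose +1 requirement the following bases satisfy), an optional kozak, the
    first ATG-to-stop open reading frame after it, a trailing encoded
    poly(A) run, and the 3' UTR in between.  ``assemble_mrna(parse_mrna(x))``
    is the identity on well-formed rows.
    """
    s = rna_to_dna(mrna).bases
    prom = None
    for p in sorted(promoters, key=lambda p: -len(p.plus_one_prefix)):
        if s.startswith(p.motif) and s[len(p.motif):].startswith(p.plus_one_prefix):
            prom = p
            s = s[len(p.motif):]
            break
    kpos = s.find(kozak)
    leader, kz = (s[:kpos], kozak) if kpos != -1 else ("", "")
    body = s[kpos + len(kozak):] if kpos != -1 else s
    atg = body.find("ATG")
    if atg == -1:
        raise SeqError(f"no ATG found in {mrna.id!r}")
    if kpos == -1:
        leader, body = body[:atg], body[atg:]
        atg = 0
    cds_end = None
    for i in range(atg + 3, len(body) - 2, 3):
        if body[i : i + 3] in _STOPS:
            cds_end = i + 3
            break
    if cds_end is None:
        raise SeqError(f"no in-frame stop codon in {mrna.id!r}")
    cds = body[atg:cds_end]
    rest = body[cds_end:]
    m = re.search(r"A{%d,}$" % _MIN_ENCODED_POLYA, rest)
    polya = PolyA()
    if m:
        polya = PolyA("ENCODED", len(rest) - m.start())
        rest = rest[: m.start()]
    return ReporterConstruct(
        promoter=prom,
        cds=cds,
        utr3=rest,
        kozak=kz,
        leader=leader,
        utr5_extra=body[:atg] if kpos != -1 else "",
        polya=polya,
    )


@dataclass(frozen=True)
class ConstructReport:
    """Validation report for a reporter mRNA against one or more guides."""

    kozak_position: int | None  # 1-based, None if absent
    cds_start: int
    cds_end: int
    hits: dict[str, tuple[SiteHit, ...]]  # per guide id, seed-mode scan
    full_hits: dict[str, tuple[SiteHit, ...]]  # per guide id, near-full scan
    seed_gaps_by_guide: dict[str, tuple[int, ...]]
    seed_site_count: int  # of the guide with the most seed sites
    seed_gaps: tuple[int, ...]  # that guide's inter-site gaps
    full_site_count: int
    flags: tuple[str, ...]


def _region_map(mrna_dna: str, kozak: str = KOZAK_EF1A) -> tuple[list[tuple[int, int, Region]], int, int, int | None]:
    kpos = mrna_dna.find(kozak)
    search_from = kpos + len(kozak) if kpos != -1 else 0
    atg = mrna_dna.find("ATG", search_from)
    if atg == -1:
        return [(1, len(mrna_dna), Region.UNANNOTATED)], 0, 0, None
    cds_end = None
    for i in range(atg + 3, len(mrna_dna) - 2, 3):
        if mrna_dna[i : i + 3] in _STOPS:
            cds_end = i + 3
            break
    if cds_end is None:
        return [(1, len(mrna_dna), Region.UNANNOTATED)], 0, 0, None
    regions = []
    if atg >= 1:
        regions.append((1, atg, Region.UTR5))
    regions.append((atg + 1, cds_end, Region.CDS))
    if cds_end < len(mrna_dna):
        regions.append((cds_end + 1, len(mrna_dna), Region.UTR3))
    return regions, atg + 1, cds_end, (kpos + 1 if kpos != -1 else None)


def validate_construct(
    mrna: NucleicSeq,
    guides: Sequence[NucleicSeq],
    spec: PatternSpec = DEFAULT_PATTERN,
    kozak: str = KOZAK_EF1A,
) -> ConstructReport:
    """Scan a reporter mRNA with the given guides and report its site
    architecture: kozak position, CDS bounds, per-guide hits, the seed-site
    census with pairwise gaps, and the full-match site count.

    Seed-site spacing is measured between the 8-nt seed regions (the windows
    pairing guide positions 1-8), not the full guide-length windows.
    """
    s = rna_to_dna(mrna).bases
    regions, cds_start, cds_end, kpos = _region_map(s, kozak)
    flags: list[str] = []
    if kpos is None:
        flags.append("missing_kozak")
    if cds_start == 0:
        flags.append("no_orf")

    hits: dict[str, tuple[SiteHit, ...]] = {}
    full_hits: dict[str, tuple[SiteHit, ...]] = {}
    gaps_by_guide: dict[str, tuple[int, ...]] = {}
    n_full = 0
    for g in guides:
        seed = tuple(
            sorted(scan_transcript(g, mrna, regions, spec, mode="seed"), key=lambda h: h.seed_start)
        )
        nf = tuple(scan_transcript(g, mrna, regions, spec, mode="near_full"))
        hits[g.id] = seed
        full_hits[g.id] = nf
        gaps_by_guide[g.id] = tuple(
            nxt.seed_start - prev.seed_end - 1 for prev, nxt in zip(seed, seed[1:])
        )
        n_full += len(nf)
    top = max(hits, key=lambda gid: len(hits[gid]), default=None)
    return ConstructReport(
        kozak_position=kpos,
        cds_start=cds_start,
        cds_end=cds_end,
        hits=hits,
        full_hits=full_hits,
        seed_gaps_by_guide=gaps_by_guide,
        seed_site_count=len(hits[top]) if top else 0,
        seed_gaps=gaps_by_guide[top] if top else (),
        full_site_count=n_full,
        flags=tuple(flags),
    )
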