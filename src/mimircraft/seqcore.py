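"""Sequence primitives and promoter-aware template <-> transcript conversion.

Short hairpin / miRNA-mimic templates for in vitro transcription are ordered
as single-stranded DNA oligos written as the *reverse complement* of
(promoter + precursor).  Decoding such a template therefore means reverse
complementing it, locating the promoter motif, and reading the transcript
from the promoter's +1 position onward.  This module provides the
:class:`NucleicSeq` container used throughout the toolkit, the promoter
registry with calibrated +1 conventions, and FASTA/FASTQ I/O built on
Biopython.

Coordinates are 1-based and inclusive on the sense strand everywhere in this
package, matching the 1-based position numbering conventional for miRNA
guides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "NucleicSeq",
    "PromoterSpec",
    "PROMOTERS",
    "DEFAULT_PROMOTERS",
    "SmallRead",
    "SeqError",
    "revcomp",
    "dna_to_rna",
    "rna_to_dna",
    "transcribe_template",
    "make_template",
    "read_fasta",
    "write_fasta",
    "read_reads",
]


class SeqError(ValueError):
    """Raised on invalid sequences, malformed records or decoding failures."""


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


_DNA_BASES = frozenset("ACGTN")
_RNA_BASES = frozenset("ACGUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


@dataclass(frozen=True)
class NucleicSeq:
    """A validated DNA or RNA sequence with an identifier.

    Input is case-insensitive; bases are stored uppercase.  ``N`` is
    permitted and flagged via :attr:`has_n`.
    """

    id: str
    alphabet: Alphabet
    bases: str

    def __post_init__(self) -> None:
        up = self.bases.upper()
        object.__setattr__(self, "bases", up)
        legal = _DNA_BASES if self.alphabet is Alphabet.DNA else _RNA_BASES
        bad = set(up) - legal
        if bad:
            raise SeqError(
                f"illegal {self.alphabet.value} base(s) {sorted(bad)} in sequence "
                f"{self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, pos: int) -> str:
        """1-based single-position access (pos in [1, len])."""
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} outside [1, {len(self.bases)}]")
        return self.bases[pos - 1]

    @property
    def has_n(self) -> bool:
        return "N" in self.bases

    def slice1(self, start: int, end: int) -> str:
        """Substring by 1-based inclusive coordinates."""
        if start < 1 or end > len(self.bases) or start > end + 1:
            raise IndexError(f"interval [{start},{end}] outside sequence of length {len(self.bases)}")
        return self.bases[start - 1 : end]


def dna(id: str, bases: str) -> NucleicSeq:
    return NucleicSeq(id, Alphabet.DNA, bases)


def rna(id: str, bases: str) -> NucleicSeq:
    return NucleicSeq(id, Alphabet.RNA, bases)


def revcomp(seq: NucleicSeq) -> NucleicSeq:
    """Reverse complement within the sequence's own alphabet (involution)."""
    table = _DNA_COMPLEMENT if seq.alphabet is Alphabet.DNA else _RNA_COMPLEMENT
    return replace(seq, bases=seq.bases.translate(table)[::-1])


def dna_to_rna(seq: NucleicSeq) -> NucleicSeq:
    if seq.alphabet is Alphabet.RNA:
        return seq
    return NucleicSeq(seq.id, Alphabet.RNA, seq.bases.replace("T", "U"))


def rna_to_dna(seq: NucleicSeq) -> NucleicSeq:
    if seq.alphabet is Alphabet.DNA:
        return seq
    return NucleicSeq(seq.id, Alphabet.DNA, seq.bases.replace("U", "T"))


@dataclass(frozen=True)
class PromoterSpec:
    """A bacteriophage promoter motif with its +1 transcript-start convention.

    ``start_offset`` gives the transcript +1 position relative to the base
    immediately following the motif (0 = transcription starts right after the
    motif, which is the convention for every packaged promoter).
    ``plus_one_prefix`` is the base prefix the transcript must start with;
    it is enforced by :func:`make_template` (strict mode) and used to
    disambiguate promoters sharing a motif.
    """

    name: str
    motif: str  # DNA, sense strand of the promoter
    start_offset: int = 0
    plus_one_prefix: str = ""

    def transcript_start_ok(self, transcript: str) -> bool:
        return transcript.startswith(self.plus_one_prefix.replace("T", "U"))


#: Calibrated promoter registry.  The +1 conventions reproduce the printed
#: ordered templates exactly; the class II phi2.5 +1 offset is a calibrated
#: convention, not a biochemical claim.
PROMOTERS: dict[str, PromoterSpec] = {
    "T7_STD": PromoterSpec("T7_STD", "TAATACGACTCACTATA", 0, "G"),
    "T7_PHI25": PromoterSpec("T7_PHI25", "TAATACGACTCACTATT", 0, "A"),
    "T7_CLEANCAP_AG": PromoterSpec("T7_CLEANCAP_AG", "TAATACGACTCACTATA", 0, "AG"),
    "SP6": PromoterSpec("SP6", "ATTTAGGTGACACTATA", 0, "G"),
}

#: Promoters tried by default when decoding a template.
DEFAULT_PROMOTERS: tuple[PromoterSpec, ...] = (
    PROMOTERS["T7_STD"],
    PROMOTERS["T7_PHI25"],
    PROMOTERS["T7_CLEANCAP_AG"],
    PROMOTERS["SP6"],
)


def transcribe_template(
    template: NucleicSeq,
    promoters: Sequence[PromoterSpec] = DEFAULT_PROMOTERS,
) -> tuple[PromoterSpec, NucleicSeq]:
    """Decode an ordered single-stranded DNA template into its transcript.

    The template is the reverse complement of (promoter + transcript).  The
    template is reverse complemented, exactly one promoter motif is located,
    and the transcript (RNA) is returned starting at that promoter's +1.

    Among multiple matching promoters the longest motif wins; promoters
    sharing a motif (T7_STD vs T7_CLEANCAP_AG) are disambiguated by the +1
    prefix requirement, preferring the more specific prefix that the
    transcript satisfies.
    """
    if template.alphabet is not Alphabet.DNA:
        raise SeqError("template must be DNA")
    sense = revcomp(template).bases
    candidates: list[tuple[PromoterSpec, str]] = []
    for prom in promoters:
        n = sense.count(prom.motif)
        if n == 0:
            continue
        if n > 1:
            raise SeqError(
                f"promoter {prom.name} motif occurs {n} times in template {template.id!r}; ambiguous"
            )
        start = sense.index(prom.motif) + len(prom.motif) + prom.start_offset
        transcript = sense[start:].replace("T", "U")
        if not transcript:
            raise SeqError(f"empty transcript after promoter {prom.name} in {template.id!r}")
        candidates.append((prom, transcript))
    if not candidates:
        raise SeqError(f"no promoter motif found in template {template.id!r}")
    # longest motif first; among equal motifs prefer the most specific
    # satisfied +1 prefix (CleanCap-AG label only when the transcript starts AG)
    candidates.sort(
        key=lambda c: (
            len(c[0].motif),
            len(c[0].plus_one_prefix) if c[1].startswith(c[0].plus_one_prefix.replace("T", "U")) else -1,
        ),
        reverse=True,
    )
    prom, transcript = candidates[0]
    return prom, NucleicSeq(f"{template.id}.transcript", Alphabet.RNA, transcript)


def make_template(
    transcript: NucleicSeq,
    promoter: PromoterSpec,
    strict: bool = True,
) -> NucleicSeq:
    """Emit the ordered DNA template: revcomp(promoter motif + transcript).

    ``strict`` enforces the promoter's +1 base requirement (e.g. T7 wants the
    transcript to begin with G); set it to ``False`` to emit anyway.
    ``transcribe_template(make_template(x))`` recovers ``x`` exactly.
    """
    if len(transcript) == 0:
        raise SeqError("transcript is empty")
    tx = dna_to_rna(transcript)
    if strict and not promoter.transcript_start_ok(tx.bases):
        raise SeqError(
            f"transcript {transcript.id!r} starts with {tx.bases[:2]!r}; promoter "
            f"{promoter.name} requires a {promoter.plus_one_prefix!r} start "
            "(pass strict=False to override)"
        )
    sense = promoter.motif + tx.bases.replace("U", "T")
    return revcomp(NucleicSeq(f"{transcript.id}.template", Alphabet.DNA, sense))


# ---------------------------------------------------------------------------
# standard-format I/O

def _guess_alphabet(bases: str) -> Alphabet:
    return Alphabet.RNA if "U" in bases.upper() and "T" not in bases.upper() else Alphabet.DNA


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[NucleicSeq]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Lowercase input is uppercased; the alphabet is inferred per record unless
    given explicitly.
    """
    out: list[NucleicSeq] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        bases = str(rec.seq).upper()
        ab = alphabet or _guess_alphabet(bases)
        try:
            out.append(NucleicSeq(rec.id, ab, bases))
        except SeqError as exc:  # re-raise with record index for usability
            raise SeqError(f"record {i} ({rec.id!r}): {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucleicSeq], path: str | Path) -> None:
    records = []
    for s in seqs:
        if not s.id:
            raise SeqError("cannot write a sequence with an empty id")
        records.append(SeqRecord(Seq(s.bases), id=s.id, description=""))
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class SmallRead:
    """One small-RNA read; qualities are preserved but unused downstream."""

    id: str
    bases: str  # uppercase DNA
    qual: str | None = None

    def __len__(self) -> int:
        return len(self.bases)


def read_reads(path: str | Path) -> list[SmallRead]:
    """Read small-RNA reads from FASTQ or FASTA (format sniffed from content)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    out: list[SmallRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            bases = str(rec.seq).upper().replace("U", "T")
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(SmallRead(rec.id, bases, qual))
    except ValueError as exc:
        raise SeqError(f"malformed {fmt.upper()} record ~index {len(out)}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.qual or 'I' * len(r.bases)}\n")
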