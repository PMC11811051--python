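"""Desk-scale quantification of mimic loading from AGO-IP small-RNA reads.

The pipeline mirrors a standard small-RNA workflow at bench-top scale:
length filtering (reads < 18 nt discarded), exact-sequence collapsing,
read-to-precursor assignment by exact (or <=k-mismatch) substring match,
strand calls by maximal overlap with the annotated guide/star/loop
intervals, normalization to reads-per-million of genome-unmapped reads,
replicate averaging, and processing-homogeneity metrics (canonical 5'-end
fraction, loop-spanning fraction and the 5'-offset histogram).  Genome
mapping itself is out of scope at this scale; the genome-unmapped total is
supplied by the caller or computed against a reference FASTA by exact
substring match.

A seeded synthetic-read generator emulating the guide/star/loop-spanning
read structure of the immunoprecipitation libraries is included for
testing and calibration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqcore import NucleicSeq, SeqError, SmallRead, rna_to_dna

__all__ = [
    "PrecursorAnnotation",
    "ReadAssignment",
    "StrandCounts",
    "LoadingQuant",
    "SynthReadConfig",
    "length_filter",
    "collapse_reads",
    "assign_reads",
    "normalize_counts",
    "average_replicates",
    "homogeneity",
    "HomogeneityMetrics",
    "simulate_reads",
    "quantify_replicates",
]


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Guide/star/loop intervals partitioning a precursor (1-based incl.)."""

    precursor: NucleicSeq  # RNA
    guide_interval: tuple[int, int]
    star_interval: tuple[int, int]
    loop_interval: tuple[int, int]

    def __post_init__(self) -> None:
        ivs = sorted([self.guide_interval, self.star_interval, self.loop_interval])
        covered = 0
        prev_end = 0
        for lo, hi in ivs:
            if lo != prev_end + 1 or hi < lo:
                raise SeqError(
                    f"intervals {ivs} do not disjointly cover the precursor"
                )
            covered += hi - lo + 1
            prev_end = hi
        if covered != len(self.precursor):
            raise SeqError("intervals do not cover the whole precursor")

    @classmethod
    def from_design(cls, design) -> "PrecursorAnnotation":
        """Annotation from a MimirDesign (scaffold flanks go to the arms)."""
        ns, nl, ng = len(design.star), len(design.loop), len(design.guide)
        if design.scaffold.arm_order == "STAR_5PRIME_GUIDE_3PRIME":
            star = (1, ns)
            loop = (ns + 1, ns + nl)
            guide = (ns + nl + 1, ns + nl + ng)
        else:
            guide = (1, ng)
            loop = (ng + 1, ng + nl)
            star = (ng + nl + 1, ng + nl + ns)
        return cls(design.precursor, guide, star, loop)


@dataclass(frozen=True)
class ReadAssignment:
    """One collapsed read's assignment to a precursor."""

    sequence: str  # DNA
    multiplicity: int
    precursor_id: str | None  # None -> 'other'
    offset: int | None  # 1-based start on the precursor
    strand: str | None  # guide | star | loop
    loop_spanning: bool = False
    five_prime_offset: int | None = None  # read start - annotated strand start


def length_filter(reads: Sequence[SmallRead], min_len: int = 18) -> list[SmallRead]:
    """Keep reads of length >= min_len (reads shorter than 18 nt are
    discarded by default); input order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r) >= min_len]


def collapse_reads(reads: Sequence[SmallRead]) -> list[tuple[str, int]]:
    """Exact-sequence deduplication; sum of multiplicities == input size."""
    counts = Counter(r.bases for r in reads)
    return list(counts.items())


def _mismatch_positions_at(seq: str, hay: str, start: int) -> int:
    return sum(1 for a, b in zip(seq, hay[start : start + len(seq)]) if a != b)


def _find_in_precursor(seq: str, prec_dna: str, max_mismatches: int) -> int | None:
    """0-based leftmost start of seq in prec_dna within max_mismatches."""
    if max_mismatches == 0:
        i = prec_dna.find(seq)
        return i if i != -1 else None
    best = None
    for i in range(len(prec_dna) - len(seq) + 1):
        if _mismatch_positions_at(seq, prec_dna, i) <= max_mismatches:
            return i
    return best


def assign_reads(
    reads: Sequence[SmallRead],
    annotations: Sequence[PrecursorAnnotation],
    max_mismatches: int = 0,
) -> list[ReadAssignment]:
    """Assign collapsed reads to precursors and strands.

    A read maps to the first annotated precursor containing it as an exact
    (or <=k-mismatch) substring, at the leftmost such offset.  The strand
    label is the annotated interval with maximal overlap; equal-overlap ties
    go to the guide (conservative toward the quantity of interest).
    Guide-assigned reads overlapping the loop by >= 1 base are flagged
    loop-spanning.  Reads matching no precursor are 'other'.
    """
    prec_dna = {
        a.precursor.id: rna_to_dna(a.precursor).bases for a in annotations
    }
    out: list[ReadAssignment] = []
    for seq, mult in collapse_reads(reads):
        hit: tuple[PrecursorAnnotation, int] | None = None
        for a in annotations:
            i = _find_in_precursor(seq, prec_dna[a.precursor.id], max_mismatches)
            if i is not None:
                hit = (a, i)
                break
        if hit is None:
            out.append(ReadAssignment(seq, mult, None, None, None))
            continue
        a, i0 = hit
        start, end = i0 + 1, i0 + len(seq)  # 1-based inclusive
        overlaps = {}
        for label, (lo, hi) in (
            ("guide", a.guide_interval),
            ("star", a.star_interval),
            ("loop", a.loop_interval),
        ):
            overlaps[label] = max(0, min(end, hi) - max(start, lo) + 1)
        best = max(overlaps.values())
        # deterministic tie-break: guide > star > loop
        for label in ("guide", "star", "loop"):
            if overlaps[label] == best:
                strand = label
                break
        loop_spanning = strand == "guide" and overlaps["loop"] >= 1
        anchor = {"guide": a.guide_interval, "star": a.star_interval, "loop": a.loop_interval}[strand][0]
        out.append(
            ReadAssignment(
                seq,
                mult,
                a.precursor.id,
                start,
                strand,
                loop_spanning,
                start - anchor,
            )
        )
    return out


@dataclass(frozen=True)
class StrandCounts:
    """Per-precursor read counts for one replicate."""

    guide: int = 0
    star: int = 0
    loop: int = 0
    loop_spanning: int = 0  # subset of guide
    other: int = 0

    @property
    def assigned(self) -> int:
        return self.guide + self.star + self.loop


def count_assignments(
    assignments: Sequence[ReadAssignment], precursor_id: str
) -> StrandCounts:
    g = s = l = ls = other = 0
    for a in assignments:
        if a.precursor_id != precursor_id:
            if a.precursor_id is None:
                other += a.multiplicity
            continue
        if a.strand == "guide":
            g += a.multiplicity
            if a.loop_spanning:
                ls += a.multiplicity
        elif a.strand == "star":
            s += a.multiplicity
        else:
            l += a.multiplicity
    return StrandCounts(g, s, l, ls, other)


def normalize_counts(count: int | float, unmapped_total: int) -> float:
    """Reads-per-million of genome-unmapped reads: count / unmapped * 1e6."""
    if unmapped_total <= 0:
        raise SeqError("unmapped_total must be > 0 for RPM normalization")
    return count / unmapped_total * 1_000_000


def average_replicates(values: Sequence[float]) -> float:
    """Arithmetic mean over biological replicates."""
    if not values:
        raise SeqError("need at least one replicate")
    return float(np.mean(values))


@dataclass(frozen=True)
class HomogeneityMetrics:
    canonical_fraction: float
    loop_spanning_fraction: float
    five_prime_offsets: dict[int, int]


def homogeneity(
    assignments: Sequence[ReadAssignment], annotation: PrecursorAnnotation
) -> HomogeneityMetrics | None:
    """Processing-homogeneity of the guide-assigned reads of one precursor.

    Canonical fraction: guide reads whose 5' end equals the annotated guide
    start.  Loop-spanning fraction: guide reads reaching >= 1 base into the
    loop (imprecise hairpin processing).  Returns None (flagged) when no
    guide reads are present.
    """
    guide_reads = [
        a
        for a in assignments
        if a.precursor_id == annotation.precursor.id and a.strand == "guide"
    ]
    total = sum(a.multiplicity for a in guide_reads)
    if total == 0:
        return None
    canonical = sum(a.multiplicity for a in guide_reads if a.five_prime_offset == 0)
    spanning = sum(a.multiplicity for a in guide_reads if a.loop_spanning)
    hist: Counter[int] = Counter()
    for a in guide_reads:
        hist[a.five_prime_offset] += a.multiplicity
    return HomogeneityMetrics(canonical / total, spanning / total, dict(hist))


# ---------------------------------------------------------------------------
# synthetic reads

@dataclass(frozen=True)
class SynthReadConfig:
    """Configuration of the synthetic AGO-IP read generator.

    ``guide_fraction`` and ``loop_spanning_fraction`` are fractions of all
    reads (they must sum to <= 1); the remainder are star reads.
    Loop-spanning reads start inside the loop and run into the guide, so
    assignment labels them guide with the loop-spanning flag.  5' jitter
    offsets (applied to plain guide and star reads) are drawn from
    ``five_prime_jitter``, a mapping offset -> probability over -2..+2.
    Read lengths are uniform over ``length_range`` (the 18-30 nt
    gel-selection window), clipped to the precursor.
    """

    n_reads: int
    guide_fraction: float = 0.7
    loop_spanning_fraction: float = 0.1
    five_prime_jitter: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    length_range: tuple[int, int] = (18, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.guide_fraction <= 1 or not 0 <= self.loop_spanning_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.guide_fraction + self.loop_spanning_fraction > 1 + 1e-12:
            raise ValueError("guide_fraction + loop_spanning_fraction must be <= 1")
        if abs(sum(self.five_prime_jitter.values()) - 1.0) > 1e-9:
            raise ValueError("jitter probabilities must sum to 1")
        if any(not -2 <= o <= 2 for o in self.five_prime_jitter):
            raise ValueError("jitter offsets must lie in -2..+2")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")


def simulate_reads(
    config: SynthReadConfig, annotation: PrecursorAnnotation
) -> list[SmallRead]:
    """Draw a reproducible synthetic read set from a precursor annotation.

    Re-quantifying the output recovers the configured fractions up to
    binomial sampling noise.
    """
    rng = np.random.default_rng(config.seed)
    prec = rna_to_dna(annotation.precursor).bases
    N = len(prec)
    g_lo, g_hi = annotation.guide_interval
    s_lo, s_hi = annotation.star_interval
    l_lo, l_hi = annotation.loop_interval

    offsets = sorted(config.five_prime_jitter)
    probs = [config.five_prime_jitter[o] for o in offsets]

    p_ls = config.loop_spanning_fraction
    p_g = config.guide_fraction
    classes = rng.choice(
        3, size=config.n_reads, p=[p_g, p_ls, max(0.0, 1.0 - p_g - p_ls)]
    )
    lens = rng.integers(config.length_range[0], config.length_range[1] + 1, size=config.n_reads)
    jit = rng.choice(len(offsets), size=config.n_reads, p=probs)

    reads: list[SmallRead] = []
    for i in range(config.n_reads):
        cls = classes[i]
        length = int(lens[i])
        if cls == 0:  # plain guide, possibly jittered
            start = g_lo + offsets[jit[i]]
        elif cls == 1:  # loop-spanning: begin 1..3 nt inside the loop
            into = int(rng.integers(1, min(4, l_hi - l_lo + 2)))
            start = g_lo - into
            length = max(length, into + (g_hi - g_lo + 1) // 2)  # reach well into the guide
        else:  # star, possibly jittered
            start = s_lo + offsets[jit[i]]
        start = max(1, start)
        end = min(N, start + length - 1)
        reads.append(
            SmallRead(
                id=f"synth_{i}",
                bases=prec[start - 1 : end],
                qual="I" * (end - start + 1),
            )
        )
    return reads


def quantify_replicates(
    replicates: Sequence[Sequence[SmallRead]],
    annotations: Sequence[PrecursorAnnotation],
    unmapped_totals: Sequence[int],
    min_len: int = 18,
    max_mismatches: int = 0,
) -> "LoadingQuant":
    """Full pipeline: filter, assign, count, normalize, average."""
    if len(replicates) != len(unmapped_totals):
        raise SeqError("one unmapped_total per replicate required")
    per_rep: list[dict[str, StrandCounts]] = []
    per_rep_assign: list[list[ReadAssignment]] = []
    for reads in replicates:
        kept = length_filter(list(reads), min_len)
        asg = assign_reads(kept, annotations, max_mismatches)
        per_rep_assign.append(asg)
        per_rep.append({a.precursor.id: count_assignments(asg, a.precursor.id) for a in annotations})
    guide_rpm: dict[str, list[float]] = {}
    star_rpm: dict[str, list[float]] = {}
    for counts, total in zip(per_rep, unmapped_totals):
        for pid, c in counts.items():
            guide_rpm.setdefault(pid, []).append(normalize_counts(c.guide, total))
            star_rpm.setdefault(pid, []).append(normalize_counts(c.star, total))
    homog = {
        a.precursor.id: [homogeneity(asg, a) for asg in per_rep_assign]
        for a in annotations
    }
    return LoadingQuant(
        counts=per_rep,
        unmapped_totals=tuple(unmapped_totals),
        guide_rpm=guide_rpm,
        star_rpm=star_rpm,
        guide_rpm_mean={p: average_replicates(v) for p, v in guide_rpm.items()},
        star_rpm_mean={p: average_replicates(v) for p, v in star_rpm.items()},
        homogeneity=homog,
    )


@dataclass(frozen=True)
class LoadingQuant:
    """Per-precursor, per-replicate counts with RPM values and means."""

    counts: list[dict[str, StrandCounts]]
    unmapped_totals: tuple[int, ...]
    guide_rpm: dict[str, list[float]]
    star_rpm: dict[str, list[float]]
    guide_rpm_mean: dict[str, float]
    star_rpm_mean: dict[str, float]
    homogeneity: dict[str, list[HomogeneityMetrics | None]]


def unmapped_from_reference(reads: Sequence[SmallRead], reference: Sequence[NucleicSeq]) -> int:
    """Count reads not matching any reference sequence exactly (desk-scale
    stand-in for genome mapping)."""
    refs = [rna_to_dna(r).bases for r in reference]
    return sum(1 for r in reads if not any(r.bases in ref for ref in refs))
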