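# Methods

## Scope and model

mimircraft treats a miRNA mimic as a triple (guide, star, loop) embedded in
a hairpin precursor and emitted as an ordered single-stranded DNA template
for in vitro transcription. Four concerns are modelled:

1. **Template ↔ transcript conversion.** An ordered template is the reverse
   complement of (promoter motif + transcript). Decoding reverse-complements
   the template, requires exactly one promoter motif, and reads the
   transcript from the +1 position. Packaged promoter conventions, each
   calibrated so that the packaged templates decode exactly:
   `T7_STD` (`TAATACGACTCACTATA`, +1 immediately after the motif, transcript
   must start G), `T7_PHI25` (class II phi2.5, `TAATACGACTCACTATT`, +1 A),
   `T7_CLEANCAP_AG` (T7 motif, transcript must start A,G) and `SP6`
   (`ATTTAGGTGACACTATA`, +1 G). The phi2.5 +1 convention is a calibrated
   convention, not a biochemical claim. When the T7 and CleanCap-AG labels
   are both admissible (they share a motif), the CleanCap label is preferred
   iff the transcript starts AG; this is a labelling rule only — the decoded
   sequence is identical either way.

2. **Duplex model and classification.** A guide of length L lies
   antiparallel and ungapped on a same-length sense-strand window; guide
   position i pairs window position L+1−i. Pair states are Watson–Crick,
   G:U wobble, or mismatch; wobbles count as mismatches by default because
   the published designs never rely on wobble pairing and the conservative
   reading cannot overcall a match (configurable flag). Binding modes are
   assigned with deterministic precedence:
   * NEAR_FULL — at most `near_full_max_mismatches` (default 2) mismatches
     overall, none of the non-fixed ones inside the seed (positions 2–8) or
     at the central positions {10, 11}. Fixed-base positions (19, see below)
     never disqualify. The default of 2 accommodates the designed
     position-19 mismatch plus one incidental mismatch.
   * CENTRAL_MM_10 / _11 / _10_11 — the only non-fixed deviations sit at
     the stated central positions.
   * SEED_SUPPLEMENTARY — seed fully paired, supplementary interval
     (13–16) fully paired, ≥ 1 central position mismatched.
   * SEED_ONLY — seed fully paired, supplementary not fully paired.
   * NONE otherwise.
   The classification seed is positions 2–8 (length 7) with position 1
   additionally required to pair by default, matching the designed guides
   whose 5'-terminal U pairs an A; seed-mode *scanning* uses the broader
   design interval 1–8. Both intervals are configurable; the duality
   reproduces both the conventional seed definition and the printed designs.

3. **Scanning.** Every window of the transcript is aligned and classified;
   seed mode keeps windows fully Watson–Crick across the design seed
   interval, near-full mode keeps NEAR_FULL windows, all mode keeps any
   window that classifies. Overlaps are resolved greedily left-to-right, so
   a base belongs to at most one reported site — deterministic, and the
   published construct's sites are non-overlapping anyway. The predicted
   cleavage coordinate is the bond between the transcript bases pairing
   guide positions 11 and 10 (reported by its 5'-side coordinate,
   start+L−11), present only when both central positions are Watson–Crick.

4. **Loading quantification.** Reads shorter than 18 nt are discarded
   (mirroring the 18–30 nt gel size-selection window, which is also the
   simulator's default length range); reads are collapsed by exact sequence
   and matched to precursors by exact substring (a ≤k-mismatch mode
   exists). The strand call is the annotated interval (guide/star/loop)
   with maximal overlap, ties to guide — deterministic and conservative
   toward the quantity of interest. Guide reads that reach ≥ 1 base into
   the loop are flagged loop-spanning (imprecise hairpin processing).
   Normalization is reads-per-million of genome-unmapped reads; replicate
   summaries are arithmetic means. Genome mapping itself is deliberately
   out of scope at desk scale: the unmapped total is an input (or an exact
   match count against a supplied reference), a documented simplification
   of the aligner-based workflow.

## Scaffold calibration

The miR-2022-derived scaffold is data, not code: its loop (`GUUGUCA`), arm
order (star 5', guide 3'), guide length (21), duplex register and star
tail were all recovered by decoding the packaged templates. The register —
star position j pairs guide position 20−j, i.e. 2-nt 3' overhangs on both
strands — is the unique small offset under which all seven mimic duplexes
break pairing at the same star positions. Under it:

* the star's pair-breaking positions are **{8, 9, 17}** (star's own 5'→3'
  numbering). The published design language also lists star position 1;
  under the calibrated register star position 1 is the precursor's first
  transcribed base, forced to G by the T7 +1 requirement, and it
  Watson–Crick pairs the guide's fixed C19. It is therefore a deviation
  relative to the unmodified target complement, not a guide-pairing break,
  and needs no substitution when deriving a star from a guide. This is why
  guide position 19 is always C.
* the star 3' overhang (`UG`) is scaffold-constant across all decoded
  mimics and is stored as data.

## Design rules

`choose_target_site` enumerates guide-length windows ending in A (sense
strand), ranked by ascending position — deterministic and inspectable.
`derive_guide` starts from the exact reverse complement of the window,
fixes position 19 to C, and converts the requested mode's designed
positions to non-pairing bases. The substitution rule picks the base
*identical to the opposing target base*: an identical base can never form
a Watson–Crick pair or a G:U wobble, and it reproduces the printed
central-mismatch guides (C facing C). The published seed-only and
seed-supplementary guides used heterogeneous substitution choices at their
altered positions; those exact rows are reproduced by the packaged
fixtures and checked in verify mode rather than claimed from the rule.
Every derived guide is verified to classify as the requested mode before
being returned.

The generic (non-mimiR) hairpin of the negative control has no known loop;
it is decoded in generic fold mode, which scans candidate loop windows
(3–12 nt, both arms ≥ guide length) and keeps the split maximizing
antiparallel Watson–Crick pairing between the arms.

## Reporter constructs

A reporter is promoter (+1 leader) + EF1α kozak + CDS (ATG…stop) +
engineered 3' UTR (+ encoded poly(A), if any). "N bases apart" for seed
sites means N bases strictly between the end of one 8-nt seed site (the
region pairing guide positions 1–8) and the start of the next; both
inter-site gaps of the packaged reporter equal 21 under this reading.
`build_utr` inserts missing seed-site copies upstream of the original site
with neutral spacer fill and verifies the final occurrence count; the
upstream placement is a toolkit choice — the published text does not state
where the two added sites sat relative to the original, so the printed end
product is authoritative. Enzymatic polyadenylation leaves no sequence
trace and is metadata only; an encoded tail (≥ 10 A's at the 3' end, as in
the sfGFP control, 40 A's) is part of the sequence. Vendor-driven edits
("two nucleotide changes for synthesis efficiency") are opaque: printed
sequences are ground truth.

## Synthetic reads

The generator emulates the read structure of AGO-IP libraries from an
annotated precursor: a configurable fraction of guide reads (5' ends
jittered −2..+2 with stated probabilities), loop-spanning guide reads
(starting 1–3 nt inside the loop), and star reads for the remainder;
lengths uniform over 18–30 nt, clipped at the precursor ends. Fractions
are fractions of all reads and must sum to ≤ 1. A fixed seed gives
byte-identical FASTQ output. What it does **not** emulate: sequencing
error, adapter artifacts, ligation bias, multi-locus genome mapping and
cross-mapping between precursors — so passing recovery tests demonstrate
the correctness of the counting and normalization arithmetic, not
robustness to those real-data effects. Note that a guide read jittered to
start one base early also reaches into the loop and is counted
loop-spanning; the two causes are indistinguishable at the read level, by
design of the flag.

## Numerical and determinism choices

All coordinates are 1-based inclusive on the sense strand. Input sequences
are case-insensitive and stored uppercase; N is allowed, flagged, and
always a mismatch. All randomness flows through explicit seeds (numpy
Generator in the simulator, seeded `random.Random` in tests). Test problem
sizes — 1,000-window scanner-equivalence scans, 10,000-read recovery runs
with 3-binomial-σ bands, a few hundred Hypothesis examples per property —
were chosen so the whole suite completes in seconds while keeping the
binomial bands tight enough to catch off-by-one counting errors.

## Known limitations

* No thermodynamics: no ΔG scoring, no bulged or asymmetric duplexes, no
  secondary-structure prediction of the hairpin (the designs are ungapped
  and the scaffold is trusted).
* No genome-scale alignment; the exact matcher is a desk-scale stand-in.
* AGO sorting (which Argonaute a mimic loads into) and Dicer cut-site
  accuracy are observed quantities, not modelled ones.
* Whether near-full complementarity tolerates G:U wobbles is biologically
  open; the default treats them as mismatches and a flag exposes the
  alternative.
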