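# mimircraft

A toolkit for designing and verifying **miRNA mimics (mimiRs)** built on
endogenous cnidarian hairpin scaffolds, and for the desk-scale analyses
around them: miRNA–target complementarity-mode classification, binding-site
scanning of transcripts, reporter-mRNA construct engineering, and
quantification of mimic loading from AGO-IP small-RNA reads.

## Who this is for

Cnidarian miRNAs — unlike those of bilaterian animals — act like plant
miRNAs: they require nearly-full complementarity to their targets and
silence them by cleavage opposite guide positions 10–11, while bilaterian
miRNAs need only a 7-nt 5' "seed" (guide positions 2–8), optionally
supplemented by 3' pairing at positions 13–16. Probing which
complementarity patterns are functional in an organism requires a family of
mimic hairpins that differ only at designed positions, reporter mRNAs
carrying engineered binding sites, and read-level evidence that the mimics
are processed and loaded. mimircraft implements that workflow end to end
for anyone designing such experiments or re-analysing their sequence
artifacts.

## The model in brief

A mimic is a hairpin precursor `star (5' arm) – loop – guide (3' arm)` on
the stem-loop of *Nematostella* miR-2022, transcribed in vitro from an
ordered single-stranded DNA oligo written as the reverse complement of
(T7 promoter + precursor). Design rules:

* the 21-nt target window is chosen to end in A, so the guide starts with
  a 5' U (native guide-strand bias);
* guide position 19 is always C: the T7 +1 base of the precursor must be G,
  and under the duplex register (star position *j* pairs guide position
  *20 − j*, leaving 2-nt 3' overhangs) that G is star position 1, pairing
  guide 19;
* pair-breaking substitutions at star positions 8, 9 and 17 make the duplex
  asymmetric so the guide strand is loaded;
* binding-mode variants convert designed guide positions to non-pairing
  bases: seed-only (positions 1–8 pair), seed + supplementary (1–8 and
  13–16 pair), and central mismatches at positions 10, 11 or 10–11.

Classification of a guide laid antiparallel and ungapped on a target window
(guide *i* pairs window *L+1−i*) is deterministic with precedence
NEAR_FULL → CENTRAL_MM_* → SEED_SUPPLEMENTARY → SEED_ONLY → NONE; G:U
wobbles count as mismatches by default. Loading quantification normalizes
guide/star read counts to reads-per-million of genome-unmapped reads and
averages biological replicates.

## Worked example

```python
from mimircraft import load_fixtures, decode_template, validate_construct
from mimircraft.verify import decode_all

fx = load_fixtures()
designs = decode_all()                       # all packaged hairpin templates
full = designs["full_match_template"]
print(full.guide.bases)                      # UAUGUUUCAGGUUCAGGGCGA
print(full.pattern.value, full.site_start)   # NEAR_FULL 827

report = validate_construct(
    fx["mcherry_mrna_nematostella_zebrafish"],
    [designs["seed_match_template"].guide],
)
print(report.seed_site_count, report.seed_gaps)   # 3 (21, 21)
```

The decoded full-match guide is 21 nt, starts with U, carries C at
position 19, and binds the reporter 3' UTR at positions 827–847 with a
single (designed) mismatch at position 19. The seed-match guide finds
exactly three seed sites in the 3' UTR, each pair separated by exactly 21
intervening bases — the architecture the reporter was built with. The
`examples/` directory contains one short script per capability (decoding,
scanning, design, construct building, loading quantification), each
printing the numbers above and what they mean. A thin CLI exposes the same
operations (`mimircraft design|decode|scan|construct|quant|simulate-reads|verify-reference`).

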