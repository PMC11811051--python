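"""Build a reporter 3' UTR with spaced seed sites and validate it.

Starting from a UTR containing one 'original' seed site, two more copies
are inserted upstream so that consecutive sites are separated by exactly 21
bases, mirroring the published reporter architecture.
"""

from mimircraft import (
    Alphabet,
    NucleicSeq,
    PolyA,
    ReporterConstruct,
    assemble_mrna,
    build_utr,
    validate_construct,
)
from mimircraft.verify import decode_all

seed_guide = decode_all()["seed_match_template"].guide
seed_site = "GAAACATA"  # reverse complement of guide positions 1-8

base_utr = "TTGCTTTAAAAAACCTGAAACATACCCACACCTCCCC"  # one original site
utr3 = build_utr(base_utr, seed_site, n_sites=3, gap=21)

construct = ReporterConstruct(
    promoter=None,
    cds="ATG" + "GCTGAA" * 20 + "TAA",
    utr3=utr3,
    polya=PolyA("ENCODED", 40),
)
mrna = assemble_mrna(construct)
report = validate_construct(mrna, [seed_guide])
print(f"UTR length {len(utr3)}; transcript length {len(mrna)}")
print(f"seed sites found: {report.seed_site_count}, gaps: {report.seed_gaps}")

# Expected: 3 seed sites with uniform gaps of 21 intervening bases.
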