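"""Decode the packaged ordered DNA templates into annotated hairpin parts.

Each template was ordered as the reverse complement of (T7 promoter +
precursor).  Decoding reverse-complements it, strips the promoter, splits
the precursor at the scaffold loop, and annotates which arm is the guide by
matching it against the reporter transcript.
"""

from mimircraft import load_fixtures, decode_template, MIR2022_SCAFFOLD
from mimircraft.fixtures import MIMIR_TEMPLATE_NAMES

fx = load_fixtures()
target = fx["mcherry_mrna_nematostella_zebrafish"]

print(f"{'template':34s} {'guide 5p->3p':24s} mode            site")
for name in MIMIR_TEMPLATE_NAMES:
    d = decode_template(fx[name], MIR2022_SCAFFOLD, target)
    print(
        f"{name:34s} {d.guide.bases:24s} {d.pattern.value:15s} "
        f"{d.site_start}-{d.site_end}"
    )

# Every guide starts with U (guide-strand bias) and carries C at position 19
# (the base pairing the T7-required G at the precursor 5' end).
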