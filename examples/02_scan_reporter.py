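"""Scan the reporter mRNA for seed-match binding sites.

The printed reporter carries three 8-nt seed sites in its 3' UTR, spaced
exactly 21 bases apart, plus one full-length site for the near-full-match
mimic.  The scan slides the 21-nt guide along the transcript and keeps
windows whose positions 1-8 pair perfectly.
"""

from mimircraft import load_fixtures, scan_transcript, validate_construct
from mimircraft.verify import decode_all

fx = load_fixtures()
mcherry = fx["mcherry_mrna_nematostella_zebrafish"]
designs = decode_all()

seed_guide = designs["seed_match_template"].guide
full_guide = designs["full_match_mrna_template"].guide

report = validate_construct(mcherry, [seed_guide, full_guide])
print(f"kozak at position {report.kozak_position}, CDS {report.cds_start}-{report.cds_end}")
print(f"seed sites: {report.seed_site_count}, inter-site gaps: {report.seed_gaps}")
print(f"full-match sites: {report.full_site_count}")
for h in report.hits[seed_guide.id]:
    print(f"  seed hit {h.start}-{h.end}  seed region {h.seed_start}-{h.seed_end}  {h.region.value}")

# Expected output: 3 seed sites in the 3' UTR with gaps (21, 21) and one
# full-match site -- the architecture the reporter was built with.
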