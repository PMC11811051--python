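"""Design a new mimic against the reporter 3' UTR for each binding mode.

The designer picks a target window ending in A (so the guide starts with
U), takes its reverse complement, fixes position 19 to C, and converts the
mode's designed positions to non-pairing bases.  The star strand is then
derived under the scaffold's duplex register and the hairpin is emitted as
an ordered T7 template.
"""

from mimircraft import Category, design_mimic, load_fixtures

target = load_fixtures("mcherry_mrna_nematostella_zebrafish")

for cat in [Category.NEAR_FULL, Category.SEED_ONLY, Category.CENTRAL_MM_10]:
    d = design_mimic(target, cat, region=(750, 962))
    print(f"{cat.value}: site {d.site_start}-{d.site_end}")
    print(f"  guide     {d.guide.bases}")
    print(f"  star      {d.star.bases}")
    print(f"  template  {d.template.bases}")

# The guide differs between modes only at the designed mismatch positions;
# the template always ends with the reverse complement of the T7 promoter.
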