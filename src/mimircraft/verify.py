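"""Self-verification of the packaged reference sequences.

Runs the full decode/scan/spacing/classification battery against the
packaged templates and reporter rows and returns a structured pass/fail
report.  This is what the ``verify-reference`` CLI subcommand executes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constructs import validate_construct
from .design import MIR2022_SCAFFOLD, GENERIC_SCAFFOLD, assemble_design, decode_template
from .duplex import Category, DEFAULT_PATTERN, PairState
from .fixtures import MIMIR_TEMPLATE_NAMES, load_fixtures

__all__ = ["VerifyReport", "verify_reference_set", "EXPECTED_CATEGORIES", "decode_all"]

#: Intended complementarity mode of each packaged mimic against its target.
EXPECTED_CATEGORIES: dict[str, Category] = {
    "full_match_template": Category.NEAR_FULL,
    "seed_match_template": Category.SEED_ONLY,
    "seed_supplementary_template": Category.SEED_SUPPLEMENTARY,
    "mismatch_10_11_template": Category.CENTRAL_MM_10_11,
    "mismatch_10_template": Category.CENTRAL_MM_10,
    "mismatch_11_template": Category.CENTRAL_MM_11,
    "full_match_mrna_template": Category.NEAR_FULL,
}


@dataclass(frozen=True)
class VerifyReport:
    checks: dict[str, bool]

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def lines(self) -> list[str]:
        return [
            f"{'PASS' if v else 'FAIL'}  {name}" for name, v in sorted(self.checks.items())
        ]


def decode_all(with_target: bool = True):
    """Decode every packaged hairpin template; mimiRs against the reporter."""
    fx = load_fixtures()
    target = fx["mcherry_mrna_nematostella_zebrafish"] if with_target else None
    designs = {}
    for name in MIMIR_TEMPLATE_NAMES:
        designs[name] = decode_template(fx[name], MIR2022_SCAFFOLD, target)
    designs["negative_control_template"] = decode_template(
        fx["negative_control_template"], GENERIC_SCAFFOLD
    )
    return designs


def verify_reference_set() -> VerifyReport:
    fx = load_fixtures()
    checks: dict[str, bool] = {}
    designs = decode_all()

    # round trip: decode -> assemble reproduces every printed template
    for name, d in designs.items():
        re_t = assemble_design(
            d.guide, d.star, d.scaffold, d.promoter, loop=d.loop
        ).template
        checks[f"roundtrip_{name}"] = re_t.bases == fx[name].bases

    mimirs = {n: d for n, d in designs.items() if n in MIMIR_TEMPLATE_NAMES}
    checks["guides_start_with_U"] = all(d.guide[1] == "U" for d in mimirs.values())
    checks["guides_C_at_19"] = all(d.guide[19] == "C" for d in mimirs.values())
    checks["intended_categories"] = all(
        d.pattern is EXPECTED_CATEGORIES[n] for n, d in mimirs.items()
    )

    # seed-site census and spacing on the printed reporter
    seed_guide = designs["seed_match_template"].guide
    full_guide = designs["full_match_mrna_template"].guide
    report = validate_construct(
        fx["mcherry_mrna_nematostella_zebrafish"], [seed_guide, full_guide]
    )
    checks["three_seed_sites"] = len(report.hits[seed_guide.id]) == 3
    checks["seed_sites_in_utr3"] = all(
        h.region.value == "UTR3" for h in report.hits[seed_guide.id]
    )
    checks["uniform_gap_21"] = all(g == 21 for g in report.seed_gaps) and bool(report.seed_gaps)
    checks["one_full_match_site"] = len(report.full_hits[full_guide.id]) == 1

    # star pair-breaking positions under the calibrated register
    sc = MIR2022_SCAFFOLD
    for name, d in mimirs.items():
        bad = set()
        for j in range(1, sc.star_length + 1):
            g = sc.star_partner(j)
            if g is None:
                continue
            if (d.star[j], d.guide[g]) not in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                bad.add(j)
        checks[f"star_mismatches_{name}"] = bad == set(sc.star_mismatch_positions)
    return VerifyReport(checks)
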