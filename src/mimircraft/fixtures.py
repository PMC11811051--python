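"""Packaged reference sequences: mimic templates, reporter mRNAs, primers.

These are the published ordered-oligo sequences the toolkit was calibrated
against: eight hairpin (shRNA/mimiR) DNA templates, five reporter mRNA
template rows, the EF1-alpha kozak, and primer groups (metadata).  Each
entry is checksummed; :func:`load_fixtures` verifies integrity at load so a
packaging corruption fails loudly rather than silently skewing results.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .seqcore import Alphabet, NucleicSeq

__all__ = ["FixtureSet", "load_fixtures", "MIMIR_TEMPLATE_NAMES", "MRNA_TEMPLATE_NAMES"]

# --- hairpin templates (ordered ssDNA: revcomp of T7 promoter + precursor) ---

SHRNA_MIMIR_TEMPLATES: dict[str, str] = {
    "negative_control_template":
        "AAGCAACACGCAGAGTCGTAATCTCTTGAATTACGACTCTGCGTGTTGCTATAGTGAGTCGTATTA",
    "full_match_template":
        "TCGCCCTGAACCTGAAACATATGACAACCATAGGTTTCAGCGTCAGGGCTATAGTGAGTCGTATTA",
    "seed_match_template":
        "ATGGAGATGCGGAGAAACATATGACAACCATAGGTTTCTCGCCATCTCCTATAGTGAGTCGTATTA",
    "seed_supplementary_template":
        "ATGGACTGACGGAGAAACATATGACAACCATAGGTTTCTCGCTCAGTCCTATAGTGAGTCGTATTA",
    "mismatch_10_11_template":
        "TCGCCCTGAAGGTGAAACATATGACAACCATAGGTTTCACGGTCAGGGCTATAGTGAGTCGTATTA",
    "mismatch_10_template":
        "TCGCCCTGAACGTGAAACATATGACAACCATAGGTTTCACCGTCAGGGCTATAGTGAGTCGTATTA",
    "mismatch_11_template":
        "TCGCCCTGAAGCTGAAACATATGACAACCATAGGTTTCAGGGTCAGGGCTATAGTGAGTCGTATTA",
    "full_match_mrna_template":
        "GCGTCACAAATTTCACAAATATGACAACCATAGTTGTGAAGGTTGTGACTATAGTGAGTCGTATTA",
}

#: mimiR rows (everything except the generic negative-control shRNA)
MIMIR_TEMPLATE_NAMES: tuple[str, ...] = (
    "full_match_template",
    "seed_match_template",
    "seed_supplementary_template",
    "mismatch_10_11_template",
    "mismatch_10_template",
    "mismatch_11_template",
    "full_match_mrna_template",
)

KOZAK_EF1A = "TGTTAAACCAACCAACCACC"

# --- reporter mRNA template rows -------------------------------------------

MCHERRY_NV_ZF = (  # 962 nt
    "TAATACGACTCACTATAGTGTTAAACCAACCAACCACCATGGTGAGCAAGGGCGAGGAGGATAACATGGCCA"
    "TCATCAAGGAGTTCATGCGCTTCAAGGTGCACATGGAGGGCTCCGTGAACGGCCACGAGTTCGAGATCGAGG"
    "GCGAGGGCGAGGGCCGCCCCTACGAGGGCACCCAGACCGCCAAGCTGAAGGTGACCAAGGGTGGCCCCCTGC"
    "CCTTCGCCTGGGACATCCTGTCCCCTCAGTTCATGTACGGCTCCAAGGCCTACGTGAAGCACCCCGCCGACA"
    "TCCCCGACTACTTGAAGCTGTCCTTCCCCGAGGGCTTCAAGTGGGAGCGCGTGATGAACTTCGAGGACGGCG"
    "GCGTGGTGACCGTGACCCAGGACTCCTCCCTCCAGGACGGCGAGTTCATCTACAAGGTGAAGCTGCGCGGCA"
    "CCAACTTCCCCTCCGACGGCCCCGTAATGCAGAAGAAGACCATGGGCTGGGAGGCCTCCTCCGAGCGGATGT"
    "ACCCCGAGGACGGCGCCCTGAAGGGCGAGATCAAGCAGAGGCTGAAGCTGAAGGACGGCGGCCACTACGACG"
    "CTGAGGTCAAGACCACCTACAAGGCCAAGAAGCCCGTGCAGCTGCCCGGCGCCTACAACGTCAACATCAAGT"
    "TGGACATCACCTCCCACAACGAGGACTACACCATCGTGGAACAGTACGAACGCGCCGAGGGCCGCCACTCCA"
    "CCGGCGGCATGGACGAGCTGTACAAGTAAGACTCTAGATCATAATCAGCCATACCACATTTGTAGAGGTTTT"
    "ACTTGCTTTAAAAAACCTGAAACATACCCACACCTCCCCCTGAACCTGAAACATAAAATGAATGCAATTGTT"
    "GTTGGAAACATATTAACTTGTTTATTGCAGCTTATAATGGTTACAAATGAAAGCAATAGCATCACAAATTTC"
    "ACAAATAGAAGCATTTTTTTCACTGC"
)
MCHERRY_ZF_CLEANCAP = (  # 963 nt
    "TAATACGACTCACTATAAGTGTTAAACCAACCAACCACCATGGTGAGCAAGGGCGAGGAGGATAACATGGCC"
    "ATCATCAAGGAGTTCATGCGCTTCAAGGTGCACATGGAGGGCTCCGTGAACGGCCACGAGTTCGAGATCGAG"
    "GGCGAGGGCGAGGGCCGCCCCTACGAGGGCACCCAGACCGCCAAGCTGAAGGTGACCAAGGGTGGCCCCCTG"
    "CCCTTCGCCTGGGACATCCTGTCCCCTCAGTTCATGTACGGCTCCAAGGCCTACGTGAAGCACCCCGCCGAC"
    "ATCCCCGACTACTTGAAGCTGTCCTTCCCCGAGGGCTTCAAGTGGGAGCGCGTGATGAACTTCGAGGACGGC"
    "GGCGTGGTGACCGTGACCCAGGACTCCTCCCTCCAGGACGGCGAGTTCATCTACAAGGTGAAGCTGCGCGGC"
    "ACCAACTTCCCCTCCGACGGCCCCGTAATGCAGAAGAAGACCATGGGCTGGGAGGCCTCCTCCGAGCGGATG"
    "TACCCCGAGGACGGCGCCCTGAAGGGCGAGATCAAGCAGAGGCTGAAGCTGAAGGACGGCGGCCACTACGAC"
    "GCTGAGGTCAAGACCACCTACAAGGCCAAGAAGCCCGTGCAGCTGCCCGGCGCCTACAACGTCAACATCAAG"
    "TTGGACATCACCTCCCACAACGAGGACTACACCATCGTGGAACAGTACGAACGCGCCGAGGGCCGCCACTCC"
    "ACCGGCGGCATGGACGAGCTGTACAAGTAAGACTCTAGATCATAATCAGCCATACCACATTTGTAGAGGTTT"
    "TACTTGCTTTAAAAAACCTGAAACATACCCACACCTCCCCCTGAACCTGAAACATAAAATGAATGCAATTGT"
    "TGTTGGAAACATATTAACTTGTTTATTGCAGCTTATAATGGTTACAAATGAAAGCAATAGCATCACAAATTT"
    "CACAAATAGAAGCATTTTTTTCACTGC"
)
SFGFP_ZF = (  # 1031 nt
    "AATACACTTGTTCTTTTTGCAATATTCAAGCTCATCGATTCGAATTCATGCCTAAGAAGAAGAGAAAGGTGG"
    "TGTCTAAAGGAGAGGAGCTGTTCACAGGCGTGGTGCCAATCCTGGTGGAGCTGGATGGAGACGTGAACGGCC"
    "ACAAGTTCAGCGTGAGAGGCGAGGGAGAGGGAGACGCCACAAACGGCAAGCTGACACTGAAATTCATCTGCA"
    "CAACAGGCAAACTGCCTGTGCCTTGGCCAACCCTGGTGACAACCCTGACATACGGAGTGCAGTGCTTTAGCA"
    "GATACCCTGATCACATGAAACAGCACGATTTCTTCAAGAGCGCCATGCCTGAGGGCTACGTGCAGGAGAGAA"
    "CCATCAGCTTCAAGGATGACGGAACCTACAAGACAAGAGCCGAGGTGAAGTTTGAGGGAGATACACTGGTGA"
    "ACAGAATCGAGCTGAAAGGCATCGATTTCAAAGAGGATGGCAACATCCTGGGACACAAACTGGAGTACAACT"
    "TCAACAGCCACAACGTGTACATCACAGCCGATAAACAGAAGAACGGCATCAAAGCCAACTTCAAGATCAGAC"
    "ACAATGTGGAGGATGGATCTGTGCAGCTGGCCGATCACTACCAGCAGAACACACCTATCGGAGACGGCCCAG"
    "TGCTGCTGCCAGATAACCACTACCTGAGCACACAGAGCGTGCTGTCTAAAGACCCTAACGAGAAGAGAGATC"
    "ACATGGTGCTGCTGGAGTTTGTGACAGCCGCCGGAATCACCCTGGGCATGGATGAGCTGTACAAACCTGCTG"
    "CTAAGAGAGTGAAACTGGATTAGCTCGAGGATGCTAGGAGATCTGAGTTCAAGGATCCTGATTGTGGTAGTG"
    "ATCTGCCTTTCTTTCTTTTTTTTTTTTTGCCTGATCATCTCACACCCTTTCTTTCTTTTTTTTTTTTTGCCT"
    "GATCCATGACTCCTGTGATGGTATCTAGAACTATAGTGAGTCGTATTACACTAGTAAAAAAAAAAAAAAAAA"
    "AAAAAAAAAAAAAAAAAAAAAAA"
)
EGFP_HYDRACTINIA = (  # 973 nt
    "TAATACGACTCACTATTAGGTGTTAAACCAACCAACCACCATGGTATCCAAGGGCGAAGAATTATTTACTGG"
    "TGTTGTACCCATATTGGTGGAGCTCGACGGAGATGTAAATGGACACAAGTTCAGTGTGTCTGGGGAAGGAGA"
    "AGGAGATGCCACCTATGGAAAGCTGACTTTAAAGTTCATCTGTACTACGGGCAAGTTGCCTGTTCCTTGGCC"
    "TACACTTGTCACAACTCTGACATATGGTGTTCAATGCTTTTCGCGGTATCCGGATCATATGAAGCAGCACGA"
    "TTTTTTTAAGAGTGCGATGCCAGAAGGTTATGTTCAGGAAAGGACCATATTTTTCAAGGACGATGGAAATTA"
    "TAAAACCAGAGCTGAGGTAAAATTTGAAGGAGATACATTGGTTAATCGCATTGAATTAAAAGGAATCGATTT"
    "TAAAGAGGATGGTAACATCCTCGGTCATAAACTTGAGTATAACTACAACTCACATAACGTCTACATAATGGC"
    "TGATAAACAAAAAAATGGCATTAAAGTCAACTTTAAAATACGTCATAACATTGAAGACGGTTCAGTCCAACT"
    "TGCCGATCACTATCAACAAAACACTCCTATTGGTGACGGTCCAGTTTTGTTACCAGACAACCACTACCTATC"
    "TACACAAAGCGCCTTAAGCAAAGACCCAAATGAAAAAAGAGATCATATGGTTTTGCTGGAATTTGTTACAGC"
    "AGCTGGAATTACACTAGGAATGGATGAATTATACAAATAAGACTCTAGATCATAATCAGCCATACCACATTT"
    "GTAGAGGTTTTACTTGCTTTAAAAAACCTGAAACATACCCACACCTCCCCCTGAACCTGAAACATAAAATGA"
    "ATGCAATTGTTGTTGGAAACATATTAACTTGTTTATTGCAGCTTATAATGGTTACAAATGAAAGCAATAGCA"
    "TCACAAATTTCACAAATAGAAGCATTTTTTTCACTGC"
)
MCHERRY_HYDRACTINIA = (  # 964 nt
    "TAATACGACTCACTATTAGGTGTTAAACCAACCAACCACCATGGTCTCGAAAGGAGAAGAGGATAATATGGC"
    "TATAATTAAGGAATTTATGCGCTTTAAAGTGCACATGGAGGGCTCCGTGAACGGACACGAATTTGAAATTGA"
    "AGGCGAAGGTGAGGGAAGACCATACGAAGGAACACAGACCGCTAAACTTAAGGTCACAAAGGGCGGTCCATT"
    "ACCATTTGCATGGGACATCCTTTCACCCCAGTTCATGTACGGAAGCAAGGCATACGTTAAACATCCCGCTGA"
    "CATCCCCGACTACTTGAAGTTGAGCTTTCCAGAGGGATTTAAGTGGGAAAGAGTGATGAATTTCGAGGATGG"
    "AGGGGTTGTTACGGTAACCCAAGATTCCAGTCTCCAGGACGGGGAATTTATCTACAAGGTAAAGCTAAGAGG"
    "TACAAATTTTCCGAGTGATGGGCCTGTTATGCAAAAGAAGACAATGGGTTGGGAAGCCAGCTCCGAGCGCAT"
    "GTACCCCGAAGACGGAGCTTTAAAAGGAGAAATCAAGCAGCGACTGAAATTGAAAGATGGAGGTCATTATGA"
    "TGCAGAAGTTAAAACTACTTACAAAGCCAAAAAACCAGTTCAGTTACCAGGTGCATATAATGTTAACATAAA"
    "ACTAGACATCACATCACACAACGAGGACTATACGATCGTTGAACAATACGAGCGCGCGGAGGGTAGACATTC"
    "TACCGGTGGAATGGACGAGCTATATAAATAAGACTCTAGATCATAATCAGCCATACCACATTTGTAGAGGTT"
    "TTACTTGCTTTAAAAAACCTGAAACATACCCACACCTCCCCCTGAACCTGAAACATAAAATGAATGCAATTG"
    "TTGTTGGAAACATATTAACTTGTTTATTGCAGCTTATAATGGTTACAAATGAAAGCAATAGCATCACAAATT"
    "TCACAAATAGAAGCATTTTTTTCACTGC"
)

MRNA_TEMPLATES: dict[str, str] = {
    "mcherry_mrna_nematostella_zebrafish": "".join(MCHERRY_NV_ZF),
    "mcherry_mrna_zebrafish_cleancap": "".join(MCHERRY_ZF_CLEANCAP),
    "sfgfp_mrna_zebrafish": "".join(SFGFP_ZF),
    "egfp_mrna_hydractinia": "".join(EGFP_HYDRACTINIA),
    "mcherry_mrna_hydractinia": "".join(MCHERRY_HYDRACTINIA),
}

MRNA_TEMPLATE_NAMES: tuple[str, ...] = tuple(MRNA_TEMPLATES)

# --- primers (metadata only; not used computationally) ----------------------

PRIMER_GROUPS: dict[str, dict[str, str]] = {
    "qpcr": {
        "mcherry_forward": "GACATCCTGTCCCCTCAGTTC",
        "mcherry_reverse": "GGGGAAGGACAGCTTCAAGTA",
        "hkg4_forward": "GCTCAAACCTGGTCTTCTACCTATG",
        "hkg4_reverse": "GCGATGGGTGCAATGACA",
    },
    "mrna_nematostella": {
        "cloning_forward": "TGTTAAACCAACCAACCACCATGGTG",
        "cloning_reverse": "GCAGTGAAAAAAATGCTTCTATTTGTG",
    },
    "race3": {
        "race_pcr": "CAAGTTGGACATCACCTCCCACAACG",
        "race_nested_pcr": "ACTACACCATCGTGGAACAGTACGAAC",
    },
    "mrna_amplification": {
        "forward_phi25": "TTTAATACGACTCACTATTAGGTGTTAA",
        "reverse": "GCAGTGAAAAAAATGCTTCTATTTGTG",
        "forward_zebrafish": "TAATACGACTCACTATAAGTGTTAAACCAA",
        "reverse_zebrafish": "GCAGTGAAAAAAATGCTTCTATTTGTGAAA",
    },
}

PROMOTER_MOTIFS: dict[str, str] = {
    "t7_std": "TAATACGACTCACTATA",
    "t7_phi25": "TAATACGACTCACTATT",
    "sp6": "ATTTAGGTGACACTATA",
}

_ALL: dict[str, str] = {
    **SHRNA_MIMIR_TEMPLATES,
    **MRNA_TEMPLATES,
    "kozak": KOZAK_EF1A,
    **{f"promoter_{k}": v for k, v in PROMOTER_MOTIFS.items()},
}

#: sha256 of the concatenated catalogue, frozen at packaging time.
_CATALOGUE_SHA256 = "e976ffa6ab7c11ef23362e8081becb87f1bc54b0e873029c773dffc9c36bae67"


def _catalogue_digest() -> str:
    h = hashlib.sha256()
    for name in sorted(_ALL):
        h.update(name.encode())
        h.update(_ALL[name].encode())
    return h.hexdigest()


@dataclass(frozen=True)
class FixtureSet:
    """Validated, checksummed named sequences."""

    sequences: dict[str, NucleicSeq]
    primers: dict[str, dict[str, str]]

    def __getitem__(self, name: str) -> NucleicSeq:
        try:
            return self.sequences[name]
        except KeyError:
            raise KeyError(
                f"unknown fixture {name!r}; available: {sorted(self.sequences)}"
            ) from None


def load_fixtures(name: str | None = None) -> FixtureSet | NucleicSeq:
    """Load the full fixture set, or a single named sequence.

    Raises a packaging error if the catalogue checksum does not match.
    """
    digest = _catalogue_digest()
    if digest != _CATALOGUE_SHA256:
        raise RuntimeError(
            f"fixture catalogue checksum mismatch ({digest}); package is corrupted"
        )
    seqs = {n: NucleicSeq(n, Alphabet.DNA, s) for n, s in _ALL.items()}
    fs = FixtureSet(sequences=seqs, primers=PRIMER_GROUPS)
    if name is not None:
        return fs[name]
    return fs
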