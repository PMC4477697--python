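"""In-silico tryptic digestion shared by the FASTA map builder and SAAV checks."""

from __future__ import annotations

from pyteomics import parser

# Cleave C-terminal to K/R except before proline.
TRYPSIN_RULE = r"[KR](?!P)"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def tryptic_peptides(
    sequence: str,
    missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 40,
) -> set[str]:
    """Tryptic peptides of ``sequence`` (after K/R, not before P).

    Defaults match conventional search settings: up to two missed cleavages,
    peptide length 6-40 residues.
    """
    peps = parser.cleave(
        sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=min_length
    )
    return {p for p in peps if len(p) <= max_length}
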