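"""Vetting of single-amino-acid-variant (SAAV) peptides.

Variant peptides come from searches against sample-specific databases built
from RNA-seq variant calls.  This module applies the post-call filters
(SNP quality, mapping quality, read depth; gapped reads for indels),
classifies each proteomic SAAV by annotation source with the precedence
somatic > COSMIC > dbSNP > novel, and screens variant peptides for isobaric
collisions with the reference proteome — peptides identical after an
I <-> L substitution have the same mass and cannot be distinguished by the
mass spectrometer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from protasm.digest import AMINO_ACIDS, tryptic_peptides

ANNOTATION_CLASSES = ("TCGA-somatic", "COSMIC-supported", "dbSNP-supported", "novel")


@dataclass(frozen=True)
class VariantCall:
    """One RNA-seq variant call with the quality fields the filters need."""

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    snp_quality: float
    mapping_quality: float
    read_depth: int
    gapped_reads: int | None = None
    type: str = "SNV"

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.snp_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")


def filter_variants(calls) -> list[VariantCall]:
    """Retain calls passing SNP quality >= 20, mapping quality >= 20 and read
    depth >= 3; indels additionally need gapped reads >= 3."""
    retained = []
    for c in calls:
        if c.type not in ("SNV", "INDEL"):
            raise ValueError(f"unknown variant type {c.type!r}")
        ok = c.snp_quality >= 20 and c.mapping_quality >= 20 and c.read_depth >= 3
        if c.type == "INDEL":
            ok = ok and (c.gapped_reads is not None and c.gapped_reads >= 3)
        if ok:
            retained.append(c)
    return retained


def read_vcf(path, gapped_reads_key: str = "GR") -> list[VariantCall]:
    """Minimal VCF reader: CHROM/POS/REF/ALT, QUAL as SNP quality, INFO MQ
    and DP, and an INFO key for gapped reads (indels)."""
    from cyvcf2 import VCF

    calls = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            vtype = "SNV" if len(v.REF) == 1 and len(alt) == 1 else "INDEL"
            gapped = v.INFO.get(gapped_reads_key)
            calls.append(
                VariantCall(
                    chromosome=v.CHROM,
                    position=v.POS,
                    ref=v.REF,
                    alt=alt,
                    snp_quality=float(v.QUAL or 0.0),
                    mapping_quality=float(v.INFO.get("MQ") or 0.0),
                    read_depth=int(v.INFO.get("DP") or 0),
                    gapped_reads=int(gapped) if gapped is not None else None,
                    type=vtype,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# annotation


@dataclass
class VariantPeptide:
    """A peptide carrying one residue substitution relative to the reference.

    Keys for annotation lookups are protein-level tuples
    ``(gene, position, ref_residue, var_residue)`` to stay independent of
    genome builds.
    """

    peptide: str
    protein: str
    gene: str
    position: int  # variant position in the protein, 1-based
    ref_residue: str
    var_residue: str
    spectral_count: int = 0
    annotation: str | None = None
    isobar_collisions: list = field(default_factory=list)

    def __post_init__(self):
        if self.ref_residue == self.var_residue:
            raise ValueError("variant residue must differ from the reference residue")

    @property
    def key(self) -> tuple:
        return (self.gene, self.position, self.ref_residue, self.var_residue)


def classify_saav(variant: VariantPeptide, somatic: set, cosmic: set, dbsnp: set) -> str:
    """Annotation class with precedence somatic > COSMIC > dbSNP > novel."""
    if variant.key in somatic:
        return "TCGA-somatic"
    if variant.key in cosmic:
        return "COSMIC-supported"
    if variant.key in dbsnp:
        return "dbSNP-supported"
    return "novel"


# ---------------------------------------------------------------------------
# isobar screening


def _collapse_il(seq: str) -> str:
    return seq.replace("I", "L")


class IsobarIndex:
    """Reference tryptic peptides indexed by their I/L-collapsed sequence."""

    def __init__(self, proteome: dict[str, str], **digest_kwargs):
        self._index: dict[str, set[tuple[str, str]]] = {}
        for acc, seq in proteome.items():
            for pep in tryptic_peptides(seq, **digest_kwargs):
                self._index.setdefault(_collapse_il(pep), set()).add((pep, acc))

    @classmethod
    def from_fasta(cls, path, **digest_kwargs) -> "IsobarIndex":
        from pyteomics import fasta as pfasta

        proteome = {h.split()[0]: seq for h, seq in pfasta.read(str(path))}
        return cls(proteome, **digest_kwargs)

    def lookup(self, collapsed: str) -> set[tuple[str, str]]:
        return self._index.get(collapsed, set())


def isobar_check(
    query: str,
    index: IsobarIndex,
    exclude: tuple[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Reference tryptic peptides indistinguishable from ``query`` by mass.

    Returns every reference ``(peptide, protein)`` equal to the query after
    mapping I to L in both; a query without I or L therefore collides only
    on an exact sequence match.  ``exclude`` removes the variant's own
    source peptide (self-matches are not collisions).
    """
    bad = set(query) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in query: {sorted(bad)}")
    hits = set(index.lookup(_collapse_il(query)))
    if exclude is not None:
        hits.discard(tuple(exclude))
    return sorted(hits)


def saav_summary(variants) -> dict:
    """Tallies per annotation class and isobar status, plus the
    spectral-count distribution."""
    variants = list(variants)
    classes = Counter(v.annotation for v in variants)
    flagged = sum(1 for v in variants if v.isobar_collisions)
    counts = sorted(v.spectral_count for v in variants)
    return {
        "n_variants": len(variants),
        "by_class": {c: classes.get(c, 0) for c in ANNOTATION_CLASSES},
        "n_isobar_flagged": flagged,
        "n_novel_clean": sum(
            1 for v in variants if v.annotation == "novel" and not v.isobar_collisions
        ),
        "spectral_counts": {
            "min": counts[0] if counts else None,
            "median": counts[len(counts) // 2] if counts else None,
            "max": counts[-1] if counts else None,
        },
    }
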