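"""Reading, validating, writing and merging PSM identification results.

The canonical interchange format is a tab-separated table (UTF-8, ``#``
comment lines) with the columns

    sample  fraction  scan  engine  peptide  charge  score  proteins  decoy

where ``proteins`` is a semicolon-joined accession list and ``decoy`` is
0/1.  Peptide strings may carry modification annotations in square brackets
after the modified residue (e.g. ``PEPTM[+15.995]IDE``); I and L are kept
distinct at this layer.  Subset readers for mzIdentML and pepXML cover only
the elements needed to populate a record.

In memory a PSM table is a :class:`pandas.DataFrame` with the same columns
(``proteins`` as a tuple of accessions); :class:`PSMRecord` is the validated
row type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from protasm import fdr
from protasm.digest import tryptic_peptides

DEFAULT_DECOY_PREFIX = "XXX_"

PSM_COLUMNS = [
    "sample",
    "fraction",
    "scan",
    "engine",
    "peptide",
    "charge",
    "score",
    "proteins",
    "decoy",
]

_MOD_RE = re.compile(r"\[[^\]]*\]")


def strip_modifications(peptide: str) -> str:
    """Bare amino-acid sequence: bracketed modification annotations removed."""
    return _MOD_RE.sub("", peptide)


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum-to-peptide match from one search engine."""

    sample: str
    fraction: int
    scan: str
    engine: str
    peptide: str
    charge: int
    score: float
    proteins: tuple[str, ...]
    decoy: bool

    def validate(self, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> None:
        if not self.proteins:
            raise ValueError(f"PSM {self.scan}: empty protein accession set")
        if self.fraction < 1:
            raise ValueError(f"PSM {self.scan}: fraction must be 1-based, got {self.fraction}")
        if self.charge < 1:
            raise ValueError(f"PSM {self.scan}: non-positive charge {self.charge}")
        flags = {acc.startswith(decoy_prefix) for acc in self.proteins}
        if len(flags) > 1:
            raise ValueError(
                f"PSM {self.scan}: accessions mix decoy and target prefixes: {self.proteins}"
            )
        if flags != {self.decoy}:
            raise ValueError(
                f"PSM {self.scan}: decoy flag {self.decoy} inconsistent with "
                f"accessions {self.proteins}"
            )


def to_table(records: Iterable[PSMRecord]) -> pd.DataFrame:
    """Build the canonical PSM DataFrame from records."""
    rows = [
        (r.sample, r.fraction, r.scan, r.engine, r.peptide, r.charge, r.score, r.proteins, r.decoy)
        for r in records
    ]
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def to_records(table: pd.DataFrame) -> list[PSMRecord]:
    return [
        PSMRecord(
            sample=row.sample,
            fraction=int(row.fraction),
            scan=str(row.scan),
            engine=row.engine,
            peptide=row.peptide,
            charge=int(row.charge),
            score=float(row.score),
            proteins=tuple(row.proteins),
            decoy=bool(row.decoy),
        )
        for row in table.itertuples(index=False)
    ]


def read_psms(
    path,
    dialect: str = "tsv",
    engine: str | None = None,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[PSMRecord]:
    """Read one identification result file into validated records.

    ``dialect`` is one of ``tsv`` (canonical), ``mzid`` or ``pepxml``
    (element subsets).  ``engine`` overrides/supplies the engine name when
    the file metadata does not carry one.
    """
    if dialect == "tsv":
        records = _read_tsv(path, engine)
    elif dialect == "mzid":
        records = _read_mzid(path, engine, decoy_prefix)
    elif dialect == "pepxml":
        records = _read_pepxml(path, engine, decoy_prefix)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    seen: set[tuple] = set()
    for rec in records:
        rec.validate(decoy_prefix)
        key = (rec.sample, rec.fraction, rec.scan, rec.engine)
        if key in seen:
            raise ValueError(f"duplicate spectrum key within one file: {key}")
        seen.add(key)
    return records


def _read_tsv(path, engine: str | None) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "scan": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        accs = tuple(str(row.proteins).split(";")) if str(row.proteins) else ()
        try:
            records.append(
                PSMRecord(
                    sample=str(row.sample),
                    fraction=int(row.fraction),
                    scan=str(row.scan),
                    engine=engine or str(row.engine),
                    peptide=str(row.peptide),
                    charge=int(row.charge),
                    score=float(row.score),
                    proteins=accs,
                    decoy=bool(int(row.decoy)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return records


def _split_run_name(name: str) -> tuple[str, int]:
    """Parse 'SAMPLE_fNN' style run names into (sample, fraction); fall back
    to fraction 1 when no suffix is present."""
    m = re.match(r"^(.*)_f(\d+)$", name)
    if m:
        return m.group(1), int(m.group(2))
    return name, 1


def _read_mzid(path, engine, decoy_prefix) -> list[PSMRecord]:
    from pyteomics import mzid

    records = []
    with mzid.MzIdentML(str(path)) as reader:
        for sir in reader:
            scan = str(sir.get("spectrumID", sir.get("id")))
            sample, fraction = _split_run_name(Path(str(path)).stem)
            for item in sir.get("SpectrumIdentificationItem", []):
                accs = tuple(
                    sorted(
                        {
                            ev["accession"]
                            for ev in item.get("PeptideEvidence", [])
                            if "accession" in ev
                        }
                    )
                )
                score = item.get("MS-GF:SpecEValue", item.get("search engine specific score", 0.0))
                records.append(
                    PSMRecord(
                        sample=sample,
                        fraction=fraction,
                        scan=scan,
                        engine=engine or "MS-GF+",
                        peptide=item["PeptideSequence"],
                        charge=int(item.get("chargeState", 2)),
                        # E-value-like scores: smaller is better, negate the log
                        score=float(-np.log10(score)) if score > 0 else 0.0,
                        proteins=accs,
                        decoy=all(a.startswith(decoy_prefix) for a in accs) if accs else False,
                    )
                )
    return records


def _read_pepxml(path, engine, decoy_prefix) -> list[PSMRecord]:
    from pyteomics import pepxml

    records = []
    with pepxml.PepXML(str(path)) as reader:
        for psm in reader:
            scan = str(psm.get("start_scan", psm.get("spectrum")))
            sample, fraction = _split_run_name(Path(str(path)).stem)
            for hit in psm.get("search_hit", [])[:1]:
                accs = tuple(sorted(p["protein"] for p in hit.get("proteins", [])))
                scores = hit.get("search_score", {})
                score = float(next(iter(scores.values()), 0.0))
                records.append(
                    PSMRecord(
                        sample=sample,
                        fraction=fraction,
                        scan=scan,
                        engine=engine or "unknown",
                        peptide=hit["peptide"],
                        charge=int(psm.get("assumed_charge", 2)),
                        score=score,
                        proteins=accs,
                        decoy=all(a.startswith(decoy_prefix) for a in accs) if accs else False,
                    )
                )
    return records


def write_psms(table: pd.DataFrame | Iterable[PSMRecord], path) -> None:
    """Write a PSM table/record list in the canonical TSV dialect."""
    if not isinstance(table, pd.DataFrame):
        table = to_table(table)
    out = table.copy()
    out["proteins"] = [";".join(p) for p in out["proteins"]]
    out["decoy"] = out["decoy"].astype(int)
    out[PSM_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide <-> protein bipartite map


@dataclass
class BipartiteMap:
    """Peptide-protein incidence with gene annotation and protein lengths.

    Gene-level bookkeeping uses, per gene, the length of its longest protein
    isoform; the shortest such gene then represents a gene group (Occam's
    razor).
    """

    peptide_to_proteins: dict[str, frozenset[str]]
    protein_gene: dict[str, str]
    protein_length: dict[str, int]
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    _protein_to_peptides: dict[str, set[str]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for pep, accs in self.peptide_to_proteins.items():
            if not accs:
                raise ValueError(f"peptide {pep} maps to no protein")
        self._protein_to_peptides = {}
        for pep, accs in self.peptide_to_proteins.items():
            for acc in accs:
                self._protein_to_peptides.setdefault(acc, set()).add(pep)

    def is_decoy_protein(self, accession: str) -> bool:
        return accession.startswith(self.decoy_prefix)

    def proteins_for(self, peptide: str) -> frozenset[str]:
        return self.peptide_to_proteins[peptide]

    def peptides_for(self, accession: str) -> set[str]:
        return self._protein_to_peptides.get(accession, set())

    @property
    def proteins(self) -> set[str]:
        return set(self._protein_to_peptides)

    def gene_of(self, accession: str) -> str:
        return self.protein_gene.get(accession, accession)

    def gene_length(self, gene: str) -> int:
        """Length of the longest protein annotated to ``gene``."""
        lengths = [
            self.protein_length.get(acc, 0)
            for acc, g in self.protein_gene.items()
            if g == gene
        ]
        if not lengths:
            raise KeyError(f"no protein annotated to gene {gene}")
        return max(lengths)

    def to_gene_level(self) -> "BipartiteMap":
        """Collapse protein accessions to genes.

        The resulting map has one 'protein' per gene whose length is the
        longest isoform length.
        """
        pep_to_genes = {
            pep: frozenset(self.gene_of(acc) for acc in accs)
            for pep, accs in self.peptide_to_proteins.items()
        }
        gene_len: dict[str, int] = {}
        for acc, gene in self.protein_gene.items():
            gene_len[gene] = max(gene_len.get(gene, 0), self.protein_length.get(acc, 0))
        genes = {g for gs in pep_to_genes.values() for g in gs} | set(gene_len)
        return BipartiteMap(
            peptide_to_proteins=pep_to_genes,
            protein_gene={g: g for g in genes},
            protein_length={g: gene_len.get(g, 0) for g in genes},
            decoy_prefix=self.decoy_prefix,
        )

    @classmethod
    def from_fasta(
        cls,
        fasta_path,
        annotations=None,
        decoy_prefix: str = DEFAULT_DECOY_PREFIX,
        add_decoys: bool = False,
        **digest_kwargs,
    ) -> "BipartiteMap":
        """Digest a protein FASTA into a peptide-protein map.

        ``annotations`` is an optional sidecar TSV path with columns
        ``accession``, ``gene``, ``length``; absent annotations default to
        gene = accession and length = sequence length.  With ``add_decoys``
        a reversed-sequence decoy is generated for every target entry.
        """
        from pyteomics import fasta as pfasta

        pep_to_prot: dict[str, set[str]] = {}
        gene: dict[str, str] = {}
        length: dict[str, int] = {}
        for header, seq in pfasta.read(str(fasta_path)):
            acc = header.split()[0]
            entries = [(acc, seq)]
            if add_decoys and not acc.startswith(decoy_prefix):
                entries.append((decoy_prefix + acc, seq[::-1]))
            for a, s in entries:
                gene[a] = a
                length[a] = len(s)
                for pep in tryptic_peptides(s, **digest_kwargs):
                    pep_to_prot.setdefault(pep, set()).add(a)
        if annotations is not None:
            ann = pd.read_csv(annotations, sep="\t")
            for row in ann.itertuples(index=False):
                gene[row.accession] = str(row.gene)
                length[row.accession] = int(row.length)
                dacc = decoy_prefix + str(row.accession)
                if dacc in gene:
                    gene[dacc] = decoy_prefix + str(row.gene)
                    length[dacc] = int(row.length)
        return cls(
            peptide_to_proteins={p: frozenset(a) for p, a in pep_to_prot.items()},
            protein_gene=gene,
            protein_length=length,
            decoy_prefix=decoy_prefix,
        )


# ---------------------------------------------------------------------------
# inclusive multi-engine combination


def merge_engines(streams: Sequence[pd.DataFrame | Iterable[PSMRecord]]) -> pd.DataFrame:
    """Inclusive best-score combination of per-engine PSM streams.

    Engines score on incommensurable scales, so each engine's scores are
    first converted to per-engine q-values (decoy-doubling estimator); for
    every spectrum (sample, fraction, scan) identified by several engines
    the record with the lowest q-value is kept, ties broken by higher raw
    score then engine name.  Spectra identified by a single engine are kept
    unchanged, so the output is the union of spectra across engines.

    The returned table carries ``engine_q`` (per-engine q-value) and
    ``qvalue`` (q-value recomputed on the merged set, ordering records by
    ``engine_q``), which downstream assembly filters on.
    """
    frames = []
    for s in streams:
        df = s if isinstance(s, pd.DataFrame) else to_table(s)
        frames.append(df)
    psms = pd.concat(frames, ignore_index=True)
    if psms.empty:
        out = psms.copy()
        out["engine_q"] = np.empty(0)
        out["qvalue"] = np.empty(0)
        return out

    # consistency of duplicate (engine, spectrum) entries
    dup_key = ["sample", "fraction", "scan", "engine"]
    dup = psms.groupby(dup_key)["peptide"].nunique()
    bad = dup[dup > 1]
    if len(bad):
        raise ValueError(
            f"inconsistent peptide assignments for identical engine+scan: {list(bad.index[:5])}"
        )
    psms = (
        psms.sort_values("score", ascending=False)
        .drop_duplicates(dup_key, keep="first")
        .reset_index(drop=True)
    )

    psms["engine_q"] = np.nan
    for eng, idx in psms.groupby("engine").groups.items():
        sub = psms.loc[idx]
        psms.loc[idx, "engine_q"] = fdr.qvalues(sub["score"].to_numpy(), sub["decoy"].to_numpy())

    psms = psms.sort_values(
        ["engine_q", "score", "engine"], ascending=[True, False, True], kind="stable"
    )
    merged = psms.drop_duplicates(["sample", "fraction", "scan"], keep="first").reset_index(
        drop=True
    )
    merged["qvalue"] = fdr.qvalues(-merged["engine_q"].to_numpy(), merged["decoy"].to_numpy())
    return merged
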