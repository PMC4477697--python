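"""Parsimony protein/gene assembly with target-decoy FDR control.

Accepted PSMs (filtered on q-value) define a set of observed peptides;
proteins indiscernible on that peptide evidence are merged into groups, and
a minimal set of groups explaining every observed peptide is chosen greedily
(largest remaining coverage first).  Stringency filters — a minimum number
of distinct peptides and a minimum spectral count per group — mirror the
standard practice of requiring two peptides per protein.  FDR is estimated
at the PSM, peptide and group level with the decoy-doubling convention
(see :mod:`protasm.fdr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protasm.fdr import FdrEstimate, decoy_doubling, estimate_fdr, qvalues  # noqa: F401
from protasm.psm_io import BipartiteMap, strip_modifications


@dataclass(frozen=True)
class AssemblyConfig:
    """Filter stringency for one assembly pass.

    ``psm_fdr_max`` is the q-value cutoff on PSMs; ``min_distinct_peptides``
    is the classic two-peptide rule (distinct bare sequences, modification
    states collapsed); ``min_spectra_per_protein`` drops weakly supported
    groups; ``level`` selects protein or gene grouping.
    """

    psm_fdr_max: float = 0.02
    min_distinct_peptides: int = 2
    min_spectra_per_protein: int = 1
    level: str = "protein"

    def __post_init__(self):
        if not 0 < self.psm_fdr_max <= 1:
            raise ValueError(f"psm_fdr_max must be in (0, 1], got {self.psm_fdr_max}")
        if self.min_distinct_peptides < 1 or self.min_spectra_per_protein < 1:
            raise ValueError("minimum peptide/spectrum counts must be >= 1")
        if self.level not in ("protein", "gene"):
            raise ValueError(f"level must be 'protein' or 'gene', got {self.level!r}")


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins indiscernible on the observed peptide evidence.

    The representative is the lexicographically smallest member accession —
    a deterministic stand-in for an arbitrary choice.
    """

    members: frozenset[str]
    representative: str
    peptides: frozenset[str]
    spectral_count: int
    is_decoy: bool


@dataclass(frozen=True)
class GeneGroup:
    """Genes indiscernible on the observed peptide evidence.

    The representative is the member gene whose longest protein isoform is
    shortest (Occam's razor); ties resolve lexicographically.
    """

    members: frozenset[str]
    representative: str
    peptides: frozenset[str]
    spectral_count: int
    is_decoy: bool


@dataclass
class AssemblyResult:
    """Groups, retained PSMs and per-level FDRs from one assembly pass."""

    groups: list
    retained_psms: pd.DataFrame
    psm_fdr: float | None
    peptide_fdr: float | None
    group_fdr: float | None
    level: str = "protein"
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_target_groups(self) -> int:
        return sum(1 for g in self.groups if not g.is_decoy)

    @property
    def distinct_peptides(self) -> set[str]:
        return set().union(*(g.peptides for g in self.groups)) if self.groups else set()

    @property
    def n_spectra(self) -> int:
        return len(self.retained_psms)


def _group_fdr(groups) -> float | None:
    if not groups:
        return None
    n_decoy = sum(1 for g in groups if g.is_decoy)
    return decoy_doubling(len(groups) - n_decoy, n_decoy)


def parsimony(
    bmap: BipartiteMap,
    retained_peptides,
    peptide_spectra: dict[str, int] | None = None,
    min_distinct_peptides: int = 1,
    min_spectra: int = 1,
    level: str = "protein",
) -> list:
    """Greedy minimal set cover over indiscernible-protein clusters.

    1. proteins with identical observed-peptide sets are merged into one
       candidate group;
    2. groups are selected greedily by largest remaining peptide coverage
       (ties: larger spectral count, then smallest member accession) until
       every retained peptide is explained;
    3. groups failing the distinct-peptide or spectral-count minima are
       dropped, together with the peptides only they explained.

    Returns :class:`ProteinGroup` (or :class:`GeneGroup` at gene level)
    objects sorted by representative.
    """
    retained = set(retained_peptides)
    orphans = [p for p in retained if p not in bmap.peptide_to_proteins]
    if orphans:
        raise ValueError(f"peptides absent from the protein map: {sorted(orphans)[:5]}")
    if peptide_spectra is None:
        peptide_spectra = {p: 1 for p in retained}

    clusters: dict[frozenset[str], set[str]] = {}
    for acc in bmap.proteins:
        peps = frozenset(bmap.peptides_for(acc) & retained)
        if peps:
            clusters.setdefault(peps, set()).add(acc)

    remaining = [
        (peps, frozenset(members), sum(peptide_spectra.get(p, 0) for p in peps))
        for peps, members in clusters.items()
    ]

    uncovered = set(retained)
    selected = []
    while uncovered:
        best = min(
            remaining,
            key=lambda e: (-len(e[0] & uncovered), -e[2], min(e[1])),
        )
        selected.append(best)
        uncovered -= best[0]
        remaining.remove(best)

    # a group picked early can become redundant after later picks; prune so
    # that removing any selected group would lose at least one peptide
    pruned = True
    while pruned:
        pruned = False
        for entry in sorted(selected, key=lambda e: (len(e[0]), e[2], min(e[1]))):
            others = set().union(*(e[0] for e in selected if e is not entry)) if len(selected) > 1 else set()
            if entry[0] <= others:
                selected.remove(entry)
                pruned = True
                break

    kept = [
        (members, peps, spectra)
        for peps, members, spectra in selected
        if len(peps) >= min_distinct_peptides and spectra >= min_spectra
    ]
    return _wrap_groups(kept, bmap, level)


def _wrap_groups(raw_groups, bmap: BipartiteMap, level: str):
    groups = []
    for members, peptides, spectra in raw_groups:
        is_decoy = any(m.startswith(bmap.decoy_prefix) for m in members)
        if level == "gene":
            # shortest longest-isoform length represents the gene group
            rep = min(members, key=lambda g: (bmap.protein_length.get(g, 0), g))
            cls = GeneGroup
        else:
            rep = min(members)
            cls = ProteinGroup
        groups.append(
            cls(
                members=members,
                representative=rep,
                peptides=peptides,
                spectral_count=spectra,
                is_decoy=is_decoy,
            )
        )
    return sorted(groups, key=lambda g: g.representative)


def assemble(psms: pd.DataFrame, bmap: BipartiteMap, config: AssemblyConfig) -> AssemblyResult:
    """Filter PSMs at a q-value threshold and assemble parsimony groups.

    ``psms`` is a merged PSM table; a ``qvalue`` column is used when present
    (e.g. from :func:`protasm.psm_io.merge_engines`) and computed from raw
    scores otherwise.  At ``level='gene'`` protein accessions collapse to
    genes before grouping.  An empty retained set yields a structured empty
    result with diagnostics rather than an exception.
    """
    psms = psms.copy()
    if "qvalue" not in psms.columns:
        psms["qvalue"] = qvalues(psms["score"].to_numpy(), psms["decoy"].to_numpy())

    kept = psms[psms["qvalue"] <= config.psm_fdr_max]
    if kept.empty:
        return AssemblyResult(
            groups=[],
            retained_psms=kept,
            psm_fdr=None,
            peptide_fdr=None,
            group_fdr=None,
            level=config.level,
            diagnostics={"reason": "no PSM passed the q-value filter", "n_input": len(psms)},
        )

    n_decoy_psm = int(kept["decoy"].sum())
    psm_fdr = decoy_doubling(len(kept) - n_decoy_psm, n_decoy_psm)

    bare = kept["peptide"].map(strip_modifications)
    pep_decoy = kept.groupby(bare)["decoy"].any()
    peptide_fdr = decoy_doubling(int((~pep_decoy).sum()), int(pep_decoy.sum()))
    peptide_spectra = bare.value_counts().to_dict()

    level_map = bmap.to_gene_level() if config.level == "gene" else bmap
    groups = parsimony(
        level_map,
        set(pep_decoy.index),
        peptide_spectra,
        min_distinct_peptides=config.min_distinct_peptides,
        min_spectra=config.min_spectra_per_protein,
        level=config.level,
    )
    explained = set().union(*(g.peptides for g in groups)) if groups else set()

    retained = kept[bare.isin(explained)].copy()
    retained["bare_peptide"] = bare[bare.isin(explained)]
    return AssemblyResult(
        groups=groups,
        retained_psms=retained,
        psm_fdr=psm_fdr,
        peptide_fdr=peptide_fdr,
        group_fdr=_group_fdr(groups),
        level=config.level,
        diagnostics={
            "n_input_psms": len(psms),
            "n_kept_psms": len(kept),
            "n_retained_psms": len(retained),
            "mixed_groups": sum(
                1
                for g in groups
                if len({m.startswith(level_map.decoy_prefix) for m in g.members}) > 1
            ),
        },
    )


def fdr_tradeoff_sweep(
    psms: pd.DataFrame,
    bmap: BipartiteMap,
    psm_fdr_grid,
    min_spectra_grid,
    protein_fdr_cap: float,
    min_distinct_peptides: int = 2,
    level: str = "protein",
) -> pd.DataFrame:
    """PSM-FDR vs minimum-spectral-count tradeoff.

    For each PSM FDR threshold, the smallest spectral-count minimum whose
    surviving groups meet the group-level FDR cap, and the resulting target
    group count.  Grid points where the cap is unachievable are recorded
    with missing values.  Groups are assembled once per threshold; the
    spectral-count minimum is applied as a post-hoc filter on the groups.
    """
    if len(list(psm_fdr_grid)) == 0 or len(list(min_spectra_grid)) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for f in sorted(psm_fdr_grid):
        res = assemble(
            psms,
            bmap,
            AssemblyConfig(
                psm_fdr_max=f,
                min_distinct_peptides=min_distinct_peptides,
                min_spectra_per_protein=1,
                level=level,
            ),
        )
        found = False
        for m in sorted(min_spectra_grid):
            surviving = [g for g in res.groups if g.spectral_count >= m]
            gf = _group_fdr(surviving)
            if gf is not None and gf <= protein_fdr_cap:
                rows.append(
                    {
                        "psm_fdr": f,
                        "min_spectra": m,
                        "group_fdr": gf,
                        "n_groups": sum(1 for g in surviving if not g.is_decoy),
                    }
                )
                found = True
                break
        if not found:
            rows.append(
                {"psm_fdr": f, "min_spectra": np.nan, "group_fdr": np.nan, "n_groups": np.nan}
            )
    return pd.DataFrame(rows)
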