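"""Two-step stringent/rescue FDR procedure.

Large multi-sample assemblies suffer from the accumulation of false protein
identifications: at a conventional PSM FDR, the spectral-count minimum
needed to control the protein-level FDR discards many true proteins.  The
two-step procedure first assembles at a very stringent PSM threshold
(default 0.1% FDR), which defines a locked inventory of confidently
identified groups, then re-admits ("rescues") PSMs at a relaxed threshold
(default 1%) only when they map to an inventory group.  Rescue grows the
peptide and spectrum counts of the inventory without ever adding or removing
groups, so the group-level FDR established in step one is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protasm.assembly import AssemblyConfig, AssemblyResult, assemble, _group_fdr
from protasm.psm_io import BipartiteMap, strip_modifications


@dataclass(frozen=True)
class RescueConfig:
    """Thresholds for the two-step procedure (step 1 inherits the assembly
    filters)."""

    stringent_psm_fdr: float = 0.001
    relaxed_psm_fdr: float = 0.01
    min_distinct_peptides: int = 2
    min_spectra_per_protein: int = 1
    level: str = "protein"

    def __post_init__(self):
        if self.stringent_psm_fdr > self.relaxed_psm_fdr:
            raise ValueError(
                f"stringent threshold {self.stringent_psm_fdr} exceeds "
                f"relaxed threshold {self.relaxed_psm_fdr}"
            )

    def step1(self) -> AssemblyConfig:
        return AssemblyConfig(
            psm_fdr_max=self.stringent_psm_fdr,
            min_distinct_peptides=self.min_distinct_peptides,
            min_spectra_per_protein=self.min_spectra_per_protein,
            level=self.level,
        )


@dataclass
class RescueResult:
    """Inventory from step 1 plus the PSMs admitted in step 2.

    The group set is identical between ``inventory`` and the final result;
    ``final_psms`` is the union of step-1 retained PSMs and ``rescued_psms``.
    ``group_fdr_final`` re-runs the decoy-doubling tally over the (unchanged)
    inventory groups so both the locked and the recomputed figure are
    available.
    """

    inventory: AssemblyResult
    rescued_psms: pd.DataFrame
    final_psms: pd.DataFrame
    median_rescued_q: float  # NaN when nothing was rescued
    group_fdr_final: float | None
    final_group_counts: dict = field(default_factory=dict)

    @property
    def groups(self):
        return self.inventory.groups

    @property
    def final_distinct_peptides(self) -> set[str]:
        return set(self.final_psms["bare_peptide"]) if len(self.final_psms) else set()

    @property
    def retained_psms(self) -> pd.DataFrame:
        """Alias making the result quack like an AssemblyResult for quant."""
        return self.final_psms


def two_step_assemble(
    psms: pd.DataFrame, bmap: BipartiteMap, config: RescueConfig
) -> RescueResult:
    """Assemble at the stringent threshold, then rescue PSMs at the relaxed
    threshold that map to an inventory group.

    A candidate PSM is rescued if at least one of its mapped units (proteins,
    or genes at gene level) belongs to an inventory group; mappings to
    non-inventory units are pruned from the record, and PSMs mapping only to
    non-inventory units are rejected.  Rescued PSMs update the spectral
    counts of inventory groups but never resurrect dropped proteins.
    """
    psms = psms.copy()
    if "qvalue" not in psms.columns:
        from protasm.fdr import qvalues

        psms["qvalue"] = qvalues(psms["score"].to_numpy(), psms["decoy"].to_numpy())

    inventory = assemble(psms, bmap, config.step1())
    inventory_units: set[str] = (
        set().union(*(g.members for g in inventory.groups)) if inventory.groups else set()
    )

    step1_idx = set(inventory.retained_psms.index)
    cand = psms[(psms["qvalue"] <= config.relaxed_psm_fdr) & ~psms.index.isin(step1_idx)]

    rescued_rows = []
    for idx, row in cand.iterrows():
        units = _units_of(row, bmap, config.level)
        surviving = tuple(sorted(units & inventory_units))
        if surviving:
            new = row.copy()
            if config.level == "protein":
                new["proteins"] = surviving  # prune non-inventory mappings
            new["bare_peptide"] = strip_modifications(row["peptide"])
            rescued_rows.append((idx, new))

    if rescued_rows:
        rescued = pd.DataFrame([r for _, r in rescued_rows], index=[i for i, _ in rescued_rows])
    else:
        rescued = inventory.retained_psms.iloc[0:0].copy()

    final = pd.concat([inventory.retained_psms, rescued])
    median_q = float(rescued["qvalue"].median()) if len(rescued) else float("nan")

    # final per-group spectral counts: a PSM counts for every inventory
    # group one of its mapped units belongs to (inclusive counting)
    member_groups: dict[str, list] = {}
    for g in inventory.groups:
        for m in g.members:
            member_groups.setdefault(m, []).append(g)
    final_counts = {g.representative: 0 for g in inventory.groups}
    for _, row in final.iterrows():
        hit = set()
        for unit in _units_of(row, bmap, config.level):
            for g in member_groups.get(unit, ()):
                hit.add(g.representative)
        for rep in hit:
            final_counts[rep] += 1

    return RescueResult(
        inventory=inventory,
        rescued_psms=rescued,
        final_psms=final,
        median_rescued_q=median_q,
        group_fdr_final=_group_fdr(inventory.groups),
        final_group_counts=final_counts,
    )


def _units_of(row, bmap: BipartiteMap, level: str) -> set[str]:
    if level == "gene":
        return {bmap.gene_of(a) for a in row["proteins"]}
    return set(row["proteins"])


def rescue_report(result: RescueResult) -> dict:
    """Summary counts and rescued-PSM q-value quantiles."""
    inv = result.inventory
    rescued_q = result.rescued_psms["qvalue"] if len(result.rescued_psms) else pd.Series(dtype=float)
    quantiles = (
        {q: float(rescued_q.quantile(q)) for q in (0.25, 0.5, 0.75)}
        if len(rescued_q)
        else {q: None for q in (0.25, 0.5, 0.75)}
    )
    return {
        "level": inv.level,
        "n_groups": inv.n_groups,
        "n_target_groups": inv.n_target_groups,
        "group_fdr_step1": inv.group_fdr,
        "group_fdr_final": result.group_fdr_final,
        "step1_distinct_peptides": len(inv.distinct_peptides),
        "final_distinct_peptides": len(result.final_distinct_peptides),
        "step1_spectra": inv.n_spectra,
        "final_spectra": len(result.final_psms),
        "n_rescued": len(result.rescued_psms),
        "median_rescued_q": None if np.isnan(result.median_rescued_q) else result.median_rescued_q,
        "rescued_q_quantiles": quantiles,
    }
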