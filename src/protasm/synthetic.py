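"""Synthetic fixtures with known ground truth.

Three generators emulate the data shapes the rest of the package consumes:

- :func:`simulate_psms` — multi-engine PSM streams over a known
  peptide-protein bipartite map with reversed-sequence decoys, emulating a
  sample x fraction x engine file structure (e.g. 95 x 15 x 3 = 4,275
  per-fraction-per-engine result units);
- :func:`simulate_qc_metrics` — run x metric tables (44 metrics by default,
  one row per LC-MS/MS run, so 95 samples x 15 fractions = 1,425 rows) with
  batch drift, zero-variance columns and injected outliers;
- :func:`simulate_counts` — two-group spectral-count matrices with planted
  fold-change signatures.

Everything is driven by a single integer seed; a fixed seed reproduces the
output exactly.  :func:`concatenation_scheme` is a bookkeeping helper for
interleaved pooling of first-dimension chromatography fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from protasm.psm_io import DEFAULT_DECOY_PREFIX, BipartiteMap
from protasm.qc import QCMetricsTable
from protasm.quant import SpectralCountMatrix

_AA = np.array(list("ACDEFGHMNQSTVWY"))  # avoid K/R/P internally, I/L for clarity


# ---------------------------------------------------------------------------
# PSM simulation


@dataclass(frozen=True)
class PsmSimConfig:
    """Conditions for the PSM stream generator.

    True proteins generate correct identifications with scores from a Gumbel
    distribution; random (false) matches draw uniformly from the combined
    target+decoy peptide space with Gaussian scores, so decoy matches occur
    at the same rate as false target matches — the assumption behind the
    decoy-doubling estimator.  Structure defaults mirror a large multi-site
    study layout (95 samples, 15 fractions, 3 engines); protein counts are
    desk-scale.
    """

    n_true_proteins: int = 150
    n_absent_proteins: int = 150
    peptides_per_protein: float = 8.0  # Poisson mean, floor 1
    shared_peptide_fraction: float = 0.1
    n_samples: int = 95
    n_fractions: int = 15
    n_engines: int = 3
    target_score_params: tuple[float, float] = (4.0, 1.0)  # Gumbel loc, scale
    decoy_score_params: tuple[float, float] = (0.0, 1.0)  # Normal loc, scale
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    spectra_per_true_peptide: float = 1.0  # Poisson mean per sample
    abundance_sigma: float = 1.0  # lognormal spread of per-protein abundance
    random_matches_per_peptide: float = 0.02  # Poisson mean per pool peptide per sample
    engine_detect_prob: float = 0.8
    isoform_gene_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_true_proteins < 0 or self.n_absent_proteins < 0:
            raise ValueError("protein counts must be non-negative")
        if self.n_true_proteins + self.n_absent_proteins == 0:
            raise ValueError("at least one protein is required")
        if min(self.n_samples, self.n_fractions, self.n_engines) < 1:
            raise ValueError("samples, fractions and engines must be positive")
        if not 0 <= self.shared_peptide_fraction <= 1:
            raise ValueError("shared_peptide_fraction must be in [0, 1]")
        if self.target_score_params[1] < 0 or self.decoy_score_params[1] < 0:
            raise ValueError("score scales must be non-negative")


def _random_peptides(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Unique tryptic-looking peptides: random residues ending in K or R."""
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(7, 20))
        pep = "".join(rng.choice(_AA, size=length - 1)) + str(rng.choice(["K", "R"]))
        if pep not in taken:
            taken.add(pep)
            out.append(pep)
    return out


def simulate_psms(config: PsmSimConfig):
    """Generate per-(sample, fraction, engine) PSM streams.

    Returns ``(psm_table, bipartite_map, true_proteins)`` where ``psm_table``
    is the canonical PSM DataFrame (one row per engine observation of a
    spectrum) plus a ground-truth ``true_match`` column, ``bipartite_map``
    covers targets and their reversed-sequence decoys, and ``true_proteins``
    is the set of accessions actually present.
    """
    rng = np.random.default_rng(config.seed)
    n_t, n_a = config.n_true_proteins, config.n_absent_proteins
    accs = [f"TP{i:05d}" for i in range(n_t)] + [f"AP{i:05d}" for i in range(n_a)]
    true_proteins = set(accs[:n_t])

    taken: set[str] = set()
    pep_to_prot: dict[str, set[str]] = {}
    prot_peptides: dict[str, list[str]] = {}
    n_peps = np.maximum(1, rng.poisson(config.peptides_per_protein, size=len(accs)))
    for acc, k in zip(accs, n_peps):
        peps = _random_peptides(rng, int(k), taken)
        prot_peptides[acc] = peps
        for p in peps:
            pep_to_prot.setdefault(p, set()).add(acc)

    # plant shared (degenerate) peptides so parsimony is non-trivial
    all_peps = [p for acc in accs for p in prot_peptides[acc]]
    n_shared = int(round(config.shared_peptide_fraction * len(all_peps)))
    if n_shared and len(accs) > 1:
        for p in rng.choice(len(all_peps), size=n_shared, replace=False):
            pep = all_peps[p]
            other = accs[int(rng.integers(len(accs)))]
            pep_to_prot[pep].add(other)

    # reversed-sequence decoys mirror every target
    for acc in accs:
        dacc = config.decoy_prefix + acc
        for pep in {p for p, owners in list(pep_to_prot.items()) if acc in owners}:
            rev = pep[::-1]
            pep_to_prot.setdefault(rev, set()).add(dacc)

    # overlap between a reversed peptide and a target peptide would blur the
    # target/decoy partition; the random alphabet makes it vanishingly rare
    mixed = [
        p
        for p, owners in pep_to_prot.items()
        if len({o.startswith(config.decoy_prefix) for o in owners}) > 1
    ]
    for p in mixed:  # pragma: no cover - astronomically unlikely
        del pep_to_prot[p]

    # gene annotation: a fraction of adjacent same-class proteins share a gene
    protein_gene: dict[str, str] = {}
    protein_length: dict[str, int] = {}
    gene_idx = 0
    prev_gene = None
    for i, acc in enumerate(accs):
        if prev_gene is not None and rng.random() < config.isoform_gene_fraction:
            gene = prev_gene
        else:
            gene = f"GENE{gene_idx:05d}"
            gene_idx += 1
        prev_gene = gene
        protein_gene[acc] = gene
        protein_length[acc] = int(
            sum(len(p) for p in prot_peptides[acc]) + rng.integers(20, 200)
        )
        protein_gene[config.decoy_prefix + acc] = config.decoy_prefix + gene
        protein_length[config.decoy_prefix + acc] = protein_length[acc]

    bmap = BipartiteMap(
        peptide_to_proteins={p: frozenset(o) for p, o in pep_to_prot.items()},
        protein_gene=protein_gene,
        protein_length=protein_length,
        decoy_prefix=config.decoy_prefix,
    )

    true_peps = sorted({p for acc in true_proteins for p in prot_peptides[acc]})
    # protein abundances span orders of magnitude; each true peptide inherits
    # the abundance of its generating protein
    abundance = {
        acc: float(np.exp(rng.normal(0.0, config.abundance_sigma))) for acc in sorted(true_proteins)
    }
    pep_rate = {}
    for acc in sorted(true_proteins):
        for p in prot_peptides[acc]:
            pep_rate.setdefault(p, abundance[acc])
    pool = sorted(pep_to_prot)  # all target + decoy peptides, the false-match space
    gloc, gscale = config.target_score_params
    nloc, nscale = config.decoy_score_params
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    engines = [f"engine{k + 1}" for k in range(config.n_engines)]

    rows = {
        c: []
        for c in ("sample", "fraction", "scan", "engine", "peptide", "charge", "score", "decoy", "true_match")
    }
    proteins_col: list[tuple[str, ...]] = []
    for sample in samples:
        spec_peps: list[str] = []
        spec_true: list[bool] = []
        if true_peps:
            lam = config.spectra_per_true_peptide * np.array([pep_rate[p] for p in true_peps])
            counts = rng.poisson(lam)
            for pep, c in zip(true_peps, counts):
                spec_peps.extend([pep] * int(c))
            spec_true = [True] * len(spec_peps)
        n_rand = rng.poisson(config.random_matches_per_peptide * len(pool))
        if n_rand:
            picks = rng.integers(0, len(pool), size=int(n_rand))
            spec_peps.extend(pool[i] for i in picks)
            spec_true.extend([False] * int(n_rand))
        n_spec = len(spec_peps)
        if n_spec == 0:
            continue
        fractions = rng.integers(1, config.n_fractions + 1, size=n_spec)
        charges = rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1], size=n_spec)
        detected = rng.random((n_spec, config.n_engines)) < config.engine_detect_prob
        for i in range(n_spec):
            pep = spec_peps[i]
            owners = tuple(sorted(pep_to_prot[pep]))
            is_decoy = owners[0].startswith(config.decoy_prefix)
            scan = f"{sample}.{i:06d}"
            for k in range(config.n_engines):
                if not detected[i, k]:
                    continue
                if spec_true[i]:
                    score = float(rng.gumbel(gloc, gscale)) if gscale > 0 else gloc
                else:
                    score = float(rng.normal(nloc, nscale)) if nscale > 0 else nloc
                rows["sample"].append(sample)
                rows["fraction"].append(int(fractions[i]))
                rows["scan"].append(scan)
                rows["engine"].append(engines[k])
                rows["peptide"].append(pep)
                rows["charge"].append(int(charges[i]))
                rows["score"].append(score)
                rows["decoy"].append(is_decoy)
                rows["true_match"].append(bool(spec_true[i]))
                proteins_col.append(owners)

    psms = pd.DataFrame(rows)
    psms.insert(7, "proteins", pd.Series(proteins_col, dtype=object))
    return psms, bmap, true_proteins


def result_units(config: PsmSimConfig) -> int:
    """Number of per-fraction-per-engine result files the layout implies."""
    return config.n_samples * config.n_fractions * config.n_engines


# ---------------------------------------------------------------------------
# QC metric simulation


@dataclass(frozen=True)
class QcSimConfig:
    """Conditions for the QC metric table generator.

    One row per LC-MS/MS run; a low-rank latent structure plus noise gives
    correlated metrics, contiguous sample blocks form batches with optional
    mean drift, a handful of columns are exactly constant (to exercise field
    exclusion) and a fraction of runs is shifted on a random metric subset
    (ground-truth outliers).
    """

    n_samples: int = 95
    n_fractions: int = 15
    n_metrics: int = 44
    n_batches: int = 10
    batch_drift_scale: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 4.0  # in column SD units
    n_constant_metrics: int = 4
    sample_effect_scale: float = 0.0
    noise_scale: float = 1.0
    n_latent: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_metrics < self.n_constant_metrics + 2:
            raise ValueError("n_metrics must exceed n_constant_metrics by at least 2")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if min(self.n_samples, self.n_fractions, self.n_batches) < 1:
            raise ValueError("counts must be positive")


def simulate_qc_metrics(config: QcSimConfig):
    """Generate a run x metric table and ground-truth outlier labels.

    Returns ``(QCMetricsTable, truth)`` where ``truth`` is a dict with the
    boolean outlier vector (aligned to rows) and the constant metric names.
    """
    rng = np.random.default_rng(config.seed)
    n_rows = config.n_samples * config.n_fractions
    n_var = config.n_metrics - config.n_constant_metrics

    latent = rng.normal(size=(n_rows, config.n_latent))
    if config.sample_effect_scale > 0:
        offsets = rng.normal(scale=config.sample_effect_scale, size=(config.n_samples, config.n_latent))
        latent += np.repeat(offsets, config.n_fractions, axis=0)
    loadings = rng.normal(size=(config.n_latent, n_var))
    x = latent @ loadings + config.noise_scale * rng.normal(size=(n_rows, n_var))

    batch_of_sample = np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(config.n_samples), config.n_batches))]
    )
    batch_rows = np.repeat(batch_of_sample, config.n_fractions)
    if config.batch_drift_scale > 0:
        drift = rng.normal(scale=config.batch_drift_scale, size=(config.n_batches, n_var))
        x += drift[batch_rows]

    col_sd = x.std(axis=0, ddof=1)
    n_out = int(round(config.outlier_fraction * n_rows))
    outlier = np.zeros(n_rows, dtype=bool)
    if n_out:
        idx = rng.choice(n_rows, size=n_out, replace=False)
        outlier[idx] = True
        n_hit = max(1, n_var // 3)
        for i in idx:
            cols = rng.choice(n_var, size=n_hit, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_hit)
            x[i, cols] += signs * config.outlier_shift * col_sd[cols]

    # metric columns get arbitrary units (scale/offset); constants appended
    scale = np.exp(rng.normal(scale=1.0, size=n_var))
    offset = rng.normal(scale=5.0, size=n_var)
    x = x * scale + offset
    var_names = [f"Metric.{i + 1:02d}" for i in range(n_var)]
    const_names = [f"Const.{i + 1:02d}" for i in range(config.n_constant_metrics)]
    const_vals = rng.normal(scale=5.0, size=config.n_constant_metrics)

    metrics = pd.DataFrame(x, columns=var_names)
    for name, v in zip(const_names, const_vals):
        metrics[name] = v

    labels = pd.DataFrame(
        {
            "sample": np.repeat([f"S{j:03d}" for j in range(config.n_samples)], config.n_fractions),
            "fraction": np.tile(np.arange(1, config.n_fractions + 1), config.n_samples),
            "batch": [f"B{b:02d}" for b in batch_rows],
            "timestamp": pd.date_range("2012-07-26", periods=n_rows, freq="4h"),
        }
    )
    table = QCMetricsTable(metrics=metrics, labels=labels)
    return table, {"outliers": outlier, "constant_metrics": const_names}


# ---------------------------------------------------------------------------
# spectral count simulation


@dataclass(frozen=True)
class CountSimConfig:
    """Conditions for the two-group spectral-count generator.

    Signature features carry a planted between-group rate ratio of
    ``signature_fold_change`` (alternating direction); counts are negative
    binomial around total-count-scaled means (Poisson when ``dispersion`` is
    zero).  Group sizes default to the 16 + 16 reference-sample layout and
    the planted ratio to the 32-fold signature criterion.
    """

    n_features: int = 5633
    n_group_a: int = 16
    n_group_b: int = 16
    n_signature_features: int = 172
    signature_fold_change: float = 32.0
    baseline_mean: float = 10.0
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("group sizes must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_signature_features > self.n_features:
            raise ValueError("signature cannot exceed the feature count")
        if self.signature_fold_change < 1:
            raise ValueError("signature_fold_change must be >= 1")


def simulate_counts(config: CountSimConfig):
    """Generate a SpectralCountMatrix and the planted signature.

    Returns ``(matrix, signature)`` where ``signature`` maps planted feature
    ids to their direction (+1 higher in group A, -1 higher in group B).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    n_a, n_b = config.n_group_a, config.n_group_b
    features = [f"F{i:05d}" for i in range(n)]
    samples = [f"A{i:02d}" for i in range(n_a)] + [f"B{i:02d}" for i in range(n_b)]
    groups = ["A"] * n_a + ["B"] * n_b

    base = config.baseline_mean * np.exp(rng.normal(scale=0.5, size=n))
    direction = np.zeros(n)
    sig_idx = np.arange(config.n_signature_features)
    direction[sig_idx] = np.where(sig_idx % 2 == 0, 1.0, -1.0)

    sqrt_fc = np.sqrt(config.signature_fold_change)
    mu_a = base * sqrt_fc**direction
    mu_b = base * sqrt_fc ** (-direction)
    size_factors = np.exp(rng.normal(scale=0.2, size=n_a + n_b))
    mu = np.column_stack([np.tile(mu_a, (n_a, 1)).T, np.tile(mu_b, (n_b, 1)).T]) * size_factors

    if config.dispersion > 0:
        lam = rng.gamma(shape=1.0 / config.dispersion, scale=mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    matrix = SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        samples=pd.DataFrame({"group": groups}, index=samples),
    )
    signature = {}
    if config.signature_fold_change > 1:
        signature = {features[i]: int(direction[i]) for i in sig_idx}
    return matrix, signature


# ---------------------------------------------------------------------------
# fraction pooling bookkeeping


def concatenation_scheme(n_collected: int, n_pools: int) -> dict[int, int]:
    """Interleaved concatenation of collected fractions into pools.

    1-based: pool ``p`` receives collected fractions ``p, p + n_pools,
    p + 2*n_pools, ...`` — e.g. pooling 60 first-dimension fractions into 15
    puts fractions 1, 16, 31 and 46 in pool 1.  Returns a mapping from
    collected fraction index to pool index.
    """
    if n_collected < 1 or n_pools < 1:
        raise ValueError("counts must be positive")
    if n_collected % n_pools != 0:
        raise ValueError(f"{n_pools} pools do not evenly divide {n_collected} fractions")
    return {f: ((f - 1) % n_pools) + 1 for f in range(1, n_collected + 1)}
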