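"""Spectral-count quantification and differential-signature evaluation.

Spectral counting uses the number of MS/MS spectra assigned to a protein or
gene group in a sample as a relative-abundance proxy.  Group comparison uses
a quasi-Poisson rate test with sample totals as offsets (the standard
count-rate model for spectral counts), Benjamini-Hochberg corrected across
features.  A differential signature (minimum fold change + FDR cutoff) can
be scored on every single cross-group sample pair by ROC AUC, measuring how
well the signature stands out from the background features when only one
sample from each group is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5  # for fold changes and log-ratios on zero cells


@dataclass
class SpectralCountMatrix:
    """Feature x sample matrix of non-negative integer spectral counts.

    ``samples`` holds per-sample metadata (``group`` label, optional
    ``replicate_of``) indexed by sample id.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not set(self.counts.columns) <= set(self.samples.index):
            missing = set(self.counts.columns) - set(self.samples.index)
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.samples.loc[s, "group"] == group]


def count_matrix(result, samples: pd.DataFrame) -> SpectralCountMatrix:
    """Tally retained PSMs into a group x sample spectral-count matrix.

    ``result`` is an assembly or rescue result; each feature is a non-decoy
    group keyed by its representative.  A PSM whose peptide maps to several
    retained groups contributes one count to each (inclusive counting).
    Raises when a PSM's sample is absent from ``samples``.
    """
    psms = result.retained_psms
    groups = [g for g in result.groups if not g.is_decoy]
    unknown = set(psms["sample"]) - set(samples.index)
    if unknown:
        raise ValueError(f"PSM samples missing from metadata: {sorted(unknown)[:5]}")

    pep_to_feats: dict[str, list[str]] = {}
    for g in groups:
        for p in g.peptides:
            pep_to_feats.setdefault(p, []).append(g.representative)

    features = sorted(g.representative for g in groups)
    cols = list(samples.index)
    mat = pd.DataFrame(0, index=features, columns=cols, dtype=int)
    if len(psms):
        bare = psms["bare_peptide"] if "bare_peptide" in psms else psms["peptide"]
        for pep, sample in zip(bare, psms["sample"]):
            for feat in pep_to_feats.get(pep, ()):
                mat.loc[feat, sample] += 1
    return SpectralCountMatrix(counts=mat, samples=samples.copy())


def resolve_duplicates(matrix: SpectralCountMatrix, duplicate_pairs) -> SpectralCountMatrix:
    """Keep one column per duplicate pair: the larger total spectral count
    (ties: lexicographically first sample id)."""
    drop = []
    for a, b in duplicate_pairs:
        for s in (a, b):
            if s not in matrix.counts.columns:
                raise ValueError(f"duplicate pair references unknown sample {s!r}")
        ta, tb = matrix.counts[a].sum(), matrix.counts[b].sum()
        if ta > tb or (ta == tb and a < b):
            drop.append(b)
        else:
            drop.append(a)
    counts = matrix.counts.drop(columns=drop)
    return SpectralCountMatrix(counts=counts, samples=matrix.samples.drop(index=drop))


def filter_min_average(matrix: SpectralCountMatrix, min_average: float) -> SpectralCountMatrix:
    """Keep features whose total count is at least ``ceil(min_average * n_samples)``.

    E.g. requiring an average of 1.4 counts across 32 samples keeps features
    with at least 45 total counts.
    """
    if min_average <= 0:
        return matrix
    threshold = math.ceil(min_average * matrix.counts.shape[1])
    keep = matrix.counts.sum(axis=1) >= threshold
    return SpectralCountMatrix(counts=matrix.counts[keep], samples=matrix.samples)


def differential_counts(
    matrix: SpectralCountMatrix, group_a: str = "A", group_b: str = "B"
) -> pd.DataFrame:
    """Per-feature quasi-Poisson rate comparison between two sample groups.

    The model is a two-group Poisson rate GLM with log link and log sample
    totals as offsets, with a quasi-likelihood (Pearson) dispersion
    correction: the rate estimates have the closed form
    ``rate_g = sum(counts in g) / sum(totals in g)``, the Wald statistic for
    the log rate ratio is ``log(rate_a/rate_b) / sqrt(phi*(1/S_a + 1/S_b))``
    with ``phi`` the Pearson chi-square over ``n - 2`` degrees of freedom,
    and p-values come from a t distribution with ``n - 2`` df.  Fold change
    is the pseudocounted ratio of normalized group rates.  FDR is
    Benjamini-Hochberg across features.
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two samples")
    counts = matrix.counts
    totals = counts.sum(axis=0)
    ta, tb = float(totals[cols_a].sum()), float(totals[cols_b].sum())
    if ta == 0 or tb == 0:
        raise ValueError("a group has an all-zero total spectral count")

    ya = counts[cols_a].to_numpy(dtype=float)
    yb = counts[cols_b].to_numpy(dtype=float)
    sa, sb = ya.sum(axis=1), yb.sum(axis=1)
    n = len(cols_a) + len(cols_b)
    df = n - 2

    rate_a = (sa + PSEUDOCOUNT) / ta
    rate_b = (sb + PSEUDOCOUNT) / tb
    fold = rate_a / rate_b

    # Wald statistic with stabilized sums; Pearson dispersion per feature
    sa_s = np.where(sa == 0, PSEUDOCOUNT, sa)
    sb_s = np.where(sb == 0, PSEUDOCOUNT, sb)
    beta = np.log((sa_s / ta) / (sb_s / tb))
    mu_a = (sa_s / ta)[:, None] * totals[cols_a].to_numpy(dtype=float)[None, :]
    mu_b = (sb_s / tb)[:, None] * totals[cols_b].to_numpy(dtype=float)[None, :]
    pearson = ((ya - mu_a) ** 2 / mu_a).sum(axis=1) + ((yb - mu_b) ** 2 / mu_b).sum(axis=1)
    phi = np.maximum(pearson / df, 1e-8)
    se = np.sqrt(phi * (1.0 / sa_s + 1.0 / sb_s))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(sa + sb == 0, 1.0, pvals)
    tstat = np.where(sa + sb == 0, 0.0, tstat)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "fold_change": fold,
            "log2_fold_change": np.log2(fold),
            "statistic": tstat,
            "pvalue": pvals,
            "fdr": fdr,
        },
        index=counts.index,
    )


def select_signature(
    results: pd.DataFrame, min_fold: float = 32.0, max_fdr: float = 0.001
) -> dict[str, int]:
    """Features at least ``min_fold``-fold higher in one group with FDR below
    ``max_fdr``; returns feature -> direction (+1 up in A, -1 up in B)."""
    if results.empty:
        return {}
    up = (results["fold_change"] >= min_fold) & (results["fdr"] < max_fdr)
    down = (results["fold_change"] <= 1.0 / min_fold) & (results["fdr"] < max_fdr)
    sig = {f: 1 for f in results.index[up]}
    sig.update({f: -1 for f in results.index[down]})
    return sig


@dataclass
class SignatureResult:
    """Pairwise single-sample ROC evaluation of a differential signature."""

    signature: dict[str, int]
    auc_matrix: pd.DataFrame  # group-A samples x group-B samples
    median_auc: float
    sd_auc: float


def pairwise_signature_auc(
    matrix: SpectralCountMatrix,
    signature: dict[str, int],
    group_a: str = "A",
    group_b: str = "B",
) -> SignatureResult:
    """Score a signature on every cross-group single-sample pair.

    For a pair (a, b) each feature gets a total-count-normalized,
    pseudocounted log count ratio.  Signature features, oriented by their
    expected direction, are the positives; the comparison population is the
    non-signature features entered under both orientations (so it is
    symmetric by construction and an uninformative signature scores 0.5).
    AUC is the rank concordance (Mann-Whitney) of positives over the
    comparison population.  Pairs where both columns are all zero yield a
    missing AUC.
    """
    if not signature:
        raise ValueError("signature is empty")
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    counts = matrix.counts
    totals = counts.sum(axis=0).astype(float)
    feats = counts.index
    sig_mask = feats.isin(signature)
    directions = np.array([signature.get(f, 0) for f in feats], dtype=float)

    auc = pd.DataFrame(np.nan, index=cols_a, columns=cols_b)
    log_norm = {}
    for c in list(cols_a) + list(cols_b):
        log_norm[c] = np.log2((counts[c].to_numpy(dtype=float) + PSEUDOCOUNT)) - np.log2(
            max(totals[c], 1.0)
        )
    for a in cols_a:
        for b in cols_b:
            if totals[a] == 0 and totals[b] == 0:
                continue
            ratio = log_norm[a] - log_norm[b]
            pos = ratio[sig_mask] * directions[sig_mask]
            bg = ratio[~sig_mask]
            neg = np.concatenate([bg, -bg])
            if len(pos) == 0 or len(neg) == 0:
                continue
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            auc.loc[a, b] = u / (len(pos) * len(neg))

    vals = auc.to_numpy().ravel()
    vals = vals[~np.isnan(vals)]
    return SignatureResult(
        signature=dict(signature),
        auc_matrix=auc,
        median_auc=float(np.median(vals)) if len(vals) else float("nan"),
        sd_auc=float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
    )
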