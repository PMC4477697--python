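"""Identification-free LC-MS/MS quality control.

Each run is summarized by a vector of instrument metrics (44 in QuaMeter's
IDFree output).  The pipeline excludes low-variation fields, projects runs
into principal-component space after robust (median/MAD) standardization,
computes normalized Euclidean distances between sibling fractions of the
same sample, and flags outlier runs whose squared Mahalanobis distance (the
T-squared statistic) from a pooled robust center exceeds a chi-square
quantile.  A two-way ANOVA decomposes identification-yield variability into
sample, fraction and residual shares.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAD_CONSISTENCY = 1.4826  # MAD -> SD under a Gaussian


@dataclass
class QCMetricsTable:
    """Run x metric matrix plus run labels (sample, fraction, batch, timestamp)."""

    metrics: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self):
        if len(self.metrics) != len(self.labels):
            raise ValueError("metrics and labels must have one row per run")
        for col in ("sample", "fraction"):
            if col not in self.labels.columns:
                raise ValueError(f"labels must include a {col!r} column")
            if self.labels[col].isna().any():
                raise ValueError(f"missing {col} labels")
        if self.metrics.columns.duplicated().any():
            raise ValueError("metric names must be unique")

    @property
    def n_runs(self) -> int:
        return len(self.metrics)


def read_quameter(path) -> QCMetricsTable:
    """Read a QuaMeter-style TSV: label columns (sample, fraction, optionally
    batch/timestamp/Filename/StartTimeStamp) plus named numeric metrics."""
    df = pd.read_csv(path, sep="\t")
    label_cols = [
        c for c in ("Filename", "StartTimeStamp", "sample", "fraction", "batch", "timestamp")
        if c in df.columns
    ]
    labels = df[label_cols].rename(columns={"StartTimeStamp": "timestamp"})
    metrics = df.drop(columns=label_cols)
    return QCMetricsTable(metrics=metrics, labels=labels)


def write_quameter(table: QCMetricsTable, path) -> None:
    pd.concat([table.labels, table.metrics], axis=1).to_csv(path, sep="\t", index=False)


def exclude_low_variance(
    table: QCMetricsTable,
    rel_floor: float = 1e-4,
    name_patterns: tuple[str, ...] = (),
) -> tuple[QCMetricsTable, list[str]]:
    """Drop metrics with insufficient variation and configured name patterns.

    A column is excluded when its MAD is strictly below ``rel_floor`` times
    the magnitude of its median (robust coefficient of variation), or when
    its name matches one of the glob ``name_patterns`` (e.g. ``Charge.*`` to
    drop all precursor charge-state fields).  Returns the reduced table and
    the excluded names.
    """
    if table.n_runs < 2:
        raise ValueError("need at least two runs")
    excluded = []
    for col in table.metrics.columns:
        if any(fnmatch.fnmatch(col, pat) for pat in name_patterns):
            excluded.append(col)
            continue
        x = table.metrics[col].to_numpy(dtype=float)
        mad = np.median(np.abs(x - np.median(x)))
        if mad < rel_floor * (abs(np.median(x)) + 1e-12):
            excluded.append(col)
    reduced = QCMetricsTable(
        metrics=table.metrics.drop(columns=excluded), labels=table.labels
    )
    return reduced, excluded


@dataclass
class PCAResult:
    scores: pd.DataFrame  # runs x components (all components)
    loadings: pd.DataFrame  # metrics x components
    explained: np.ndarray  # explained-variance fractions
    n_retained: int  # components kept for distances / T-squared

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def robust_pca(
    table: QCMetricsTable,
    n_components: int | None = None,
    variance_target: float = 0.6,
    max_components: int = 5,
    center: str = "median",
    scale: str = "mad",
    covariance: str = "classical",
) -> PCAResult:
    """PCA of run metrics after robust standardization.

    Default robustness comes from median centering and MAD scaling of each
    metric before a classical eigendecomposition; ``covariance='mcd'``
    additionally estimates the covariance with the minimum covariance
    determinant.  ``center='mean', scale='none'`` gives plain PCA.  When
    ``n_components`` is not given, the smallest number of components
    explaining ``variance_target`` of the variance is retained, capped at
    ``max_components``.
    """
    x = table.metrics.to_numpy(dtype=float)
    n, p = x.shape
    if n_components is not None and n_components > min(n, p):
        raise ValueError(f"cannot retain {n_components} components from a {n}x{p} table")

    mu = np.median(x, axis=0) if center == "median" else x.mean(axis=0)
    xc = x - mu
    if scale == "mad":
        s = MAD_CONSISTENCY * np.median(np.abs(xc), axis=0)
        if (s == 0).any():
            bad = list(table.metrics.columns[s == 0])
            raise ValueError(f"zero-MAD metrics must be excluded first: {bad[:5]}")
        xc = xc / s
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")

    if covariance == "mcd":
        from sklearn.covariance import MinCovDet

        cov = MinCovDet(random_state=0).fit(xc).covariance_
    else:
        cov = np.cov(xc, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    explained = evals / evals.sum() if evals.sum() > 0 else evals

    scores = xc @ evecs
    comp_names = [f"PC{i + 1}" for i in range(p)]
    if n_components is None:
        n_retained = int(np.searchsorted(np.cumsum(explained), variance_target) + 1)
        n_retained = min(n_retained, max_components, p)
    else:
        n_retained = n_components
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.metrics.index, columns=comp_names),
        loadings=pd.DataFrame(evecs, index=table.metrics.columns, columns=comp_names),
        explained=explained,
        n_retained=n_retained,
    )


def fraction_distances(scores: pd.DataFrame, sample_labels: pd.Series) -> pd.Series:
    """Per-run median normalized Euclidean distance to sibling fractions.

    Scores are standardized per component (divided by the component SD over
    all runs) before distances are taken; each run's statistic is the median
    distance to the other runs of the same sample.
    """
    sample_labels = pd.Series(np.asarray(sample_labels), index=scores.index)
    sd = scores.std(axis=0, ddof=1).to_numpy()
    sd[sd == 0] = 1.0
    z = scores.to_numpy(dtype=float) / sd
    out = pd.Series(np.nan, index=scores.index)
    for _, idx in sample_labels.groupby(sample_labels).groups.items():
        pos = scores.index.get_indexer(idx)
        if len(pos) < 2:
            raise ValueError("every sample needs at least two runs")
        block = z[pos]
        d = np.sqrt(((block[:, None, :] - block[None, :, :]) ** 2).sum(axis=2))
        med = np.array([np.median(np.delete(d[i], i)) for i in range(len(pos))])
        out.iloc[pos] = med
    return out


@dataclass
class OutlierReport:
    """Per-run QC statistics and the outlier calls."""

    runs: pd.DataFrame  # sample, fraction, median_distance, t2, pvalue, outlier
    alpha: float
    n_components: int
    excluded_metrics: list[str] = field(default_factory=list)
    loadings: pd.DataFrame | None = None
    explained: np.ndarray | None = None

    @property
    def n_outliers(self) -> int:
        return int(self.runs["outlier"].sum())


def t2_outliers(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.01,
    robust: bool = True,
) -> OutlierReport:
    """Flag runs whose T-squared statistic is extreme under a chi-square law.

    T-squared is the squared Mahalanobis distance of each run's component
    scores from a center and covariance pooled across all runs (robust MCD
    estimates by default); under multivariate normality it follows a
    chi-square with as many degrees of freedom as components, so a run is
    flagged when ``P(chi2_k >= T2) < alpha``.
    """
    k = scores.shape[1]
    if k < 1:
        raise ValueError("at least one component is required")
    x = scores.to_numpy(dtype=float)
    if robust:
        from sklearn.covariance import MinCovDet

        est = MinCovDet(random_state=0).fit(x)
        center, cov = est.location_, est.covariance_
    else:
        center, cov = x.mean(axis=0), np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular score covariance; retain fewer components"
        ) from exc
    d = x - center
    t2 = np.einsum("ij,jk,ik->i", d, prec, d)
    pvals = stats.chi2.sf(t2, df=k)
    med_dist = fraction_distances(scores, labels["sample"])
    runs = pd.DataFrame(
        {
            "sample": labels["sample"].to_numpy(),
            "fraction": labels["fraction"].to_numpy(),
            "median_distance": med_dist.to_numpy(),
            "t2": t2,
            "pvalue": pvals,
            "outlier": pvals < alpha,
        },
        index=scores.index,
    )
    return OutlierReport(runs=runs, alpha=alpha, n_components=k)


def qc_pipeline(
    table: QCMetricsTable,
    alpha: float = 0.01,
    rel_floor: float = 1e-4,
    name_patterns: tuple[str, ...] = (),
    robust: bool = True,
    **pca_kwargs,
) -> OutlierReport:
    """Field exclusion -> robust PCA -> distances and T-squared outlier calls."""
    reduced, excluded = exclude_low_variance(table, rel_floor, name_patterns)
    pca = robust_pca(reduced, **pca_kwargs)
    report = t2_outliers(pca.retained_scores, reduced.labels, alpha=alpha, robust=robust)
    report.excluded_metrics = excluded
    report.loadings = pca.loadings
    report.explained = pca.explained
    return report


def variance_components(yields: pd.DataFrame, value: str = "value") -> dict[str, float]:
    """Two-way ANOVA (no interaction) variance shares of per-run yields.

    ``yields`` must be a complete sample x fraction layout with columns
    ``sample``, ``fraction`` and the value column.  Returns sum-of-squares
    fractions for sample, fraction and residual; the three sum to 1.
    """
    cells = yields.groupby(["sample", "fraction"]).size()
    n_expected = yields["sample"].nunique() * yields["fraction"].nunique()
    if len(cells) != n_expected or (cells != 1).any():
        raise ValueError("layout must be complete with one observation per cell")
    y = yields[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    if ss_total == 0:
        return {"sample": 0.0, "fraction": 0.0, "residual": 1.0}
    sample_means = yields.groupby("sample")[value].transform("mean").to_numpy()
    fraction_means = yields.groupby("fraction")[value].transform("mean").to_numpy()
    ss_sample = ((sample_means - grand) ** 2).sum()
    ss_fraction = ((fraction_means - grand) ** 2).sum()
    ss_resid = ss_total - ss_sample - ss_fraction
    return {
        "sample": ss_sample / ss_total,
        "fraction": ss_fraction / ss_total,
        "residual": ss_resid / ss_total,
    }


#: documented instrument-standard acceptance constants (BSA recalibration):
#: mass drift tolerance in ppm, minimum base-peak intensity, minimum sequence
#: coverage.  Recorded as configuration only; no raw-file computation here.
BSA_THRESHOLDS = {"mass_drift_ppm": 10.0, "min_intensity": 1e7, "min_coverage": 0.65}


def compref_acceptance(
    identified_spectra: float, ms2_density_q3: float, charge2_fraction: float
) -> tuple[bool, list[str]]:
    """Reference-sample run acceptance: >5,000 identified spectra, third
    quartile MS2 density >200, and >40% charge-2 identified spectra.

    Returns ``(passed, violated_rules)``; all three bounds are strict.
    """
    reasons = []
    if not identified_spectra > 5000:
        reasons.append("identified spectra must exceed 5000")
    if not ms2_density_q3 > 200:
        reasons.append("third-quartile MS2 density must exceed 200")
    if not charge2_fraction > 0.40:
        reasons.append("charge-2 fraction of identified spectra must exceed 0.40")
    return (not reasons, reasons)
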