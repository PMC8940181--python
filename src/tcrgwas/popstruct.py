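"""Genotype PCA, ancestry clusters, inflation and multiple-testing tools."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "PcaResult",
    "InflationReport",
    "genotype_pca",
    "assign_clusters",
    "genomic_inflation",
    "bonferroni_threshold",
    "bonferroni_adjust",
    "snps_near_locus",
    "cluster_feature_test",
    "maf_by_cluster",
    "CHI2_1_MEDIAN",
]

#: the printed chi-squared(1 df) median used in the inflation-factor
#: denominator (the analytic value 0.4549 differs in the third decimal;
#: the printed constant is used so lambda matches the published definition)
CHI2_1_MEDIAN = 0.456


@dataclass
class PcaResult:
    scores: pd.DataFrame              # subjects x components
    variance_explained: np.ndarray    # fraction per component
    n_components: int


def genotype_pca(gm: GenotypeMatrix, k: int = 8) -> PcaResult:
    """PCA of the centered, allele-frequency-scaled dosage matrix.

    Missing dosages are mean-imputed for the decomposition only.  The
    default of eight retained components matches the number of PC
    covariates carried into the association models.
    """
    if gm.n_subjects < k + 1:
        raise ValueError("need at least k+1 subjects")
    X = gm.dosage.copy()
    p = gm.maf
    col_mean = 2.0 * p
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.take(col_mean, np.where(nan)[1])
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    Xs = (X[:, ok] - col_mean[ok]) / scale[ok]
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    var = S ** 2
    ve = var / var.sum()
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=gm.subject_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(scores=scores, variance_explained=ve[:k], n_components=k)


def assign_clusters(
    pca: PcaResult,
    labeled_subset: Mapping[str, str],
) -> pd.Series:
    """Assign every subject to the nearest labeled cluster.

    Per-label robust centroids (coordinate-wise medians) and covariances
    are fit on the labeled subset; subjects are assigned by Mahalanobis
    distance, falling back to Euclidean when a covariance is singular.
    """
    if not labeled_subset:
        raise ValueError("labeled subset is empty: no anchor subjects")
    labels = sorted(set(labeled_subset.values()))
    X = pca.scores
    params = {}
    for lab in labels:
        members = [s for s, l in labeled_subset.items() if l == lab]
        if not members:
            raise ValueError(f"label {lab!r} has no anchor subjects")
        pts = X.loc[members].to_numpy(float)
        center = np.median(pts, axis=0)
        if len(members) > X.shape[1]:
            cov = np.cov(pts, rowvar=False)
            try:
                vi = np.linalg.inv(cov)
            except np.linalg.LinAlgError:
                warnings.warn(f"singular covariance for {lab}; Euclidean fallback")
                vi = np.eye(X.shape[1])
        else:
            vi = np.eye(X.shape[1])
        params[lab] = (center, vi)
    out = {}
    M = X.to_numpy(float)
    dists = np.empty((len(X), len(labels)))
    for c, lab in enumerate(labels):
        center, vi = params[lab]
        d = M - center
        dists[:, c] = np.einsum("ij,jk,ik->i", d, vi, d)
    best = np.argmin(dists, axis=1)
    for i, subj in enumerate(X.index):
        out[subj] = labels[best[i]]
    return pd.Series(out, name="cluster")


@dataclass
class InflationReport:
    lam: float
    n_statistics: int
    threshold: float
    subsampled: bool

    @property
    def passed(self) -> bool:
        return self.lam < self.threshold


def genomic_inflation(
    t_statistics: Sequence[float] | np.ndarray,
    mode: str = "all",
    threshold: float = 1.03,
    subsample_size: int = 10_000,
    seed: int | None = None,
    min_statistics: int = 100,
) -> InflationReport:
    """lambda = median(T^2) / 0.456 over the scan's test statistics.

    ``mode='subsample'`` draws ``subsample_size`` statistics without
    replacement under the given seed (the rule used for gene-conditioned
    scans where computing every bootstrap statistic is infeasible).
    """
    t = np.asarray(t_statistics, dtype=float)
    t = t[np.isfinite(t)]
    if t.size < min_statistics:
        raise ValueError(f"need >= {min_statistics} statistics, got {t.size}")
    if mode == "subsample":
        rng = np.random.default_rng(seed)
        if t.size > subsample_size:
            t = rng.choice(t, size=subsample_size, replace=False)
        subsampled = True
    elif mode == "all":
        subsampled = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lam = float(np.median(t ** 2) / CHI2_1_MEDIAN)
    return InflationReport(lam=lam, n_statistics=int(t.size),
                           threshold=threshold, subsampled=subsampled)


def bonferroni_threshold(
    alpha: float,
    n_feature_subtypes: int,
    n_productivity: int,
    n_snps: int,
) -> float:
    """alpha / (feature subtypes x productivity types x SNPs tested)."""
    if alpha <= 0 or n_feature_subtypes < 1 or n_productivity < 1 or n_snps < 1:
        raise ValueError("all inputs must be positive")
    return alpha / (n_feature_subtypes * n_productivity * n_snps)


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Multiply a raw p-value by the number of tests, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def snps_near_locus(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    window: int = 200_000,
) -> list[str]:
    """SNP ids with position in the closed interval [start-window, end+window]."""
    on_chrom = gm.chrom == chrom
    if not on_chrom.any():
        warnings.warn(f"chromosome {chrom!r} not present")
        return []
    lo, hi = start - window, end + window
    keep = on_chrom & (gm.pos >= lo) & (gm.pos <= hi)
    return [gm.snp_ids[j] for j in np.flatnonzero(keep)]


def cluster_feature_test(
    values: pd.Series,
    labels: pd.Series,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-sample t-test of each cluster's feature means vs the population mean.

    Bonferroni adjustment multiplies each raw p by the number of clusters
    tested, capped at 1.  Zero within-cluster variance flags the p-value
    as undefined (NaN).
    """
    values = values.dropna()
    labels = labels.reindex(values.index)
    pop_mean = float(values.mean())
    rows = []
    clusters = sorted(labels.dropna().unique())
    tested = [c for c in clusters
              if (labels == c).sum() >= min_cluster_size]
    for c in tested:
        vals = values[labels == c]
        if float(np.std(vals)) == 0.0:
            rows.append((c, len(vals), np.nan, np.nan, np.nan, "degenerate"))
            continue
        t, p = stats.ttest_1samp(vals, popmean=pop_mean)
        rows.append((c, len(vals), float(t), float(p),
                     bonferroni_adjust(float(p), len(tested)), "ok"))
    return pd.DataFrame(rows, columns=[
        "cluster", "n", "t", "p_raw", "p_adjusted", "flag",
    ])


def maf_by_cluster(
    gm: GenotypeMatrix,
    labels: pd.Series,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster frequencies of the population-minor allele.

    MAF_jr = sum_i(x_ij) / (2 * I_r) over cluster members with non-missing
    genotype; the minor allele is fixed by the whole-cohort orientation,
    so per-cluster values may exceed 0.5.  For a supplied SNP set, each
    cluster's MAFs are compared with the population MAFs by a one-sample
    t-test on the SNP-wise paired differences, Bonferroni-adjusted over
    clusters.
    """
    idx = (range(gm.n_snps) if snp_ids is None
           else [gm.snp_index(s) for s in snp_ids])
    idx = list(idx)
    sub = np.asarray([gm.dosage[:, j] for j in idx]).T  # subjects x snps
    members = pd.Series(gm.subject_ids).map(labels)
    clusters = sorted(labels.dropna().unique())
    pop_maf = np.nanmean(sub, axis=0) / 2.0
    rows = []
    tests = []
    for c in clusters:
        mask = (members == c).to_numpy()
        if not mask.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            maf_r = np.nanmean(sub[mask], axis=0) / 2.0
        for k, j in enumerate(idx):
            rows.append((gm.snp_ids[j], c, float(maf_r[k]), int(mask.sum()),
                         float(pop_maf[k])))
        diffs = maf_r - pop_maf
        diffs = diffs[np.isfinite(diffs)]
        if len(diffs) >= 2 and np.std(diffs) > 0:
            t, p = stats.ttest_1samp(diffs, popmean=0.0)
            tests.append((c, float(t), float(p)))
        else:
            tests.append((c, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["snp_id", "cluster", "maf_cluster",
                                        "n_cluster", "maf_population"])
    n_tested = sum(1 for _, _, p in tests if np.isfinite(p))
    test_df = pd.DataFrame(tests, columns=["cluster", "t", "p_raw"])
    test_df["p_adjusted"] = [
        bonferroni_adjust(p, max(n_tested, 1)) if np.isfinite(p) else np.nan
        for p in test_df["p_raw"]
    ]
    table.attrs["cluster_tests"] = test_df
    return table
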