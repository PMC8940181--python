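"""Fixed-effects association models for SNP x repertoire-feature scans.

Three nested model families are provided: a per-subject "simple" OLS
model, a per-(subject x gene-allele-group) weighted "gene-conditioned"
model with group fixed effects, and the gene-conditioned model with an
additional categorical TRBD2-genotype covariate.  Test statistics
T = beta1/se are compared to N(0,1); p-values for promising hits are
re-derived from a clustered bootstrap with subjects as the sampling
unit.  A stepwise conditional scan identifies independent signals
within a locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix
from .repertoire_features import feature_spec

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "fit_simple",
    "fit_gene_conditioned",
    "fit_trbd2_corrected",
    "clustered_bootstrap_p",
    "conditional_scan",
    "genome_scan",
]


@dataclass
class ModelSpec:
    model: str = "simple"
    n_pcs: int = 8
    trbd2_correction: bool = False
    conditioning_snps: list[str] = field(default_factory=list)
    bootstrap_trigger: float = 5e-5
    bootstrap_reps: int = 100
    seed: int | None = None
    #: when set, one-tailed p in the direction (sign) supplied — used for
    #: validation-cohort mode; default two-sided.
    one_tailed_sign: float | None = None

    def __post_init__(self) -> None:
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


@dataclass
class AssociationResult:
    snp_id: str
    feature: str
    productivity: str
    beta1: float
    se: float
    t: float
    p_analytic: float
    p_bootstrap: float | None
    n_subjects: int
    n_rows: int
    model: str
    flag: str = "ok"  # ok | unestimable | degenerate

    @property
    def p(self) -> float:
        return self.p_bootstrap if self.p_bootstrap is not None else self.p_analytic


class _FitData:
    """Aligned design pieces for one SNP x feature x productivity fit."""

    def __init__(self, df: pd.DataFrame, covariate_cols: list[str],
                 group_col: str | None, weighted: bool):
        self.df = df  # columns: subject_id, y, x, [w], covariates, [group]
        self.covariate_cols = covariate_cols
        self.group_col = group_col
        self.weighted = weighted

    def design(self, df: pd.DataFrame | None = None):
        df = self.df if df is None else df
        cols = [np.ones(len(df)), df["x"].to_numpy(float)]
        if self.group_col is not None:
            levels = sorted(df[self.group_col].unique())
            for lev in levels[1:]:  # first level absorbed by the intercept
                cols.append((df[self.group_col] == lev).to_numpy(float))
        for c in self.covariate_cols:
            cols.append(df[c].to_numpy(float))
        X = np.column_stack(cols)
        y = df["y"].to_numpy(float)
        w = df["w"].to_numpy(float) if self.weighted else None
        return X, y, w


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """(W)LS of y on X; returns (beta, se_of_beta1, flag)."""
    n, k = X.shape
    if n < k + 1:
        return None, None, "unestimable"
    if w is not None:
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        return None, None, "unestimable"
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(float(yw @ yw), 1e-12):  # exact fit
        return beta, 0.0, "degenerate"
    sigma2 = rss / (n - k)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se1 = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    if se1 == 0.0:
        return beta, 0.0, "degenerate"
    return beta, se1, "ok"


def _p_from_t(t: float, spec: ModelSpec) -> float:
    if spec.one_tailed_sign is not None:
        return float(stats.norm.sf(t * np.sign(spec.one_tailed_sign)))
    return float(2.0 * stats.norm.sf(abs(t)))


def _pc_frame(pcs, n_pcs: int) -> pd.DataFrame | None:
    if pcs is None or n_pcs == 0:
        return None
    df = pcs if isinstance(pcs, pd.DataFrame) else pcs.scores
    if n_pcs > df.shape[1]:
        raise ValueError(f"requested {n_pcs} PCs, only {df.shape[1]} available")
    return df.iloc[:, :n_pcs]


def _assemble(
    y_table: pd.DataFrame,
    dosage: pd.Series,
    pcs,
    spec: ModelSpec,
    grouped: bool,
    z: pd.Series | None = None,
    conditioning: Mapping[str, pd.Series] | None = None,
) -> _FitData:
    df = y_table.rename(columns={"mean": "y"}).copy()
    df["x"] = df["subject_id"].map(dosage)
    df = df[df["x"].notna()]  # per-SNP complete-case; never impute
    covs: list[str] = []
    pcf = _pc_frame(pcs, spec.n_pcs)
    if pcf is not None:
        for c in pcf.columns:
            df[c] = df["subject_id"].map(pcf[c])
            covs.append(c)
        df = df[df[covs].notna().all(axis=1)]
    if conditioning:
        for sid, dos in conditioning.items():
            col = f"cond_{sid}"
            df[col] = df["subject_id"].map(dos)
            covs.append(col)
        df = df[df[[f"cond_{s}" for s in conditioning]].notna().all(axis=1)]
    if z is not None:
        zz = df["subject_id"].map(z)
        df = df[zz.notna() & (zz != "unknown")]
        zz = df["subject_id"].map(z)
        levels = sorted(zz.unique())
        if len(levels) == 1:
            warnings.warn("TRBD2 genotype constant; covariate dropped")
        else:
            for lev in levels[1:]:
                col = f"z_{lev}"
                df[col] = (zz == lev).astype(float)
                covs.append(col)
    if grouped:
        df = df.rename(columns={"weight": "w"})
    return _FitData(df.reset_index(drop=True), covs,
                    "group_id" if grouped else None, grouped)


def _finish(fd: _FitData, snp_id: str, feature: str, productivity: str,
            spec: ModelSpec, model_name: str) -> AssociationResult:
    X, y, w = fd.design()
    n_subjects = fd.df["subject_id"].nunique()
    base = dict(snp_id=snp_id, feature=feature, productivity=productivity,
                n_subjects=n_subjects, n_rows=len(fd.df), model=model_name,
                p_bootstrap=None)
    beta, se1, flag = _wls(X, y, w)
    if flag == "unestimable":
        return AssociationResult(beta1=np.nan, se=np.nan, t=np.nan,
                                 p_analytic=np.nan, flag=flag, **base)
    if flag == "degenerate":
        return AssociationResult(beta1=float(beta[1]), se=0.0, t=np.nan,
                                 p_analytic=np.nan, flag=flag, **base)
    t = float(beta[1] / se1)
    res = AssociationResult(beta1=float(beta[1]), se=se1, t=t,
                            p_analytic=_p_from_t(t, spec), flag="ok", **base)
    res._fit_data = fd  # type: ignore[attr-defined]
    return res


def fit_simple(
    y_table: pd.DataFrame,
    dosage: pd.Series,
    pcs=None,
    spec: ModelSpec | None = None,
    snp_id: str | None = None,
) -> AssociationResult:
    """OLS of per-subject means on dosage, intercept, and PC covariates."""
    spec = spec or ModelSpec(model="simple", n_pcs=0 if pcs is None else 8)
    if pcs is None:
        spec = replace(spec, n_pcs=0)
    conditioning = None
    fd = _assemble(y_table, dosage, pcs, spec, grouped=False,
                   conditioning=conditioning)
    return _finish(fd, snp_id or str(dosage.name), y_table["feature"].iloc[0],
                   y_table["productivity"].iloc[0], spec, "simple")


def fit_gene_conditioned(
    y_table: pd.DataFrame,
    dosage: pd.Series,
    pcs=None,
    spec: ModelSpec | None = None,
    snp_id: str | None = None,
    conditioning: Mapping[str, pd.Series] | None = None,
) -> AssociationResult:
    """WLS with gene-allele-group fixed effects, dosage, and PC covariates."""
    spec = spec or ModelSpec(model="gene_conditioned",
                             n_pcs=0 if pcs is None else 8)
    if pcs is None:
        spec = replace(spec, n_pcs=0)
    if y_table["group_id"].nunique() < 1:
        raise ValueError("no gene-allele groups present")
    fd = _assemble(y_table, dosage, pcs, spec, grouped=True,
                   conditioning=conditioning)
    return _finish(fd, snp_id or str(dosage.name), y_table["feature"].iloc[0],
                   y_table["productivity"].iloc[0], spec, "gene_conditioned")


def fit_trbd2_corrected(
    y_table: pd.DataFrame,
    dosage: pd.Series,
    pcs=None,
    z: pd.Series | None = None,
    spec: ModelSpec | None = None,
    snp_id: str | None = None,
) -> AssociationResult:
    """Gene-conditioned fit with a categorical TRBD2-genotype covariate.

    Subjects with unknown genotype are dropped; at least 90% of subjects
    must have a known genotype.
    """
    if z is None:
        raise ValueError("TRBD2 genotype series required")
    known = (z != "unknown").mean()
    if known < 0.9:
        raise ValueError(
            f"TRBD2 genotype known for only {known:.0%} of subjects (<90%)"
        )
    spec = spec or ModelSpec(model="gene_conditioned",
                             n_pcs=0 if pcs is None else 8)
    if pcs is None:
        spec = replace(spec, n_pcs=0)
    fd = _assemble(y_table, dosage, pcs, spec, grouped=True, z=z)
    return _finish(fd, snp_id or str(dosage.name), y_table["feature"].iloc[0],
                   y_table["productivity"].iloc[0], spec, "trbd2_corrected")


def clustered_bootstrap_p(
    result: AssociationResult,
    spec: ModelSpec | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> AssociationResult:
    """Recompute the p-value with a subject-level clustered bootstrap.

    Subjects are resampled with replacement (all of a subject's rows move
    together), the model is refit per resample, and the standard error is
    the standard deviation of the B coefficient estimates.
    """
    spec = spec or ModelSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fd: _FitData | None = getattr(result, "_fit_data", None)
    if fd is None:
        raise ValueError("result carries no fit data (unestimable fit?)")
    X, y, w = fd.design()
    if w is not None:
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    row_idx = fd.df.groupby("subject_id").indices
    subjects = np.array(fd.df["subject_id"].unique())
    k = X.shape[1]
    betas = []
    retries = 0
    while len(betas) < spec.bootstrap_reps:
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        rows = np.concatenate([row_idx[s] for s in draw])
        beta, _, rank, _ = np.linalg.lstsq(Xw[rows], yw[rows], rcond=None)
        if rank < k:  # e.g. a group level absent from the resample
            retries += 1
            if retries > max_retries:
                return replace(result, flag="degenerate")
            continue
        betas.append(float(beta[1]))
    se_boot = float(np.std(betas, ddof=1))
    if se_boot <= 1e-12 * max(1.0, abs(result.beta1)):  # no resample variation
        return replace(result, flag="degenerate")
    t = result.beta1 / se_boot
    out = replace(result, p_bootstrap=_p_from_t(t, spec))
    out._fit_data = fd  # type: ignore[attr-defined]
    return out


def _fit_for_model(model: str, y_table, dosage, pcs, spec, snp_id,
                   conditioning=None, z=None) -> AssociationResult:
    if model == "simple":
        if conditioning:
            fd = _assemble(y_table, dosage, pcs, spec, grouped=False,
                           conditioning=conditioning)
            return _finish(fd, snp_id, y_table["feature"].iloc[0],
                           y_table["productivity"].iloc[0], spec, "simple")
        return fit_simple(y_table, dosage, pcs, spec, snp_id)
    if model == "gene_conditioned":
        return fit_gene_conditioned(y_table, dosage, pcs, spec, snp_id,
                                    conditioning=conditioning)
    if model == "trbd2_corrected":
        return fit_trbd2_corrected(y_table, dosage, pcs, z, spec, snp_id)
    raise ValueError(f"unknown model {model!r}")


def conditional_scan(
    gm: GenotypeMatrix,
    locus_snp_ids: Sequence[str],
    y_table: pd.DataFrame,
    pcs,
    spec: ModelSpec,
    threshold: float,
) -> list[str]:
    """Stepwise nested scan for independent signals within a locus.

    The most significant SNP is added as a covariate and the locus is
    rescanned until the top remaining p-value is no longer below the
    gene-level threshold; the accumulated covariate SNPs are the
    independent signals.
    """
    if not locus_snp_ids:
        raise ValueError("locus SNP subset is empty")
    independent: list[str] = []
    while True:
        conditioning = {s: gm.dosage_for(s) for s in independent}
        best_p, best_snp = np.inf, None
        for sid in locus_snp_ids:
            if sid in independent:
                continue
            res = _fit_for_model(spec.model, y_table, gm.dosage_for(sid), pcs,
                                 spec, sid, conditioning=conditioning or None)
            if res.flag != "ok":
                continue  # collinear with a conditioning SNP: not significant
            if res.p_analytic < best_p:
                best_p, best_snp = res.p_analytic, sid
        if best_snp is None or best_p >= threshold:
            return independent
        independent.append(best_snp)


class _ScanDesign:
    """Pre-assembled design pieces reused across the SNPs of one scan cell.

    The design matrix is built once; per SNP only the dosage column is
    swapped in.  SNPs with missing dosages fall back to the general
    per-fit path (per-SNP complete-case semantics preserved).
    """

    def __init__(self, y_table: pd.DataFrame, pcs, spec: ModelSpec,
                 grouped: bool, subject_order: Sequence[str]):
        fd = _assemble(y_table, pd.Series(0.0, index=list(subject_order)),
                       pcs, spec, grouped=grouped)
        self.fd = fd
        X, y, w = fd.design()
        self.X, self.y = X, y
        self.sw = np.sqrt(w) if w is not None else None
        pos = {s: i for i, s in enumerate(subject_order)}
        self.subj_codes = fd.df["subject_id"].map(pos).to_numpy()
        self.n_subjects = fd.df["subject_id"].nunique()

    def fit(self, dosage_col: np.ndarray):
        x = dosage_col[self.subj_codes]
        if np.isnan(x).any():
            return None  # caller uses the general complete-case path
        X = self.X
        X[:, 1] = x
        if self.sw is not None:
            Xw = X * self.sw[:, None]
            yw = self.y * self.sw
        else:
            Xw, yw = X, self.y
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        k = X.shape[1]
        if rank < k:
            return np.nan, np.nan, "unestimable"
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        if rss <= 1e-12 * max(float(yw @ yw), 1e-12):
            return float(beta[1]), 0.0, "degenerate"
        sigma2 = rss / (len(yw) - k)
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        se1 = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
        if se1 == 0.0:
            return float(beta[1]), 0.0, "degenerate"
        return float(beta[1]), se1, "ok"


def genome_scan(
    gm: GenotypeMatrix,
    condensed: Mapping[tuple[str, str], pd.DataFrame],
    pcs=None,
    spec: ModelSpec | None = None,
    models: Mapping[str, str] | None = None,
    z: pd.Series | None = None,
    bootstrap: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Per-SNP fits over every (feature, productivity) condensed table.

    ``models`` overrides the per-feature default model choice.  Hits with
    analytic p below the bootstrap trigger are re-evaluated with the
    clustered bootstrap.  Output ordering is deterministic:
    (snp, feature, productivity).
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    keys = sorted(condensed)
    for feature, productivity in keys:
        y_table = condensed[(feature, productivity)]
        model = (models or {}).get(feature, feature_spec(feature).default_model)
        design = (_ScanDesign(y_table, pcs, spec,
                              grouped=model == "gene_conditioned",
                              subject_order=gm.subject_ids)
                  if model in ("simple", "gene_conditioned") else None)
        for j, sid in enumerate(gm.snp_ids):
            res = None
            if design is not None:
                fast = design.fit(gm.dosage[:, j])
                if fast is not None:
                    beta1, se1, flag = fast
                    t = beta1 / se1 if flag == "ok" else np.nan
                    res = AssociationResult(
                        sid, feature, productivity, beta1, se1, t,
                        _p_from_t(t, spec) if flag == "ok" else np.nan,
                        None, design.n_subjects, len(design.fd.df), model,
                        flag=flag)
            needs_slow = res is None or (
                bootstrap and res.flag == "ok"
                and res.p_analytic < spec.bootstrap_trigger)
            if needs_slow:
                dosage = pd.Series(gm.dosage[:, j], index=gm.subject_ids,
                                   name=sid)
                try:
                    res = _fit_for_model(
                        model, y_table, dosage, pcs, spec, sid,
                        z=z if model == "trbd2_corrected" else None)
                except ValueError:
                    res = AssociationResult(sid, feature, productivity,
                                            np.nan, np.nan, np.nan, np.nan,
                                            None, 0, 0, model,
                                            flag="unestimable")
                if (bootstrap and res.flag == "ok"
                        and res.p_analytic < spec.bootstrap_trigger):
                    res = clustered_bootstrap_p(res, spec, rng)
            rows.append(res)
            if progress and (j + 1) % 500 == 0:
                print(f"  {feature}/{productivity}: {j + 1}/{gm.n_snps} SNPs")
    recs = []
    pos_of = {sid: (gm.chrom[j], gm.pos[j]) for j, sid in enumerate(gm.snp_ids)}
    for r in sorted(rows, key=lambda r: (r.snp_id, r.feature, r.productivity)):
        chrom, pos = pos_of[r.snp_id]
        recs.append((r.snp_id, chrom, pos, r.feature, r.productivity, r.beta1,
                     r.se, r.t, r.p_analytic, r.p_bootstrap, r.n_subjects,
                     r.n_rows, r.model, r.flag))
    return pd.DataFrame(recs, columns=[
        "snp_id", "chrom", "pos", "feature", "productivity", "beta", "se",
        "t", "p", "p_bootstrap", "n_subjects", "n_rows", "model", "flag",
    ])
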