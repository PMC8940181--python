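"""Condense annotated repertoires into model-ready feature tables.

Per-read junction statistics become per-subject means (simple model) or
per-(subject x gene-allele-group) weighted means (gene-conditioned
model).  Feature names follow a small registry: trims, insertion counts,
P counts, untrimmed-P fractions, and ``usage:<GENE>`` indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RepertoireTable, exclude_rows_for_feature
from .vdj_annotation import (GeneAlleleGroup, GermlineReference,
                             allele_group_map, build_allele_groups)

__all__ = [
    "FeatureSpec",
    "feature_spec",
    "feature_names",
    "condense_simple",
    "condense_by_gene_group",
    "untrimmed_p_fraction",
    "call_trbd2_genotype",
    "restrict_trbj1",
    "SubjectMetadata",
]


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str           # trim | insertion | p_count | p_fraction | usage
    gene_type: str      # conditioning gene type (V/D/J); "" for n_total
    d_dependent: bool
    column: str         # per-read value column, or gene name for usage
    default_model: str  # simple | gene_conditioned


_BASE_FEATURES = {
    "v_trim": FeatureSpec("v_trim", "trim", "V", False, "v_trim", "gene_conditioned"),
    "d5_trim": FeatureSpec("d5_trim", "trim", "D", True, "d5_trim", "gene_conditioned"),
    "d3_trim": FeatureSpec("d3_trim", "trim", "D", True, "d3_trim", "gene_conditioned"),
    "j_trim": FeatureSpec("j_trim", "trim", "J", False, "j_trim", "gene_conditioned"),
    "n_vd": FeatureSpec("n_vd", "insertion", "D", True, "n_vd", "simple"),
    "n_dj": FeatureSpec("n_dj", "insertion", "D", True, "n_dj", "simple"),
    "n_vj": FeatureSpec("n_vj", "insertion", "V", False, "n_vj", "simple"),
    "n_total": FeatureSpec("n_total", "insertion", "D", True, "n_total", "simple"),
    "p_v": FeatureSpec("p_v", "p_count", "V", False, "p_v", "gene_conditioned"),
    "p_d5": FeatureSpec("p_d5", "p_count", "D", True, "p_d5", "gene_conditioned"),
    "p_d3": FeatureSpec("p_d3", "p_count", "D", True, "p_d3", "gene_conditioned"),
    "p_j": FeatureSpec("p_j", "p_count", "J", False, "p_j", "gene_conditioned"),
}

_CALL_COLUMN = {"V": "v_call", "D": "d_call", "J": "j_call"}
_GROUP_COLUMN = {"V": "v_group", "D": "d_group", "J": "j_group"}


def feature_spec(name: str) -> FeatureSpec:
    """Resolve a feature name, including dynamic ``usage:<GENE>`` features."""
    if name in _BASE_FEATURES:
        return _BASE_FEATURES[name]
    if name.startswith("usage:"):
        gene = name.split(":", 1)[1]
        gene_type = _usage_gene_type(gene)
        return FeatureSpec(name, "usage", gene_type, gene_type == "D", gene,
                           "simple")
    raise KeyError(f"unknown feature {name!r}")


def _usage_gene_type(gene: str) -> str:
    for gt, tag in (("V", "V"), ("D", "D"), ("J", "J")):
        if f"B{tag}" in gene or f"A{tag}" in gene or gene.upper().startswith(tag):
            return gt
    raise KeyError(f"cannot infer gene type of {gene!r}")


def feature_names() -> list[str]:
    return list(_BASE_FEATURES)


def _per_read_values(df: pd.DataFrame, spec: FeatureSpec) -> pd.Series:
    if spec.kind == "usage":
        calls = df[_CALL_COLUMN[spec.gene_type]].fillna("")
        genes = calls.str.split("*").str[0]
        return (genes == spec.column).astype(float)
    if spec.name == "n_total":
        return df["n_vd"].astype(float) + df["n_dj"].astype(float)
    return df[spec.column].astype(float)


def _productivity_mask(df: pd.DataFrame, productivity: str) -> pd.Series:
    if productivity not in ("productive", "non_productive"):
        raise ValueError(f"unknown productivity {productivity!r}")
    return df["productive"] == (productivity == "productive")


def _qualifying(df: pd.DataFrame, feature: str, productivity: str,
                orphan_markers: Sequence[str]) -> pd.DataFrame:
    sub = df[_productivity_mask(df, productivity)]
    sub, _ = exclude_rows_for_feature(sub, feature, orphan_markers)
    return sub


def _pooled_qualifying(tables, feature, productivity, orphan_markers):
    """One concatenated frame of qualifying reads plus the subject list."""
    frames, subject_ids = [], []
    for t in tables:
        subject_ids.append(t.subject_id)
        df = t.df
        if "subject_id" not in df.columns:
            df = df.assign(subject_id=t.subject_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["subject_id"]), subject_ids
    pooled = pd.concat(frames, ignore_index=True)
    pooled = _qualifying(pooled, feature, productivity, orphan_markers)
    return pooled, subject_ids


def condense_simple(
    tables: Iterable[RepertoireTable],
    feature: str,
    productivity: str,
    orphan_markers: Sequence[str] = ("OR",),
) -> pd.DataFrame:
    """Per-subject feature means: columns subject_id, mean, count."""
    spec = feature_spec(feature)
    tables = list(tables)
    pooled, subject_ids = _pooled_qualifying(tables, feature, productivity,
                                             orphan_markers)
    if len(pooled) == 0:
        agg = pd.DataFrame(columns=["mean", "size"])
    else:
        vals = _per_read_values(pooled, spec)
        ok = vals.notna()
        agg = vals[ok].groupby(pooled.loc[ok, "subject_id"]).agg(
            ["mean", "size"])
    for sid in subject_ids:
        if sid not in agg.index:
            warnings.warn(f"subject {sid}: no qualifying reads for "
                          f"{feature}/{productivity}; dropped")
    order = [s for s in subject_ids if s in agg.index]
    agg = agg.loc[order]
    out = pd.DataFrame({
        "subject_id": agg.index,
        "mean": agg["mean"].astype(float).to_numpy(),
        "count": agg["size"].astype(int).to_numpy(),
    })
    out["feature"] = feature
    out["productivity"] = productivity
    return out


def condense_by_gene_group(
    tables: Iterable[RepertoireTable],
    feature: str,
    productivity: str,
    groups: Sequence[GeneAlleleGroup] | None = None,
    orphan_markers: Sequence[str] = ("OR",),
) -> pd.DataFrame:
    """Per-(subject, allele-group) means with weights W_im = N_im / sum_m N_im.

    Reads with an ambiguous call at the conditioning gene type are
    excluded (their group column is null).  Groups with no reads for a
    subject are omitted.
    """
    spec = feature_spec(feature)
    group_col = _GROUP_COLUMN[spec.gene_type]
    pooled, subject_ids = _pooled_qualifying(list(tables), feature,
                                             productivity, orphan_markers)
    if len(pooled):
        pooled = pooled[pooled[group_col].notna()]
    if len(pooled) == 0:
        out = pd.DataFrame(columns=["subject_id", "group_id", "mean",
                                    "count", "weight"])
        out["feature"] = feature
        out["productivity"] = productivity
        return out
    vals = _per_read_values(pooled, spec)
    ok = vals.notna()
    pooled, vals = pooled[ok], vals[ok]
    agg = vals.groupby(
        [pooled["subject_id"], pooled[group_col]]).agg(["mean", "size"])
    agg = agg.reset_index()
    agg.columns = ["subject_id", "group_id", "mean", "count"]
    totals = agg.groupby("subject_id")["count"].transform("sum")
    agg["weight"] = agg["count"] / totals
    # deterministic ordering: input subject order, then group id
    pos = {s: i for i, s in enumerate(subject_ids)}
    agg = agg.sort_values(
        ["subject_id", "group_id"],
        key=lambda c: c.map(pos) if c.name == "subject_id" else c,
    ).reset_index(drop=True)
    agg["mean"] = agg["mean"].astype(float)
    agg["count"] = agg["count"].astype(int)
    agg["feature"] = feature
    agg["productivity"] = productivity
    return agg


_P_COLUMN_FOR_END = {"V": ("v_trim", "p_v"), "D5": ("d5_trim", "p_d5"),
                     "D3": ("d3_trim", "p_d3"), "J": ("j_trim", "p_j")}


def untrimmed_p_fraction(
    table: RepertoireTable,
    end: str,
    productivity: str,
) -> float | None:
    """Among reads untrimmed at ``end``, the fraction carrying P-nucleotides.

    Returns None when the subject has no untrimmed reads at that end.
    """
    trim_col, p_col = _P_COLUMN_FOR_END[end]
    df = table.df[_productivity_mask(table.df, productivity)]
    if end in ("D5", "D3"):
        df = df[df["d_call"].notna()]
    untrimmed = df[df[trim_col] == 0]
    if len(untrimmed) == 0:
        return None
    return float((untrimmed[p_col] > 0).mean())


@dataclass
class SubjectMetadata:
    subject_id: str
    cluster: str | None = None
    trbd2_genotype: str = "unknown"


TRBD2_01_HOM = "TRBD2*01 homozygous"
TRBD2_HET = "heterozygous"
TRBD2_02_HOM = "TRBD2*02 homozygous"


def call_trbd2_genotype(
    table: RepertoireTable,
    hom_threshold: float = 0.9,
    min_informative: int = 50,
) -> str:
    """Qualitative TRBD2 allele genotype from unambiguous allele-level D calls.

    f = fraction of informative reads assigned TRBD2*01; f >= 0.9 calls
    *01 homozygous, f <= 0.1 calls *02 homozygous, otherwise
    heterozygous.  Thresholds are an interpretation (configurable).
    """
    calls = table.df["d_call"].fillna("")
    informative = calls.str.startswith("TRBD2*0") & ~table.df["d_ambiguous"].astype(bool)
    n = int(informative.sum())
    if n < min_informative:
        return "unknown"
    f01 = float((calls[informative] == "TRBD2*01").mean())
    if f01 >= hom_threshold:
        return TRBD2_01_HOM
    if f01 <= 1.0 - hom_threshold:
        return TRBD2_02_HOM
    return TRBD2_HET


def restrict_trbj1(
    table: RepertoireTable,
    germline: GermlineReference | None = None,
    config=None,
) -> RepertoireTable:
    """Keep TRBJ1-family reads and force their D assignment to TRBD1.

    TRBJ1 junctions can only contain TRBD1, so ambiguous or TRBD2 D calls
    are re-resolved by re-running parsimony against TRBD1 alleles when a
    germline reference is supplied; otherwise such rows are dropped.
    """
    df = table.df
    j_gene = df["j_call"].fillna("").str.split("*").str[0]
    df = df[j_gene.str.startswith("TRBJ1")].copy()
    needs_fix = df["d_call"].notna() & (
        df["d_ambiguous"].astype(bool)
        | ~df["d_call"].fillna("").str.startswith("TRBD1")
    )
    if needs_fix.any():
        if germline is None:
            df = df[~needs_fix]
        else:
            from .vdj_annotation import (AnnotationConfig, call_p_nucleotides,
                                         parsimonious_scenario)
            cfg = config or AnnotationConfig()
            trbd1 = [a.name for a in germline.by_type("D")
                     if a.gene == "TRBD1"]
            gmap = allele_group_map(build_allele_groups(germline))
            for idx in df.index[needs_fix]:
                row = df.loc[idx]
                scen = parsimonious_scenario(
                    row["sequence"], row["v_call"], row["j_call"], trbd1,
                    germline, cfg)
                scen = call_p_nucleotides(scen, germline, cap=cfg.p_cap)
                has_d = scen.d_allele is not None
                df.loc[idx, ["d_call", "d_group"]] = (
                    (scen.d_allele, gmap.get(scen.d_allele)) if has_d
                    else (None, None))
                df.loc[idx, ["d5_trim", "d3_trim", "n_vd", "n_dj", "n_vj"]] = (
                    (scen.d5_trim, scen.d3_trim, scen.n_vd, scen.n_dj, np.nan)
                    if has_d else
                    (np.nan, np.nan, np.nan, np.nan, scen.n_vj))
                df.loc[idx, ["p_d5", "p_d3"]] = (scen.p_d5, scen.p_d3)
                df.loc[idx, "d_ambiguous"] = False
    if len(df) == 0:
        df = table.df.iloc[0:0]
    return RepertoireTable(subject_id=table.subject_id, df=df.reset_index(drop=True),
                           chain=table.chain)
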