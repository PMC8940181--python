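"""Synthetic paired genotype + repertoire cohorts with known ground truth.

The generator plants three kinds of SNP effects — cis gene-usage shifts
(logit scale), trans shifts of gene-end trimming means, and trans shifts
of N-insertion means — on top of gene-group-specific trimming baselines,
cluster-structured allele frequencies, and optional cluster-level
feature shifts, so that every pipeline stage can be validated against
recorded truth without external data.

Reads are assembled base-by-base: trimmed V + [P]N insertions[P] +
trimmed D + [P]N insertions[P] + trimmed J, with productivity emerging
from reading-frame and stop-codon arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (GenotypeMatrix, GermlineAllele, GermlineReference,
                         RepertoireTable)
from .vdj_annotation import (STOP_CODONS, allele_group_map,
                             build_allele_groups, revcomp)

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "make_germline",
    "simulate_genotypes",
    "simulate_repertoire",
    "simulate_cohort",
    "preset_config",
]

_NT = "ACGT"
_NT_ARR = np.array(list(_NT))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(_NT_ARR[rng.integers(0, 4, size=n)])

V_OBS_LEN = 30
J_OBS_LEN = 24
V_MAX_TRIM = 18
J_MAX_TRIM = 12


# ---------------------------------------------------------------------------
# germline construction


def _stop_free_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(rng.choice(list(_NT), size=3))
            if codon not in STOP_CODONS:
                break
        out.append(codon)
    return "".join(out)


def _lcs_len(s: str, t: str) -> int:
    best = 0
    for L in range(min(len(s), len(t)), 0, -1):
        if L <= best:
            return best
        for i in range(len(s) - L + 1):
            if s[i:i + L] in t:
                return L
    return best


def make_germline(seed: int = 20_240_101) -> GermlineReference:
    """Deterministic small germline: 12 V, 3 D, 6 J alleles.

    V and J sequences are stop-free in their coding frame (anchors 0) and
    pairwise distinguishable over the observed span except one designed
    ambiguous V pair (TRBV09*01/*02, identical sequences).  D alleles are
    12-16 nt; TRBD2*01 and TRBD2*02 differ at three central positions.
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        v_seqs = [_stop_free_codons(rng, V_OBS_LEN // 3) for _ in range(11)]
        j_seqs = [_stop_free_codons(rng, J_OBS_LEN // 3) for _ in range(6)]
        distinct = all(
            _lcs_len(a, b) < 10
            for seqs in (v_seqs, j_seqs)
            for i, a in enumerate(seqs)
            for b in seqs[i + 1:]
        )
        if distinct:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build a distinguishable germline")

    alleles: list[GermlineAllele] = []
    for g in range(1, 11):
        alleles.append(GermlineAllele(
            f"TRBV{g:02d}*01", f"TRBV{g:02d}", "V", v_seqs[g - 1], 0))
    # distinguishable second allele of TRBV05 (three substitutions)
    v5 = list(v_seqs[4])
    for pos, alt in ((4, "A"), (13, "C"), (22, "G")):
        v5[pos] = alt if v5[pos] != alt else ("T" if alt != "T" else "C")
    v5b = "".join(v5)
    for i in range(0, len(v5b) - 2, 3):
        if v5b[i:i + 3] in STOP_CODONS:
            v5 = list(v5b)
            v5[i + 2] = "C" if v5[i + 2] != "C" else "G"
            v5b = "".join(v5)
    alleles.append(GermlineAllele("TRBV05*02", "TRBV05", "V", v5b, 0))
    # designed ambiguous pair: identical over the full observed span
    alleles.append(GermlineAllele("TRBV09*02", "TRBV09", "V", v_seqs[8], 0))

    d1 = "".join(rng.choice(list(_NT), size=12))
    d2 = "".join(rng.choice(list(_NT), size=16))
    d2b = list(d2)
    for pos in (6, 8, 10):
        d2b[pos] = _NT[(_NT.index(d2b[pos]) + 2) % 4]
    alleles.append(GermlineAllele("TRBD1*01", "TRBD1", "D", d1, 0))
    alleles.append(GermlineAllele("TRBD2*01", "TRBD2", "D", d2, 0))
    alleles.append(GermlineAllele("TRBD2*02", "TRBD2", "D", "".join(d2b), 0))

    jnames = ["TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ2-1", "TRBJ2-2", "TRBJ2-3"]
    for name, seq in zip(jnames, j_seqs):
        alleles.append(GermlineAllele(f"{name}*01", name, "J", seq, 0))
    return GermlineReference(alleles)


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class PlantedEffect:
    snp_id: str
    feature: str  # v_trim / j_trim / d5_trim / d3_trim / n_vd / n_dj / n_total / usage:<GENE>
    beta: float
    mode: str  # usage | trimming | insertion

    def validate(self, snp_ids: Sequence[str]) -> None:
        if self.snp_id not in snp_ids:
            raise ValueError(f"planted SNP {self.snp_id} not in genotype matrix")
        if self.mode not in ("usage", "trimming", "insertion"):
            raise ValueError(f"bad effect mode {self.mode!r}")


@dataclass
class CohortConfig:
    n_subjects: int = 300
    n_snps: int = 2000
    n_reads: int = 3000
    n_clusters: int = 3
    divergence: float = 0.05
    maf_range: tuple[float, float] = (0.08, 0.5)
    cluster_weights: tuple[float, ...] | None = None
    #: (feature, beta, mode) planted at deterministic SNP indices
    planted: tuple[tuple[str, float, str], ...] = (
        ("usage:TRBV05", 0.8, "usage"),
        ("v_trim", 0.5, "trimming"),
        ("n_total", 0.5, "insertion"),
    )
    #: additive shift of the total-insertion mean per cluster index
    cluster_insertion_shift: tuple[float, ...] = ()
    insertion_mean: float = 3.5
    nb_size: float = 5.0
    p_prob: float = 0.15
    trbd2_02_freq: float = 0.4
    #: target share of productive reads after selection resampling
    #: (None disables selection and productivity falls out of the frame
    #: arithmetic, roughly one third productive)
    target_productive_fraction: float | None = 0.82
    #: force all trims, insertions and P-additions to zero (reads become
    #: exact V+D+J concatenations); for annotator round-trip tests
    zero_noise: bool = False
    germline_seed: int = 20_240_101


@dataclass
class SyntheticTruth:
    config: CohortConfig
    seed: int
    planted: list[PlantedEffect]
    cluster_of: dict[str, int]
    trbd2_genotype: dict[str, str]
    #: per-group baseline trimming means (gamma_m analogues)
    trim_means: dict[str, float]
    ancestral_freq: list[float]
    cluster_freq: list[list[float]]  # clusters x snps

    def planted_for(self, mode: str) -> list[PlantedEffect]:
        return [e for e in self.planted if e.mode == mode]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "planted": [dataclasses.asdict(e) for e in self.planted],
            "cluster_of": self.cluster_of,
            "trbd2_genotype": self.trbd2_genotype,
            "trim_means": self.trim_means,
            "ancestral_freq": self.ancestral_freq,
            "cluster_freq": self.cluster_freq,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    repertoires: list[RepertoireTable]
    metadata: pd.DataFrame  # subject_id, cluster, trbd2_genotype
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.08, 0.5),
    n_clusters: int = 3,
    divergence: float = 0.05,
    seed: int = 0,
    cluster_weights: Sequence[float] | None = None,
    planted_idx: Sequence[int] = (),
) -> tuple[GenotypeMatrix, dict[str, int], list[float], list[list[float]]]:
    """Balding-Nichols style cluster-structured biallelic genotypes.

    Cluster allele frequencies are Beta-distributed around shared
    ancestral frequencies with spread controlled by ``divergence``
    (F = 0 collapses every cluster onto the ancestral frequency).
    Planted SNPs get mid-range frequencies so they survive MAF filtering.
    """
    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    if cluster_weights is None:
        cluster_weights = [1.0 / n_clusters] * n_clusters
    w = np.asarray(cluster_weights, dtype=float)
    clusters = rng.choice(n_clusters, size=n_subjects, p=w / w.sum())
    p_anc = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    for j in planted_idx:
        p_anc[j] = rng.uniform(0.25, 0.45)
    if divergence > 0:
        F = divergence
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        cf = np.vstack([
            np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
            for _ in range(n_clusters)
        ])
    else:
        cf = np.vstack([p_anc for _ in range(n_clusters)])
    dosage = rng.binomial(2, cf[clusters, :]).astype(float)
    # keep planted SNPs comfortably polymorphic
    for j in planted_idx:
        tries = 0
        while np.nanmean(dosage[:, j]) / 2 in (0.0, 1.0) and tries < 10:
            dosage[:, j] = rng.binomial(2, cf[clusters, j])
            tries += 1
    snp_ids = [f"chr1:{100_000 + 1_000 * j}:snp{j:05d}" for j in range(n_snps)]
    chrom = np.array(["chr1"] * n_snps, dtype=object)
    pos = np.array([100_000 + 1_000 * j for j in range(n_snps)], dtype=int)
    gm = GenotypeMatrix(subject_ids, snp_ids, chrom, pos, dosage)
    cluster_of = {s: int(c) for s, c in zip(subject_ids, clusters)}
    return gm, cluster_of, p_anc.tolist(), cf.tolist()


# ---------------------------------------------------------------------------
# repertoires


def _baseline_trim_means(germline: GermlineReference,
                         seed: int) -> dict[str, float]:
    """Gene-group-specific baseline trimming means (the gamma_m analogues)."""
    rng = np.random.default_rng(seed + 77)
    groups = build_allele_groups(germline)
    means = {}
    # means kept away from zero so that parsimony boundary ambiguity
    # (an N base coinciding with the trimmed germline base) stays in its
    # saturated regime and does not couple to planted mean shifts
    for g in groups:
        if g.gene_type == "V":
            means[f"v_trim:{g.group_id}"] = float(rng.uniform(2.5, 4.0))
        elif g.gene_type == "J":
            means[f"j_trim:{g.group_id}"] = float(rng.uniform(2.0, 3.5))
        else:
            means[f"d5_trim:{g.group_id}"] = float(rng.uniform(1.0, 2.0))
            means[f"d3_trim:{g.group_id}"] = float(rng.uniform(1.0, 2.0))
    return means


_GEOM_CACHE: dict[tuple[float, int], float] = {}


def _trunc_geom_p(mean: float, cap: int) -> float:
    """Geometric parameter whose cap-truncated mean equals ``mean``.

    Solved by bisection on the closed-form truncated mean so that planted
    mean shifts survive truncation exactly.
    """
    key = (round(mean, 9), cap)
    if key in _GEOM_CACHE:
        return _GEOM_CACHE[key]

    def trunc_mean(p: float) -> float:
        q = 1.0 - p
        qc = q ** (cap + 1)
        return (q / p - qc * (cap + 1 + q / p)) / (1.0 - qc)

    lo, hi = 1e-9, 1.0 - 1e-9  # mean decreasing in p
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if trunc_mean(mid) > mean:
            lo = mid
        else:
            hi = mid
    _GEOM_CACHE[key] = lo
    return lo


def _trunc_geom(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0.0:
        return 0
    mean = min(max(mean, 0.05), 0.9 * cap)
    p = _trunc_geom_p(mean, cap)
    for _ in range(100):
        k = int(rng.geometric(p)) - 1
        if k <= cap:
            return k
    return cap


def _neg_binom(rng: np.random.Generator, mean: float, size: float) -> int:
    if mean <= 0.0:
        return 0
    mean = max(mean, 0.05)
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


class _RepertoireSampler:
    """Per-cohort sampling machinery shared across subjects."""

    def __init__(self, germline: GermlineReference, truth: SyntheticTruth):
        self.germline = germline
        self.truth = truth
        self.group_of = allele_group_map(build_allele_groups(germline))
        cfg = truth.config
        self.v_alleles = sorted(germline.by_type("V"), key=lambda a: a.name)
        self.j_alleles = sorted(germline.by_type("J"), key=lambda a: a.name)
        self.d1 = germline["TRBD1*01"]
        self.d2 = {"TRBD2*01": germline["TRBD2*01"],
                   "TRBD2*02": germline["TRBD2*02"]}
        rng = np.random.default_rng(cfg.germline_seed + 13)
        # gene-level base usage (mildly uneven, Dirichlet-drawn)
        self.v_genes = sorted({a.gene for a in self.v_alleles})
        self.v_base_logit = {g: float(rng.normal(0, 0.4)) for g in self.v_genes}
        self.j_probs = rng.dirichlet([8.0] * len(self.j_alleles))
        self.alleles_of_gene = {
            g: [a for a in self.v_alleles if a.gene == g] for g in self.v_genes
        }

    def v_usage_probs(self, dosage_of: dict[str, float]) -> np.ndarray:
        logits = np.array([self.v_base_logit[g] for g in self.v_genes])
        for eff in self.truth.planted_for("usage"):
            gene = eff.feature.split(":", 1)[1]
            if gene in self.v_genes:
                gi = self.v_genes.index(gene)
                logits[gi] += eff.beta * dosage_of.get(eff.snp_id, 0.0)
        ex = np.exp(logits - logits.max())
        return ex / ex.sum()

    def trim_shift(self, feature: str, dosage_of: dict[str, float]) -> float:
        shift = 0.0
        for eff in self.truth.planted_for("trimming"):
            if eff.feature == feature:
                shift += eff.beta * dosage_of.get(eff.snp_id, 0.0)
        return shift

    def insertion_means(self, dosage_of: dict[str, float],
                        cluster: int) -> tuple[float, float]:
        cfg = self.truth.config
        base = cfg.insertion_mean
        m_vd, m_dj = base, base
        for eff in self.truth.planted_for("insertion"):
            d = eff.beta * dosage_of.get(eff.snp_id, 0.0)
            if eff.feature == "n_vd":
                m_vd += d
            elif eff.feature == "n_dj":
                m_dj += d
            elif eff.feature == "n_total":
                m_vd += d / 2.0
                m_dj += d / 2.0
        if cfg.cluster_insertion_shift and cluster < len(cfg.cluster_insertion_shift):
            s = cfg.cluster_insertion_shift[cluster]
            m_vd += s / 2.0
            m_dj += s / 2.0
        return m_vd, m_dj


def _maybe_p(rng: np.random.Generator, terminal: str, side: str,
             prob: float) -> str:
    """P-nucleotide emission at an untrimmed gene end."""
    if rng.random() >= prob:
        return ""
    k = 1 if rng.random() < 0.7 else 2
    k = min(k, len(terminal))
    if side == "after":  # off a 3' end: revcomp of the terminal suffix
        return revcomp(terminal[-k:])
    return revcomp(terminal[:k])  # off a 5' end, placed before the gene


def simulate_repertoire(
    subject_id: str,
    dosage_of: dict[str, float],
    cluster: int,
    trbd2_genotype: str,
    sampler: _RepertoireSampler,
    n_reads: int,
    rng: np.random.Generator,
) -> RepertoireTable:
    """Generate one subject's reads with truth annotation columns."""
    cfg = sampler.truth.config
    tm = sampler.truth.trim_means
    gof = sampler.group_of
    v_cum = np.cumsum(sampler.v_usage_probs(dosage_of))
    j_cum = np.cumsum(sampler.j_probs)
    dv_shift = sampler.trim_shift("v_trim", dosage_of)
    dj_shift = sampler.trim_shift("j_trim", dosage_of)
    d5_shift = sampler.trim_shift("d5_trim", dosage_of)
    d3_shift = sampler.trim_shift("d3_trim", dosage_of)
    m_vd, m_dj = sampler.insertion_means(dosage_of, cluster)
    target = cfg.target_productive_fraction

    # per-subject sampling plan: everything indexable, no dict lookups in
    # the per-read loop
    def _geom_p(mean: float, cap: int) -> float | None:
        if mean <= 0.0:
            return None
        return _trunc_geom_p(min(max(mean, 0.05), 0.9 * cap), cap)

    v_plan = [(a.name, a.seq, gof[a.name],
               _geom_p(tm[f"v_trim:{gof[a.name]}"] + dv_shift, V_MAX_TRIM))
              for g in sampler.v_genes for a in sampler.alleles_of_gene[g]]
    # index ranges of each gene's alleles within v_plan
    v_offsets, off = [], 0
    for g in sampler.v_genes:
        n_a = len(sampler.alleles_of_gene[g])
        v_offsets.append((off, n_a))
        off += n_a
    j_plan = [(a.name, a.seq, gof[a.name],
               _geom_p(tm[f"j_trim:{gof[a.name]}"] + dj_shift, J_MAX_TRIM))
              for a in sampler.j_alleles]
    d_plan = {
        a.name: (a.name, a.seq, gof[a.name],
                 _geom_p(tm[f"d5_trim:{gof[a.name]}"] + d5_shift, len(a.seq)),
                 _geom_p(tm[f"d3_trim:{gof[a.name]}"] + d3_shift, len(a.seq)))
        for a in [sampler.d1, *sampler.d2.values()]
    }
    size = cfg.nb_size
    p_vd = size / (size + max(m_vd, 0.05)) if m_vd > 0 else None
    p_dj = size / (size + max(m_dj, 0.05)) if m_dj > 0 else None

    plan = (v_plan, v_offsets, j_plan, d_plan, p_vd, p_dj, size,
            cfg.p_prob, trbd2_genotype)
    rows = []
    for _ in range(n_reads):
        want_productive = (None if target is None
                           else bool(rng.random() < target))
        for _attempt in range(300):
            row = _one_read(sampler, rng, v_cum, j_cum, plan)
            if want_productive is None or row["productive"] == want_productive:
                break
        rows.append(row)
    df = pd.DataFrame(rows)
    return RepertoireTable(subject_id=subject_id, df=df)


def _geom_draw(rng: np.random.Generator, p: float | None, cap: int) -> int:
    if p is None:
        return 0
    for _ in range(100):
        k = int(rng.geometric(p)) - 1
        if k <= cap:
            return k
    return cap


def _one_read(sampler: _RepertoireSampler, rng: np.random.Generator,
              v_cum, j_cum, plan) -> dict:
    (v_plan, v_offsets, j_plan, d_plan, p_vd, p_dj, nb_size, p_prob,
     trbd2_genotype) = plan
    off, n_a = v_offsets[int(np.searchsorted(v_cum, rng.random()))]
    v_name, v_seq, v_group, pv = v_plan[off + (int(rng.integers(n_a))
                                               if n_a > 1 else 0)]
    j_name, j_seq, j_group, pj = j_plan[int(np.searchsorted(j_cum,
                                                            rng.random()))]
    if j_name.startswith("TRBJ1") or rng.random() < 0.5:
        # topological constraint: TRBJ1 implies TRBD1
        d_name, d_seq, d_group, pd5, pd3 = d_plan["TRBD1*01"]
    else:
        if trbd2_genotype == "TRBD2*01 homozygous":
            key = "TRBD2*01"
        elif trbd2_genotype == "TRBD2*02 homozygous":
            key = "TRBD2*02"
        else:
            key = "TRBD2*01" if rng.random() < 0.5 else "TRBD2*02"
        d_name, d_seq, d_group, pd5, pd3 = d_plan[key]

    v_trim = _geom_draw(rng, pv, V_MAX_TRIM)
    j_trim = _geom_draw(rng, pj, J_MAX_TRIM)
    d_len = len(d_seq)
    for _ in range(100):
        d5 = _geom_draw(rng, pd5, d_len)
        d3 = _geom_draw(rng, pd3, d_len)
        if d5 + d3 <= d_len:
            break
    n_vd_raw = int(rng.negative_binomial(nb_size, p_vd)) if p_vd else 0
    n_dj_raw = int(rng.negative_binomial(nb_size, p_dj)) if p_dj else 0

    v_part = v_seq[:len(v_seq) - v_trim]
    d_part = d_seq[d5:d_len - d3]
    j_part = j_seq[j_trim:]
    p_v_str = _maybe_p(rng, v_seq, "after", p_prob) if v_trim == 0 else ""
    p_d5_str = (_maybe_p(rng, d_seq, "before", p_prob)
                if d5 == 0 and d_part else "")
    p_d3_str = (_maybe_p(rng, d_seq, "after", p_prob)
                if d3 == 0 and d_part else "")
    p_j_str = _maybe_p(rng, j_seq, "before", p_prob) if j_trim == 0 else ""
    n_vd_str = _random_nt(rng, n_vd_raw)
    n_dj_str = _random_nt(rng, n_dj_raw)
    insert_vd = p_v_str + n_vd_str + p_d5_str
    insert_dj = p_d3_str + n_dj_str + p_j_str
    read = v_part + insert_vd + d_part + insert_dj + j_part

    # frame/stop arithmetic, written independently of the annotator:
    # both V and J anchors are phase 0 at their stored 5' ends
    j_start = len(v_part) + len(insert_vd) + len(d_part) + len(insert_dj)
    in_frame = (j_start % 3) == (j_trim % 3)
    productive = in_frame
    if in_frame:
        for stop in STOP_CODONS:
            i = read.find(stop)
            while i != -1:
                if i % 3 == 0:
                    productive = False
                    break
                i = read.find(stop, i + 1)
            if not productive:
                break

    return {
        "sequence": read,
        "v_call": v_name, "d_call": d_name, "j_call": j_name,
        "v_group": v_group, "d_group": d_group, "j_group": j_group,
        "v_trim": v_trim, "d5_trim": d5, "d3_trim": d3, "j_trim": j_trim,
        "n_vd": len(insert_vd), "n_dj": len(insert_dj), "n_vj": np.nan,
        "p_v": len(p_v_str), "p_d5": len(p_d5_str),
        "p_d3": len(p_d3_str), "p_j": len(p_j_str),
        "productive": productive,
        "v_ambiguous": False, "d_ambiguous": False, "j_ambiguous": False,
    }


# ---------------------------------------------------------------------------
# cohorts


def _planted_snp_indices(cfg: CohortConfig) -> list[int]:
    """Deterministic, well-separated SNP indices for planted effects."""
    step = max(cfg.n_snps // (len(cfg.planted) + 1), 1)
    return [min(step * (i + 1), cfg.n_snps - 1) for i in range(len(cfg.planted))]


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    germline: GermlineReference | None = None,
) -> SyntheticCohort:
    config = config or CohortConfig()
    germline = germline or make_germline(config.germline_seed)
    idx = _planted_snp_indices(config)
    gm, cluster_of, p_anc, cf = simulate_genotypes(
        config.n_subjects, config.n_snps, config.maf_range,
        config.n_clusters, config.divergence, seed,
        cluster_weights=config.cluster_weights, planted_idx=idx,
    )
    planted = [
        PlantedEffect(gm.snp_ids[j], feat, beta, mode)
        for j, (feat, beta, mode) in zip(idx, config.planted)
    ]
    for e in planted:
        e.validate(gm.snp_ids)
    rng = np.random.default_rng(seed + 1)
    trbd2 = {}
    for s in gm.subject_ids:
        n02 = rng.binomial(2, config.trbd2_02_freq)
        trbd2[s] = ("TRBD2*02 homozygous" if n02 == 2
                    else "heterozygous" if n02 == 1
                    else "TRBD2*01 homozygous")
    trim_means = _baseline_trim_means(germline, config.germline_seed)
    if config.zero_noise:
        trim_means = {k: 0.0 for k in trim_means}
        config = dataclasses.replace(config, insertion_mean=0.0, p_prob=0.0)
    truth = SyntheticTruth(
        config=config, seed=seed, planted=planted, cluster_of=cluster_of,
        trbd2_genotype=trbd2, trim_means=trim_means,
        ancestral_freq=p_anc, cluster_freq=cf,
    )
    sampler = _RepertoireSampler(germline, truth)
    planted_cols = {e.snp_id: gm.dosage_for(e.snp_id) for e in planted}
    repertoires = []
    for i, s in enumerate(gm.subject_ids):
        dosage_of = {sid: float(col[s]) for sid, col in planted_cols.items()}
        rep = simulate_repertoire(
            s, dosage_of, cluster_of[s], trbd2[s], sampler, config.n_reads,
            np.random.default_rng((seed, 997, i)),
        )
        repertoires.append(rep)
    metadata = pd.DataFrame({
        "subject_id": gm.subject_ids,
        "cluster": [cluster_of[s] for s in gm.subject_ids],
        "trbd2_genotype": [trbd2[s] for s in gm.subject_ids],
    })
    return SyntheticCohort(genotypes=gm, repertoires=repertoires,
                           metadata=metadata, truth=truth)


def preset_config(name: str) -> CohortConfig:
    """Named cohort presets.

    desk        — the reference integration-scale cohort
    desk_small  — a minutes-scale version for unit/property tests
    null        — desk_small with no planted effects
    """
    if name == "desk":
        return CohortConfig()
    if name == "desk_small":
        return CohortConfig(n_subjects=80, n_snps=300, n_reads=300)
    if name == "null":
        return CohortConfig(n_subjects=80, n_snps=300, n_reads=300,
                            planted=())
    raise KeyError(f"unknown preset {name!r}")
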