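"""Readers, writers, and data-preparation filters.

Formats handled: plain genotype tables (TSV), VCF 4.2 (GT field only),
AIRR Rearrangement TSV (with junction-feature extension columns), and a
germline allele FASTA whose headers carry ``name|gene|type|frame_anchor``
tokens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RepertoireTable",
    "GermlineAllele",
    "GermlineReference",
    "read_genotypes",
    "write_genotype_table",
    "read_germline_fasta",
    "write_germline_fasta",
    "read_airr",
    "write_airr",
    "filter_snps",
    "filter_repertoires",
    "exclude_rows_for_feature",
    "DEFAULT_REPERTOIRE_LOG10_MIN",
    "AIRR_EXTENSION_COLUMNS",
]

VALID_NT = set("ACGT")

# log10(unique rearrangement count) below which a repertoire is dropped
DEFAULT_REPERTOIRE_LOG10_MIN = {"productive": 4.25, "non_productive": 3.5}

#: extension columns appended to the AIRR Rearrangement schema by annotation
AIRR_EXTENSION_COLUMNS = [
    "v_trim", "d5_trim", "d3_trim", "j_trim",
    "n_vd", "n_dj", "p_v", "p_d5", "p_d3", "p_j",
]

AIRR_CORE_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call",
    "junction", "productive",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the declared dialect."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with SNP metadata.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for
    missing genotypes, oriented so each column counts the cohort minor
    allele.  ``maf`` is computed over non-missing entries.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    build: str = "synthetic"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match subject/snp ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0/1/2 or missing")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        self._orient_to_minor()

    def _orient_to_minor(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        flip = freq > 0.5
        if flip.any():
            self.dosage[:, flip] = 2.0 - self.dosage[:, flip]
            freq = np.where(flip, 1.0 - freq, freq)
        self.maf = freq

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def dosage_for(self, snp_id: str) -> pd.Series:
        """Per-subject dosage of one SNP, indexed by subject id."""
        j = self.snp_index(snp_id)
        return pd.Series(self.dosage[:, j], index=self.subject_ids, name=snp_id)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snp_ids=[self.snp_ids[j] for j in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx].copy(),
            build=self.build,
        )


@dataclass
class RepertoireTable:
    """One subject's rearrangement table (AIRR-style DataFrame)."""

    subject_id: str
    df: pd.DataFrame
    chain: str = "beta"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id required")
        if "sequence" not in self.df.columns:
            raise ValueError("rearrangement table needs a 'sequence' column")
        seqs = self.df["sequence"]
        if seqs.isna().any() or (seqs.str.len() == 0).any():
            raise ValueError("every row needs a non-empty nucleotide sequence")
        bad = ~seqs.map(lambda s: set(s) <= VALID_NT)
        if bad.any():
            raise ValueError(
                f"non-ACGT sequence in rows {list(self.df.index[bad])[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class GermlineAllele:
    name: str
    gene: str
    gene_type: str  # V, D or J
    seq: str
    frame_anchor: int  # codon phase of the first base of the stored sequence

    def __post_init__(self) -> None:
        if self.gene_type not in ("V", "D", "J"):
            raise ValueError(f"bad gene_type {self.gene_type!r} for {self.name}")
        if not set(self.seq) <= VALID_NT:
            raise ValueError(f"non-ACGT sequence for allele {self.name}")
        if self.gene_type == "D" and not (12 <= len(self.seq) <= 16):
            raise ValueError(
                f"D allele {self.name} length {len(self.seq)} outside 12-16 nt"
            )


class GermlineReference:
    """Mapping of allele name -> :class:`GermlineAllele`."""

    def __init__(self, alleles: Iterable[GermlineAllele]):
        self.alleles: dict[str, GermlineAllele] = {}
        for a in alleles:
            if a.name in self.alleles:
                raise ValueError(f"duplicate allele {a.name}")
            self.alleles[a.name] = a

    def __getitem__(self, name: str) -> GermlineAllele:
        return self.alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __iter__(self):
        return iter(self.alleles.values())

    def __len__(self) -> int:
        return len(self.alleles)

    def by_type(self, gene_type: str) -> list[GermlineAllele]:
        return [a for a in self.alleles.values() if a.gene_type == gene_type]


# ---------------------------------------------------------------------------
# genotype I/O


def _read_genotype_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "subject_id":
        raise GenotypeParseError(
            f"{path}: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    snp_ids = list(df.columns[1:])
    subject_ids = df["subject_id"].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    dosage = np.full(raw.shape, np.nan)
    for (i, j), tok in np.ndenumerate(raw):
        if isinstance(tok, float) and math.isnan(tok):
            continue
        tok = str(tok).strip()
        if tok in ("NA", "", "."):
            continue
        if tok not in ("0", "1", "2"):
            raise GenotypeParseError(
                f"{path}: malformed genotype token {tok!r} at line {i + 2}"
            )
        dosage[i, j] = float(tok)
    chrom, pos = _snp_metadata_from_ids(snp_ids)
    return GenotypeMatrix(subject_ids, snp_ids, chrom, pos, dosage)


def _snp_metadata_from_ids(snp_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """SNP ids of the form chrom:pos[:name] carry their own coordinates."""
    chrom, pos = [], []
    for sid in snp_ids:
        parts = sid.split(":")
        if len(parts) >= 2 and parts[1].isdigit():
            chrom.append(parts[0])
            pos.append(int(parts[1]))
        else:
            chrom.append("unknown")
            pos.append(0)
    return np.array(chrom, dtype=object), np.array(pos, dtype=int)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids, chrom, pos, columns = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multi-allelic SNP {variant.ID or variant.POS} rejected"
            )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = variant.gt_types.astype(float)
        col = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(sid)
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        columns.append(col)
    dosage = np.column_stack(columns) if columns else np.empty((len(subject_ids), 0))
    return GenotypeMatrix(subject_ids, snp_ids, np.array(chrom, dtype=object),
                          np.array(pos, dtype=int), dosage)


def read_genotypes(path: str | Path, format: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix, orienting dosages to the cohort minor allele.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"table"`` for the TSV dialect (header ``subject_id`` then SNP
        ids, values 0/1/2/NA) or ``"vcf"`` for VCF 4.2 with GT genotypes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_genotype_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    out = pd.DataFrame(
        gm.dosage, index=pd.Index(gm.subject_ids, name="subject_id"),
        columns=gm.snp_ids,
    )
    out = out.map(lambda v: "NA" if math.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write minor-allele dosages as a minimal VCF 4.2 (GT only, REF=A ALT=G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=tcrgwas (build {gm.build})\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for c in gm.chrom:
            if c not in chroms:
                chroms.append(c)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.subject_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, sid in enumerate(gm.snp_ids):
            gts = [
                "./." if math.isnan(v) else gt_map[v] for v in gm.dosage[:, j]
            ]
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# germline FASTA


def read_germline_fasta(path: str | Path) -> GermlineReference:
    """Parse a germline FASTA with ``name|gene|type|frame_anchor`` headers."""
    from Bio import SeqIO

    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()[0].split("|")
        if len(fields) != 4:
            raise ValueError(
                f"germline header {rec.description!r} must have 4 '|' fields"
            )
        name, gene, gtype, anchor = fields
        alleles.append(
            GermlineAllele(name, gene, gtype, str(rec.seq).upper(), int(anchor))
        )
    return GermlineReference(alleles)


def write_germline_fasta(germline: GermlineReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in germline:
            fh.write(f">{a.name}|{a.gene}|{a.gene_type}|{a.frame_anchor}\n")
            fh.write(a.seq + "\n")


# ---------------------------------------------------------------------------
# AIRR rearrangement TSV


def read_airr(path: str | Path, subject_id: str | None = None,
              chain: str = "beta") -> RepertoireTable:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str}, keep_default_na=True)
    if subject_id is None:
        if "subject_id" in df.columns:
            ids = df["subject_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"{path}: expected a single subject, got {ids}")
            subject_id = str(ids[0])
        else:
            subject_id = Path(path).stem
    if "productive" in df.columns:
        df["productive"] = df["productive"].map(
            {"T": True, "F": False, True: True, False: False,
             "True": True, "False": False}
        )
    return RepertoireTable(subject_id=subject_id, df=df, chain=chain)


def write_airr(table: RepertoireTable, path: str | Path) -> None:
    df = table.df.copy()
    df.insert(0, "subject_id", table.subject_id)
    if "productive" in df.columns:
        df["productive"] = df["productive"].map({True: "T", False: "F"})
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# data-preparation filters


def filter_snps(gm: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with cohort MAF strictly above ``min_maf``.

    Monomorphic SNPs (MAF 0) are always removed for any ``min_maf >= 0``.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = gm.maf > min_maf
    out = gm.subset_snps(keep)
    out.n_removed = int((~keep).sum())  # type: ignore[attr-defined]
    return out


def filter_repertoires(
    tables: Sequence[RepertoireTable],
    productivity: str,
    log10_min: Mapping[str, float] | None = None,
) -> list[RepertoireTable]:
    """Drop subjects with too few rearrangements of the given productivity.

    A subject is retained iff log10(count) >= threshold; the exclusion
    rule is strict ``<``, so equality keeps the subject.
    """
    if productivity not in ("productive", "non_productive"):
        raise ValueError(f"unknown productivity {productivity!r}")
    thresholds = dict(DEFAULT_REPERTOIRE_LOG10_MIN)
    if log10_min:
        thresholds.update(log10_min)
    bound = thresholds[productivity]
    want = productivity == "productive"
    kept = []
    for t in tables:
        if "productive" not in t.df.columns:
            raise ValueError(f"subject {t.subject_id}: productivity not assigned")
        n = int((t.df["productive"] == want).sum())
        if n > 0 and math.log10(n) >= bound:
            kept.append(t)
    return kept


def _is_orphan(gene: str, orphan_markers: Sequence[str]) -> bool:
    return any(m in gene for m in orphan_markers)


def exclude_rows_for_feature(
    df: pd.DataFrame,
    feature: str,
    orphan_markers: Sequence[str] = ("OR",),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the per-feature row-exclusion rules.

    D-dependent features drop rows without an identifiable D; gene-usage
    features drop rows whose relevant gene call is an orphan gene.
    Returns the filtered frame and counts removed per rule.
    """
    from .repertoire_features import feature_spec  # local to avoid cycle

    spec = feature_spec(feature)
    removed = {"unidentifiable_d": 0, "orphan_gene": 0}
    out = df
    if spec.d_dependent:
        if "d_call" not in out.columns:
            raise ValueError("annotation incomplete: no d_call column")
        mask = out["d_call"].notna() & (out["d_call"] != "")
        removed["unidentifiable_d"] = int((~mask).sum())
        out = out[mask]
    if spec.kind == "usage":
        call_col = {"V": "v_call", "D": "d_call", "J": "j_call"}[spec.gene_type]
        calls = out[call_col].fillna("")
        mask = ~calls.map(lambda g: _is_orphan(g, orphan_markers))
        removed["orphan_gene"] = int((~mask).sum())
        out = out[mask]
    return out, removed
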