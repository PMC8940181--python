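"""End-to-end orchestration: prepare -> annotate -> condense -> scan -> diagnostics.

Every stage is a pure function of (inputs, config, seed); outputs are
stamped with the config hash and seed so a re-run with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io_formats, popstruct, repertoire_features, synthetic
from .vdj_annotation import AnnotationConfig, annotate_repertoire

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("tcrgwas")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declarative run description; every constant is surfaced here."""

    # inputs: either a synthetic preset or on-disk paths
    simulate_preset: str | None = "desk"
    genotypes: str | None = None
    genotype_format: str = "table"
    repertoire_dir: str | None = None
    germline: str | None = None

    features: list[str] = field(default_factory=lambda: [
        "usage:TRBV05", "v_trim", "n_total",
    ])
    productivities: list[str] = field(default_factory=lambda: [
        "productive", "non_productive",
    ])
    models: dict[str, str] = field(default_factory=dict)

    min_maf: float = 0.05
    repertoire_log10_min: dict[str, float] = field(default_factory=lambda: {
        "productive": 4.25, "non_productive": 3.5,
    })
    n_pcs: int = 8
    bootstrap_trigger: float = 5e-5
    bootstrap_reps: int = 100
    alpha: float = 0.05
    lambda_threshold: float = 1.03
    lambda_subsample: int = 10_000
    locus_window: int = 200_000
    #: named loci ("chrom:start-end") for gene-level conditional scans
    loci: dict[str, str] = field(default_factory=dict)
    min_read_len: int = 40
    seed: int = 1

    def digest(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def _validate(config: RunConfig) -> None:
    if config.simulate_preset is None:
        for key in ("genotypes", "repertoire_dir", "germline"):
            val = getattr(config, key)
            if val is None:
                raise ValueError(f"config requires {key} when not simulating")
            if not Path(val).exists():
                raise ValueError(f"{key} path does not exist: {val}")
    for f in config.features:
        repertoire_features.feature_spec(f)  # raises on unknown names


def _load_inputs(config: RunConfig):
    if config.simulate_preset is not None:
        cohort = synthetic.simulate_cohort(
            synthetic.preset_config(config.simulate_preset), seed=config.seed)
        germline = synthetic.make_germline(cohort.truth.config.germline_seed)
        # keep only raw sequences: the pipeline must re-derive annotations
        tables = [
            io_formats.RepertoireTable(t.subject_id, t.df[["sequence"]].copy())
            for t in cohort.repertoires
        ]
        return cohort.genotypes, tables, germline, cohort
    gm = io_formats.read_genotypes(config.genotypes, config.genotype_format)
    germline = io_formats.read_germline_fasta(config.germline)
    tables = [
        io_formats.read_airr(p)
        for p in sorted(Path(config.repertoire_dir).glob("*.tsv"))
    ]
    return gm, tables, germline, None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    try:
        log.info("run %s seed=%s", stamp["config_hash"], config.seed)

        gm, tables, germline, cohort = _load_inputs(config)
        log.info("inputs: %d subjects, %d SNPs, %d repertoires",
                 gm.n_subjects, gm.n_snps, len(tables))

        gm = io_formats.filter_snps(gm, config.min_maf)
        log.info("prepare: %d SNPs pass MAF > %s", gm.n_snps, config.min_maf)

        acfg = AnnotationConfig(min_read_len=config.min_read_len)
        needs_annotation = any("v_trim" not in t.df.columns for t in tables)
        if needs_annotation:
            tables = [annotate_repertoire(t, germline, acfg) for t in tables]
            log.info("annotate: done (%d tables)", len(tables))
        else:
            log.info("annotate: tables pre-annotated, skipped")

        pca = popstruct.genotype_pca(gm, k=config.n_pcs)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t",
                          float_format=FLOAT_FMT)

        condensed = {}
        kept = {}
        for productivity in config.productivities:
            kept[productivity] = io_formats.filter_repertoires(
                tables, productivity, config.repertoire_log10_min)
            log.info("filter: %d/%d subjects pass %s size cut",
                     len(kept[productivity]), len(tables), productivity)
        spec = association.ModelSpec(
            n_pcs=config.n_pcs, bootstrap_trigger=config.bootstrap_trigger,
            bootstrap_reps=config.bootstrap_reps, seed=config.seed)
        models = dict(config.models)
        for feature in config.features:
            fspec = repertoire_features.feature_spec(feature)
            model = models.get(feature, fspec.default_model)
            models[feature] = model
            for productivity in config.productivities:
                if model == "simple":
                    tab = repertoire_features.condense_simple(
                        kept[productivity], feature, productivity)
                else:
                    tab = repertoire_features.condense_by_gene_group(
                        kept[productivity], feature, productivity)
                condensed[(feature, productivity)] = tab
                tab.to_csv(out / f"condensed.{feature.replace(':', '_')}"
                                 f".{productivity}.tsv",
                           sep="\t", index=False, float_format=FLOAT_FMT)

        results = association.genome_scan(
            gm, condensed, pcs=pca, spec=spec, models=models)
        results.to_csv(out / "associations.tsv", sep="\t", index=False,
                       float_format=FLOAT_FMT)
        log.info("scan: %d fits", len(results))

        if config.loci:
            signals = {}
            for name, span in config.loci.items():
                chrom, rest = span.split(":")
                start, end = (int(x) for x in rest.split("-"))
                locus_snps = popstruct.snps_near_locus(
                    gm, chrom, start, end, config.locus_window)
                if not locus_snps:
                    continue
                for (feature, productivity), tab in condensed.items():
                    kind = repertoire_features.feature_spec(feature).kind
                    n_sub = sum(
                        1 for f in config.features
                        if repertoire_features.feature_spec(f).kind == kind)
                    threshold = popstruct.bonferroni_threshold(
                        config.alpha, n_sub, len(config.productivities),
                        len(locus_snps))
                    lspec = dataclasses.replace(spec, model=models[feature])
                    hits = association.conditional_scan(
                        gm, locus_snps, tab, pca, lspec, threshold)
                    signals[f"{name}|{feature}|{productivity}"] = hits
            (out / "independent_signals.json").write_text(
                json.dumps(signals, indent=1, sort_keys=True))
            log.info("conditional: %d locus/feature cells", len(signals))

        diagnostics = {"stamp": stamp, "lambda": {}, "thresholds": {}}
        for (feature, productivity), _ in condensed.items():
            sub = results[(results["feature"] == feature)
                          & (results["productivity"] == productivity)
                          & (results["flag"] == "ok")]
            if len(sub) >= 100:
                rep = popstruct.genomic_inflation(
                    sub["t"], mode="all", threshold=config.lambda_threshold,
                    seed=config.seed)
                diagnostics["lambda"][f"{feature}|{productivity}"] = {
                    "lambda": rep.lam, "n": rep.n_statistics,
                    "pass": rep.passed,
                }
        n_subtypes = {"usage": 0, "trim": 0, "insertion": 0}
        for feature in config.features:
            kind = repertoire_features.feature_spec(feature).kind
            if kind in ("trim",):
                n_subtypes["trim"] += 1
            elif kind == "insertion":
                n_subtypes["insertion"] += 1
            elif kind == "usage":
                n_subtypes["usage"] += 1
        for kind, n in n_subtypes.items():
            if n:
                diagnostics["thresholds"][kind] = popstruct.bonferroni_threshold(
                    config.alpha, n, len(config.productivities), gm.n_snps)
        (out / "diagnostics.json").write_text(
            json.dumps(diagnostics, indent=1, sort_keys=True))
        if cohort is not None:
            cohort.truth.to_json(out / "truth.json")
            cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        log.info("done in %.1f s", time.time() - t0)
    except Exception:
        log.exception("pipeline stage failed; partial outputs kept in %s", out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
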