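"""Configuration, validation and stage orchestration.

A single YAML config drives the pipeline: a ``simulate`` section (or
``inputs`` paths to existing files), a ``stages`` list, global
``thresholds`` and a ``seed``.  Stages run in dependency order and every
output TSV plus a ``manifest.json`` (config, seed, package version,
per-stage wall time and record counts) lands in the output directory,
so re-running an identical config and seed reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, microenv as me, xqtl as xq
from .enrichment import go_enrichment, map_variants_to_genes, study_overlap
from .gwa import classify_effects, derive_phenotypes, effect_correlations, scan_phenotypes
from .quantgen.report import panel_report
from .simulate import (
    AipCohortSpec,
    PanelDesign,
    TrueComponents,
    pool_select_and_sequence,
    simulate_aip_cohort,
    simulate_founder_genotypes,
    simulate_lifespan_panel,
)

log = logging.getLogger("ctxlife")

ALL_STAGES = ("simulate", "quantgen", "microenv", "gwa", "xqtl", "enrich", "overlap")

DEFAULT_THRESHOLDS = {
    "maf_min": 0.05,
    "dgrp_report_p": 1e-5,
    "xqtl_report_p": 1e-7,
    "n_perm": 10_000,
    "gene_window_bp": 1000,
}


@dataclasses.dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    seed: int = 0
    output_dir: str = "ctxlife_out"
    stages: tuple = ("simulate", "quantgen", "microenv")
    thresholds: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    gwa: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds)
        for k in ("maf_min", "dgrp_report_p", "xqtl_report_p"):
            if not 0 < th[k] < 1:
                raise ValueError(f"threshold {k} must be in (0, 1)")
        self.thresholds = th
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(config: RunConfig) -> dict:
    """Schema-check every configured input file.

    Returns ``{"errors": [...], "warnings": [...]}``; hard errors mean
    the pipeline refuses to run.
    """
    errors, warnings_ = [], []
    paths = config.inputs or {}
    readers = {
        "lifespan": io.read_lifespan_tsv,
        "pooled_counts": io.read_pooled_counts_tsv,
        "covariates": io.read_covariates_tsv,
        "go_annotations": io.read_go_annotations,
    }
    for kind, path in paths.items():
        if kind == "gene_lists":
            continue
        if not Path(path).exists():
            errors.append(f"{kind}: file not found: {path}")
            continue
        try:
            if kind in readers:
                readers[kind](path)
            elif kind == "genotypes":
                if str(path).endswith(".vcf"):
                    io.read_vcf_genotypes(path)
                else:
                    io.read_genotype_matrix_tsv(path)
            elif kind == "gene_models":
                if str(path).endswith((".gff", ".gff3")):
                    io.read_gff3_genes(path)
                else:
                    io.read_bed_genes(path)
            else:
                warnings_.append(f"unknown input kind {kind!r} ignored")
        except io.ValidationError as e:
            errors.extend(f"{kind}: {msg}" for msg in e.errors)
        except Exception as e:  # malformed beyond schema level
            errors.append(f"{kind}: {e}")
    needs = {
        "quantgen": ["lifespan"], "microenv": ["lifespan"],
        "gwa": ["lifespan", "genotypes"], "xqtl": ["pooled_counts"],
        "enrich": ["go_annotations", "gene_models"],
    }
    simulated = "simulate" in config.stages
    for stage in config.stages:
        for kind in needs.get(stage, []):
            if kind not in paths and not (
                simulated and kind in ("lifespan", "pooled_counts")
            ):
                errors.append(f"stage {stage!r} needs input {kind!r}")
    return {"errors": errors, "warnings": warnings_}


def _write(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ctxlife {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    report = validate_inputs(config)
    if report["errors"]:
        raise io.ValidationError(report["errors"])
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    th = config.thresholds
    manifest = {
        "version": __version__, "seed": seed, "config": config.to_dict(),
        "stages": {},
    }

    lifespan = counts = None
    if "lifespan" in (config.inputs or {}):
        lifespan = io.read_lifespan_tsv(config.inputs["lifespan"])
    if "pooled_counts" in (config.inputs or {}):
        counts = io.read_pooled_counts_tsv(config.inputs["pooled_counts"])

    def stage(name):
        return name in config.stages

    def record(name, t0, **info):
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3), **info}
        log.info("stage %s done in %.2fs %s", name, time.time() - t0, info)

    if stage("simulate"):
        t0 = time.time()
        sim = config.simulate or {}
        pd_kw = sim.get("panel", {})
        design = PanelDesign(**{k: v for k, v in pd_kw.items() if k != "components"})
        comp = TrueComponents(**pd_kw.get("components", {}))
        lifespan = simulate_lifespan_panel(design, comp, seed)
        io.write_lifespan_tsv(lifespan, out / "lifespan.tsv", seed=seed)
        n_counts = 0
        if "aip" in sim:
            aip_kw = dict(sim["aip"])
            panel = simulate_founder_genotypes(
                n_founders=aip_kw.pop("n_founders", 40),
                n_variants=aip_kw.pop("n_variants", 500),
                seed=seed + 1,
            )
            spec = AipCohortSpec(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in aip_kw.items()
            })
            cohort = simulate_aip_cohort(panel, spec, seed + 2)
            counts = pool_select_and_sequence(cohort, seed + 3)
            io.write_pooled_counts_tsv(counts, out / "pooled_counts.tsv", seed=seed)
            n_counts = len(counts)
        record("simulate", t0, lifespan_records=len(lifespan), pooled_count_rows=n_counts)

    if stage("quantgen"):
        t0 = time.time()
        tables = panel_report(lifespan)
        for name, df in tables.items():
            _write(df, out / f"{name}.tsv", seed)
        record("quantgen", t0, lines=lifespan["line"].nunique())

    micro = None
    if stage("microenv"):
        t0 = time.time()
        split = me.split_replicate_groups(lifespan)
        micro = me.ln_sigma_eps(split)
        _write(micro, out / "microenv.tsv", seed)
        bf = me.brown_forsythe_by_context(lifespan)
        cc = me.cochran_c_by_context(lifespan)
        _write(bf, out / "varhet_brown_forsythe.tsv", seed)
        _write(cc, out / "varhet_cochran_c.tsv", seed)
        if micro["line"].nunique() >= 2:
            tables = panel_report(micro, response="ln_sigma_eps", vial_terms=False)
            for name, df in tables.items():
                _write(df, out / f"microenv_{name}.tsv", seed)
        record("microenv", t0, groups=len(micro))

    if stage("gwa"):
        t0 = time.time()
        gpath = str(config.inputs["genotypes"])
        geno = (
            io.read_vcf_genotypes(gpath) if gpath.endswith(".vcf")
            else io.read_genotype_matrix_tsv(gpath)
        )
        cov = (
            io.read_covariates_tsv(config.inputs["covariates"])
            if "covariates" in config.inputs else None
        )
        phenos = derive_phenotypes(lifespan)
        wanted = config.gwa.get("phenotypes")
        if wanted:
            phenos = phenos[wanted]
        scans = scan_phenotypes(
            phenos, geno, cov, maf_min=th["maf_min"], report_p=th["dgrp_report_p"],
            n_pcs=int(config.gwa.get("n_pcs", 0)),
        )
        long = pd.concat(
            [s.assign(phenotype=name) for name, s in scans.items()], ignore_index=True
        )
        _write(long, out / "gwa_scan.tsv", seed)
        _write(
            classify_effects(scans, p_threshold=th["dgrp_report_p"]),
            out / "gwa_classification.tsv", seed,
        )
        effect_correlations(scans).to_csv(out / "gwa_effect_correlations.tsv", sep="\t")
        record("gwa", t0, phenotypes=len(scans), variants=len(geno.meta))

    within = None
    if stage("xqtl"):
        t0 = time.time()
        within = xq.z_test_hc(counts, report_p=th["xqtl_report_p"])
        _write(within, out / "xqtl_within.tsv", seed)
        cross = xq.cross_context_contrasts(within, report_p=th["xqtl_report_p"])
        _write(cross, out / "xqtl_cross.tsv", seed)
        summ = xq.antagonism_summary(within, p_threshold=th["xqtl_report_p"])
        _write(summ["variants"], out / "xqtl_variant_classes.tsv", seed)
        summ["delta_f_correlation"].to_csv(out / "xqtl_delta_f_correlation.tsv", sep="\t")
        record("xqtl", t0, variants=within["variant_id"].nunique())

    if stage("enrich"):
        t0 = time.time()
        gm_path = str(config.inputs["gene_models"])
        genes = (
            io.read_gff3_genes(gm_path) if gm_path.endswith((".gff", ".gff3"))
            else io.read_bed_genes(gm_path)
        )
        ann = io.read_go_annotations(config.inputs["go_annotations"])
        if within is not None:
            hits = within[within["significant"]]
            vmap = map_variants_to_genes(
                hits.rename(columns={"variant_id": "variant_id"}),
                genes, window_bp=int(th["gene_window_bp"]),
            )
            gene_set = sorted(set(vmap["gene_id"]))
        else:
            gene_set = sorted(set(ann["gene_id"]))[:0]
        if gene_set:
            res = go_enrichment(
                gene_set, genes.set_index("gene_id")["length"], ann,
                n_perm=int(th["n_perm"]), seed=seed,
            )
            _write(res, out / "enrichment.tsv", seed)
        record("enrich", t0, genes=len(gene_set))

    if stage("overlap"):
        t0 = time.time()
        lists = {
            name: list(pd.read_csv(p, sep="\t", header=None)[0])
            for name, p in (config.inputs.get("gene_lists") or {}).items()
        }
        res = study_overlap(lists)
        pd.Series(res["shared_genes"]).to_csv(
            out / "overlap_shared_genes.tsv", sep="\t", index=False, header=False
        )
        res["overlap_matrix"].to_csv(out / "overlap_matrix.tsv", sep="\t")
        record("overlap", t0, lists=len(lists))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
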