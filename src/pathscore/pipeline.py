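"""End-to-end orchestration: ingest -> QC -> map -> score -> (condition |
drop-gene) -> enrichment -> FDR -> report, with a reproducible run manifest.

``run_pipeline`` drives the stages from a :class:`RunConfig` (usually read
from YAML) and writes deterministic TSV tables plus a ``manifest.json``
recording the config snapshot, package version, per-stage counts, output
checksums and wall-clock. Two mutually exclusive perturbations of a
designated gene are supported, mirroring the two ways a dominant locus can
be interrogated: *conditioning* (downstream scores use the residual
phenotype after regressing status on the gene's SNPs) and *dropping* (the
gene is removed from the scored universe before enrichment).

``compare_runs`` cross-tabulates the reported pathways of several runs
sharing a pathway universe — the bookkeeping behind multi-cohort overlap
figures.
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

from . import __version__
from .annotation_and_qc import (
    QcThresholds,
    apply_qc,
    map_snps_to_genes,
    read_bed,
    read_gmt,
    read_phenotype,
    read_vcf,
)
from .enrichment import EnrichmentConfig, two_step_fdr
from .gene_scores import (
    PcaConfig,
    best_snp_score,
    condition_on_gene,
    pca_regression_score,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_runs"]

logger = logging.getLogger("pathscore")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Complete description of one pipeline run."""

    vcf: str
    phenotype: str
    bed: str
    gmt: str
    out_dir: str
    seed: int
    qc: QcThresholds = field(default_factory=QcThresholds)
    pca: PcaConfig = field(default_factory=PcaConfig)
    enrichment: EnrichmentConfig = None
    flank: int = 10_000
    score_method: str = "pca"  # "pca" | "bestsnp"
    enrich_method: str = "rs"  # "rs" | "bin"
    n_perm_bestsnp: int = 1000
    condition_gene: str = None
    drop_gene: str = None
    threads: int = 1

    def __post_init__(self):
        if self.enrichment is None:
            self.enrichment = EnrichmentConfig(seed=self.seed)
        if self.condition_gene and self.drop_gene:
            raise ValueError("condition_gene and drop_gene are mutually exclusive")
        if self.score_method not in ("pca", "bestsnp"):
            raise ValueError(f"unknown score method {self.score_method!r}")
        if self.enrich_method not in ("rs", "bin"):
            raise ValueError(f"unknown enrichment method {self.enrich_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("qc", QcThresholds), ("pca", PcaConfig),
                         ("enrichment", EnrichmentConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write result tables under ``cfg.out_dir``.

    Outputs: ``gene_scores.tsv``, ``enrichment.tsv`` (with ``ev_null``,
    ``fdr``, ``reported``), ``reported_pathways.tsv``, ``qc_log.tsv`` and
    ``manifest.json``. Returns a dict with the output paths and in-memory
    tables. Identical config + seed give byte-identical tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    tables = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                manifest["stages"].setdefault(name, {})
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                manifest["stages"].setdefault(name, {})["seconds"] = round(dt, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, "stage_failure", str(exc)) from exc
                return False

        return _Timer()

    with stage("ingest"):
        g = read_vcf(cfg.vcf)
        ph = read_phenotype(cfg.phenotype)
        genes = read_bed(cfg.bed, flank=cfg.flank)
        pathways = read_gmt(cfg.gmt)
        manifest["stages"]["ingest"].update(
            n_subjects=g.n_subjects, n_snps=g.n_snps,
            n_genes=len(genes), n_pathways=len(pathways),
        )

    with stage("qc"):
        g, subj_log, snp_log = apply_qc(g, cfg.qc)
        ph = ph.aligned_to(g.subject_ids)
        manifest["stages"]["qc"].update(
            n_subjects=g.n_subjects,
            n_snps=g.n_snps,
            subjects_removed=len(subj_log),
            snps_removed=len(snp_log),
        )
        logger.info(
            "qc: %d subjects, %d SNPs survive (%d subjects, %d SNPs removed)",
            g.n_subjects, g.n_snps, len(subj_log), len(snp_log),
        )
        qc_log = pd.concat(
            [
                subj_log.rename(columns={"subject_id": "item"}).assign(kind="subject"),
                snp_log.rename(columns={"snp_id": "item"}).assign(kind="snp"),
            ],
            ignore_index=True,
        )
        _write_tsv(qc_log[["kind", "item", "reason", "value"]], out / "qc_log.tsv")

    with stage("map"):
        snp_map = map_snps_to_genes(g, genes)
        manifest["stages"]["map"].update(
            n_mapped_genes=len(snp_map.genes()),
            n_unmapped_snps=len(snp_map.unmapped),
        )

    with stage("perturb"):
        if cfg.condition_gene:
            ph = condition_on_gene(g, cfg.condition_gene, snp_map, ph)
            manifest["stages"]["perturb"]["mode"] = f"condition:{cfg.condition_gene}"
        elif cfg.drop_gene:
            snp_map = type(snp_map)(
                assignments={(s, gn) for s, gn in snp_map.assignments
                             if gn != cfg.drop_gene},
                unmapped=snp_map.unmapped,
            )
            manifest["stages"]["perturb"]["mode"] = f"drop:{cfg.drop_gene}"
        else:
            manifest["stages"]["perturb"]["mode"] = "none"

    with stage("score"):
        if cfg.score_method == "pca":
            scores = pca_regression_score(g, snp_map, ph, cfg.pca)
        else:
            scores = best_snp_score(
                g, snp_map, ph, n_perm=cfg.n_perm_bestsnp, seed=cfg.seed
            )
        manifest["stages"]["score"].update(
            n_scored_genes=len(scores.genes), n_skipped=len(scores.skipped)
        )
        tables["gene_scores"] = scores.to_frame()
        _write_tsv(tables["gene_scores"], out / "gene_scores.tsv")

    with stage("enrich_fdr"):
        enr = two_step_fdr(
            pathways, g, snp_map, ph,
            method=cfg.enrich_method,
            score_method=cfg.score_method,
            cfg=cfg.enrichment,
            pca_cfg=cfg.pca,
            n_perm_inner=cfg.n_perm_bestsnp,
            threads=cfg.threads,
        )
        enr = enr.sort_values(
            ["p_value", "pathway"], kind="mergesort", ignore_index=True, na_position="last"
        )
        tables["enrichment"] = enr
        _write_tsv(enr, out / "enrichment.tsv")
        reported = enr[enr["reported"].fillna(False)].reset_index(drop=True)
        tables["reported"] = reported
        _write_tsv(reported, out / "reported_pathways.tsv")
        manifest["stages"]["enrich_fdr"].update(
            n_tested=int((~enr["untested"]).sum()),
            n_reported=int(len(reported)),
        )
        logger.info("enrichment: %d pathways reported at FDR < %g",
                    len(reported), cfg.enrichment.fdr_report_threshold)

    for name in ("qc_log.tsv", "gene_scores.tsv", "enrichment.tsv",
                 "reported_pathways.tsv"):
        manifest["outputs"][name] = _sha256(out / name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tables["manifest"] = manifest
    tables["out_dir"] = out
    return tables


def rerun_from_manifest(manifest_path) -> dict:
    """Re-execute a run from its manifest's config snapshot (the outputs are
    re-derivable from the manifest alone, given the original input files)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    raw = dict(raw)
    raw["qc"] = QcThresholds(**raw["qc"])
    raw["pca"] = PcaConfig(**raw["pca"])
    raw["enrichment"] = EnrichmentConfig(**raw["enrichment"])
    return run_pipeline(RunConfig(**raw))


def compare_runs(run_dirs, out_path=None) -> pd.DataFrame:
    """Presence matrix of reported pathways across completed runs.

    All runs must share the same pathway universe (the set of pathway
    names in ``enrichment.tsv``). The result has one row per pathway ever
    reported, one 0/1 column per run, plus an ``n_runs`` intersection
    count; the attribute ``.attrs['pairwise']`` holds the pairwise
    intersection-count matrix and ``.attrs['all_runs']`` the size of the
    full intersection.
    """
    run_dirs = [Path(d) for d in run_dirs]
    if len(run_dirs) < 2:
        raise ValueError("need at least two runs to compare")
    universes, reported = [], {}
    for d in run_dirs:
        enr = pd.read_csv(d / "enrichment.tsv", sep="\t")
        universes.append(frozenset(enr["pathway"]))
        rep = pd.read_csv(d / "reported_pathways.tsv", sep="\t")
        reported[d.name] = set(rep["pathway"]) if len(rep) else set()
    if len(set(universes)) != 1:
        raise ValueError("runs do not share a pathway universe")
    names = sorted(set().union(*reported.values()))
    run_names = [d.name for d in run_dirs]
    mat = pd.DataFrame(
        {rn: [int(p in reported[rn]) for p in names] for rn in run_names},
        index=pd.Index(names, name="pathway"),
    )
    mat["n_runs"] = mat[run_names].sum(axis=1)
    pair = pd.DataFrame(
        [[len(reported[a] & reported[b]) for b in run_names] for a in run_names],
        index=run_names, columns=run_names,
    )
    mat.attrs["pairwise"] = pair
    mat.attrs["all_runs"] = len(set.intersection(*reported.values())) if reported else 0
    if out_path is not None:
        mat.reset_index().to_csv(out_path, sep="\t", index=False)
    return mat
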