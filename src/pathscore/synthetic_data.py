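"""Synthetic GWAS fixtures: genotypes with LD blocks, a case-control
phenotype from a logistic disease model, gene models, and pathway sets.

The real cohorts this pipeline targets (Crohn's disease case-control GWAS)
are access-controlled, so every pipeline stage is exercised on simulated
data with the statistical structure the analysis assumes:

* Within each gene, SNP dosages are correlated (linkage disequilibrium),
  generated from a latent Gaussian AR(1) process thresholded at each SNP's
  minor-allele-frequency quantile; two independent haplotypes per subject
  sum to the dosage. Hardy-Weinberg equilibrium therefore holds by
  construction and the default fixtures pass the HWE filter.
* Disease status follows a logistic model over designated causal SNP
  dosages, with the intercept tuned by bisection to a target population
  prevalence; cases and controls are then sampled to exact quotas from a
  larger simulated pool (retrospective case-control design).
* Pathway sizes follow a log-normal law matched to a realistic curated
  annotation (median 28 genes, mean 47). One designated pathway collects
  all distributed-signal causal genes, one collects a single "hero" gene
  with a large effect, and the remainder are signal-free.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .annotation_and_qc import (
    GeneModel,
    GenotypeMatrix,
    PathwayCollection,
    Phenotype,
)

__all__ = [
    "SimulationScenario",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_pathways",
    "simulate_dataset",
    "write_fixture",
]

import pandas as pd


@dataclass
class SimulationScenario:
    """Everything needed to simulate one case-control study.

    ``causal_spec`` lists (gene_id, snp_index_within_gene, odds_ratio)
    triples for the distributed signal; ``hero_gene`` optionally names one
    gene whose first SNP receives ``hero_or``. Pathway sizes follow a
    log-normal law with the given median, with the dispersion chosen so
    the law's mean matches ``pathway_size_mean``.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 200
    snps_per_gene: tuple = (3, 10)  # inclusive range
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.7
    n_pathways: int = 30
    pathway_size_median: float = 28.0
    pathway_size_mean: float = 47.0
    causal_spec: list = field(default_factory=list)
    hero_gene: str = None
    hero_or: float = 2.5
    missing_rate: float = 0.01
    prevalence: float = 0.1
    n_overlapping_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_genes, self.n_pathways) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        for _, _, orr in self.causal_spec:
            if orr <= 0:
                raise ValueError("odds ratios must be positive")

    @property
    def size_sigma(self) -> float:
        """Log-normal dispersion implied by the median/mean pair."""
        ratio = self.pathway_size_mean / self.pathway_size_median
        if ratio <= 1.0:
            return 0.0
        return math.sqrt(2.0 * math.log(ratio))

    def all_effects(self) -> list:
        """causal_spec plus the hero gene's effect, if any."""
        eff = list(self.causal_spec)
        if self.hero_gene is not None:
            eff.append((self.hero_gene, 0, self.hero_or))
        return eff


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_GENE_SPAN = 20_000
_GENE_SPACING = 60_000  # > span + 2 * 10 kb flank: windows never overlap


def simulate_genotypes(sc: SimulationScenario, n_subjects: int = None, seed=None):
    """Simulate a dosage matrix and matching gene models.

    Per gene, haplotypes come from a latent Gaussian AR(1) process with
    correlation ``ld_rho`` between adjacent SNPs, thresholded at the
    normal quantile of each SNP's target MAF; the dosage is the sum of two
    independent haplotypes. Genes occupy non-overlapping windows on one
    synthetic chromosome, except for ``n_overlapping_pairs`` extra genes
    duplicated over existing windows to exercise many-to-many mapping.
    Missing calls are introduced completely at random at ``missing_rate``,
    and the matrix is coded on the empirical minor allele.
    """
    rng = np.random.default_rng(
        [int(sc.seed if seed is None else seed), 0x6E0]
    )
    n = n_subjects if n_subjects is not None else sc.n_cases + sc.n_controls
    lo, hi = sc.snps_per_gene
    n_snps_per_gene = rng.integers(lo, hi + 1, size=sc.n_genes)
    col_start = np.concatenate([[0], np.cumsum(n_snps_per_gene)])
    total_snps = int(col_start[-1])
    genes, snp_ids, meta_rows = [], [], []
    thresholds = np.empty(total_snps)
    for gi in range(sc.n_genes):
        gene_id = f"G{gi:04d}"
        s = int(n_snps_per_gene[gi])
        mafs = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=s)
        thresholds[col_start[gi] : col_start[gi + 1]] = stats.norm.ppf(mafs)
        start = gi * _GENE_SPACING + 50_000
        end = start + _GENE_SPAN - 1
        genes.append(GeneModel(gene_id, "1", start, end))
        positions = np.linspace(start, end, s).astype(int)
        for j in range(s):
            snp_ids.append(f"{gene_id}_snp{j}")
            meta_rows.append(("1", int(positions[j]), "A", "G"))
    # latent AR(1) haplotype draws, batched over genes with equal SNP counts;
    # blocks are generated contiguously and mapped back with one gather
    parts, part_cols = [], []
    for s in np.unique(n_snps_per_gene):
        s = int(s)
        which = np.flatnonzero(n_snps_per_gene == s)
        if sc.ld_rho > 0.0:
            C = sc.ld_rho ** np.abs(np.subtract.outer(np.arange(s), np.arange(s)))
            L = np.linalg.cholesky(C)
        else:
            L = np.eye(s)
        cols = np.concatenate(
            [np.arange(col_start[gi], col_start[gi + 1]) for gi in which]
        )
        thr = thresholds[cols]
        H = np.zeros((n, cols.size), dtype=np.uint8)
        for _hap in range(2):
            Z = rng.standard_normal((n, which.size, s)) @ L.T
            H += Z.reshape(n, -1) < thr
        parts.append(H)
        part_cols.append(cols)
    gen_cols = np.concatenate(part_cols)
    inv = np.empty(total_snps, dtype=np.intp)
    inv[gen_cols] = np.arange(total_snps)
    dosage = np.concatenate(parts, axis=1)[:, inv].astype(float)
    # optional second gene over an existing window: shares that gene's SNPs
    for k in range(sc.n_overlapping_pairs):
        host = genes[k % sc.n_genes]
        genes.append(
            GeneModel(f"OV{k:03d}", host.chromosome, host.start + _GENE_SPAN // 2,
                      host.end + _GENE_SPAN // 2)
        )
    if sc.missing_rate > 0.0:
        mask = rng.random(dosage.shape) < sc.missing_rate
        dosage[mask] = np.nan
    subject_ids = [f"S{i:05d}" for i in range(n)]
    meta = pd.DataFrame(meta_rows, index=snp_ids, columns=["chrom", "pos", "ref", "alt"])
    g = GenotypeMatrix(subject_ids, snp_ids, dosage, meta).recode_minor()
    return g, genes


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def _linear_predictor(g: GenotypeMatrix, effects) -> np.ndarray:
    """Sum of log-OR-weighted causal dosages (missing calls mean-imputed)."""
    eta = np.zeros(g.n_subjects)
    pos = {s: j for j, s in enumerate(g.snp_ids)}
    for gene_id, snp_index, orr in effects:
        sid = f"{gene_id}_snp{snp_index}"
        if sid not in pos:
            raise ValueError(f"causal SNP {sid!r} not present in genotypes")
        d = g.dosage[:, pos[sid]].copy()
        m = np.nanmean(d)
        d[np.isnan(d)] = m
        eta += math.log(orr) * d
    return eta


def simulate_phenotype(
    g: GenotypeMatrix, sc: SimulationScenario, seed=None, intercept: float = None
) -> Phenotype:
    """Draw case-control status from the logistic disease model.

    P(case) = logistic(b0 + sum log(OR_i) * dosage_i); ``b0`` is tuned by
    bisection so the mean case probability over the supplied subjects
    equals ``sc.prevalence`` (skipped when ``intercept`` is given). Cases
    and controls are then sampled, in subject order, to the exact
    ``n_cases``/``n_controls`` quotas; the returned phenotype covers just
    those subjects (use :func:`subset_to_phenotype` to cut the genotype
    matrix down to match). Raises if either quota cannot be met.
    """
    rng = np.random.default_rng([int(sc.seed if seed is None else seed), 0xBE7A])
    eta = _linear_predictor(g, sc.all_effects())
    if intercept is None:
        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            prev = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))))
            if prev < sc.prevalence:
                lo = mid
            else:
                hi = mid
        b0 = 0.5 * (lo + hi)
        prev = float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))
        if abs(prev - sc.prevalence) > 0.01:
            raise ValueError("unreachable prevalence for this effect configuration")
    else:
        b0 = intercept
    p_case = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    status = (rng.random(g.n_subjects) < p_case).astype(float)
    case_idx = np.flatnonzero(status == 1.0)
    ctrl_idx = np.flatnonzero(status == 0.0)
    if case_idx.size < sc.n_cases or ctrl_idx.size < sc.n_controls:
        raise ValueError(
            f"pool yields {case_idx.size} cases / {ctrl_idx.size} controls; "
            f"need {sc.n_cases}/{sc.n_controls} — enlarge the pool"
        )
    take = np.sort(np.concatenate([case_idx[: sc.n_cases], ctrl_idx[: sc.n_controls]]))
    ids = [g.subject_ids[i] for i in take]
    return Phenotype(ids, status[take], mode="binary")


def subset_to_phenotype(g: GenotypeMatrix, ph: Phenotype) -> GenotypeMatrix:
    """Restrict a genotype matrix to a phenotype's subjects (re-coding the
    minor allele for the new sample)."""
    pos = {s: i for i, s in enumerate(g.subject_ids)}
    idx = np.array([pos[s] for s in ph.subject_ids])
    return g.subset(subject_idx=idx, recode=True)


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------

def simulate_pathways(sc: SimulationScenario, gene_ids, seed=None):
    """Draw a pathway collection plus truth labels.

    Sizes come from the configured log-normal law (clipped to the number
    of available genes, with a warning implied by the clip). The first
    pathway gathers every distributed-signal causal gene (padded with null
    genes up to its drawn size), the second holds the hero gene plus null
    genes, and the rest are random sets of signal-free genes. Truth labels
    partition pathway names into ``distributed`` / ``hero`` / ``null``.
    """
    rng = np.random.default_rng([int(sc.seed if seed is None else seed), 0x9A7])
    gene_ids = list(gene_ids)
    causal_genes = sorted({gid for gid, _, _ in sc.causal_spec})
    signal_genes = set(causal_genes)
    if sc.hero_gene is not None:
        signal_genes.add(sc.hero_gene)
    null_pool = [g for g in gene_ids if g not in signal_genes]
    mu = math.log(sc.pathway_size_median)
    sizes = np.rint(rng.lognormal(mu, sc.size_sigma, size=sc.n_pathways)).astype(int)
    sizes = np.clip(sizes, 2, len(gene_ids))
    pathways, truth = {}, {"distributed": None, "hero": None, "null": []}
    next_size = iter(sizes)
    if causal_genes:
        size = max(next(next_size, len(causal_genes)), len(causal_genes))
        pad = min(size - len(causal_genes), len(null_pool))
        members = set(causal_genes) | set(rng.choice(null_pool, pad, replace=False))
        pathways["PW_DISTRIBUTED"] = members
        truth["distributed"] = "PW_DISTRIBUTED"
    if sc.hero_gene is not None:
        size = max(next(next_size, 2), 2)
        pad = min(size - 1, len(null_pool))
        members = {sc.hero_gene} | set(rng.choice(null_pool, pad, replace=False))
        pathways["PW_HERO"] = members
        truth["hero"] = "PW_HERO"
    for i, size in enumerate(next_size):
        name = f"PW{i:04d}"
        size = min(size, len(null_pool))
        pathways[name] = set(rng.choice(null_pool, size, replace=False))
        truth["null"].append(name)
    return PathwayCollection(pathways), truth


# ---------------------------------------------------------------------------
# Whole-dataset convenience and fixture writer
# ---------------------------------------------------------------------------

def simulate_dataset(sc: SimulationScenario, pool_factor: float = 1.3):
    """Simulate genotypes, phenotype, gene models, pathways and truth.

    A subject pool large enough to satisfy the case/control quotas at the
    target prevalence is simulated first; the returned genotype matrix is
    the sampled case-control subset. Returns
    ``(genotypes, phenotype, genes, pathways, truth)``.
    """
    need = max(
        sc.n_cases / sc.prevalence, sc.n_controls / (1.0 - sc.prevalence)
    )
    pool_n = int(math.ceil(need * pool_factor)) + 50
    g_pool, genes = simulate_genotypes(sc, n_subjects=pool_n)
    ph = simulate_phenotype(g_pool, sc)
    g = subset_to_phenotype(g_pool, ph)
    pathways, truth = simulate_pathways(sc, [gm.gene_id for gm in genes])
    return g, ph, genes, pathways, truth


def _vcf_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[d]


def write_fixture(out_dir, g: GenotypeMatrix, ph: Phenotype, genes, pathways, truth=None):
    """Write a dataset as VCF + BED + GMT + phenotype TSV (+ truth JSON).

    Files are plain text with deterministic ordering and round-trip
    bit-faithfully through the package readers: the VCF ALT allele is the
    coded (minor) allele, so re-reading reproduces the dosage matrix.
    Returns a dict of the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf_path = out / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.subject_ids) + "\n")
        order = np.lexsort((g.snp_meta["pos"].to_numpy(),
                            g.snp_meta["chrom"].to_numpy()))
        for j in order:
            row = g.snp_meta.iloc[j]
            gts = "\t".join(_vcf_gt(d) for d in g.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{g.snp_ids[j]}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    paths["vcf"] = vcf_path

    bed_path = out / "genes.bed"
    with open(bed_path, "w") as fh:
        for gm in sorted(genes, key=lambda x: (x.chromosome, x.start, x.gene_id)):
            fh.write(f"{gm.chromosome}\t{gm.start - 1}\t{gm.end}\t{gm.gene_id}\n")
    paths["bed"] = bed_path

    gmt_path = out / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for name in sorted(pathways.names):
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
    paths["gmt"] = gmt_path

    pheno_path = out / "phenotype.tsv"
    with open(pheno_path, "w") as fh:
        for sid, v in zip(ph.subject_ids, ph.values):
            val = f"{int(v)}" if ph.mode == "binary" else f"{v:.10g}"
            fh.write(f"{sid}\t{val}\n")
    paths["phenotype"] = pheno_path

    if truth is not None:
        truth_path = out / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["truth"] = truth_path
    return paths
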