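"""Genotype containers, QC filters, and SNP-to-gene annotation.

This module holds the data types shared by the whole pipeline (genotype
dosage matrix, gene models, SNP-gene map, pathway collection, phenotype)
together with the standard GWAS quality-control steps: per-SNP filters on
missingness, Hardy-Weinberg equilibrium and minor-allele frequency, a
per-subject missingness filter, and position-window assignment of SNPs to
genes.

Conventions
-----------
* Dosages count copies of the *minor* allele (empirical, per dataset) and
  live in {0, 1, 2}; missing calls are NaN.
* Genomic coordinates are 1-based and intervals are closed on both ends.
  BED input (0-based, half-open) is converted at the boundary.
* A SNP belongs to a gene when it falls inside the gene interval extended
  by a flank (default 10 kb) on both sides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "GeneModel",
    "SnpGeneMap",
    "PathwayCollection",
    "Phenotype",
    "hwe_test",
    "filter_subjects",
    "filter_snps",
    "map_snps_to_genes",
    "read_vcf",
    "read_bed",
    "read_gmt",
    "read_phenotype",
]


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    Parameters
    ----------
    subject_ids : list of str
        Unique subject identifiers (rows).
    snp_ids : list of str
        Unique SNP identifiers (columns).
    dosage : ndarray of float, shape (n_subjects, n_snps)
        Minor-allele counts in {0, 1, 2}; missing calls are ``nan``.
    snp_meta : DataFrame indexed by SNP id
        Columns ``chrom`` (str), ``pos`` (1-based int), ``ref``, ``alt``.
        ``alt`` is the coded (minor) allele.
    """

    subject_ids: list
    snp_ids: list
    dosage: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self):
        self.subject_ids = list(self.subject_ids)
        self.snp_ids = list(self.snp_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")
        d = self.dosage
        ok = (d == 0.0) | (d == 1.0) | (d == 2.0) | np.isnan(d)
        if not ok.all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        if list(self.snp_meta.index) != self.snp_ids:
            raise ValueError("snp_meta index must equal snp_ids, in order")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def minor_allele_freq(self) -> np.ndarray:
        """Empirical frequency of the coded allele per SNP (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def missing_rate_snps(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def missing_rate_subjects(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def recode_minor(self) -> "GenotypeMatrix":
        """Return a copy coded on the minor allele in the current sample.

        SNPs whose coded-allele frequency exceeds 0.5 are flipped (dosage
        ``2 - d``) and their ref/alt labels swapped. Exact ties at 0.5
        keep the current coding.
        """
        freq = self.minor_allele_freq()
        flip = freq > 0.5
        dosage = self.dosage.copy()
        dosage[:, flip] = 2.0 - dosage[:, flip]
        meta = self.snp_meta.copy()
        ref = meta["ref"].to_numpy().copy()
        alt = meta["alt"].to_numpy().copy()
        ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
        meta["ref"] = ref
        meta["alt"] = alt
        return GenotypeMatrix(self.subject_ids, self.snp_ids, dosage, meta)

    def subset(self, subject_idx=None, snp_idx=None, recode=True) -> "GenotypeMatrix":
        """Row/column subset; re-checks minor-allele coding by default."""
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        out = GenotypeMatrix(
            [self.subject_ids[i] for i in si],
            [self.snp_ids[j] for j in vi],
            self.dosage[np.ix_(si, vi)],
            self.snp_meta.iloc[vi],
        )
        return out.recode_minor() if recode else out


@dataclass
class QcThresholds:
    """QC cut-offs: SNPs need missing rate < ``max_snp_missing_rate``,
    HWE p > ``hwe_alpha`` and MAF > ``min_maf``; subjects with missing
    fraction > ``max_subject_missing_rate`` are dropped."""

    max_snp_missing_rate: float = 0.10
    hwe_alpha: float = 0.001
    min_maf: float = 0.01
    max_subject_missing_rate: float = 0.06

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{f.name} must lie in (0, 1), got {v}")


@dataclass
class GeneModel:
    """A gene interval (1-based, closed) with a flanking window in bp."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    flank: int = 10_000

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.flank < 0:
            raise ValueError(f"{self.gene_id}: flank must be >= 0")

    @property
    def window(self) -> tuple:
        """(low, high) closed window including the flank; low clipped at 1."""
        return (max(1, self.start - self.flank), self.end + self.flank)


@dataclass
class SnpGeneMap:
    """Many-to-many SNP <-> gene assignment."""

    assignments: set  # of (snp_id, gene_id)
    unmapped: list = field(default_factory=list)

    def genes(self) -> list:
        return sorted({g for _, g in self.assignments})

    def snps_for_gene(self, gene_id: str) -> list:
        return sorted({s for s, g in self.assignments if g == gene_id})

    def gene_to_snps(self) -> dict:
        out: dict = {}
        for s, g in self.assignments:
            out.setdefault(g, []).append(s)
        return {g: sorted(v) for g, v in sorted(out.items())}


@dataclass
class PathwayCollection:
    """Named gene sets; a gene may occur in more than one pathway."""

    pathways: dict  # pathway_name -> set of gene_ids

    def __post_init__(self):
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            self.pathways[name] = set(genes)

    @property
    def names(self) -> list:
        return list(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> set:
        return self.pathways[name]


@dataclass
class Phenotype:
    """Outcome vector: binary case/control status or continuous residuals."""

    subject_ids: list
    values: np.ndarray
    mode: str = "binary"  # "binary" | "residual"

    def __post_init__(self):
        self.subject_ids = list(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids),):
            raise ValueError("phenotype length does not match subject count")
        if self.mode == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary phenotype values must be 0 or 1")
            if len(np.unique(self.values)) < 2:
                raise ValueError("binary phenotype needs both classes present")
        elif self.mode == "residual":
            if self.values.std() == 0.0:
                raise ValueError("residual phenotype has zero variance")
        else:
            raise ValueError(f"unknown phenotype mode {self.mode!r}")

    def aligned_to(self, subject_ids) -> "Phenotype":
        """Reorder to a given subject order (subjects must match as a set)."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            idx = [pos[s] for s in subject_ids]
        except KeyError as e:
            raise ValueError(f"phenotype missing subject {e.args[0]!r}") from None
        return Phenotype(list(subject_ids), self.values[idx], self.mode)


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Pearson 1-df chi-square goodness-of-fit test of Hardy-Weinberg
    equilibrium, without continuity correction.

    Expected genotype counts come from the sample allele frequency.
    Returns 1.0 for a monomorphic SNP (the test is degenerate).
    """
    counts = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty genotype vector")
    q = (2 * counts[2] + counts[1]) / (2 * n)  # minor-allele frequency
    if q == 0.0 or q == 1.0:
        return 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-values per SNP column of a dosage matrix."""
    n0 = np.nansum(dosage == 0, axis=0).astype(float)
    n1 = np.nansum(dosage == 1, axis=0).astype(float)
    n2 = np.nansum(dosage == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (2 * n2 + n1) / (2 * n)
        e0 = n * (1 - q) ** 2
        e1 = n * 2 * q * (1 - q)
        e2 = n * q**2
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    p = stats.chi2.sf(chi2, df=1)
    degenerate = (q == 0.0) | (q == 1.0) | (n == 0)
    p = np.where(degenerate, 1.0, p)
    return p


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_subjects(g: GenotypeMatrix, t: QcThresholds = None):
    """Drop subjects whose missing fraction exceeds the threshold.

    Returns ``(filtered_matrix, removal_log)`` where the log is a DataFrame
    with columns ``subject_id``, ``reason``, ``value``. Minor-allele coding
    is re-checked after removal (allele frequencies shift with the sample).
    """
    t = t or QcThresholds()
    if g.n_subjects == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss = g.missing_rate_subjects()
    keep = miss <= t.max_subject_missing_rate
    if not keep.any():
        raise ValueError("no subjects survive QC")
    log = pd.DataFrame(
        {
            "subject_id": [s for s, k in zip(g.subject_ids, keep) if not k],
            "reason": "missing_rate",
            "value": miss[~keep],
        }
    )
    out = g.subset(subject_idx=np.flatnonzero(keep), recode=True)
    return out, log


def filter_snps(g: GenotypeMatrix, t: QcThresholds = None):
    """Keep SNPs with missing rate < threshold, HWE p > alpha, MAF > minimum.

    Returns ``(filtered_matrix, removal_log)``; the log assigns each removed
    SNP the first rule it failed, checking missingness, then HWE, then MAF.
    """
    t = t or QcThresholds()
    if g.n_subjects == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss = g.missing_rate_snps()
    hwe = _hwe_pvalues(g.dosage)
    maf = g.minor_allele_freq()
    maf = np.minimum(maf, 1.0 - maf)  # guard against non-minor coding
    maf = np.where(np.isnan(maf), 0.0, maf)

    fail_miss = ~(miss < t.max_snp_missing_rate)
    fail_hwe = ~(hwe > t.hwe_alpha)
    fail_maf = ~(maf > t.min_maf)

    reasons = []
    for j, sid in enumerate(g.snp_ids):
        if fail_miss[j]:
            reasons.append((sid, "missing_rate", miss[j]))
        elif fail_hwe[j]:
            reasons.append((sid, "hwe", hwe[j]))
        elif fail_maf[j]:
            reasons.append((sid, "maf", maf[j]))
    log = pd.DataFrame(reasons, columns=["snp_id", "reason", "value"])
    keep = ~(fail_miss | fail_hwe | fail_maf)
    out = g.subset(snp_idx=np.flatnonzero(keep), recode=True)
    return out, log


def apply_qc(g: GenotypeMatrix, t: QcThresholds = None):
    """Subject filter followed by SNP filter (SNP statistics are computed on
    the surviving subjects). Returns (matrix, subject_log, snp_log)."""
    t = t or QcThresholds()
    g1, subj_log = filter_subjects(g, t)
    g2, snp_log = filter_snps(g1, t)
    return g2, subj_log, snp_log


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

def map_snps_to_genes(g: GenotypeMatrix, genes) -> SnpGeneMap:
    """Assign each SNP to every gene whose flanked window contains it.

    The window is the closed interval ``[start - flank, end + flank]`` on the
    gene's chromosome. A SNP inside several (overlapping) windows is assigned
    to each; SNPs matching no window are reported in ``unmapped``.
    """
    chrom = g.snp_meta["chrom"].to_numpy()
    pos = g.snp_meta["pos"].to_numpy()
    snp_ids = np.asarray(g.snp_ids, dtype=object)
    assignments = set()
    mapped = np.zeros(len(snp_ids), dtype=bool)
    by_chrom: dict = {}
    for i, c in enumerate(chrom):
        by_chrom.setdefault(c, []).append(i)
    for gene in genes:
        idx = by_chrom.get(gene.chromosome)
        if idx is None:
            continue
        idx = np.asarray(idx)
        low, high = gene.window
        hit = idx[(pos[idx] >= low) & (pos[idx] <= high)]
        for i in hit:
            assignments.add((snp_ids[i], gene.gene_id))
        mapped[hit] = True
    unmapped = [s for s, m in zip(g.snp_ids, mapped) if not m]
    return SnpGeneMap(assignments=assignments, unmapped=unmapped)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic diploid SNPs from a VCF into a minor-allele dosage
    matrix. GT is converted to alt-allele counts, then re-coded so the coded
    allele is the minor allele in this sample."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    snp_ids, rows, meta = [], [], []
    seen = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{path}: site {v.CHROM}:{v.POS} is not biallelic")
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if sid in seen:
            raise ValueError(f"{path}: duplicate SNP identifier {sid!r}")
        seen.add(sid)
        snp_ids.append(sid)
        gt = v.gt_types.astype(float)  # 0/1/2 = alt count, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        meta.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if not snp_ids:
        raise ValueError(f"{path}: no variant records")
    dosage = np.column_stack(rows) if rows else np.empty((len(subjects), 0))
    snp_meta = pd.DataFrame(meta, index=snp_ids, columns=["chrom", "pos", "ref", "alt"])
    g = GenotypeMatrix(subjects, snp_ids, dosage, snp_meta)
    return g.recode_minor()


def read_bed(path, flank: int = 10_000):
    """Read gene models from BED (0-based half-open; column 4 = gene id),
    converting to the internal 1-based closed convention."""
    genes, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene identifier {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, chrom, start_i + 1, end_i, flank=flank))
    if not genes:
        raise ValueError(f"{path}: no gene records")
    return genes


def read_gmt(path) -> PathwayCollection:
    """Read a GMT pathway file: name <TAB> description <TAB> gene..."""
    pathways: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected name, description, >=1 gene")
            name, genes = parts[0], [x for x in parts[2:] if x]
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = set(genes)
    if not pathways:
        raise ValueError(f"{path}: no pathways")
    return PathwayCollection(pathways)


def read_phenotype(path) -> Phenotype:
    """Read a headerless two-column table: subject id, then status.

    Values restricted to {0,1} give a binary phenotype; anything else is
    treated as a continuous residual phenotype.
    """
    ids, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                v = float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric status {parts[1]!r}") from None
            if parts[0] in ids:
                raise ValueError(f"{path}:{lineno}: duplicate subject {parts[0]!r}")
            ids.append(parts[0])
            vals.append(v)
    if not ids:
        raise ValueError(f"{path}: empty phenotype file")
    values = np.asarray(vals)
    mode = "binary" if np.isin(values, (0.0, 1.0)).all() else "residual"
    return Phenotype(ids, values, mode)
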