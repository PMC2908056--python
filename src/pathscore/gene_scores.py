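"""Gene-level association scores.

Two gene scores are implemented, both producing one p-value per gene:

* **PCA regression** — principal components of the gene's SNP correlation
  matrix explaining at least ``variance_threshold`` (default 85%) of the
  variance are used as regressors; the gene score is the overall F-test
  p-value of the component model against the intercept-only model.
* **Best SNP** — the minimum per-SNP regression p-value within the gene,
  standardised for the number and correlation of SNPs by permuting the
  phenotype (add-one estimator, so the score is never exactly zero).

Also here: conditioning the phenotype on a designated gene (regress the
status on all of that gene's SNP dosages and keep the residuals), and a
pathway-level variant of the PCA score run on the pooled SNPs of all genes
in a pathway.

Both binary status and continuous residual phenotypes go through the same
ordinary-least-squares machinery, which keeps conditioned and unconditioned
analyses directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_and_qc import GenotypeMatrix, Phenotype, SnpGeneMap

__all__ = [
    "PcaConfig",
    "GeneScoreTable",
    "pca_regression_score",
    "best_snp_score",
    "condition_on_gene",
    "pathway_pca_score",
]


@dataclass
class PcaConfig:
    """Retention rule for gene PCA: keep the smallest number of leading
    components whose cumulative eigenvalue fraction reaches
    ``variance_threshold``, never more than min(n_snps, n_subjects - 2)."""

    variance_threshold: float = 0.85

    def __post_init__(self):
        if not (0.0 < self.variance_threshold <= 1.0):
            raise ValueError("variance_threshold must lie in (0, 1]")


@dataclass
class GeneScoreTable:
    """Per-gene association p-values for one scoring method."""

    method: str  # "pca_regression" | "best_snp"
    entries: dict  # gene_id -> p-value in (0, 1]
    n_snps_used: dict = field(default_factory=dict)
    k_components: dict = field(default_factory=dict)  # pca only
    cum_var: dict = field(default_factory=dict)  # pca only
    skipped: list = field(default_factory=list)  # genes with no usable SNP

    def __post_init__(self):
        for gene, p in self.entries.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"gene {gene!r}: p-value {p} outside (0, 1]")

    @property
    def genes(self) -> list:
        return list(self.entries)

    def pvalues(self, genes=None) -> np.ndarray:
        genes = self.genes if genes is None else genes
        return np.array([self.entries[g] for g in genes])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, p in self.entries.items():
            rows.append(
                (
                    g,
                    self.method,
                    p,
                    self.n_snps_used.get(g, np.nan),
                    self.k_components.get(g, np.nan),
                    self.cum_var.get(g, np.nan),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "method", "p_value", "n_snps", "k_components", "cum_var"],
        ).sort_values("gene_id", kind="mergesort", ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneScoreTable":
        method = frame["method"].iloc[0] if len(frame) else "pca_regression"
        return cls(
            method=method,
            entries=dict(zip(frame["gene_id"], frame["p_value"])),
            n_snps_used=dict(zip(frame["gene_id"], frame["n_snps"])),
            k_components=dict(zip(frame["gene_id"], frame["k_components"])),
            cum_var=dict(zip(frame["gene_id"], frame["cum_var"])),
        )


# ---------------------------------------------------------------------------
# Shared numerics
# ---------------------------------------------------------------------------

def _impute_and_clean(dosage: np.ndarray):
    """Mean-impute missing entries per SNP column and drop columns that are
    monomorphic in the analysis sample. Returns (X, kept_column_indices)."""
    X = np.array(dosage, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0.0)
    return X[:, keep], keep


def _gene_components(X: np.ndarray, variance_threshold: float, max_k: int):
    """PCA of the SNP correlation matrix.

    Columns of ``X`` are standardised; the correlation-matrix eigenvectors
    give component loadings. Returns (scores, k, cumulative variance
    fraction). Component sign is fixed by making the largest-magnitude
    loading positive so repeated runs agree exactly.
    """
    n, m = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    corr = (Xs.T @ Xs) / n
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    frac = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    k = min(k, max_k, m)
    # numerically null dimensions carry no signal; never retain them
    positive = max(int((evals > 1e-10).sum()), 1)
    k = min(k, positive)
    V = evecs[:, :k].copy()
    top = np.argmax(np.abs(V), axis=0)
    sign = np.sign(V[top, np.arange(k)])
    sign[sign == 0] = 1.0
    V *= sign
    scores = Xs @ V
    return scores, k, float(frac[k - 1])


def _ols_f_pvalue(y: np.ndarray, C: np.ndarray) -> float:
    """Overall F-test p-value of OLS of ``y`` on columns of ``C`` plus an
    intercept, against the intercept-only model."""
    n = y.shape[0]
    yc = y - y.mean()
    ssy = float(yc @ yc)
    if ssy <= 0.0:
        raise ValueError("phenotype has zero variance")
    Cc = C - C.mean(axis=0)
    Q, R = np.linalg.qr(Cc)
    diag = np.abs(np.diag(R))
    rank_keep = diag > (diag.max() * 1e-10 if diag.size else 0.0)
    Q = Q[:, rank_keep]
    k = Q.shape[1]
    if k == 0:
        raise ValueError("design collinear with intercept")
    df2 = n - k - 1
    if df2 <= 0:
        raise ValueError("too few subjects for the F test")
    proj = Q.T @ yc
    ssr = float(proj @ proj)
    r2 = min(ssr / ssy, 1.0)
    if r2 >= 1.0:
        return float(np.finfo(float).tiny)
    f = (r2 / k) / ((1.0 - r2) / df2)
    return float(stats.f.sf(f, k, df2))


def _gene_submatrix(g: GenotypeMatrix, snp_ids):
    pos = {s: j for j, s in enumerate(g.snp_ids)}
    idx = [pos[s] for s in snp_ids if s in pos]
    return g.dosage[:, idx]


# ---------------------------------------------------------------------------
# PCA regression score
# ---------------------------------------------------------------------------

def pca_regression_score(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    ph: Phenotype,
    cfg: PcaConfig = None,
) -> GeneScoreTable:
    """Score every mapped gene by PCA regression.

    Per gene: extract the dosage submatrix, mean-impute missing calls, drop
    monomorphic SNPs, eigendecompose the SNP correlation matrix, keep the
    leading components reaching the variance threshold, and regress the
    phenotype on them. The gene score is the overall F-test p-value.
    Genes left with no polymorphic SNP are omitted and listed in
    ``skipped``.
    """
    cfg = cfg or PcaConfig()
    if g.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    ph = ph.aligned_to(g.subject_ids)
    y = ph.values
    entries, n_used, k_comp, cum_var, skipped = {}, {}, {}, {}, []
    for gene, snps in snp_map.gene_to_snps().items():
        X, kept = _impute_and_clean(_gene_submatrix(g, snps))
        if kept.size == 0:
            skipped.append(gene)
            continue
        max_k = min(X.shape[1], g.n_subjects - 2)
        scores, k, cv = _gene_components(X, cfg.variance_threshold, max_k)
        try:
            p = _ols_f_pvalue(y, scores)
        except ValueError as e:
            raise ValueError(f"gene {gene!r}: {e}") from None
        entries[gene] = p
        n_used[gene] = int(kept.size)
        k_comp[gene] = k
        cum_var[gene] = cv
    return GeneScoreTable(
        method="pca_regression",
        entries=entries,
        n_snps_used=n_used,
        k_components=k_comp,
        cum_var=cum_var,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Best-SNP score with permutation standardisation
# ---------------------------------------------------------------------------

def _abs_corr(Xu: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| between each unit-norm centred column of Xu and y."""
    yc = y - y.mean()
    norm = np.sqrt(yc @ yc)
    return np.abs(Xu.T @ yc) / norm


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of the OLS slope t-test, from |r| (identical ordering)."""
    r = np.clip(r, 0.0, 1.0 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(t, df=n - 2)


def permutation_indices(n: int, n_perm: int, seed: int) -> np.ndarray:
    """The shared phenotype-permutation stream: (n_perm, n) index rows."""
    rng = np.random.default_rng([int(seed), 0x5EED])
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def best_snp_score(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    ph: Phenotype,
    n_perm: int = 1000,
    seed: int = 0,
    perm_idx: np.ndarray = None,
) -> GeneScoreTable:
    """Best-SNP gene score, standardised by phenotype permutation.

    The raw statistic is the smallest per-SNP regression p-value in the
    gene; the score is ``(1 + r) / (n_perm + 1)`` where ``r`` counts
    permutations of the phenotype whose within-gene minimum p is at least
    as small. One permutation stream is generated per phenotype and shared
    by all genes, which preserves between-gene score correlation.

    Because a permutation comparison only uses the ordering of the per-SNP
    statistic, the score is invariant to any monotone transformation of it;
    internally |r| is compared, which orders identically to the p-value.
    """
    if n_perm < 100 and perm_idx is None:
        raise ValueError("n_perm must be >= 100")
    ph = ph.aligned_to(g.subject_ids)
    y = ph.values
    n = y.shape[0]
    if perm_idx is None:
        perm_idx = permutation_indices(n, n_perm, seed)
    B = perm_idx.shape[0]
    Yp = y[perm_idx]  # (B, n)
    Ypc = Yp - Yp.mean(axis=1, keepdims=True)
    Ypc /= np.sqrt((Ypc**2).sum(axis=1, keepdims=True))
    entries, n_used, raw = {}, {}, {}
    skipped = []
    for gene, snps in snp_map.gene_to_snps().items():
        X, kept = _impute_and_clean(_gene_submatrix(g, snps))
        if kept.size == 0:
            skipped.append(gene)
            continue
        Xc = X - X.mean(axis=0)
        Xu = Xc / np.sqrt((Xc**2).sum(axis=0))
        obs_r = _abs_corr(Xu, y).max()
        perm_r = np.abs(Ypc @ Xu).max(axis=1)  # (B,)
        exceed = int((perm_r >= obs_r - 1e-12).sum())
        entries[gene] = (1 + exceed) / (B + 1)
        n_used[gene] = int(kept.size)
        raw[gene] = float(_corr_pvalue(np.array([obs_r]), n)[0])
    tab = GeneScoreTable(
        method="best_snp", entries=entries, n_snps_used=n_used, skipped=skipped
    )
    tab.raw_min_p = raw
    return tab


# ---------------------------------------------------------------------------
# Conditioning on a gene
# ---------------------------------------------------------------------------

def condition_on_gene(
    g: GenotypeMatrix,
    target_gene: str,
    snp_map: SnpGeneMap,
    ph: Phenotype,
) -> Phenotype:
    """Regress the binary status on all of one gene's SNP dosages and return
    the residuals as a new (continuous) phenotype.

    The design uses raw mean-imputed dosages with an intercept;
    rank-deficient designs are resolved by the least-norm solution. This
    removes the target gene's linear contribution from every downstream
    score, mirroring a conditional association analysis on a known major
    gene such as IL23R in Crohn's disease.
    """
    if ph.mode != "binary":
        raise ValueError("conditioning expects a binary phenotype")
    snps = snp_map.snps_for_gene(target_gene)
    if not snps:
        raise ValueError(f"gene {target_gene!r} has no mapped SNPs")
    ph = ph.aligned_to(g.subject_ids)
    X, kept = _impute_and_clean(_gene_submatrix(g, snps))
    if kept.size == 0:
        raise ValueError(f"gene {target_gene!r} has no polymorphic SNPs")
    A = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(A, ph.values, rcond=None)
    resid = ph.values - A @ beta
    if resid.var() < 1e-12:
        raise ValueError("phenotype fully explained by conditioning gene")
    return Phenotype(g.subject_ids, resid, mode="residual")


# ---------------------------------------------------------------------------
# Pathway-level PCA score
# ---------------------------------------------------------------------------

def pathway_pca_score(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    pathway_genes,
    ph: Phenotype,
    cfg: PcaConfig = None,
) -> float:
    """PCA-regression p-value on the pooled SNPs of all genes in a pathway.

    SNPs shared by overlapping member genes enter once. Same recipe as the
    per-gene score: impute, drop monomorphic, eigendecompose the pooled
    correlation matrix, retain to the variance threshold, F-test.
    """
    cfg = cfg or PcaConfig()
    gene_map = snp_map.gene_to_snps()
    snps = sorted({s for gene in pathway_genes for s in gene_map.get(gene, [])})
    if not snps:
        raise ValueError("no scored genes in pathway")
    ph = ph.aligned_to(g.subject_ids)
    X, kept = _impute_and_clean(_gene_submatrix(g, snps))
    if kept.size == 0:
        raise ValueError("no polymorphic SNPs in pathway")
    max_k = min(X.shape[1], g.n_subjects - 2)
    scores, _, _ = _gene_components(X, cfg.variance_threshold, max_k)
    return _ols_f_pvalue(ph.values, scores)
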