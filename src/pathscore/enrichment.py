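"""Pathway enrichment tests and the two-step permutation FDR.

Two per-pathway tests operate on a table of gene scores (per-gene
p-values):

* **Random Set (RS)** — statistic ``-sum(ln p_i)`` over the pathway's
  scored genes, so each gene is weighted by its significance. The null is
  built from random same-size gene sets drawn without replacement from all
  scored genes: exhaustively when the number of subsets is small, by
  Monte-Carlo sampling with the add-one estimator otherwise.
* **BIN** — the binomial approximation to Fisher's exact test on the count
  of pathway genes with score below ``gene_sig_alpha`` (default 0.05),
  with the success probability estimated from the full scored-gene
  universe.

The false discovery rate is estimated by a nested two-step scheme: gene
scores are recomputed under permutations of the phenotype, pathway
p-values are recomputed for each permuted score set, and the expected
number of null pathways beating each observed p-value is averaged over
permutations. Dividing by the observed discovery count and enforcing
monotonicity (cumulative minimum from least to most significant) turns
that expectation into an empirical FDR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_and_qc import GenotypeMatrix, PathwayCollection, Phenotype, SnpGeneMap
from .gene_scores import (
    GeneScoreTable,
    PcaConfig,
    _abs_corr,
    _gene_components,
    _gene_submatrix,
    _impute_and_clean,
    _ols_f_pvalue,
    permutation_indices,
)

__all__ = [
    "EnrichmentConfig",
    "rs_statistic",
    "RandomSetNull",
    "rs_pvalue",
    "bin_test",
    "enrich_pathways",
    "two_step_fdr",
]


@dataclass
class EnrichmentConfig:
    """Knobs for the enrichment layer.

    ``n_perm_genes`` gene-score permutations build the RS null per pathway
    size; ``n_perm_pheno`` phenotype permutations drive the FDR; pathways
    with estimated FDR below ``fdr_report_threshold`` are reported. The RS
    null switches to exhaustive subset enumeration whenever C(N, m) does
    not exceed ``exhaustive_limit``.
    """

    gene_sig_alpha: float = 0.05
    n_perm_genes: int = 10_000
    n_perm_pheno: int = 1_000
    fdr_report_threshold: float = 0.01
    seed: int = 0
    exhaustive_limit: int = 5_000

    def __post_init__(self):
        for name in ("gene_sig_alpha", "fdr_report_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_perm_genes < 10 or self.n_perm_pheno < 10:
            raise ValueError("permutation counts must be >= 10")


# ---------------------------------------------------------------------------
# Random Set test
# ---------------------------------------------------------------------------

def rs_statistic(pathway_scores) -> float:
    """Random Set enrichment statistic: minus the sum of natural-log
    gene p-values. Large values mean many small scores in the pathway."""
    p = np.asarray(list(pathway_scores), dtype=float)
    if p.size == 0:
        raise ValueError("no scored genes in pathway")
    if (p <= 0.0).any() or (p > 1.0).any():
        raise ValueError("gene scores must lie in (0, 1]")
    return float(-np.log(p).sum())


class RandomSetNull:
    """Shared null-draw machinery for the RS test over one score table.

    Subset index draws depend only on (number of scored genes, pathway
    size, seed), so pathways of the same size reuse the same draws and the
    result does not depend on the order pathways are tested in. The same
    index draws can be re-applied to permuted score vectors, which is what
    the FDR layer does.
    """

    def __init__(self, scores: GeneScoreTable, cfg: EnrichmentConfig):
        self.cfg = cfg
        self.gene_ids = list(scores.genes)
        self.gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self.logp = -np.log(scores.pvalues(self.gene_ids))
        self._draws: dict = {}  # m -> (n_draws, m) index matrix, or None for exhaustive

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def _subset_indices(self, m: int):
        """Index draws for size m; None signals exhaustive enumeration."""
        if m not in self._draws:
            n_subsets = math.comb(self.n_genes, m)
            if n_subsets <= self.cfg.exhaustive_limit:
                self._draws[m] = None
            else:
                rng = np.random.default_rng([int(self.cfg.seed), 0xA11E, m])
                N, B = self.n_genes, self.cfg.n_perm_genes
                out = np.empty((B, m), dtype=np.intp)
                chunk = max(1, min(B, 64_000_000 // max(N, 1) // 8))
                for lo in range(0, B, chunk):
                    hi = min(lo + chunk, B)
                    u = rng.random((hi - lo, N))
                    out[lo:hi] = np.argpartition(u, m - 1, axis=1)[:, :m]
                self._draws[m] = out
        return self._draws[m]

    def pvalue_from_logp(self, logp: np.ndarray, member_idx: np.ndarray) -> float:
        """RS permutation p-value for one pathway given a -log(p) vector."""
        m = member_idx.size
        if m == 0:
            raise ValueError("no scored genes in pathway")
        if m > self.n_genes:
            raise ValueError("pathway larger than the scored gene universe")
        draws = self._subset_indices(m)
        obs = float(logp[np.sort(member_idx)].sum())
        if draws is None:
            count = 0
            total = 0
            for combo in itertools.combinations(range(self.n_genes), m):
                total += 1
                if logp[list(combo)].sum() >= obs:
                    count += 1
            return count / total
        stat = logp[draws].sum(axis=1)
        exceed = int((stat >= obs).sum())
        return (1 + exceed) / (draws.shape[0] + 1)

    def member_indices(self, pathway_genes) -> np.ndarray:
        return np.array(
            sorted(self.gene_pos[g] for g in pathway_genes if g in self.gene_pos),
            dtype=np.intp,
        )

    def pvalue(self, pathway_genes) -> float:
        return self.pvalue_from_logp(self.logp, self.member_indices(pathway_genes))


def rs_pvalue(pathway_genes, scores: GeneScoreTable, cfg: EnrichmentConfig = None) -> float:
    """Random Set p-value of one pathway against random same-size gene sets.

    Null sets are drawn without replacement from all scored genes. When the
    subset space is small (``C(N, m) <= cfg.exhaustive_limit``) the null is
    enumerated exactly and the p-value is the tail fraction of all subsets;
    otherwise ``cfg.n_perm_genes`` Monte-Carlo draws are used with the
    add-one estimator ``(1 + r) / (B + 1)``, which never returns 0.
    Pathway genes without a score are ignored.
    """
    cfg = cfg or EnrichmentConfig()
    null = RandomSetNull(scores, cfg)
    idx = null.member_indices(pathway_genes)
    if idx.size == 0:
        raise ValueError("no scored genes in pathway")
    return null.pvalue_from_logp(null.logp, idx)


# ---------------------------------------------------------------------------
# Binomial test
# ---------------------------------------------------------------------------

def _bin_tail(x: int, m: int, pi0: float) -> float:
    if x <= 0:
        return 1.0
    return float(stats.binom.sf(x - 1, m, pi0))


def bin_test(pathway_genes, scores: GeneScoreTable, cfg: EnrichmentConfig = None) -> float:
    """Binomial over-representation test (approximation to Fisher's exact).

    ``x`` pathway genes score below ``gene_sig_alpha``; under the null each
    of the pathway's ``m`` scored genes is significant with probability
    ``pi0``, the significant fraction of the whole scored universe. Returns
    the upper tail P(X >= x) of Binomial(m, pi0); x = 0 gives 1.0.
    """
    cfg = cfg or EnrichmentConfig()
    member = [g for g in pathway_genes if g in scores.entries]
    if not member:
        raise ValueError("no scored genes in pathway")
    allp = scores.pvalues()
    pi0 = float((allp < cfg.gene_sig_alpha).mean())
    x = int((scores.pvalues(member) < cfg.gene_sig_alpha).sum())
    return _bin_tail(x, len(member), pi0)


# ---------------------------------------------------------------------------
# Observed enrichment table
# ---------------------------------------------------------------------------

def enrich_pathways(
    pathways: PathwayCollection,
    scores: GeneScoreTable,
    method: str = "rs",
    cfg: EnrichmentConfig = None,
) -> pd.DataFrame:
    """Per-pathway statistic and p-value for every pathway in a collection.

    Pathways with zero scored genes are kept in the table but flagged
    ``untested`` with NaN statistic and p-value.
    """
    cfg = cfg or EnrichmentConfig()
    if method not in ("rs", "bin"):
        raise ValueError(f"unknown enrichment method {method!r}")
    null = RandomSetNull(scores, cfg) if method == "rs" else None
    allp = scores.pvalues()
    pi0 = float((allp < cfg.gene_sig_alpha).mean()) if len(allp) else 0.0
    rows = []
    for name in pathways.names:
        genes = pathways[name]
        member = [g for g in genes if g in scores.entries]
        if not member:
            rows.append((name, len(genes), 0, np.nan, np.nan, True))
            continue
        ps = scores.pvalues(member)
        if method == "rs":
            stat = rs_statistic(ps)
            p = null.pvalue(member)
        else:
            stat = float((ps < cfg.gene_sig_alpha).sum())
            p = _bin_tail(int(stat), len(member), pi0)
        rows.append((name, len(genes), len(member), stat, p, False))
    return pd.DataFrame(
        rows,
        columns=["pathway", "n_genes", "n_scored", "statistic", "p_value", "untested"],
    )


# ---------------------------------------------------------------------------
# Two-step permutation FDR
# ---------------------------------------------------------------------------

class _FastScorer:
    """Recompute all gene scores for arbitrary phenotype vectors.

    The genotype side of each gene score is fixed under phenotype
    permutation, so per gene we precompute either the orthonormal basis of
    its retained principal components (PCA regression) or its unit-norm
    dosage columns plus the permutation null of max |r| (best SNP), and
    score any phenotype with a couple of matrix products.
    """

    def __init__(
        self,
        g: GenotypeMatrix,
        snp_map: SnpGeneMap,
        score_method: str = "pca",
        pca_cfg: PcaConfig = None,
        n_perm_inner: int = 1000,
        seed: int = 0,
    ):
        pca_cfg = pca_cfg or PcaConfig()
        self.method = score_method
        self.n = g.n_subjects
        self.genes: list = []
        self._bases: list = []
        gene_map = snp_map.gene_to_snps()
        for gene, snps in gene_map.items():
            X, kept = _impute_and_clean(_gene_submatrix(g, snps))
            if kept.size == 0:
                continue
            if score_method == "pca":
                max_k = min(X.shape[1], self.n - 2)
                scores, k, _ = _gene_components(X, pca_cfg.variance_threshold, max_k)
                Q, R = np.linalg.qr(scores - scores.mean(axis=0))
                diag = np.abs(np.diag(R))
                Q = Q[:, diag > diag.max() * 1e-10]
                self._bases.append(Q)
            else:
                Xc = X - X.mean(axis=0)
                Xu = Xc / np.sqrt((Xc**2).sum(axis=0))
                self._bases.append(Xu)
            self.genes.append(gene)
        if score_method == "bestsnp":
            self._inner_idx = permutation_indices(self.n, n_perm_inner, seed)
            self._inner_null = None

    def _prepare_bestsnp_null(self, y_template: np.ndarray):
        """Inner permutation null of max|r| per gene, built once; valid for
        any phenotype that is a permutation of ``y_template``."""
        Yp = y_template[self._inner_idx]
        Ypc = Yp - Yp.mean(axis=1, keepdims=True)
        Ypc /= np.sqrt((Ypc**2).sum(axis=1, keepdims=True))
        self._inner_null = [np.abs(Ypc @ Xu).max(axis=1) for Xu in self._bases]

    def score_vector(self, y: np.ndarray) -> np.ndarray:
        """Gene scores (aligned with ``self.genes``) for one phenotype."""
        yc = y - y.mean()
        ssy = float(yc @ yc)
        if self.method == "pca":
            n = self.n
            G = len(self.genes)
            r2 = np.empty(G)
            ks = np.empty(G)
            for i, Q in enumerate(self._bases):
                proj = Q.T @ yc
                r2[i] = min(float(proj @ proj) / ssy, 1.0)
                ks[i] = Q.shape[1]
            df2 = n - ks - 1
            with np.errstate(divide="ignore"):
                f = (r2 / ks) / ((1.0 - r2) / df2)
            out = stats.f.sf(f, ks, df2)
            out[r2 >= 1.0] = np.finfo(float).tiny
            return out
        out = np.empty(len(self.genes))
        B = self._inner_idx.shape[0]
        for i, Xu in enumerate(self._bases):
            obs = _abs_corr(Xu, y).max()
            exceed = int((self._inner_null[i] >= obs - 1e-12).sum())
            out[i] = (1 + exceed) / (B + 1)
        return out

    def table(self, y: np.ndarray, method_name: str) -> GeneScoreTable:
        vals = self.score_vector(y)
        return GeneScoreTable(method=method_name, entries=dict(zip(self.genes, vals)))


def _pathway_pvalues(
    member_idx: list,
    logp: np.ndarray,
    null: RandomSetNull,
    method: str,
    pvec: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Pathway p-values for one gene-score vector (shared by obs and perms)."""
    J = len(member_idx)
    out = np.full(J, np.nan)
    if method == "rs":
        for j in range(J):
            if member_idx[j].size:
                out[j] = null.pvalue_from_logp(logp, member_idx[j])
    else:
        pi0 = float((pvec < alpha).mean())
        for j in range(J):
            idx = member_idx[j]
            if idx.size:
                x = int((pvec[idx] < alpha).sum())
                out[j] = _bin_tail(x, idx.size, pi0)
    return out


def two_step_fdr(
    pathways: PathwayCollection,
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    ph: Phenotype,
    method: str = "rs",
    score_method: str = "pca",
    cfg: EnrichmentConfig = None,
    pca_cfg: PcaConfig = None,
    n_perm_inner: int = 1000,
    threads: int = 1,
) -> pd.DataFrame:
    """Nested-permutation FDR for pathway enrichment.

    Step one permutes the phenotype ``cfg.n_perm_pheno`` times and
    recomputes every gene score; step two recomputes every pathway p-value
    for each permuted score set (RS reuses one set of ``cfg.n_perm_genes``
    subset draws per pathway size). For each observed pathway p the
    expected null exceedance count ``ev_null`` averages, over phenotype
    permutations, the number of pathways with a strictly smaller p-value;
    ``fdr = min(1, ev_null / #observed discoveries at that level)`` with a
    cumulative-minimum pass from least to most significant to enforce
    monotonicity. Pathways with ``fdr < cfg.fdr_report_threshold`` are
    flagged ``reported``.

    Returns the observed enrichment table with ``ev_null``, ``fdr`` and
    ``reported`` columns appended. Deterministic for a fixed config seed,
    independent of ``threads``.
    """
    cfg = cfg or EnrichmentConfig()
    if cfg.n_perm_pheno < 10:
        raise ValueError("insufficient permutations for FDR")
    ph = ph.aligned_to(g.subject_ids)
    scorer = _FastScorer(
        g, snp_map, "pca" if score_method == "pca" else "bestsnp",
        pca_cfg, n_perm_inner=n_perm_inner, seed=cfg.seed,
    )
    if scorer.method == "bestsnp":
        scorer._prepare_bestsnp_null(ph.values)
    method_name = "pca_regression" if scorer.method == "pca" else "best_snp"
    obs_scores = scorer.table(ph.values, method_name)
    obs_tab = enrich_pathways(pathways, obs_scores, method=method, cfg=cfg)

    null = RandomSetNull(obs_scores, cfg)
    member_idx = [null.member_indices(pathways[n]) for n in pathways.names]
    sizes = np.array([idx.size for idx in member_idx])
    tested = np.array([s > 0 for s in sizes])

    # phenotype permutation stream for the FDR layer (distinct from any
    # inner best-SNP standardisation stream)
    rng = np.random.default_rng([int(cfg.seed), 0xFD0])
    perms = np.array([rng.permutation(g.n_subjects) for _ in range(cfg.n_perm_pheno)])

    # warm the draw cache serially so threaded workers share it read-only
    for m in np.unique(sizes[tested]):
        null._subset_indices(int(m))

    def _one_perm(b: int) -> np.ndarray:
        yb = ph.values[perms[b]]
        pvec = scorer.score_vector(yb)
        logp = -np.log(pvec)
        return _pathway_pvalues(
            member_idx, logp, null, method, pvec, cfg.gene_sig_alpha
        )

    if threads > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=threads, prefer="threads")(
            delayed(_one_perm)(b) for b in range(cfg.n_perm_pheno)
        )
    else:
        rows = [_one_perm(b) for b in range(cfg.n_perm_pheno)]
    perm_p = np.vstack(rows)  # (n_perm_pheno, J)

    p_obs = obs_tab["p_value"].to_numpy()
    flat = np.sort(perm_p[:, tested].ravel())
    ev_null = np.full(len(p_obs), np.nan)
    fdr = np.full(len(p_obs), np.nan)
    obs_tested = p_obs[tested]
    # strictly-smaller count, averaged over permutations
    ev = np.searchsorted(flat, obs_tested, side="left") / cfg.n_perm_pheno
    sorted_obs = np.sort(obs_tested)
    denom = np.searchsorted(sorted_obs, obs_tested, side="right")
    raw_fdr = np.minimum(1.0, ev / np.maximum(1, denom))
    # cumulative minimum walking from least to most significant
    order = np.argsort(-obs_tested, kind="mergesort")
    adj = np.minimum.accumulate(raw_fdr[order])
    mono = np.empty_like(adj)
    mono[order] = adj
    ev_null[tested] = ev
    fdr[tested] = mono
    obs_tab["ev_null"] = ev_null
    obs_tab["fdr"] = fdr
    obs_tab["reported"] = fdr < cfg.fdr_report_threshold
    return obs_tab
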