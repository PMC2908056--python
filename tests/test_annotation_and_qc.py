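"""QC filters, Hardy-Weinberg test, SNP-gene mapping, and file readers."""

import numpy as np
import pytest
from scipy import stats

from pathscore import (
    GeneModel,
    QcThresholds,
    filter_snps,
    filter_subjects,
    hwe_test,
    map_snps_to_genes,
    read_bed,
    read_gmt,
    read_phenotype,
    read_vcf,
)


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

class TestHwe:
    def test_exact_hwe_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # q = 0.5, expected (50, 100, 50); chi2 = 50 + 100 + 50 = 200
        p = hwe_test(100, 0, 100)
        assert p == pytest.approx(stats.chi2.sf(200.0, 1), rel=1e-12)

    def test_monomorphic_is_degenerate(self):
        assert hwe_test(60, 0, 0) == 1.0
        assert hwe_test(0, 0, 60) == 1.0

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError, match="empty genotype vector"):
            hwe_test(0, 0, 0)

    def test_property_matches_independent_chisquare(self):
        """Over arbitrary genotype count triples the p-value agrees with an
        independently assembled chi-square survival evaluation."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=200, derandomize=True, deadline=None)
        @given(
            st.tuples(
                st.integers(0, 2000), st.integers(0, 2000), st.integers(0, 2000)
            ).filter(lambda c: sum(c) > 0)
        )
        def check(counts):
            n0, n1, n2 = counts
            n = n0 + n1 + n2
            q = (2 * n2 + n1) / (2 * n)
            if q in (0.0, 1.0):
                assert hwe_test(*counts) == 1.0
                return
            e = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
            chi2 = (([n0, n1, n2] - e) ** 2 / e).sum()
            assert hwe_test(*counts) == pytest.approx(
                stats.chi2.sf(chi2, 1), rel=1e-10, abs=1e-300
            )

        check()

    @pytest.mark.parametrize(
        "counts",
        [(30, 40, 30), (80, 15, 5), (12, 7, 1), (500, 400, 100), (3, 90, 7)],
    )
    def test_matches_independent_chisquare(self, counts):
        """Agreement with scipy's chi-square GOF on hand-built expected
        counts, to 1e-10 relative error."""
        n0, n1, n2 = counts
        n = n0 + n1 + n2
        q = (2 * n2 + n1) / (2 * n)
        expected = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
        # chisquare with 1 estimated parameter: ddof=1 leaves 1 df
        ref = stats.chisquare([n0, n1, n2], expected, ddof=1).pvalue
        assert hwe_test(*counts) == pytest.approx(ref, rel=1e-10)


# ---------------------------------------------------------------------------
# SNP filter
# ---------------------------------------------------------------------------

class TestFilterSnps:
    def _matrix_with(self, make_gm):
        """100 subjects x 4 SNPs: clean / 12% missing / HWE-violating /
        MAF exactly at the 1% boundary."""
        rng = np.random.default_rng(11)
        n = 100
        clean = rng.binomial(2, 0.3, n).astype(float)
        missing = rng.binomial(2, 0.3, n).astype(float)
        missing[:12] = np.nan
        hwe_bad = np.array([0.0, 2.0] * (n // 2))  # no hets at q = 0.5
        maf_boundary = np.zeros(n)
        maf_boundary[:2] = 1.0  # two hets: MAF exactly 0.01, HWE fine
        return make_gm(np.column_stack([clean, missing, hwe_bad, maf_boundary]),
                       snp_ids=["clean", "miss12", "hwe_bad", "maf_1pct"])

    def test_each_rule_fires_with_its_reason(self, make_gm):
        g = self._matrix_with(make_gm)
        out, log = filter_snps(g)
        assert out.snp_ids == ["clean"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert reasons == {
            "miss12": "missing_rate",
            "hwe_bad": "hwe",
            "maf_1pct": "maf",
        }

    def test_maf_exactly_at_threshold_is_removed(self, make_gm):
        # "greater than 1%" is strict: MAF == 0.01 fails
        d = np.zeros((100, 1))
        d[:2, 0] = 1.0
        out, log = filter_snps(make_gm(d))
        assert out.n_snps == 0 and list(log["reason"]) == ["maf"]

    def test_passing_snp_is_retained(self, make_gm):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, (200, 1)).astype(float)
        out, log = filter_snps(make_gm(d))
        assert out.n_snps == 1 and len(log) == 0

    def test_idempotent_and_survivors_recheck(self, make_gm):
        g = self._matrix_with(make_gm)
        once, _ = filter_snps(g)
        twice, log2 = filter_snps(once)
        assert twice.snp_ids == once.snp_ids and len(log2) == 0
        t = QcThresholds()
        for j in range(once.n_snps):
            col = once.dosage[:, j]
            miss = np.isnan(col).mean()
            obs = col[~np.isnan(col)]
            counts = [(obs == k).sum() for k in (0, 1, 2)]
            maf = obs.mean() / 2
            assert miss < t.max_snp_missing_rate
            assert hwe_test(*counts) > t.hwe_alpha
            assert min(maf, 1 - maf) > t.min_maf


# ---------------------------------------------------------------------------
# Subject filter
# ---------------------------------------------------------------------------

class TestFilterSubjects:
    def test_boundary_is_strictly_greater_than(self, make_gm):
        d = np.ones((3, 50))
        d[0, :4] = np.nan  # 8% missing -> removed
        d[1, :3] = np.nan  # 6% missing -> retained (not > 6%)
        out, log = filter_subjects(make_gm(d))
        assert out.subject_ids == ["S1", "S2"]
        assert list(log["subject_id"]) == ["S0"]

    def test_complete_matrix_is_identity(self, make_gm):
        rng = np.random.default_rng(0)
        g = make_gm(rng.binomial(2, 0.3, (20, 10)).astype(float)).recode_minor()
        out, log = filter_subjects(g)
        assert len(log) == 0
        assert np.array_equal(out.dosage, g.dosage)
        assert out.subject_ids == g.subject_ids

    def test_all_removed_raises(self, make_gm):
        d = np.full((4, 10), np.nan)
        d[:, 0] = 1.0
        with pytest.raises(ValueError, match="no subjects survive QC"):
            filter_subjects(make_gm(d))

    def test_minor_coding_rechecked_after_removal(self, make_gm):
        # After dropping S2..S9 the coded allele becomes the major one and
        # must be flipped back to minor coding.
        d = np.zeros((10, 20))
        d[:2, 0] = 2.0
        d[2:, 0] = 0.0
        d[2:, 1:] = np.nan  # subjects 2..9 are 95% missing
        d[:, 1] = 1.0
        out, _ = filter_subjects(make_gm(d))
        assert out.subject_ids == ["S0", "S1"]
        assert out.minor_allele_freq()[0] <= 0.5


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

class TestMapSnpsToGenes:
    def test_flank_window_closed_boundaries(self, make_gm):
        g = make_gm(np.ones((3, 3)), positions=[95_000, 90_000, 89_999])
        gene = GeneModel("GENE", "1", 100_000, 105_000, flank=10_000)
        m = map_snps_to_genes(g, [gene])
        assert ("snp0", "GENE") in m.assignments
        assert ("snp1", "GENE") in m.assignments  # exactly start - flank
        assert ("snp2", "GENE") not in m.assignments  # 1 bp outside
        assert m.unmapped == ["snp2"]

    def test_overlapping_genes_both_receive_snp(self, make_gm):
        g = make_gm(np.ones((2, 1)), positions=[103_000])
        genes = [
            GeneModel("A", "1", 100_000, 105_000),
            GeneModel("B", "1", 102_000, 110_000),
        ]
        m = map_snps_to_genes(g, genes)
        assert m.assignments == {("snp0", "A"), ("snp0", "B")}

    def test_chromosome_mismatch_is_unmapped_not_error(self, make_gm):
        g = make_gm(np.ones((2, 1)), chrom="7", positions=[100_000])
        m = map_snps_to_genes(g, [GeneModel("A", "1", 90_000, 120_000)])
        assert m.assignments == set() and m.unmapped == ["snp0"]

    def test_matches_bruteforce_interval_scan(self, make_gm):
        rng = np.random.default_rng(33)
        n_snps, n_genes = 400, 60
        positions = rng.integers(1, 2_000_000, n_snps)
        chroms = rng.choice(["1", "2"], n_snps)
        d = np.ones((2, n_snps))
        g = make_gm(d, positions=positions)
        g.snp_meta["chrom"] = chroms
        genes = []
        for i in range(n_genes):
            start = int(rng.integers(1, 1_900_000))
            genes.append(
                GeneModel(f"g{i}", str(rng.choice(["1", "2"])), start,
                          start + int(rng.integers(1, 80_000)))
            )
        m = map_snps_to_genes(g, genes)
        brute = set()
        for j, sid in enumerate(g.snp_ids):
            for gene in genes:
                low, high = gene.window
                if chroms[j] == gene.chromosome and low <= positions[j] <= high:
                    brute.add((sid, gene.gene_id))
        assert m.assignments == brute


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

class TestReaders:
    def test_gmt_line_defines_pathway(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tG1\tG2\nP2\tdesc\tG3\n")
        pw = read_gmt(p)
        assert pw["P1"] == {"G1", "G2"} and pw["P2"] == {"G3"}

    def test_gmt_duplicate_pathway_errors_with_line(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\td\tG1\nP1\td\tG2\n")
        with pytest.raises(ValueError, match=r":2:"):
            read_gmt(p)

    def test_bed_zero_based_conversion(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t99999\t105000\tGENE\n")
        genes = read_bed(p)
        assert genes[0].start == 100_000 and genes[0].end == 105_000

    def test_bed_malformed_line_number(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t1\t100\tA\nchr1\tnope\t200\tB\n")
        with pytest.raises(ValueError, match=r":2:"):
            read_bed(p)

    def test_vcf_recodes_to_minor_allele(self, tmp_path):
        # alt frequency 0.7 > 0.5, so the REF allele is coded: GT 0/1 -> 1,
        # 1/1 -> 0, 0/0 -> 2
        p = tmp_path / "g.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD\tE\n"
        )
        row = "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/1\t0/0\n"
        p.write_text(header + row)
        g = read_vcf(p)
        assert g.snp_meta.loc["rs1", "alt"] == "A"  # coded allele is now ref
        assert list(g.dosage[:, 0]) == [0.0, 0.0, 0.0, 1.0, 2.0]

    def test_vcf_missing_and_ids(self, tmp_path):
        p = tmp_path / "g.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
        )
        p.write_text(header + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\n")
        g = read_vcf(p)
        assert np.isnan(g.dosage[0, 0]) and g.dosage[1, 0] == 1.0

    def test_phenotype_binary_and_residual_modes(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("A\t0\nB\t1\nC\t1\n")
        ph = read_phenotype(p)
        assert ph.mode == "binary" and list(ph.values) == [0.0, 1.0, 1.0]
        p2 = tmp_path / "ph2.tsv"
        p2.write_text("A\t-0.25\nB\t0.75\nC\t0.1\n")
        assert read_phenotype(p2).mode == "residual"

    def test_phenotype_duplicate_subject_errors(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("A\t0\nA\t1\n")
        with pytest.raises(ValueError, match="duplicate subject"):
            read_phenotype(p)
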