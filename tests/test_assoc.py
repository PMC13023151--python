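"""GWAS machinery: scenarios, mixed-model scan, haplotype windows,
Fisher exact oracle, inflation factor, binning and gene lookup."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pigiris import assoc, kinship, simdata
from tests.conftest import make_genotypes


def make_classified(counts, breed="L"):
    rows = []
    for cat, n in counts.items():
        rows += [{"category": cat}] * n
    df = pd.DataFrame(rows)
    df["breed"] = breed
    df["animal_id"] = [f"{breed}{i}" for i in range(len(df))]
    return df


FULL_COUNTS = {"dark brown": 40, "light brown": 20, "pale": 10, "iridum": 15, "iridis": 15}


class TestBuildScenarios:
    def test_twelve_scenarios_from_full_cohort(self):
        scenarios = assoc.build_scenarios(make_classified(FULL_COUNTS))
        assert [s.id for s in scenarios] == list(range(1, 13))

    def test_scenario_11_dark_vs_light_only(self):
        scenarios = {s.id: s for s in assoc.build_scenarios(make_classified(FULL_COUNTS))}
        s11 = scenarios[11]
        assert len(s11.case_ids) == 40 and len(s11.control_ids) == 20

    def test_scenario_1_excludes_heterochromia(self):
        df = make_classified(FULL_COUNTS)
        scenarios = {s.id: s for s in assoc.build_scenarios(df)}
        labels = scenarios[1].labels(list(df.animal_id))
        # iridum/iridis animals are neither case nor control
        assert np.isnan(labels).sum() == 30
        assert np.nansum(labels) == 60  # any brown cases

    def test_scenario_12_iridum_cases(self):
        scenarios = {s.id: s for s in assoc.build_scenarios(make_classified(FULL_COUNTS))}
        assert len(scenarios[12].case_ids) == 15
        assert len(scenarios[12].control_ids) == 70

    def test_all_pale_cohort_skips_brown_scenarios(self):
        with pytest.warns(UserWarning, match="empty group"):
            scenarios = assoc.build_scenarios(make_classified({"pale": 30}))
        assert scenarios == []

    def test_combined_sizes_are_breed_sums(self):
        df = pd.concat(
            [make_classified(FULL_COUNTS, "L"), make_classified(FULL_COUNTS, "W")],
            ignore_index=True,
        )
        scenarios = assoc.build_scenarios(df)
        for sc in scenarios:
            n_case = sum(v[0] for v in sc.sizes_by_breed.values())
            n_ctrl = sum(v[1] for v in sc.sizes_by_breed.values())
            assert n_case == len(sc.case_ids)
            assert n_ctrl == len(sc.control_ids)


class TestMlmaScan:
    def test_identity_grm_matches_linear_regression(self):
        """With GRM = I and no covariates the mixed model collapses to OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n, m = 120, 25
        d = rng.binomial(2, 0.4, (n, m))
        g = make_genotypes(d)
        y = rng.binomial(1, 0.5, n).astype(float)
        grm = kinship.RelationshipMatrix(g.sample_ids, np.eye(n), "G")
        res = assoc.mlma_scan(g, y, grm)
        for j in range(5):
            fit = sm.OLS(y, sm.add_constant(d[:, j].astype(float))).fit()
            z2 = (fit.params[1] / fit.bse[1]) ** 2
            p_ref = stats.chi2.sf(z2, 1)
            assert res.p.iloc[j] == pytest.approx(p_ref, abs=1e-6)

    def test_planted_causal_snp_is_top_hit(self):
        ped = simdata.simulate_pedigree(200, 1, 3, seed=10)  # n = 500
        g = simdata.simulate_genotypes(ped, 120, 0.2, 0.5, [("1", 1, 10**8)], seed=10)
        rng = np.random.default_rng(10)
        causal = 60
        liab = 1.6 * g.dosages[:, causal] + rng.standard_normal(g.n_samples)
        y = (liab > np.median(liab)).astype(float)
        grm = kinship.g_matrix(g)
        res = assoc.mlma_scan(g, y, grm)
        top = res.loc[res.p.idxmin()]
        assert top.pos == g.variants.pos.iloc[causal]

    def test_stratification_control_vs_naive(self):
        """Polygenic family confounding: naive lambda inflates, mixed-model
        lambda stays near 1."""
        import statsmodels.api as sm

        ped = simdata.simulate_pedigree(120, 2, 2, seed=12)  # n = 240
        g = simdata.simulate_genotypes(
            ped, 500, 0.1, 0.5, [("1", 1, 10**8), ("2", 1, 10**8)], seed=12
        )
        rng = np.random.default_rng(12)
        # polygenic liability from chromosome-1 SNPs; test chromosome 2
        chr1 = (g.variants.chrom == "1").to_numpy()
        effects = rng.standard_normal(chr1.sum()) * 0.35
        liab = g.dosages[:, chr1] @ effects + rng.standard_normal(g.n_samples)
        y = (liab > np.median(liab)).astype(float)
        test_idx = np.flatnonzero(~chr1)
        # leave-one-chromosome-out GRM: captures relatedness without
        # double-fitting the tested SNPs
        grm = kinship.g_matrix(g.subset(variant_idx=chr1))
        res = assoc.mlma_scan(g.subset(variant_idx=test_idx), y, grm)
        lam_mm = assoc.genomic_inflation(res.p)
        naive_p = []
        for j in test_idx:
            x = g.dosages[:, j].astype(float)
            if x.std() == 0:
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            z2 = (fit.params[1] / fit.bse[1]) ** 2
            naive_p.append(stats.chi2.sf(z2, 1))
        lam_naive = assoc.genomic_inflation(naive_p)
        assert 0.9 <= lam_mm <= 1.1
        assert lam_naive > lam_mm


class TestHaplotypeWindows:
    def make_phased(self, m, n=4, seed=0):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, (n, 2, m), dtype=np.int8)
        return make_genotypes(haps, phased=True)

    def test_window_arithmetic_25_snps(self):
        wins = assoc.haplotype_windows(self.make_phased(25))
        spans = [(w.start_idx, w.start_idx + w.n_snps) for w in wins]
        assert spans == [(0, 10), (5, 15), (10, 20), (15, 25)]

    def test_trailing_partial_emitted_when_two_uncovered(self):
        wins = assoc.haplotype_windows(self.make_phased(27))
        assert (wins[-1].start_idx, wins[-1].n_snps) == (20, 7)

    def test_ten_snps_single_window(self):
        assert len(assoc.haplotype_windows(self.make_phased(10))) == 1

    def test_one_uncovered_snp_dropped(self):
        wins = assoc.haplotype_windows(self.make_phased(11))
        assert len(wins) == 1

    def test_identical_haplotypes_single_allele(self):
        haps = np.ones((2, 2, 10), dtype=np.int8)
        wins = assoc.haplotype_windows(make_genotypes(haps, phased=True))
        assert len(wins[0].alleles) == 1
        assert np.bincount(wins[0].codes.ravel())[0] == 4

    def test_unphased_errors(self):
        g = make_genotypes(np.zeros((2, 10), dtype=int))
        with pytest.raises(ValueError, match="phase"):
            assoc.haplotype_windows(g)


def fisher_oracle(a, b, c, d):
    """Exact-rational full enumeration over the hypergeometric support."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    probs = {}
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[k] = Fraction(comb(row1, k) * comb(n - row1, col1 - k), comb(n, col1))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert assoc.fisher_exact_2x2([[10, 10], [10, 10]]) == 1.0

    @pytest.mark.parametrize("table", [(12, 2, 3, 13), (5, 0, 1, 9), (1, 1, 1, 1)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        assert assoc.fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    def test_random_tables_vs_oracle_and_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            cells = rng.integers(0, 50, 4)
            a, b, c, d = (int(x) for x in cells)
            ours = assoc.fisher_exact_2x2([[a, b], [c, d]])
            assert ours == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert ours == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)


class TestHaplotypeFisherScan:
    def test_rare_haplotype_excluded(self):
        # 1 copy among 200 chromosomes: frequency 0.005 < 0.01
        haps = np.zeros((100, 2, 10), dtype=np.int8)
        haps[0, 0, :] = 1
        g = make_genotypes(haps, phased=True)
        wins = assoc.haplotype_windows(g)
        labels = np.array([1.0] * 50 + [0.0] * 50)
        res = assoc.haplotype_fisher_scan(wins, labels)
        assert "1" * 10 not in set(res.haplotype)

    def test_associated_haplotype_small_p(self):
        haps = np.zeros((40, 2, 10), dtype=np.int8)
        haps[:20] = 1  # cases carry the all-1 haplotype
        g = make_genotypes(haps, phased=True)
        wins = assoc.haplotype_windows(g)
        labels = np.array([1.0] * 20 + [0.0] * 20)
        res = assoc.haplotype_fisher_scan(wins, labels)
        assert res.p.min() == pytest.approx(fisher_oracle(40, 0, 0, 40), abs=1e-12)
        assert res.freq.between(0.01, 0.99).all()


class TestGenomicInflation:
    def test_constant_half_is_exactly_one(self):
        with pytest.warns(UserWarning):
            assert assoc.genomic_inflation([0.5] * 99) == pytest.approx(1.0)

    def test_uniform_near_one(self):
        rng = np.random.default_rng(1)
        lam = assoc.genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_halving_p_inflates(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=10_000)
        assert assoc.genomic_inflation(p / 2) > assoc.genomic_inflation(p)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            assoc.genomic_inflation([0.0, 0.5])


class TestClassifySignificance:
    def test_strict_boundaries(self):
        df = pd.DataFrame({"p": [5e-8, 2e-13, 0.5, 9.9e-6]})
        out = assoc.classify_significance(df)
        assert list(out.tag) == ["suggestive", "genome_wide", "ns", "suggestive"]


class TestTopPerBin:
    def test_argmin_within_bin(self):
        df = pd.DataFrame(
            {"breed": "L", "chrom": "5", "pos": [94_000_100, 94_200_000],
             "p": [1e-9, 1e-7], "scenario": [1, 2]}
        )
        out = assoc.top_per_bin(df)
        assert len(out) == 1 and out.p.iloc[0] == 1e-9

    def test_flooring_bins(self):
        df = pd.DataFrame(
            {"breed": "L", "chrom": "5", "pos": [94_000_000, 94_200_000, 95_100_000],
             "p": [1e-6, 1e-7, 1e-8], "scenario": 1}
        )
        out = assoc.top_per_bin(df)
        assert list(out.bin) == [94, 95]

    def test_empty_results(self):
        assert len(assoc.top_per_bin(pd.DataFrame(columns=["pos", "p", "chrom"]))) == 0


class TestCandidateGenes:
    ANN = pd.DataFrame(
        {
            "chrom": ["5", "5", "5"],
            "start": [93_000_000, 94_017_386, 97_000_000],
            "end": [93_050_000, 94_110_214, 97_100_000],
            "gene": ["GENE_A", "KITLG", "GENE_C"],
        }
    )

    def test_gene_inside_flank_reported(self):
        hits = assoc.candidate_genes([("5", 94_084_790)], self.ANN)
        assert "KITLG" in set(hits[("5", 94_084_790)].gene)

    def test_gene_ending_at_flank_start_excluded(self):
        # half-open: gene [x, hit - 2 Mb) does not overlap [hit - 2 Mb, ...)
        hit = 93_050_000 + 2_000_000
        hits = assoc.candidate_genes([("5", hit)], self.ANN)
        assert "GENE_A" not in set(hits[("5", hit)].gene)

    def test_hit_between_genes_reports_both_in_range(self):
        hits = assoc.candidate_genes([("5", 94_500_000)], self.ANN)
        genes = set(hits[("5", 94_500_000)].gene)
        assert genes == {"KITLG", "GENE_A"}  # GENE_C is 2.5 Mb away

    def test_chromosome_mismatch_errors(self):
        with pytest.raises(ValueError, match="absent"):
            assoc.candidate_genes([("9", 1000)], self.ANN)


class TestHaplotypeLogisticScan:
    def test_planted_association_detected(self):
        rng = np.random.default_rng(9)
        haps = np.zeros((80, 2, 10), dtype=np.int8)
        haps[:40] = 1  # first half carries the risk haplotype
        g = make_genotypes(haps, phased=True)
        wins = assoc.haplotype_windows(g)
        labels = (rng.random(80) < np.where(np.arange(80) < 40, 0.9, 0.1)).astype(float)
        res = assoc.haplotype_logistic_scan(wins, labels)
        assert res.p.min() < 1e-4
        assert (res.method == "haplotype-logistic").all()
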