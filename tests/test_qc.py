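"""QC cascade tests, including the exact-rational HWE enumeration oracle."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pigiris import qc
from pigiris.containers import MISSING, GenotypeMatrix
from tests.conftest import make_genotypes


# ---------------------------------------------------------------------------
# Exact-rational oracle for the HWE exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Enumerate the conditional distribution of heterozygote counts with
    exact rational arithmetic and sum outcomes no likelier than observed."""
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = (2 * n - n_rare - h) // 2
        if hom_common < 0:
            continue
        weight = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        )
        probs[h] = weight
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(100, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(0, 50, 0), (2, 4, 2), (25, 50, 25), (1, 0, 9)])
    def test_matches_enumeration_oracle(self, counts):
        assert qc.hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)

    def test_random_tables_up_to_n200(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 200))
            n_Aa = int(rng.integers(0, n + 1))
            n_AA = int(rng.integers(0, n - n_Aa + 1))
            n_aa = n - n_Aa - n_AA
            assert qc.hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
            )

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 0, 2)
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)


class TestDropDuplicatePositions:
    def test_both_duplicates_removed(self):
        g = make_genotypes(np.zeros((2, 3), dtype=int), pos=[100, 100, 200])
        out = qc.drop_duplicate_positions(g)
        assert list(out.variants.pos) == [200]

    def test_unique_positions_identity(self, small_genotypes):
        out = qc.drop_duplicate_positions(small_genotypes)
        assert out.n_variants == small_genotypes.n_variants

    def test_counting(self):
        g = make_genotypes(np.zeros((2, 5), dtype=int), pos=[1, 2, 2, 3, 4])
        assert qc.drop_duplicate_positions(g).n_variants == 3


class TestSampleQC:
    def test_identical_complete_samples_kept(self):
        g = make_genotypes(np.ones((5, 10), dtype=int))
        out, report = qc.sample_qc(g)
        assert out.n_samples == 5 and not report.removed_samples

    def test_low_call_rate_removed(self):
        d = np.ones((4, 10), dtype=int)
        d[2, :2] = MISSING  # 80% call rate
        out, report = qc.sample_qc(make_genotypes(d))
        assert out.n_samples == 3
        assert report.removed_samples[0][0] == "S2"
        assert "call_rate" in report.removed_samples[0][1]

    def test_planted_het_outlier_flagged(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(100, 400))
        d[17] = 1  # all heterozygous
        out, report = qc.sample_qc(make_genotypes(d))
        assert [s for s, _ in report.removed_samples] == ["S17"]

    def test_all_removed_errors(self):
        d = np.full((2, 10), MISSING, dtype=int)
        with pytest.raises(ValueError, match="every sample"):
            qc.sample_qc(make_genotypes(d))


class TestVariantQC:
    def test_rare_and_monomorphic_removed(self):
        d = np.zeros((100, 3), dtype=int)
        d[0, 0] = 1          # MAF 0.005 -> removed
        d[:50, 2] = 1        # MAF 0.25, HWE fine? 50 het of 100 at p=.25: borderline
        d[:, 2] = np.random.default_rng(3).binomial(2, 0.3, 100)
        out, report = qc.variant_qc(make_genotypes(d))
        reasons = dict(report.removed_variants)
        assert out.n_variants == 1
        assert any("maf" in r for r in reasons.values())

    def test_planted_hwe_violation_removed(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(200, 2))
        d[:, 1] = 1  # all het, n = 200
        assert qc.hwe_exact_test(0, 200, 0) < 1e-4
        out, report = qc.variant_qc(make_genotypes(d))
        assert out.n_variants == 1
        assert "hwe" in report.removed_variants[-1][1]

    def test_hwe_skipped_off_autosomes(self):
        d = np.ones((200, 1), dtype=int)  # all het
        g = make_genotypes(d, chrom="X")
        out, _ = qc.variant_qc(g)
        assert out.n_variants == 1  # kept: HWE not applied to X

    def test_idempotent(self, small_genotypes):
        once, _ = qc.variant_qc(small_genotypes)
        twice, report = qc.variant_qc(once)
        assert twice.n_variants == once.n_variants
        assert not report.removed_variants


class TestXParHandling:
    def make_x(self, pos, dosage, sex):
        g = make_genotypes(np.array([[dosage]]), chrom="chrX", pos=[pos])
        g.samples["sex"] = [sex]
        return g

    def test_male_het_outside_par_set_missing(self):
        out = qc.x_par_handling(self.make_x(10_000_000, 1, "male"))
        assert out.dosages[0, 0] == MISSING

    def test_male_het_inside_par_unchanged(self):
        out = qc.x_par_handling(self.make_x(5_000_000, 1, "male"))
        assert out.dosages[0, 0] == 1

    def test_female_het_unchanged(self):
        out = qc.x_par_handling(self.make_x(10_000_000, 1, "female"))
        assert out.dosages[0, 0] == 1

    def test_unknown_sex_warns(self):
        g = self.make_x(10_000_000, 1, "unknown")
        with pytest.warns(UserWarning, match="unknown sex"):
            out = qc.x_par_handling(g)
        assert out.dosages[0, 0] == 1


class TestImputationFilter:
    def test_boundary_r2_removed(self):
        d = np.tile([0, 1, 2, 1], (10, 1)).T  # polymorphic columns
        g = make_genotypes(d.T[:4].T if False else np.array([[0, 1], [1, 1], [2, 0], [1, 2]]),
                           r2=[0.5, 0.51])
        out, _ = qc.imputation_filter(g)
        assert list(out.variants.r2) == [0.51]

    def test_counting(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(50, 10))
        r2 = [0.9] * 7 + [0.4, 0.5, 0.2]
        g = make_genotypes(d, r2=r2)
        out, report = qc.imputation_filter(g)
        assert out.n_variants == 7
        assert len(report.removed_variants) == 3

    def test_missing_r2_errors(self):
        g = make_genotypes(np.array([[0, 1], [1, 2]]), r2=[0.9, np.nan])
        with pytest.raises(ValueError, match="missing imputation r2"):
            qc.imputation_filter(g)

    def test_no_r2_column_errors(self):
        g = make_genotypes(np.array([[0, 1], [1, 2]]))
        with pytest.raises(ValueError, match="no imputation r2"):
            qc.imputation_filter(g)


class TestIntersectBreeds:
    def test_identical_panels_concatenate_samples(self, small_genotypes):
        out = qc.intersect_breeds(small_genotypes, small_genotypes)
        assert out.n_samples == 2 * small_genotypes.n_samples
        assert out.n_variants == small_genotypes.n_variants

    def test_disjoint_variants_warn_empty(self):
        g1 = make_genotypes(np.array([[0, 1]]), pos=[100, 200])
        g2 = make_genotypes(np.array([[1, 2]]), pos=[300, 400])
        with pytest.warns(UserWarning, match="no shared"):
            out = qc.intersect_breeds(g1, g2)
        assert out.n_variants == 0

    def test_partial_overlap_counts(self):
        rng = np.random.default_rng(4)
        g1 = make_genotypes(rng.binomial(2, 0.5, (3, 100)), pos=np.arange(1, 101))
        g2 = make_genotypes(rng.binomial(2, 0.5, (3, 80)), pos=np.arange(41, 121))
        out = qc.intersect_breeds(g1, g2)
        assert out.n_variants == 60

    def test_allele_mismatch_errors(self):
        g1 = make_genotypes(np.array([[0]]), pos=[100])
        g2 = make_genotypes(np.array([[0]]), pos=[100])
        g2.variants.loc[0, "alt"] = "G"
        with pytest.raises(ValueError, match="allele mismatch"):
            qc.intersect_breeds(g1, g2)
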