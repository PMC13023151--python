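"""Genotype quality control: sample, variant, X-PAR and imputation filters.

The cascade mirrors standard array-genotype QC for a two-breed design:
duplicate-position removal, sample call-rate and heterozygosity-outlier
filtering, variant call-rate / MAF / Hardy-Weinberg filtering (HWE on
autosomes only, each breed separately), X-chromosome handling where
male heterozygous calls outside the pseudoautosomal region (0-7 Mb) are
set to missing, a post-imputation MAF/accuracy filter, and the
intersection of per-breed panels into a combined dataset.

All thresholds follow the conventions: samples are removed at call rate
< 0.95 or |heterozygosity - mean| > 3 sd (two-sided); variants at call
rate < 0.95, MAF < 0.01, or HWE exact p < 1e-4; the post-imputation
filter retains variants with MAF > 0.01 and imputation r^2 > 0.5
(strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "QCReport",
    "drop_duplicate_positions",
    "sample_qc",
    "hwe_exact_test",
    "variant_qc",
    "x_par_handling",
    "imputation_filter",
    "intersect_breeds",
    "split_by_breed",
    "is_autosome",
]

#: Pseudoautosomal region on the X chromosome: positions <= 7,000,000.
PAR_END = 7_000_000

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "W", "Z"}


def is_autosome(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") not in _NON_AUTOSOMES


def _is_x(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") == "X"


@dataclass
class QCReport:
    """Per-filter removal log with before/after counts."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_variants_before: int = 0
    n_variants_after: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("variant", i, r) for i, r in self.removed_variants]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def _variant_key(variants: pd.DataFrame) -> pd.Series:
    return (
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str)
    )


def drop_duplicate_positions(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove ALL variants sharing a duplicated (chrom, pos)."""
    pos_key = g.variants["chrom"].astype(str) + ":" + g.variants["pos"].astype(str)
    keep = ~pos_key.duplicated(keep=False).to_numpy()
    return g.subset(variant_idx=keep)


def sample_qc(
    g: GenotypeMatrix, call_rate_min: float = 0.95, het_sd: float = 3.0
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples with low call rate or outlying heterozygosity.

    Heterozygosity is the proportion of non-missing autosomal genotypes
    that are heterozygous; outliers deviate more than ``het_sd``
    standard deviations from the cohort mean (two-sided). With zero
    heterozygosity variance no sample is an outlier.
    """
    if g.n_samples < 2:
        raise ValueError("sample QC needs >= 2 samples")
    report = QCReport(
        n_samples_before=g.n_samples, n_variants_before=g.n_variants,
        n_variants_after=g.n_variants,
    )
    call_rate = g.sample_call_rate()
    auto = np.array([is_autosome(c) for c in g.variants["chrom"]])
    d_auto = g.dosages[:, auto]
    called = d_auto != MISSING
    n_called = called.sum(axis=1)
    het = np.where(n_called > 0, (d_auto == 1).sum(axis=1) / np.maximum(n_called, 1), 0.0)
    mu, sd = het.mean(), het.std()

    drop = np.zeros(g.n_samples, dtype=bool)
    ids = g.sample_ids
    for i in range(g.n_samples):
        if call_rate[i] < call_rate_min:
            drop[i] = True
            report.removed_samples.append((ids[i], f"call_rate={call_rate[i]:.4f}"))
        elif sd > 0 and abs(het[i] - mu) > het_sd * sd:
            drop[i] = True
            report.removed_samples.append((ids[i], f"heterozygosity={het[i]:.4f}"))
    if drop.all():
        raise ValueError("sample QC removed every sample")
    out = g.subset(sample_idx=~drop)
    report.n_samples_after = out.n_samples
    return out, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts and enumerates all heterozygote
    counts of the same parity, summing the probabilities of outcomes no
    more likely than the observed one (with a 1e-12 relative tie gate).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(2 * n - n_rare - hets) >= 0]
    # log P(het = h | n, n_rare) up to the normalizing constant
    logp = (
        hets * np.log(2.0)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - n_rare - hets) / 2 + 1)
    )
    logp -= logsumexp(logp)
    p_obs = np.exp(logp[hets == n_Aa][0])
    p = float(np.exp(logp)[np.exp(logp) <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def variant_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    autosomes_only_for_hwe: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Variant filters in order: call rate, MAF, HWE (autosomes only).

    Intended to run after :func:`sample_qc`, and per breed when breeds
    are analyzed separately (see :func:`split_by_breed`).
    """
    report = QCReport(
        n_samples_before=g.n_samples, n_samples_after=g.n_samples,
        n_variants_before=g.n_variants,
    )
    keys = _variant_key(g.variants)
    keep = np.ones(g.n_variants, dtype=bool)

    call_rate = g.variant_call_rate()
    for j in np.flatnonzero(call_rate < call_rate_min):
        keep[j] = False
        report.removed_variants.append((keys.iloc[j], f"call_rate={call_rate[j]:.4f}"))

    maf = g.maf()
    for j in np.flatnonzero(keep & ~(maf >= maf_min)):
        keep[j] = False
        report.removed_variants.append((keys.iloc[j], f"maf={maf[j]:.4f}"))

    d = g.dosages
    for j in np.flatnonzero(keep):
        if autosomes_only_for_hwe and not is_autosome(g.variants["chrom"].iloc[j]):
            continue
        col = d[:, j]
        col = col[col != MISSING]
        p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if p < hwe_p_min:
            keep[j] = False
            report.removed_variants.append((keys.iloc[j], f"hwe_p={p:.3g}"))

    out = g.subset(variant_idx=keep)
    report.n_variants_after = out.n_variants
    return out, report


def x_par_handling(
    g: GenotypeMatrix, sexes: dict[str, str] | None = None, par_end: int = PAR_END
) -> GenotypeMatrix:
    """Set male heterozygous X calls outside the PAR (pos <= 7 Mb) to missing.

    The remaining X genotypes are treated as homozygous diploid
    downstream (no recoding needed). Samples of unknown sex are skipped
    with a warning.
    """
    if sexes is None:
        if "sex" not in g.samples.columns:
            raise ValueError("no sex information available")
        sexes = dict(zip(g.sample_ids, g.samples["sex"]))
    x_outside = np.array(
        [_is_x(c) and p > par_end for c, p in zip(g.variants["chrom"], g.variants["pos"])]
    )
    if not x_outside.any():
        return g.copy()
    dosages = g.dosages.copy()
    haps = None if g.haplotypes is None else g.haplotypes.copy()
    for i, sid in enumerate(g.sample_ids):
        sex = sexes.get(sid)
        if sex not in ("male", "female", "castrate"):
            warnings.warn(f"sample {sid}: unknown sex, X-PAR handling skipped")
            continue
        if sex == "female":
            continue
        mask = x_outside & (dosages[i] == 1)
        dosages[i, mask] = MISSING
    return GenotypeMatrix(g.samples, g.variants, dosages, haps)


def imputation_filter(
    g: GenotypeMatrix, maf_min: float = 0.01, r2_min: float = 0.5
) -> tuple[GenotypeMatrix, QCReport]:
    """Post-imputation filter: retain MAF > maf_min AND r^2 > r2_min (strict)."""
    if "r2" not in g.variants.columns:
        raise ValueError("variants carry no imputation r2 column")
    r2 = g.variants["r2"].to_numpy(dtype=float)
    if np.isnan(r2).any():
        bad = _variant_key(g.variants)[np.isnan(r2)].tolist()
        raise ValueError(f"missing imputation r2 for variants: {bad}")
    report = QCReport(
        n_samples_before=g.n_samples, n_samples_after=g.n_samples,
        n_variants_before=g.n_variants,
    )
    maf = g.maf()
    keep = (maf > maf_min) & (r2 > r2_min)
    keys = _variant_key(g.variants)
    for j in np.flatnonzero(~keep):
        report.removed_variants.append(
            (keys.iloc[j], f"maf={maf[j]:.4f},r2={r2[j]:.3f}")
        )
    out = g.subset(variant_idx=keep)
    report.n_variants_after = out.n_variants
    return out, report


def intersect_breeds(g1: GenotypeMatrix, g2: GenotypeMatrix) -> GenotypeMatrix:
    """Combine two per-breed panels on their shared variants.

    Variants are keyed by (chrom, pos, ref, alt); an allele mismatch at
    a shared position is an error (no strand flipping is attempted).
    Samples are concatenated.
    """
    k1, k2 = _variant_key(g1.variants), _variant_key(g2.variants)
    pos1 = g1.variants["chrom"].astype(str) + ":" + g1.variants["pos"].astype(str)
    pos2 = g2.variants["chrom"].astype(str) + ":" + g2.variants["pos"].astype(str)
    shared_pos = set(pos1) & set(pos2)
    key_by_pos2 = dict(zip(pos2, k2))
    mismatch = [
        p for p, k in zip(pos1, k1) if p in shared_pos and key_by_pos2[p] != k
    ]
    if mismatch:
        raise ValueError(f"allele mismatch at shared positions: {mismatch[:10]}")
    shared = set(k1) & set(k2)
    if not shared:
        warnings.warn("no shared variants between panels")
    idx1 = np.array([k in shared for k in k1])
    idx2_map = {k: j for j, k in enumerate(k2)}
    order1 = np.flatnonzero(idx1)
    order2 = np.array([idx2_map[k1.iloc[j]] for j in order1], dtype=int)

    samples = pd.concat([g1.samples, g2.samples], ignore_index=True)
    variants = g1.variants.iloc[order1].reset_index(drop=True)
    dosages = np.vstack([g1.dosages[:, order1], g2.dosages[:, order2]])
    haps = None
    if g1.haplotypes is not None and g2.haplotypes is not None:
        haps = np.concatenate(
            [g1.haplotypes[:, :, order1], g2.haplotypes[:, :, order2]], axis=0
        )
    return GenotypeMatrix(samples, variants, dosages, haps)


def split_by_breed(g: GenotypeMatrix) -> dict[str, GenotypeMatrix]:
    """Split a panel into per-breed matrices (for per-breed QC)."""
    if "breed" not in g.samples.columns:
        raise ValueError("samples carry no breed column")
    out = {}
    for breed in pd.unique(g.samples["breed"]):
        out[str(breed)] = g.subset(sample_idx=(g.samples["breed"] == breed).to_numpy())
    return out
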