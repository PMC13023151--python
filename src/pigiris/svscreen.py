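"""Read-depth structural-variant screen around a focal haplotype.

Sequenced samples are partitioned into homozygous carriers,
heterozygous carriers and non-carriers of a focal haplotype (or variant
allele). Mean depth per 250-bp window is z-score normalised per sample
across the analysed interval, group means are contrasted per window,
and windows where the homozygous-carrier and non-carrier means differ
by more than 3 (strict) are flagged; a deletion-consistent flag should
additionally show hom <= het <= non ordering. Candidate structural
variants are then screened for linkage disequilibrium with a focal
(e.g. missense) variant via the squared dosage correlation r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .assoc import HaplotypeWindow

__all__ = [
    "CoverageProfile",
    "assign_carrier_groups",
    "carrier_frequency",
    "zscore_normalize",
    "group_contrast",
    "dosage_monotonicity",
    "ld_r2",
    "sv_ld_screen",
]


@dataclass
class CoverageProfile:
    """Per-sample window depths and z-scores on a shared window grid."""

    windows: pd.DataFrame  # chrom, start, end (half-open)
    sample_ids: list[str]
    depth: np.ndarray  # (n_samples, n_windows)
    zscore: np.ndarray  # (n_samples, n_windows)


# ---------------------------------------------------------------------------
# Carrier groups
# ---------------------------------------------------------------------------

def carrier_frequency(n_hom: int, n_het: int, n_non: int) -> float:
    """Focal-allele frequency from carrier-group counts: (2 hom + het) / 2n."""
    n = n_hom + n_het + n_non
    if n == 0:
        raise ValueError("no samples")
    return (2 * n_hom + n_het) / (2 * n)


def assign_carrier_groups(
    g: GenotypeMatrix,
    focal_window: HaplotypeWindow | None = None,
    focal_allele: str | None = None,
    focal_variant: str | None = None,
) -> tuple[dict[str, str], float]:
    """Partition samples by focal-allele copy number (2/1/0 -> hom/het/non).

    The focal allele is either a haplotype string within a phased SNP
    window, or the ALT allele of a single variant given as
    ``"chrom_pos"``. Returns the sample -> group mapping and the focal
    allele frequency. If the allele is absent, all samples are
    non-carriers (with a warning).
    """
    if focal_window is not None:
        if focal_allele is None:
            raise ValueError("haplotype mode needs focal_allele")
        if focal_allele in focal_window.alleles:
            h = focal_window.alleles.index(focal_allele)
            copies = (focal_window.codes == h).sum(axis=1)
        else:
            warnings.warn("focal haplotype absent from data: all non-carriers")
            copies = np.zeros(len(focal_window.codes), dtype=int)
    elif focal_variant is not None:
        key = g.variants["chrom"].astype(str) + "_" + g.variants["pos"].astype(str)
        j = np.flatnonzero((key == focal_variant).to_numpy())
        if len(j) == 0:
            raise ValueError(f"variant {focal_variant} not found")
        copies = np.clip(g.dosages[:, j[0]], 0, 2)
        if (g.dosages[:, j[0]] == MISSING).any():
            warnings.warn("missing genotypes at focal variant treated as non-carrier")
    else:
        raise ValueError("give either a focal window+allele or a focal variant")
    group = np.where(copies == 2, "hom", np.where(copies == 1, "het", "non"))
    groups = dict(zip(g.sample_ids, group))
    counts = {k: int((group == k).sum()) for k in ("hom", "het", "non")}
    return groups, carrier_frequency(counts["hom"], counts["het"], counts["non"])


# ---------------------------------------------------------------------------
# Coverage normalisation and contrasts
# ---------------------------------------------------------------------------

def zscore_normalize(coverage: pd.DataFrame) -> CoverageProfile:
    """Per-sample z-scores of window depth across the analysed interval.

    ``coverage`` is tidy with columns chrom, start, end, sample, depth
    (half-open windows). The z-score uses the population
    (n-denominator) standard deviation across the interval's windows;
    a sample with zero depth variance is an error.
    """
    wide = coverage.pivot_table(
        index="sample", columns=["chrom", "start", "end"], values="depth", sort=True
    )
    if wide.shape[1] < 2:
        raise ValueError("need >= 2 windows to normalise")
    depth = wide.to_numpy(dtype=float)
    mu = depth.mean(axis=1, keepdims=True)
    sd = depth.std(axis=1, keepdims=True)  # population sd
    zero = np.flatnonzero(sd.ravel() == 0)
    if len(zero):
        bad = [wide.index[i] for i in zero]
        raise ValueError(f"zero depth variance for samples: {bad}")
    z = (depth - mu) / sd
    windows = pd.DataFrame(
        [(c, s, e) for c, s, e in wide.columns], columns=["chrom", "start", "end"]
    )
    return CoverageProfile(windows, [str(i) for i in wide.index], depth, z)


def group_contrast(
    profile: CoverageProfile, groups: dict[str, str], threshold: float = 3.0
) -> pd.DataFrame:
    """Per-window carrier-group mean z-scores with |hom - non| > threshold flags.

    The primary contrast is homozygous carriers vs non-carriers
    (strict >). With no homozygous carriers the contrast is downgraded
    to het vs non with a warning. Heterozygote means are reported for
    the intermediacy check.
    """
    labels = np.array([groups.get(s, "non") for s in profile.sample_ids])
    means = {}
    for grp in ("hom", "het", "non"):
        mask = labels == grp
        means[grp] = profile.zscore[mask].mean(axis=0) if mask.any() else np.full(
            len(profile.windows), np.nan
        )
    if not (labels == "non").any():
        raise ValueError("non-carrier group is empty")
    if (labels == "hom").any():
        diff = means["hom"] - means["non"]
        contrast = "hom_vs_non"
    else:
        warnings.warn("no homozygous carriers: contrasting het vs non")
        diff = means["het"] - means["non"]
        contrast = "het_vs_non"
    out = profile.windows.copy()
    out["mean_z_hom"] = means["hom"]
    out["mean_z_het"] = means["het"]
    out["mean_z_non"] = means["non"]
    out["diff"] = diff
    out["contrast"] = contrast
    out["flagged"] = np.abs(diff) > threshold
    return out


def dosage_monotonicity(contrast: pd.DataFrame, tol: float = 0.1) -> pd.DataFrame:
    """Deletion-consistent ordering hom <= het <= non per flagged window.

    Requires all three group means; windows lacking a group are skipped
    with a note column.
    """
    flagged = contrast[contrast["flagged"]].copy()
    has_all = ~(
        flagged[["mean_z_hom", "mean_z_het", "mean_z_non"]].isna().any(axis=1)
    )
    ordered = (
        (flagged["mean_z_hom"] <= flagged["mean_z_het"] + tol)
        & (flagged["mean_z_het"] <= flagged["mean_z_non"] + tol)
    )
    flagged["deletion_consistent"] = np.where(has_all, ordered, False)
    flagged["note"] = np.where(has_all, "", "group missing: skipped")
    return flagged


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage (or indicator) vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the sample set")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic vector: r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def sv_ld_screen(
    sv_dosages: pd.DataFrame, focal: np.ndarray, r2_min: float = 0.8
) -> pd.DataFrame:
    """Structural variants in high LD with a focal variant.

    ``sv_dosages`` has one row per SV with an ``id`` column and one
    dosage column per sample (same order as ``focal``). Returns SVs with
    r^2 > r2_min (strict), sorted by r^2 descending, with a
    ``perfect_ld`` flag at r^2 >= 1 - 1e-9. Monomorphic SVs are skipped.
    """
    focal = np.asarray(focal, dtype=float)
    dose_cols = [c for c in sv_dosages.columns if c != "id"]
    rows = []
    for _, rec in sv_dosages.iterrows():
        d = rec[dose_cols].to_numpy(dtype=float)
        if np.std(d) == 0:
            continue
        r2 = ld_r2(d, focal)
        if r2 > r2_min:
            rows.append({"id": rec["id"], "r2": r2, "perfect_ld": r2 >= 1 - 1e-9})
    return (
        pd.DataFrame(rows, columns=["id", "r2", "perfect_ld"])
        .sort_values("r2", ascending=False)
        .reset_index(drop=True)
    )
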