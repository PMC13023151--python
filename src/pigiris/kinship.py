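"""Relationship structures: pedigree A, genomic G, single-step H, and PCA.

The numerator relationship matrix A comes from the tabular (recursive)
method; its inverse from Henderson's rules with inbreeding. The genomic
relationship matrix G is the centered dosage cross-product scaled by
sum 2p(1-p) with observed allele frequencies (VanRaden method 1). The
single-step H combines both so genotyped and ungenotyped animals are
analyzed jointly: H-inverse equals A-inverse plus a correction block
(Gw^-1 - A22^-1) on the genotyped animals, where Gw blends a
diagonal/off-diagonal-tuned G with A22 at weight w (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "a_matrix",
    "a_inverse",
    "g_matrix",
    "mean_impute_dosages",
    "blend_g",
    "HInverse",
    "h_matrix_inverse",
    "h_matrix_dense",
    "pca_covariates",
]


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive-relationship matrix with ordered ids."""

    ids: list[str]
    values: np.ndarray
    kind: str  # A | G | H | A22

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        index = {i: j for j, i in enumerate(self.ids)}
        idx = np.array([index[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders get diagonal 1; a(i,i) = 1 + 0.5 a(sire, dam);
    a(i,j) = 0.5 (a(j, sire) + a(j, dam)) for j earlier than i.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0:
            A[i, i] = 1.0
        else:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(ped.ids, A, "A")


def a_inverse(ped: Pedigree, a: RelationshipMatrix | None = None) -> RelationshipMatrix:
    """A-inverse by Henderson's rules, accounting for inbreeding.

    The Mendelian sampling variance of animal i is
    d_i = 1 - 0.25 (a_ss + a_dd) = 0.5 - 0.25 (F_s + F_d)
    (founders: d_i = 1); 1/d_i is scattered over the (i, sire, dam)
    block. Equivalent to dense inversion of :func:`a_matrix` but O(n)
    per animal.
    """
    if a is None:
        a = a_matrix(ped)
    A = a.values
    n = len(ped)
    sire, dam = ped.parent_indices()
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0:
            d_i = 1.0
        else:
            d_i = 1.0 - 0.25 * (A[s, s] + A[d, d])
        alpha = 1.0 / d_i
        Ainv[i, i] += alpha
        if s >= 0:
            for p in (s, d):
                Ainv[i, p] -= alpha / 2
                Ainv[p, i] -= alpha / 2
            Ainv[s, s] += alpha / 4
            Ainv[d, d] += alpha / 4
            Ainv[s, d] += alpha / 4
            Ainv[d, s] += alpha / 4
    return RelationshipMatrix(ped.ids, Ainv, "A")


def mean_impute_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing entries replaced by 2p."""
    d = g.dosages.astype(float)
    d[g.dosages == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(np.isnan(d))
    d[nan_idx] = col_mean[nan_idx[1]]
    return d


def g_matrix(g: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    G = (M - 2p)(M - 2p)' / sum 2p(1-p), allele frequencies observed in
    the data. Missing genotypes must be imputed to the mean first (done
    internally via :func:`mean_impute_dosages`).
    """
    if g.n_variants < 2:
        raise ValueError("need >= 2 variants for a genomic relationship matrix")
    M = mean_impute_dosages(g)
    p = M.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all variants monomorphic: zero denominator for G")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(g.sample_ids, G, "G")


def blend_g(
    g22: np.ndarray, a22: np.ndarray, w: float = 0.05
) -> np.ndarray:
    """Tune G's mean diagonal/off-diagonal to A22, then blend with weight w.

    G_adj = alpha + beta * G solves the two moment equations; the
    blend is Gw = (1 - w) G_adj + w A22, which guards invertibility.
    """
    k = len(a22)
    if k != len(g22):
        raise ValueError("G and A22 dimensions differ")
    if k >= 2:
        off = ~np.eye(k, dtype=bool)
        gd, go = g22.diagonal().mean(), g22[off].mean()
        ad, ao = a22.diagonal().mean(), a22[off].mean()
        if abs(gd - go) > 1e-12:
            beta = (ad - ao) / (gd - go)
            alpha = ad - beta * gd
        else:
            beta, alpha = 1.0, ad - gd
        g_adj = alpha + beta * g22
    else:
        g_adj = g22 + (a22.diagonal().mean() - g22.diagonal().mean())
    return (1.0 - w) * g_adj + w * a22


@dataclass
class HInverse:
    """H-inverse as A-inverse plus a genotyped-block correction."""

    ids: list[str]
    a_inv: np.ndarray
    genotyped_idx: np.ndarray
    correction: np.ndarray  # Gw^-1 - A22^-1 on the genotyped block

    def dense(self) -> np.ndarray:
        H_inv = self.a_inv.copy()
        gi = self.genotyped_idx
        H_inv[np.ix_(gi, gi)] += self.correction
        return H_inv


def h_matrix_inverse(
    a: RelationshipMatrix,
    g: RelationshipMatrix | None,
    genotyped_ids: list[str],
    w: float = 0.05,
    ped: Pedigree | None = None,
) -> HInverse:
    """Single-step H-inverse structure.

    H^-1 = A^-1 + [0 0; 0 Gw^-1 - A22^-1] on the genotyped block,
    with Gw from :func:`blend_g`. With no genotyped animals this is
    exactly A^-1.
    """
    ids = a.ids
    index = {i: j for j, i in enumerate(ids)}
    missing = [i for i in genotyped_ids if i not in index]
    if missing:
        raise ValueError(f"genotyped ids not in pedigree: {missing[:10]}")
    a_inv_dense = (
        a_inverse(ped, a).values if ped is not None else np.linalg.inv(a.values)
    )
    gi = np.array([index[i] for i in genotyped_ids], dtype=int)
    if len(gi) == 0:
        return HInverse(ids, a_inv_dense, gi, np.zeros((0, 0)))
    if g is None:
        raise ValueError("genotyped ids supplied but no G matrix")
    g22 = g.submatrix(genotyped_ids)
    a22 = a.values[np.ix_(gi, gi)]
    gw = blend_g(g22, a22, w)
    try:
        gw_inv = np.linalg.inv(gw)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"blended G is singular; increase the blending weight (w={w})"
        ) from err
    correction = gw_inv - np.linalg.inv(a22)
    return HInverse(ids, a_inv_dense, gi, correction)


def h_matrix_dense(
    a: RelationshipMatrix,
    g: RelationshipMatrix | None,
    genotyped_ids: list[str],
    w: float = 0.05,
) -> RelationshipMatrix:
    """Textbook dense H assembly (reference form; O(n^3)).

    H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21, H12 = A12 A22^-1 Gw,
    H22 = Gw. Useful as the covariance for samplers and as the oracle
    for :func:`h_matrix_inverse`.
    """
    index = {i: j for j, i in enumerate(a.ids)}
    gi = np.array([index[i] for i in genotyped_ids], dtype=int)
    H = a.values.copy()
    if len(gi) == 0:
        return RelationshipMatrix(a.ids, H, "H")
    if g is None:
        raise ValueError("genotyped ids supplied but no G matrix")
    ni = np.setdiff1d(np.arange(len(a.ids)), gi)
    a22 = a.values[np.ix_(gi, gi)]
    gw = blend_g(g.submatrix(genotyped_ids), a22, w)
    a22_inv = np.linalg.inv(a22)
    B = a.values[np.ix_(ni, gi)] @ a22_inv  # A12 A22^-1
    H[np.ix_(gi, gi)] = gw
    H[np.ix_(ni, gi)] = B @ gw
    H[np.ix_(gi, ni)] = (B @ gw).T
    H[np.ix_(ni, ni)] = a.values[np.ix_(ni, ni)] + B @ (gw - a22) @ B.T
    return RelationshipMatrix(a.ids, H, "H")


def pca_covariates(g: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal component scores of the scaled genotype matrix.

    Dosages are mean-imputed, centered, and scaled to unit variance per
    SNP (monomorphic SNPs dropped); scores come in decreasing
    eigenvalue order with the sign fixed so each component's
    largest-magnitude SNP loading is positive.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return pd.DataFrame(index=g.sample_ids)
    if k >= min(g.n_samples, g.n_variants):
        raise ValueError(f"k={k} too large for {g.n_samples} x {g.n_variants} panel")
    M = mean_impute_dosages(g)
    sd = M.std(axis=0)
    poly = sd > 0
    X = (M[:, poly] - M[:, poly].mean(axis=0)) / sd[poly]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=g.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
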