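"""Case-control GWAS: mixed-model SNP scan and haplotype Fisher scan.

Twelve case-control contrasts of the five iris categories are screened
two ways: (i) a per-SNP mixed linear model with the genomic
relationship matrix as polygenic covariance, four principal components
and sex as covariates (variance components fitted once under the null
by REML, then generalized-least-squares effect and Wald p per SNP);
(ii) a sliding-window haplotype scan (10 SNPs, step 5) testing each
segregating haplotype's case/control chromosome counts with a
two-sided Fisher exact test. Calibration is monitored with the genomic
inflation factor, hits are tagged at the genome-wide (5e-8) and
suggestive (1e-5) thresholds, summarised per 1-Mb bin, and annotated
with genes within +-2 Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix
from .kinship import RelationshipMatrix, mean_impute_dosages

__all__ = [
    "Scenario",
    "SCENARIO_DEFS",
    "build_scenarios",
    "mlma_scan",
    "HaplotypeWindow",
    "haplotype_windows",
    "fisher_exact_2x2",
    "haplotype_fisher_scan",
    "haplotype_logistic_scan",
    "genomic_inflation",
    "classify_significance",
    "top_per_bin",
    "candidate_genes",
]

ANY_BROWN = ("dark brown", "light brown")

#: The twelve case-control contrasts: id -> (name, case set, control set).
SCENARIO_DEFS: dict[int, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    1: ("any brown vs pale", ANY_BROWN, ("pale",)),
    2: ("any brown vs iridis", ANY_BROWN, ("iridis",)),
    3: ("any brown vs iridum", ANY_BROWN, ("iridum",)),
    4: ("any brown vs iridis or iridum", ANY_BROWN, ("iridis", "iridum")),
    5: ("any brown vs pale or iridis or iridum", ANY_BROWN, ("pale", "iridis", "iridum")),
    6: ("dark brown vs pale", ("dark brown",), ("pale",)),
    7: ("dark brown vs iridis", ("dark brown",), ("iridis",)),
    8: ("dark brown vs iridum", ("dark brown",), ("iridum",)),
    9: ("dark brown vs iridis or iridum", ("dark brown",), ("iridis", "iridum")),
    10: ("dark brown vs pale or iridis or iridum", ("dark brown",), ("pale", "iridis", "iridum")),
    11: ("dark brown vs light brown", ("dark brown",), ("light brown",)),
    12: ("iridum vs any brown or pale", ("iridum",), ANY_BROWN + ("pale",)),
}


@dataclass
class Scenario:
    """One case-control contrast with resolved memberships."""

    id: int
    name: str
    case_categories: tuple[str, ...]
    control_categories: tuple[str, ...]
    case_ids: list[str] = field(default_factory=list)
    control_ids: list[str] = field(default_factory=list)
    sizes_by_breed: dict[str, tuple[int, int]] = field(default_factory=dict)

    def labels(self, sample_ids: list[str]) -> np.ndarray:
        """0/1 labels in sample order; NaN for excluded animals."""
        cases, controls = set(self.case_ids), set(self.control_ids)
        return np.array(
            [1.0 if s in cases else 0.0 if s in controls else np.nan for s in sample_ids]
        )


def build_scenarios(classified: pd.DataFrame) -> list[Scenario]:
    """Instantiate the twelve contrasts from classified phenotypes.

    ``classified`` needs ``animal_id``, ``category`` and ``breed``.
    Overlapping categories never occur (case and control sets are
    disjoint by definition); animals in neither set are excluded.
    Scenarios with an empty case or control group are skipped with a
    warning.
    """
    out = []
    for sid, (name, cases, controls) in SCENARIO_DEFS.items():
        case_mask = classified["category"].isin(cases)
        ctrl_mask = classified["category"].isin(controls)
        if not case_mask.any() or not ctrl_mask.any():
            warnings.warn(f"scenario {sid} ({name}): empty group, skipped")
            continue
        sc = Scenario(
            sid, name, cases, controls,
            case_ids=[str(i) for i in classified.loc[case_mask, "animal_id"]],
            control_ids=[str(i) for i in classified.loc[ctrl_mask, "animal_id"]],
        )
        for breed in pd.unique(classified["breed"]):
            b = classified["breed"] == breed
            sc.sizes_by_breed[str(breed)] = (
                int((case_mask & b).sum()), int((ctrl_mask & b).sum())
            )
        out.append(sc)
    return out


# ---------------------------------------------------------------------------
# SNP mixed-model scan
# ---------------------------------------------------------------------------

def _reml_null(
    y: np.ndarray, X: np.ndarray, d: np.ndarray, U: np.ndarray
) -> tuple[float, float]:
    """REML variance components for y = Xb + g + e, var(g) = sigma2_g K.

    Works in the eigenbasis of K (eigenvalues d); profiles out sigma2_g
    and maximises over delta = sigma2_e / sigma2_g on a log grid plus
    bounded refinement. Returns (sigma2_g, sigma2_e).
    """
    yt, Xt = U.T @ y, U.T @ X
    n, p = Xt.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        XtW = Xt.T * w
        A = XtW @ Xt
        beta = np.linalg.solve(A, XtW @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        sigma2 = rss / (n - p)
        _, logdet_A = np.linalg.slogdet(A)
        return 0.5 * (
            (n - p) * np.log(sigma2) - np.log(w).sum() + logdet_A + (n - p)
        )

    grid = np.linspace(-8, 8, 33)
    best = grid[int(np.argmin([neg_reml(g) for g in grid]))]
    res = optimize.minimize_scalar(
        neg_reml, bounds=(best - 1.0, best + 1.0), method="bounded"
    )
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res}")
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    XtW = Xt.T * w
    beta = np.linalg.solve(XtW @ Xt, XtW @ yt)
    r = yt - Xt @ beta
    sigma2_g = float(r @ (w * r)) / (n - p)
    return sigma2_g, sigma2_g * delta


def mlma_scan(
    g: GenotypeMatrix,
    labels: np.ndarray,
    grm: RelationshipMatrix,
    pcs: pd.DataFrame | None = None,
    sex: np.ndarray | None = None,
    scenario_id: int | None = None,
) -> pd.DataFrame:
    """Mixed-linear-model association scan of a 0/1 phenotype.

    ``labels`` holds 1 (case), 0 (control) or NaN (excluded) per sample
    of ``g``. The binary phenotype is treated as a 0/1 linear response;
    variance components are estimated once under the null and reused
    for every SNP (generalized least squares with Wald p-values).
    Monomorphic SNPs are skipped.
    """
    labels = np.asarray(labels, dtype=float)
    use = ~np.isnan(labels)
    if use.sum() < 10:
        raise ValueError("too few labelled samples")
    ids = [s for s, u in zip(g.sample_ids, use) if u]
    y = labels[use]
    cols = [np.ones(len(y))]
    if pcs is not None:
        cols.append(pcs.loc[ids].to_numpy(dtype=float))
    if sex is not None:
        s = np.asarray(sex)[use]
        for lev in sorted(set(s))[1:]:
            cols.append((s == lev).astype(float)[:, None])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])

    K = grm.submatrix(ids)
    dvals, U = np.linalg.eigh(K)
    dvals = np.clip(dvals, 1e-8, None)
    sigma2_g, sigma2_e = _reml_null(y, X, dvals, U)
    delta = sigma2_e / sigma2_g
    w = 1.0 / (dvals + delta)

    M = mean_impute_dosages(g.subset(sample_idx=np.flatnonzero(use)))
    poly = M.std(axis=0) > 0
    Gt = U.T @ M[:, poly]
    yt, Xt = U.T @ y, U.T @ X
    XtW = Xt.T * w
    A = XtW @ Xt
    A_inv = np.linalg.inv(A)
    XtWy = XtW @ yt
    XtWG = XtW @ Gt  # (p, m)
    gWg = np.einsum("ij,i,ij->j", Gt, w, Gt)
    gWy = Gt.T @ (w * yt)
    sxx = gWg - np.einsum("pj,pq,qj->j", XtWG, A_inv, XtWG)
    sxy = gWy - XtWG.T @ (A_inv @ XtWy)
    ok = sxx > 1e-12
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
    # per-SNP residual scaling of the (fixed-ratio) GLS covariance, so the
    # scan collapses exactly to ordinary regression when the GRM is identity
    resid0 = yt - Xt @ (A_inv @ XtWy)
    rss0 = float(resid0 @ (w * resid0))
    n_used, p_cov = Xt.shape
    df = n_used - p_cov - 1
    rss_j = np.clip(rss0 - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 1e-12, None)
    sigma2_j = rss_j / df
    se = np.where(ok, np.sqrt(sigma2_j / np.where(ok, sxx, 1.0)), np.nan)
    chi2 = (beta / se) ** 2
    pvals = stats.chi2.sf(chi2, df=1)

    sub = g.variants.loc[poly].reset_index(drop=True)
    freq = g.subset(sample_idx=np.flatnonzero(use)).alt_freq()[poly]
    return pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "pos": sub["pos"],
            "id": sub["chrom"].astype(str) + "_" + sub["pos"].astype(str),
            "freq": freq,
            "beta": beta,
            "se": se,
            "p": pvals,
            "method": "imputed",
            "scenario": scenario_id,
        }
    ).dropna(subset=["p"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Haplotype windows and Fisher scan
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeWindow:
    """A window of consecutive phased SNPs with coded haplotype alleles."""

    chrom: str
    start_idx: int  # first SNP index within the chromosome block
    n_snps: int
    bp_start: int  # position of the first SNP
    bp_end: int  # position of the last SNP
    alleles: list[str]  # distinct haplotype strings
    codes: np.ndarray  # (n_samples, 2) indices into `alleles`


def haplotype_windows(
    g: GenotypeMatrix, window_size: int = 10, step: int = 5
) -> list[HaplotypeWindow]:
    """Sliding haplotype windows (default 10 SNPs, step 5) per chromosome.

    A trailing partial window (< window_size SNPs) is emitted only when
    at least 2 SNPs would otherwise stay uncovered. Requires phase.
    """
    if not g.phased:
        raise ValueError("haplotype windows require phased genotypes")
    out: list[HaplotypeWindow] = []
    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    haps = g.haplotypes
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = len(idx)
        starts = []
        covered = 0
        for s in range(0, m, step):
            if s + window_size <= m:
                starts.append((s, s + window_size))
                covered = s + window_size
            else:
                if m - covered >= 2 and s < m:
                    starts.append((s, m))
                break
        for s, e in starts:
            cols = idx[s:e]
            block = haps[:, :, cols]  # (n, 2, k)
            flat = block.reshape(-1, e - s)
            strings = np.array(["".join(map(str, row)) for row in flat])
            alleles, codes = np.unique(strings, return_inverse=True)
            out.append(
                HaplotypeWindow(
                    chrom=str(chrom),
                    start_idx=s,
                    n_snps=e - s,
                    bp_start=int(pos[cols[0]]),
                    bp_end=int(pos[cols[-1]]),
                    alleles=list(alleles),
                    codes=codes.reshape(-1, 2),
                )
            )
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by hypergeometric tail summation.

    Sums, over all tables with the observed margins, the probabilities
    no larger than the observed table's (1e-12 relative tie gate).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    mask = pmf <= p_obs * (1 + 1e-12)
    if mask.all():
        return 1.0
    return float(min(pmf[mask].sum(), 1.0))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def haplotype_fisher_scan(
    windows: list[HaplotypeWindow],
    labels: np.ndarray,
    freq_min: float = 0.01,
    freq_max: float = 0.99,
    scenario_id: int | None = None,
) -> pd.DataFrame:
    """Fisher exact test of each segregating haplotype against all others.

    ``labels`` holds 1/0/NaN per sample (as in :func:`mlma_scan`).
    Haplotypes with overall frequency in [freq_min, freq_max] are
    tested on the 2x2 table (this haplotype vs all others) x (case vs
    control chromosomes). Frequencies are reported over all included
    chromosomes; odds ratios use the Haldane-Anscombe 0.5 correction
    when a cell is empty.
    """
    labels = np.asarray(labels, dtype=float)
    use = ~np.isnan(labels)
    is_case = labels[use] == 1.0
    rows = []
    for win in windows:
        codes = win.codes[use]  # (n_used, 2)
        n_chrom = codes.size
        counts = np.bincount(codes.ravel(), minlength=len(win.alleles))
        case_counts = np.bincount(
            codes[is_case].ravel(), minlength=len(win.alleles)
        )
        n_case_chrom = int(is_case.sum()) * 2
        n_ctrl_chrom = n_chrom - n_case_chrom
        for h, allele in enumerate(win.alleles):
            f = counts[h] / n_chrom
            if not (freq_min <= f <= freq_max):
                continue
            a = int(case_counts[h])
            b = n_case_chrom - a
            c = int(counts[h]) - a
            d = n_ctrl_chrom - c
            rows.append(
                {
                    "chrom": win.chrom,
                    "pos": (win.bp_start + win.bp_end) // 2,
                    "span_start": win.bp_start,
                    "span_end": win.bp_end,
                    "id": f"{win.chrom}_{win.bp_start}-{win.bp_end}_{allele}",
                    "haplotype": allele,
                    "freq": f,
                    "odds_ratio": _odds_ratio(a, b, c, d),
                    "p": fisher_exact_2x2([[a, b], [c, d]]),
                    "method": "haplotype",
                    "scenario": scenario_id,
                }
            )
    columns = [
        "chrom", "pos", "span_start", "span_end", "id", "haplotype",
        "freq", "odds_ratio", "p", "method", "scenario",
    ]
    return pd.DataFrame(rows, columns=columns)


def haplotype_logistic_scan(
    windows: list[HaplotypeWindow],
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    freq_min: float = 0.01,
    freq_max: float = 0.99,
    scenario_id: int | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted alternative to the Fisher scan.

    Logistic regression of case status on per-sample haplotype dosage
    plus optional covariates (e.g. 20 PCs and sex). Offered for the
    covariate-adjusted reading of the haplotype analysis; the Fisher
    scan is the primary mode.
    """
    import statsmodels.api as sm

    labels = np.asarray(labels, dtype=float)
    use = ~np.isnan(labels)
    y = labels[use]
    base = [np.ones(use.sum())]
    if covariates is not None:
        base.append(np.asarray(covariates)[use])
    base_X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in base])
    rows = []
    for win in windows:
        codes = win.codes[use]
        n_chrom = codes.size
        counts = np.bincount(codes.ravel(), minlength=len(win.alleles))
        for h, allele in enumerate(win.alleles):
            f = counts[h] / n_chrom
            if not (freq_min <= f <= freq_max):
                continue
            dose = (codes == h).sum(axis=1).astype(float)
            X = np.column_stack([base_X, dose])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
                p = float(fit.pvalues[-1])
                beta = float(fit.params[-1])
            except Exception:  # separation etc.
                p, beta = np.nan, np.nan
            rows.append(
                {
                    "chrom": win.chrom,
                    "pos": (win.bp_start + win.bp_end) // 2,
                    "span_start": win.bp_start,
                    "span_end": win.bp_end,
                    "haplotype": allele,
                    "freq": f,
                    "beta": beta,
                    "p": p,
                    "method": "haplotype-logistic",
                    "scenario": scenario_id,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549364...


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi2 / chi2 null median."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) < 100:
        warnings.warn("fewer than 100 p-values: lambda estimate is noisy")
    return float(np.median(stats.chi2.isf(p, df=1)) / _CHI2_MEDIAN)


def classify_significance(
    results: pd.DataFrame, genome_wide: float = 5e-8, suggestive: float = 1e-5
) -> pd.DataFrame:
    """Tag results genome_wide / suggestive / ns with strict inequalities."""
    out = results.copy()
    p = out["p"].to_numpy()
    tag = np.where(p < genome_wide, "genome_wide", np.where(p < suggestive, "suggestive", "ns"))
    out["tag"] = tag
    return out


def top_per_bin(results: pd.DataFrame, bin_bp: int = 1_000_000) -> pd.DataFrame:
    """Minimum-p record per (breed, chrom, 1-Mb bin) over all scenarios.

    Haplotype records are binned by their span midpoint (already in
    ``pos``).
    """
    if len(results) == 0:
        return results.copy()
    work = results.copy()
    if "breed" not in work.columns:
        work["breed"] = "all"
    work["bin"] = work["pos"] // bin_bp
    idx = work.groupby(["breed", "chrom", "bin"])["p"].idxmin()
    return (
        work.loc[idx]
        .sort_values(["breed", "chrom", "bin"])
        .reset_index(drop=True)
    )


def candidate_genes(
    regions: list[tuple],
    annotation: pd.DataFrame,
    flank: int = 2_000_000,
) -> dict[tuple, pd.DataFrame]:
    """Genes within +-flank of each associated position or span.

    ``regions`` holds (chrom, pos) or (chrom, start, end) tuples;
    ``annotation`` a frame with half-open ``chrom, start, end, gene``
    (see :func:`pigiris.io.read_gene_annotation`). Overlap is half-open:
    a gene ending exactly at the flank start is not reported. Unmatched
    chromosome names are an error.
    """
    ann_chroms = set(annotation["chrom"].astype(str))
    missing = sorted({str(r[0]) for r in regions} - ann_chroms)
    if missing:
        raise ValueError(f"chromosomes absent from annotation: {missing}")
    out = {}
    for region in regions:
        chrom = str(region[0])
        start, end = (region[1], region[1]) if len(region) == 2 else (region[1], region[2])
        f_start, f_end = max(0, start - flank), end + flank
        sub = annotation[
            (annotation["chrom"].astype(str) == chrom)
            & (annotation["start"] < f_end)
            & (annotation["end"] > f_start)
        ]
        out[tuple(region)] = sub.reset_index(drop=True)
    return out
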