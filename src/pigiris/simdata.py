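"""Synthetic-data generation with known ground truth.

Every input the pipeline consumes can be generated here: a
multi-generation pedigree, biallelic SNP genotypes gene-dropped through
it with Haldane recombination, five-category ordinal iris phenotypes
from a liability-threshold model with farm-date and sex fixed effects,
a companion continuous production trait with a chosen genetic
correlation, and per-250-bp sequencing coverage with depth reductions at
deletion sites in haplotype carriers.

Randomness discipline
---------------------
Each public generator takes one integer ``seed`` and builds its own
``numpy.random.default_rng``. Within :func:`simulate_phenotypes` the
stream order is fixed and documented: (1) the (n, 2) standard-normal
matrix behind the additive genetic values, (2) farm-date level
assignment, (3) castrate assignment among males, (4) age at recording,
(5) residuals of the liability trait, (6) residuals of the continuous
trait. :func:`simulate_liability_phenotypes` and
:func:`simulate_continuous_trait` are views of one such run, so calling
them with the same seed yields traits whose genetic values are
correlated exactly as requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree, SimTruth

__all__ = [
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_liability_phenotypes",
    "simulate_continuous_trait",
    "make_window_grid",
    "simulate_coverage",
    "CATEGORY_ORDER",
    "CARRIER_GROUPS",
]

#: Ordinal category order used throughout (mirrors the prevalence table).
CATEGORY_ORDER = ("dark brown", "light brown", "pale", "iridum", "iridis")

#: Carrier-group labels for the coverage simulation / SV screen.
CARRIER_GROUPS = ("hom", "het", "non")

#: Haldane map: 1 cM per Mb, i.e. 1e-8 Morgan per bp.
MORGAN_PER_BP = 1e-8


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int,
    seed: int,
    breed: str = "Landrace",
) -> Pedigree:
    """Simulate a closed random-mating pedigree.

    Founders (generation 0) are split as evenly as possible between the
    sexes. In each later generation every female of the previous
    generation is mated to a randomly drawn male of that generation and
    produces ``offspring_per_mating`` offspring. Offspring sexes
    alternate within a litter (starting from a random side) so that both
    sexes are always present and the mating structure never collapses.

    Raises
    ------
    ValueError
        If a mating structure is impossible (fewer than 2 founders, a
        sex absent in some generation, or non-positive sizes).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0 or offspring_per_mating < 1:
        raise ValueError("n_generations must be >= 0 and offspring_per_mating >= 1")
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    n_f = n_founders // 2
    founders_f = [f"G0_F{i:04d}" for i in range(n_f)]
    founders_m = [f"G0_M{i:04d}" for i in range(n_founders - n_f)]
    for iid in founders_f:
        rows.append((iid, None, None, "female", breed, 0))
    for iid in founders_m:
        rows.append((iid, None, None, "male", breed, 0))

    females, males = founders_f, founders_m
    for g in range(1, n_generations + 1):
        if not females or not males:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
        new_f: list[str] = []
        new_m: list[str] = []
        sires = rng.choice(males, size=len(females), replace=True)
        for k, (dam, sire) in enumerate(zip(females, sires)):
            start = int(rng.integers(2))
            for j in range(offspring_per_mating):
                sex = "female" if (j + start) % 2 == 0 else "male"
                iid = f"G{g}_{'F' if sex == 'female' else 'M'}{k:04d}_{j}"
                rows.append((iid, sire, dam, sex, breed, g))
                (new_f if sex == "female" else new_m).append(iid)
        females, males = new_f, new_m
        if n_generations > g and (not females or not males):
            raise ValueError(f"generation {g} lacks one sex; cannot continue mating")

    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "breed", "generation"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# Genotypes: gene dropping with Haldane recombination
# ---------------------------------------------------------------------------

def _snp_positions(
    n_snps: int, chrom_map: list[tuple[str, int, int]], rng: np.random.Generator
) -> pd.DataFrame:
    lengths = np.array([end - start + 1 for _, start, end in chrom_map], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome intervals must be non-empty")
    alloc = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    while alloc.sum() < n_snps:
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1
    frames = []
    for (chrom, start, end), k in zip(chrom_map, alloc):
        avail = end - start + 1
        if k > avail:
            raise ValueError(
                f"{chrom}: {k} SNPs requested but only {avail} positions available"
            )
        pos = np.sort(rng.choice(avail, size=k, replace=False)) + start
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def simulate_genotypes(
    pedigree: Pedigree,
    n_snps: int,
    maf_low: float,
    maf_high: float,
    chrom_map: list[tuple[str, int, int]],
    seed: int,
) -> GenotypeMatrix:
    """Gene-drop phased biallelic SNPs through a pedigree.

    Founder haplotype alleles are Bernoulli draws at per-SNP ALT
    frequencies uniform in ``[maf_low, maf_high]``. Every non-founder
    receives one recombined gamete from each parent under the Haldane
    model at 1 cM/Mb; chromosomes segregate independently. Phase is
    recorded, so Mendelian transmission is exact by construction.
    """
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    variants = _snp_positions(n_snps, chrom_map, rng)
    variants["ref"] = "A"
    variants["alt"] = "C"
    m = len(variants)
    n = len(pedigree)

    # Per-SNP probability of a crossover relative to the previous SNP;
    # 0.5 at each chromosome start (independent segregation).
    pos = variants["pos"].to_numpy(dtype=float)
    chrom = variants["chrom"].to_numpy()
    d = np.diff(pos, prepend=pos[:1]) * MORGAN_PER_BP
    switch_p = 0.5 * (1.0 - np.exp(-2.0 * d))
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    switch_p[new_chrom] = 0.5

    freqs = rng.uniform(maf_low, maf_high, size=m)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    sire_idx, dam_idx = pedigree.parent_indices()
    for i in range(n):
        if sire_idx[i] < 0:
            haps[i, 0] = rng.random(m) < freqs
            haps[i, 1] = rng.random(m) < freqs
        else:
            for slot, parent in enumerate((sire_idx[i], dam_idx[i])):
                switches = rng.random(m) < switch_p
                which = np.cumsum(switches) % 2
                haps[i, slot] = haps[parent, which, np.arange(m)]

    dosages = haps.sum(axis=1, dtype=np.int8)
    samples = pedigree.table[["id", "breed", "sex"]].copy()
    return GenotypeMatrix(samples, variants, dosages, haps)


# ---------------------------------------------------------------------------
# Phenotypes: liability model + correlated continuous trait
# ---------------------------------------------------------------------------

def _relationship_factor(
    pedigree: Pedigree,
    kinship_source: str,
    genotypes: GenotypeMatrix | None,
) -> np.ndarray:
    """Lower Cholesky factor of the chosen relationship matrix."""
    from .kinship import a_matrix, g_matrix  # local import avoids a cycle

    if kinship_source == "pedigree-A":
        rel = a_matrix(pedigree).values
    elif kinship_source == "genotypes":
        if genotypes is None:
            raise ValueError("kinship_source='genotypes' requires a GenotypeMatrix")
        rel = g_matrix(genotypes).values
        rel = rel + 1e-6 * np.eye(len(rel))
    else:
        raise ValueError(f"unknown kinship source: {kinship_source!r}")
    try:
        return np.linalg.cholesky(rel)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"relationship matrix ({kinship_source}) is not positive definite"
        ) from err


def simulate_phenotypes(
    pedigree: Pedigree,
    truth: SimTruth,
    seed: int,
    kinship_source: str = "pedigree-A",
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Simulate the liability trait and the companion continuous trait.

    Returns a DataFrame with one row per pedigree individual:
    ``id, breed, sex, farm_date, sex_level, age, liability, category,
    genetic1, genetic2, trait2``. ``category`` is the ordinal label
    (see :data:`CATEGORY_ORDER`); ``liability`` the latent value
    including fixed effects; ``genetic1``/``genetic2`` the additive
    genetic values of the two traits; ``trait2`` the continuous
    phenotype.
    """
    thresholds = np.asarray(truth.thresholds, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(pedigree)

    # (1) bivariate genetic values with correlation r_g
    L = _relationship_factor(pedigree, kinship_source, genotypes)
    sd1, sd2 = np.sqrt(truth.h2), np.sqrt(truth.h2_trait2)
    cov = np.array(
        [
            [sd1 * sd1, truth.r_g * sd1 * sd2],
            [truth.r_g * sd1 * sd2, sd2 * sd2],
        ]
    )
    # guard the r_g = +-1 boundary
    w, v = np.linalg.eigh(cov)
    c_factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    u = rng.standard_normal((n, 2))
    genetic = L @ u @ c_factor.T

    # (2)-(4) design: farm-date, sex level, age
    farm_date = rng.integers(0, len(truth.farm_date_effects), size=n)
    sex = pedigree.table["sex"].to_numpy()
    sex_level = np.where(sex == "female", 0, 1)
    castrate = (sex == "male") & (rng.random(n) < 0.5)
    sex_level = np.where(castrate, 2, sex_level)
    age = rng.uniform(150.0, 200.0, size=n)

    fixed = np.asarray(truth.farm_date_effects)[farm_date] + np.asarray(
        truth.sex_effects
    )[sex_level]

    # (5) liability trait
    e1 = rng.standard_normal(n) * np.sqrt(max(1.0 - truth.h2, 0.0))
    liability = fixed + genetic[:, 0] + e1
    if truth.causal_variant is not None and genotypes is not None:
        j = genotypes.variants.index[
            genotypes.variants.apply(
                lambda r: f"{r.chrom}_{r.pos}" == truth.causal_variant, axis=1
            )
        ]
        if len(j):
            liability = liability + truth.causal_effect * genotypes.dosages[:, j[0]]
    category_idx = np.searchsorted(thresholds, liability, side="left")

    # (6) continuous trait: same fixed effects, independent residual
    e2 = rng.standard_normal(n) * np.sqrt(max(1.0 - truth.h2_trait2, 0.0))
    trait2 = fixed + genetic[:, 1] + e2

    return pd.DataFrame(
        {
            "id": pedigree.table["id"],
            "breed": pedigree.table["breed"],
            "sex": sex,
            "farm_date": farm_date,
            "sex_level": sex_level,
            "age": age,
            "liability": liability,
            "category_idx": category_idx,
            "category": [CATEGORY_ORDER[i] for i in category_idx],
            "genetic1": genetic[:, 0],
            "genetic2": genetic[:, 1],
            "trait2": trait2,
        }
    )


def simulate_liability_phenotypes(
    pedigree: Pedigree,
    truth: SimTruth,
    kinship_source: str = "pedigree-A",
    seed: int = 0,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Iris category per individual plus the latent liability.

    Thin view of :func:`simulate_phenotypes`; see there for the stream
    order guarantee.
    """
    df = simulate_phenotypes(pedigree, truth, seed, kinship_source, genotypes)
    return df[
        ["id", "breed", "sex", "farm_date", "sex_level", "age",
         "liability", "category_idx", "category", "genetic1"]
    ].copy()


def simulate_continuous_trait(
    pedigree: Pedigree,
    truth: SimTruth,
    seed: int = 0,
    kinship_source: str = "pedigree-A",
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Continuous production-trait phenotype (id, age, trait2, genetic2).

    Shares the seeded stream with :func:`simulate_liability_phenotypes`:
    called with the same seed, the two traits' genetic values have the
    correlation ``truth.r_g``.
    """
    df = simulate_phenotypes(pedigree, truth, seed, kinship_source, genotypes)
    return df[["id", "farm_date", "sex_level", "age", "trait2", "genetic2"]].copy()


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def make_window_grid(chrom: str, start: int, end: int, size: int = 250) -> pd.DataFrame:
    """Non-overlapping half-open windows of ``size`` bp tiling [start, end)."""
    starts = np.arange(start, end, size)
    if len(starts) == 0:
        raise ValueError("empty window grid")
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + size, end)}
    )


def simulate_coverage(
    samples: dict[str, str],
    window_grid: pd.DataFrame,
    deletion_intervals: list[tuple[str, int, int]],
    mean_depth: float = 30.0,
    overdispersion: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window read depth for carrier groups around planted deletions.

    ``samples`` maps sample id to a carrier group in
    :data:`CARRIER_GROUPS`. Expected depth is ``mean_depth`` everywhere
    except inside a deletion interval, where it is scaled by 0.0 for
    homozygous carriers and 0.5 for heterozygous carriers. Depth is
    negative binomial with variance ``mu + overdispersion * mu**2``
    (Poisson in the limit ``overdispersion -> 0``). Returns a tidy
    DataFrame with columns chrom, start, end, sample, group, depth
    (BED-style half-open coordinates).
    """
    if len(window_grid) == 0:
        raise ValueError("empty window grid")
    bad = set(samples.values()) - set(CARRIER_GROUPS)
    if bad:
        raise ValueError(f"unknown carrier groups: {sorted(bad)}")
    for chrom, s, e in deletion_intervals:
        if chrom not in set(window_grid["chrom"]):
            raise ValueError(f"deletion interval on {chrom} not on the window grid")
    rng = np.random.default_rng(seed)
    w_chrom = window_grid["chrom"].to_numpy()
    w_start = window_grid["start"].to_numpy()
    w_end = window_grid["end"].to_numpy()
    in_del = np.zeros(len(window_grid), dtype=bool)
    for chrom, s, e in deletion_intervals:
        in_del |= (w_chrom == chrom) & (w_start < e) & (w_end > s)

    scale_by_group = {"hom": 0.0, "het": 0.5, "non": 1.0}
    frames = []
    for sample_id, group in samples.items():
        mu = np.full(len(window_grid), float(mean_depth))
        mu[in_del] *= scale_by_group[group]
        depth = np.zeros(len(mu), dtype=np.int64)
        live = mu > 0
        if overdispersion <= 1e-9:
            depth[live] = rng.poisson(mu[live])
        else:
            r = 1.0 / overdispersion
            p = r / (r + mu[live])
            depth[live] = rng.negative_binomial(r, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": w_chrom,
                    "start": w_start,
                    "end": w_end,
                    "sample": sample_id,
                    "group": group,
                    "depth": depth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
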