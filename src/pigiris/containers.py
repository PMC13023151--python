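"""Shared in-memory containers for the iris-pigmentation pipeline.

The pipeline moves three core objects between its stages: a
:class:`Pedigree` (the directed acyclic parent map that underlies the
numerator relationship matrix and gene dropping), a
:class:`GenotypeMatrix` (individuals x biallelic SNPs, optionally
phased), and a :class:`SimTruth` record holding the generative
parameters of a simulation so that downstream estimates can be compared
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "GenotypeMatrix", "SimTruth", "MISSING"]

#: Sentinel for a missing genotype dosage.
MISSING: int = -1

_SEXES = {"female", "male", "castrate"}


class Pedigree:
    """A multi-generation pedigree with sex and breed labels.

    Parameters
    ----------
    table:
        DataFrame with columns ``id``, ``sire``, ``dam``, ``sex``,
        ``breed``, ``generation``. Missing parents are ``None``/NaN and
        are only allowed for founders. Parents must precede offspring
        in generation order and the parent map must be acyclic.
    """

    REQUIRED = ("id", "sire", "dam", "sex", "breed", "generation")

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        missing_cols = [c for c in self.REQUIRED if c not in table.columns]
        if missing_cols:
            raise ValueError(f"pedigree table missing columns: {missing_cols}")
        df = table.loc[:, list(self.REQUIRED)].copy()
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            df[col] = df[col].where(df[col].notna(), None)
            df[col] = df[col].map(lambda v: None if v is None else str(v))
        df["generation"] = df["generation"].astype(int)
        df = df.sort_values(["generation", "id"], kind="stable").reset_index(drop=True)
        self.table = df
        self._index = {iid: i for i, iid in enumerate(df["id"])}
        if len(self._index) != len(df):
            raise ValueError("duplicate individual ids in pedigree")
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.table
        bad_sex = set(df["sex"]) - _SEXES
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        gen = dict(zip(df["id"], df["generation"]))
        for iid, sire, dam, g in zip(df["id"], df["sire"], df["dam"], df["generation"]):
            for parent in (sire, dam):
                if parent is None:
                    continue
                if parent not in gen:
                    raise ValueError(f"{iid}: parent {parent} not in pedigree")
                if gen[parent] >= g:
                    raise ValueError(
                        f"{iid}: parent {parent} does not precede offspring "
                        f"in generation order (acyclicity violated)"
                    )
            if (sire is None) != (dam is None):
                raise ValueError(f"{iid}: exactly one parent missing (need both or neither)")
            if sire is None and g != 0:
                raise ValueError(f"{iid}: missing parents only allowed for founders")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def index_of(self, iid: str) -> int:
        return self._index[str(iid)]

    @property
    def founders(self) -> pd.DataFrame:
        return self.table[self.table["sire"].isna() if False else self.table["sire"].isnull()]

    def is_founder(self) -> np.ndarray:
        """Boolean mask, True where both parents are missing."""
        return self.table["sire"].isnull().to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row indices (−1 for missing), in table order."""
        sire = np.array(
            [self._index[s] if s is not None else -1 for s in self.table["sire"]],
            dtype=np.int64,
        )
        dam = np.array(
            [self._index[d] if d is not None else -1 for d in self.table["dam"]],
            dtype=np.int64,
        )
        return sire, dam


class GenotypeMatrix:
    """Individuals x biallelic SNPs, with optional phase.

    Attributes
    ----------
    samples:
        DataFrame with at least ``id``; ``breed`` and ``sex`` columns are
        carried when known.
    variants:
        DataFrame with ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and
        optionally ``r2`` (imputation accuracy).
    dosages:
        (n_samples, n_variants) int8 array of ALT-allele counts in
        {0, 1, 2}, with :data:`MISSING` (−1) for no-calls.
    haplotypes:
        Optional (n_samples, 2, n_variants) int8 array of phased ALT
        indicators; where present, ``dosages == haplotypes.sum(axis=1)``.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        variants: pd.DataFrame,
        dosages: np.ndarray,
        haplotypes: np.ndarray | None = None,
    ):
        samples = samples.reset_index(drop=True).copy()
        variants = variants.reset_index(drop=True).copy()
        if "id" not in samples.columns:
            raise ValueError("samples frame needs an 'id' column")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in variants.columns:
                raise ValueError(f"variants frame needs a '{col}' column")
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes, dtype=np.int8)
            if haplotypes.shape != (len(samples), 2, len(variants)):
                raise ValueError("haplotype array must be (n_samples, 2, n_variants)")
            hsum = haplotypes.sum(axis=1, dtype=np.int8)
            called = dosages != MISSING
            if not np.array_equal(hsum[called], dosages[called]):
                raise ValueError("dosages inconsistent with haplotype allele sums")
        self.samples = samples
        self.variants = variants
        self.dosages = dosages
        self.haplotypes = haplotypes

    # -- shape -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.samples["id"]]

    # -- summaries -------------------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency among non-missing calls."""
        d = self.dosages
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def sample_call_rate(self, variant_mask: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages if variant_mask is None else self.dosages[:, variant_mask]
        if d.shape[1] == 0:
            return np.ones(self.n_samples)
        return (d != MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        variant_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        hap = None
        if self.haplotypes is not None:
            hap = self.haplotypes[np.ix_(si, [0, 1], vi)]
        return GenotypeMatrix(
            self.samples.iloc[si],
            self.variants.iloc[vi],
            self.dosages[np.ix_(si, vi)],
            hap,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.copy(),
            self.variants.copy(),
            self.dosages.copy(),
            None if self.haplotypes is None else self.haplotypes.copy(),
        )


@dataclass
class SimTruth:
    """Generative parameters for a simulation run.

    ``h2`` is the liability-scale heritability of the categorical trait;
    ``h2_trait2`` the heritability of the companion continuous trait;
    ``r_g`` their additive-genetic correlation. ``thresholds`` are the
    four strictly increasing cut points partitioning a unit-variance
    liability into five ordinal categories. Fixed effects are the
    farm-date (6 levels) and sex (3 levels) contributions to liability.
    """

    h2: float = 0.576
    h2_trait2: float = 0.40
    r_g: float = 0.0
    thresholds: tuple[float, ...] = (-0.04, 0.39, 0.59, 1.34)
    farm_date_effects: tuple[float, ...] = (0.0, 0.15, -0.10, 0.25, -0.20, 0.05)
    sex_effects: tuple[float, ...] = (0.0, -0.12, 0.08)
    causal_variant: str | None = None
    causal_effect: float = 0.0
    deletion_intervals: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.h2_trait2 <= 1.0:
            raise ValueError("h2_trait2 must lie in [0, 1]")
        if not -1.0 <= self.r_g <= 1.0:
            raise ValueError("r_g must lie in [-1, 1]")
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) != 4 or not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be 4 strictly increasing reals")
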