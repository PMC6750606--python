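"""RBC fatty-acid indices and FADS2 (rs1535) genotype statistics.

The omega-3 index (O3I) is the sum of EPA and DHA as a percentage of total
red-blood-cell membrane fatty acids.  Delta-6 desaturase (FADS2) activity is
proxied by the product/precursor ratio of arachidonic to linoleic acid
(ArA/LA); carriers of the minor G allele of rs1535 desaturate less and show
lower ratios.  Genotype distributions are checked against Hardy-Weinberg
equilibrium with the standard 1-degree-of-freedom chi-square on observed
allele frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError

#: rs1535 genotype categories; G is the minor allele.
GENOTYPES = ("AA", "AG", "GG")


@dataclass(frozen=True)
class FattyAcidProfile:
    """RBC membrane fatty acids, each as percent of total identified fatty acids."""

    epa_pct: float
    dha_pct: float
    ara_pct: float
    la_pct: float
    ala_pct: float = 0.0

    def __post_init__(self) -> None:
        for name in ("epa_pct", "dha_pct", "ara_pct", "la_pct", "ala_pct"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0 <= v <= 100):
                raise DomainError(f"{name} must be in [0, 100] percent, got {v}")
        if self.epa_pct + self.dha_pct > 100:
            raise DomainError("EPA + DHA cannot exceed 100% of total fatty acids")


def omega3_index(profile: FattyAcidProfile) -> float:
    """Omega-3 index: EPA% + DHA% of total RBC fatty acids."""
    return profile.epa_pct + profile.dha_pct


def fads2_activity(profile: FattyAcidProfile) -> float:
    """Desaturase-activity surrogate: ArA/LA product-to-precursor ratio."""
    if profile.la_pct == 0:
        raise DomainError("linoleic acid percentage is zero; ArA/LA undefined")
    return profile.ara_pct / profile.la_pct


@dataclass(frozen=True)
class GenotypeTable:
    """Counts of rs1535 genotypes (AA homozygote, AG heterozygote, GG homozygote)."""

    n_aa: int
    n_ag: int
    n_gg: int

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ag", "n_gg"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise DomainError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise DomainError("genotype table is empty")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ag + self.n_gg

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_ag, self.n_gg)

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[str]) -> "GenotypeTable":
        counts = {g: 0 for g in GENOTYPES}
        for g in genotypes:
            if g not in counts:
                raise DomainError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")
            counts[g] += 1
        return cls(counts["AA"], counts["AG"], counts["GG"])

    def proportions(self) -> tuple[float, float, float]:
        n = self.total
        return (self.n_aa / n, self.n_ag / n, self.n_gg / n)


def allele_frequencies(table: GenotypeTable) -> tuple[float, float]:
    """(freq_A, freq_G) from genotype counts; each chromosome counted once."""
    n_alleles = 2 * table.total
    freq_a = (2 * table.n_aa + table.n_ag) / n_alleles
    return freq_a, 1.0 - freq_a


@dataclass(frozen=True)
class HWEResult:
    statistic: float
    p_value: float
    expected: tuple[float, float, float]
    small_expected_cell: bool


def hwe_chi_square(table: GenotypeTable) -> HWEResult:
    """1-df chi-square test of Hardy-Weinberg equilibrium.

    Expected counts are n*p^2, 2npq, n*q^2 from the observed allele
    frequencies; one degree of freedom remains after estimating p.  A
    monomorphic sample (p = 0 or 1) fits HWE trivially and returns
    statistic 0.  An expected cell below 1 attaches a warning flag (the
    asymptotic approximation is then poor) without raising.
    """
    n = table.total
    if n < 5:
        raise InsufficientDataError(f"need at least 5 individuals, got {n}")
    p, q = allele_frequencies(table)
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    if p == 0.0 or q == 0.0:
        return HWEResult(0.0, 1.0, expected, False)
    small = any(e < 1 for e in expected)
    if small:
        warnings.warn(
            "an expected genotype count is below 1; chi-square approximation is poor",
            RuntimeWarning,
            stacklevel=2,
        )
    observed = np.array(table.counts, dtype=float)
    exp = np.array(expected)
    statistic = float(np.sum((observed - exp) ** 2 / exp))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return HWEResult(statistic, p_value, expected, small)
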