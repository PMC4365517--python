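"""Exact test for departure from Hardy-Weinberg proportions.

The test conditions on the observed allele counts: given ``n`` diploid
individuals carrying ``n_minor`` copies of the minor allele, the number of
heterozygotes ``h`` under random union of gametes follows

    P(h | n, n_minor)  propto  n! / (n_aa! h! n_AA!) * 2**h,

where ``n_aa = (n_minor - h) / 2`` and ``h`` has the parity of ``n_minor``.
The two-sided p-value is the total probability of all heterozygote counts
whose conditional probability does not exceed that of the observed
configuration (ties included in the rejection sum). This is the exact
conditional construction suited to low-MAF variants, where the usual
chi-square approximation breaks down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .genotype_data import GenotypeMatrix

logger = logging.getLogger(__name__)

_REL_TIE_TOL = 1e-9  # relative tolerance when grouping tied probabilities


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic variant."""

    n_hom_minor: int
    n_het: int
    n_hom_major: int

    def __post_init__(self) -> None:
        for name in ("n_hom_minor", "n_het", "n_hom_major"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_minor + self.n_het + self.n_hom_major

    def folded(self) -> "GenotypeCounts":
        """Relabel so the 'minor' homozygote really is the rarer allele."""
        if 2 * self.n_hom_minor + self.n_het > self.n:
            return GenotypeCounts(self.n_hom_major, self.n_het, self.n_hom_minor)
        return self


@dataclass(frozen=True)
class HweResult:
    p_value: float
    departing: bool
    alpha: float


@lru_cache(maxsize=65536)
def hwe_het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Returns (feasible het counts, their probabilities); the probabilities
    sum to 1 exactly up to floating rounding.
    """
    if n < 1:
        raise ValueError("need at least one diploid individual")
    if not 1 <= n_minor <= n:
        raise ValueError(f"n_minor={n_minor} out of range for n={n} (fold first)")
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hs = hs[(n_minor - hs) // 2 + hs <= n]
    logw = (
        hs * np.log(2.0)
        - gammaln((n_minor - hs) // 2 + 1)
        - gammaln(hs + 1)
        - gammaln(n - (n_minor + hs) // 2 + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return hs, w / w.sum()


def hwe_exact_pvalue(counts: GenotypeCounts, alpha: float = 0.05) -> HweResult:
    """Exact conditional HWE p-value for one variant's genotype counts.

    Monomorphic input is an error: with zero copies of the minor allele the
    conditional distribution is a point mass and the test is undefined.
    """
    c = counts.folded()
    n = c.n
    n_minor = 2 * c.n_hom_minor + c.n_het
    if n_minor == 0:
        raise ValueError("HWE test undefined for a monomorphic variant")
    hs, probs = hwe_het_distribution(n, n_minor)
    obs = probs[hs == c.n_het]
    if obs.size == 0:
        raise ValueError(
            f"heterozygote count {c.n_het} infeasible for n={n}, "
            f"minor copies {n_minor} (parity constraint)"
        )
    p = float(probs[probs <= obs[0] * (1.0 + _REL_TIE_TOL)].sum())
    p = min(p, 1.0)
    return HweResult(p_value=p, departing=p <= alpha, alpha=alpha)


def counts_from_calls(calls: np.ndarray) -> GenotypeCounts:
    """Genotype counts of one variant column, folded to the minor allele."""
    calls = np.asarray(calls)
    return GenotypeCounts(
        n_hom_minor=int((calls == 2).sum()),
        n_het=int((calls == 1).sum()),
        n_hom_major=int((calls == 0).sum()),
    ).folded()


@dataclass
class HweSummary:
    """Per-dataset departure summary: totals, counts and percentage."""

    n_total: int
    n_departing: int
    alpha: float
    p_values: np.ndarray
    variant_ids: list[str]

    @property
    def fraction(self) -> float:
        return self.n_departing / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def hwe_departure_fraction(g: GenotypeMatrix, alpha: float = 0.05) -> HweSummary:
    """Fraction of variants departing from HWE at ``p <= alpha``.

    Requires every variant to be polymorphic (run after MAF filtering).
    The conditional distribution is cached per (n, minor-copy-count) pair,
    so large panels over a fixed sample cost little more than counting.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    n = g.n_samples
    calls = g.calls
    n_het = (calls == 1).sum(axis=0)
    n_hom_coded = (calls == 2).sum(axis=0)
    coded_copies = 2 * n_hom_coded + n_het
    minor_copies = np.minimum(coded_copies, 2 * n - coded_copies)
    if (minor_copies == 0).any():
        v = int(np.flatnonzero(minor_copies == 0)[0])
        raise ValueError(
            f"monomorphic variant {g.variant_ids[v]!r}: filter before HWE testing"
        )
    p_values = np.empty(g.n_variants)
    for v in range(g.n_variants):
        hs, probs = hwe_het_distribution(n, int(minor_copies[v]))
        obs = probs[hs == n_het[v]][0]
        p_values[v] = min(
            float(probs[probs <= obs * (1.0 + _REL_TIE_TOL)].sum()), 1.0
        )
    n_departing = int((p_values <= alpha).sum())
    return HweSummary(
        n_total=g.n_variants,
        n_departing=n_departing,
        alpha=alpha,
        p_values=p_values,
        variant_ids=list(g.variant_ids),
    )
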