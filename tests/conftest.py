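"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by enumeration or naive
recursion so they stay independent of the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from relkit import GenotypeMatrix, Pedigree


# ---------------------------------------------------------------------------
# Genotype fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """5 individuals x 6 variants with a spread of MAFs."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 1, 1, 0, 0, 2],
            [1, 0, 2, 0, 1, 2],
            [0, 2, 1, 0, 0, 2],
            [0, 1, 2, 1, 1, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(5)],
        variant_ids=[f"v{i}" for i in range(6)],
        calls=calls,
    )


def random_genotypes(rng: np.random.Generator, n: int, m: int) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, m), dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=[f"v{i}" for i in range(m)],
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Pedigree fixtures and oracle
# ---------------------------------------------------------------------------

@pytest.fixture
def family_pedigree() -> Pedigree:
    """Founders A,B,C; full sibs D,E; half sib F; inbred H from D x E."""
    return Pedigree.from_records(
        [
            ("A", "0", "0"),
            ("B", "0", "0"),
            ("C", "0", "0"),
            ("D", "A", "B"),
            ("E", "A", "B"),
            ("F", "A", "C"),
            ("H", "D", "E"),
        ]
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random acyclic pedigree: each parent drawn from earlier ids or unknown."""
    records = []
    for i in range(n):
        name = f"i{i}"
        parents = []
        for _ in range(2):
            if i > 0 and rng.random() < 0.7:
                parents.append(f"i{rng.integers(0, i)}")
            else:
                parents.append("0")
        if parents[0] == parents[1] and parents[0] != "0":
            parents[1] = "0"
        records.append((name, parents[0], parents[1]))
    return Pedigree.from_records(records)


def oracle_relationship(p: Pedigree, a: str, b: str) -> float:
    """Brute-force additive relationship: naive coancestry recursion with
    explicit ancestor-set checks (no topological machinery)."""

    def ancestors(x: str, acc: set[str]) -> set[str]:
        for par in p.parents[x]:
            if par is not None and par not in acc:
                acc.add(par)
                ancestors(par, acc)
        return acc

    def coan(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        if x == y:
            s, d = p.parents[x]
            return 0.5 * (1.0 + coan(s, d))
        # recurse on whichever individual is not an ancestor of the other
        if x in ancestors(y, set()):
            x, y = y, x
        s, d = p.parents[x]
        return 0.5 * (coan(s, y) + coan(d, y))

    return 2.0 * coan(a, b) if a != b else 1.0 + coan(*p.parents[a])


# ---------------------------------------------------------------------------
# HWE enumeration oracle
# ---------------------------------------------------------------------------

def oracle_hwe_distribution(n: int, n_minor: int) -> dict[int, float]:
    """Heterozygote-count distribution by enumerating every placement of the
    minor alleles over the 2n ordered allele slots (slots 2i, 2i+1 pair up)."""
    from math import comb

    counts: dict[int, int] = {}
    slots = list(range(2 * n))
    for placement in combinations(slots, n_minor):
        chosen = set(placement)
        het = sum(
            1 for i in range(n) if (2 * i in chosen) != (2 * i + 1 in chosen)
        )
        counts[het] = counts.get(het, 0) + 1
    total = comb(2 * n, n_minor)
    return {h: c / total for h, c in counts.items()}


def oracle_hwe_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    n = n_hom_minor + n_het + n_hom_major
    m = 2 * n_hom_minor + n_het
    m = min(m, 2 * n - m)
    dist = oracle_hwe_distribution(n, m)
    obs = dist[n_het]
    return sum(pr for pr in dist.values() if pr <= obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# Wilcoxon enumeration oracle
# ---------------------------------------------------------------------------

def oracle_wilcoxon_pvalue(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Uses average ranks on tied |d| and the two-sided rule
    p = min(1, 2 * min(P(T+ <= t), P(T+ >= t))).
    """
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    stats = []
    for mask in range(2 ** n):
        signs = np.array([(mask >> k) & 1 for k in range(n)], dtype=bool)
        stats.append(ranks[signs].sum())
    stats = np.asarray(stats)
    le = np.mean(stats <= t_obs + 1e-12)
    ge = np.mean(stats >= t_obs - 1e-12)
    return min(1.0, 2.0 * min(le, ge))
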