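"""Genomic relationship matrices and genomic inbreeding.

Two marker-based estimators of the additive relationship between
individuals j and k from 0/1/2 allele counts x_ij at N variants:

* Allele-frequency-weighted ("Yang") estimator, with a distinct diagonal:

      G_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
      G_jj = 1 + (1/N) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

  where p_i is the frequency of the allele whose homozygote is coded 2.
  Standardising by 2p(1-p) gives rare alleles more weight, so the
  estimator emphasises sharing of low-MAF variants.

* Similarity (allele-sharing) estimator

      G = (M - 1)(M - 1)' / (N / 2),

  which counts identical alleles without any frequency correction. Its
  entries lie in [-2, 2]: -2 for opposing homozygotes at every variant,
  2 for identical homozygotes throughout; it is equivalent to the
  weighted estimator evaluated at all frequencies equal to 0.5 (up to the
  diagonal convention).

Genomic inbreeding is the self-relationship minus 1 — the correlation
between an individual's uniting gametes — and may be negative when
heterozygosity exceeds its frequency-based expectation.

Both estimators accumulate per-variant contributions in variant chunks,
so sequence-scale panels never need the whole standardised genotype
matrix in memory at once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

_DEFAULT_CHUNK = 20_000


def _drop_monomorphic(g: GenotypeMatrix, label: str) -> GenotypeMatrix:
    p = g.calls.mean(axis=0) / 2.0
    mask = (p > 0.0) & (p < 1.0)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("%s: removed %d monomorphic variants", label, n_drop)
        g = g.subset_variants(mask)
    return g


def grm_yang(
    g: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    chunk_size: int = _DEFAULT_CHUNK,
) -> RelationshipMatrix:
    """Allele-frequency-weighted GRM.

    Parameters
    ----------
    g:
        Genotype matrix; variants monomorphic in the sample are removed
        (with a logged count) when frequencies are sample-estimated.
    freqs:
        Optional per-variant frequencies of the coded allele, e.g. founder
        or base-population frequencies. Must be strictly inside (0, 1);
        defaults to the current-sample estimates.
    """
    if freqs is None:
        g = _drop_monomorphic(g, "grm_yang")
        p = g.calls.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (g.n_variants,):
            raise ValueError(
                f"freqs has shape {p.shape}, expected ({g.n_variants},)"
            )
        bad = (p <= 0.0) | (p >= 1.0)
        if bad.any():
            v = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"frequency {p[v]} for variant {g.variant_ids[v]!r} is outside "
                "(0, 1); filter fixed variants before the weighted estimator"
            )
    n_var = g.n_variants
    if n_var == 0:
        raise ValueError("no polymorphic variants left for the weighted GRM")
    n = g.n_samples
    off = np.zeros((n, n))
    diag = np.zeros(n)
    for start in range(0, n_var, chunk_size):
        stop = min(start + chunk_size, n_var)
        x = g.calls[:, start:stop].astype(np.float64)
        pc = p[start:stop]
        denom = 2.0 * pc * (1.0 - pc)
        w = (x - 2.0 * pc) / np.sqrt(denom)
        off += w @ w.T
        diag += ((x * x - (1.0 + 2.0 * pc) * x + 2.0 * pc * pc) / denom).sum(axis=1)
    values = off / n_var
    values[np.diag_indices(n)] = 1.0 + diag / n_var
    values = (values + values.T) / 2.0  # exact symmetry after accumulation
    return RelationshipMatrix(
        ids=list(g.sample_ids), values=values, method="G_yang", n_variants=n_var
    )


def grm_similarity(
    g: GenotypeMatrix,
    keep_monomorphic: bool = False,
    chunk_size: int = _DEFAULT_CHUNK,
) -> RelationshipMatrix:
    """Allele-sharing GRM, (M - 1)(M - 1)' / (N / 2), entries in [-2, 2].

    Monomorphic variants are removed by default ("segregating variants");
    pass keep_monomorphic=True to retain them.
    """
    if not keep_monomorphic:
        g = _drop_monomorphic(g, "grm_similarity")
    n_var = g.n_variants
    if n_var == 0:
        raise ValueError("no variants left for the similarity GRM")
    n = g.n_samples
    acc = np.zeros((n, n))
    for start in range(0, n_var, chunk_size):
        stop = min(start + chunk_size, n_var)
        m = g.calls[:, start:stop].astype(np.float64) - 1.0
        acc += m @ m.T
    values = acc / (n_var / 2.0)
    values = (values + values.T) / 2.0
    return RelationshipMatrix(
        ids=list(g.sample_ids), values=values, method="G_sim", n_variants=n_var
    )


def genomic_inbreeding(G: RelationshipMatrix) -> pd.Series:
    """Genomic inbreeding per individual: self-relationship minus 1.

    Negative values indicate an excess of observed heterozygous genotypes
    relative to the allele-frequency expectation.
    """
    return pd.Series(
        np.diag(G.values) - 1.0, index=G.ids, name="F"
    )
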