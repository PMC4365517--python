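"""Synthetic cohorts with known ground truth.

This module generates everything the analysis needs without external data:

* founder allele-frequency spectra — uniform over the folded MAF range
  (chip-like: ascertainment makes every MAF class equally represented) or
  L-shaped with density proportional to 1/p (sequence-like: rare alleles
  dominate);
* multi-generation livestock-style pedigrees with half-sib families built
  around heavily used sires, occasional full sibs, and a final genotyped
  cohort;
* gene dropping: founder alleles are drawn from the founder frequencies and
  transmitted down the pedigree one uniformly chosen allele per parent per
  variant (unlinked loci). With founder-allele tracking on, every founder
  allele carries a unique label and the exact identity-by-descent
  relationship matrix is returned on the additive-relationship scale, so
  its expectation over replicates equals the pedigree A matrix;
* record censoring, which hides the parents of a fraction of ancestors per
  generation to emulate partial pedigree depth;
* the allele-frequency sensitivity simulation: per-variant frequencies are
  redrawn from a normal centred on the observed frequency with binomial
  sampling standard deviation sqrt(p(1-p)/(2 n)), truncated to one allele
  copy, and the frequency-weighted GRM is recomputed and correlated with
  the baseline.

Every generator takes an explicit integer seed; there is no implicit
entropy, and outputs are bit-reproducible per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .genotype_data import GenotypeMatrix
from .grm import grm_yang
from .pedigree import Pedigree, topological_order
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the structure of a sequenced key-ancestor bull cohort:
    118 genotyped individuals (78 from the final generation plus 40 of
    their sires and grandsires) bred over five generations from 40
    founders, with half-sib families of up to four offspring per sire and
    occasional full-sib matings. Pedigree-record loss is concentrated in
    the cohort's dam lines (high rate one generation back, low rates
    deeper), which leaves every cohort member with recorded parents,
    roughly half with two complete ancestral generations and roughly a
    third with four — nested depth groups like those of a real genotyped
    cohort with partial genealogy.
    """

    seed: int
    n_founders: int = 40
    n_generations: int = 5
    n_per_generation: int = 60
    cohort_size: int = 118
    n_cohort_parents: int = 40
    half_sib_family_size: int = 4
    full_sib_fraction: float = 0.05
    n_variants: int = 50_000
    spectrum: str = "l_shaped"
    maf_min: float = 0.01
    censor_rates: tuple[float, ...] = (0.05, 0.02, 0.04, 0.7, 0.0)
    track_founder_alleles: bool = False

    def __post_init__(self) -> None:
        if self.maf_min <= 0.0:
            raise ValueError("maf_min must be positive")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need >= 2 founders and >= 1 generation")
        if len(self.censor_rates) != self.n_generations:
            raise ValueError(
                "censor_rates must give one rate per generation "
                f"({self.n_generations}), got {len(self.censor_rates)}"
            )
        if not 0 <= self.n_cohort_parents < self.cohort_size:
            raise ValueError(
                "n_cohort_parents must be in [0, cohort_size)"
            )


# ---------------------------------------------------------------------------
# Frequency spectra
# ---------------------------------------------------------------------------

def draw_frequency_spectrum(
    n_variants: int,
    spectrum: str = "l_shaped",
    seed: int = 0,
    maf_min: float = 0.01,
) -> np.ndarray:
    """Per-variant founder frequencies of the coded allele.

    The minor allele frequency is drawn from the requested folded spectrum
    on [maf_min, 0.5]; the orientation of the coded allele is then
    randomised, so the coded allele is not systematically the minor one.
    """
    if not 0.0 < maf_min < 0.5:
        raise ValueError("maf_min must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    if n_variants == 0:
        return np.empty(0)
    if spectrum == "uniform":
        maf = rng.uniform(maf_min, 0.5, size=n_variants)
    elif spectrum == "l_shaped":
        # density proportional to 1/p on [maf_min, 0.5]; inverse-CDF draw
        u = rng.uniform(0.0, 1.0, size=n_variants)
        maf = maf_min * (0.5 / maf_min) ** u
    else:
        raise ValueError(f"unknown spectrum {spectrum!r}")
    flip = rng.random(n_variants) < 0.5
    return np.where(flip, 1.0 - maf, maf)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPedigree:
    """A simulated pedigree plus its bookkeeping.

    generation maps id -> generation number (founders are 0); cohort lists
    the genotyped individuals (the final generation plus any genotyped
    sires/grandsires).
    """

    pedigree: Pedigree
    generation: dict[str, int]
    sex: dict[str, str]  # "M" / "F"
    cohort: list[str]


def simulate_pedigree(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedPedigree:
    """Overlapping half-sib family pedigree, deterministic per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[tuple[str, str | None, str | None]] = []
    generation: dict[str, int] = {}
    sex: dict[str, str] = {}

    def add(iid, sire, dam, g):
        records.append((iid, sire, dam))
        generation[iid] = g
        sex[iid] = "M" if rng.random() < 0.5 else "F"

    for i in range(config.n_founders):
        add(f"F{i:03d}", None, None, 0)
    # guarantee both sexes among founders
    founder_ids = [r[0] for r in records]
    sex[founder_ids[0]] = "M"
    sex[founder_ids[1]] = "F"

    prev = founder_ids
    cohort: list[str] = []
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError(
                f"infeasible design: generation {g - 1} lacks one sex"
            )
        n_off = (
            config.cohort_size - config.n_cohort_parents
            if g == config.n_generations
            else config.n_per_generation
        )
        n_sires = max(1, int(np.ceil(n_off / config.half_sib_family_size)))
        sires = rng.choice(males, size=n_sires, replace=n_sires > len(males))
        children = []
        prev_mating: tuple[str, str] | None = None
        used_dams: set[str] = set()
        for i in range(n_off):
            sire = str(sires[min(i // config.half_sib_family_size, n_sires - 1)])
            if prev_mating is not None and prev_mating[0] != sire:
                used_dams = set()  # new half-sib family
            if (
                prev_mating is not None
                and prev_mating[0] == sire
                and rng.random() < config.full_sib_fraction
            ):
                dam = prev_mating[1]
            else:
                # prefer dams not yet mated to this sire (half sibs, not full)
                fresh = [f for f in females if f not in used_dams]
                dam = str(rng.choice(fresh if fresh else females))
            used_dams.add(dam)
            iid = f"G{g}_{i:03d}"
            add(iid, sire, dam, g)
            prev_mating = (sire, dam)
            children.append(iid)
        prev = children
        if g == config.n_generations:
            cohort = list(children)
    if config.n_cohort_parents:
        # genotype a set of the final generation's sires too (a bull cohort),
        # so the cohort spans generations and carries parent-offspring pairs
        sire_pool: list[str] = []
        seen: set[str] = set()
        rec_by_id = {r[0]: r for r in records}
        for child in cohort:
            _, s, _ = rec_by_id[child]
            if s is not None and s not in seen:
                seen.add(s)
                sire_pool.append(s)
        if len(sire_pool) >= config.n_cohort_parents:
            chosen = list(
                rng.choice(sire_pool, config.n_cohort_parents, replace=False)
            )
        else:
            chosen = list(sire_pool)
            for g_back in range(config.n_generations - 1, 0, -1):
                deficit = config.n_cohort_parents - len(chosen)
                if deficit <= 0:
                    break
                males = [
                    iid for iid, g_ in generation.items()
                    if g_ == g_back and iid not in seen
                    and iid not in cohort and sex[iid] == "M"
                ]
                take = list(
                    rng.choice(males, min(deficit, len(males)), replace=False)
                )
                chosen.extend(take)
                seen.update(take)
        cohort = [str(c) for c in chosen] + cohort
    ped = Pedigree.from_records(records)
    return SimulatedPedigree(
        pedigree=ped, generation=generation, sex=sex, cohort=cohort
    )


def censor_pedigree(
    sim: SimulatedPedigree,
    rates: tuple[float, ...],
    seed: int,
    exempt_cohort: bool = True,
) -> Pedigree:
    """Recorded pedigree with parent links hidden for a fraction of each
    generation (rates[g - 1] applies to generation g individuals).

    Emulates genealogies whose early records are incomplete: a censored
    ancestor becomes a founder in the recorded pedigree, capping the
    complete-generation depth of its descendants. Genotyped cohort members
    keep their parent records by default — a sequenced key-ancestor cohort
    has well documented immediate parentage.
    """
    rng = np.random.default_rng(seed)
    exempt = set(sim.cohort) if exempt_cohort else set()
    records = []
    for iid in sim.pedigree.ids:
        sire, dam = sim.pedigree.parents[iid]
        g = sim.generation.get(iid, 0)
        drop = g >= 1 and rng.random() < rates[g - 1]
        if drop and iid not in exempt:
            sire, dam = None, None
        records.append((iid, sire, dam))
    return Pedigree.from_records(
        [(i, s if s is not None else "0", d if d is not None else "0")
         for i, s, d in records]
    )


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact simulation truth accompanying a gene-dropped genotype matrix."""

    founder_frequencies: np.ndarray
    ibd: RelationshipMatrix
    pedigree: Pedigree


def gene_drop(
    p: Pedigree,
    frequencies: np.ndarray,
    seed: int,
    track_founder_alleles: bool = False,
    ids: list[str] | None = None,
):
    """Drop founder alleles down the pedigree at unlinked loci.

    Founder alleles are Bernoulli draws from the per-variant founder
    frequency; every non-founder inherits one uniformly chosen allele per
    parent per variant. Returns the 0/1/2 genotype matrix over ``ids``
    (default: all pedigree members, pedigree order). With
    ``track_founder_alleles`` the unique founder-allele labels are followed
    as well and a :class:`GroundTruth` carrying the exact IBD relationship
    matrix (scaled so its expectation is the additive relationship matrix)
    is returned alongside.
    """
    frequencies = np.asarray(frequencies, dtype=np.float64)
    if ((frequencies <= 0.0) | (frequencies >= 1.0)).any():
        raise ValueError("founder frequencies must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    order = topological_order(p)
    n_var = frequencies.size
    state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for iid in order:
        sire, dam = p.parents[iid]
        haps = []
        labs = []
        for par in (sire, dam):
            if par is None:
                haps.append(
                    (rng.random(n_var) < frequencies).astype(np.int8)
                )
                if track_founder_alleles:
                    labs.append(np.full(n_var, next_label, dtype=np.int32))
                    next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_var).astype(bool)
                h0, h1 = state[par]
                haps.append(np.where(pick, h1, h0))
                if track_founder_alleles:
                    l0, l1 = labels[par]
                    labs.append(np.where(pick, l1, l0))
        state[iid] = (haps[0], haps[1])
        if track_founder_alleles:
            labels[iid] = (labs[0], labs[1])
    if ids is None:
        ids = p.ids
    calls = np.empty((len(ids), n_var), dtype=np.int8)
    for row, iid in enumerate(ids):
        h0, h1 = state[iid]
        calls[row] = h0 + h1
    g = GenotypeMatrix(
        sample_ids=list(ids),
        variant_ids=[f"var{v}" for v in range(n_var)],
        calls=calls,
    )
    if not track_founder_alleles:
        return g
    ibd = _ibd_matrix(labels, ids, n_var, next_label)
    truth = GroundTruth(
        founder_frequencies=frequencies,
        ibd=RelationshipMatrix(
            ids=list(ids), values=ibd, method="IBD_true"
        ),
        pedigree=p,
    )
    return g, truth


def _ibd_matrix(labels, ids, n_var: int, n_labels: int) -> np.ndarray:
    """Pairwise IBD sharing on the additive-relationship scale.

    Per variant each individual holds two founder-allele labels; the pair
    statistic is the number of label matches among the four cross
    comparisons, divided by 2 and averaged over variants. Implemented as a
    sparse label-count inner product: each individual's two labels per
    variant form a count vector and the four-way match count is its dot
    product with the partner's.
    """
    n = len(ids)
    rows = np.repeat(np.arange(n), 2 * n_var)
    cols = np.empty(n * 2 * n_var, dtype=np.int64)
    offset = np.arange(n_var, dtype=np.int64) * n_labels
    for i, iid in enumerate(ids):
        l0, l1 = labels[iid]
        cols[i * 2 * n_var: i * 2 * n_var + n_var] = offset + l0
        cols[i * 2 * n_var + n_var: (i + 1) * 2 * n_var] = offset + l1
    data = np.ones(n * 2 * n_var, dtype=np.float64)
    D = sp.coo_matrix(
        (data, (rows, cols)), shape=(n, n_var * n_labels)
    ).tocsr()
    S = (D @ D.T).toarray()
    return S / (2.0 * n_var)


def replicate_gene_drop_means(
    p: Pedigree,
    frequencies: np.ndarray,
    n_replicates: int,
    seed: int,
    ids: list[str] | None = None,
):
    """Monte-Carlo means and standard errors of gene-dropped estimates.

    For each replicate the pedigree is gene-dropped afresh, the
    frequency-weighted GRM is computed with the TRUE founder frequencies,
    and the tracked-IBD matrix is recorded. Returns a dict with elementwise
    ``mean``/``se`` arrays for both the GRM (``yang``) and the exact IBD
    sharing (``ibd``); both estimates are unbiased for the pedigree
    additive relationship matrix.
    """
    if ids is None:
        ids = p.ids
    n = len(ids)
    sums = {k: np.zeros((n, n)) for k in ("yang", "ibd")}
    sq = {k: np.zeros((n, n)) for k in ("yang", "ibd")}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        g, truth = gene_drop(
            p, frequencies, seed=rep_seed, track_founder_alleles=True, ids=ids
        )
        G = grm_yang(g, freqs=frequencies).values
        for key, mat in (("yang", G), ("ibd", truth.ibd.values)):
            sums[key] += mat
            sq[key] += mat * mat
    out = {}
    for key in ("yang", "ibd"):
        mean = sums[key] / n_replicates
        var = (sq[key] / n_replicates - mean * mean) * (
            n_replicates / (n_replicates - 1)
        )
        out[key] = {
            "mean": mean,
            "se": np.sqrt(np.maximum(var, 0.0) / n_replicates),
        }
    out["ids"] = list(ids)
    return out


# ---------------------------------------------------------------------------
# Allele-frequency sensitivity simulation
# ---------------------------------------------------------------------------

def resample_frequencies(
    frequencies: np.ndarray,
    n_diploid: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicate frequency sets with binomial estimation noise.

    Each variant's frequency is redrawn from a normal centred on the
    observed value with sd sqrt(p (1 - p) / (2 n)), then truncated (by
    clipping) to [1 / (2n), 1 - 1 / (2n)] — at least one copy of each
    allele. Returns an (n_replicates, n_variants) array.
    """
    p = np.asarray(frequencies, dtype=np.float64)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("frequencies must be strictly inside (0, 1)")
    if n_diploid < 1:
        raise ValueError("n_diploid must be >= 1")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(p * (1.0 - p) / (2.0 * n_diploid))
    draws = rng.normal(loc=p, scale=sd, size=(n_replicates, p.size))
    bound = 1.0 / (2.0 * n_diploid)
    return np.clip(draws, bound, 1.0 - bound)


@dataclass
class FrequencySensitivityResult:
    correlations: np.ndarray
    min: float
    mean: float
    n_variants: int
    n_replicates: int


def frequency_sensitivity(
    g: GenotypeMatrix,
    n_replicates: int,
    seed: int,
    n_diploid: int | None = None,
) -> FrequencySensitivityResult:
    """Sensitivity of the frequency-weighted GRM to frequency estimation error.

    The baseline GRM uses sample-estimated frequencies; each replicate
    redraws every variant's frequency with binomial sampling noise for
    ``n_diploid`` individuals (default: the sample size), recomputes the
    GRM, and correlates all diagonal plus upper-triangle entries with the
    baseline. Returns the per-replicate correlations with their minimum
    and mean.
    """
    if n_diploid is None:
        n_diploid = g.n_samples
    p = g.calls.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        logger.info(
            "frequency_sensitivity: dropping %d monomorphic variants",
            int((~poly).sum()),
        )
        g = g.subset_variants(poly)
        p = p[poly]
    baseline = grm_yang(g, freqs=p).upper_entries(include_diagonal=True)
    freq_sets = resample_frequencies(p, n_diploid, n_replicates, seed)
    corrs = np.empty(n_replicates)
    for k in range(n_replicates):
        entries = grm_yang(g, freqs=freq_sets[k]).upper_entries(
            include_diagonal=True
        )
        corrs[k] = np.corrcoef(baseline, entries)[0, 1]
    return FrequencySensitivityResult(
        correlations=corrs,
        min=float(corrs.min()),
        mean=float(corrs.mean()),
        n_variants=g.n_variants,
        n_replicates=n_replicates,
    )
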