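"""Comparison of relationship and inbreeding estimates across data sources.

Pairs of individuals are grouped by the degree of relationship implied by
the pedigree matrix: first degree (A in [0.5, 1): parent-offspring, full
sibs), second degree (A in [0.25, 0.5): half sibs, grandparent-offspring),
and less related (A < 0.25). Self-relationships (the diagonal) feed the
inbreeding analysis rather than the pair groups. Within groups the module
computes descriptive statistics, Pearson correlations with significance
against 0 and against 1, paired Wilcoxon signed-rank comparisons between
MAF scenarios, Fisher-z comparison of two correlations, and
pedigree-depth-stratified inbreeding correlations.

A Fisher-z test directly against rho = 1 is degenerate (the transform
diverges), so "not significantly different from 1" is operationalised as
the 95% Fisher-z confidence interval reaching above 1 - epsilon for a small
configurable epsilon; every result records the method used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, depth_groups, pedigree_inbreeding
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

# Near-unity boundary for the "different from 1" flag: with r = 0.999 and
# several thousand pairs the Fisher-z CI upper bound sits near 0.9990-0.9995,
# so a 1e-3 boundary leaves such correlations unflagged while r <= 0.998 at
# the same n is flagged.
DIFF_FROM_ONE_EPSILON = 1e-3


@dataclass
class DegreeGroups:
    """Unordered off-diagonal pairs partitioned by pedigree relationship."""

    ids: list[str]
    self_pairs: np.ndarray   # (n,) diagonal indices
    first: np.ndarray        # (m, 2) index pairs, A in [0.5, 1)
    second: np.ndarray       # A in [0.25, 0.5)
    less: np.ndarray         # A in [0, 0.25)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"first": self.first, "second": self.second, "less": self.less}


def group_pairs(A: RelationshipMatrix) -> DegreeGroups:
    """Partition all unordered pairs by the pedigree relationship value.

    Off-diagonal values >= 1 (possible under strong inbreeding) are routed
    to the first-degree group with a warning, since the bins cap at < 1.
    """
    n = A.n
    iu = np.triu_indices(n, k=1)
    vals = A.values[iu]
    pairs = np.column_stack(iu)
    over = vals >= 1.0
    if over.any():
        logger.warning(
            "%d off-diagonal pedigree relationships >= 1 assigned to the "
            "first-degree group", int(over.sum()),
        )
    first = pairs[(vals >= 0.5)]
    second = pairs[(vals >= 0.25) & (vals < 0.5)]
    less = pairs[(vals < 0.25)]
    return DegreeGroups(
        ids=list(A.ids),
        self_pairs=np.arange(n),
        first=first,
        second=second,
        less=less,
    )


def describe(values: np.ndarray) -> dict[str, float]:
    """min / mean / max / variance (n - 1 denominator) of a value list."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot describe an empty value list")
    if values.size == 1:
        raise ValueError("variance undefined for a single value")
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "mean": float(values.mean()),
        "max": float(values.max()),
        "var": float(values.var(ddof=1)),
    }


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_vs_zero: float
    different_from_zero: bool
    different_from_one: bool
    method_note: str
    alpha: float = 0.05

    def flags(self) -> str:
        """Table-style superscript: 'a' different from 0, 'b' from 1."""
        parts = (["a"] if self.different_from_zero else []) + (
            ["b"] if self.different_from_one else []
        )
        return ",".join(parts)


def pearson_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    epsilon: float = DIFF_FROM_ONE_EPSILON,
) -> CorrelationResult:
    """Pearson r with significance versus 0 and versus 1.

    The test versus 0 is the usual two-sided t-test. The "different from 1"
    flag holds when the upper bound of the 95% Fisher-z confidence interval
    stays below 1 - epsilon.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired estimates must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation test")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    r, p_vs_zero = stats.pearsonr(x, y)
    r = float(r)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        upper = np.tanh(z + half)
    else:
        # perfect correlation, or too few pairs for the Fisher interval
        upper = 1.0 if r > -1.0 else -1.0
    different_from_one = bool(upper < 1.0 - epsilon)
    return CorrelationResult(
        r=r,
        n=n,
        p_vs_zero=float(p_vs_zero),
        different_from_zero=bool(p_vs_zero <= alpha),
        different_from_one=different_from_one,
        method_note=(
            "t-test vs 0; vs 1 via 95% Fisher-z CI upper bound "
            f"< 1 - {epsilon:g}"
        ),
        alpha=alpha,
    )


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    method: str


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped. The exact null distribution is used for
    up to exact_max_n non-zero pairs, the normal approximation with
    continuity correction above. All differences zero degenerates to
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        logger.warning("all paired differences are zero; p = 1")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    method = "exact" if d.size <= exact_max_n else "approx"
    res = stats.wilcoxon(
        d,
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
        zero_method="wilcox",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_nonzero=int(d.size),
        method=method,
    )


@dataclass
class CorrelationComparison:
    z: float
    p_value: float
    note: str = "independence of the two samples assumed"


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> CorrelationComparison:
    """Two-sided z-test for equality of two independent Pearson correlations."""
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError(f"degenerate correlation {r}")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(z=float(z), p_value=float(p))


def depth_correlation_table(
    F_ped: pd.Series,
    F_gen: dict[str, pd.Series],
    groups: dict[int, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pedigree-vs-genomic inbreeding correlations per pedigree-depth group.

    One row per (genomic F label, depth threshold); groups smaller than 3
    are skipped with a warning.
    """
    rows = []
    for label, fg in F_gen.items():
        for t, members in groups.items():
            if len(members) < 3:
                logger.warning(
                    "depth>=%d group has %d members (< 3); skipped", t, len(members)
                )
                continue
            try:
                res = pearson_test(
                    F_ped.loc[members].to_numpy(),
                    fg.loc[members].to_numpy(),
                    alpha=alpha,
                )
            except ValueError as exc:
                logger.warning(
                    "depth>=%d group vs %s: %s; skipped", t, label, exc
                )
                continue
            rows.append(
                {
                    "comparison": f"F_ped ~ {label}",
                    "depth": t,
                    "n": res.n,
                    "r": res.r,
                    "p_vs_zero": res.p_vs_zero,
                    "flags": res.flags(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Bundle of the analysis tables plus the group membership they trace to."""

    variant_counts: pd.DataFrame
    descriptive: pd.DataFrame
    correlations: pd.DataFrame
    wilcoxon: pd.DataFrame
    inbreeding_depth: pd.DataFrame
    groups: DegreeGroups = field(repr=False)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variant_counts.to_csv(outdir / "scenario_counts.tsv", sep="\t", index=False)
        self.descriptive.to_csv(outdir / "descriptive.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        self.wilcoxon.to_csv(outdir / "wilcoxon.tsv", sep="\t", index=False)
        self.inbreeding_depth.to_csv(
            outdir / "inbreeding_by_depth.tsv", sep="\t", index=False
        )


def scenario_report(
    a_ped: RelationshipMatrix,
    genomic: dict[str, RelationshipMatrix],
    pedigree: Pedigree,
    depth_thresholds: tuple[int, ...] = (1, 2, 4),
    alpha: float = 0.05,
) -> ComparisonReport:
    """Assemble the full cross-scenario comparison over a genotyped cohort.

    a_ped is the pedigree relationship matrix over the genotyped ids;
    genomic maps scenario labels (e.g. "G_SNP_5+") to genomic matrices over
    the same ids in the same order. Deterministic given its inputs.
    """
    ids = a_ped.ids
    for label, G in genomic.items():
        if G.ids != ids:
            offenders = sorted(set(G.ids) ^ set(ids))[:10]
            raise ValueError(
                f"id mismatch between A_ped and {label}: {offenders}"
            )
    groups = group_pairs(a_ped)
    matrices = {"A_ped": a_ped, **genomic}

    counts = pd.DataFrame(
        [
            {
                "scenario": label,
                "method": M.method,
                "n_variants": 0 if M.n_variants is None else M.n_variants,
            }
            for label, M in matrices.items()
        ]
    )

    desc_rows = []
    for label, M in matrices.items():
        for gname, pairs in groups.as_dict().items():
            if pairs.shape[0] >= 2:
                desc_rows.append(
                    {"scenario": label, "group": gname, **describe(M.pair_values(pairs))}
                )
        F = np.diag(M.values) - 1.0
        if F.size >= 2:
            desc_rows.append(
                {"scenario": label, "group": "inbreeding", **describe(F)}
            )
    descriptive = pd.DataFrame(desc_rows)

    labels = list(matrices)
    corr_rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for gname, pairs in groups.as_dict().items():
                if pairs.shape[0] < 3:
                    continue
                xa = matrices[la].pair_values(pairs)
                xb = matrices[lb].pair_values(pairs)
                if xa.var() == 0.0 or xb.var() == 0.0:
                    logger.warning(
                        "zero variance for %s ~ %s in group %s; skipped",
                        la, lb, gname,
                    )
                    continue
                res = pearson_test(xa, xb, alpha=alpha)
                corr_rows.append(
                    {
                        "comparison": f"{la} ~ {lb}",
                        "group": gname,
                        "n": res.n,
                        "r": res.r,
                        "p_vs_zero": res.p_vs_zero,
                        "flags": res.flags(),
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    # paired scenario comparisons on the pooled off-diagonal estimates
    wil_rows = []
    gen_labels = list(genomic)
    all_pairs = np.vstack([groups.first, groups.second, groups.less])
    for i, la in enumerate(gen_labels):
        for lb in gen_labels[i + 1:]:
            res = wilcoxon_signed_rank(
                genomic[la].pair_values(all_pairs),
                genomic[lb].pair_values(all_pairs),
            )
            wil_rows.append(
                {
                    "comparison": f"{la} vs {lb}",
                    "what": "relationships",
                    "n_nonzero": res.n_nonzero,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
            res_f = wilcoxon_signed_rank(
                np.diag(genomic[la].values) - 1.0,
                np.diag(genomic[lb].values) - 1.0,
            )
            wil_rows.append(
                {
                    "comparison": f"{la} vs {lb}",
                    "what": "inbreeding",
                    "n_nonzero": res_f.n_nonzero,
                    "statistic": res_f.statistic,
                    "p_value": res_f.p_value,
                    "method": res_f.method,
                }
            )
    wilcoxon = pd.DataFrame(wil_rows)

    F_ped_all = pedigree_inbreeding(pedigree)
    F_ped = F_ped_all.loc[ids]
    F_gen = {
        label: pd.Series(np.diag(G.values) - 1.0, index=ids, name="F")
        for label, G in genomic.items()
    }
    dgroups = depth_groups(pedigree, ids, depth_thresholds)
    inbreeding_depth = depth_correlation_table(F_ped, F_gen, dgroups, alpha=alpha)

    return ComparisonReport(
        variant_counts=counts,
        descriptive=descriptive,
        correlations=correlations,
        wilcoxon=wilcoxon,
        inbreeding_depth=inbreeding_depth,
        groups=groups,
    )
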