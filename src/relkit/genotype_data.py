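"""Genotype matrices: loading, validation, allele-frequency summaries and MAF filtering.

Genotypes are diploid biallelic calls coded 0/1/2 as the count of the
"coded" allele (for VCF input, the ALT allele). A :class:`GenotypeMatrix`
holds an individuals-by-variants integer matrix together with sample and
variant identifiers and optional per-variant metadata (chromosome,
position, SNP/INDEL class).

MAF-restriction scenarios are half-open intervals ``[maf_low, maf_high)``
on the minor allele frequency, with the top of the folded spectrum
(maf = 0.5) always included when ``maf_high == 0.5``. Under this convention
the named scenarios satisfy an exact partition: the variants kept under
``1+`` (MAF >= 1%) are the disjoint union of those kept under ``5+``
(MAF >= 5%) and ``1_5`` (1% <= MAF < 5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_CALLS = frozenset({0, 1, 2})
MISSING = -1  # internal sentinel during loading only

#: Named MAF-restriction scenarios: name -> (maf_low, maf_high).
NAMED_SCENARIOS: dict[str, tuple[float, float]] = {
    "5+": (0.05, 0.5),
    "1+": (0.01, 0.5),
    "1_5": (0.01, 0.05),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A MAF interval defining variant inclusion, ``maf_low <= maf < maf_high``.

    ``maf_high == 0.5`` is treated as an inclusive top so that the folded
    spectrum's maximum is never silently excluded. Monomorphic variants
    (maf == 0) never pass any scenario.
    """

    name: str
    maf_low: float
    maf_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_low < self.maf_high <= 0.5):
            raise ValueError(
                f"invalid MAF interval [{self.maf_low}, {self.maf_high}): "
                "need 0 <= maf_low < maf_high <= 0.5"
            )

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        try:
            low, high = NAMED_SCENARIOS[name]
        except KeyError:
            raise KeyError(
                f"unknown scenario {name!r}; known: {sorted(NAMED_SCENARIOS)}"
            ) from None
        return cls(name, low, high)

    def contains(self, maf: np.ndarray | float) -> np.ndarray | bool:
        maf = np.asarray(maf)
        inside = (maf >= self.maf_low) & (maf < self.maf_high)
        if self.maf_high == 0.5:
            inside |= maf == 0.5
        return (inside & (maf > 0.0)) if inside.ndim else bool(inside and maf > 0.0)


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele-count matrix with identifiers.

    ``calls[i, v]`` is the number of copies (0/1/2) of the coded allele
    carried by sample ``i`` at variant ``v``.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    calls: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    variant_class: np.ndarray | None = None  # "SNP" or "INDEL"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x variants array")
        if self.calls.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if not np.issubdtype(self.calls.dtype, np.integer):
            if not np.all(np.mod(self.calls, 1) == 0):
                raise ValueError("calls must be integers in {0, 1, 2}")
            self.calls = self.calls.astype(np.int8)
        bad = ~np.isin(self.calls, (0, 1, 2))
        if bad.any():
            i, v = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, v]} for sample "
                f"{self.sample_ids[i]!r} at variant {self.variant_ids[v]!r}; "
                "calls must be in {0, 1, 2}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the variants selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[i] for i in index],
            calls=self.calls[:, index],
            chrom=None if self.chrom is None else self.chrom[index],
            pos=None if self.pos is None else self.pos[index],
            variant_class=None
            if self.variant_class is None
            else self.variant_class[index],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            calls=self.calls[idx, :],
            chrom=self.chrom,
            pos=self.pos,
            variant_class=self.variant_class,
        )


@dataclass
class VariantStats:
    """Per-variant frequency summaries.

    p:    frequency of the coded allele (mean call / 2)
    maf:  min(p, 1 - p)
    mac:  minor-allele copy count, round(2 * n_obs * maf)
    """

    p: np.ndarray
    maf: np.ndarray
    mac: np.ndarray
    n_obs: int


def variant_stats(g: GenotypeMatrix) -> VariantStats:
    if g.n_samples == 0 or g.n_variants == 0:
        raise ValueError("cannot compute variant statistics on an empty matrix")
    p = g.calls.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    counts = g.calls.sum(axis=0)
    mac = np.minimum(counts, 2 * g.n_samples - counts).astype(np.int64)
    return VariantStats(p=p, maf=maf, mac=mac, n_obs=g.n_samples)


def maf_mask(g: GenotypeMatrix, spec: ScenarioSpec) -> np.ndarray:
    """Boolean mask of variants passing a MAF scenario."""
    return np.asarray(spec.contains(variant_stats(g).maf))


def apply_maf_scenario(g: GenotypeMatrix, spec: ScenarioSpec) -> GenotypeMatrix:
    """Keep exactly the variants whose MAF falls in the scenario interval.

    Monomorphic variants never pass. Kept/removed counts are logged; an
    empty result is a warning, not an error.
    """
    mask = maf_mask(g, spec)
    kept = int(mask.sum())
    logger.info(
        "scenario %s: kept %d of %d variants (removed %d)",
        spec.name, kept, g.n_variants, g.n_variants - kept,
    )
    if kept == 0:
        logger.warning("scenario %s removed every variant", spec.name)
    return g.subset_variants(mask)


def subset_chip(g: GenotypeMatrix, variant_ids) -> GenotypeMatrix:
    """Restrict to a chip-style id list (set semantics; original order kept).

    Ids in the list but absent from the matrix are reported via a warning,
    mirroring how a fixed commercial-chip manifest intersects a sequenced
    variant set.
    """
    wanted = set(variant_ids)
    mask = np.fromiter(
        (v in wanted for v in g.variant_ids), dtype=bool, count=g.n_variants
    )
    found = {g.variant_ids[i] for i in np.flatnonzero(mask)}
    not_found = wanted - found
    if not_found:
        logger.warning(
            "%d chip ids not present in the genotype matrix (e.g. %s)",
            len(not_found), sorted(not_found)[:5],
        )
    if not wanted:
        logger.warning("empty chip id list: result has no variants")
    return g.subset_variants(mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MATRIX_META_COLS = ("chrom", "pos", "class")


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    missing_policy: str = "fail",
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a plain TSV matrix.

    Parameters
    ----------
    path:
        Input file. ``.vcf``/``.vcf.gz`` are read as VCF, anything else as
        the plain matrix format (header of sample ids, first column variant
        id, optional chrom/pos/class columns, cells 0/1/2 or '.').
    format:
        Force ``"vcf"`` or ``"matrix"`` instead of inferring from the suffix.
    missing_policy:
        ``"fail"`` (default) raises on any missing call, ``"drop_variant"``
        removes variants with missing calls, ``"mean_impute"`` fills with the
        variant mean rounded to the nearest integer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if missing_policy not in ("fail", "drop_variant", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if format is None:
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "matrix"
    if format == "vcf":
        raw = _read_vcf(path)
    elif format == "matrix":
        raw = _read_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _resolve_missing(raw, missing_policy)


def _resolve_missing(g: "_RawMatrix", policy: str) -> GenotypeMatrix:
    calls = g.calls
    miss = calls == MISSING
    if miss.any():
        miss_variants = miss.any(axis=0)
        if policy == "fail":
            v = int(np.flatnonzero(miss_variants)[0])
            raise ValueError(
                f"missing genotype at variant {g.variant_ids[v]!r} "
                "(missing_policy='fail')"
            )
        if policy == "drop_variant":
            n_drop = int(miss_variants.sum())
            logger.warning("dropping %d variants with missing calls", n_drop)
            keep = ~miss_variants
            return _raw_to_matrix(g, keep)._replace_calls_checked()
        # mean_impute: round the mean of the observed calls
        calls = calls.astype(np.float64)
        calls[miss] = np.nan
        col_mean = np.nanmean(calls, axis=0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        idx = np.argwhere(miss)
        calls[miss] = fill[idx[:, 1]]
        g.calls = calls.astype(np.int8)
        logger.info("mean-imputed %d missing calls", int(miss.sum()))
    return GenotypeMatrix(
        sample_ids=g.sample_ids,
        variant_ids=g.variant_ids,
        calls=g.calls.astype(np.int8),
        chrom=g.chrom,
        pos=g.pos,
        variant_class=g.variant_class,
    )


@dataclass
class _RawMatrix:
    sample_ids: list[str]
    variant_ids: list[str]
    calls: np.ndarray  # may contain MISSING
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    variant_class: np.ndarray | None = None


def _raw_to_matrix(g: _RawMatrix, keep: np.ndarray) -> "_Kept":
    idx = np.flatnonzero(keep)
    return _Kept(
        _RawMatrix(
            g.sample_ids,
            [g.variant_ids[i] for i in idx],
            g.calls[:, idx],
            None if g.chrom is None else g.chrom[idx],
            None if g.pos is None else g.pos[idx],
            None if g.variant_class is None else g.variant_class[idx],
        )
    )


@dataclass
class _Kept:
    raw: _RawMatrix

    def _replace_calls_checked(self) -> GenotypeMatrix:
        r = self.raw
        return GenotypeMatrix(
            r.sample_ids, r.variant_ids, r.calls.astype(np.int8),
            r.chrom, r.pos, r.variant_class,
        )


def _read_vcf(path: Path) -> _RawMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    vclass: list[str] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            logger.warning(
                "skipping non-biallelic record %s:%d (%d ALT alleles)",
                rec.CHROM, rec.POS, len(rec.ALT),
            )
            continue
        # with gts012=True: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        is_snp = len(rec.REF) == 1 and len(rec.ALT[0]) == 1
        vclass.append("SNP" if is_snp else "INDEL")
    if n_multi:
        logger.warning("skipped %d non-biallelic records in %s", n_multi, path)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return _RawMatrix(
        sample_ids, variant_ids, calls,
        np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64),
        np.asarray(vclass, dtype=object),
    )


def _read_matrix(path: Path) -> _RawMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"malformed matrix file {path}: need id column + samples")
    id_col = df.columns[0]
    meta_cols = [c for c in df.columns[1:] if c.lower() in _MATRIX_META_COLS]
    sample_cols = [c for c in df.columns[1:] if c not in meta_cols]
    variant_ids = df[id_col].tolist()
    cells = df[sample_cols].to_numpy()
    calls = np.empty(cells.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(cells):
        s = str(cell).strip()
        if s in (".", "", "nan"):
            calls[i, j] = MISSING
        else:
            try:
                value = int(s)
            except ValueError:
                raise ValueError(
                    f"malformed cell {cell!r} at line {i + 2} of {path}"
                ) from None
            if value not in _VALID_CALLS:
                raise ValueError(
                    f"invalid call {value} at line {i + 2} of {path}; "
                    "calls must be 0, 1, 2 or '.'"
                )
            calls[i, j] = value
    lower = {c.lower(): c for c in meta_cols}
    chrom = df[lower["chrom"]].to_numpy(dtype=object) if "chrom" in lower else None
    pos = (
        df[lower["pos"]].astype(np.int64).to_numpy() if "pos" in lower else None
    )
    vclass = df[lower["class"]].to_numpy(dtype=object) if "class" in lower else None
    return _RawMatrix(sample_cols, variant_ids, calls.T, chrom, pos, vclass)


def write_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the plain TSV matrix format (inverse of ``read_genotypes``)."""
    path = Path(path)
    data: dict[str, object] = {"variant_id": g.variant_ids}
    if g.chrom is not None:
        data["chrom"] = g.chrom
    if g.pos is not None:
        data["pos"] = g.pos
    if g.variant_class is not None:
        data["class"] = g.variant_class
    for i, s in enumerate(g.sample_ids):
        data[s] = g.calls[i, :]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
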