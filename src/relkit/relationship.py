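"""Shared container for pairwise relationship estimates.

Both the pedigree-expected additive relationship matrix (A) and the
marker-based genomic relationship matrices (G) are square symmetric
matrices over an ordered id list; this module holds the common container
plus helpers for extracting pair values and writing the square and
long-format TSV layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_SYM_TOL = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric per-pair relationship estimates tagged by method/scenario.

    method is one of "A_ped", "G_yang", "G_sim"; scenario names the MAF
    restriction the matrix was computed under (None for pedigree).
    n_variants records how many variants entered a genomic estimate.
    """

    ids: list[str]
    values: np.ndarray
    method: str
    scenario: str | None = None
    n_variants: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if n and not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        return np.asarray([pos[s] for s in ids], dtype=np.intp)

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            method=self.method,
            scenario=self.scenario,
            n_variants=self.n_variants,
        )

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.ids, name="self")

    def upper_entries(self, include_diagonal: bool = True) -> np.ndarray:
        """Diagonal-plus-upper-triangle (or strictly upper) entries, row order."""
        iu = np.triu_indices(self.n, k=0 if include_diagonal else 1)
        return self.values[iu]

    def pair_values(self, pairs: np.ndarray) -> np.ndarray:
        """Values at an (m, 2) array of index pairs."""
        pairs = np.asarray(pairs)
        if pairs.size == 0:
            return np.empty(0)
        return self.values[pairs[:, 0], pairs[:, 1]]

    # -- output ------------------------------------------------------------

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            Path(path), sep="\t", index_label="id"
        )

    def to_long_tsv(self, path: str | Path) -> None:
        iu = np.triu_indices(self.n)
        pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu[0]],
                "id2": [self.ids[j] for j in iu[1]],
                "value": self.values[iu],
            }
        ).to_csv(Path(path), sep="\t", index=False)


def read_square_tsv(
    path: str | Path, method: str = "A_ped", scenario: str | None = None
) -> RelationshipMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return RelationshipMatrix(
        ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=np.float64),
        method=method,
        scenario=scenario,
    )
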