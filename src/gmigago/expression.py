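"""Expression-matrix input and preprocessing.

Covers the steps that precede module detection: loading a genes × samples
table, converting raw read counts to FPKM, removing genes with too many
zero-expression samples, and selecting differentially expressed genes by
fold change plus a two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "load_gene_lengths",
    "counts_to_fpkm",
    "filter_low_expression",
    "select_degs",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes × samples expression values.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float array of shape ``(len(gene_ids), len(sample_ids))``,
        finite and nonnegative.
    units : free-form units tag, typically ``"counts"`` or ``"fpkm"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    units: str = "fpkm"
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} identifier: {x!r}")
                seen.add(x)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, units: str = "fpkm") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), units)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx], self.units)


def load_expression(path, units: str = "fpkm") -> ExpressionMatrix:
    """Read a delimited genes × samples table (tab or comma, auto-detected).

    First column holds gene IDs, header row holds sample IDs. Duplicate
    gene IDs, non-numeric cells and negative values are hard errors.
    """
    raw = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene ID in {path}: {dup[0]!r}")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise ValueError(f"missing expression value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    arr = numeric.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative expression value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(list(raw.index), list(raw.columns), arr, units)


def load_gene_lengths(path) -> dict[str, float]:
    """Read a two-column (gene_id, length_bp) table, tab or comma delimited."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("gene-length table must have two columns: gene_id, length_bp")
    return {str(g): float(l) for g, l in zip(df.iloc[:, 0], df.iloc[:, 1])}


def counts_to_fpkm(counts: ExpressionMatrix, gene_lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Convert raw read counts to FPKM.

    FPKM(g, s) = counts(g, s) · 1e9 / (length_bp(g) · total_counts(s)).
    """
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if (lengths <= 0).any():
        bad = [g for g, l in zip(counts.gene_ids, lengths) if l <= 0]
        raise ValueError(f"non-positive gene length for: {bad}")
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(counts.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero total counts in samples: {bad}")
    fpkm = counts.values * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), fpkm, units="fpkm")


def filter_low_expression(
    X: ExpressionMatrix, max_zero_fraction: float = 0.2
) -> ExpressionMatrix:
    """Drop genes whose fraction of zero-valued samples exceeds the cutoff.

    A gene at exactly the cutoff is kept (only genes with *more* zeros than
    the allowed fraction are removed). Gene order is preserved.
    """
    if not 0 <= max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    zero_frac = (X.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        warnings.warn("filter_low_expression removed every gene", stacklevel=2)
    kept_ids = [g for g, k in zip(X.gene_ids, keep) if k]
    return ExpressionMatrix(kept_ids, list(X.sample_ids), X.values[keep], X.units)


def select_degs(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    x: float,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[str]:
    """Differentially expressed genes by fold change and two-sided t-test.

    A gene is selected when mean(case)/mean(control) ≥ x or ≤ 1/x and the
    two-sample t-test p-value is below ``alpha``. Fold change is the ratio
    of arithmetic means of the raw expression values (no pseudocount, no
    log). A zero control mean with a nonzero case mean counts as infinite
    fold change (passes the ≥ x arm); genes with both means zero are
    excluded.
    """
    if x < 1:
        raise ValueError("fold-change cutoff x must be >= 1")
    if set(case.gene_ids) != set(control.gene_ids):
        raise ValueError("case and control must share the same gene set")
    control = control.subset_genes(case.gene_ids)

    case_mean = case.values.mean(axis=1)
    ctrl_mean = control.values.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case.values, control.values, axis=1, equal_var=equal_var)

    selected: list[str] = []
    for i, g in enumerate(case.gene_ids):
        if ctrl_mean[i] == 0:
            if case_mean[i] == 0:
                logger.debug("gene %s excluded: zero mean in both groups", g)
                continue
            fc = np.inf
            logger.debug("gene %s: zero control mean, fold change treated as +inf", g)
        else:
            fc = case_mean[i] / ctrl_mean[i]
        if (fc >= x or fc <= 1.0 / x) and np.isfinite(p[i]) and p[i] < alpha:
            selected.append(g)
    return selected
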