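"""Co-expression screening of candidate genes across RPKM profiles.

A candidate accessory-subunit gene is screened by correlating its
expression profile with a reference gene (the channel gene) across a
tissue panel and a developmental series.  Correlations are Pearson r on
``log10(RPKM + offset)`` profiles; the 8-level equal-width binning used
for plotting is provided separately and, optionally, as an alternative
correlation substrate for sensitivity checks.  Candidates are ranked by
the mean of their tissue and developmental correlations with the
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CorrelationReport",
    "RankedCandidate",
    "load_rpkm_table",
    "log_transform",
    "bin_expression",
    "pairwise_correlation",
    "rank_candidates",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample non-negative RPKM values.

    ``dataset_kind`` records which profile family the samples come from
    ("tissue" for a dissected-tissue panel, "developmental" for a staged
    whole-animal series).
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    dataset_kind: str

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError(f"duplicate gene ids: {sorted(v.index[v.index.duplicated()])}")
        if v.columns.duplicated().any():
            raise ValueError(f"duplicate sample labels: {sorted(v.columns[v.columns.duplicated()])}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"missing value for gene {v.index[g]!r}, sample {v.columns[s]!r}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative RPKM {arr[g, s]} for gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def load_rpkm_table(path: str | Path, dataset_kind: str = "tissue") -> ExpressionMatrix:
    """Read a tab-separated gene x sample RPKM table.

    First column = gene id, header row = sample labels.  Negative,
    missing, non-numeric values and duplicate labels are rejected with
    the offending cell named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample labels in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from None
    return ExpressionMatrix(values=df, dataset_kind=dataset_kind)


def log_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> pd.DataFrame:
    """``log10(RPKM + offset)`` profiles, shape-preserving."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    return np.log10(matrix.values + offset)


def bin_expression(
    values: np.ndarray | pd.DataFrame, n_bins: int = 8, offset: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Classify expression values into equal-width log10 bins (1..n_bins).

    Bin edges partition the dataset-wide log10 range into ``n_bins``
    equal widths; the top edge is inclusive so the maximum lands in the
    last bin.  A constant dataset degenerates to all bin 1 with a
    warning.  Returns ``(bin indices, edges)``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = np.log10(np.asarray(values, dtype=float) + offset)
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        warnings.warn("all expression values identical; assigning every value to bin 1", stacklevel=2)
        edges = np.linspace(lo, lo + 1.0, n_bins + 1)
        return np.ones(arr.shape, dtype=int), edges
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(arr, edges[1:-1], right=False) + 1  # 1..n_bins, top edge inclusive
    return idx, edges


@dataclass(frozen=True)
class CorrelationReport:
    """Symmetric Pearson r matrix for a gene set on one dataset.

    Zero-variance (degenerate) genes are listed explicitly and their r
    entries are NaN markers — undefined, not silently dropped.
    """

    r: pd.DataFrame
    dataset_kind: str
    n_samples: int
    degenerate: tuple[str, ...]

    def pair(self, a: str, b: str) -> float:
        return float(self.r.loc[a, b])


def pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    offset: float = 1.0,
    use_bins: bool = False,
    n_bins: int = 8,
) -> CorrelationReport:
    """Pearson correlations between gene profiles.

    Profiles are ``log10(RPKM + offset)`` by default; ``use_bins=True``
    correlates the 8-level binned values instead (sensitivity check).
    Requires >= 3 samples.  Zero-variance genes are flagged as
    degenerate; their correlations are undefined (NaN) and the diagonal
    is 1 only for non-degenerate genes.
    """
    if genes is None:
        genes = matrix.gene_ids
    unknown = [g for g in genes if g not in matrix.values.index]
    if unknown:
        raise ValueError(f"genes not in matrix: {unknown}")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    prof = log_transform(matrix, offset=offset).loc[list(genes)]
    if use_bins:
        idx, _ = bin_expression(matrix.values.loc[list(genes)], n_bins=n_bins, offset=offset)
        prof = pd.DataFrame(idx.astype(float), index=list(genes), columns=matrix.sample_ids)
    arr = prof.to_numpy()
    # exact constancy check (std of identical floats can be a nonzero ulp)
    spread = arr.max(axis=1) - arr.min(axis=1)
    degenerate = tuple(g for g, s in zip(genes, spread) if s == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.asarray(r, dtype=float)
    for i, g in enumerate(genes):
        if g in degenerate:
            r[i, :] = np.nan
            r[:, i] = np.nan
        else:
            r[i, i] = 1.0
    rdf = pd.DataFrame(r, index=list(genes), columns=list(genes))
    return CorrelationReport(
        r=rdf, dataset_kind=matrix.dataset_kind, n_samples=matrix.n_samples, degenerate=degenerate
    )


@dataclass(frozen=True)
class RankedCandidate:
    gene: str
    mean_r: float
    per_dataset_r: dict[str, float]

    def to_dict(self) -> dict:
        return {"gene": self.gene, "mean_r": self.mean_r, "per_dataset_r": self.per_dataset_r}


def rank_candidates(
    reports: CorrelationReport | Sequence[CorrelationReport], reference_gene: str
) -> list[RankedCandidate]:
    """Rank candidate genes by mean correlation with the reference.

    Candidates are every non-reference gene present in all reports,
    sorted by the mean of their per-dataset r with the reference
    (descending), ties broken lexicographically by gene id.  Degenerate
    candidates are excluded from the ranking (their r is undefined); a
    degenerate reference is an error.
    """
    if isinstance(reports, CorrelationReport):
        reports = [reports]
    if not reports:
        raise ValueError("no correlation reports given")
    for rep in reports:
        if reference_gene not in rep.r.index:
            raise ValueError(f"reference gene {reference_gene!r} not in {rep.dataset_kind} report")
        if reference_gene in rep.degenerate:
            raise ValueError(f"reference gene {reference_gene!r} is degenerate (zero variance)")
    common = set(reports[0].r.index)
    for rep in reports[1:]:
        common &= set(rep.r.index)
    ranked = []
    for gene in sorted(common - {reference_gene}):
        per = {rep.dataset_kind: rep.pair(reference_gene, gene) for rep in reports}
        if any(np.isnan(v) for v in per.values()):
            continue  # degenerate candidate: correlation undefined
        ranked.append(RankedCandidate(gene=gene, mean_r=float(np.mean(list(per.values()))), per_dataset_r=per))
    ranked.sort(key=lambda c: (-c.mean_r, c.gene))
    return ranked
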