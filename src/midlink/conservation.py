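"""Alignment conservation profiling and cysteine-motif tracking.

Works on consumed multiple sequence alignments (aligned FASTA over the
20-amino-acid alphabet plus 'X' and the gap '-').  Columns that are
majority-gapped are stripped first; each retained column gets an
entropy-based conservation score

    score = 1 - H / ln(20)

where H is the Shannon entropy of the column's amino-acid frequencies
(gaps and 'X' are treated as missing observations).  Anchored motif
positions — e.g. the essential cysteines of the C1/C2 cysteine-rich
region — are specified in ungapped reference coordinates and mapped
through the reference row's gaps to alignment columns.  Whether a region
(such as the cysteine-rich domain) is more conserved than the rest of
the protein is tested by permuting column labels.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .stats import permutation_p

__all__ = [
    "AMINO_ACIDS",
    "Msa",
    "MotifSpec",
    "ConservationProfile",
    "MotifConservation",
    "RegionTestResult",
    "read_alignment",
    "strip_gapped_columns",
    "conservation_scores",
    "conservation_profile",
    "map_reference_positions",
    "motif_conservation",
    "region_vs_rest_test",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {"X", GAP}


@dataclass(frozen=True)
class Msa:
    """An alignment: equal-length rows over amino acids + 'X' + gap."""

    seq_ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows differ in length")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            bad = [sid for sid, r in zip(self.seq_ids, self.rows) if len(r) != len(self.rows[0])]
            raise ValueError(f"ragged alignment; offending ids: {bad}")
        for sid, row in zip(self.seq_ids, self.rows):
            illegal = set(row) - ALPHABET
            if illegal:
                raise ValueError(f"illegal characters {sorted(illegal)} in sequence {sid!r}")
        if self.reference_id not in self.seq_ids:
            raise ValueError(f"reference {self.reference_id!r} not among sequence ids")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def reference_row(self) -> str:
        return self.rows[self.seq_ids.index(self.reference_id)]

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])


@dataclass(frozen=True)
class MotifSpec:
    """Anchored motif positions in ungapped reference coordinates (1-based)."""

    reference_id: str
    positions: tuple[int, ...]
    expected_residue: str = "C"

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based; must be >= 1")
        if self.expected_residue not in set(AMINO_ACIDS):
            # 'X' is coverage, never an expected residue
            raise ValueError(f"expected residue must be one of the 20 amino acids, not {self.expected_residue!r}")


def read_alignment(path: str | Path, reference_id: str | None = None) -> Msa:
    """Read an aligned FASTA file; lowercase residues are upcased.

    ``reference_id`` defaults to the first sequence.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    return Msa(seq_ids=ids, rows=rows, reference_id=reference_id or ids[0])


def strip_gapped_columns(msa: Msa, max_gap_fraction: float = 0.5) -> tuple[Msa, np.ndarray]:
    """Remove majority-gapped columns.

    A column is removed iff its gap fraction is *strictly greater* than
    ``max_gap_fraction`` (exactly half gapped is retained).  Returns the
    filtered alignment and the 1-based map from retained to original
    column indices.
    """
    if not 0.0 <= max_gap_fraction < 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1)")
    arr = msa.to_array()
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("every column is majority-gapped; nothing left to analyze")
    column_map = np.flatnonzero(keep) + 1
    kept = arr[:, keep]
    rows = tuple("".join(r) for r in kept)
    return Msa(seq_ids=msa.seq_ids, rows=rows, reference_id=msa.reference_id), column_map


@dataclass(frozen=True)
class ConservationProfile:
    """Per-retained-column conservation scores in [0, 1]."""

    scores: np.ndarray
    column_map: np.ndarray  # 1-based original column per retained column
    gap_threshold: float
    empty_columns: np.ndarray  # True where the column had no scorable residues

    def to_records(self) -> list[dict]:
        return [
            {"retained_index": i + 1, "original_column": int(c), "score": float(s)}
            for i, (c, s) in enumerate(zip(self.column_map, self.scores))
        ]


def conservation_scores(
    msa: Msa, column_map: np.ndarray | None = None, gap_threshold: float = 0.5
) -> ConservationProfile:
    """Entropy-based conservation score per column.

    ``score = 1 - H/ln(20)`` with H the Shannon entropy of the column's
    amino-acid frequencies.  Gaps and 'X' are missing observations and
    excluded from the frequencies; a column with no scorable residues
    scores 0 and is flagged.  Scores are clipped to [0, 1] (a column
    dominated by one residue scores 1; a uniform column scores 0).
    """
    if msa.n_seqs < 2:
        raise ValueError("conservation needs at least 2 sequences")
    arr = msa.to_array()
    L = msa.length
    scores = np.zeros(L)
    empty = np.zeros(L, dtype=bool)
    ln20 = np.log(20.0)
    for j in range(L):
        col = arr[:, j]
        residues = col[(col != GAP) & (col != "X")]
        if residues.size == 0:
            empty[j] = True
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        H = float(-(p * np.log(p)).sum())
        scores[j] = np.clip(1.0 - H / ln20, 0.0, 1.0)
    cmap = np.arange(1, L + 1) if column_map is None else np.asarray(column_map)
    return ConservationProfile(
        scores=scores, column_map=cmap, gap_threshold=gap_threshold, empty_columns=empty
    )


def conservation_profile(msa: Msa, max_gap_fraction: float = 0.5) -> ConservationProfile:
    """Convenience: strip majority-gapped columns, then score the rest."""
    stripped, cmap = strip_gapped_columns(msa, max_gap_fraction)
    return conservation_scores(stripped, column_map=cmap, gap_threshold=max_gap_fraction)


@dataclass(frozen=True)
class MotifConservation:
    position: int  # ungapped reference coordinate (1-based)
    column: int  # alignment column (1-based)
    fraction: float  # fraction of sequences with the expected residue

    def to_dict(self) -> dict:
        return {"position": self.position, "column": self.column, "fraction": self.fraction}


def map_reference_positions(msa: Msa, reference_id: str, positions: Sequence[int]) -> list[int]:
    """Map 1-based ungapped reference positions to 1-based alignment columns."""
    ref = msa.rows[msa.seq_ids.index(reference_id)]
    ungapped_to_col = [i + 1 for i, ch in enumerate(ref) if ch != GAP]
    out = []
    for p in positions:
        if p > len(ungapped_to_col):
            raise ValueError(
                f"position {p} beyond the ungapped reference length {len(ungapped_to_col)}"
            )
        out.append(ungapped_to_col[p - 1])
    return out


def motif_conservation(msa: Msa, spec: MotifSpec) -> list[MotifConservation]:
    """Conserved fraction of the expected residue at each anchored position.

    Each ungapped reference position is mapped through the reference
    row's gaps to its alignment column; the fraction counts sequences
    (including the reference) carrying the expected residue there.  Gaps
    and 'X' count as not conserved.
    """
    if spec.reference_id not in msa.seq_ids:
        raise ValueError(f"reference {spec.reference_id!r} not in alignment")
    cols = map_reference_positions(msa, spec.reference_id, spec.positions)
    arr = msa.to_array()
    out = []
    for pos, col in zip(spec.positions, cols):
        frac = float((arr[:, col - 1] == spec.expected_residue).mean())
        out.append(MotifConservation(position=pos, column=col, fraction=frac))
    return out


@dataclass(frozen=True)
class RegionTestResult:
    observed_diff: float  # mean(region scores) - mean(rest)
    p_value: float
    n_perm: int
    region_size: int

    def to_dict(self) -> dict:
        return {
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "region_size": self.region_size,
        }


def region_vs_rest_test(
    profile: ConservationProfile,
    region_columns: Sequence[int],
    n_perm: int = 999,
    seed: int = 0,
) -> RegionTestResult:
    """Is a region more conserved than the rest of the protein?

    ``region_columns`` are 1-based indices into the retained profile
    (a nonempty proper subset of its columns).  The statistic is
    ``mean(region scores) - mean(non-region scores)``; the null is built
    by permuting column labels, and the one-sided add-one p-value is
    ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    scores = profile.scores
    L = scores.size
    region = np.zeros(L, dtype=bool)
    idx = np.asarray(region_columns, dtype=int)
    if idx.size == 0:
        raise ValueError("region_columns is empty")
    if idx.min() < 1 or idx.max() > L:
        raise ValueError("region_columns out of range of the retained profile")
    region[idx - 1] = True
    k = int(region.sum())
    if k == L:
        raise ValueError("region covers every column; nothing to compare against")
    observed = float(scores[region].mean() - scores[~region].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(L)[:k]
        mask = np.zeros(L, dtype=bool)
        mask[perm] = True
        null[b] = scores[mask].mean() - scores[~mask].mean()
    p = permutation_p(observed, null, alternative="greater")
    return RegionTestResult(observed_diff=observed, p_value=p, n_perm=n_perm, region_size=k)
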